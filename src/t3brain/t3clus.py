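"""Supervised Tucker3 clustering (T3Clus).

The Tucker3 model writes the matricized three-way array as

    X_(I x JK) = U Y_(G x QR) (C kron B)^T + E

with U an I x G binary indicator of class membership, B (J x Q) and C
(K x R) column-wise orthonormal loading matrices for regions and metrics,
and Y the class-centroid core.  T3Clus minimizes ||X - U Y (C kron B)^T||^2.
In the supervised variant used here U is fixed by the known condition
labels, so the problem reduces to a Tucker2-type decomposition of the
weighted class-mean tensor W = (U^T U)^(-1/2) U^T X reshaped to G x J x K:
minimizing the loss is equivalent to maximizing ||W x_2 B^T x_3 C^T||^2.
The solver is higher-order orthogonal iteration (HOOI) with an HOSVD
initialization, which is deterministic and needs no random restarts at
these problem sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_tensor import FeatureTensor, matricize


@dataclass
class TuckerConfig:
    """Model orders and solver settings.

    G: number of classes (2 = rest/meditation); Q: region components;
    R: metric components; tol: relative loss-change convergence threshold;
    max_iter: HOOI iteration cap.
    """

    G: int = 2
    Q: int = 2
    R: int = 1
    tol: float = 1e-9
    max_iter: int = 500

    def validate(self, J: int, K: int) -> None:
        if not (1 <= self.Q <= J):
            raise ValueError(f"Q must be in [1, J={J}], got {self.Q}")
        if not (1 <= self.R <= K):
            raise ValueError(f"R must be in [1, K={K}], got {self.R}")
        if self.G < 1:
            raise ValueError("G must be >= 1")


@dataclass
class TuckerResult:
    """Fitted supervised Tucker3 model."""

    B: np.ndarray  # J x Q region loadings, columns orthonormal
    C: np.ndarray  # K x R metric loadings, columns orthonormal
    Y: np.ndarray  # G x Q x R centroid core
    loss: float
    n_iter: int
    converged: bool
    config: TuckerConfig = field(default_factory=TuckerConfig)


@dataclass
class ScoreMatrix:
    """Component scores: raw per-observation projections X (C kron B) and
    the centroid scores U (U^T U)^(-1) U^T X (C kron B), which are constant
    within each class."""

    raw_scores: np.ndarray
    centroid_scores: np.ndarray


def build_indicator(labels, G: int = 2) -> np.ndarray:
    """Binary row-stochastic I x G indicator from class labels.

    Classes are numbered in order of first appearance in ``labels``.
    """
    classes: list = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    if len(classes) != G:
        raise ValueError(f"found {len(classes)} class(es) {classes}, expected G={G}")
    U = np.zeros((len(labels), G))
    for i, lab in enumerate(labels):
        U[i, classes.index(lab)] = 1.0
    return U


def _leading_left_singular(M: np.ndarray, r: int) -> np.ndarray:
    return np.linalg.svd(M, full_matrices=False)[0][:, :r]


def _fit_arrays(
    X_mat: np.ndarray, U: np.ndarray, J: int, K: int, config: TuckerConfig
) -> TuckerResult:
    """HOOI core of :func:`fit`, operating on the matricized array."""
    I = X_mat.shape[0]
    if X_mat.shape[1] != J * K:
        raise ValueError("X_mat column count must be J*K")
    if U.shape != (I, config.G):
        raise ValueError(f"U must be {I} x {config.G}")
    n_g = U.sum(axis=0)
    if np.any(n_g == 0):
        raise ValueError("every class must be nonempty")
    config.validate(J, K)
    Q, R = config.Q, config.R

    # weighted class means: W_mat = diag(n_g)^(-1/2) U^T X, reshaped G x J x K
    W_mat = (U.T @ X_mat) / np.sqrt(n_g)[:, None]
    W = W_mat.reshape(config.G, K, J).transpose(0, 2, 1)
    x_sq = float(np.sum(X_mat * X_mat))

    # HOSVD initialization from mode-2 and mode-3 unfoldings of W
    B = _leading_left_singular(W.transpose(1, 0, 2).reshape(J, -1), Q)
    C = _leading_left_singular(W.transpose(2, 0, 1).reshape(K, -1), R)

    Wt = W.transpose(0, 2, 1)  # G x K x J

    def core_of(Bm, Cm):
        WC = W @ Cm  # G x J x R
        return np.tensordot(WC, Bm, axes=([1], [0])).transpose(0, 2, 1)  # G x Q x R

    loss = x_sq - float(np.sum(core_of(B, C) ** 2))
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        WC = W @ C  # G x J x R
        B = _leading_left_singular(WC.transpose(1, 0, 2).reshape(J, -1), Q)
        WB = Wt @ B  # G x K x Q
        C = _leading_left_singular(WB.transpose(1, 0, 2).reshape(K, -1), R)
        new_loss = x_sq - float(np.sum(core_of(B, C) ** 2))
        if new_loss > loss + 1e-9 * max(1.0, abs(loss)):
            raise RuntimeError("HOOI loss increased; this indicates a numerical failure")
        if abs(loss - new_loss) <= config.tol * max(1.0, abs(loss)):
            loss = new_loss
            converged = True
            break
        loss = new_loss
    if not converged:
        warnings.warn(f"HOOI did not converge in {config.max_iter} iterations")
    loss = max(loss, 0.0)  # mathematically >= 0; guards float cancellation

    core = core_of(B, C)  # G x Q x R

    # column order: B columns by decreasing explained norm
    expl = (core**2).sum(axis=(0, 2))
    order = np.argsort(-expl, kind="stable")
    B = B[:, order]
    core = core[:, order, :]
    # deterministic signs: maximum-magnitude element of each column positive
    for q in range(Q):
        jmax = int(np.argmax(np.abs(B[:, q])))
        if B[jmax, q] < 0:
            B[:, q] = -B[:, q]
            core[:, q, :] = -core[:, q, :]
    for r in range(R):
        kmax = int(np.argmax(np.abs(C[:, r])))
        if C[kmax, r] < 0:
            C[:, r] = -C[:, r]
            core[:, :, r] = -core[:, :, r]

    # undo the class-size weighting: Y = diag(n_g)^(-1/2) core
    Y = core / np.sqrt(n_g)[:, None, None]
    return TuckerResult(B, C, Y, loss, n_iter, converged, config)


def fit(tensor_or_mat, U: np.ndarray, config: TuckerConfig | None = None, *, J=None, K=None) -> TuckerResult:
    """Fit the supervised T3Clus model with the class indicator U fixed.

    Accepts either a :class:`FeatureTensor` or a matricized I x (J*K)
    array (then J and K must be given).  Returns loadings with a
    deterministic sign and column-order convention; the loss is the full
    matricized residual ||X - U Y (C kron B)^T||^2.
    """
    if config is None:
        config = TuckerConfig()
    if isinstance(tensor_or_mat, FeatureTensor):
        X_mat = matricize(tensor_or_mat)
        _, J, K = tensor_or_mat.shape
    else:
        X_mat = np.asarray(tensor_or_mat, dtype=float)
        if J is None or K is None:
            raise ValueError("J and K are required when passing a matricized array")
    return _fit_arrays(X_mat, np.asarray(U, dtype=float), J, K, config)


def kron_loadings(result: TuckerResult) -> np.ndarray:
    """The JK x QR weight matrix C kron B of the fitted model."""
    return np.kron(result.C, result.B)


def component_scores(result: TuckerResult, tensor_or_mat, U: np.ndarray) -> ScoreMatrix:
    """Raw and centroid component scores of each observation.

    Raw scores are X_(I x JK) (C kron B); centroid scores project them onto
    the class means, U (U^T U)^(-1) U^T X (C kron B), and are constant
    within each class.
    """
    if isinstance(tensor_or_mat, FeatureTensor):
        X_mat = matricize(tensor_or_mat)
    else:
        X_mat = np.asarray(tensor_or_mat, dtype=float)
    raw = X_mat @ kron_loadings(result)
    n_g = U.sum(axis=0)
    centroid = U @ ((U.T @ raw) / n_g[:, None])
    return ScoreMatrix(raw, centroid)


def loadings(result: TuckerResult, region_names=None, metric_names=None) -> dict:
    """First-component loading tables and the full Kronecker matrix.

    Returns a dict with DataFrames ``regions`` (column 1 of B) and
    ``metrics`` (column 1 of C), plus the JK x QR array ``kron``.
    """
    J, K = result.B.shape[0], result.C.shape[0]
    region_names = region_names or [f"R{j + 1:03d}" for j in range(J)]
    metric_names = metric_names or [f"M{k + 1}" for k in range(K)]
    regions = pd.DataFrame({"region": region_names, "loading": result.B[:, 0]})
    metrics = pd.DataFrame({"metric": metric_names, "loading": result.C[:, 0]})
    return {"regions": regions, "metrics": metrics, "kron": kron_loadings(result)}
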