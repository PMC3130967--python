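"""Per-subject PCA whitening/reduction and two-stage group reduction.

The group model compresses each subject's ``Q x V`` data to ``L``
whitened principal components, stacks the ``M`` subjects' reduced data
into an ``LM x V`` matrix, and compresses once more to the ``N``
components handed to ICA:

    X = G^-1 [R_1^-1 Y_1; ...; R_M^-1 Y_M]

``R_i^-1`` (``L x Q``) is subject *i*'s reducing/whitening matrix with
de-whitening pseudo-inverse ``R_i`` (a.k.a. ``F_i``); ``G^-1``
(``N x LM``) is the second-stage reducer with de-whitener ``G``. The rows
of ``G`` belonging to subject *i* form the partition ``G_i`` used in
back-reconstruction.

Model order can be chosen by the eigenvalue-based minimum description
length (MDL) criterion for source-number detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import GroupDataset

__all__ = [
    "ReductionResult",
    "GroupReduction",
    "pca_reduce",
    "estimate_order_mdl",
    "reduce_group",
]

logger = logging.getLogger(__name__)


@dataclass
class ReductionResult:
    """One subject's PCA whitening/reduction.

    Attributes
    ----------
    reducer : ndarray, shape (L, Q)
        Whitening/reducing matrix R^-1; applied to row-centered data it
        yields L uncorrelated timecourses (unit variance when whitened).
    dewhitener : ndarray, shape (Q, L)
        Moore-Penrose inverse of ``reducer`` (R, also written F); maps
        reduced timecourses back to channel space.
    eigenvalues : ndarray, shape (Q,)
        Covariance eigenvalues, nonincreasing.
    L : int
        Retained dimension.
    variance_retained : float
        Fraction of total variance in the first L eigenvalues.
    mean : ndarray, shape (Q,)
        Row means removed before projection.
    whitened : bool
        Whether the reduced rows are scaled to unit variance.
    """

    reducer: np.ndarray
    dewhitener: np.ndarray
    eigenvalues: np.ndarray
    L: int
    variance_retained: float
    mean: np.ndarray
    whitened: bool = True

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Apply the reducer to channel data: R^-1 (Y - mean)."""
        return self.reducer @ (data - self.mean[:, None])


@dataclass
class GroupReduction:
    """Two-stage group PCA: per-subject reductions plus the second stage.

    ``partitions[i]`` is the slice of rows of ``group_dewhitener`` (G)
    belonging to subject *i* — the L x N block G_i.
    """

    per_subject: list[ReductionResult]
    group_reducer: np.ndarray  # N x (L*M), G^-1
    group_dewhitener: np.ndarray  # (L*M) x N, G
    partitions: list[slice]
    X: np.ndarray  # N x V aggregate reduced data
    reduced_stack: np.ndarray  # (L*M) x V stacked per-subject reduced data
    N: int

    @property
    def L(self) -> int:
        return self.per_subject[0].L

    @property
    def n_subjects(self) -> int:
        return len(self.per_subject)

    def partition(self, i: int) -> np.ndarray:
        """Subject *i*'s L x N block G_i of the de-whitening matrix."""
        return self.group_dewhitener[self.partitions[i]]


def pca_reduce(data: np.ndarray, L: int, whiten: bool = True) -> ReductionResult:
    """PCA-reduce a Q x V matrix to its top-L principal subspace.

    Rows are mean-centered, then the SVD of the centered data provides the
    principal axes (more stable than eigendecomposing the covariance).
    With ``whiten=True`` the reduced rows have exactly unit variance.

    Each principal axis is oriented so its largest-magnitude channel
    loading is positive, making the output deterministic across BLAS
    implementations. Degenerate (tied) eigenvalues keep SVD order.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x time)")
    q, v = data.shape
    if not 1 <= L <= q:
        raise ValueError(f"L={L} outside valid range 1..{q}")
    mean = data.mean(axis=1)
    centered = data - mean[:, None]
    # economy SVD: data = U diag(sv) Vt; covariance eigenvalues sv^2/(V-1)
    u, sv, _ = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = np.zeros(q)
    eigenvalues[: sv.size] = sv**2 / max(v - 1, 1)
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("constant (zero-variance) data cannot be reduced")
    rank = int(np.sum(sv > sv[0] * max(q, v) * np.finfo(float).eps))
    if L > rank:
        raise ValueError(f"L={L} exceeds numerical rank {rank} of centered data")
    if eigenvalues[L - 1] > 0 and np.isclose(eigenvalues[L - 1], eigenvalues[min(L, q - 1)]):
        logger.info("degenerate eigenvalues at the L=%d cut; SVD order kept", L)
    axes = u[:, :L]  # Q x L, orthonormal columns
    flip = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(L)])
    flip[flip == 0] = 1.0
    axes = axes * flip
    if whiten:
        scale = np.sqrt(eigenvalues[:L])
        reducer = (axes / scale).T  # L x Q
        dewhitener = axes * scale  # Q x L
    else:
        reducer = axes.T
        dewhitener = axes
    return ReductionResult(
        reducer=reducer,
        dewhitener=dewhitener,
        eigenvalues=eigenvalues,
        L=L,
        variance_retained=float(eigenvalues[:L].sum() / total),
        mean=mean,
        whitened=whiten,
    )


def mdl_criterion(eigenvalues: np.ndarray, n: int) -> np.ndarray:
    """MDL cost at every candidate order k = 1..Q-1.

    For covariance eigenvalues lambda_1 >= ... >= lambda_Q and n effective
    samples,

        MDL(k) = -(Q - k) n log( gm(lambda_{k+1..Q}) / am(lambda_{k+1..Q}) )
                 + 0.5 k (2Q - k) log n

    with gm/am the geometric and arithmetic means of the trailing
    eigenvalues. The first term measures how spherical the discarded
    subspace is (zero when all trailing eigenvalues are equal), the second
    penalizes model complexity.
    """
    lam = np.asarray(eigenvalues, dtype=np.float64)
    q = lam.size
    if np.any(~np.isfinite(lam)) or np.any(lam < 0):
        raise ValueError("eigenvalues must be finite and nonnegative")
    lam = np.maximum(lam, np.finfo(float).tiny)
    ks = np.arange(1, q)
    out = np.empty(ks.size)
    for j, k in enumerate(ks):
        tail = lam[k:]
        log_gm = np.mean(np.log(tail))
        am = np.mean(tail)
        out[j] = -(q - k) * n * (log_gm - np.log(am)) + 0.5 * k * (2 * q - k) * np.log(n)
    return out


def estimate_order_mdl(data: np.ndarray, effective_samples: int | None = None) -> int:
    """Estimate the number of latent sources by MDL.

    SVD of the (row-centered) data supplies covariance eigenvalues, which
    are scored with :func:`mdl_criterion`; the minimizing order is
    returned.

    ``effective_samples`` defaults to the number of columns V. Epoched EEG
    samples are serially correlated, so this i.i.d. count overstates the
    evidence and biases the order upward; pass a smaller effective count
    to compensate.
    """
    data = np.asarray(data, dtype=np.float64)
    q, v = data.shape
    if q < 2:
        raise ValueError("need at least 2 channels to estimate model order")
    n = v if effective_samples is None else int(effective_samples)
    if n < q:
        raise ValueError(f"effective_samples={n} is fewer than channels={q}")
    centered = data - data.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(centered, compute_uv=False)
    lam = np.zeros(q)
    lam[: sv.size] = sv**2 / max(v - 1, 1)
    crit = mdl_criterion(lam, n)
    return int(np.argmin(crit)) + 1


def reduce_group(group: GroupDataset, L: int, N: int) -> GroupReduction:
    """Two-stage reduction: per-subject PCA to L, stack, second PCA to N.

    Per-subject reductions are computed independently (each whitened), the
    reduced data are stacked in subject order, and a second whitened PCA
    reduces the ``LM x V`` stack to the ``N x V`` aggregate ``X`` passed
    to ICA.
    """
    m = group.n_subjects
    if L > group.n_channels:
        raise ValueError(f"L={L} exceeds channel count {group.n_channels}")
    if N > L * m:
        raise ValueError(f"N={N} exceeds stacked dimension L*M={L * m}")
    per_subject = []
    for ds in group:
        try:
            per_subject.append(pca_reduce(ds.data, L, whiten=True))
        except ValueError as exc:
            raise ValueError(f"subject {ds.subject_id!r}: {exc}") from exc
    stacked = np.vstack([r.transform(ds.data) for r, ds in zip(per_subject, group)])
    second = pca_reduce(stacked, N, whiten=True)
    x = second.transform(stacked)
    partitions = [slice(i * L, (i + 1) * L) for i in range(m)]
    return GroupReduction(
        per_subject=per_subject,
        group_reducer=second.reducer,
        group_dewhitener=second.dewhitener,
        partitions=partitions,
        X=x,
        reduced_stack=stacked,
        N=N,
    )
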