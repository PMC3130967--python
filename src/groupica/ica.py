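"""ICA algorithms for the whitened aggregate matrix.

All algorithms consume an ``N x V`` whitened matrix ``X`` and return an
:class:`IcaResult` satisfying the exact linear model ``X = A S`` with
``A`` the ``N x N`` mixing matrix and ``S`` the ``N x V`` component
timecourses. ICA's inherent scale and sign indeterminacies are fixed by
convention: every source row has unit variance and its largest-magnitude
sample is positive, with ``A`` adjusted inversely, so results are
reproducible across runs given the same seed.

Implemented algorithms: Infomax (stochastic natural-gradient maximum
likelihood with a logistic nonlinearity), FastICA (symmetric
decorrelation, tanh contrast, via scikit-learn) and JADE (joint
approximate diagonalization of fourth-order cumulant matrices, fully
deterministic). Additional algorithms can be added through
:func:`register_algorithm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit
from sklearn.decomposition import FastICA as _SkFastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "IcaResult",
    "infomax",
    "fastica",
    "jade",
    "run_ica",
    "register_algorithm",
    "available_algorithms",
]

_JADE_MAX_N = 64  # cumulant set needs N^2 (N(N+1)/2) doubles; cap memory


@dataclass
class IcaResult:
    """Result of one ICA decomposition of the aggregate matrix.

    ``mixing @ sources`` reproduces the input ``X`` to numerical
    tolerance, and ``mixing @ unmixing`` is the identity.
    """

    mixing: np.ndarray  # N x N, A-hat
    unmixing: np.ndarray  # N x N, W = A-hat^-1
    sources: np.ndarray  # N x V, S-hat, unit-variance rows
    algorithm: str
    n_iterations: int
    converged: bool
    seed: int | None
    params: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[0]


def _finalize(x: np.ndarray, w: np.ndarray, algorithm: str, n_iterations: int,
              converged: bool, seed: int | None, params: dict) -> IcaResult:
    """Apply the scale/sign convention and package an exact factorization.

    Given any invertible unmixing ``w``, sources are ``w x`` rescaled to
    unit variance with the max-abs sample positive; the mixing matrix
    absorbs the inverse scaling, so ``mixing @ sources == x`` by
    construction (not merely to algorithmic convergence tolerance).
    """
    s = w @ x
    std = s.std(axis=1, ddof=0)
    std[std == 0] = 1.0
    sign = np.sign(s[np.arange(s.shape[0]), np.argmax(np.abs(s), axis=1)])
    sign[sign == 0] = 1.0
    d = sign / std
    s = s * d[:, None]
    unmixing = w * d[:, None]
    mixing = np.linalg.inv(unmixing)
    return IcaResult(
        mixing=mixing,
        unmixing=unmixing,
        sources=s,
        algorithm=algorithm,
        n_iterations=n_iterations,
        converged=converged,
        seed=seed,
        params=params,
    )


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("X must be 2-D (components x time)")
    n, v = x.shape
    if n < 2:
        raise ValueError("need at least 2 components for ICA")
    if v <= n:
        raise ValueError(f"need more samples than components (got {v} <= {n})")
    if not np.all(np.isfinite(x)):
        raise ValueError("X contains non-finite values")
    return x


class InfomaxDivergenceError(RuntimeError):
    """Weights blew up on every annealing restart."""


def infomax(
    x: np.ndarray,
    seed: int,
    learning_rate: float = 0.001,
    anneal: float = 0.9,
    anneal_angle_deg: float = 60.0,
    max_steps: int = 512,
    tol: float = 1e-6,
    block_size: int | None = None,
    max_restarts: int = 10,
) -> IcaResult:
    """Bell–Sejnowski Infomax ICA by stochastic natural gradient.

    Maximizes the entropy of logistically squashed unmixed outputs, which
    for super-Gaussian sources (the event-related case) is maximum
    likelihood separation. Updates follow the natural gradient

        dW ∝ (B I + (1 - 2 g(U)) U^T) W,   g(u) = 1 / (1 + e^-u)

    over random mini-batches of ``B`` columns. The learning rate anneals
    by ``anneal`` whenever the angle between successive weight updates
    exceeds ``anneal_angle_deg``; a weight blow-up triggers a restart at a
    lower rate. Convergence is declared when the per-step relative weight
    change falls below ``tol``.

    Parameters follow common practice for the algorithm (the rate,
    annealing factor, 60-degree rule and ``sqrt(V/3)`` block size); they
    are recorded in ``result.params``.
    """
    x = _check_input(x)
    n, v = x.shape
    rng = np.random.default_rng(seed)
    if block_size is None:
        block_size = max(int(np.floor(np.sqrt(v / 3.0))), 8)
    block_size = min(block_size, v)
    params = {
        "learning_rate": learning_rate,
        "anneal": anneal,
        "anneal_angle_deg": anneal_angle_deg,
        "max_steps": max_steps,
        "tol": tol,
        "block_size": block_size,
    }
    cos_limit = np.cos(np.deg2rad(anneal_angle_deg))
    lr = learning_rate
    eye_b = None
    for restart in range(max_restarts):
        w = np.eye(n)
        prev_delta = None
        converged = False
        step = 0
        diverged = False
        for step in range(1, max_steps + 1):
            perm = rng.permutation(v)
            w_before = w.copy()
            for start in range(0, v - block_size + 1, block_size):
                u = w @ x[:, perm[start : start + block_size]]
                y = expit(u)
                if eye_b is None or eye_b.shape[0] != n:
                    eye_b = np.eye(n)
                grad = (block_size * eye_b + (1.0 - 2.0 * y) @ u.T) @ w
                w = w + lr * grad
                if not np.all(np.isfinite(w)) or np.max(np.abs(w)) > 1e8:
                    diverged = True
                    break
            if diverged:
                break
            delta = w - w_before
            change = np.linalg.norm(delta) / max(np.linalg.norm(w_before), 1e-30)
            if prev_delta is not None:
                denom = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
                if denom > 0 and (delta.ravel() @ prev_delta.ravel()) / denom < cos_limit:
                    lr *= anneal
            prev_delta = delta
            if change < tol:
                converged = True
                break
        if not diverged:
            return _finalize(x, w, "infomax", step, converged, seed,
                             {**params, "restarts": restart, "final_rate": lr})
        lr *= anneal
    raise InfomaxDivergenceError(
        f"infomax diverged on all {max_restarts} restarts; learning-rate "
        f"schedule ended at {lr:.3e} (initial {learning_rate:.3e}, anneal {anneal})"
    )


def fastica(
    x: np.ndarray,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> IcaResult:
    """FastICA with symmetric decorrelation and tanh contrast.

    Thin wrapper over scikit-learn's implementation, operating on the
    already-whitened input. On non-convergence the best iterate is
    returned with ``converged=False``.
    """
    x = _check_input(x)
    n = x.shape[0]
    est = _SkFastICA(
        algorithm="parallel",
        whiten=False,
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(x.T)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(x.T)
    return _finalize(x, est.components_, "fastica", int(est.n_iter_), converged,
                     seed, {"max_iter": max_iter, "tol": tol})


def _jade_cumulant_set(x: np.ndarray) -> np.ndarray:
    """Parallel set of fourth-order cumulant matrices of whitened data.

    For each channel pair (i, j) the matrix
    ``C_ij = E[x_i x_j x x^T] - delta_ij I - e_i e_j^T - e_j e_i^T``
    estimates a slice of the cumulant tensor; the e_i corrections remove
    the Gaussian part (x is whitened, so E[x x^T] = I).
    """
    n, v = x.shape
    eye = np.eye(n)
    mats = np.empty((n * (n + 1) // 2, n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1):
            w = x[i] * x[j]
            m = (x * w) @ x.T / v
            m -= eye[:, [i]] @ eye[[j], :] + eye[:, [j]] @ eye[[i], :]
            if i == j:
                m -= eye
            mats[k] = m
            k += 1
    return mats


def _joint_diagonalize(mats: np.ndarray, threshold: float, max_sweeps: int = 100):
    """Joint approximate diagonalization by Jacobi rotations.

    Sweeps Givens rotations over all index pairs, each time choosing the
    angle that maximizes the summed squared diagonals of the stacked
    matrices; stops when no rotation angle exceeds ``threshold``.
    """
    n = mats.shape[1]
    v = np.eye(n)
    for sweep in range(max_sweeps):
        rotated = False
        for p in range(n - 1):
            for q in range(p + 1, n):
                h1 = mats[:, p, p] - mats[:, q, q]
                h2 = mats[:, p, q] + mats[:, q, p]
                ton = h1 @ h1 - h2 @ h2
                toff = 2.0 * (h1 @ h2)
                theta = 0.5 * np.arctan2(toff, ton + np.sqrt(ton * ton + toff * toff))
                if abs(np.sin(theta)) > threshold:
                    rotated = True
                    c, s = np.cos(theta), np.sin(theta)
                    rp, rq = mats[:, p, :].copy(), mats[:, q, :].copy()
                    mats[:, p, :] = c * rp + s * rq
                    mats[:, q, :] = -s * rp + c * rq
                    cp, cq = mats[:, :, p].copy(), mats[:, :, q].copy()
                    mats[:, :, p] = c * cp + s * cq
                    mats[:, :, q] = -s * cp + c * cq
                    vp, vq = v[:, p].copy(), v[:, q].copy()
                    v[:, p] = c * vp + s * vq
                    v[:, q] = -s * vp + c * vq
        if not rotated:
            return v, sweep + 1, True
    return v, max_sweeps, False


def jade(x: np.ndarray, seed: int | None = None) -> IcaResult:
    """JADE: joint diagonalization of fourth-order cumulant matrices.

    Deterministic given ``x`` (``seed`` is accepted for interface
    uniformity and recorded but unused). Memory for the cumulant set
    grows as N^4, so N is capped at {max_n}.
    """
    x = _check_input(x)
    n, v = x.shape
    if n > _JADE_MAX_N:
        raise ValueError(
            f"jade supports at most {_JADE_MAX_N} components "
            f"(cumulant storage grows as N^4); got N={n}"
        )
    mats = _jade_cumulant_set(x - x.mean(axis=1, keepdims=True))
    rot, sweeps, converged = _joint_diagonalize(mats, threshold=1.0 / np.sqrt(v) / 100.0)
    return _finalize(x, rot.T, "jade", sweeps, converged, seed, {})


jade.__doc__ = jade.__doc__.format(max_n=_JADE_MAX_N)

_REGISTRY: dict[str, Callable[..., IcaResult]] = {
    "infomax": infomax,
    "fastica": fastica,
    "jade": jade,
}


def register_algorithm(name: str, fn: Callable[..., IcaResult]) -> None:
    """Register a user-supplied ICA algorithm for :func:`run_ica`.

    ``fn`` must accept ``(x, seed, **params)`` and return an
    :class:`IcaResult`.
    """
    _REGISTRY[name] = fn


def available_algorithms() -> list[str]:
    return sorted(_REGISTRY)


def run_ica(x: np.ndarray, algorithm: str, seed: int | None = None, **params) -> IcaResult:
    """Dispatch to a registered ICA algorithm by name."""
    try:
        fn = _REGISTRY[algorithm]
    except KeyError:
        raise ValueError(
            f"algorithm {algorithm!r} not implemented; "
            f"available: {', '.join(available_algorithms())}"
        ) from None
    return fn(x, seed=seed, **params)
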