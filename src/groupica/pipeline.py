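"""Group ICA pipeline: reduction → aggregate ICA → back-reconstruction.

The group model estimates a single set of ``N`` components from the
concatenated, PCA-reduced data of all subjects, then reconstructs
subject-specific timecourses and scalp maps by partitioning the
second-stage de-whitening matrix ``G`` by subject:

    S_i = (G_i A)^+ R_i^-1 Y_i            (timecourses)
    Y_i ≈ F_i G_i A S_i                   (scalp maps F_i G_i A)

The component order is identical across subjects by construction — the
property that makes group-level inference straightforward.
"""

from __future__ import annotations

import json
import logging
import statistics
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .datasets import GroupDataset
from .ica import IcaResult, run_ica
from .reduction import GroupReduction, ReductionResult, estimate_order_mdl, reduce_group

__all__ = [
    "SubjectComponents",
    "GroupResult",
    "back_reconstruct",
    "run_group_ica",
    "save_result",
    "load_result",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "groupica-result-1"
_COND_LIMIT = 1e10


@dataclass
class SubjectComponents:
    """Back-reconstructed components of one subject.

    ``scalp_maps @ timecourses`` reproduces the subject's centered data up
    to the subject's PCA truncation loss.
    """

    subject_id: str
    timecourses: np.ndarray  # N x V
    scalp_maps: np.ndarray  # Q x N
    samples_per_epoch: int
    n_trials: int

    def trial_images(self) -> np.ndarray:
        """Timecourses as (N, samples_per_epoch, n_trials) single-trial images."""
        n = self.timecourses.shape[0]
        return self.timecourses.reshape(n, self.n_trials, self.samples_per_epoch).transpose(0, 2, 1)


@dataclass
class GroupResult:
    reduction: GroupReduction
    ica: IcaResult
    subjects: list[SubjectComponents]
    group_mean_timecourses: np.ndarray  # N x samples_per_epoch
    config_snapshot: dict = field(default_factory=dict)


def back_reconstruct(red: GroupReduction, ica: IcaResult, subject_index: int,
                     reduced_data: np.ndarray | None = None,
                     subject_id: str | None = None,
                     samples_per_epoch: int | None = None,
                     n_trials: int | None = None,
                     method: str = "regression") -> SubjectComponents:
    """Reconstruct subject-specific timecourses and scalp maps.

    The subject-space pattern of aggregate component k is column k of
    ``G_i A`` (the single-subject mixing in reduced coordinates); the
    scalp maps are ``F_i G_i A`` in either method.

    ``method="regression"`` (default) estimates each component's
    timecourse by ordinary least squares of the subject's whitened data
    on that component's pattern (a matched filter, since whitened rows
    are uncorrelated): stable even when some aggregate components are
    weakly expressed in this subject.

    ``method="pinv"`` jointly inverts the subject partition,
    ``timecourses = pinv(G_i A) R_i^-1 Y_i`` — the algebraically exact
    solution of the partitioned group model (the plain inverse when
    ``L = N``), which reproduces the subject's data to truncation loss
    but amplifies noise through the inverse when ``G_i A`` is poorly
    conditioned.

    ``reduced_data`` is the subject's ``L x V`` reduced matrix
    ``R_i^-1 Y_i``; defaults to the slice stored in ``red``.
    """
    i = subject_index
    g_i = red.partition(i)  # L x N
    m_i = g_i @ ica.mixing  # L x N
    sv = np.linalg.svd(m_i, compute_uv=False)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    if method == "pinv" and cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"subject {i}: G_i A is rank-deficient beyond tolerance "
            f"(condition number {cond:.3e} > {_COND_LIMIT:.0e})"
        )
    if reduced_data is None:
        reduced_data = red.reduced_stack[red.partitions[i]]
    if method == "regression":
        norms = np.sum(m_i**2, axis=0)
        norms[norms == 0] = 1.0
        timecourses = (m_i.T @ reduced_data) / norms[:, None]
    elif method == "pinv":
        timecourses = np.linalg.pinv(m_i) @ reduced_data
    else:
        raise ValueError(f"unknown back-reconstruction method {method!r}")
    scalp_maps = red.per_subject[i].dewhitener @ m_i  # Q x N
    if not (np.all(np.isfinite(timecourses)) and np.all(np.isfinite(scalp_maps))):
        raise ValueError(f"subject {i}: non-finite values in back-reconstruction")
    return SubjectComponents(
        subject_id=subject_id if subject_id is not None else f"subject{i:03d}",
        timecourses=timecourses,
        scalp_maps=scalp_maps,
        samples_per_epoch=samples_per_epoch if samples_per_epoch is not None else -1,
        n_trials=n_trials if n_trials is not None else -1,
    )


def run_group_ica(
    group: GroupDataset,
    L: int = 20,
    N: int | str = 20,
    algorithm: str = "infomax",
    seed: int = 0,
    ica_params: dict | None = None,
    reconstruction: str | None = None,
) -> GroupResult:
    """Run the full group pipeline on a multi-subject dataset.

    Parameters
    ----------
    group : GroupDataset
        Dimensionally homogeneous subjects. A group of one collapses to
        ordinary single-subject ICA.
    L : int
        Per-subject PCA dimension.
    N : int or "mdl"
        Number of components; ``"mdl"`` estimates the order per subject
        by MDL and uses the median across subjects.
    algorithm : str
        Registered ICA algorithm name.
    seed : int
        Seed for the stochastic algorithms; recorded in the snapshot.
    reconstruction : {"regression", "pinv"}, optional
        Back-reconstruction estimator (see :func:`back_reconstruct`).
        Defaults to ``"pinv"`` for a single-subject group — where the
        partitioned model collapses to ordinary ICA and the exact
        inverse is well conditioned — and ``"regression"`` otherwise.
    """
    if reconstruction is None:
        reconstruction = "pinv" if group.n_subjects == 1 else "regression"
    ica_params = dict(ica_params or {})
    t0 = time.perf_counter()
    order_source = "fixed"
    if N == "mdl":
        orders = [estimate_order_mdl(ds.data) for ds in group]
        N = int(statistics.median(orders))
        N = min(max(N, 2), L * group.n_subjects)  # ICA needs at least 2 components
        order_source = f"mdl(per-subject orders={orders})"
        logger.info("MDL model order: %d (%s)", N, order_source)
    elif not isinstance(N, int):
        raise ValueError(f"N must be an integer or 'mdl', got {N!r}")
    try:
        red = reduce_group(group, L=L, N=N)
    except ValueError as exc:
        raise ValueError(f"reduction stage: {exc}") from exc
    t1 = time.perf_counter()
    logger.info("reduction done in %.2fs (L=%d, N=%d, M=%d)", t1 - t0, L, N, group.n_subjects)
    try:
        ica_res = run_ica(red.X, algorithm, seed=seed, **ica_params)
    except Exception as exc:
        raise RuntimeError(f"ica stage ({algorithm}): {exc}") from exc
    t2 = time.perf_counter()
    logger.info("ica done in %.2fs (%s, %d iterations, converged=%s)",
                t2 - t1, algorithm, ica_res.n_iterations, ica_res.converged)
    subjects = []
    for i, ds in enumerate(group):
        try:
            subjects.append(
                back_reconstruct(
                    red, ica_res, i,
                    subject_id=ds.subject_id,
                    samples_per_epoch=ds.samples_per_epoch,
                    n_trials=ds.n_trials,
                    method=reconstruction,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"back-reconstruction stage, subject {ds.subject_id!r}: {exc}") from exc
    # trial-average within subject first, then average across subjects
    per_subject_means = [sc.trial_images().mean(axis=2) for sc in subjects]
    group_mean = np.mean(per_subject_means, axis=0)
    snapshot = {
        "L": L,
        "N": N,
        "order_source": order_source,
        "algorithm": algorithm,
        "reconstruction": reconstruction,
        "seed": seed,
        "ica_params": ica_res.params,
        "n_subjects": group.n_subjects,
        "n_channels": group.n_channels,
        "samples_per_epoch": group.samples_per_epoch,
        "n_trials": group.n_trials,
    }
    logger.info("back-reconstruction done in %.2fs", time.perf_counter() - t2)
    return GroupResult(
        reduction=red,
        ica=ica_res,
        subjects=subjects,
        group_mean_timecourses=group_mean,
        config_snapshot=snapshot,
    )


def _write_array(grp: h5py.Group, name: str, arr: np.ndarray) -> None:
    grp.create_dataset(name, data=np.asarray(arr), track_times=False)


def save_result(res: GroupResult, path: str | Path) -> None:
    """Persist a GroupResult to a hierarchical HDF5 results file."""
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        red_g = fh.create_group("reduction")
        for i, r in enumerate(res.reduction.per_subject):
            sg = red_g.create_group(f"subject{i:03d}")
            for name in ("reducer", "dewhitener", "eigenvalues", "mean"):
                _write_array(sg, name, getattr(r, name))
            sg.attrs["L"] = r.L
            sg.attrs["variance_retained"] = r.variance_retained
            sg.attrs["whitened"] = r.whitened
        _write_array(red_g, "group_reducer", res.reduction.group_reducer)
        _write_array(red_g, "group_dewhitener", res.reduction.group_dewhitener)
        _write_array(red_g, "X", res.reduction.X)
        _write_array(red_g, "reduced_stack", res.reduction.reduced_stack)
        red_g.attrs["N"] = res.reduction.N
        ica_g = fh.create_group("ica")
        for name in ("mixing", "unmixing", "sources"):
            _write_array(ica_g, name, getattr(res.ica, name))
        ica_g.attrs["algorithm"] = res.ica.algorithm
        ica_g.attrs["n_iterations"] = res.ica.n_iterations
        ica_g.attrs["converged"] = res.ica.converged
        ica_g.attrs["seed"] = -1 if res.ica.seed is None else res.ica.seed
        ica_g.attrs["params"] = json.dumps(res.ica.params)
        subj_g = fh.create_group("subjects")
        for sc in res.subjects:
            sg = subj_g.create_group(sc.subject_id)
            _write_array(sg, "timecourses", sc.timecourses)
            _write_array(sg, "scalp_maps", sc.scalp_maps)
            sg.attrs["samples_per_epoch"] = sc.samples_per_epoch
            sg.attrs["n_trials"] = sc.n_trials
        _write_array(fh, "group_mean_timecourses", res.group_mean_timecourses)
        fh.create_group("config").attrs["json"] = json.dumps(res.config_snapshot)


def load_result(path: str | Path) -> GroupResult:
    """Load a results file written by :func:`save_result`."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"{path}: results schema {version!r} does not match {SCHEMA_VERSION!r}"
            )
        required = {"reduction", "ica", "subjects", "group_mean_timecourses", "config"}
        missing = required - set(fh.keys())
        if missing:
            raise ValueError(f"{path}: incomplete results file, missing {sorted(missing)}")
        red_g = fh["reduction"]
        per_subject = []
        subj_keys = sorted(k for k in red_g.keys() if k.startswith("subject"))
        for k in subj_keys:
            sg = red_g[k]
            per_subject.append(
                ReductionResult(
                    reducer=sg["reducer"][()],
                    dewhitener=sg["dewhitener"][()],
                    eigenvalues=sg["eigenvalues"][()],
                    L=int(sg.attrs["L"]),
                    variance_retained=float(sg.attrs["variance_retained"]),
                    mean=sg["mean"][()],
                    whitened=bool(sg.attrs["whitened"]),
                )
            )
        l_dim = per_subject[0].L
        red = GroupReduction(
            per_subject=per_subject,
            group_reducer=red_g["group_reducer"][()],
            group_dewhitener=red_g["group_dewhitener"][()],
            partitions=[slice(i * l_dim, (i + 1) * l_dim) for i in range(len(per_subject))],
            X=red_g["X"][()],
            reduced_stack=red_g["reduced_stack"][()],
            N=int(red_g.attrs["N"]),
        )
        ica_g = fh["ica"]
        seed = int(ica_g.attrs["seed"])
        ica_res = IcaResult(
            mixing=ica_g["mixing"][()],
            unmixing=ica_g["unmixing"][()],
            sources=ica_g["sources"][()],
            algorithm=str(ica_g.attrs["algorithm"]),
            n_iterations=int(ica_g.attrs["n_iterations"]),
            converged=bool(ica_g.attrs["converged"]),
            seed=None if seed == -1 else seed,
            params=json.loads(ica_g.attrs["params"]),
        )
        subjects = []
        for sid in fh["subjects"]:
            sg = fh["subjects"][sid]
            subjects.append(
                SubjectComponents(
                    subject_id=sid,
                    timecourses=sg["timecourses"][()],
                    scalp_maps=sg["scalp_maps"][()],
                    samples_per_epoch=int(sg.attrs["samples_per_epoch"]),
                    n_trials=int(sg.attrs["n_trials"]),
                )
            )
        return GroupResult(
            reduction=red,
            ica=ica_res,
            subjects=subjects,
            group_mean_timecourses=fh["group_mean_timecourses"][()],
            config_snapshot=json.loads(fh["config"].attrs["json"]),
        )
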