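"""Containers and file I/O for multi-subject epoched EEG.

A subject's single-trial data live in an :class:`EpochedDataset`: a
``Q x V`` matrix where ``Q`` is the number of channels and
``V = samples_per_epoch * n_trials`` is the concatenated time dimension.
Columns are ordered trial-major (all samples of trial 1, then trial 2, ...);
every operation in the package preserves this ordering.

Two on-disk dialects are supported: a native single-file container (JSON
header followed by raw float64 payload) and EEGLAB epoched ``.set`` files
(MATLAB v5, with either embedded data or a companion ``.fdt`` float file).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.io

__all__ = [
    "EpochedDataset",
    "GroupDataset",
    "read_epoched",
    "write_epoched",
    "pad_missing_trials",
]

_NATIVE_MAGIC = b"GICA1\n"


@dataclass
class EpochedDataset:
    """One subject's preprocessed single-trial EEG.

    Parameters
    ----------
    subject_id : str
        Identifier carried through the pipeline.
    data : ndarray, shape (Q, V)
        Channel-by-time matrix, ``V = samples_per_epoch * n_trials``,
        trial-major column order. Units are microvolts for real data,
        arbitrary for simulated data.
    samples_per_epoch : int
        Number of time samples per trial epoch.
    n_trials : int
        Number of trials.
    sampling_rate : float, optional
        Sampling rate in Hz; metadata only.
    channel_labels : list of str, optional
        One label per channel; defaults to ``ch000, ch001, ...``.
    trial_valid : ndarray of bool, shape (n_trials,), optional
        False marks a missing/rejected trial awaiting padding.
    """

    subject_id: str
    data: np.ndarray
    samples_per_epoch: int
    n_trials: int
    sampling_rate: float | None = None
    channel_labels: list[str] = field(default_factory=list)
    trial_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x time) matrix")
        if self.samples_per_epoch < 1 or self.n_trials < 1:
            raise ValueError("samples_per_epoch and n_trials must be positive")
        q, v = self.data.shape
        if v != self.samples_per_epoch * self.n_trials:
            raise ValueError(
                f"data has {v} columns, expected samples_per_epoch * n_trials "
                f"= {self.samples_per_epoch * self.n_trials}"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(q)]
        if len(self.channel_labels) != q:
            raise ValueError("channel_labels length must equal channel count")
        if self.trial_valid is None:
            self.trial_valid = np.ones(self.n_trials, dtype=bool)
        else:
            self.trial_valid = np.asarray(self.trial_valid, dtype=bool)
            if self.trial_valid.shape != (self.n_trials,):
                raise ValueError("trial_valid must have length n_trials")
        if not np.all(np.isfinite(self.data[:, self.valid_columns()])):
            raise ValueError("valid trials contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        """Total columns V."""
        return self.data.shape[1]

    def valid_columns(self) -> np.ndarray:
        """Boolean mask over the V columns belonging to valid trials."""
        return np.repeat(self.trial_valid, self.samples_per_epoch)

    def as_trials(self) -> np.ndarray:
        """View the data as (Q, samples_per_epoch, n_trials).

        The reshape is lossless: ``as_trials().reshape(Q, V, order='F')``
        on the last two axes recovers ``data`` exactly.
        """
        q = self.n_channels
        return self.data.reshape(q, self.n_trials, self.samples_per_epoch).transpose(0, 2, 1)

    def trial(self, t: int) -> np.ndarray:
        """The (Q, samples_per_epoch) slab of trial ``t``."""
        s = self.samples_per_epoch
        return self.data[:, t * s : (t + 1) * s]


@dataclass
class GroupDataset:
    """An ordered collection of dimensionally homogeneous subjects."""

    subjects: list[EpochedDataset]

    def __post_init__(self) -> None:
        if len(self.subjects) < 1:
            raise ValueError("group needs at least one subject")
        ref = self.subjects[0]
        for s in self.subjects[1:]:
            if (
                s.n_channels != ref.n_channels
                or s.samples_per_epoch != ref.samples_per_epoch
                or s.n_trials != ref.n_trials
            ):
                raise ValueError(
                    f"subject {s.subject_id!r} dimensions "
                    f"({s.n_channels}, {s.samples_per_epoch}, {s.n_trials}) "
                    f"differ from {ref.subject_id!r}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_channels(self) -> int:
        return self.subjects[0].n_channels

    @property
    def samples_per_epoch(self) -> int:
        return self.subjects[0].samples_per_epoch

    @property
    def n_trials(self) -> int:
        return self.subjects[0].n_trials

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


def write_epoched(ds: EpochedDataset, path: str | Path) -> None:
    """Write a dataset to the native single-file container.

    Layout: magic line, 8-byte little-endian header length, UTF-8 JSON
    header, then the row-major float64 payload.
    """
    path = Path(path)
    header = {
        "subject_id": ds.subject_id,
        "n_channels": ds.n_channels,
        "samples_per_epoch": ds.samples_per_epoch,
        "n_trials": ds.n_trials,
        "sampling_rate": ds.sampling_rate,
        "channel_labels": ds.channel_labels,
        "trial_valid": ds.trial_valid.astype(int).tolist(),
        "dtype": "float64",
    }
    blob = json.dumps(header).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_NATIVE_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        fh.write(np.ascontiguousarray(ds.data, dtype=np.float64).tobytes())


def _read_native(path: Path) -> EpochedDataset:
    with open(path, "rb") as fh:
        magic = fh.read(len(_NATIVE_MAGIC))
        if magic != _NATIVE_MAGIC:
            raise ValueError(f"{path}: not a native epoched-dataset file")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        try:
            header = json.loads(fh.read(hlen).decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: corrupt header") from exc
        q = header["n_channels"]
        v = header["samples_per_epoch"] * header["n_trials"]
        payload = fh.read(q * v * 8)
    if len(payload) != q * v * 8:
        raise ValueError(f"{path}: payload shorter than header promises")
    data = np.frombuffer(payload, dtype=np.float64).reshape(q, v).copy()
    return EpochedDataset(
        subject_id=header["subject_id"],
        data=data,
        samples_per_epoch=header["samples_per_epoch"],
        n_trials=header["n_trials"],
        sampling_rate=header["sampling_rate"],
        channel_labels=list(header["channel_labels"]),
        trial_valid=np.asarray(header["trial_valid"], dtype=bool),
    )


def _read_eeglab(path: Path) -> EpochedDataset:
    # EEGLAB .set is a MATLAB v5 file with an EEG struct; data may be embedded
    # or live in a companion float32 .fdt file (channels x frames, F order).
    try:
        mat = scipy.io.loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except Exception as exc:  # noqa: BLE001 - loadmat raises a zoo of types
        raise ValueError(f"{path}: unreadable EEGLAB file ({exc})") from exc
    eeg = mat.get("EEG", mat)
    if hasattr(eeg, "nbchan"):
        get = lambda k: getattr(eeg, k)  # noqa: E731
        has = lambda k: hasattr(eeg, k)  # noqa: E731
    else:
        get = lambda k: np.squeeze(mat[k])[()] if np.ndim(mat[k]) else mat[k]  # noqa: E731
        has = lambda k: k in mat  # noqa: E731
    nbchan = int(get("nbchan"))
    pnts = int(get("pnts"))
    trials = int(get("trials"))
    if trials <= 1:
        raise ValueError(f"{path}: continuous (non-epoched) EEGLAB data")
    srate = float(get("srate")) if has("srate") else None
    raw = get("data")
    if isinstance(raw, str) or (isinstance(raw, np.ndarray) and raw.dtype.kind == "U"):
        fdt = path.parent / str(np.atleast_1d(raw)[0] if isinstance(raw, np.ndarray) else raw)
        if not fdt.exists():
            fdt = path.with_suffix(".fdt")
        if not fdt.exists():
            raise ValueError(f"{path}: companion data file {fdt.name} not found")
        flat = np.fromfile(fdt, dtype="<f4")
        if flat.size != nbchan * pnts * trials:
            raise ValueError(
                f"{fdt}: {flat.size} values, header promises {nbchan * pnts * trials}"
            )
        data = flat.reshape(nbchan, pnts * trials, order="F")
    else:
        data = np.asarray(raw, dtype=np.float64)
        if data.ndim == 3:  # channels x samples x trials
            data = data.reshape(nbchan, pnts * trials, order="F")
        if data.shape != (nbchan, pnts * trials):
            raise ValueError(
                f"{path}: data shape {data.shape} does not match header "
                f"({nbchan} x {pnts} x {trials})"
            )
    labels: list[str] = []
    if has("chanlocs"):
        try:
            locs = np.atleast_1d(get("chanlocs"))
            labels = [str(c.labels) for c in locs]
        except Exception:  # noqa: BLE001 - labels are best-effort metadata
            labels = []
    if len(labels) != nbchan:
        labels = [f"ch{i:03d}" for i in range(nbchan)]
    return EpochedDataset(
        subject_id=path.stem,
        data=np.asarray(data, dtype=np.float64),
        samples_per_epoch=pnts,
        n_trials=trials,
        sampling_rate=srate,
        channel_labels=labels,
    )


def read_epoched(path: str | Path, dialect: str = "native") -> EpochedDataset:
    """Read an epoched dataset file.

    Parameters
    ----------
    path : path-like
        Dataset file.
    dialect : {"native", "eeglab"}
        File format. ``eeglab`` accepts epoched ``.set`` files only; ICA
        fields inside the file are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native":
        return _read_native(path)
    if dialect == "eeglab":
        return _read_eeglab(path)
    raise ValueError(f"unknown dialect {dialect!r}; choose 'native' or 'eeglab'")


def pad_missing_trials(ds: EpochedDataset) -> EpochedDataset:
    """Replace invalid trials by the mean of the surrounding valid trials.

    Each missing trial is filled, per channel and per sample, with the mean
    of the nearest valid trial before and the nearest valid trial after it;
    one-sided at the edges (a leading missing trial copies the first valid
    trial). Reflects the gradual trial-to-trial drift of event-related
    responses, which makes the local mean a better fill than zeros or the
    grand average. Idempotent; the output has all trials marked valid.
    """
    valid_idx = np.flatnonzero(ds.trial_valid)
    if valid_idx.size == 0:
        raise ValueError("cannot pad: all trials are invalid")
    if valid_idx.size == ds.n_trials:
        return replace(ds, data=ds.data.copy(), trial_valid=ds.trial_valid.copy())
    s = ds.samples_per_epoch
    out = ds.data.copy()
    for t in np.flatnonzero(~ds.trial_valid):
        before = valid_idx[valid_idx < t]
        after = valid_idx[valid_idx > t]
        if before.size and after.size:
            fill = 0.5 * (ds.trial(before[-1]) + ds.trial(after[0]))
        elif before.size:
            fill = ds.trial(before[-1])
        else:
            fill = ds.trial(after[0])
        out[:, t * s : (t + 1) * s] = fill
    return replace(ds, data=out, trial_valid=np.ones(ds.n_trials, dtype=bool))
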