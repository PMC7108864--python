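"""Spike-table ingest, epoching, binarization and ensemble sampling.

The raw input is a table of spike times per unit (single- or multi-unit) plus
a list of stimulus onset times.  Recordings are cut into adjacent epochs
(default 100 s); within each epoch the spontaneous activity is the
concatenation of fixed-length windows (default 1.5 s) ending at each stimulus
onset.  Activity is binarized into +/-1 values in non-overlapping bins
(default 10 ms): +1 iff the unit spiked at least once in the bin.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeDataset",
    "EpochWindows",
    "BinaryRaster",
    "PatternSamples",
    "EnsembleSet",
    "read_spike_table",
    "write_spike_table",
    "segment_epochs",
    "binarize",
    "extract_patterns",
    "sample_ensembles",
]

_TOL = 1e-9  # absolute slack for window/bin arithmetic on float seconds


@dataclass
class SpikeDataset:
    """Spike times, unit classes and stimulus events for one recording.

    Parameters
    ----------
    units : DataFrame with columns ``unit_id`` (int, unique) and ``cls``
        (``"single"`` or ``"multi"``).
    spikes : DataFrame with columns ``unit_id`` and ``time_s`` (seconds,
        within ``[0, duration]``), sorted by unit then time.
    events : strictly increasing stimulus onset times in seconds.
    duration : recording length in seconds.
    """

    units: pd.DataFrame
    spikes: pd.DataFrame
    events: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.units = pd.DataFrame(self.units).reset_index(drop=True)
        self.spikes = pd.DataFrame(self.spikes).reset_index(drop=True)
        self.events = np.asarray(self.events, dtype=np.float64)
        for col in ("unit_id", "cls"):
            if col not in self.units.columns:
                raise ValueError(f"units table missing column {col!r}")
        for col in ("unit_id", "time_s"):
            if col not in self.spikes.columns:
                raise ValueError(f"spikes table missing column {col!r}")
        if self.units["unit_id"].duplicated().any():
            raise ValueError("unit_ids must be unique")
        bad = set(self.units["cls"]) - {"single", "multi"}
        if bad:
            raise ValueError(f"unknown unit classes: {sorted(bad)}")
        if len(self.spikes):
            t = self.spikes["time_s"].to_numpy()
            if (t < 0).any() or (t > self.duration + _TOL).any():
                raise ValueError("spike times must lie within [0, duration]")
            unknown = set(self.spikes["unit_id"]) - set(self.units["unit_id"])
            if unknown:
                raise ValueError(f"spikes reference unknown units {sorted(unknown)}")
            self.spikes = self.spikes.sort_values(
                ["unit_id", "time_s"], kind="stable"
            ).reset_index(drop=True)
        if len(self.events) > 1 and not (np.diff(self.events) > 0).all():
            raise ValueError("event onsets must be strictly increasing")

    @property
    def single_unit_ids(self) -> np.ndarray:
        return self.units.loc[self.units["cls"] == "single", "unit_id"].to_numpy()

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    def spike_times(self, unit_id: int) -> np.ndarray:
        sel = self.spikes["unit_id"] == unit_id
        return self.spikes.loc[sel, "time_s"].to_numpy()


@dataclass
class EpochWindows:
    """Epoch boundaries plus per-epoch pre-stimulus (spontaneous) windows."""

    epoch_length: float
    epochs: list[tuple[float, float]]
    windows: list[list[tuple[float, float]]]  # per epoch
    events: list[np.ndarray]  # per epoch
    pre_window: float = 1.5

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def has_events(self) -> np.ndarray:
        """Epochs without any usable window are excluded from evoked/fit work."""
        return np.array([len(w) > 0 for w in self.windows])

    @property
    def valid_epochs(self) -> np.ndarray:
        return np.nonzero(self.has_events)[0]


@dataclass
class BinaryRaster:
    """+/-1 binarized activity over concatenated windows.

    ``values`` has shape (n_units, n_bins), entries +1 iff >=1 spike of that
    unit fell in the half-open bin [t, t+dt).
    """

    unit_ids: np.ndarray
    values: np.ndarray
    dt: float
    windows: list[tuple[float, float]]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row(self, unit_id: int) -> np.ndarray:
        (pos,) = np.nonzero(self.unit_ids == unit_id)
        if pos.size == 0:
            raise KeyError(f"unit {unit_id} not in raster")
        return self.values[pos[0]]


@dataclass
class PatternSamples:
    """Sequence of N-dimensional +/-1 patterns for one ensemble and epoch."""

    unit_ids: np.ndarray
    X: np.ndarray  # (n_samples, N), int8
    epoch: int | None = None

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_units(self) -> int:
        return self.X.shape[1]


@dataclass
class EnsembleSet:
    """Q ensembles of N distinct single-unit ids, plus the sampling seed."""

    ensembles: list[np.ndarray]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.ensembles)

    def __iter__(self):
        return iter(self.ensembles)

    def __getitem__(self, q):
        return self.ensembles[q]


# ---------------------------------------------------------------------------
# table I/O


def read_spike_table(path, events_path=None) -> SpikeDataset:
    """Read a spike table (CSV/TSV: unit_id,time_s,cls) and its events file.

    The first line may carry ``# duration_s=<float>``; otherwise the duration
    is taken as the ceiling of the last spike/event time.  ``events_path``
    defaults to ``<path stem>.events.csv`` (column ``onset_s``) and may be
    absent, in which case the dataset has no stimulus events.
    """
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        duration = None
        if first.startswith("#"):
            key, _, val = first.lstrip("#").strip().partition("=")
            if key.strip() == "duration_s":
                duration = float(val)
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body), sep=sep)
    required = {"unit_id", "time_s", "cls"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spike table missing columns {sorted(missing)}")
    if len(df) and (df["time_s"].to_numpy() < 0).any():
        raise ValueError("negative spike times")

    units = (
        df[["unit_id", "cls"]]
        .drop_duplicates("unit_id")
        .sort_values("unit_id")
        .reset_index(drop=True)
    )
    spikes = df.loc[df["time_s"].notna(), ["unit_id", "time_s"]]

    if events_path is None:
        stem = path.rsplit(".", 1)[0]
        events_path = stem + ".events.csv"
    events = np.empty(0)
    try:
        ev = pd.read_csv(events_path)
        if "onset_s" not in ev.columns:
            raise ValueError("events file missing column 'onset_s'")
        events = ev["onset_s"].to_numpy(dtype=np.float64)
    except FileNotFoundError:
        pass

    if duration is None:
        hi = [0.0]
        if len(spikes):
            hi.append(float(spikes["time_s"].max()))
        if len(events):
            hi.append(float(events.max()))
        duration = float(np.ceil(max(hi)))
    return SpikeDataset(units=units, spikes=spikes, events=events, duration=duration)


def _declared_rows(dataset: SpikeDataset) -> pd.DataFrame:
    """Spike rows plus NaN-time rows for units that never spiked (so the
    round trip preserves the unit roster)."""
    cls_of = dict(zip(dataset.units["unit_id"], dataset.units["cls"]))
    rows = dataset.spikes.copy()
    rows["cls"] = rows["unit_id"].map(cls_of)
    silent = sorted(set(dataset.units["unit_id"]) - set(rows["unit_id"]))
    if silent:
        extra = pd.DataFrame(
            {"unit_id": silent, "time_s": np.nan, "cls": [cls_of[u] for u in silent]}
        )
        rows = pd.concat([rows, extra], ignore_index=True)
    return rows.sort_values(["unit_id", "time_s"], kind="stable")[
        ["unit_id", "time_s", "cls"]
    ]


def write_spike_table(dataset: SpikeDataset, path) -> str:
    """Write the dataset as CSV (+ events sidecar); inverse of read_spike_table."""
    path = str(path)
    rows = _declared_rows(dataset)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# duration_s={dataset.duration!r}\n")
        rows.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")
    stem = path.rsplit(".", 1)[0]
    pd.DataFrame({"onset_s": dataset.events}).to_csv(
        stem + ".events.csv", index=False, float_format="%.6f", lineterminator="\n"
    )
    return path


# ---------------------------------------------------------------------------
# epoching / binarization


def segment_epochs(
    dataset: SpikeDataset, epoch_length: float = 100.0, pre_window: float = 1.5
) -> EpochWindows:
    """Cut the recording into NE = floor(duration/epoch_length) adjacent
    epochs and attach each epoch's pre-stimulus spontaneous windows.

    A window is the ``pre_window``-long interval ending exactly at a stimulus
    onset; windows that would cross their epoch's start are dropped so every
    window keeps its full length.
    """
    if dataset.duration < epoch_length:
        raise ValueError("recording shorter than one epoch")
    n_epochs = int(np.floor(dataset.duration / epoch_length + _TOL))
    epochs = [(k * epoch_length, (k + 1) * epoch_length) for k in range(n_epochs)]
    windows: list[list[tuple[float, float]]] = []
    ev_per_epoch: list[np.ndarray] = []
    for t0, t1 in epochs:
        ev = dataset.events[(dataset.events >= t0) & (dataset.events < t1)]
        ev_per_epoch.append(ev)
        wins = [(e - pre_window, e) for e in ev if e - pre_window >= t0 - _TOL]
        windows.append(wins)
    return EpochWindows(
        epoch_length=epoch_length,
        epochs=epochs,
        windows=windows,
        events=ev_per_epoch,
        pre_window=pre_window,
    )


def _window_bins(w0: float, w1: float, dt: float) -> int:
    nbins = (w1 - w0) / dt
    if abs(nbins - round(nbins)) > 1e-6:
        raise ValueError(
            f"window [{w0}, {w1}) length is not an exact multiple of dt={dt}"
        )
    return int(round(nbins))


def binarize(
    dataset: SpikeDataset,
    windows: list[tuple[float, float]],
    dt: float = 0.010,
    units=None,
) -> BinaryRaster:
    """Binarize activity over concatenated windows: +1 iff >=1 spike in bin.

    Bins are half-open [t, t+dt); a spike exactly on a boundary belongs to
    the later bin.  Every window length must be an exact multiple of dt.
    """
    if units is None:
        units = dataset.unit_ids
    units = np.asarray(units)
    unknown = set(units) - set(dataset.unit_ids)
    if unknown:
        raise KeyError(f"unknown unit ids {sorted(unknown)}")
    nbins = [_window_bins(w0, w1, dt) for w0, w1 in windows]
    total = int(np.sum(nbins)) if nbins else 0
    values = np.full((len(units), total), -1, dtype=np.int8)
    offsets = np.concatenate([[0], np.cumsum(nbins)]).astype(int)
    for row, uid in enumerate(units):
        t = dataset.spike_times(uid)
        for k, (w0, w1) in enumerate(windows):
            sel = t[(t >= w0) & (t < w1)]
            if sel.size:
                idx = np.floor((sel - w0) / dt + _TOL).astype(int)
                idx = idx[idx < nbins[k]]
                values[row, offsets[k] + idx] = 1
    return BinaryRaster(unit_ids=units, values=values, dt=dt, windows=list(windows))


def extract_patterns(raster: BinaryRaster, ensemble, epoch: int | None = None) -> PatternSamples:
    """Pattern time series (one +/-1 vector per bin) for an ordered ensemble."""
    ensemble = np.asarray(ensemble)
    rows = []
    for uid in ensemble:
        rows.append(raster.row(uid))
    X = np.stack(rows, axis=1).astype(np.int8) if rows else np.empty((0, 0), np.int8)
    return PatternSamples(unit_ids=ensemble, X=X, epoch=epoch)


def sample_ensembles(
    single_unit_ids, n_units: int = 10, q: int = 20, seed: int | None = None
) -> EnsembleSet:
    """Draw Q ensembles of N distinct single units, uniformly at random.

    Units within an ensemble are distinct; ensembles may overlap.  The draw
    is deterministic under a fixed seed.
    """
    ids = np.asarray(single_unit_ids)
    if ids.size < n_units:
        raise ValueError(f"need >= {n_units} single units, got {ids.size}")
    if q < 1:
        raise ValueError("q must be >= 1")
    rng = np.random.default_rng(seed)
    ensembles = [np.sort(rng.choice(ids, size=n_units, replace=False)) for _ in range(q)]
    return EnsembleSet(ensembles=ensembles, seed=seed)
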