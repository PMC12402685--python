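"""Epoched-ERP data model and epoch-level operations.

Voltages are microvolts everywhere; time axes are milliseconds relative to
word onset.  The canonical grid is a 1200 ms epoch sampled at 500 Hz taken
as 600 samples on [-200, +998] ms (half-open end), which after decimation
to 250 Hz becomes 300 samples on the same interval.

The experimental design is a fully-crossed 2x2x2: Accent (L1/L2),
Constraint (HC/LC: high vs. low sentence constraint) and Face (speaker
face cued or not).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

ACCENT_LEVELS = ("L1", "L2")
CONSTRAINT_LEVELS = ("HC", "LC")
FACE_LEVELS = ("Face", "NoFace")

#: canonical order of the 8 design cells: (accent, constraint, face)
DESIGN_CELLS = tuple(itertools.product(ACCENT_LEVELS, CONSTRAINT_LEVELS, FACE_LEVELS))


class DatasetError(ValueError):
    """Raised for malformed epochs, montages or design tables."""


@dataclass(frozen=True)
class Montage:
    """Electrode labels with a 2D layout (arbitrary units, topography only)."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_labels, 2)

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(labels)) != len(labels):
            raise DatasetError("montage labels must be unique")
        if pos.shape != (len(labels), 2):
            raise DatasetError(f"positions must be ({len(labels)}, 2), got {pos.shape}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, labels) -> np.ndarray:
        """Indices of ``labels`` in this montage; unknown labels raise."""
        missing = [lab for lab in labels if lab not in self.labels]
        if missing:
            raise DatasetError(f"electrodes not in montage: {missing}")
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([lookup[lab] for lab in labels], dtype=int)


@dataclass(frozen=True)
class ClusterSpec:
    """A named electrode cluster."""

    name: str
    electrodes: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        if not self.electrodes:
            raise DatasetError(f"cluster {self.name!r} is empty")


#: centro-parietal cluster used for posterior components (P3b, N400)
CENTRO_PARIETAL = ClusterSpec("centro_parietal", ("Cz", "C3", "C4", "Pz", "P3", "P4"))
#: fronto-central cluster used for anterior components (N1, P2, P3a)
FRONTO_CENTRAL = ClusterSpec("fronto_central", ("Cz", "C3", "C4", "Fz", "F3", "F4"))

CLUSTERS = {c.name: c for c in (CENTRO_PARIETAL, FRONTO_CENTRAL)}

#: a priori N400 analysis window, ms (closed at both ends at sample resolution)
N400_WINDOW = (300.0, 500.0)

_EVENT_COLUMNS = ("accent", "constraint", "face", "item")


def _check_time_axis(times: np.ndarray, sfreq: float) -> None:
    if times.ndim != 1 or times.size < 2:
        raise DatasetError("time axis must be 1D with at least two samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise DatasetError("time axis must be strictly increasing")
    expected = 1000.0 / sfreq
    if not np.allclose(steps, expected, rtol=0, atol=1e-6):
        raise DatasetError(
            f"time axis step must be uniform and equal 1000/sfreq = {expected} ms"
        )


def _check_events(events: pd.DataFrame) -> pd.DataFrame:
    events = events.reset_index(drop=True)
    for col in _EVENT_COLUMNS:
        if col not in events.columns:
            raise DatasetError(f"events table missing column {col!r}")
    bad_accent = set(events["accent"]) - set(ACCENT_LEVELS)
    bad_constraint = set(events["constraint"]) - set(CONSTRAINT_LEVELS)
    bad_face = set(events["face"]) - set(FACE_LEVELS)
    if bad_accent or bad_constraint or bad_face:
        raise DatasetError(
            f"unknown condition levels: accent={bad_accent}, "
            f"constraint={bad_constraint}, face={bad_face}"
        )
    return events


@dataclass
class EpochsSet:
    """Single-trial voltages for one participant.

    voltages : (n_trials, n_electrodes, n_times) array, microvolts
    events   : one row per trial with accent/constraint/face/item labels
    """

    participant_id: str
    voltages: np.ndarray
    events: pd.DataFrame
    times: np.ndarray  # ms
    sfreq: float
    montage: Montage
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.voltages.ndim != 3:
            raise DatasetError("voltages must be (trials, electrodes, times)")
        _check_time_axis(self.times, self.sfreq)
        if self.voltages.shape[2] != self.times.size:
            raise DatasetError("voltage time dimension does not match time axis")
        if self.voltages.shape[1] != len(self.montage):
            raise DatasetError(
                f"electrode count {self.voltages.shape[1]} does not match "
                f"montage size {len(self.montage)}"
            )
        self.events = _check_events(self.events)
        if len(self.events) != self.voltages.shape[0]:
            raise DatasetError("events table length does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]


@dataclass
class AverageSet:
    """Trial-averaged waveforms: participants x design cells x electrodes x times."""

    voltages: np.ndarray
    participants: tuple[str, ...]
    cells: pd.DataFrame  # one row per cell slot: accent, constraint, face
    times: np.ndarray
    sfreq: float
    montage: Montage
    trial_counts: np.ndarray  # (n_participants, n_cells)
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_counts = np.asarray(self.trial_counts, dtype=int)
        n_p, n_c, n_e, n_t = self.voltages.shape
        _check_time_axis(self.times, self.sfreq)
        if n_t != self.times.size:
            raise DatasetError("voltage time dimension does not match time axis")
        if n_e != len(self.montage):
            raise DatasetError("electrode count does not match montage")
        if len(self.participants) != n_p or len(self.cells) != n_c:
            raise DatasetError("participants/cells index does not match voltages")
        if self.trial_counts.shape != (n_p, n_c):
            raise DatasetError("trial_counts must be (participants, cells)")
        if np.any(self.trial_counts < 1):
            raise DatasetError("every design cell needs at least one trial")

    def cell_index(self, accent=None, constraint=None, face=None) -> np.ndarray:
        """Boolean mask over cell slots matching the given levels."""
        mask = np.ones(len(self.cells), dtype=bool)
        for col, val in (("accent", accent), ("constraint", constraint), ("face", face)):
            if val is not None:
                mask &= (self.cells[col] == val).to_numpy()
        return mask


def _window_mask(times: np.ndarray, window, closed: bool) -> np.ndarray:
    lo, hi = float(window[0]), float(window[1])
    if lo < times[0] - 1e-9 or hi > times[-1] + (0 if closed else 1000.0):
        raise DatasetError(f"window {window} outside time axis [{times[0]}, {times[-1]}]")
    if closed:
        mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    else:
        mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
    if not mask.any():
        raise DatasetError(f"window {window} contains no samples")
    return mask


def baseline_correct(data, window=(-200.0, 0.0)):
    """Subtract the mean over a pre-stimulus window, per trial and electrode.

    The window is half-open, [start, stop), so the default [-200, 0) covers
    the 200 ms pre-stimulus interval and excludes the onset sample.  Works
    on :class:`EpochsSet` and :class:`AverageSet`.
    """
    mask = _window_mask(data.times, window, closed=False)
    base = data.voltages[..., mask].mean(axis=-1, keepdims=True)
    return replace(
        data,
        voltages=data.voltages - base,
        provenance=data.provenance + (f"baseline[{window[0]},{window[1]})",),
    )


def resample(data, target_rate: float):
    """Polyphase resampling to a lower rate (e.g. 500 -> 250 Hz).

    Constant signals are preserved exactly (linear padding); sub-Nyquist
    content passes with unity gain up to filter ripple.  Upsampling is out
    of scope and raises.
    """
    if target_rate >= data.sfreq:
        raise DatasetError(
            f"target rate {target_rate} must be below original {data.sfreq} Hz"
        )
    from fractions import Fraction

    frac = Fraction(target_rate / data.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(data.voltages, up, down, axis=-1, padtype="line")
    n_out = out.shape[-1]
    new_times = data.times[0] + np.arange(n_out) * (1000.0 / target_rate)
    return replace(
        data,
        voltages=out,
        times=new_times,
        sfreq=float(target_rate),
        provenance=data.provenance + (f"resample[{target_rate}Hz]",),
    )


def average_trials(epochs_sets: list[EpochsSet]) -> AverageSet:
    """Per-participant, per-design-cell arithmetic mean over trials."""
    if not epochs_sets:
        raise DatasetError("no participants given")
    ref = epochs_sets[0]
    cells = pd.DataFrame(DESIGN_CELLS, columns=["accent", "constraint", "face"])
    n_c = len(cells)
    n_p = len(epochs_sets)
    out = np.empty((n_p, n_c, len(ref.montage), ref.times.size))
    counts = np.zeros((n_p, n_c), dtype=int)
    participants = []
    for i, es in enumerate(epochs_sets):
        if es.montage.labels != ref.montage.labels or es.times.size != ref.times.size:
            raise DatasetError("all participants must share montage and time axis")
        participants.append(es.participant_id)
        for j, (acc, con, fac) in enumerate(DESIGN_CELLS):
            sel = (
                (es.events["accent"] == acc)
                & (es.events["constraint"] == con)
                & (es.events["face"] == fac)
            ).to_numpy()
            if not sel.any():
                raise DatasetError(
                    f"participant {es.participant_id!r} has no trials in cell "
                    f"({acc}, {con}, {fac})"
                )
            out[i, j] = es.voltages[sel].mean(axis=0)
            counts[i, j] = int(sel.sum())
    return AverageSet(
        voltages=out,
        participants=tuple(participants),
        cells=cells,
        times=ref.times.copy(),
        sfreq=ref.sfreq,
        montage=ref.montage,
        trial_counts=counts,
        provenance=ref.provenance + ("average_trials",),
    )


def window_mean(
    epochs_sets,
    window=N400_WINDOW,
    cluster: ClusterSpec = CENTRO_PARIETAL,
) -> pd.DataFrame:
    """Single-trial mean voltage in a time window over an electrode cluster.

    Returns one row per trial with participant/item/condition labels and the
    amplitude in microvolts.  The window is closed at both ends at sample
    resolution (the N400 default [300, 500] includes both endpoint samples).
    """
    if isinstance(epochs_sets, EpochsSet):
        epochs_sets = [epochs_sets]
    rows = []
    for es in epochs_sets:
        idx = es.montage.index(cluster.electrodes)
        mask = _window_mask(es.times, window, closed=True)
        # window-then-cluster ordering; order is irrelevant for nested means
        amp = es.voltages[:, idx][..., mask].mean(axis=-1).mean(axis=-1)
        tab = es.events[list(_EVENT_COLUMNS)].copy()
        tab.insert(0, "participant", es.participant_id)
        tab["amplitude"] = amp
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def cell_window_mean(
    averages: AverageSet,
    window=N400_WINDOW,
    cluster: ClusterSpec = CENTRO_PARIETAL,
    accent: str | None = None,
) -> pd.DataFrame:
    """Window/cluster mean of averaged waveforms, one value per participant x cell.

    With ``accent`` given, restricts to that accent's four Constraint x Face
    cells — the layout consumed by the factor-wise repeated-measures ANOVA.
    """
    idx = averages.montage.index(cluster.electrodes)
    mask = _window_mask(averages.times, window, closed=True)
    amp = averages.voltages[:, :, idx][..., mask].mean(axis=-1).mean(axis=-1)
    recs = []
    cmask = averages.cell_index(accent=accent)
    for j in np.flatnonzero(cmask):
        cell = averages.cells.iloc[j]
        for i, pid in enumerate(averages.participants):
            recs.append(
                dict(
                    participant=pid,
                    accent=cell["accent"],
                    constraint=cell["constraint"],
                    face=cell["face"],
                    amplitude=amp[i, j],
                )
            )
    return pd.DataFrame.from_records(recs)
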