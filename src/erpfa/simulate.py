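"""Ground-truth synthetic ERP generator.

Emulates the study design — 42 participants, 2x2x2 design (Accent x
Constraint x Face), 42 trials per cell, 60 scalp channels at 500 Hz —
with multi-component ERPs, participant random effects and temporally
autocorrelated noise, so every pipeline stage can be tested against a
known truth without any recorded data.

Each component k contributes

    (base_k + effect_k(cell) + u_ik) * g_k(t) * h_k(e)

with g_k a unit-peak temporal kernel (Gaussian, or half-Gaussian rise with
a plateau for slow waves), h_k a unit-peak Gaussian over 2D layout
distance from the component's topography centre, and u_ik per-participant
amplitude deviations.  Noise is AR(1) in time (coefficient referenced to
250 Hz and converted to the simulated rate); averaged waveforms carry
noise scaled by 1/sqrt(trials per cell).

Identical seeds produce bit-identical datasets.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .dataset import (
    DESIGN_CELLS,
    AverageSet,
    DatasetError,
    EpochsSet,
    Montage,
)
from .lmm import SUM_CODES, term_label

__all__ = [
    "ELECTRODES_60",
    "default_montage",
    "subset_montage",
    "ComponentSpec",
    "GroundTruth",
    "scenario_preset",
    "recovery_truth",
    "simulate_averages",
    "simulate_trials",
    "simulate_trial_table",
]

#: the 60 active scalp electrodes of the recording setup
ELECTRODES_60 = (
    "Fp1", "Fp2", "AF3", "AF4", "AF7", "AF8", "AFz",
    "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "Fz",
    "FT7", "FT8", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FCz",
    "T7", "T8", "C1", "C2", "C3", "C4", "C5", "C6", "Cz",
    "TP7", "TP8", "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "CPz",
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "Pz",
    "PO3", "PO4", "PO7", "PO8", "POz", "O1", "O2", "Oz",
)


@functools.lru_cache(maxsize=1)
def default_montage() -> Montage:
    """The 60-channel montage with a 2D azimuthal-equidistant layout.

    3D positions come from the standard 10-05 template; the 2D projection
    maps the vertex to the origin with the nose up (positive y anterior).
    Units are radians of polar angle — arbitrary for topography rendering.
    """
    import mne

    std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    pos2 = np.zeros((len(ELECTRODES_60), 2))
    for i, lab in enumerate(ELECTRODES_60):
        p = np.asarray(ch_pos[lab], dtype=float)
        p = p / np.linalg.norm(p)
        theta = np.arccos(np.clip(p[2], -1, 1))
        r_xy = np.hypot(p[0], p[1])
        if r_xy < 1e-12:
            pos2[i] = (0.0, 0.0)
        else:
            pos2[i] = (theta * p[0] / r_xy, theta * p[1] / r_xy)
    return Montage(ELECTRODES_60, pos2)


def subset_montage(montage: Montage, labels) -> Montage:
    idx = montage.index(labels)
    return Montage(tuple(labels), montage.positions[idx])


@dataclass(frozen=True)
class ComponentSpec:
    """One synthetic ERP component and its condition-effect table.

    ``effects`` maps design cells to amplitude offsets (microvolts): keys
    are either (constraint, face) pairs — applied in both accents — or
    full (accent, constraint, face) triples.
    """

    name: str
    peak_latency_ms: float
    width_ms: float
    center: str = "Cz"  # electrode label of the topography centre
    spatial_spread: float = 0.8  # layout units (radians)
    amplitude: float = 5.0  # signed base amplitude, uV
    effects: dict = field(default_factory=dict)
    participant_sd: float = 1.0
    kernel: str = "gaussian"  # or "slow" (half-Gaussian rise + plateau)

    def __post_init__(self):
        if self.width_ms <= 0:
            raise DatasetError(f"component {self.name}: width must be positive")
        if abs(self.amplitude) > 20:
            raise DatasetError(f"component {self.name}: |base amplitude| > 20 uV")
        for v in self.effects.values():
            if not np.isfinite(v):
                raise DatasetError(f"component {self.name}: non-finite effect offset")

    def effect(self, accent, constraint, face) -> float:
        if (accent, constraint, face) in self.effects:
            return float(self.effects[(accent, constraint, face)])
        return float(self.effects.get((constraint, face), 0.0))


@dataclass(frozen=True)
class GroundTruth:
    """Full parameter record of a synthetic dataset."""

    components: tuple[ComponentSpec, ...]
    n_participants: int = 42
    trials_per_cell: int = 42
    noise_sd: float = 25.0  # single-trial AR(1) noise sd, uV
    ar_coef: float = 0.9  # AR(1) coefficient per sample at 250 Hz
    item_sd: float = 0.5
    sfreq: float = 500.0
    n_times: int = 600
    tmin_ms: float = -200.0
    montage: Montage | None = None
    seed: int | None = None

    def resolve_montage(self) -> Montage:
        return self.montage if self.montage is not None else default_montage()

    @property
    def times(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_times) * (1000.0 / self.sfreq)


def scenario_preset(name: str) -> GroundTruth:
    """Named study-condition presets.

    L1_like : P2 / P3b / N400 / slow wave with Constraint and
              Constraint x Face effects (posterior positivity for
              predictable words, centro-parietal negativity for
              unpredictable ones).
    L2_like : N1 with a Face effect, fronto-central P3a, N400 with Face
              and Constraint effects, slow wave.
    null    : same component inventory as L1_like with all condition
              effects zeroed — the type-I-error scenario.
    """
    hc, lc = "HC", "LC"
    if name == "L1_like":
        comps = (
            ComponentSpec("N1", 92, 25, "Cz", 0.6, -2.0),
            ComponentSpec(
                "P2", 180, 40, "FCz", 0.7, 3.0,
                effects={(hc, "Face"): -0.5, (hc, "NoFace"): -0.5,
                         (lc, "Face"): 0.5, (lc, "NoFace"): 0.5},
            ),
            ComponentSpec(
                "P3b", 300, 55, "Pz", 0.8, 4.0,
                effects={(hc, "Face"): 1.2, (hc, "NoFace"): 0.6,
                         (lc, "Face"): -0.9, (lc, "NoFace"): -0.9},
            ),
            ComponentSpec(
                "N400", 400, 60, "CPz", 0.8, -3.0,
                effects={(hc, "Face"): 1.35, (hc, "NoFace"): 0.95,
                         (lc, "Face"): -1.15, (lc, "NoFace"): -1.15},
            ),
            ComponentSpec(
                "SW", 700, 120, "Pz", 0.9, -2.0, kernel="slow",
                effects={(hc, "Face"): 0.8, (hc, "NoFace"): 0.8,
                         (lc, "Face"): -0.8, (lc, "NoFace"): -0.8},
            ),
        )
    elif name == "L2_like":
        comps = (
            ComponentSpec(
                "N1", 116, 25, "Cz", 0.6, -2.0,
                effects={(hc, "Face"): 0.45, (lc, "Face"): 0.45,
                         (hc, "NoFace"): -0.45, (lc, "NoFace"): -0.45},
            ),
            ComponentSpec(
                "P2", 208, 40, "FCz", 0.7, 3.0,
                effects={(hc, "Face"): -0.6, (hc, "NoFace"): -0.6,
                         (lc, "Face"): 0.6, (lc, "NoFace"): 0.6},
            ),
            ComponentSpec(
                "P3a", 280, 50, "FCz", 0.7, 3.5,
                effects={(hc, "Face"): -0.5, (hc, "NoFace"): -0.5,
                         (lc, "Face"): 0.5, (lc, "NoFace"): 0.5},
            ),
            ComponentSpec(
                "N400", 430, 60, "CPz", 0.8, -3.0,
                effects={(hc, "Face"): 1.5, (hc, "NoFace"): 1.1,
                         (lc, "Face"): -1.1, (lc, "NoFace"): -1.5},
            ),
            ComponentSpec(
                "SW", 720, 120, "CPz", 0.9, -2.0, kernel="slow",
                effects={(hc, "Face"): 0.9, (hc, "NoFace"): 0.9,
                         (lc, "Face"): -0.9, (lc, "NoFace"): -0.9},
            ),
        )
    elif name == "null":
        comps = (
            ComponentSpec("N1", 92, 25, "Cz", 0.6, -2.0),
            ComponentSpec("P2", 180, 40, "FCz", 0.7, 3.0),
            ComponentSpec("P3b", 300, 55, "Pz", 0.8, 4.0),
            ComponentSpec("N400", 400, 60, "CPz", 0.8, -3.0),
        )
    else:
        raise DatasetError(f"unknown scenario preset {name!r}")
    # single-trial noise for already-cleaned epochs: chosen so that trial
    # averages are signal-dominated, the regime in which the variance-
    # explained filter isolates components from residual noise factors
    return GroundTruth(components=comps, noise_sd=6.0, ar_coef=0.35)


#: 20-electrode layout for scaled-down recovery runs: both analysis
#: clusters plus a spread of peripheral sites
RECOVERY_ELECTRODES = (
    "Cz", "C3", "C4", "Pz", "P3", "P4", "Fz", "F3", "F4",
    "Fp1", "Fp2", "F7", "F8", "T7", "T8", "CPz", "P7", "P8", "POz", "Oz",
)


def recovery_truth(
    n_components: int = 4,
    n_participants: int = 12,
    electrodes=RECOVERY_ELECTRODES,
    noise_sd: float = 8.0,
    ar_coef: float = 0.2,
    constraint_delta: float = 1.0,
) -> GroundTruth:
    """Well-separated, equal-strength components for recovery experiments.

    Component 2 (when present) carries a Constraint contrast of
    ``constraint_delta`` microvolts (HC minus LC cell means) so amplitude
    recovery can be scored against a known effect.  The noise is much
    weaker and less autocorrelated than in the scenario presets: recovery
    scoring needs the retained solution to be signal-dominated (the
    variance-explained filter separates signal from noise factors), which
    mirrors the high explained-variance regime of clean trial-averaged
    ERPs rather than raw single-trial noise.
    """
    if not 1 <= n_components <= 8:
        raise DatasetError("n_components must be in 1..8")
    peaks = np.linspace(100.0, 800.0, n_components)
    # spatially distinct centres so component score vectors stay separable
    centers = ["Fz", "Pz", "T7", "T8", "Fp1", "Oz", "C3", "C4"][:n_components]
    amps = [6.0, -6.0, 5.5, -5.5, 6.0, 5.0, -5.0, 5.5][:n_components]
    comps = []
    for k in range(n_components):
        effects = {}
        if k == 1 and constraint_delta:
            d = constraint_delta / 2.0
            effects = {("HC", "Face"): d, ("HC", "NoFace"): d,
                       ("LC", "Face"): -d, ("LC", "NoFace"): -d}
        comps.append(
            ComponentSpec(
                f"C{k + 1}",
                peak_latency_ms=peaks[k],
                width_ms=55.0,
                center=centers[k],
                spatial_spread=0.55,
                amplitude=amps[k],
                effects=effects,
                participant_sd=1.5,
            )
        )
    return GroundTruth(
        components=tuple(comps),
        n_participants=n_participants,
        montage=subset_montage(default_montage(), electrodes),
        noise_sd=noise_sd,
        ar_coef=ar_coef,
    )


# ---------------------------------------------------------------------------
# kernels and noise


def _temporal_kernels(truth: GroundTruth) -> np.ndarray:
    t = truth.times
    G = np.empty((len(truth.components), t.size))
    for k, c in enumerate(truth.components):
        g = np.exp(-0.5 * ((t - c.peak_latency_ms) / c.width_ms) ** 2)
        if c.kernel == "slow":
            g[t >= c.peak_latency_ms] = 1.0  # plateau after the rise
        elif c.kernel != "gaussian":
            raise DatasetError(f"unknown kernel {c.kernel!r}")
        G[k] = g
    return G


def _spatial_kernels(truth: GroundTruth, montage: Montage) -> np.ndarray:
    H = np.empty((len(truth.components), len(montage)))
    for k, c in enumerate(truth.components):
        if isinstance(c.center, str):
            # the centre is a layout coordinate; it need not be a recorded site
            ref = montage if c.center in montage.labels else default_montage()
            center = ref.positions[ref.index([c.center])[0]]
        else:
            center = np.asarray(c.center, dtype=float)
        d2 = ((montage.positions - center) ** 2).sum(axis=1)
        H[k] = np.exp(-0.5 * d2 / c.spatial_spread**2)
    return H


def _ar_coef_at(truth: GroundTruth, sfreq: float) -> float:
    # ar_coef is referenced to 250 Hz; convert to the per-sample value
    return float(truth.ar_coef ** (250.0 / sfreq))


def _ar1_noise(rng, shape, sd, rho):
    """Stationary AR(1) noise along the last axis."""
    e = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=shape)
    e[..., 0] = rng.normal(0.0, sd, size=shape[:-1])
    return signal.lfilter([1.0], [1.0, -rho], e, axis=-1)


def _cell_amplitudes(truth: GroundTruth, rng):
    """(n_participants, 8 cells, K) noiseless component amplitudes + u draws."""
    K = len(truth.components)
    u = np.column_stack(
        [rng.normal(0.0, c.participant_sd, size=truth.n_participants)
         for c in truth.components]
    )
    amp = np.empty((truth.n_participants, len(DESIGN_CELLS), K))
    for j, (acc, con, fac) in enumerate(DESIGN_CELLS):
        for k, c in enumerate(truth.components):
            amp[:, j, k] = c.amplitude + c.effect(acc, con, fac) + u[:, k]
    return amp, u


# ---------------------------------------------------------------------------
# simulators


def simulate_averages(truth: GroundTruth, seed: int | None = None):
    """Trial-averaged waveforms for the full design, plus the truth record.

    Average-level noise has sd noise_sd / sqrt(trials_per_cell), AR(1) in
    time.  Returns (AverageSet, record) where record carries the per
    participant x cell x component amplitudes and the kernels.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    montage = truth.resolve_montage()
    G = _temporal_kernels(truth)
    H = _spatial_kernels(truth, montage)
    amp, u = _cell_amplitudes(truth, rng)
    # signal[i,j,e,t] = sum_k amp[i,j,k] H[k,e] G[k,t]
    sig = np.einsum("ijk,ke,kt->ijet", amp, H, G)
    sd_avg = truth.noise_sd / np.sqrt(truth.trials_per_cell)
    rho = _ar_coef_at(truth, truth.sfreq)
    noise = _ar1_noise(rng, sig.shape, sd_avg, rho)
    cells = pd.DataFrame(DESIGN_CELLS, columns=["accent", "constraint", "face"])
    avg = AverageSet(
        voltages=sig + noise,
        participants=tuple(f"P{i + 1:02d}" for i in range(truth.n_participants)),
        cells=cells,
        times=truth.times,
        sfreq=truth.sfreq,
        montage=montage,
        trial_counts=np.full((truth.n_participants, len(cells)), truth.trials_per_cell),
        provenance=("synthetic:averages", f"seed={seed}"),
    )
    record = dict(
        amplitudes=amp,
        participant_effects=u,
        temporal_kernels=G,
        spatial_kernels=H,
        cells=cells,
        noise_sd_average=sd_avg,
        seed=seed,
    )
    return avg, record


def _item_step(times: np.ndarray) -> np.ndarray:
    # smooth post-onset step so item offsets survive baseline correction
    return 1.0 / (1.0 + np.exp(-(times - 25.0) / 12.0))


def simulate_trials(truth: GroundTruth, seed: int | None = None):
    """Single-trial epochs per participant, plus the trial-level truth table.

    Items follow the design structure: 8 x trials_per_cell items, each seen
    once per participant, rotated over cells across participants (Latin-
    square style), with item intercepts constant across participants.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    montage = truth.resolve_montage()
    G = _temporal_kernels(truth)
    H = _spatial_kernels(truth, montage)
    amp, u = _cell_amplitudes(truth, rng)
    expect = np.einsum("ijk,ke,kt->ijet", amp, H, G)
    n_items = len(DESIGN_CELLS) * truth.trials_per_cell
    delta = rng.normal(0.0, truth.item_sd, size=n_items)
    step = _item_step(truth.times)
    rho = _ar_coef_at(truth, truth.sfreq)
    items = np.arange(n_items)
    epochs_sets, truth_rows = [], []
    for i in range(truth.n_participants):
        cell_of_item = (items + i) % len(DESIGN_CELLS)
        noise = _ar1_noise(
            rng, (n_items, len(montage), truth.n_times), truth.noise_sd, rho
        )
        volts = expect[i, cell_of_item] + delta[:, None, None] * step + noise
        ev = pd.DataFrame(
            {
                "accent": [DESIGN_CELLS[c][0] for c in cell_of_item],
                "constraint": [DESIGN_CELLS[c][1] for c in cell_of_item],
                "face": [DESIGN_CELLS[c][2] for c in cell_of_item],
                "item": items,
            }
        )
        pid = f"P{i + 1:02d}"
        epochs_sets.append(
            EpochsSet(
                participant_id=pid,
                voltages=volts,
                events=ev,
                times=truth.times,
                sfreq=truth.sfreq,
                montage=montage,
                provenance=("synthetic:trials", f"seed={seed}"),
            )
        )
        for j, it in enumerate(items):
            truth_rows.append(
                dict(
                    participant=pid,
                    item=int(it),
                    accent=ev["accent"][j],
                    constraint=ev["constraint"][j],
                    face=ev["face"][j],
                    item_offset=delta[it],
                )
            )
    return epochs_sets, pd.DataFrame(truth_rows)


def simulate_trial_table(
    n_participants: int = 42,
    trials_per_cell: int = 42,
    fixed: dict | None = None,
    intercept: float = 0.5,
    re_sd=(1.3, 0.6, 0.2, 0.5),  # participant intercept, slope, corr, item
    resid_sd: float = 6.2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trial-level N400 amplitudes drawn directly from a mixed-model structure.

    ``fixed`` maps ladder term names (e.g. ``"constraint"``,
    ``"constraint:face"``) to sum-coded coefficients; unlisted terms are
    zero, so the generating model is whichever rung of the ladder the dict
    spans.  Random effects follow the shared ladder structure: correlated
    participant intercepts/Constraint slopes and item intercepts; residuals
    are iid Gaussian.  Defaults mirror the study scale (42 participants,
    42 trials per cell, residual sd 6.2 uV).
    """
    fixed = dict(fixed or {})
    rng = np.random.default_rng(seed)
    sd0, sd1, corr, sd_item = re_sd
    cov = np.array(
        [[sd0**2, corr * sd0 * sd1], [corr * sd0 * sd1, sd1**2]]
    )
    u = rng.multivariate_normal([0.0, 0.0], cov, size=n_participants)
    n_items = len(DESIGN_CELLS) * trials_per_cell
    delta = rng.normal(0.0, sd_item, size=n_items)
    items = np.arange(n_items)
    rows = []
    for i in range(n_participants):
        cell_of_item = (items + i) % len(DESIGN_CELLS)
        for it, c in zip(items, cell_of_item):
            acc, con, fac = DESIGN_CELLS[c]
            rows.append((f"P{i + 1:02d}", int(it), acc, con, fac))
    tab = pd.DataFrame(rows, columns=["participant", "item", "accent", "constraint", "face"])
    codes = {f: tab[f].map(SUM_CODES[f]).to_numpy() for f in SUM_CODES}
    mu = np.full(len(tab), float(intercept))
    for term, beta in fixed.items():
        x = np.ones(len(tab))
        for f in term.split(":"):
            x = x * codes[f]
        mu += beta * x
    pidx = tab["participant"].str.slice(1).astype(int).to_numpy() - 1
    mu += u[pidx, 0] + u[pidx, 1] * codes["constraint"]
    mu += delta[tab["item"].to_numpy()]
    tab["amplitude"] = mu + rng.normal(0.0, resid_sd, size=len(tab))
    tab.attrs["fixed"] = {term_label(t): b for t, b in fixed.items()}
    tab.attrs["intercept"] = intercept
    return tab
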