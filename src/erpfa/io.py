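"""Readers and writers for epoched ERP data.

Two on-disk forms are supported:

* the package container — a long-format delimited table (participant, trial,
  condition fields, electrode, time_ms, voltage_uV) plus a JSON sidecar with
  montage, sampling rate, units and provenance; round-trips bit-identically;
* BrainVision triplets (.vhdr/.vmrk/.eeg), read through :mod:`mne`, with a
  user-supplied mapping from stimulus codes to design cells.  A minimal
  BrainVision writer (IEEE float32, multiplexed) is provided so the reader
  can be exercised without recorded data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DatasetError, EpochsSet, Montage

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_brainvision",
    "read_brainvision_epochs",
    "UnknownEventError",
]


class UnknownEventError(DatasetError):
    """A stimulus code in the recording has no entry in the event mapping."""


# ---------------------------------------------------------------------------
# package container


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_epochs(epochs: EpochsSet, path) -> Path:
    """Write the long-format container and its JSON sidecar."""
    path = Path(path)
    n_tr, n_el, n_t = epochs.voltages.shape
    trial = np.repeat(np.arange(n_tr), n_el * n_t)
    elec = np.tile(np.repeat(np.arange(n_el), n_t), n_tr)
    time = np.tile(epochs.times, n_tr * n_el)
    tab = pd.DataFrame(
        {
            "participant": epochs.participant_id,
            "trial": trial,
            "accent": epochs.events["accent"].to_numpy()[trial],
            "constraint": epochs.events["constraint"].to_numpy()[trial],
            "face": epochs.events["face"].to_numpy()[trial],
            "item": epochs.events["item"].to_numpy()[trial],
            "electrode": np.asarray(epochs.montage.labels)[elec],
            "time_ms": time,
            "voltage_uV": epochs.voltages.ravel(),
        }
    )
    tab.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "participant_id": epochs.participant_id,
        "sfreq": epochs.sfreq,
        "units": "uV",
        "montage": {
            "labels": list(epochs.montage.labels),
            "positions": epochs.montage.positions.tolist(),
        },
        "provenance": list(epochs.provenance),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_container(path: Path) -> EpochsSet:
    sidecar = json.loads(_sidecar_path(path).read_text())
    tab = pd.read_csv(path, float_precision="round_trip")
    montage = Montage(
        tuple(sidecar["montage"]["labels"]),
        np.asarray(sidecar["montage"]["positions"], dtype=float),
    )
    trials = np.sort(tab["trial"].unique())
    times = np.sort(tab["time_ms"].unique())
    n_el = len(montage)
    # rebuild the (trial, electrode, time) cube from the long table
    elec_idx = montage.index(tab["electrode"])
    trial_idx = tab["trial"].to_numpy()
    t_lookup = {t: i for i, t in enumerate(times)}
    time_idx = tab["time_ms"].map(t_lookup).to_numpy()
    volts = np.empty((trials.size, n_el, times.size))
    volts[trial_idx, elec_idx, time_idx] = tab["voltage_uV"].to_numpy()
    ev = (
        tab.drop_duplicates("trial")
        .sort_values("trial")[["accent", "constraint", "face", "item"]]
        .reset_index(drop=True)
    )
    return EpochsSet(
        participant_id=str(sidecar["participant_id"]),
        voltages=volts,
        events=ev,
        times=times.astype(float),
        sfreq=float(sidecar["sfreq"]),
        montage=montage,
        provenance=tuple(sidecar.get("provenance", ())),
    )


def read_epochs(path, format: str = "container", **kwargs) -> EpochsSet:
    """Read epochs from the package container or a BrainVision header."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if format == "container":
        return _read_container(path)
    if format == "brainvision":
        return read_brainvision_epochs(path, **kwargs)
    raise DatasetError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# BrainVision

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by erpfa

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_ch}
SamplingInterval={interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channels}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
{markers}
"""


def write_brainvision(path_base, data, sfreq, ch_names, events) -> Path:
    """Write a continuous recording as a BrainVision triplet.

    data    : (n_channels, n_samples) array, microvolts
    events  : iterable of (sample_index, code) stimulus markers (0-based)

    Returns the .vhdr path.
    """
    path_base = Path(path_base)
    data = np.asarray(data, dtype=np.float32)
    if data.shape[0] != len(ch_names):
        raise DatasetError("channel count does not match data")
    stem = path_base.name
    channels = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(ch_names)
    )
    vhdr = path_base.with_suffix(".vhdr")
    vhdr.write_text(
        _VHDR_TEMPLATE.format(
            stem=stem,
            n_ch=len(ch_names),
            interval=int(round(1e6 / sfreq)),
            channels=channels,
        ),
        encoding="utf-8",
    )
    lines = ["Mk1=New Segment,,1,1,0,00000000000000000000"]
    for k, (sample, code) in enumerate(events, start=2):
        lines.append(f"Mk{k}=Stimulus,S{int(code):>3d},{int(sample) + 1},1,0")
    path_base.with_suffix(".vmrk").write_text(
        _VMRK_TEMPLATE.format(stem=stem, markers="\n".join(lines)), encoding="utf-8"
    )
    # multiplexed: sample-major, channel-minor
    data.T.astype("<f4").tofile(path_base.with_suffix(".eeg"))
    return vhdr


def read_brainvision_epochs(
    vhdr_path,
    event_map: dict,
    montage: Montage | None = None,
    tmin_ms: float = -200.0,
    n_samples: int | None = None,
) -> EpochsSet:
    """Epoch a BrainVision recording around mapped stimulus markers.

    event_map maps integer stimulus codes to dicts with keys
    ``accent``/``constraint``/``face`` (and optionally ``item``).  Codes
    present in the recording but absent from the map raise
    :class:`UnknownEventError` naming the code.  Items default to the trial
    order index when the map does not provide them.
    """
    import mne

    vhdr_path = Path(vhdr_path)
    if not vhdr_path.exists():
        raise DatasetError(f"no such file: {vhdr_path}")
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    if montage is not None:
        extra = [ch for ch in raw.ch_names if ch not in montage.labels]
        missing = [lab for lab in montage.labels if lab not in raw.ch_names]
        if extra or missing:
            raise DatasetError(
                f"channel/montage mismatch: unexpected {extra}, missing {missing}"
            )
        labels = montage.labels
    else:
        labels = tuple(raw.ch_names)
        montage = Montage(labels, np.zeros((len(labels), 2)))

    events, event_id = mne.events_from_annotations(raw, verbose="error")
    code_of = {}
    for desc, eid in event_id.items():
        if "Stimulus" in desc and "S" in desc:
            code_of[eid] = int(desc.split("S")[-1].strip())
    keep, rows = [], []
    for onset, _, eid in events:
        if eid not in code_of:
            continue  # segment markers etc.
        code = code_of[eid]
        if code not in event_map:
            raise UnknownEventError(
                f"stimulus code {code} has no entry in the event mapping"
            )
        keep.append((onset, 0, eid))
        rows.append(dict(event_map[code]))
    if not keep:
        raise DatasetError("no mapped stimulus events found")
    if n_samples is None:
        n_samples = int(round(1.2 * sfreq))
    tmin = tmin_ms / 1000.0
    tmax = tmin + (n_samples - 1) / sfreq
    ep = mne.Epochs(
        raw,
        np.asarray(keep),
        tmin=tmin,
        tmax=tmax,
        baseline=None,
        preload=True,
        verbose="error",
        picks=list(labels),
    )
    volts = ep.get_data(picks=list(labels), units="uV")
    ev = pd.DataFrame(rows)
    if "item" not in ev.columns:
        ev["item"] = np.arange(len(ev))
    times = ep.times * 1000.0
    return EpochsSet(
        participant_id=str(vhdr_path.stem),
        voltages=volts,
        events=ev,
        times=times,
        sfreq=sfreq,
        montage=montage,
        provenance=(f"brainvision:{vhdr_path.name}",),
    )
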