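"""Recording I/O: plain-text fixture format and EDF/BDF readers.

The fixture format is a pair of files sharing a stem:

* ``<stem>.csv`` — samples x channels numeric matrix with a header row
  of channel names,
* ``<stem>.json`` — sidecar ``{"fs": ..., "channel_names": [...],
  "events": [{"onset_sample": ..., "target_hz": ...}, ...]}``.

Real recordings (EDF / BioSemi BDF) are read through MNE; events are
taken from the sidecar-style annotations when present, otherwise the
event table is left empty and must be supplied by the caller.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocessing import EEGRecording, Event

__all__ = ["write_fixture", "read_fixture", "read_edf", "read_bdf"]


def _paths(stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    return stem.with_suffix(".csv"), stem.with_suffix(".json")


def write_fixture(rec: EEGRecording, stem: str | Path) -> tuple[Path, Path]:
    """Write a recording as ``<stem>.csv`` + ``<stem>.json``; returns the paths."""
    csv_path, json_path = _paths(stem)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_names))
    df.to_csv(csv_path, index=False, float_format="%.8g")
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "events": [
            {"onset_sample": ev.onset_sample, "target_hz": ev.target_hz}
            for ev in rec.events
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_fixture(stem: str | Path) -> EEGRecording:
    """Read a fixture-format recording written by :func:`write_fixture`."""
    csv_path, json_path = _paths(stem)
    if not csv_path.exists() or not json_path.exists():
        raise ConfigurationError(f"fixture pair {csv_path} / {json_path} not found")
    sidecar = json.loads(json_path.read_text())
    df = pd.read_csv(csv_path)
    names = sidecar.get("channel_names", list(df.columns))
    return EEGRecording(
        data=df[names].to_numpy().T,
        fs=float(sidecar["fs"]),
        channel_names=tuple(names),
        events=tuple(
            Event(int(e["onset_sample"]), float(e["target_hz"]))
            for e in sidecar.get("events", [])
        ),
    )


def _from_mne_raw(raw, events) -> EEGRecording:
    data = raw.get_data()
    return EEGRecording(
        data=np.asarray(data),
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        events=tuple(events),
    )


def _events_from_annotations(raw) -> list[Event]:
    """Annotations whose description parses as a frequency become events."""
    out = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        try:
            hz = float(str(desc).removesuffix("Hz").strip())
        except ValueError:
            continue
        out.append(Event(int(round(onset * raw.info["sfreq"])), hz))
    return out


def read_edf(path: str | Path, picks=None) -> EEGRecording:
    """Read an EDF recording via MNE into an :class:`EEGRecording`."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if picks is not None:
        raw = raw.pick(picks)
    return _from_mne_raw(raw, _events_from_annotations(raw))


def read_bdf(path: str | Path, picks=None) -> EEGRecording:
    """Read a BioSemi BDF recording via MNE into an :class:`EEGRecording`."""
    import mne

    raw = mne.io.read_raw_bdf(str(path), preload=True, verbose="error")
    if picks is not None:
        raw = raw.pick(picks)
    return _from_mne_raw(raw, _events_from_annotations(raw))
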