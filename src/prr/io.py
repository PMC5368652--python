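"""Flat-file session layout.

A session directory holds plain-text files only:

    lfp.csv, respiration.csv   two columns (time_s, value); '#'-prefixed
                               header lines carry fs and the channel label
    immobility.csv             start_s, end_s per line
    spikes/unit<k>.csv         one spike time (s) per line
    waveforms/unit<k>.csv      '# waveform_fs=...' header, one sample per line
    truth.json                 full ground-truth parameter record (synthetic
                               sessions only)

All floats are written with 10 significant digits so a write/read round
trip reproduces values exactly at that precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .core import EpochSet, Signal
from .units import SpikeTrain

__all__ = ["write_session", "read_session", "write_signal", "read_signal",
           "write_epochs", "read_epochs"]

_FMT = "%.10g"


def write_signal(path: Path, signal: Signal) -> None:
    header = f"fs={signal.fs!r} label={signal.label} t0={signal.t0!r}"
    data = np.column_stack([signal.times, signal.samples])
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=header)


def read_signal(path: Path) -> Signal:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    fs = float(meta["fs"])
    t0 = float(meta.get("t0", "0"))
    return Signal(data[:, 1], fs, label=meta.get("label", ""), t0=t0)


def write_epochs(path: Path, epochs: EpochSet) -> None:
    arr = np.array(list(epochs), dtype=float).reshape(-1, 2)
    np.savetxt(path, arr, fmt=_FMT, delimiter=",", header="start_s,end_s")


def read_epochs(path: Path) -> EpochSet:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # empty file is valid
        arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if arr.size == 0:
        return EpochSet(())
    return EpochSet(tuple((float(a), float(b)) for a, b in arr))


def write_session(session, out_dir: str | Path) -> Path:
    """Write a session (e.g. a SyntheticSession) as a flat-file directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_signal(out / "lfp.csv", session.lfp)
    write_signal(out / "respiration.csv", session.respiration)
    write_epochs(out / "immobility.csv", session.immobility)
    (out / "spikes").mkdir(exist_ok=True)
    (out / "waveforms").mkdir(exist_ok=True)
    for k, train in enumerate(session.spike_trains):
        np.savetxt(out / "spikes" / f"unit{k}.csv", train.spike_times_s,
                   fmt=_FMT, header=f"unit_id={train.unit_id}")
        if train.waveform is not None:
            np.savetxt(out / "waveforms" / f"unit{k}.csv", train.waveform,
                       fmt=_FMT, header=f"waveform_fs={train.waveform_fs!r}")
    if getattr(session, "truth", None) is not None:
        truth = asdict(session.truth)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=list)
    return out


def _read_header_value(path: Path, key: str, default: str | None = None) -> str | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if tok.startswith(key + "="):
                    return tok.split("=", 1)[1]
    return default


def read_session(in_dir: str | Path) -> dict:
    """Read a flat-file session directory.

    Returns a dict with keys ``lfp``, ``respiration`` (may be None),
    ``immobility``, ``spike_trains`` and ``truth`` (raw dict or None).
    """
    d = Path(in_dir)
    lfp = read_signal(d / "lfp.csv")
    resp_path = d / "respiration.csv"
    respiration = read_signal(resp_path) if resp_path.exists() else None
    imm_path = d / "immobility.csv"
    immobility = read_epochs(imm_path) if imm_path.exists() else EpochSet(
        ((lfp.t0, lfp.t0 + lfp.duration),))
    trains = []
    spikes_dir = d / "spikes"
    if spikes_dir.is_dir():
        for f in sorted(spikes_dir.glob("unit*.csv"),
                        key=lambda p: int(p.stem[4:])):
            times = np.loadtxt(f, comments="#", ndmin=1)
            unit_id = _read_header_value(f, "unit_id", f.stem)
            wf_path = d / "waveforms" / f.name
            waveform = None
            wf_fs = 30000.0
            if wf_path.exists():
                waveform = np.loadtxt(wf_path, comments="#", ndmin=1)
                wf_fs = float(_read_header_value(wf_path, "waveform_fs", "30000"))
            trains.append(SpikeTrain(unit_id, times, waveform, wf_fs))
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return {
        "lfp": lfp,
        "respiration": respiration,
        "immobility": immobility,
        "spike_trains": trains,
        "truth": truth,
    }
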