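"""Sweep-bundle I/O.

A cell is stored as a directory::

    <cell_id>/
        meta.json                 # cell metadata, protocols, sweep index
        <protocol>_<sweep#>.csv   # time_s,response,command (one per sweep)

The on-disk format is columnar text: transparent, diffable and
language-neutral. Numeric samples are written with 9 significant digits,
which round-trips the float64 values used in analysis to well below
recording precision; a save→load→save cycle is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .core import (
    CellRecording,
    FormatError,
    ProtocolSpec,
    StimEvent,
    Sweep,
    ValidationError,
)

_FMT = "%.9g"
_META_NAME = "meta.json"


def _sweep_filename(kind: str, index: int) -> str:
    return f"{kind}_{index:03d}.csv"


def save_recording(rec: CellRecording, path: str | Path) -> Path:
    """Write a :class:`CellRecording` as a sweep bundle directory.

    Returns the bundle directory (``path``). An existing bundle at the
    same path is overwritten file-by-file.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    sweep_index = []
    for kind in sorted(rec.sweep_sets):
        for i, sw in enumerate(rec.sweep_sets[kind]):
            fname = _sweep_filename(kind, i)
            arr = np.column_stack([sw.time, sw.response, sw.command])
            np.savetxt(
                root / fname, arr, fmt=_FMT, delimiter=",",
                header="time_s,response,command", comments="",
            )
            sweep_index.append({
                "protocol": kind,
                "index": i,
                "file": fname,
                "mode": sw.mode,
                "sampling_rate_Hz": sw.sampling_rate,
                "n_samples": sw.n_samples,
                "units": {"response": "mV" if sw.mode == "cc" else "pA",
                          "command": "pA" if sw.mode == "cc" else "mV"},
                "events": [asdict(ev) for ev in sw.t0_events],
                "meta": _jsonable(sw.meta),
            })

    meta = {
        "format": "spinephys-bundle-v1",
        "cell_id": rec.cell_id,
        "group": rec.group,
        "junction_potential_mV": rec.junction_potential,
        "drug_condition": rec.drug_condition,
        "protocols": {k: asdict(p) for k, p in sorted(rec.protocols.items())},
        "sweeps": sweep_index,
        "meta": _jsonable(rec.meta),
    }
    with open(root / _META_NAME, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return root


def load_recording(path: str | Path) -> CellRecording:
    """Read a sweep bundle written by :func:`save_recording`.

    Raises :class:`FormatError` if the metadata sidecar is missing and
    :class:`ValidationError`, naming the sweep file, if a sweep file is
    truncated or inconsistent with the sidecar.
    """
    root = Path(path)
    meta_path = root / _META_NAME
    if not meta_path.is_file():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)

    sweep_sets: dict[str, list[Sweep]] = {}
    for entry in meta["sweeps"]:
        fpath = root / entry["file"]
        if not fpath.is_file():
            raise ValidationError(f"sweep file missing: {entry['file']}")
        try:
            arr = np.loadtxt(fpath, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as exc:
            raise ValidationError(
                f"sweep file {entry['file']} is malformed: {exc}"
            ) from exc
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] != entry["n_samples"]:
            raise ValidationError(
                f"sweep file {entry['file']} truncated: expected "
                f"{entry['n_samples']} samples, found {arr.shape[0]}"
            )
        sw = Sweep(
            sampling_rate=entry["sampling_rate_Hz"],
            response=arr[:, 1],
            command=arr[:, 2],
            mode=entry["mode"],
            t0_events=[StimEvent(**ev) for ev in entry["events"]],
            meta=dict(entry["meta"]),
        )
        sweep_sets.setdefault(entry["protocol"], []).append(sw)

    protocols = {
        k: ProtocolSpec(**{**p, "step_amplitudes": tuple(p["step_amplitudes"])})
        for k, p in meta["protocols"].items()
    }
    return CellRecording(
        cell_id=meta["cell_id"],
        group=meta["group"],
        sweep_sets=sweep_sets,
        protocols=protocols,
        junction_potential=meta["junction_potential_mV"],
        drug_condition=meta["drug_condition"],
        meta=dict(meta.get("meta", {})),
    )


def _jsonable(obj):
    """Coerce metadata to JSON-serializable plain types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)
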