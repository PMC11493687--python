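"""Portable on-disk containers: npz arrays + JSON sidecar, montage CSV.

Every saved object ``<stem>`` becomes ``<stem>.npz`` (the arrays) and
``<stem>.json`` (a structured-text sidecar with provenance: model name,
preset, seed, spacing, units). Montages are plain CSV with a header row
``label,x,y,z`` in meters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .headmodel import ElectrodeMontage, Leadfield, SourceSpace
from .inverse import InverseOperator
from .simulate import EpochSet


def save_container(stem, arrays: dict, sidecar: dict) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez(stem.with_suffix(".npz"), **arrays)
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return stem


def load_container(stem) -> tuple[dict, dict]:
    stem = Path(stem)
    npz = stem.with_suffix(".npz")
    js = stem.with_suffix(".json")
    if not npz.exists() or not js.exists():
        raise InvalidArgumentError(f"container {stem} is missing its .npz or .json part")
    with np.load(npz, allow_pickle=False) as f:
        arrays = {k: f[k] for k in f.files}
    return arrays, json.loads(js.read_text())


def write_montage_csv(path, montage: ElectrodeMontage) -> None:
    lines = ["label,x,y,z"]
    for lab, p in zip(montage.labels, montage.positions):
        lines.append(f"{lab},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage_csv(path) -> ElectrodeMontage:
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0].strip().lower() != "label,x,y,z":
        raise InvalidArgumentError("montage CSV must start with header 'label,x,y,z'")
    labels, rows = [], []
    for line in text[1:]:
        parts = line.split(",")
        if len(parts) != 4:
            raise InvalidArgumentError(f"malformed montage row: {line!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return ElectrodeMontage(tuple(labels), np.array(rows), montage_id=Path(path).stem)


def save_leadfield(stem, lf: Leadfield) -> Path:
    return save_container(
        stem,
        {"gain": lf.gain},
        {
            "kind": "leadfield",
            "reference": lf.reference,
            "units": "V per A*m",
            "source_space_id": lf.source_space_id,
            "montage_id": lf.montage_id,
            "shell_model_id": lf.shell_model_id,
        },
    )


def load_leadfield(stem) -> Leadfield:
    arrays, meta = load_container(stem)
    return Leadfield(
        gain=arrays["gain"],
        reference=meta["reference"],
        source_space_id=meta["source_space_id"],
        montage_id=meta["montage_id"],
        shell_model_id=meta["shell_model_id"],
    )


def save_source_space(stem, src: SourceSpace) -> Path:
    return save_container(
        stem,
        {"positions": src.positions},
        {
            "kind": "source_space",
            "units": "m",
            "nominal_spacing_mm": src.nominal_spacing_mm,
            "per_dipole_volume_mm3": src.per_dipole_volume_mm3,
            "source_space_id": src.source_space_id,
        },
    )


def load_source_space(stem) -> SourceSpace:
    arrays, meta = load_container(stem)
    return SourceSpace(
        positions=arrays["positions"],
        nominal_spacing_mm=meta["nominal_spacing_mm"],
        per_dipole_volume_mm3=meta["per_dipole_volume_mm3"],
        source_space_id=meta["source_space_id"],
    )


def save_epochs(stem, epochs: EpochSet) -> Path:
    arrays = {"data": epochs.data, "condition": epochs.condition.astype("U")}
    if epochs.clean_erp is not None:
        arrays["clean_erp"] = epochs.clean_erp
    return save_container(
        stem,
        arrays,
        {
            "kind": "epochs",
            "fs": epochs.fs,
            "t0_ms": epochs.t0_ms,
            "montage_id": epochs.montage_id,
            "units": "V (arbitrary overall scale)",
            **{k: v for k, v in epochs.meta.items()},
        },
    )


def load_epochs(stem) -> EpochSet:
    arrays, meta = load_container(stem)
    return EpochSet(
        data=arrays["data"],
        condition=arrays["condition"],
        fs=float(meta["fs"]),
        t0_ms=float(meta["t0_ms"]),
        montage_id=meta.get("montage_id", ""),
        clean_erp=arrays.get("clean_erp"),
        meta={k: v for k, v in meta.items() if k not in {"kind", "fs", "t0_ms", "montage_id", "units"}},
    )


def save_inverse_operator(stem, op: InverseOperator) -> Path:
    arrays = {"kernel": op.kernel, "weights": op.weights}
    if op.whitener is not None:
        arrays["whitener"] = op.whitener
    return save_container(
        stem,
        arrays,
        {
            "kind": "inverse_operator",
            "alpha": op.alpha,
            "alpha_eff": op.alpha_eff,
            "iterations_run": op.iterations_run,
            "converged": op.converged,
            "source_space_id": op.source_space_id,
            "montage_id": op.montage_id,
            "shell_model_id": op.shell_model_id,
        },
    )


def load_inverse_operator(stem) -> InverseOperator:
    arrays, meta = load_container(stem)
    return InverseOperator(
        kernel=arrays["kernel"],
        weights=arrays["weights"],
        alpha=float(meta["alpha"]),
        alpha_eff=float(meta["alpha_eff"]),
        iterations_run=int(meta["iterations_run"]),
        converged=bool(meta["converged"]),
        whitener=arrays.get("whitener"),
        source_space_id=meta["source_space_id"],
        montage_id=meta["montage_id"],
        shell_model_id=meta["shell_model_id"],
    )


def evoked_to_csv(path, evoked, time_axis_ms=None) -> None:
    """Condition-averaged sensor data as plain CSV (rows: time; cols: sensors)."""
    import pandas as pd

    arr = np.asarray(evoked)
    t = time_axis_ms if time_axis_ms is not None else np.arange(arr.shape[1])
    df = pd.DataFrame(arr.T, index=np.asarray(t))
    df.index.name = "time_ms"
    df.to_csv(path)
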