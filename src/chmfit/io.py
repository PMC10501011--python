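"""Dataset, configuration and model I/O.

Geometries travel as (extended) XYZ with ``key=value`` metadata on the
comment line (``energy=... unit=hartree``); run configuration is YAML
with a strict schema; fitted models serialize to JSON.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import yaml

from .chm import CHMFeaturizer, CHMModel, Dataset, NonlinearParams, PIPModel
from .constants import CM_TO_HARTREE
from .molsys import AtomTyping, Configuration, InputError
from .pipbasis import basis_from_dict, basis_to_dict

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_dataset",
    "write_dataset",
    "typing_from_dict",
    "typing_to_dict",
    "load_run_config",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# XYZ


def _parse_comment(line: str) -> dict:
    meta = {}
    for token in line.split():
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    return meta


def read_xyz(path) -> list[tuple[Configuration, dict]]:
    """Read a (multi-frame) XYZ file; returns [(config, metadata)]."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise InputError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + n >= len(lines) + 1:
            raise InputError(f"{path}:{i + 1}: truncated frame")
        meta = _parse_comment(lines[i + 1])
        elements = []
        coords = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise InputError(f"{path}:{i + 3 + j}: malformed atom line")
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append(
            (Configuration(elements=tuple(elements), coords=np.array(coords)),
             meta)
        )
        i += 2 + n
    return frames


def write_xyz(path, frames) -> None:
    """Write [(config, metadata-dict)] as extended XYZ."""
    out = []
    for config, meta in frames:
        out.append(str(config.n_atoms))
        out.append(" ".join(f"{k}={v}" for k, v in meta.items()))
        for e, (x, y, z) in zip(config.elements, config.coords):
            out.append(f"{e} {x:.12f} {y:.12f} {z:.12f}")
    Path(path).write_text("\n".join(out) + "\n")


def write_dataset(path, dataset: Dataset, unit: str = "hartree",
                  provenance: dict | None = None) -> None:
    frames = []
    for config, e_h in zip(dataset.configs, dataset.energies):
        e = e_h if unit == "hartree" else e_h / CM_TO_HARTREE
        meta = {"energy": f"{e:.12e}", "unit": unit}
        if provenance:
            meta.update(provenance)
        frames.append((config, meta))
    write_xyz(path, frames)


def read_dataset(path) -> Dataset:
    frames = read_xyz(path)
    configs = []
    energies = []
    for k, (config, meta) in enumerate(frames):
        if "energy" not in meta:
            raise InputError(f"{path}: frame {k} missing energy= metadata")
        unit = meta.get("unit", "hartree")
        e = float(meta["energy"])
        if unit in ("cm-1", "cm^-1"):
            e *= CM_TO_HARTREE
        elif unit != "hartree":
            raise InputError(f"{path}: frame {k}: unknown unit {unit!r}")
        configs.append(config)
        energies.append(e)
    return Dataset(configs=configs, energies=np.array(energies))


# ---------------------------------------------------------------------------
# typing / run configuration


def typing_from_dict(d: dict) -> AtomTyping:
    return AtomTyping(
        classes={k: tuple(v) for k, v in d["classes"].items()},
        populations={k: float(v) for k, v in d.get("populations", {}).items()},
        formal_charge=int(d.get("formal_charge", 0)),
        exponents={k: float(v) for k, v in d.get("exponents", {}).items()},
    )


def typing_to_dict(t: AtomTyping) -> dict:
    return {
        "classes": {k: list(v) for k, v in t.classes.items()},
        "populations": dict(t.populations),
        "formal_charge": t.formal_charge,
        "exponents": dict(t.exponents),
    }


_SCHEMA = {
    "system": {"elements", "classes", "populations", "formal_charge",
               "exponents"},
    "basis": {"M", "patterns", "per_class_constant", "term_cap"},
    "fit": {"model", "charge_weight", "d0", "t0", "tau_rs", "alpha",
            "optimize", "search", "seed"},
    "data": {"preset", "system", "kinetic_energy", "steps", "timestep",
             "stride", "seed", "restraints", "train", "test", "unit"},
    "output": {"unit", "model", "report", "basis", "train", "test"},
}


def load_run_config(path) -> dict:
    """Load and schema-check a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: top level must be a mapping")
    for block, content in cfg.items():
        if block not in _SCHEMA:
            raise InputError(f"{path}: unknown block {block!r}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise InputError(f"{path}: block {block!r} must be a mapping")
        for key in content:
            if key not in _SCHEMA[block]:
                raise InputError(
                    f"{path}: unknown key {block}.{key}"
                )
    return cfg


# ---------------------------------------------------------------------------
# models


def save_model(path, model, provenance: dict | None = None) -> None:
    if isinstance(model, CHMModel):
        f = model.featurizer
        payload = {
            "kind": "chm",
            "typing": typing_to_dict(f.typing),
            "n_atoms": f.n_atoms,
            "M": f.M,
            "patterns": f.patterns,
            "coeffs": model.coeffs.tolist(),
            "nlparams": {
                "d0": model.nlparams.d0,
                "t0": model.nlparams.t0,
                "alpha": dict(model.nlparams.alpha),
                "tau_rs": model.nlparams.tau_rs,
            },
            "energy_offset": model.energy_offset,
        }
    elif isinstance(model, PIPModel):
        payload = {
            "kind": "pip",
            "typing": None,
            "basis": basis_to_dict(model.basis),
            "coeffs": model.coeffs.tolist(),
            "d0": model.d0,
            "energy_offset": model.energy_offset,
        }
    else:
        raise InputError(f"cannot serialize model of type {type(model)}")
    payload["provenance"] = dict(provenance or {})
    payload["provenance"].setdefault("written", time.strftime("%Y-%m-%dT%H:%M:%S"))
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path, typing: AtomTyping | None = None):
    data = json.loads(Path(path).read_text())
    if data["kind"] == "chm":
        t = typing_from_dict(data["typing"])
        featurizer = CHMFeaturizer(
            t, data["n_atoms"], data["M"], patterns=data["patterns"]
        )
        nl = data["nlparams"]
        return CHMModel(
            featurizer=featurizer,
            coeffs=np.array(data["coeffs"]),
            nlparams=NonlinearParams(
                d0=nl["d0"], t0=nl["t0"], alpha=nl["alpha"],
                tau_rs=nl["tau_rs"],
            ),
            energy_offset=float(data["energy_offset"]),
        )
    if data["kind"] == "pip":
        if typing is None:
            raise InputError("loading a PIP model requires the atom typing")
        basis = basis_from_dict(data["basis"], typing)
        return PIPModel(
            basis=basis,
            coeffs=np.array(data["coeffs"]),
            d0=float(data["d0"]),
            energy_offset=float(data["energy_offset"]),
        )
    raise InputError(f"unknown model kind {data['kind']!r}")
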