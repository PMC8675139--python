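"""Extended-XYZ datasets and the model archive.

Extended XYZ: multi-frame, with a key=value comment line carrying the total
energy (``energy=...``, eV) and a ``Properties=`` descriptor declaring the
per-atom columns (species, positions in A, optionally forces in eV/A).
Numeric fields are written with 17 significant digits so round trips are
bit-faithful.

The model archive is a structured JSON text file with a format version and a
SHA-256 checksum over the payload; loading verifies both, and a loaded
model's predictions are bitwise equal to the saved model's.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .bbasis import BasisSet, SymmetricBasisFunction
from .potential import LinearACEModel
from .radial import OrthogonalPolynomialSet, RadialSpec
from .structures import AtomicConfiguration

__all__ = ["read_extxyz", "write_extxyz", "save_model", "load_model"]

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------


def _parse_comment(line: str) -> dict:
    """key=value pairs; values may be double-quoted and contain spaces."""
    out: dict[str, str] = {}
    i, n = 0, len(line)
    while i < n:
        while i < n and line[i].isspace():
            i += 1
        start = i
        while i < n and line[i] not in "= \t":
            i += 1
        key = line[start:i]
        if not key:
            break
        if i < n and line[i] == "=":
            i += 1
            if i < n and line[i] == '"':
                i += 1
                v0 = i
                while i < n and line[i] != '"':
                    i += 1
                val = line[v0:i]
                i += 1
            else:
                v0 = i
                while i < n and not line[i].isspace():
                    i += 1
                val = line[v0:i]
            out[key] = val
        else:
            out[key] = "T"
    return out


def _parse_properties(desc: str):
    parts = desc.split(":")
    if len(parts) % 3 != 0:
        raise ValueError(f"malformed Properties descriptor {desc!r}")
    cols = []
    for k in range(0, len(parts), 3):
        name, kind, width = parts[k], parts[k + 1], int(parts[k + 2])
        cols.append((name, kind, width))
    return cols


def read_extxyz(path) -> list[AtomicConfiguration]:
    """Parse a (multi-frame) extended-XYZ file into labeled configurations."""
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[AtomicConfiguration] = []
    ln = 0
    frame = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nat = int(lines[ln].strip())
        except ValueError:
            raise ValueError(
                f"{path}: frame {frame}, line {ln + 1}: expected atom count, "
                f"got {lines[ln]!r}"
            ) from None
        if ln + 2 + nat > len(lines):
            raise ValueError(
                f"{path}: frame {frame}: atom count {nat} at line {ln + 1} "
                f"exceeds remaining file"
            )
        info = _parse_comment(lines[ln + 1])
        cols = _parse_properties(info.get("Properties", "species:S:1:pos:R:3"))
        elements, positions, forces = [], [], []
        has_forces = any(name == "forces" for name, _, _ in cols)
        for a in range(nat):
            fields = lines[ln + 2 + a].split()
            want = sum(w for _, _, w in cols)
            if len(fields) < want:
                raise ValueError(
                    f"{path}: frame {frame}, line {ln + 3 + a}: expected "
                    f"{want} fields, got {len(fields)}"
                )
            pos_f = 0
            for name, kind, width in cols:
                chunk = fields[pos_f : pos_f + width]
                pos_f += width
                if name == "species":
                    elements.append(chunk[0])
                elif name == "pos":
                    positions.append([float(v) for v in chunk])
                elif name == "forces":
                    forces.append([float(v) for v in chunk])
        config = AtomicConfiguration(
            elements,
            np.array(positions),
            energy=float(info["energy"]) if "energy" in info else None,
            forces=np.array(forces) if has_forces else None,
        )
        extra = {
            k: v
            for k, v in info.items()
            if k not in ("Properties", "energy", "Lattice", "pbc")
        }
        config.info.update(extra)
        configs.append(config)
        ln += 2 + nat
        frame += 1
    return configs


def write_extxyz(configs, path) -> None:
    """Standard-conformant multi-frame extended XYZ, 17 significant digits."""
    path = Path(path)
    out = []
    for config in configs:
        has_f = config.forces is not None
        props = "species:S:1:pos:R:3" + (":forces:R:3" if has_f else "")
        comment = f"Properties={props}"
        if config.energy is not None:
            comment += f" energy={config.energy:.17g}"
        for k, v in config.info.items():
            if isinstance(v, (str, int, float, bool, np.floating, np.integer)):
                sv = f"{v:.17g}" if isinstance(v, (float, np.floating)) else str(v)
                if " " in sv:
                    sv = f'"{sv}"'
                comment += f" {k}={sv}"
        out.append(str(config.n_atoms))
        out.append(comment)
        for a in range(config.n_atoms):
            row = [f"{config.elements[a]:2s}"] + [
                f"{v:.17g}" for v in config.positions[a]
            ]
            if has_f:
                row += [f"{v:.17g}" for v in config.forces[a]]
            out.append(" ".join(row))
    path.write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------


def _model_payload(model: LinearACEModel) -> dict:
    return {
        "elements": list(model.elements),
        "radial": model.radial.to_dict(),
        "polys": model.polys.to_dict(),
        "pair_polys": model.pair_polys.to_dict(),
        "basis": {
            "functions": [f.to_dict() for f in model.basis.functions],
            "provenance": model.basis.provenance,
        },
        "coefficients": [[f"{v:.17g}" for v in row] for row in model.coefficients],
        "pair_coefficients": [
            [f"{v:.17g}" for v in row] for row in model.pair_coefficients
        ],
        "one_body": {z: f"{v:.17g}" for z, v in model.one_body.items()},
        "one_body_strategy": model.one_body_strategy,
        "energy_shift": f"{model.energy_shift:.17g}",
    }


def save_model(model: LinearACEModel, path, diagnostics: dict | None = None) -> None:
    payload = _model_payload(model)
    blob = json.dumps(payload, sort_keys=True).encode()
    doc = {
        "format_version": FORMAT_VERSION,
        "checksum_sha256": hashlib.sha256(blob).hexdigest(),
        "payload": payload,
        "diagnostics": diagnostics or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path) -> LinearACEModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive format_version={doc.get('format_version')!r}"
        )
    payload = doc["payload"]
    blob = json.dumps(payload, sort_keys=True).encode()
    if hashlib.sha256(blob).hexdigest() != doc.get("checksum_sha256"):
        raise ValueError("model archive checksum mismatch (file corrupted?)")
    basis = BasisSet(
        elements=tuple(payload["elements"]),
        functions=[
            SymmetricBasisFunction.from_dict(d) for d in payload["basis"]["functions"]
        ],
        provenance=payload["basis"]["provenance"],
    )
    model = LinearACEModel(
        elements=tuple(payload["elements"]),
        radial=RadialSpec.from_dict(payload["radial"]),
        polys=OrthogonalPolynomialSet.from_dict(payload["polys"]),
        pair_polys=OrthogonalPolynomialSet.from_dict(payload["pair_polys"]),
        basis=basis,
        coefficients=np.array(
            [[float(v) for v in row] for row in payload["coefficients"]]
        ),
        pair_coefficients=np.array(
            [[float(v) for v in row] for row in payload["pair_coefficients"]]
        ),
        one_body={z: float(v) for z, v in payload["one_body"].items()},
        one_body_strategy=payload["one_body_strategy"],
        energy_shift=float(payload["energy_shift"]),
    )
    return model
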