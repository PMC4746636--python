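"""Readers and writers for trajectories, tables, and reports.

Formats are deliberately plain text: XYZ for trajectories (one element tag
per bead kind, comment line carrying time and box), optional PDB snapshots
for molecular viewers, CSV tables with ``# key: value`` header metadata, and
JSON reports.  Every writer embeds the config hash, seed and package version
it was given; read(write(x)) round-trips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .forcefield import BeadKind, SystemState
from .dynamics import Trajectory

__all__ = [
    "config_hash",
    "write_xyz",
    "read_xyz",
    "write_pdb_snapshot",
    "write_csv",
    "read_csv",
    "write_json_report",
]

#: element tag per bead kind for XYZ/PDB output
KIND_TO_ELEMENT = {
    BeadKind.DNA_SPECIFIC_LOW: "C",
    BeadKind.DNA_SPECIFIC_HIGH: "N",
    BeadKind.MYB_SITE: "O",
    BeadKind.DIMER_SITE: "S",
    BeadKind.BASIC_SITE: "P",
    BeadKind.CORE: "H",
}
ELEMENT_TO_KIND = {v: k for k, v in KIND_TO_ELEMENT.items()}


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _frame_records(state: SystemState):
    for i, p in enumerate(state.dna.positions):
        yield KIND_TO_ELEMENT[BeadKind(int(state.dna.kinds[i]))], p
    for prot in state.proteins:
        yield KIND_TO_ELEMENT[BeadKind.CORE], prot.center
        for kind, sp in zip(prot.site_kinds, prot.site_positions()):
            yield KIND_TO_ELEMENT[BeadKind(int(kind))], sp


def write_xyz(path: str | Path, trajectory: Trajectory, metadata: dict | None = None) -> None:
    """Write a trajectory as multi-frame XYZ.

    The comment line of each frame carries ``time_ns`` and ``box``; the
    first frame's comment also carries the metadata (seed, config hash,
    version) as ``key=value`` pairs.
    """
    meta = dict(metadata or {})
    meta.setdefault("version", __version__)
    with open(path, "w") as fh:
        for fi, (frame, t) in enumerate(zip(trajectory.frames, trajectory.times_ns)):
            records = list(_frame_records(frame))
            fh.write(f"{len(records)}\n")
            comment = f"time_ns={t:.6f} box={frame.box_side:.6f}"
            if fi == 0:
                comment += "".join(f" {k}={v}" for k, v in meta.items())
            fh.write(comment + "\n")
            for tag, p in records:
                fh.write(f"{tag} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_xyz(path: str | Path) -> tuple[list[np.ndarray], list[np.ndarray], list[float], list[float]]:
    """Read a multi-frame XYZ file.

    Returns (positions per frame, element kinds per frame, times, boxes).
    Malformed records raise ``ValueError`` naming the offending line and
    frame.
    """
    frames, kinds, times, boxes = [], [], [], []
    lines = Path(path).read_text().splitlines()
    i, frame_index = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 + n >= len(lines) + 1:
            raise ValueError(f"truncated XYZ: frame {frame_index} at line {i + 1} needs {n} atoms")
        comment = lines[i + 1]
        fields = dict(kv.split("=", 1) for kv in comment.split() if "=" in kv)
        times.append(float(fields.get("time_ns", 0.0)))
        boxes.append(float(fields.get("box", 0.0)))
        pos = np.empty((n, 3))
        kin = np.empty(n, dtype=np.int8)
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) != 4:
                raise ValueError(f"line {i + 3 + j}: malformed atom record {lines[i + 2 + j]!r}")
            kin[j] = ELEMENT_TO_KIND.get(parts[0], BeadKind.CORE)
            pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(pos)
        kinds.append(kin)
        i += 2 + n
        frame_index += 1
    return frames, kinds, times, boxes


def write_pdb_snapshot(path: str | Path, state: SystemState) -> None:
    """Single-frame PDB for molecular viewers (HETATM records, one chain)."""
    with open(path, "w") as fh:
        fh.write(f"REMARK   generated by telocompact {__version__}\n")
        if state.box_side > 0:
            b = state.box_side
            fh.write(f"CRYST1{b:9.3f}{b:9.3f}{b:9.3f}  90.00  90.00  90.00 P 1           1\n")
        serial = 1
        for tag, p in _frame_records(state):
            fh.write(
                f"HETATM{serial:5d} {tag:<4s}BED A{min(serial, 9999):4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00          {tag:>2s}\n"
            )
            serial += 1
        fh.write("END\n")


def write_csv(path: str | Path, table: pd.DataFrame, metadata: dict | None = None) -> None:
    """CSV with ``# key: value`` header metadata lines (version included)."""
    meta = dict(metadata or {})
    meta.setdefault("version", __version__)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        table.to_csv(fh, index=False)


def read_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a metadata-headed CSV; columns are header-keyed, order-free."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        table = pd.read_csv(fh)
    return table, meta


def write_json_report(path: str | Path, payload: dict, metadata: dict | None = None) -> None:
    meta = dict(metadata or {})
    meta.setdefault("version", __version__)
    out = {"metadata": meta, **payload}
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
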