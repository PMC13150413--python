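"""Plain and extended XYZ trajectory I/O.

Extended XYZ stores, per frame, an atom count line, a comment line carrying
``key=value`` fields (``Lattice="ax ay az bx by bz cx cy cz"`` with row cell
vectors, ``pbc="T T T"``, optionally ``Time=…`` in fs and a ``Properties``
descriptor), and one line per atom. Only ``species`` and ``pos`` columns are
interpreted; extra per-atom columns are ignored on read and not written.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import ParseError
from .trajectory import CellGeometry, Frame, Trajectory

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(comment)}


def _parse_cell(fields: dict[str, str]) -> CellGeometry | None:
    if "Lattice" not in fields:
        return None
    try:
        nums = [float(x) for x in fields["Lattice"].split()]
        vectors = np.array(nums, dtype=float).reshape(3, 3)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"unreadable Lattice field {fields['Lattice']!r}") from exc
    if "pbc" in fields:
        periodic = tuple(tok.upper() in ("T", "TRUE", "1")
                         for tok in fields["pbc"].split())
        if len(periodic) != 3:
            raise ParseError(f"pbc field {fields['pbc']!r} needs three flags")
    else:
        periodic = (True, True, True)
    return CellGeometry(vectors, periodic)


def _species_pos_columns(fields: dict[str, str]) -> tuple[int, int]:
    """Column offsets of the species and position entries from Properties."""
    props = fields.get("Properties", "species:S:1:pos:R:3")
    col = 0
    s_col = p_col = None
    parts = props.split(":")
    for name, _kind, width in zip(parts[0::3], parts[1::3], parts[2::3]):
        w = int(width)
        if name == "species":
            s_col = col
        elif name == "pos":
            p_col = col
        col += w
    if s_col is None or p_col is None:
        raise ParseError(f"Properties descriptor {props!r} lacks species/pos")
    return s_col, p_col


def iter_frames(path):
    """Yield (Frame, per-frame CellGeometry or None) from an (ext)XYZ file."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(
                f"frame {frame_index}: atom-count line {lines[pos]!r} is not "
                "an integer") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        fields = _parse_comment(comment)
        cell = _parse_cell(fields)
        s_col, p_col = _species_pos_columns(fields)
        symbols: list[str] = []
        coords = np.empty((n_atoms, 3))
        for k in range(n_atoms):
            row = pos + 2 + k
            if row >= len(lines):
                raise ParseError(
                    f"frame {frame_index}: declares {n_atoms} atoms but lists {k}")
            toks = lines[row].split()
            try:
                symbols.append(toks[s_col])
                coords[k] = [float(toks[p_col + a]) for a in range(3)]
            except (IndexError, ValueError) as exc:
                raise ParseError(
                    f"frame {frame_index}: atom line {k} malformed: "
                    f"{lines[row]!r}") from exc
        time = float(fields["Time"]) if "Time" in fields else None
        yield Frame(coords, symbols, time=time), cell
        pos += 2 + n_atoms
        frame_index += 1


def read_trajectory(path, frame_skip: int = 1, timestep: float = 1.0) -> Trajectory:
    """Read an (extended-)XYZ trajectory, keeping frames 0, frame_skip,
    2·frame_skip, …

    ``timestep`` is the time between *consecutive stored frames in the file*
    (fs); the returned trajectory's timestep is ``timestep * frame_skip``.
    Cells read from Lattice fields; all-nonperiodic when absent.
    """
    if frame_skip < 1:
        raise ParseError("frame_skip must be >= 1")
    frames: list[Frame] = []
    shared_cell: CellGeometry | None = None
    per_frame_cells = False
    for k, (frame, cell) in enumerate(iter_frames(path)):
        if k % frame_skip:
            continue
        if cell is not None:
            if shared_cell is None:
                shared_cell = cell
            elif not np.allclose(cell.vectors, shared_cell.vectors) or \
                    cell.periodic != shared_cell.periodic:
                per_frame_cells = True
                frame.cell = cell
        frames.append(frame)
    if not frames:
        raise ParseError(f"no frames read from {path}")
    if shared_cell is None:
        shared_cell = CellGeometry.nonperiodic()
    if per_frame_cells:
        for fr in frames:
            if fr.cell is None:
                fr.cell = shared_cell
    return Trajectory(frames, shared_cell, timestep=timestep * frame_skip)


def write_trajectory(path, traj: Trajectory, precision: int = 8) -> None:
    """Write a trajectory as extended XYZ (Lattice/pbc/Properties header)."""
    fmt = f"%.{precision}f"
    with open(path, "w") as fh:
        for k, fr in enumerate(traj.frames):
            cell = traj.cell_of(k)
            lattice = " ".join(fmt % x for x in cell.vectors.ravel())
            pbc = " ".join("T" if p else "F" for p in cell.periodic)
            comment = (f'Lattice="{lattice}" '
                       f'Properties=species:S:1:pos:R:3 pbc="{pbc}"')
            if fr.time is not None:
                comment += f" Time={fr.time:g}"
            fh.write(f"{fr.n_atoms}\n{comment}\n")
            for sym, (x, y, z) in zip(fr.elements, fr.positions):
                fh.write(f"{sym} {fmt % x} {fmt % y} {fmt % z}\n")
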