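"""Readers and writers for XYZ geometry files and the internal dataset format.

XYZ follows the universal convention: a count line, a comment line, then
``element x y z`` in angstrom.  Coordinates are converted to bohr on read.

The dataset format stores :class:`~nqevib.geometry.EnergyGradientRecord`
blocks in plain text, everything in atomic units::

    <natoms>
    <energy_hartree> [<provenance>]
    <element> <x> <y> <z> [<gx> <gy> <gz>]
    ... (natoms lines)

Gradient columns are present either on every atom line of a block or on
none of them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import EnergyGradientRecord, Geometry
from .units import BOHR_TO_ANGSTROM


class ParseError(ValueError):
    pass


def read_xyz(path: str | Path) -> list[Geometry]:
    """Read a (possibly multi-frame) XYZ file into geometries in bohr."""
    lines = Path(path).read_text().splitlines()
    geoms: list[Geometry] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected an atom count, got {lines[i]!r}")
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ParseError(
                f"line {i + 1}: count line says {n} atoms but only "
                f"{len(body)} atom lines follow"
            )
        symbols, coords = [], []
        for k, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + k}: malformed atom line {ln!r}")
            symbols.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        geoms.append(Geometry(symbols, np.array(coords) / BOHR_TO_ANGSTROM))
        i += 2 + n
    return geoms


def write_xyz(geoms: Sequence[Geometry] | Geometry, path: str | Path,
              comment: str = "") -> None:
    """Write geometries to an XYZ file (angstrom on disk)."""
    if isinstance(geoms, Geometry):
        geoms = [geoms]
    out = []
    for g in geoms:
        out.append(str(g.natoms))
        out.append(comment)
        ang = g.coords * BOHR_TO_ANGSTROM
        for s, (x, y, z) in zip(g.symbols, ang):
            out.append(f"{s:2s} {x: 18.10f} {y: 18.10f} {z: 18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


def write_dataset(records: Iterable[EnergyGradientRecord], path: str | Path) -> None:
    out = []
    for r in records:
        out.append(str(r.geometry.natoms))
        out.append(f"{r.energy:.14e} {r.provenance}")
        grad = None if r.gradient is None else r.gradient.reshape(-1, 3)
        for a in range(r.geometry.natoms):
            x, y, z = r.geometry.coords[a]
            line = f"{r.geometry.symbols[a]:2s} {x: .14e} {y: .14e} {z: .14e}"
            if grad is not None:
                gx, gy, gz = grad[a]
                line += f" {gx: .14e} {gy: .14e} {gz: .14e}"
            out.append(line)
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def read_dataset(path: str | Path) -> list[EnergyGradientRecord]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    records: list[EnergyGradientRecord] = []
    i = 0
    block = 0
    while i < len(lines):
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"block {block}: expected an atom count, got {lines[i]!r}")
        header = lines[i + 1].split()
        energy = float(header[0])
        provenance = header[1] if len(header) > 1 else "low-level"
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ParseError(f"block {block}: expected {n} atom lines, got {len(body)}")
        symbols, coords, grads = [], [], []
        width = len(body[0].split())
        for ln in body:
            parts = ln.split()
            if len(parts) != width or width not in (4, 7):
                raise ParseError(f"block {block}: inconsistent atom line {ln!r}")
            symbols.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
            if width == 7:
                grads.append([float(v) for v in parts[4:7]])
        geom = Geometry(symbols, np.array(coords))
        grad = np.array(grads).reshape(-1) if grads else None
        records.append(EnergyGradientRecord(geom, energy, grad, provenance))
        i += 2 + n
        block += 1
    return records
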