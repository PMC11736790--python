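"""Plain-text file formats: topology, XYZ with cubic box, frame logs.

Topology file — two sections, 1-based atom indices (XYZ convention),
``#`` comments allowed::

    atoms
    1 C 12.011 1 CO2
    2 O 15.999 1
    3 O 15.999 1
    bonds
    1 2
    1 3

Atom lines are ``index element mass molecule_id [species]``; the species
label may be given on any atom of the molecule.  XYZ files are standard, with
the cubic box edge carried on the comment line as ``box_edge=<Å>``.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np

from .topology import AtomSpec, TopologyError

_BOX_RE = re.compile(r"box_edge\s*=\s*([0-9.eE+-]+)")
_TIME_RE = re.compile(r"time\s*=\s*([0-9.eE+-]+)")


def read_topology(path):
    """Parse a topology file.

    Returns (atoms, mol_ids, bonds, species_map) with 0-based indices.
    """
    atoms: dict[int, AtomSpec] = {}
    mol_ids: dict[int, int] = {}
    bonds: list[tuple[int, int]] = []
    species_map: dict[int, str] = {}
    section = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.lower() in ("atoms", "bonds"):
                section = line.lower()
                continue
            parts = line.split()
            if section == "atoms":
                if len(parts) < 4:
                    raise TopologyError(f"{path}:{ln}: bad atom line {line!r}")
                idx = int(parts[0]) - 1
                if idx in atoms:
                    raise TopologyError(f"{path}:{ln}: atom {idx + 1} defined twice")
                atoms[idx] = AtomSpec(parts[1], float(parts[2]))
                mol_ids[idx] = int(parts[3])
                if len(parts) >= 5:
                    species_map[int(parts[3])] = parts[4]
            elif section == "bonds":
                i, j = int(parts[0]) - 1, int(parts[1]) - 1
                bonds.append((min(i, j), max(i, j)))
            else:
                raise TopologyError(f"{path}:{ln}: line outside atoms/bonds section")
    if not atoms:
        raise TopologyError(f"{path}: no atoms")
    order = sorted(atoms)
    if order != list(range(len(order))):
        raise TopologyError(f"{path}: atom indices must be contiguous from 1")
    atom_list = [atoms[i] for i in order]
    ids = [mol_ids[i] for i in order]
    return atom_list, ids, bonds, species_map


def write_topology(path, elements, masses, mol_ids, bonds, species_map=None) -> None:
    species_map = species_map or {}
    with open(path, "w") as fh:
        fh.write("atoms\n")
        written = set()
        for i, (el, m, mid) in enumerate(zip(elements, masses, mol_ids)):
            sp = ""
            if mid in species_map and mid not in written:
                sp = f" {species_map[mid]}"
                written.add(mid)
            fh.write(f"{i + 1} {el} {m:.6g} {mid}{sp}\n")
        fh.write("bonds\n")
        for i, j in bonds:
            fh.write(f"{i + 1} {j + 1}\n")


def read_xyz(path):
    """Read the first frame of an XYZ file: (elements, positions, box, time)."""
    frames = list(iter_xyz(path))
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    return frames[0]


def iter_xyz(path):
    """Yield (elements, positions, box_edge, time) per frame."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                return
            n = int(header)
            comment = fh.readline()
            m = _BOX_RE.search(comment)
            if m is None:
                # fall back: first bare float on the comment line
                floats = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", comment)
                if not floats:
                    raise ValueError(f"{path}: no box edge on comment line {comment!r}")
                box = float(floats[0])
            else:
                box = float(m.group(1))
            tm = _TIME_RE.search(comment)
            time = float(tm.group(1)) if tm else 0.0
            elements = []
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                elements.append(parts[0])
                pos[i] = [float(x) for x in parts[1:4]]
            yield elements, pos, box, time


def write_xyz_frame(fh, elements: Sequence[str], positions: np.ndarray,
                    box_edge: float, time: float = 0.0) -> None:
    fh.write(f"{len(elements)}\n")
    fh.write(f"box_edge={box_edge:.10g} time={time:.10g}\n")
    for el, (x, y, z) in zip(elements, positions):
        fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


def write_xyz(path, elements, positions, box_edge, time=0.0) -> None:
    with open(path, "w") as fh:
        write_xyz_frame(fh, elements, positions, box_edge, time)
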