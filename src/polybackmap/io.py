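"""Coordinate and sequence file I/O.

GRO is the primary coordinate dialect (fixed columns, nm, 3 decimals);
multi-frame trajectories are concatenated GRO blocks.  Stereo sequences
are plain text: one line of L/D letters per chain, blank lines and
``#`` comments ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoordinateFrame", "read_gro", "write_gro",
           "read_sequence_file", "write_sequence_file",
           "frame_from_config", "cg_frame_from_config"]

RESNAMES = {"L": "LLA", "D": "DLA"}


@dataclass
class CoordinateFrame:
    """One frame of named, residue-indexed positions (nm) with a box."""

    atom_names: list
    res_ids: np.ndarray      # 1-based monomer (residue) index per atom
    res_names: list
    positions: np.ndarray    # (n, 3)
    box: np.ndarray
    title: str = ""

    def __post_init__(self):
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")


def read_gro(path):
    """Read one or more concatenated GRO frames.

    Raises ``ValueError`` naming the offending line on malformed records
    or on an atom count that disagrees with the header.
    """
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\n")
        if i + 1 >= len(lines):
            raise ValueError(f"{path}: truncated file after line {i + 1} (missing atom count)")
        try:
            natoms = int(lines[i + 1])
        except ValueError:
            raise ValueError(f"{path}: line {i + 2}: expected atom count, got "
                             f"{lines[i + 1].strip()!r}") from None
        if i + 2 + natoms >= len(lines):
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}: "
                             f"expected {natoms} atom lines plus a box line")
        names, rids, rnames, pos = [], [], [], []
        for n in range(natoms):
            ln = lines[i + 2 + n]
            lineno = i + 3 + n
            if len(ln.rstrip("\n")) < 44:
                raise ValueError(f"{path}: line {lineno}: GRO record too short")
            try:
                rids.append(int(ln[0:5]))
                rnames.append(ln[5:10].strip())
                names.append(ln[10:15].strip())
                pos.append([float(ln[20:28]), float(ln[28:36]), float(ln[36:44])])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed GRO record "
                                 f"{ln.rstrip()!r}") from None
        box_line = lines[i + 2 + natoms].split()
        try:
            box = np.array([float(v) for v in box_line[:3]])
        except (ValueError, IndexError):
            raise ValueError(f"{path}: line {i + 3 + natoms}: malformed box line") from None
        frames.append(CoordinateFrame(
            atom_names=names, res_ids=np.array(rids), res_names=rnames,
            positions=np.array(pos), box=box, title=title))
        i += natoms + 3
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def write_gro(frames, path) -> None:
    """Write frames as concatenated GRO blocks (3-decimal nm positions)."""
    if isinstance(frames, CoordinateFrame):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            fh.write((fr.title or "polybackmap frame") + "\n")
            fh.write(f"{len(fr.atom_names):5d}\n")
            for j, (name, rid, rname) in enumerate(
                    zip(fr.atom_names, fr.res_ids, fr.res_names)):
                x, y, z = fr.positions[j]
                fh.write(f"{rid % 100000:5d}{rname:<5s}{name:>5s}{(j + 1) % 100000:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


def frame_from_config(config, title: str = "") -> CoordinateFrame:
    """Build a CoordinateFrame from an atomistic configuration."""
    top = config.topology
    names, rids, rnames = [], [], []
    res = 0
    for chain in top.chains:
        for ai in range(chain.n_atoms):
            mi = chain.atom_monomer[ai]
            names.append(chain.atom_names[ai])
            rids.append(res + mi + 1)
            rnames.append(RESNAMES[chain.sequence[mi]])
        res += chain.n_monomers
    return CoordinateFrame(atom_names=names, res_ids=np.array(rids),
                           res_names=rnames, positions=config.coords,
                           box=config.box, title=title)


def cg_frame_from_config(cg, title: str = "") -> CoordinateFrame:
    """Represent a CG configuration as one bead ('Q') per residue."""
    top = cg.topology
    names, rids, rnames = [], [], []
    res = 0
    for chain in top.chains:
        for mi, label in enumerate(chain.sequence):
            names.append("Q")
            rids.append(res + mi + 1)
            rnames.append(RESNAMES[label])
        res += chain.n_monomers
    return CoordinateFrame(atom_names=names, res_ids=np.array(rids),
                           res_names=rnames, positions=cg.Q, box=cg.box,
                           title=title)


def read_sequence_file(path):
    """Parse per-chain stereo sequences (one line of L/D letters per chain)."""
    seqs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            letters = list(s.replace(" ", ""))
            bad = sorted({c for c in letters if c not in ("L", "D")})
            if bad:
                raise ValueError(f"{path}: line {lineno}: illegal stereo "
                                 f"characters {bad}; only L and D are allowed")
            seqs.append(letters)
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    return seqs


def write_sequence_file(sequences, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for seq in sequences:
            fh.write("".join(seq) + "\n")
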