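"""CG mapping and the bond-vector codec.

The coarse-grained picture places one bead at the center of mass of each
monomer (1:1 mapping).  For the network, every atom of a chain becomes one
row of a fixed-height tensor: the monomer root atom's row carries the
anchor vector v0 = r(root) - Q(monomer), every other row carries the bond
vector from its traversal parent.  Rows are zero-padded to the smallest
power of two ``S`` and all vectors are rescaled into [-1, 1].

Reconstruction is anchored on the beads: provisional positions follow the
traversal from the root, then each monomer is rigidly translated so its
center of mass coincides exactly with its bead.  This makes the roundtrip
lossless and guarantees that re-mapping a decoded structure returns the
input beads, independently of the predicted v0 rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import ChainTopology, SystemTopology

__all__ = [
    "AtomisticConfig",
    "CGConfig",
    "VectorScheme",
    "EncodedSample",
    "DEFAULT_VECTOR_SCALE",
    "DEFAULT_CG_SCALE",
    "COMPOSITIONS",
    "map_to_cg",
    "assign_types",
    "build_scheme",
    "encode_chain",
    "decode_vectors",
    "fragment_chain",
    "next_pow2",
]

DEFAULT_VECTOR_SCALE = 0.3  # nm; generous bound on any bond/anchor vector
DEFAULT_CG_SCALE = 1.5      # nm; bound on neighbor-bead displacements

COMPOSITIONS = ("homopolymer", "copolymer", "combined")


@dataclass
class AtomisticConfig:
    """All-atom coordinates (nm, unwrapped) with a periodic box."""

    coords: np.ndarray
    box: np.ndarray
    topology: SystemTopology

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.shape != (self.topology.total_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match topology "
                f"({self.topology.total_atoms} atoms)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    def chain_coords(self, i: int) -> np.ndarray:
        off = self.topology.chain_atom_offsets
        return self.coords[off[i]:off[i + 1]]


@dataclass
class CGConfig:
    """Bead coordinates Q, integer bead types c (1..k) and the box."""

    Q: np.ndarray
    c: np.ndarray
    k: int
    box: np.ndarray
    topology: SystemTopology

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.c = np.asarray(self.c, dtype=np.int64)
        if self.Q.shape != (self.topology.total_monomers, 3):
            raise ValueError("Q shape does not match topology monomer count")
        if self.c.min() < 1 or self.c.max() > self.k:
            raise ValueError("bead types must lie in 1..k")

    def chain_Q(self, i: int) -> np.ndarray:
        off = self.topology.chain_monomer_offsets
        return self.Q[off[i]:off[i + 1]]

    def chain_c(self, i: int) -> np.ndarray:
        off = self.topology.chain_monomer_offsets
        return self.c[off[i]:off[i + 1]]


@dataclass
class VectorScheme:
    """Traversal metadata of one chain: per-atom role and parent."""

    roles: np.ndarray       # "anchor" / "bond" per atom
    parents: np.ndarray     # chain-local parent index; -1 for anchors
    version: str = "traversal-v1"

    @property
    def anchor_rows(self) -> np.ndarray:
        return np.where(self.roles == "anchor")[0]

    @property
    def bond_rows(self) -> np.ndarray:
        return np.where(self.roles == "bond")[0]


@dataclass
class EncodedSample:
    """Padded network input/target pair for one chain (or fragment)."""

    input: np.ndarray       # (S, k+3)
    target: np.ndarray      # (S, 3)
    mask: np.ndarray        # (S,) bool, True on informative rows
    vector_scale: float
    cg_scale: float
    k: int
    n_rows: int = 0

    def __post_init__(self):
        if self.n_rows == 0:
            self.n_rows = int(self.mask.sum())


def next_pow2(n: int) -> int:
    s = 1
    while s < n:
        s *= 2
    return s


def build_scheme(chain: ChainTopology) -> VectorScheme:
    """Derive the traversal scheme from a chain topology.

    Each monomer's O1 is the root (anchor); every other atom's parent is
    its earliest bonded neighbour within the same monomer, which by the
    template atom order always precedes it.
    """
    n = chain.n_atoms
    parents = np.full(n, -1, dtype=np.int64)
    roles = np.full(n, "bond", dtype=object)
    neighbors = [[] for _ in range(n)]
    for a, b in chain.bonds:
        neighbors[a].append(b)
        neighbors[b].append(a)
    for i in range(n):
        if chain.atom_names[i] == "O1":
            roles[i] = "anchor"
            continue
        same = [j for j in neighbors[i]
                if j < i and chain.atom_monomer[j] == chain.atom_monomer[i]]
        if not same:
            raise ValueError(f"atom {i} ({chain.atom_names[i]}) has no in-monomer parent")
        parents[i] = min(same)
    return VectorScheme(roles=np.asarray(roles), parents=parents)


def map_to_cg(config: AtomisticConfig, composition: str = "homopolymer") -> CGConfig:
    """Map an atomistic configuration to beads at monomer centers of mass."""
    top = config.topology
    c, k = assign_types(top, composition)
    Q = np.empty((top.total_monomers, 3))
    m_off = top.chain_monomer_offsets
    a_off = top.chain_atom_offsets
    for ci, chain in enumerate(top.chains):
        coords = config.coords[a_off[ci]:a_off[ci + 1]]
        for mi, (s, e) in enumerate(chain.monomer_slices):
            w = chain.atom_masses[s:e]
            Q[m_off[ci] + mi] = w @ coords[s:e] / w.sum()
    return CGConfig(Q=Q, c=c, k=k, box=config.box, topology=top)


def assign_types(topology: SystemTopology, training_composition: str):
    """Integer bead types (1..k) under a declared training composition.

    The first and last monomers of every chain are distinct types.  A
    homopolymer training set needs k = 3 (interior/first/last); a
    copolymer one k = 4 (L-interior/D-interior/first/last); the union of
    homopolymer and copolymer data keeps their interior labels distinct,
    giving k = 6.
    """
    if training_composition not in COMPOSITIONS:
        raise ValueError(
            f"unknown composition {training_composition!r}; expected one of {COMPOSITIONS}")
    c = np.empty(topology.total_monomers, dtype=np.int64)
    pos = 0
    for chain in topology.chains:
        n = chain.n_monomers
        uniform = len(set(chain.sequence)) == 1
        for mi, label in enumerate(chain.sequence):
            if training_composition == "homopolymer":
                k = 3
                t = 2 if mi == 0 else (3 if mi == n - 1 else 1)
            elif training_composition == "copolymer":
                k = 4
                if mi == 0:
                    t = 3
                elif mi == n - 1:
                    t = 4
                else:
                    t = 1 if label == "L" else 2
            else:  # combined
                k = 6
                if mi == 0:
                    t = 5
                elif mi == n - 1:
                    t = 6
                elif uniform:
                    t = 1 if label == "L" else 2
                else:
                    t = 3 if label == "L" else 4
            c[pos] = t
            pos += 1
    return c, k


def _cg_features(Q: np.ndarray, mode: str) -> np.ndarray:
    """Per-monomer 3-vector CG feature (translation invariant)."""
    feat = np.zeros_like(Q)
    if mode == "neighbor":
        feat[1:] = Q[1:] - Q[:-1]
    elif mode == "com":
        feat[:] = Q - Q.mean(axis=0)
    else:
        raise ValueError(f"unknown CG feature mode {mode!r}")
    return feat


def encode_chain(coords: np.ndarray, chain: ChainTopology, Q: np.ndarray,
                 c: np.ndarray, k: int, scheme: VectorScheme | None = None,
                 vector_scale: float = DEFAULT_VECTOR_SCALE,
                 cg_scale: float = DEFAULT_CG_SCALE,
                 S: int | None = None,
                 feature_mode: str = "neighbor",
                 monomers: tuple | None = None) -> EncodedSample:
    """Encode one chain (or a monomer range of it) into a padded sample.

    ``coords`` must be unwrapped (no periodic jumps along bonds).  Raises
    ``ValueError`` if any scaled component falls outside [-1, 1], naming
    the offending atom.
    """
    if scheme is None:
        scheme = build_scheme(chain)
    if monomers is None:
        monomers = (0, chain.n_monomers)
    m0, m1 = monomers
    a0 = chain.monomer_slices[m0][0]
    a1 = chain.monomer_slices[m1 - 1][1]
    n_rows = a1 - a0
    if S is None:
        S = next_pow2(n_rows)
    if n_rows > S:
        raise ValueError(f"chain fragment has {n_rows} rows > S={S}")

    mon = chain.atom_monomer[a0:a1]
    vec = np.empty((n_rows, 3))
    anchors = scheme.roles[a0:a1] == "anchor"
    parents = scheme.parents[a0:a1]
    rows = np.arange(a0, a1)
    vec[anchors] = coords[rows[anchors]] - Q[mon[anchors]]
    vec[~anchors] = coords[rows[~anchors]] - coords[parents[~anchors]]

    target = vec / vector_scale
    bad = np.abs(target) > 1.0
    if bad.any():
        i = int(np.where(bad.any(axis=1))[0][0])
        raise ValueError(
            f"scaled vector out of [-1, 1] at atom {a0 + i} "
            f"({chain.atom_names[a0 + i]}, monomer {mon[i]}): "
            f"|v| = {np.linalg.norm(vec[i]):.4f} nm exceeds scale {vector_scale} nm")

    feat = _cg_features(Q, feature_mode) / cg_scale
    if np.abs(feat).max() > 1.0:
        raise ValueError("scaled CG feature out of [-1, 1]; cg_scale too small")

    inp = np.zeros((S, k + 3), dtype=np.float32)
    tgt = np.zeros((S, 3), dtype=np.float32)
    mask = np.zeros(S, dtype=bool)
    inp[:n_rows, :3] = feat[mon]
    inp[np.arange(n_rows), 3 + np.asarray(c)[mon] - 1] = 1.0
    tgt[:n_rows] = target
    mask[:n_rows] = True
    return EncodedSample(input=inp, target=tgt, mask=mask,
                         vector_scale=vector_scale, cg_scale=cg_scale, k=k)


def encode_input(chain: ChainTopology, Q: np.ndarray, c: np.ndarray, k: int,
                 cg_scale: float = DEFAULT_CG_SCALE, S: int | None = None,
                 feature_mode: str = "neighbor",
                 monomers: tuple | None = None) -> np.ndarray:
    """Input tensor only (no targets) — what the trained model consumes."""
    if monomers is None:
        monomers = (0, chain.n_monomers)
    m0, m1 = monomers
    a0 = chain.monomer_slices[m0][0]
    a1 = chain.monomer_slices[m1 - 1][1]
    n_rows = a1 - a0
    if S is None:
        S = next_pow2(n_rows)
    mon = chain.atom_monomer[a0:a1]
    feat = _cg_features(Q, feature_mode) / cg_scale
    inp = np.zeros((S, k + 3), dtype=np.float32)
    inp[:n_rows, :3] = feat[mon]
    inp[np.arange(n_rows), 3 + np.asarray(c)[mon] - 1] = 1.0
    return inp


def decode_vectors(predicted: np.ndarray, mask: np.ndarray, chain: ChainTopology,
                   Q: np.ndarray, scheme: VectorScheme | None = None,
                   vector_scale: float = DEFAULT_VECTOR_SCALE,
                   monomers: tuple | None = None) -> np.ndarray:
    """Reconstruct Cartesian coordinates from (scaled) predicted vectors.

    Provisional positions follow the traversal (root at the origin,
    children by cumulative bond vectors); each monomer is then rigidly
    translated so its center of mass sits exactly on its bead.
    """
    if scheme is None:
        scheme = build_scheme(chain)
    if monomers is None:
        monomers = (0, chain.n_monomers)
    m0, m1 = monomers
    a0 = chain.monomer_slices[m0][0]
    a1 = chain.monomer_slices[m1 - 1][1]
    n_rows = a1 - a0
    if int(mask.sum()) != n_rows:
        raise ValueError(f"mask marks {int(mask.sum())} rows, topology expects {n_rows}")

    vec = np.asarray(predicted[:n_rows], dtype=float) * vector_scale
    coords = np.empty((n_rows, 3))
    for m in range(m0, m1):
        s, e = chain.monomer_slices[m]
        prov = np.empty((e - s, 3))
        for i in range(s, e):
            if scheme.roles[i] == "anchor":
                prov[i - s] = 0.0
            else:
                prov[i - s] = prov[scheme.parents[i] - s] + vec[i - a0]
        w = chain.atom_masses[s:e]
        com = w @ prov / w.sum()
        coords[s - a0:e - a0] = prov - com + Q[m]
    return coords


def fragment_chain(chain: ChainTopology, s: int):
    """Consecutive non-overlapping monomer windows of at most ``s`` monomers.

    Returns ``(start, stop)`` monomer-index pairs whose decoded pieces
    concatenate to the original chain (each monomer is bead-anchored, so
    fragment boundaries are exact).
    """
    if s < 1:
        raise ValueError("fragment size must be >= 1")
    return [(i, min(i + s, chain.n_monomers)) for i in range(0, chain.n_monomers, s)]
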