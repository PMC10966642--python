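"""Chemical model of linear poly(lactic acid) chains.

One monomer is the lactic-acid repeat unit -O-CH(CH3)-C(=O)- with nine
atoms: ester oxygen O1, alpha carbon C2 (bearing hydrogen H5 and the methyl
carbon C4 with hydrogens H6-H8) and carbonyl carbon C3 with its oxygen O2.
C2 is a chiral center with four distinct substituents (O1, C3, C4, H5),
giving the L and D stereoisomers.  Chains are terminated by hydroxyl groups
at both extremes: the first monomer's O1 carries an extra hydrogen (H1) and
the last monomer's C3 carries a terminal O-H (O3, H3), so a chain of n
monomers has 9n + 3 atoms (903 for a 100-mer).

Atom order within each monomer is the fixed traversal used by the
bond-vector codec: O1 (root) -> [H1] -> C2 -> H5 -> C4 -> H6, H7, H8 ->
C3 -> O2 -> [O3 -> H3].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomSpec",
    "MonomerTemplate",
    "ChainTopology",
    "SystemTopology",
    "build_monomer_template",
    "build_chain",
    "build_system",
    "random_copolymer_sequence",
    "export_itp",
]

MASSES = {"C": 12.011, "O": 15.999, "H": 1.008}

STEREO_LABELS = ("L", "D")
POSITION_FLAGS = ("first", "interior", "last", "single")

# (name, element) in traversal order for the interior repeat unit
_CORE_ATOMS = [
    ("O1", "O"), ("C2", "C"), ("H5", "H"), ("C4", "C"),
    ("H6", "H"), ("H7", "H"), ("H8", "H"), ("C3", "C"), ("O2", "O"),
]
_CORE_BONDS = [
    ("O1", "C2"), ("C2", "H5"), ("C2", "C4"), ("C4", "H6"),
    ("C4", "H7"), ("C4", "H8"), ("C2", "C3"), ("C3", "O2"),
]


@dataclass(frozen=True)
class AtomSpec:
    """A single atom of a monomer template."""

    name: str
    element: str
    mass: float

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")


@dataclass(frozen=True)
class MonomerTemplate:
    """Constitution of one monomer at a given chain position.

    The constitution is identical for L and D; only the reference
    handedness at the chiral alpha carbon differs.
    """

    stereo_label: str
    position_flag: str
    atoms: tuple          # ordered AtomSpec
    intra_bonds: tuple    # pairs of atom names
    chiral_center: tuple  # (center, (substituents in fixed priority order))
    link_in: str = "O1"
    link_out: str = "C3"

    @property
    def atom_names(self):
        return [a.name for a in self.atoms]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def build_monomer_template(stereo_label: str, position_flag: str) -> MonomerTemplate:
    """Return the monomer template for a stereo label and chain position.

    Interior monomers have 9 atoms and 8 intra-monomer bonds; the first
    monomer adds the hydroxyl hydrogen H1 on O1 and the last adds the
    terminal O3-H3 on C3 (together 3 cap atoms per chain).
    """
    if stereo_label not in STEREO_LABELS:
        raise ValueError(f"unknown stereo label {stereo_label!r}; expected one of {STEREO_LABELS}")
    if position_flag not in POSITION_FLAGS:
        raise ValueError(f"unknown position flag {position_flag!r}; expected one of {POSITION_FLAGS}")

    atoms = list(_CORE_ATOMS)
    bonds = list(_CORE_BONDS)
    if position_flag in ("first", "single"):
        atoms.insert(1, ("H1", "H"))
        bonds.insert(0, ("O1", "H1"))
    if position_flag in ("last", "single"):
        atoms += [("O3", "O"), ("H3", "H")]
        bonds += [("C3", "O3"), ("O3", "H3")]

    specs = tuple(AtomSpec(n, e, MASSES[e]) for n, e in atoms)
    return MonomerTemplate(
        stereo_label=stereo_label,
        position_flag=position_flag,
        atoms=specs,
        intra_bonds=tuple(bonds),
        chiral_center=("C2", ("O1", "C3", "C4", "H5")),
    )


@dataclass
class ChainTopology:
    """Full bonded topology of one linear chain."""

    sequence: list
    atom_names: list
    atom_elements: list
    atom_masses: np.ndarray
    atom_monomer: np.ndarray          # monomer index per atom
    monomer_slices: list              # (start, stop) per monomer
    bonds: np.ndarray                 # (n_bonds, 2)
    angles: np.ndarray                # (n_angles, 3)
    dihedrals: np.ndarray             # (n_dihedrals, 4)
    backbone: np.ndarray              # O1, C2, C3 of every monomer, in order
    chiral_centers: list              # per monomer: (C2, O1, C3, C4, H5) indices
    dihedral_names: list = field(default_factory=list)
    dihedral_stereo: list = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_monomers(self) -> int:
        return len(self.sequence)

    def atom_index(self, monomer: int, name: str) -> int:
        start, stop = self.monomer_slices[monomer]
        for i in range(start, stop):
            if self.atom_names[i] == name:
                return i
        raise KeyError(f"monomer {monomer} has no atom {name!r}")


@dataclass
class SystemTopology:
    """Concatenation of chain topologies with global atom indexing."""

    chains: list

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def total_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains)

    @property
    def total_monomers(self) -> int:
        return sum(c.n_monomers for c in self.chains)

    @property
    def chain_atom_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum([c.n_atoms for c in self.chains])])

    @property
    def chain_monomer_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum([c.n_monomers for c in self.chains])])

    @property
    def sequences(self) -> list:
        return [c.sequence for c in self.chains]

    @property
    def atom_masses(self) -> np.ndarray:
        return np.concatenate([c.atom_masses for c in self.chains])


def _enumerate_angles_dihedrals(bonds: np.ndarray, n_atoms: int):
    """All unique 3- and 4-paths of the bond graph, canonically ordered."""
    adj = [[] for _ in range(n_atoms)]
    for a, b in bonds:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    angles = []
    for j in range(n_atoms):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))
    dihedrals = []
    for a, b in bonds:
        j, k = int(a), int(b)
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                quad = (i, j, k, l)
                if quad[0] > quad[3]:
                    quad = quad[::-1]
                dihedrals.append(quad)
    dihedrals = sorted(set(dihedrals))
    return (np.array(angles, dtype=np.int64).reshape(-1, 3),
            np.array(dihedrals, dtype=np.int64).reshape(-1, 4))


def build_chain(sequence) -> ChainTopology:
    """Build the full bonded topology of one chain from its stereo sequence.

    Consecutive monomers are linked C3(i) -> O1(i+1); angles and dihedrals
    are enumerated as all unique bonded 3- and 4-paths.
    """
    sequence = list(sequence)
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for s in sequence:
        if s not in STEREO_LABELS:
            raise ValueError(f"unknown stereo label {s!r} in sequence")

    n = len(sequence)
    atom_names, atom_elements, masses, atom_monomer = [], [], [], []
    monomer_slices = []
    bonds = []
    chiral_centers = []
    backbone = []
    name_to_idx_per_monomer = []

    for m, label in enumerate(sequence):
        if n == 1:
            flag = "single"
        elif m == 0:
            flag = "first"
        elif m == n - 1:
            flag = "last"
        else:
            flag = "interior"
        tpl = build_monomer_template(label, flag)
        start = len(atom_names)
        local = {}
        for spec in tpl.atoms:
            local[spec.name] = len(atom_names)
            atom_names.append(spec.name)
            atom_elements.append(spec.element)
            masses.append(spec.mass)
            atom_monomer.append(m)
        monomer_slices.append((start, len(atom_names)))
        name_to_idx_per_monomer.append(local)
        for a, b in tpl.intra_bonds:
            bonds.append((local[a], local[b]))
        if m > 0:
            prev = name_to_idx_per_monomer[m - 1]
            bonds.append((prev["C3"], local["O1"]))
        center = tpl.chiral_center
        chiral_centers.append((local[center[0]],) + tuple(local[s] for s in center[1]))
        backbone += [local["O1"], local["C2"], local["C3"]]

    bonds = np.array(bonds, dtype=np.int64)
    angles, dihedrals = _enumerate_angles_dihedrals(bonds, len(atom_names))

    chain = ChainTopology(
        sequence=sequence,
        atom_names=atom_names,
        atom_elements=atom_elements,
        atom_masses=np.array(masses),
        atom_monomer=np.array(atom_monomer, dtype=np.int64),
        monomer_slices=monomer_slices,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        backbone=np.array(backbone, dtype=np.int64),
        chiral_centers=chiral_centers,
    )
    chain.dihedral_names, chain.dihedral_stereo = _classify_dihedrals(chain)
    return chain


def _classify_dihedrals(chain: ChainTopology):
    """Name each dihedral by its atom names and stereo context.

    The name is the '-'-joined atom-name tuple read in the direction that is
    lexicographically smaller; the stereo context is the concatenated stereo
    labels of the monomers owning the two central atoms, in name direction.
    """
    names, stereo = [], []
    for quad in chain.dihedrals:
        fw = tuple(chain.atom_names[i] for i in quad)
        quad_dir = quad
        if fw[::-1] < fw:
            fw = fw[::-1]
            quad_dir = quad[::-1]
        names.append("-".join(fw))
        mid = quad_dir[1:3]
        stereo.append("".join(chain.sequence[chain.atom_monomer[i]] for i in mid))
    return names, stereo


def build_system(n_chains: int, sequences) -> SystemTopology:
    """Build a melt topology of ``n_chains`` chains.

    ``sequences`` is either a single sequence (applied to every chain) or a
    list of one sequence per chain.
    """
    if n_chains <= 0:
        raise ValueError("n_chains must be positive")
    if sequences and isinstance(sequences[0], str) and len(sequences[0]) == 1:
        sequences = [list(sequences)] * n_chains
    sequences = [list(s) for s in sequences]
    if len(sequences) == 1:
        sequences = sequences * n_chains
    if len(sequences) != n_chains:
        raise ValueError(f"expected 1 or {n_chains} sequences, got {len(sequences)}")
    return SystemTopology(chains=[build_chain(s) for s in sequences])


def random_copolymer_sequence(n_monomers: int, d_fraction: float, rng_seed,
                              n_chains: int = 1,
                              per_chain_identical: bool = True):
    """Random L/D copolymer sequences with a fixed D content per chain.

    Every chain receives exactly ``round(d_fraction * n_monomers)`` D
    monomers, placed uniformly at random.  With ``per_chain_identical`` the
    same random placement is used for every chain (the 100-mer protocol);
    otherwise each chain is shuffled independently (the 30-mer protocol).
    """
    if not 0.0 <= d_fraction <= 1.0:
        raise ValueError("d_fraction must lie in [0, 1]")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n_d = int(round(d_fraction * n_monomers))
    base = np.array(["D"] * n_d + ["L"] * (n_monomers - n_d))
    if per_chain_identical:
        seq = list(rng.permutation(base))
        return [list(seq) for _ in range(n_chains)]
    return [list(rng.permutation(base)) for _ in range(n_chains)]


def chain_to_json(chain: ChainTopology) -> str:
    """Serialize a chain topology.

    The bonded topology is a pure function of the stereo sequence, so the
    schema stores the sequence plus derived counts for validation:
    ``{"schema": "polybackmap-chain-v1", "sequence": [...],
    "n_atoms": int, "n_bonds": int}``.
    """
    import json
    return json.dumps({
        "schema": "polybackmap-chain-v1",
        "sequence": chain.sequence,
        "n_atoms": chain.n_atoms,
        "n_bonds": int(len(chain.bonds)),
    })


def chain_from_json(text: str) -> ChainTopology:
    """Rebuild a chain from :func:`chain_to_json` output, with validation."""
    import json
    data = json.loads(text)
    if data.get("schema") != "polybackmap-chain-v1":
        raise ValueError(f"unknown topology schema {data.get('schema')!r}")
    chain = build_chain(data["sequence"])
    if chain.n_atoms != data["n_atoms"] or len(chain.bonds) != data["n_bonds"]:
        raise ValueError("topology counts in JSON do not match the rebuilt chain")
    return chain


def export_itp(chain: ChainTopology, path, name: str = "PLA") -> None:
    """Write a minimal GROMACS-style listing (atoms/bonds only).

    Deliberately force-field-free: no types, charges or parameters.
    """
    lines = ["; generated by polybackmap (force-field-free listing)",
             "[ moleculetype ]", f"{name}  3", "", "[ atoms ]",
             ";  nr  element  resnr  name  mass"]
    for i, (nm, el, mass) in enumerate(
            zip(chain.atom_names, chain.atom_elements, chain.atom_masses), start=1):
        res = chain.atom_monomer[i - 1] + 1
        lines.append(f"{i:6d}  {el:>2s}  {res:5d}  {nm:>4s}  {mass:8.3f}")
    lines += ["", "[ bonds ]", ";  ai  aj"]
    for a, b in chain.bonds:
        lines.append(f"{a + 1:6d} {b + 1:6d}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
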