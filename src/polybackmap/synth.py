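"""Synthetic all-atom/CG ensembles with known statistics.

The generator grows each chain atom-by-atom with exact bond lengths,
wrapped-Gaussian backbone bending angles and stereo-label-dependent
von Mises torsion mixtures, then drops independently rotated/translated
chains into a periodic box.  Every distribution is known analytically, so
training, backmapping and the whole analysis stack can be validated
without external trajectories.

Frames are i.i.d. (no time correlation): the backmapping model is trained
frame-wise, so temporal structure is irrelevant for exercising it.
Geometric defaults are loosely PLA-like; they are generator configuration,
not force-field values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import i0

from .geometry import nerf_place
from .represent import AtomisticConfig, CGConfig, map_to_cg
from .topology import SystemTopology, build_chain, build_system

__all__ = [
    "VonMisesMixture",
    "GeneratorParams",
    "Ensemble",
    "sample_chain",
    "pack_frames",
    "ground_truth",
    "GroundTruth",
    "freely_rotating_msid",
]

_DEG = np.pi / 180.0

# wedge half-angle giving tetrahedral substituent geometry at C2
_TETRA_W = np.arccos(1.0 / np.sqrt(3.0))


@dataclass(frozen=True)
class VonMisesMixture:
    """Mixture of von Mises components on the circle (mode locations in deg)."""

    modes_deg: tuple
    kappas: tuple
    weights: tuple

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if len({len(self.modes_deg), len(self.kappas), len(self.weights)}) != 1:
            raise ValueError("mixture component lists must have equal length")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=size, p=self.weights)
        mu = np.asarray(self.modes_deg)[comp] * _DEG
        kappa = np.asarray(self.kappas)[comp]
        return rng.vonmises(mu, kappa)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Density per radian on (-pi, pi]."""
        x = np.asarray(x)[..., None]
        mu = np.asarray(self.modes_deg) * _DEG
        kappa = np.asarray(self.kappas)
        w = np.asarray(self.weights)
        comp = np.exp(kappa * np.cos(x - mu)) / (2 * np.pi * i0(kappa))
        return comp @ w

    def mirrored(self) -> "VonMisesMixture":
        """Parity image: every mode location negated."""
        return VonMisesMixture(tuple(-m for m in self.modes_deg), self.kappas, self.weights)


def _default_torsions():
    psi_L = VonMisesMixture((-65.0, 160.0), (12.0, 12.0), (0.6, 0.4))
    omega_L = VonMisesMixture((180.0,), (40.0,), (1.0,))
    phi_L = VonMisesMixture((-70.0, 75.0), (12.0, 12.0), (0.7, 0.3))
    return {
        "psi": {"L": psi_L, "D": psi_L.mirrored()},
        "omega": {"L": omega_L, "D": omega_L.mirrored()},
        "phi": {"L": phi_L, "D": phi_L.mirrored()},
    }


# dihedral class -> canonical topology dihedral name (see topology module)
TORSION_CLASS_NAMES = {
    "psi": "O1-C2-C3-O1",
    "omega": "C2-C3-O1-C2",
    "phi": "C3-C2-O1-C3",
}


@dataclass
class GeneratorParams:
    """Conditions of a synthetic ensemble.

    Defaults mirror the reference melt setup: 70 chains of 100 monomers,
    frames saved every 200 ps over 1 us (5000 snapshots).  Lengths in nm,
    angles in degrees, times in ps.
    """

    n_chains: int = 70
    n_monomers: int = 100
    box_length: float = 9.1
    duration_ps: float = 1.0e6
    save_interval_ps: float = 200.0
    seed: int = 0
    bond_lengths: dict = field(default_factory=lambda: {
        "O1-C2": 0.143, "C2-C3": 0.152, "C3-O1": 0.143, "C2-C4": 0.153,
        "C2-H5": 0.109, "C4-H": 0.109, "C3-O2": 0.122, "C3-O3": 0.134,
        "O3-H3": 0.097, "O1-H1": 0.097,
    })
    # backbone bending angles: class -> (mean_deg, sigma_deg)
    angles: dict = field(default_factory=lambda: {
        "O1-C2-C3": (109.5, 3.0), "C2-C3-O1": (111.4, 3.0), "C3-O1-C2": (116.0, 3.0),
    })
    torsions: dict = field(default_factory=_default_torsions)
    min_com_separation: float = 0.0   # nm; >0 enables hard-core chain placement

    @property
    def n_frames(self) -> int:
        return int(self.duration_ps // self.save_interval_ps)

    def scaled_down(self, **kw) -> "GeneratorParams":
        return replace(self, **kw)


def _sample_angle(params, name, rng) -> float:
    mean, sigma = params.angles[name]
    return (mean + sigma * rng.standard_normal()) * _DEG


def sample_chain(params: GeneratorParams, sequence, rng: np.random.Generator,
                 topology=None) -> np.ndarray:
    """Grow one chain; returns coordinates in topology atom order (nm).

    Bond lengths are exact; the backbone follows the angle/torsion
    statistics; H5 and the methyl carbon complete a tetrahedral center
    whose handedness is fixed by the sequence letter (chirality holds by
    construction).  The methyl and hydroxyl rotors are free (uniform).
    """
    if topology is None:
        topology = build_chain(sequence)
    n = len(sequence)
    bl = params.bond_lengths
    coords = np.zeros((topology.n_atoms, 3))

    # --- backbone: O1, C2, C3 per monomer
    bb = np.zeros((3 * n, 3))
    bb[0] = 0.0
    bb[1] = np.array([bl["O1-C2"], 0.0, 0.0])
    th = _sample_angle(params, "O1-C2-C3", rng)
    bb[2] = bb[1] + bl["C2-C3"] * np.array([-np.cos(th), np.sin(th), 0.0])
    for m in range(1, n):
        label = sequence[m - 1]  # torsions at the junction follow the upstream monomer
        psi = params.torsions["psi"][label].sample(rng)
        omega = params.torsions["omega"][label].sample(rng)
        phi = params.torsions["phi"][label].sample(rng)
        i = 3 * m
        bb[i] = nerf_place(bb[i - 3], bb[i - 2], bb[i - 1], bl["C3-O1"],
                           _sample_angle(params, "C2-C3-O1", rng), psi)
        bb[i + 1] = nerf_place(bb[i - 2], bb[i - 1], bb[i], bl["O1-C2"],
                               _sample_angle(params, "C3-O1-C2", rng), omega)
        bb[i + 2] = nerf_place(bb[i - 1], bb[i], bb[i + 1], bl["C2-C3"],
                               _sample_angle(params, "O1-C2-C3", rng), phi)

    for m, label in enumerate(sequence):
        o1, c2, c3 = bb[3 * m], bb[3 * m + 1], bb[3 * m + 2]
        coords[topology.atom_index(m, "O1")] = o1
        coords[topology.atom_index(m, "C2")] = c2
        coords[topology.atom_index(m, "C3")] = c3

        # tetrahedral substituents on the chiral alpha carbon
        u1 = (o1 - c2) / np.linalg.norm(o1 - c2)
        u2 = (c3 - c2) / np.linalg.norm(c3 - c2)
        bis = -(u1 + u2)
        bis /= np.linalg.norm(bis)
        perp = np.cross(u1, u2)
        perp /= np.linalg.norm(perp)
        s = 1.0 if label == "L" else -1.0
        d_c4 = np.cos(_TETRA_W) * bis + s * np.sin(_TETRA_W) * perp
        d_h5 = np.cos(_TETRA_W) * bis - s * np.sin(_TETRA_W) * perp
        c4 = c2 + bl["C2-C4"] * d_c4
        coords[topology.atom_index(m, "C4")] = c4
        coords[topology.atom_index(m, "H5")] = c2 + bl["C2-H5"] * d_h5

        # methyl rotor: free rotation about C2-C4
        gamma = rng.uniform(-np.pi, np.pi)
        for j, name in enumerate(("H6", "H7", "H8")):
            coords[topology.atom_index(m, name)] = nerf_place(
                o1, c2, c4, bl["C4-H"], 110.0 * _DEG, gamma + j * 2 * np.pi / 3)

        # carbonyl oxygen (sp2 at C3)
        v1 = (c2 - c3) / np.linalg.norm(c2 - c3)
        if m < n - 1:
            o1_next = bb[3 * (m + 1)]
            v2 = (o1_next - c3) / np.linalg.norm(o1_next - c3)
            d_o2 = -(v1 + v2)
            d_o2 /= np.linalg.norm(d_o2)
            coords[topology.atom_index(m, "O2")] = c3 + bl["C3-O2"] * d_o2
        else:
            # chain end: O2 (double bond) and hydroxyl O3-H3 at +-120 deg
            ref = np.cross(v1, o1 - c2)
            ref /= np.linalg.norm(ref)
            q = np.cross(ref, v1)
            d_plus = -np.cos(60 * _DEG) * v1 + np.sin(60 * _DEG) * q
            d_minus = -np.cos(60 * _DEG) * v1 - np.sin(60 * _DEG) * q
            o2 = c3 + bl["C3-O2"] * d_plus
            o3 = c3 + bl["C3-O3"] * d_minus
            coords[topology.atom_index(m, "O2")] = o2
            coords[topology.atom_index(m, "O3")] = o3
            coords[topology.atom_index(m, "H3")] = nerf_place(
                c2, c3, o3, bl["O3-H3"], 106.0 * _DEG, np.pi)
        if m == 0:
            coords[topology.atom_index(m, "H1")] = nerf_place(
                c3, c2, o1, bl["O1-H1"], 108.0 * _DEG, rng.uniform(-np.pi, np.pi))
    return coords


@dataclass
class Ensemble:
    """Multi-frame paired atomistic/CG data for one system."""

    topology: SystemTopology
    box: np.ndarray
    coords: np.ndarray      # (n_frames, n_atoms, 3)
    cg: CGConfig            # types/k; Q per frame in cg_coords
    cg_coords: np.ndarray   # (n_frames, n_monomers, 3)
    params: GeneratorParams

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def sequences(self):
        return self.topology.sequences

    def atomistic(self, i: int) -> AtomisticConfig:
        return AtomisticConfig(coords=self.coords[i], box=self.box, topology=self.topology)

    def cg_frame(self, i: int) -> CGConfig:
        return CGConfig(Q=self.cg_coords[i], c=self.cg.c, k=self.cg.k,
                        box=self.box, topology=self.topology)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def pack_frames(params: GeneratorParams, sequences=None,
                composition: str = "homopolymer",
                n_frames: int | None = None) -> Ensemble:
    """Generate independent frames of randomly placed chains in the box.

    Each frame draws fresh chain conformations, rotates them uniformly and
    places chain centers of mass uniformly in the periodic box (no
    inter-chain relaxation is claimed).  CG configurations are obtained by
    the center-of-mass mapping.  Frame count is ``duration / interval``
    unless overridden.
    """
    rng = np.random.default_rng(params.seed)
    if sequences is None:
        sequences = [["L"] * params.n_monomers] * params.n_chains
    topology = build_system(len(sequences), sequences)
    if n_frames is None:
        n_frames = params.n_frames
    box = np.full(3, params.box_length)

    n_atoms = topology.total_atoms
    all_coords = np.empty((n_frames, n_atoms, 3))
    offs = topology.chain_atom_offsets
    for f in range(n_frames):
        placed_coms = []
        for ci, chain_top in enumerate(topology.chains):
            xyz = sample_chain(params, chain_top.sequence, rng, topology=chain_top)
            xyz = xyz @ _random_rotation(rng).T
            m = chain_top.atom_masses
            com = m @ xyz / m.sum()
            for attempt in range(1000):
                pos = rng.uniform(0.0, params.box_length, size=3)
                if params.min_com_separation <= 0:
                    break
                d = np.array(placed_coms) - pos if placed_coms else np.empty((0, 3))
                d -= box * np.round(d / box)
                if d.size == 0 or np.min(np.linalg.norm(d, axis=1)) >= params.min_com_separation:
                    break
            else:
                raise ValueError("cannot place chains: box too small at the "
                                 "requested hard-core separation")
            placed_coms.append(pos)
            all_coords[f, offs[ci]:offs[ci + 1]] = xyz - com + pos

    first = AtomisticConfig(coords=all_coords[0], box=box, topology=topology)
    cg0 = map_to_cg(first, composition)
    cg_coords = np.empty((n_frames, topology.total_monomers, 3))
    for f in range(n_frames):
        cfg = AtomisticConfig(coords=all_coords[f], box=box, topology=topology)
        cg_coords[f] = map_to_cg(cfg, composition).Q
    return Ensemble(topology=topology, box=box, coords=all_coords, cg=cg0,
                    cg_coords=cg_coords, params=params)


@dataclass
class GroundTruth:
    """Analytic reference distributions of a generator configuration."""

    params: GeneratorParams

    def torsion_density(self, class_name: str, label: str, grid: np.ndarray) -> np.ndarray:
        """Analytic torsion density (per radian) on ``grid`` (radians)."""
        return self.params.torsions[class_name][label].pdf(grid)

    def bond_length(self, bond_class: str) -> float:
        return self.params.bond_lengths[bond_class]

    def angle_params(self, angle_class: str):
        return self.params.angles[angle_class]

    def to_json(self, grid_points: int = 361) -> str:
        grid = np.linspace(-np.pi, np.pi, grid_points)
        out = {
            "bond_lengths": self.params.bond_lengths,
            "angles": self.params.angles,
            "torsion_grid_deg": list(np.degrees(grid)),
            "torsions": {
                cls: {lab: list(self.torsion_density(cls, lab, grid))
                      for lab in ("L", "D")}
                for cls in self.params.torsions
            },
        }
        return json.dumps(out)


def ground_truth(params: GeneratorParams) -> GroundTruth:
    return GroundTruth(params=params)


def freely_rotating_msid(n, b: float, theta_deg: float) -> np.ndarray:
    """Closed-form mean-squared internal distance of a freely rotating chain.

    ``<R_n^2> = n b^2 (1+c)/(1-c) - 2 b^2 c (1-c^n)/(1-c)^2`` with
    ``c = -cos(theta)`` the correlation of successive bond vectors; the
    freely jointed limit (c = 0) gives ``n b^2``.
    """
    n = np.asarray(n, dtype=float)
    c = -np.cos(theta_deg * _DEG)
    if abs(c) < 1e-12:
        return n * b * b
    return n * b * b * (1 + c) / (1 - c) - 2 * b * b * c * (1 - c ** n) / (1 - c) ** 2
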