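"""Validation statistics: torsion distributions, RDFs, internal distances,
radius of gyration, density and block averaging.

These are the observables used to judge backmapped structures against
their source ensembles.  All of them are invariant under rigid motion of
every frame; errors are estimated by the block-average method (default
four contiguous blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import dihedral_angles, minimum_image

__all__ = [
    "Histogram",
    "RDFProfile",
    "InternalDistanceProfile",
    "select_dihedrals",
    "dihedral_distribution",
    "rdf",
    "internal_distances",
    "radius_of_gyration",
    "density",
    "block_average",
    "AMU_PER_NM3_TO_KG_M3",
]

AMU_PER_NM3_TO_KG_M3 = 1.66053906892e3  # 1 amu/nm^3 in kg/m^3


@dataclass
class Histogram:
    """Normalized histogram: the density integrates to one."""

    edges: np.ndarray
    density: np.ndarray
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class RDFProfile:
    r: np.ndarray           # bin centers, nm
    g: np.ndarray
    mode: str               # intramolecular | intermolecular
    n_pairs: int            # pairs satisfying the mode filter (per frame)


@dataclass
class InternalDistanceProfile:
    n: np.ndarray                 # backbone separations
    msid_over_n: np.ndarray       # <R_n^2>/n, nm^2
    ci: np.ndarray                # block-average half-widths


def select_dihedrals(topology, class_name: str | None = None,
                     stereo: str | None = None,
                     intermonomeric: bool | None = None):
    """Per-chain dihedral row indices matching a named class.

    ``class_name`` is the canonical atom-name string (e.g. "O1-C2-C3-O1"),
    ``stereo`` the stereo context of the two central atoms ("LL", "LD", ...,
    or "L"/"D" to match either central monomer), ``intermonomeric``
    restricts to dihedrals spanning more than one monomer.  Returns a list
    of index arrays, one per chain.
    """
    out = []
    for chain in topology.chains:
        keep = np.ones(len(chain.dihedrals), dtype=bool)
        if class_name is not None:
            keep &= np.array([nm == class_name for nm in chain.dihedral_names])
        if stereo is not None:
            if len(stereo) == 2:
                keep &= np.array([st == stereo for st in chain.dihedral_stereo])
            else:
                keep &= np.array([stereo in st for st in chain.dihedral_stereo])
        if intermonomeric is not None:
            spans = np.array([
                len({chain.atom_monomer[i] for i in quad}) > 1
                for quad in chain.dihedrals])
            keep &= spans if intermonomeric else ~spans
        out.append(np.where(keep)[0])
    return out


def dihedral_distribution(ensemble, class_name: str | None = None,
                          stereo: str | None = None,
                          bins: int = 100,
                          intermonomeric: bool | None = None) -> Histogram:
    """Pooled, normalized dihedral-angle histogram over (-180, 180] degrees."""
    selections = select_dihedrals(ensemble.topology, class_name, stereo, intermonomeric)
    if sum(len(s) for s in selections) == 0:
        raise ValueError(f"empty dihedral selection ({class_name!r}, stereo={stereo!r})")
    offs = ensemble.topology.chain_atom_offsets
    values = []
    for f in range(ensemble.n_frames):
        frame = ensemble.coords[f]
        for ci, chain in enumerate(ensemble.topology.chains):
            sel = selections[ci]
            if len(sel) == 0:
                continue
            quads = chain.dihedrals[sel]
            values.append(np.degrees(
                dihedral_angles(frame[offs[ci]:offs[ci + 1]], quads)))
    values = np.concatenate(values)
    values = values[np.isfinite(values)]
    dens, edges = np.histogram(values, bins=bins, range=(-180.0, 180.0), density=True)
    return Histogram(edges=edges, density=dens, n_samples=len(values))


def rdf(ensemble, selection_a, selection_b, mode: str = "intermolecular",
        r_max: float = 1.0, bin_width: float = 0.01) -> RDFProfile:
    """Radial distribution function between two atom selections.

    Pair distances use the minimum-image convention; ``intramolecular``
    counts only same-chain pairs and ``intermolecular`` only
    different-chain pairs.  Normalization is against the ideal-gas shell
    expectation at the selections' pair density, so an uncorrelated system
    gives g(r) = 1.
    """
    if mode not in ("intramolecular", "intermolecular"):
        raise ValueError(f"unknown RDF mode {mode!r}")
    box = ensemble.box
    if r_max >= box.min() / 2:
        raise ValueError(f"r_max={r_max} must be below half the smallest box length "
                         f"({box.min() / 2:.3f} nm)")
    sel_a = np.asarray(selection_a, dtype=np.int64)
    sel_b = np.asarray(selection_b, dtype=np.int64)

    # chain id per atom
    chain_id = np.empty(ensemble.topology.total_atoms, dtype=np.int64)
    offs = ensemble.topology.chain_atom_offsets
    for ci in range(ensemble.topology.n_chains):
        chain_id[offs[ci]:offs[ci + 1]] = ci
    same_chain = chain_id[sel_a][:, None] == chain_id[sel_b][None, :]
    valid = same_chain if mode == "intramolecular" else ~same_chain
    valid &= sel_a[:, None] != sel_b[None, :]
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        raise ValueError(f"no {mode} pairs between the given selections")

    n_bins = int(np.round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts = np.zeros(n_bins)
    for f in range(ensemble.n_frames):
        ra = ensemble.coords[f][sel_a]
        rb = ensemble.coords[f][sel_b]
        d = minimum_image(ra[:, None, :] - rb[None, :, :], box)
        dist = np.linalg.norm(d, axis=-1)[valid]
        h, _ = np.histogram(dist, bins=edges)
        counts += h

    volume = float(np.prod(box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * shell / volume * ensemble.n_frames
    g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    return RDFProfile(r=0.5 * (edges[:-1] + edges[1:]), g=g, mode=mode, n_pairs=n_pairs)


def internal_distances(ensemble, n_blocks: int = 4) -> InternalDistanceProfile:
    """Mean-squared internal distances <R_n^2>/n along chain backbones.

    Averages over all backbone atom pairs separated by n bonds, all
    chains and all frames (unwrapped coordinates); the confidence
    half-width comes from block averaging over frames.
    """
    offs = ensemble.topology.chain_atom_offsets
    lengths = [len(c.backbone) for c in ensemble.topology.chains]
    n_max = min(lengths) - 1
    per_frame = np.zeros((ensemble.n_frames, n_max))
    for f in range(ensemble.n_frames):
        frame = ensemble.coords[f]
        acc = np.zeros(n_max)
        cnt = np.zeros(n_max)
        for ci, chain in enumerate(ensemble.topology.chains):
            bb = frame[offs[ci]:offs[ci + 1]][chain.backbone]
            L = len(bb)
            for n in range(1, min(L, n_max + 1)):
                d = bb[n:] - bb[:-n]
                acc[n - 1] += np.sum(np.einsum("ij,ij->i", d, d))
                cnt[n - 1] += L - n
        per_frame[f] = acc / cnt
    ns = np.arange(1, n_max + 1)
    means = np.empty(n_max)
    cis = np.empty(n_max)
    for i in range(n_max):
        means[i], cis[i] = block_average(per_frame[:, i], n_blocks)
    return InternalDistanceProfile(n=ns, msid_over_n=means / ns, ci=cis / ns)


def radius_of_gyration(ensemble, n_blocks: int = 4):
    """Mass-weighted radius of gyration averaged over chains and frames."""
    offs = ensemble.topology.chain_atom_offsets
    per_frame = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        vals = []
        for ci, chain in enumerate(ensemble.topology.chains):
            xyz = ensemble.coords[f][offs[ci]:offs[ci + 1]]
            m = chain.atom_masses
            com = m @ xyz / m.sum()
            vals.append(np.sqrt(np.sum(m * np.sum((xyz - com) ** 2, axis=1)) / m.sum()))
        per_frame[f] = np.mean(vals)
    return block_average(per_frame, n_blocks)


def density(ensemble, n_blocks: int = 4):
    """Mass density of the box in kg/m^3 (constant box: zero spread)."""
    total_mass = ensemble.topology.atom_masses.sum()
    volume = float(np.prod(ensemble.box))
    rho = total_mass / volume * AMU_PER_NM3_TO_KG_M3
    series = np.full(max(ensemble.n_frames, n_blocks), rho)
    return block_average(series, n_blocks)


def block_average(series, n_blocks: int = 4):
    """Mean and std of contiguous block means (trailing remainder dropped)."""
    series = np.asarray(series, dtype=float)
    if len(series) < n_blocks:
        raise ValueError(f"series of length {len(series)} is shorter than "
                         f"{n_blocks} blocks")
    m = len(series) // n_blocks
    blocks = series[:m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(blocks.mean()), float(blocks.std())
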