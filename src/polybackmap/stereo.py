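"""Chirality assignment, sequence checking and reflection-based correction.

The handedness of each monomer is read off the signed volume (scalar
triple product) of the three substituent vectors of the alpha carbon seen
from H5.  The sign-to-label convention below is fixed by the canonical L
monomer of the synthetic generator and is consistent system-wide; a CIP
cross-check for the fixed substituent priority O1 > C3 > C4 > H5 is
provided (L corresponds to the (S) descriptor, as for lactic acid).

A wrong monomer is corrected by mirroring H5 and the methyl group through
the plane containing C2, O1 and C3 — the unique plane that keeps the
backbone fixed while swapping the two off-backbone substituents.  The
reflection is an isometry and an involution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import reflect_through_plane, signed_volume
from .topology import ChainTopology, SystemTopology

__all__ = [
    "StereoReport",
    "chirality_label",
    "check_sequence",
    "correct_monomer",
    "correct_all",
    "cip_descriptor",
    "L_SIGN",
    "DEGENERATE_VOLUME",
]

# sign of det[rO1-rH5, rC3-rH5, rC4-rH5] for the generator's canonical L monomer
L_SIGN = +1.0
# |triple product| below this (nm^3) means a planar/degenerate center
DEGENERATE_VOLUME = 1e-6

_REFLECTED_ATOMS = ("H5", "C4", "H6", "H7", "H8")


@dataclass
class StereoReport:
    """Per-monomer chirality labels and mismatch statistics."""

    labels: list            # assigned {L, D, undefined} per monomer (global order)
    requested: list
    mismatch_indices: np.ndarray

    @property
    def n_monomers(self) -> int:
        return len(self.labels)

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_indices)

    @property
    def mismatch_percent(self) -> float:
        return 100.0 * self.mismatch_count / self.n_monomers

    def summary(self) -> str:
        """``count/percent`` with the percent at 2 significant figures."""
        pct = self.mismatch_percent
        if pct == 0:
            return f"{self.mismatch_count}/0"
        return f"{self.mismatch_count}/{pct:.2g}"

    def to_dict(self) -> dict:
        return {
            "n_monomers": self.n_monomers,
            "mismatch_count": self.mismatch_count,
            "mismatch_percent": float(self.mismatch_percent),
            "summary": self.summary(),
            "mismatch_indices": [int(i) for i in self.mismatch_indices],
        }


def _center_indices(chain: ChainTopology, monomer: int):
    return chain.chiral_centers[monomer]  # (C2, O1, C3, C4, H5)


def chirality_label(coords: np.ndarray, chain: ChainTopology, monomer: int) -> str:
    """Label one monomer {L, D, undefined} from its chiral-center geometry."""
    c2, o1, c3, c4, h5 = _center_indices(chain, monomer)
    r = coords
    det = signed_volume(r[o1] - r[h5], r[c3] - r[h5], r[c4] - r[h5])
    if abs(det) < DEGENERATE_VOLUME:
        return "undefined"
    return "L" if det * L_SIGN > 0 else "D"


def cip_descriptor(coords: np.ndarray, chain: ChainTopology, monomer: int) -> str:
    """R/S descriptor under the fixed priority O1 > C3 > C4 > H5.

    Independent cross-check of :func:`chirality_label`; for this center
    the (S) descriptor corresponds to the L label.
    """
    c2, o1, c3, c4, h5 = _center_indices(chain, monomer)
    r = coords
    det = signed_volume(r[o1] - r[c2], r[c3] - r[c2], r[c4] - r[c2])
    if abs(det) < DEGENERATE_VOLUME:
        return "undefined"
    return "S" if det > 0 else "R"


def _iter_chain_monomers(topology: SystemTopology):
    a_off = topology.chain_atom_offsets
    g = 0
    for ci, chain in enumerate(topology.chains):
        for mi in range(chain.n_monomers):
            yield g, ci, chain, mi, a_off[ci]
            g += 1


def check_sequence(coords: np.ndarray, topology: SystemTopology,
                   requested) -> StereoReport:
    """Compare assigned chirality labels against the requested sequences.

    ``requested`` is one sequence per chain.  An undefined center counts
    as a mismatch; the percentage is over all monomers in the system.
    """
    requested = [list(s) for s in requested]
    if len(requested) != topology.n_chains:
        raise ValueError("one requested sequence per chain is required")
    for chain, seq in zip(topology.chains, requested):
        if len(seq) != chain.n_monomers:
            raise ValueError("requested sequence length does not match chain")
    labels, want, bad = [], [], []
    for g, ci, chain, mi, off in _iter_chain_monomers(topology):
        lab = chirality_label(coords[off:off + chain.n_atoms], chain, mi)
        labels.append(lab)
        want.append(requested[ci][mi])
        if lab != requested[ci][mi]:
            bad.append(g)
    return StereoReport(labels=labels, requested=want,
                        mismatch_indices=np.array(bad, dtype=np.int64))


def correct_monomer(coords: np.ndarray, chain: ChainTopology, monomer: int) -> np.ndarray:
    """Flip one monomer's handedness by reflecting H5 and the methyl group.

    Mirrors H5, C4 and H6-H8 through the C2/O1/C3 plane; all other atoms
    are untouched.  Returns a new coordinate array.
    """
    c2, o1, c3, c4, h5 = _center_indices(chain, monomer)
    idx = [chain.atom_index(monomer, nm) for nm in _REFLECTED_ATOMS]
    out = np.array(coords, copy=True)
    out[idx] = reflect_through_plane(coords[idx], coords[c2], coords[o1], coords[c3])
    return out


def correct_all(coords: np.ndarray, topology: SystemTopology, requested):
    """Correct every mismatching monomer; returns (coords, before, after).

    Undefined centers cannot be corrected by reflection and are left for
    the after-report (reported unresolved).
    """
    before = check_sequence(coords, topology, requested)
    bad = set(before.mismatch_indices.tolist())
    out = np.array(coords, copy=True)
    for g, ci, chain, mi, off in _iter_chain_monomers(topology):
        if g in bad and before.labels[g] != "undefined":
            out[off:off + chain.n_atoms] = correct_monomer(
                out[off:off + chain.n_atoms], chain, mi)
    after = check_sequence(out, topology, requested)
    return out, before, after


def min_distance_audit(coords: np.ndarray, indices, cutoff: float = 0.12) -> dict:
    """Report atom pairs closer than ``cutoff`` nm around corrected monomers.

    Reflection can create a few overlaps; they are reported, not resolved
    (that is the job of downstream relaxation outside this package).
    """
    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    pairs = []
    for i in indices:
        for j in tree.query_ball_point(coords[i], cutoff):
            if j != i:
                pairs.append((int(min(i, j)), int(max(i, j))))
    pairs = sorted(set(pairs))
    return {"cutoff_nm": cutoff, "n_close_pairs": len(pairs), "pairs": pairs}
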