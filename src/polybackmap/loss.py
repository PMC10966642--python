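"""Composite physics-informed training loss on bond vectors.

Five terms, each a mean penalty over its own count of geometric objects:

* ``L_bv`` — squared Euclidean deviation of the bond vectors,
* ``L_bl`` — squared deviation of the bond lengths (vector magnitudes),
* ``L_ba`` — squared deviation of the bending angles (radians),
* ``L_da`` — ``1 - cos(dphi)`` of the dihedral angles (periodic-safe),
* ``L_v0`` — squared deviation of the anchor vectors.

The total is the weighted linear combination; the reference model uses
``lambda_bv = lambda_bl = 1`` and zero for the rest.  All terms act on
unscaled (nm) vectors so the weights are physically comparable: the
[-1, 1] tanh scaling is inverted inside the loss.  Padding rows
contribute nothing.

Angle and dihedral terms need Cartesian geometry; positions are an
affine function of the predicted vectors (traversal cumulative sums,
center-of-mass anchoring onto beads reconstructed from the sample's CG
displacement features), so their gradients are exact and are verified
against finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .represent import DEFAULT_CG_SCALE, DEFAULT_VECTOR_SCALE, build_scheme
from .topology import ChainTopology

__all__ = ["LossWeights", "LossTerms", "PhysicsLoss", "total_loss"]

_EPS = 1e-8


@dataclass(frozen=True)
class LossWeights:
    lambda_bv: float = 1.0
    lambda_bl: float = 1.0
    lambda_ba: float = 0.0
    lambda_da: float = 0.0
    lambda_v0: float = 0.0

    def __post_init__(self):
        vals = (self.lambda_bv, self.lambda_bl, self.lambda_ba,
                self.lambda_da, self.lambda_v0)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass
class LossTerms:
    bv: float
    bl: float
    ba: float
    da: float
    v0: float

    def total(self, w: LossWeights) -> float:
        return (w.lambda_bv * self.bv + w.lambda_bl * self.bl +
                w.lambda_ba * self.ba + w.lambda_da * self.da +
                w.lambda_v0 * self.v0)

    def as_dict(self) -> dict:
        return {"bv": self.bv, "bl": self.bl, "ba": self.ba,
                "da": self.da, "v0": self.v0}


def total_loss(terms: LossTerms, weights: LossWeights) -> float:
    """Weighted linear combination of the five terms."""
    return terms.total(weights)


class PhysicsLoss:
    """Loss evaluator bound to one chain layout.

    Precomputes the affine operator taking (unscaled) per-row vectors to
    bead-anchored Cartesian positions, plus the bonded index tables.
    """

    def __init__(self, chain: ChainTopology, scheme=None,
                 vector_scale: float = DEFAULT_VECTOR_SCALE,
                 cg_scale: float = DEFAULT_CG_SCALE):
        if scheme is None:
            scheme = build_scheme(chain)
        self.chain = chain
        self.scheme = scheme
        self.vector_scale = vector_scale
        self.cg_scale = cg_scale
        n = chain.n_atoms
        self.n_rows = n
        self.anchor_rows = scheme.anchor_rows
        self.bond_rows = scheme.bond_rows
        self.mon = chain.atom_monomer

        # prov = T @ vec (path indicator along the traversal tree)
        T = np.zeros((n, n), dtype=np.float32)
        for a in range(n):
            i = a
            while scheme.parents[i] >= 0:
                T[a, i] = 1.0
                i = scheme.parents[i]
        # per-monomer mass-weighted COM removal
        W = np.zeros((n, n), dtype=np.float32)
        for s, e in chain.monomer_slices:
            w = chain.atom_masses[s:e] / chain.atom_masses[s:e].sum()
            W[s:e, s:e] = w[None, :]
        self.A = (np.eye(n, dtype=np.float32) - W) @ T

        self.angles = chain.angles
        self.dihedrals = chain.dihedrals

    # ------------------------------------------------------------------
    def _vectors(self, arr: np.ndarray) -> np.ndarray:
        return np.asarray(arr, dtype=np.float64)[:, :self.n_rows] * self.vector_scale

    def _positions(self, vec: np.ndarray, inputs: np.ndarray | None):
        """Bead-anchored positions (up to a global translation per chain)."""
        pos = self.A @ vec
        if inputs is not None:
            disp = np.asarray(inputs, dtype=np.float64)[:, :self.n_rows, :3] * self.cg_scale
            # one CG displacement per monomer; rows of a monomer repeat it
            first_rows = np.array([s for s, _ in self.chain.monomer_slices])
            q_rel = np.cumsum(disp[:, first_rows], axis=1)
            pos = pos + q_rel[:, self.mon]
        return pos

    # ------------------------------------------------------------------
    def terms(self, predicted, target, mask=None, inputs=None) -> LossTerms:
        t, _, _ = self._evaluate(predicted, target, inputs, want_grad=False)
        return t

    def value_and_grad(self, predicted, target, weights: LossWeights,
                       inputs=None):
        """Returns (terms, total, d total/d predicted) on the scaled scale."""
        terms, total, gvec = self._evaluate(predicted, target, inputs,
                                            want_grad=True, weights=weights)
        S = np.asarray(predicted).shape[1]
        gpred = np.zeros((gvec.shape[0], S, 3), dtype=np.float32)
        gpred[:, :self.n_rows] = gvec * self.vector_scale
        return terms, total, gpred

    # ------------------------------------------------------------------
    def _evaluate(self, predicted, target, inputs, want_grad: bool,
                  weights: LossWeights | None = None):
        pred = np.asarray(predicted)
        if pred.ndim == 2:
            pred = pred[None]
            target = np.asarray(target)[None]
            if inputs is not None:
                inputs = np.asarray(inputs)[None]
        vec_p = self._vectors(pred)
        vec_t = self._vectors(target)
        B = vec_p.shape[0]
        br, ar = self.bond_rows, self.anchor_rows
        gvec = np.zeros_like(vec_p) if want_grad else None
        w = weights or LossWeights(1, 1, 0, 0, 0)

        # bond vectors
        d_bv = vec_p[:, br] - vec_t[:, br]
        n_bv = B * len(br)
        L_bv = float(np.sum(d_bv ** 2) / n_bv)
        # bond lengths
        len_p = np.linalg.norm(vec_p[:, br], axis=-1)
        len_t = np.linalg.norm(vec_t[:, br], axis=-1)
        dlen = len_p - len_t
        L_bl = float(np.sum(dlen ** 2) / n_bv)
        # anchors
        d_v0 = vec_p[:, ar] - vec_t[:, ar]
        n_v0 = B * len(ar)
        L_v0 = float(np.sum(d_v0 ** 2) / n_v0)

        if want_grad:
            if w.lambda_bv:
                gvec[:, br] += w.lambda_bv * 2.0 * d_bv / n_bv
            if w.lambda_bl:
                safe = np.maximum(len_p, _EPS)
                gvec[:, br] += (w.lambda_bl * 2.0 * dlen / n_bv / safe)[..., None] \
                    * vec_p[:, br]
            if w.lambda_v0:
                gvec[:, ar] += w.lambda_v0 * 2.0 * d_v0 / n_v0

        # angles / dihedrals from bead-anchored positions; without `inputs`
        # all beads sit at the origin and inter-monomer geometry is meaningless,
        # so pass the encoded inputs whenever lambda_ba/lambda_da matter.
        pos_p = self._positions(vec_p, inputs)
        pos_t = self._positions(vec_t, inputs)

        th_p, ang_cache = _angles(pos_p, self.angles)
        th_t, _ = _angles(pos_t, self.angles)
        dth = th_p - th_t
        n_th = B * len(self.angles)
        L_ba = float(np.sum(dth ** 2) / n_th)

        ph_p, dih_cache = _dihedrals(pos_p, self.dihedrals)
        ph_t, _ = _dihedrals(pos_t, self.dihedrals)
        dph = ph_p - ph_t
        n_ph = B * len(self.dihedrals)
        L_da = float(np.sum(1.0 - np.cos(dph)) / n_ph)

        if want_grad and (w.lambda_ba or w.lambda_da):
            gpos = np.zeros_like(pos_p)
            if w.lambda_ba:
                _angles_backward(gpos, w.lambda_ba * 2.0 * dth / n_th,
                                 self.angles, ang_cache)
            if w.lambda_da:
                _dihedrals_backward(gpos, w.lambda_da * np.sin(dph) / n_ph,
                                    self.dihedrals, dih_cache)
            # pos = A @ vec + const  =>  gvec += A^T gpos
            gvec += np.swapaxes(self.A, 0, 1) @ gpos

        terms = LossTerms(bv=L_bv, bl=L_bl, ba=L_ba, da=L_da, v0=L_v0)
        total = terms.total(w)
        return terms, total, gvec


# ----------------------------------------------------------------------
def _angles(pos, triples):
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    u = pos[:, i] - pos[:, j]
    v = pos[:, k] - pos[:, j]
    nu = np.maximum(np.linalg.norm(u, axis=-1), _EPS)
    nv = np.maximum(np.linalg.norm(v, axis=-1), _EPS)
    c = np.einsum("bnd,bnd->bn", u, v) / (nu * nv)
    c = np.clip(c, -1.0 + 1e-7, 1.0 - 1e-7)
    theta = np.arccos(c)
    return theta, (u, v, nu, nv, c)


def _angles_backward(gpos, gtheta, triples, cache):
    u, v, nu, nv, c = cache
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    dc = (-1.0 / np.sqrt(1.0 - c * c)) * gtheta
    gu = dc[..., None] * (v / (nu * nv)[..., None] - (c / nu ** 2)[..., None] * u)
    gv = dc[..., None] * (u / (nu * nv)[..., None] - (c / nv ** 2)[..., None] * v)
    _scatter(gpos, i, gu)
    _scatter(gpos, j, -gu - gv)
    _scatter(gpos, k, gv)


def _dihedrals(pos, quads):
    p1, p2, p3, p4 = (pos[:, quads[:, t]] for t in range(4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.maximum(np.linalg.norm(b2, axis=-1), _EPS)
    m1 = np.cross(n1, b2 / nb2[..., None])
    x = np.einsum("bnd,bnd->bn", n1, n2)
    y = np.einsum("bnd,bnd->bn", m1, n2)
    phi = np.arctan2(y, x)
    return phi, (b1, b2, b3, n1, n2, nb2)


def _dihedrals_backward(gpos, gphi, quads, cache):
    b1, b2, b3, n1, n2, nb2 = cache
    sn1 = np.maximum(np.einsum("bnd,bnd->bn", n1, n1), _EPS)
    sn2 = np.maximum(np.einsum("bnd,bnd->bn", n2, n2), _EPS)
    dp1 = (nb2 / sn1)[..., None] * n1
    dp4 = (-nb2 / sn2)[..., None] * n2
    c12 = (np.einsum("bnd,bnd->bn", b1, b2) / nb2 ** 2)[..., None]
    c32 = (np.einsum("bnd,bnd->bn", b3, b2) / nb2 ** 2)[..., None]
    dp2 = -(1.0 + c12) * dp1 + c32 * dp4
    dp3 = c12 * dp1 - (1.0 + c32) * dp4
    g = gphi[..., None]
    i, j, k, l = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    _scatter(gpos, i, g * dp1)
    _scatter(gpos, j, g * dp2)
    _scatter(gpos, k, g * dp3)
    _scatter(gpos, l, g * dp4)


def _scatter(gpos, idx, vals):
    # scatter-add along the atom axis (the swapped array is a view of gpos)
    np.add.at(np.swapaxes(gpos, 0, 1), idx, np.swapaxes(vals, 0, 1))
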