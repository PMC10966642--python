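"""End-to-end backmapping: CG input -> prediction -> Cartesian
reconstruction -> stereo check/correct -> QC report.

The downstream molecular-dynamics relaxation that a melt configuration
ultimately needs (excluded volume, thermalization) is outside this
package; instead the pipeline emits quality-control metrics — implied
inter-monomer bond statistics, a minimum-distance audit and the
CG-consistency residual — together with coordinates ready for an
external MD engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .nn import load_checkpoint
from .represent import (CGConfig, AtomisticConfig, build_scheme, decode_vectors,
                        encode_input, fragment_chain, map_to_cg, next_pow2,
                        DEFAULT_CG_SCALE, DEFAULT_VECTOR_SCALE)
from .stereo import StereoReport, correct_all

__all__ = ["PipelineResult", "backmap", "qc_report"]

CG_RESIDUAL_TOL = 1e-6  # nm


@dataclass
class PipelineResult:
    config: AtomisticConfig
    report_before: StereoReport
    report_after: StereoReport
    qc: dict


def backmap(cg: CGConfig, sequences, checkpoint=None, model=None,
            vector_scale: float = DEFAULT_VECTOR_SCALE,
            cg_scale: float = DEFAULT_CG_SCALE,
            fragment_size: int | None = None,
            batch_size: int = 64) -> PipelineResult:
    """Reconstruct an all-atom configuration from a CG one.

    ``model`` is any object with ``predict((B, S, k+3)) -> (B, S, 3)``;
    alternatively ``checkpoint`` names a saved network whose metadata
    (k, scales, scheme version) must match the CG input.  Chains longer
    than the fragment size are processed as consecutive fragments.
    """
    if model is None:
        if checkpoint is None:
            raise ValueError("either a model or a checkpoint is required")
        model, meta = load_checkpoint(checkpoint, expect={"k": int(cg.k)})
        vector_scale = meta["vector_scale"]
        cg_scale = meta["cg_scale"]
        fragment_size = fragment_size or meta.get("fragment_size")

    top = cg.topology
    coords = np.empty((top.total_atoms, 3))
    a_off = top.chain_atom_offsets
    m_off = top.chain_monomer_offsets

    # group (chain, fragment) jobs by padded height so they batch cleanly
    jobs = []
    for ci, chain in enumerate(top.chains):
        s = fragment_size or chain.n_monomers
        for frag in fragment_chain(chain, s):
            a0 = chain.monomer_slices[frag[0]][0]
            a1 = chain.monomer_slices[frag[1] - 1][1]
            jobs.append((ci, frag, next_pow2(a1 - a0), a0, a1))
    schemes = {id(c): build_scheme(c) for c in top.chains}

    by_S = {}
    for job in jobs:
        by_S.setdefault(job[2], []).append(job)
    for S, group in by_S.items():
        for i in range(0, len(group), batch_size):
            chunk = group[i:i + batch_size]
            X = np.stack([
                encode_input(top.chains[ci], cg.chain_Q(ci), cg.chain_c(ci),
                             cg.k, cg_scale=cg_scale, S=S, monomers=frag)
                for ci, frag, _, _, _ in chunk])
            pred = model.predict(X)
            for (ci, frag, _, a0, a1), p in zip(chunk, pred):
                chain = top.chains[ci]
                mask = np.zeros(S, dtype=bool)
                mask[:a1 - a0] = True
                xyz = decode_vectors(p, mask, chain, cg.chain_Q(ci),
                                     scheme=schemes[id(chain)],
                                     vector_scale=vector_scale, monomers=frag)
                coords[a_off[ci] + a0:a_off[ci] + a1] = xyz

    # the decoded (pre-correction) structure is exactly bead-anchored;
    # stereo reflection moves the COM of each corrected monomer slightly,
    # so both residuals are reported
    decoded = AtomisticConfig(coords=coords, box=cg.box, topology=top)
    residual_decoded = float(np.abs(map_to_cg(decoded).Q - cg.Q).max())
    corrected, before, after = correct_all(coords, top, sequences)
    config = AtomisticConfig(coords=corrected, box=cg.box, topology=top)
    qc = _qc_metrics(config, cg)
    qc["cg_residual_nm"] = residual_decoded
    return PipelineResult(config=config, report_before=before,
                          report_after=after, qc=qc)


def _qc_metrics(config: AtomisticConfig, cg: CGConfig) -> dict:
    top = config.topology
    a_off = top.chain_atom_offsets
    # implied inter-monomer bonds: C3(i) -> O1(i+1), not used for placement
    implied = []
    rg = []
    for ci, chain in enumerate(top.chains):
        xyz = config.coords[a_off[ci]:a_off[ci + 1]]
        for mi in range(chain.n_monomers - 1):
            c3 = chain.atom_index(mi, "C3")
            o1 = chain.atom_index(mi + 1, "O1")
            implied.append(np.linalg.norm(xyz[o1] - xyz[c3]))
        m = chain.atom_masses
        com = m @ xyz / m.sum()
        rg.append(float(np.sqrt(np.sum(m * np.sum((xyz - com) ** 2, axis=1)) / m.sum())))
    implied = np.asarray(implied)

    tree = cKDTree(config.coords)
    dmin, _ = tree.query(config.coords, k=2)
    min_dist = float(dmin[:, 1].min())

    remapped = map_to_cg(config, composition="homopolymer")
    residual = float(np.abs(remapped.Q - cg.Q).max())
    return {
        "implied_bond_mean_nm": float(implied.mean()) if len(implied) else float("nan"),
        "implied_bond_std_nm": float(implied.std()) if len(implied) else float("nan"),
        "min_interatomic_distance_nm": min_dist,
        "cg_residual_after_correction_nm": residual,
        "radius_of_gyration_nm": rg,
    }


def qc_report(result: PipelineResult) -> dict:
    """JSON-ready quality-control report (stereo in 'count/percent' form)."""
    if result.config.topology.total_atoms == 0:
        raise ValueError("empty system")
    qc = dict(result.qc)
    if qc["cg_residual_nm"] > CG_RESIDUAL_TOL:
        qc["cg_consistency_warning"] = (
            f"residual {qc['cg_residual_nm']:.2e} nm exceeds {CG_RESIDUAL_TOL} nm")
    return {
        "stereo_before": result.report_before.to_dict(),
        "stereo_after": result.report_after.to_dict(),
        **qc,
    }
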