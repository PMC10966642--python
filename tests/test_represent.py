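"""CG mapping, type assignment and the bond-vector codec."""

import numpy as np
import pytest

from polybackmap.represent import (AtomisticConfig, assign_types, build_scheme,
                                   decode_vectors, encode_chain, fragment_chain,
                                   map_to_cg, next_pow2)
from polybackmap.topology import build_chain, build_system


def _chain_sample(ensemble, frame=0, chain=0):
    top = ensemble.topology
    a = top.chain_atom_offsets
    m = top.chain_monomer_offsets
    return (ensemble.coords[frame][a[chain]:a[chain + 1]],
            top.chains[chain],
            ensemble.cg_coords[frame][m[chain]:m[chain + 1]],
            ensemble.cg.c[m[chain]:m[chain + 1]],
            ensemble.cg.k)


class TestMapToCG:
    def test_equal_mass_midpoint(self):
        top = build_system(1, ["L"])
        chain = top.chains[0]
        coords = np.zeros((chain.n_atoms, 3))
        coords[:, 0] = np.linspace(0, 1, chain.n_atoms)
        cfg = AtomisticConfig(coords=coords, box=np.ones(3) * 5, topology=top)
        cg = map_to_cg(cfg)
        m = chain.atom_masses
        assert np.allclose(cg.Q[0], m @ coords / m.sum())

    def test_translation_equivariance(self, small_ensemble):
        cfg = small_ensemble.atomistic(0)
        cg = map_to_cg(cfg)
        shifted = AtomisticConfig(coords=cfg.coords + [1.0, -2.0, 0.5],
                                  box=cfg.box, topology=cfg.topology)
        cg2 = map_to_cg(shifted)
        assert np.allclose(cg2.Q, cg.Q + [1.0, -2.0, 0.5])

    def test_one_bead_per_monomer(self, small_ensemble):
        cg = map_to_cg(small_ensemble.atomistic(0))
        assert cg.Q.shape == (small_ensemble.topology.total_monomers, 3)


class TestAssignTypes:
    @pytest.mark.parametrize("composition,k", [
        ("homopolymer", 3), ("copolymer", 4), ("combined", 6)])
    def test_k_values(self, composition, k):
        sys = build_system(2, ["L"] * 5)
        _, got = assign_types(sys, composition)
        assert got == k

    def test_chain_ends_have_own_types(self):
        sys = build_system(1, ["L"] * 5)
        c, _ = assign_types(sys, "homopolymer")
        assert c[0] != c[1] and c[-1] != c[1]
        assert len(set(c[1:-1])) == 1

    def test_copolymer_distinguishes_interior_stereo(self):
        sys = build_system(1, list("LDDDL"))
        c, k = assign_types(sys, "copolymer")
        assert k == 4
        assert c[1] != c[2] or sys.chains[0].sequence[1] == sys.chains[0].sequence[2]

    def test_unknown_composition_rejected(self):
        sys = build_system(1, ["L"] * 3)
        with pytest.raises(ValueError):
            assign_types(sys, "blend")


class TestCodec:
    def test_tensor_layout_100mer(self):
        chain = build_chain(["L"] * 100)
        sys = build_system(1, ["L"] * 100)
        c, k = assign_types(sys, "homopolymer")
        rng = np.random.default_rng(0)
        # compact synthetic coordinates well inside the scale bound
        from polybackmap.synth import GeneratorParams, sample_chain
        coords = sample_chain(GeneratorParams(), chain.sequence, rng, topology=chain)
        Q = np.array([chain.atom_masses[s:e] @ coords[s:e] / chain.atom_masses[s:e].sum()
                      for s, e in chain.monomer_slices])
        sample = encode_chain(coords, chain, Q, c, k)
        assert sample.input.shape == (1024, k + 3)
        assert sample.target.shape == (1024, 3)
        assert sample.n_rows == 903
        assert np.all(sample.target[903:] == 0)
        assert np.all(sample.input[903:] == 0)
        assert np.abs(sample.target).max() <= 1.0

    def test_roundtrip(self, small_ensemble):
        coords, chain, Q, c, k = _chain_sample(small_ensemble)
        sample = encode_chain(coords, chain, Q, c, k)
        dec = decode_vectors(sample.target, sample.mask, chain, Q)
        assert np.abs(dec - coords).max() < 1e-6

    def test_cg_consistency_for_arbitrary_vectors(self, small_ensemble, rng):
        """Decoding any vector field must exactly re-map to the input beads."""
        coords, chain, Q, c, k = _chain_sample(small_ensemble)
        sample = encode_chain(coords, chain, Q, c, k)
        arbitrary = rng.uniform(-1, 1, size=sample.target.shape)
        dec = decode_vectors(arbitrary, sample.mask, chain, Q)
        for m, (s, e) in enumerate(chain.monomer_slices):
            w = chain.atom_masses[s:e]
            com = w @ dec[s:e] / w.sum()
            assert np.abs(com - Q[m]).max() < 1e-9

    def test_translation_invariance_of_encoding(self, small_ensemble):
        coords, chain, Q, c, k = _chain_sample(small_ensemble)
        a = encode_chain(coords, chain, Q, c, k)
        b = encode_chain(coords + 3.0, chain, Q + 3.0, c, k)
        assert np.allclose(a.input, b.input, atol=1e-6)
        assert np.allclose(a.target, b.target, atol=1e-6)

    def test_degenerate_all_atoms_at_com(self):
        chain = build_chain(["L"] * 2)
        sys = build_system(1, ["L"] * 2)
        c, k = assign_types(sys, "homopolymer")
        Q = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        coords = Q[chain.atom_monomer].astype(float)
        sample = encode_chain(coords, chain, Q, c, k)
        assert np.all(sample.target[sample.mask] == 0)

    def test_scale_violation_names_atom(self, small_ensemble):
        coords, chain, Q, c, k = _chain_sample(small_ensemble)
        bad = coords.copy()
        bad[5] += 2.0  # stretch one bond far beyond the vector scale
        with pytest.raises(ValueError, match="monomer"):
            encode_chain(bad, chain, Q, c, k)

    def test_fragments_concatenate_to_whole(self, homopolymer_ensemble):
        coords, chain, Q, c, k = _chain_sample(homopolymer_ensemble)
        frags = fragment_chain(chain, 3)
        assert [f[1] - f[0] for f in frags] == [3, 3, 2]
        full = encode_chain(coords, chain, Q, c, k)
        whole = decode_vectors(full.target, full.mask, chain, Q)
        pieces = []
        for frag in frags:
            s = encode_chain(coords, chain, Q, c, k, monomers=frag)
            pieces.append(decode_vectors(s.target, s.mask, chain, Q, monomers=frag))
        assert np.abs(np.concatenate(pieces) - whole).max() < 1e-6

    def test_fragment_size_validation(self):
        chain = build_chain(["L"] * 4)
        with pytest.raises(ValueError):
            fragment_chain(chain, 0)

    def test_next_pow2(self):
        assert next_pow2(903) == 1024
        assert next_pow2(273) == 512
        assert next_pow2(1) == 1


class TestScheme:
    def test_one_anchor_per_monomer(self, small_ensemble):
        chain = small_ensemble.topology.chains[0]
        scheme = build_scheme(chain)
        assert len(scheme.anchor_rows) == chain.n_monomers
        assert len(scheme.bond_rows) == chain.n_atoms - chain.n_monomers

    def test_parents_precede_children(self, small_ensemble):
        chain = small_ensemble.topology.chains[0]
        scheme = build_scheme(chain)
        for i in scheme.bond_rows:
            assert scheme.parents[i] < i
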