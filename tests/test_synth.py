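"""The synthetic-ensemble generator against its own declared statistics."""

import numpy as np
import pytest

from polybackmap.analysis import dihedral_distribution, internal_distances
from polybackmap.geometry import dihedral_angles
from polybackmap.stereo import chirality_label
from polybackmap.synth import (GeneratorParams, VonMisesMixture,
                               freely_rotating_msid, ground_truth,
                               pack_frames, sample_chain)
from polybackmap.topology import build_chain, build_system


class TestVonMisesMixture:
    def test_pdf_normalized(self):
        mix = VonMisesMixture((-65.0, 160.0), (12.0, 12.0), (0.6, 0.4))
        grid = np.linspace(-np.pi, np.pi, 2001)
        assert np.trapezoid(mix.pdf(grid), grid) == pytest.approx(1.0, abs=1e-6)

    def test_samples_match_analytic_density(self):
        """Sample histogram stays inside 3-sigma multinomial bands at n=1e5."""
        mix = VonMisesMixture((-65.0, 160.0), (10.0, 14.0), (0.7, 0.3))
        rng = np.random.default_rng(0)
        x = mix.sample(rng, size=100_000)
        edges = np.linspace(-np.pi, np.pi, 73)
        counts, _ = np.histogram(x, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p = mix.pdf(centers) * np.diff(edges)
        expected = len(x) * p
        sigma = np.sqrt(len(x) * p * (1 - p))
        assert np.all(np.abs(counts - expected) < 3.5 * sigma + 3)

    def test_mirrored_is_parity_image(self):
        mix = VonMisesMixture((-65.0, 160.0), (12.0, 12.0), (0.6, 0.4))
        grid = np.linspace(-np.pi, np.pi, 501)
        assert np.allclose(mix.mirrored().pdf(-grid), mix.pdf(grid))

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            VonMisesMixture((0.0,), (1.0,), (0.5,))


class TestSampleChain:
    def test_bond_lengths_exact(self):
        params = GeneratorParams()
        chain = build_chain(["L"] * 8)
        xyz = sample_chain(params, chain.sequence, np.random.default_rng(0),
                           topology=chain)
        names = chain.atom_names
        for a, b in chain.bonds:
            key = f"{names[a]}-{names[b]}"
            alt = f"{names[b]}-{names[a]}"
            bl = params.bond_lengths
            if names[a].startswith("H") and names[b] == "C4":
                want = bl["C4-H"]
            elif names[b].startswith("H") and names[a] == "C4":
                want = bl["C4-H"]
            else:
                want = bl.get(key, bl.get(alt))
            assert want is not None, key
            assert np.linalg.norm(xyz[a] - xyz[b]) == pytest.approx(want, abs=1e-9)

    def test_chirality_by_construction(self):
        seq = list("LDDLLDLD")
        chain = build_chain(seq)
        xyz = sample_chain(GeneratorParams(), seq, np.random.default_rng(1),
                           topology=chain)
        assert [chirality_label(xyz, chain, m) for m in range(len(seq))] == seq

    def test_backbone_torsions_follow_mixture(self):
        """Measured psi dihedrals on many chains match the analytic density."""
        params = GeneratorParams()
        chain = build_chain(["L"] * 30)
        rng = np.random.default_rng(2)
        quads = chain.dihedrals[[i for i, nm in enumerate(chain.dihedral_names)
                                 if nm == "O1-C2-C3-O1"]]
        vals = []
        for _ in range(120):
            xyz = sample_chain(params, chain.sequence, rng, topology=chain)
            vals.append(dihedral_angles(xyz, quads))
        vals = np.concatenate(vals)
        edges = np.linspace(-np.pi, np.pi, 37)
        dens, _ = np.histogram(vals, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ana = params.torsions["psi"]["L"].pdf(centers)
        assert np.abs(dens - ana).max() < 0.12 * ana.max()


class TestPackFrames:
    def test_frame_count_from_schedule(self):
        assert GeneratorParams().n_frames == 5000
        assert GeneratorParams(duration_ps=1000.0, save_interval_ps=200.0).n_frames == 5

    def test_seed_reproducibility(self, small_params):
        a = pack_frames(small_params, n_frames=2)
        b = pack_frames(small_params, n_frames=2)
        assert np.array_equal(a.coords, b.coords)
        c = pack_frames(GeneratorParams(n_chains=3, n_monomers=6,
                                        box_length=3.0, seed=43), n_frames=2)
        assert not np.array_equal(a.coords, c.coords)

    def test_cg_is_com_mapping(self, small_ensemble):
        top = small_ensemble.topology
        chain = top.chains[0]
        s, e = chain.monomer_slices[0]
        w = chain.atom_masses[s:e]
        com = w @ small_ensemble.coords[0][s:e] / w.sum()
        assert np.allclose(small_ensemble.cg_coords[0][0], com)

    def test_impossible_packing_rejected(self):
        params = GeneratorParams(n_chains=30, n_monomers=2, box_length=1.0,
                                 seed=0, min_com_separation=0.9)
        with pytest.raises(ValueError, match="box too small"):
            pack_frames(params, n_frames=1)

    def test_stereo_parity_of_torsion_statistics(self):
        """L and D homopolymers have mirror-image psi distributions."""
        pl = GeneratorParams(n_chains=2, n_monomers=12, box_length=4.0, seed=5)
        ens_l = pack_frames(pl, sequences=[["L"] * 12] * 2, n_frames=25)
        ens_d = pack_frames(pl, sequences=[["D"] * 12] * 2, n_frames=25)
        hl = dihedral_distribution(ens_l, class_name="O1-C2-C3-O1", bins=24)
        hd = dihedral_distribution(ens_d, class_name="O1-C2-C3-O1", bins=24)
        assert np.abs(hl.density - hd.density[::-1]).max() < 0.25 * hl.density.max()


class TestGroundTruth:
    def test_torsion_reference_integrates_to_one(self):
        gt = ground_truth(GeneratorParams())
        grid = np.linspace(-np.pi, np.pi, 1441)
        for cls in ("psi", "omega", "phi"):
            for lab in ("L", "D"):
                dens = gt.torsion_density(cls, lab, grid)
                assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-5)

    def test_reference_independent_of_frame_count(self):
        a = ground_truth(GeneratorParams(duration_ps=1e6))
        b = ground_truth(GeneratorParams(duration_ps=1e3))
        grid = np.linspace(-np.pi, np.pi, 11)
        assert np.allclose(a.torsion_density("psi", "L", grid),
                           b.torsion_density("psi", "L", grid))

    def test_freely_rotating_chain_limits(self):
        n = np.arange(1, 50)
        # freely jointed limit: flat b^2
        assert np.allclose(freely_rotating_msid(n, 0.15, 90.0), n * 0.15 ** 2)
        # generated freely-rotating-like chains approach the closed form
        uniform = VonMisesMixture((0.0,), (1e-9,), (1.0,))
        params = GeneratorParams(
            angles={"O1-C2-C3": (120.0, 1e-9), "C2-C3-O1": (120.0, 1e-9),
                    "C3-O1-C2": (120.0, 1e-9)},
            bond_lengths={**GeneratorParams().bond_lengths,
                          "O1-C2": 0.15, "C2-C3": 0.15, "C3-O1": 0.15},
            torsions={"psi": {"L": uniform, "D": uniform},
                      "omega": {"L": uniform, "D": uniform},
                      "phi": {"L": uniform, "D": uniform}})
        top = build_system(12, ["L"] * 12)
        coords = np.stack([
            np.concatenate([
                sample_chain(params, c.sequence, np.random.default_rng(100 + f * 31 + i),
                             topology=c)
                for i, c in enumerate(top.chains)])
            for f in range(8)])

        class E:
            topology = top
            box = np.array([100.0] * 3)
        e = E()
        e.coords = coords
        e.n_frames = 8
        prof = internal_distances(e)
        expect = freely_rotating_msid(prof.n, 0.15, 120.0) / prof.n
        mid = prof.n < 20
        assert np.abs(prof.msid_over_n[mid] - expect[mid]).max() < 0.15 * expect[mid].max()
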