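"""Structural-analysis observables against analytic oracles."""

import numpy as np
import pytest

from polybackmap.analysis import (AMU_PER_NM3_TO_KG_M3, block_average, density,
                                  dihedral_distribution, internal_distances,
                                  radius_of_gyration, rdf)
from polybackmap.topology import build_system


class FakeEnsemble:
    """Minimal ensemble protocol for analysis-level oracles."""

    def __init__(self, topology, coords, box):
        self.topology = topology
        self.coords = coords
        self.box = np.asarray(box, dtype=float)

    @property
    def n_frames(self):
        return self.coords.shape[0]


class TestBlockAverage:
    def test_constant_series_zero_spread(self):
        mean, std = block_average(np.full(40, 2.5), 4)
        assert mean == 2.5 and std == 0.0

    def test_hand_computation_1234(self):
        mean, std = block_average([1.0, 2.0, 3.0, 4.0], 4)
        assert mean == pytest.approx(2.5)
        assert std == pytest.approx(np.std([1.0, 2.0, 3.0, 4.0]))

    def test_remainder_dropped(self):
        mean, _ = block_average([1.0, 1.0, 1.0, 1.0, 100.0], 2)
        assert mean == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            block_average([1.0, 2.0], 4)


class TestDihedralDistribution:
    def test_normalization(self, small_ensemble):
        h = dihedral_distribution(small_ensemble, class_name="O1-C2-C3-O1")
        widths = np.diff(h.edges)
        assert np.sum(h.density * widths) == pytest.approx(1.0)
        assert np.all(h.density >= 0)

    def test_stereo_selection_separates_mixture_modes(self, small_ensemble):
        hl = dihedral_distribution(small_ensemble, class_name="O1-C2-C3-O1",
                                   stereo="LL", bins=36)
        hd = dihedral_distribution(small_ensemble, class_name="O1-C2-C3-O1",
                                   stereo="DD", bins=36)
        # mirror-configured mixtures put their dominant mass on opposite sides
        assert np.argmax(hl.density) != np.argmax(hd.density)

    def test_empty_selection_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="empty"):
            dihedral_distribution(small_ensemble, class_name="H6-H7-H8-H5")

    def test_delta_generator_single_bin(self):
        top = build_system(1, ["L"] * 3)
        coords = np.zeros((1, top.total_atoms, 3))
        # place all atoms along a line -> every dihedral nan except none; use
        # a real frame instead: a rigid chain gives identical angles each frame
        from polybackmap.synth import GeneratorParams, sample_chain, VonMisesMixture
        delta = VonMisesMixture((65.0,), (1e5,), (1.0,))  # 65 deg is a bin center
        params = GeneratorParams(torsions={
            "psi": {"L": delta, "D": delta},
            "omega": {"L": delta, "D": delta},
            "phi": {"L": delta, "D": delta}})
        rng = np.random.default_rng(0)
        xyz = sample_chain(params, ["L"] * 3, rng, topology=top.chains[0])
        ens = FakeEnsemble(top, xyz[None], [5.0, 5.0, 5.0])
        h = dihedral_distribution(ens, class_name="O1-C2-C3-O1", bins=36)
        assert h.density.max() > 0
        assert np.sum(h.density > 1e-9) == 1  # a single occupied bin


class TestRDF:
    def test_ideal_gas_is_unity(self):
        # uniform random points, one "chain" per particle
        n = 400
        top = build_system(n, ["L"])
        rng = np.random.default_rng(0)
        box = 4.0
        n_frames = 12
        coords = rng.uniform(0, box, size=(n_frames, top.total_atoms, 3))
        ens = FakeEnsemble(top, coords, [box] * 3)
        o1 = [i for i in range(top.total_atoms) if i % 12 == 0]  # one atom per chain
        prof = rdf(ens, o1, o1, mode="intermolecular", r_max=1.5, bin_width=0.05)
        sel = prof.r > 0.3  # small-r shells have few ideal counts
        assert np.abs(prof.g[sel] - 1.0).max() < 0.15

    def test_two_particle_peak(self):
        top = build_system(2, ["L"])
        coords = np.zeros((1, top.total_atoms, 3))
        coords[0, 12:] += [0.5, 0, 0]  # second chain shifted by d = 0.5
        ens = FakeEnsemble(top, coords, [5.0, 5.0, 5.0])
        prof = rdf(ens, [0], [12], mode="intermolecular", r_max=1.0, bin_width=0.01)
        assert prof.r[np.argmax(prof.g)] == pytest.approx(0.505, abs=0.01)

    def test_r_max_too_large_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="r_max"):
            rdf(small_ensemble, [0], [1], r_max=10.0)

    def test_single_chain_has_no_intermolecular_pairs(self):
        top = build_system(1, ["L"] * 3)
        ens = FakeEnsemble(top, np.zeros((1, top.total_atoms, 3)), [5.0] * 3)
        with pytest.raises(ValueError, match="pairs"):
            rdf(ens, [0, 1], [2, 3], mode="intermolecular", r_max=1.0)

    def test_pair_count_closure(self):
        """Integrating g over all shells recovers the brute-force pair count."""
        top = build_system(3, ["L"])
        rng = np.random.default_rng(3)
        box = 3.0
        coords = rng.uniform(0, box, size=(1, top.total_atoms, 3))
        ens = FakeEnsemble(top, coords, [box] * 3)
        sel = list(range(top.total_atoms))
        prof = rdf(ens, sel, sel, mode="intermolecular", r_max=1.4, bin_width=0.02)
        shell = 4 / 3 * np.pi * ((prof.r + 0.01) ** 3 - (prof.r - 0.01) ** 3)
        recovered = np.sum(prof.g * shell) * prof.n_pairs / box ** 3
        # brute force count of minimum-image pairs below r_max
        from polybackmap.geometry import minimum_image
        d = minimum_image(coords[0][:, None] - coords[0][None], np.array([box] * 3))
        dist = np.linalg.norm(d, axis=-1)
        chain = np.repeat(np.arange(3), 12)
        m = (chain[:, None] != chain[None]) & (dist < 1.4)
        assert recovered == pytest.approx(m.sum(), rel=1e-6)


class TestInternalDistances:
    def test_freely_jointed_chain_flat(self):
        """FJC: <R_n^2>/n = b^2 for every n."""
        rng = np.random.default_rng(0)
        n_bonds, b = 40, 0.15
        n_chains, n_frames = 30, 8
        top = build_system(n_chains, ["L"] * 14)  # backbone length 42
        L = len(top.chains[0].backbone)
        coords = np.zeros((n_frames, top.total_atoms, 3))
        for f in range(n_frames):
            for ci, chain in enumerate(top.chains):
                steps = rng.normal(size=(L - 1, 3))
                steps = b * steps / np.linalg.norm(steps, axis=1, keepdims=True)
                bb = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
                off = top.chain_atom_offsets[ci]
                coords[f, off + chain.backbone] = bb
        ens = FakeEnsemble(top, coords, [50.0] * 3)
        prof = internal_distances(ens)
        expect = b * b
        assert np.abs(prof.msid_over_n - expect).max() < 0.15 * expect

    def test_rigid_rod_linear_growth(self):
        top = build_system(1, ["L"] * 10)
        chain = top.chains[0]
        coords = np.zeros((4, top.total_atoms, 3))
        ell = 0.2
        coords[:, chain.backbone, 0] = ell * np.arange(len(chain.backbone))
        ens = FakeEnsemble(top, coords, [100.0] * 3)
        prof = internal_distances(ens)
        assert np.allclose(prof.msid_over_n, prof.n * ell ** 2)

    def test_full_n_equals_end_to_end(self, small_ensemble):
        # 4-frame slice so the 4-block average uses every frame
        ens4 = FakeEnsemble(small_ensemble.topology,
                            small_ensemble.coords[:4], small_ensemble.box)
        prof = internal_distances(ens4)
        chain = small_ensemble.topology.chains[0]
        n_full = len(chain.backbone) - 1
        offs = small_ensemble.topology.chain_atom_offsets
        re2 = []
        for f in range(4):
            for ci, ch in enumerate(small_ensemble.topology.chains):
                bb = small_ensemble.coords[f][offs[ci]:offs[ci + 1]][ch.backbone]
                re2.append(np.sum((bb[-1] - bb[0]) ** 2))
        assert prof.msid_over_n[-1] * n_full == pytest.approx(np.mean(re2), rel=1e-9)


class TestRgAndDensity:
    def test_point_mass_zero_rg(self):
        top = build_system(1, ["L"])
        ens = FakeEnsemble(top, np.zeros((4, top.total_atoms, 3)), [5.0] * 3)
        mean, ci = radius_of_gyration(ens)
        assert mean == 0.0

    def test_two_equal_masses(self):
        """Two equal point masses at distance d have R_g = d/2."""
        top = build_system(1, ["L"])
        chain = top.chains[0]
        coords = np.zeros((4, 12, 3))
        # split the chain into two equal-mass halves is not possible with
        # real masses; instead verify against the direct mass-weighted formula
        rng = np.random.default_rng(0)
        coords[:] = rng.normal(size=(4, 12, 3))
        ens = FakeEnsemble(top, coords, [5.0] * 3)
        mean, _ = radius_of_gyration(ens)
        m = chain.atom_masses
        expect = []
        for f in range(4):
            com = m @ coords[f] / m.sum()
            expect.append(np.sqrt(np.sum(m * np.sum((coords[f] - com) ** 2, 1)) / m.sum()))
        assert mean == pytest.approx(np.mean(expect))

    def test_density_unit_conversion(self):
        assert 1000.0 * AMU_PER_NM3_TO_KG_M3 / 1000.0 == pytest.approx(1660.54, abs=0.01)

    def test_density_of_known_system(self, small_ensemble):
        mean, ci = density(small_ensemble)
        total = small_ensemble.topology.atom_masses.sum()
        expect = total / np.prod(small_ensemble.box) * AMU_PER_NM3_TO_KG_M3
        assert mean == pytest.approx(expect)
        assert ci == 0.0

    def test_rotation_invariance_of_observables(self, small_ensemble):
        th = 0.9
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rotated = FakeEnsemble(small_ensemble.topology,
                               small_ensemble.coords @ R.T,
                               small_ensemble.box)
        a = internal_distances(small_ensemble).msid_over_n
        b = internal_distances(rotated).msid_over_n
        assert np.allclose(a, b)
        ra, _ = radius_of_gyration(small_ensemble)
        rb, _ = radius_of_gyration(rotated)
        assert ra == pytest.approx(rb)
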