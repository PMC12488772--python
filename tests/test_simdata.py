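"""Tests of the synthetic bridging-population generator.

Monte-Carlo checks compare simulated transmission statistics with
closed-form expectations under the Haldane meiosis model and the
BC1 + two-selfing pedigree; tolerances are three binomial standard
errors of the estimate.
"""

import numpy as np
import pytest

from ucbridge import genetics, simdata


class TestGeneticMap:
    def test_even_spacing_endpoints_and_gaps(self):
        gmap = simdata.simulate_genetic_map(1, 2.0, 5)
        pos = gmap["position_morgan"].to_numpy()
        assert pos[0] == 0.0 and pos[-1] == 2.0
        assert np.allclose(np.diff(pos), 0.5)

    def test_reproducible_and_sized(self):
        a = simdata.simulate_genetic_map(2, 1.5, 100, seed=7, spacing="uniform")
        b = simdata.simulate_genetic_map(2, 1.5, 100, seed=7, spacing="uniform")
        assert len(a) == 200
        assert a.equals(b)

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_genetic_map(1, 1.0, 1)


class TestParents:
    def test_inbred_coding_and_determinism(self):
        gmap = simdata.simulate_genetic_map(2, 1.0, 20)
        a = simdata.simulate_parents(gmap, 3, 4, seed=5)
        b = simdata.simulate_parents(gmap, 3, 4, seed=5)
        assert set(np.unique(a.to_numpy())) <= {0, 2}
        assert a.equals(b)
        assert list(a.index) == ["R1", "R2", "R3", "D1", "D2", "D3", "D4"]

    def test_forced_polymorphism(self):
        gmap = simdata.simulate_genetic_map(1, 1.0, 30)
        parents = simdata.simulate_parents(
            gmap, 2, 2, seed=0, recipient_allele_freq=0.0, donor_allele_freq=1.0
        )
        rec = parents.loc["R1"].to_numpy()
        don = parents.loc["D1"].to_numpy()
        assert np.all(rec == 0) and np.all(don == 2)


class TestDesign:
    def test_shape_and_connectivity(self):
        design = simdata.simulate_design(seed=11)
        assert len(design) == 20
        assert design["recipient_id"].nunique() == 7
        assert design["donor_id"].nunique() == 9
        pairs = design[["recipient_id", "donor_id"]].apply(tuple, axis=1)
        assert not pairs.duplicated().any()
        assert design["n_progeny"].between(38, 66).all()
        per_recipient = design.groupby("recipient_id").size()
        assert per_recipient.between(2, 3).all()


class TestMeiosis:
    def test_homozygous_parent_gamete_identity(self, rng):
        gmap = simdata.simulate_genetic_map(1, 1.0, 10)
        h = np.ones((2, 10), dtype=np.int8)
        gam = simdata.simulate_gamete(h, gmap, rng)
        assert np.array_equal(gam, h[0])

    def test_zero_distance_complete_linkage(self, rng):
        gmap = simdata.simulate_genetic_map(1, 1.0, 3).copy()
        gmap.loc[1, "position_morgan"] = 0.0
        gmap.loc[2, "position_morgan"] = 1.0
        h = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        for _ in range(200):
            gam = simdata.simulate_gamete(h, gmap, rng)
            assert gam[0] == gam[1]  # d = 0 between first two markers

    def test_f1_recombinant_fraction_matches_haldane(self, rng):
        n = 100_000
        gmap = simdata.simulate_genetic_map(1, 0.5, 2)
        h1 = np.zeros((n, 2), dtype=np.int8)
        h2 = np.ones((n, 2), dtype=np.int8)
        gam = simdata.simulate_gametes(h1, h2, gmap, rng)
        rec_frac = np.mean(gam[:, 0] != gam[:, 1])
        expected = genetics.haldane_c1(0.5)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec_frac - expected) < 3 * se

    def test_single_and_batch_gamete_routes_agree(self):
        # Poisson-crossover and Markov marker-skeleton simulators draw from
        # the same gamete distribution: compare recombinant fractions.
        gmap = simdata.simulate_genetic_map(1, 0.4, 2)
        rng1 = np.random.default_rng(1)
        n = 40_000
        singles = np.array(
            [
                simdata.simulate_gamete(
                    np.array([[0, 0], [1, 1]], dtype=np.int8), gmap, rng1
                )
                for _ in range(n)
            ]
        )
        rng2 = np.random.default_rng(2)
        batch = simdata.simulate_gametes(
            np.zeros((n, 2), np.int8), np.ones((n, 2), np.int8), gmap, rng2
        )
        f1 = np.mean(singles[:, 0] != singles[:, 1])
        f2 = np.mean(batch[:, 0] != batch[:, 1])
        se = np.sqrt(2 * 0.3 * 0.7 / n)
        assert abs(f1 - f2) < 3 * se


class TestBC1S2:
    def test_monomorphic_marker_constant(self, rng):
        gmap = simdata.simulate_genetic_map(1, 1.0, 4)
        x_r = np.array([0, 0, 2, 2])
        x_d = np.array([0, 2, 2, 0])
        dos = simdata.simulate_bc1s2_family(x_r, x_d, gmap, 500, rng)
        assert np.all(dos[:, 0] == 0)
        assert np.all(dos[:, 2] == 2)
        assert set(np.unique(dos)) <= {0, 1, 2}

    def test_transmission_frequencies(self, rng):
        n = 100_000
        gmap = simdata.simulate_genetic_map(1, 1.0, 2)
        dos = simdata.simulate_bc1s2_family(
            np.array([0, 0]), np.array([2, 2]), gmap, n, rng
        )
        # donor-allele frequency 1/4; residual heterozygosity (1/2)(1/4) = 1/8
        freq = dos[:, 0].mean() / 2.0
        se_f = np.sqrt(0.25 * 0.75 / (2 * n))
        assert abs(freq - 0.25) < 3 * se_f
        het = (dos[:, 0] == 1).mean()
        se_h = np.sqrt(0.125 * 0.875 / n)
        assert abs(het - 0.125) < 3 * se_h

    def test_cross_chromosome_ld_vanishes(self, rng):
        gmap = simdata.simulate_genetic_map(2, 1.0, 2)
        x_r = np.zeros(4)
        x_d = np.full(4, 2)
        dos = simdata.simulate_bc1s2_family(x_r, x_d, gmap, 50_000, rng).astype(float)
        r = np.corrcoef(dos[:, 0], dos[:, 2])[0, 1]
        assert abs(r) < 3 / np.sqrt(50_000)

    def test_determinism(self):
        gmap = simdata.simulate_genetic_map(2, 1.0, 10)
        x_r = np.zeros(20)
        x_d = np.full(20, 2)
        a = simdata.simulate_bc1s2_family(x_r, x_d, gmap, 50, rng=42)
        b = simdata.simulate_bc1s2_family(x_r, x_d, gmap, 50, rng=42)
        assert np.array_equal(a, b)


class TestTrait:
    def test_pure_noise_and_noiseless_limits(self, rng):
        dos = rng.integers(0, 3, size=(5_000, 20))
        arch = simdata.TraitArchitecture(
            "null", np.zeros(20), heritability=0.5, error_variance=2.0
        )
        y, ve = simdata.simulate_trait(dos, arch, rng)
        assert ve == 2.0
        assert np.var(y) == pytest.approx(2.0, rel=0.1)

        arch2 = simdata.TraitArchitecture(
            "exact", np.arange(20) * 0.1, heritability=1.0, error_variance=0.0
        )
        y2, _ = simdata.simulate_trait(dos, arch2, rng)
        assert np.allclose(y2, dos @ arch2.true_effects)

    def test_realized_heritability(self, rng):
        dos = rng.integers(0, 3, size=(5_000, 50))
        arch = simdata.TraitArchitecture(
            "h2", rng.normal(0, 0.2, 50), heritability=0.5
        )
        y, ve = simdata.simulate_trait(dos, arch, rng)
        vg = np.var(dos.astype(float) @ arch.true_effects)
        h2 = vg / np.var(y)
        assert h2 == pytest.approx(0.5, abs=0.05)

    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError):
            simdata.TraitArchitecture("bad", np.zeros(3), heritability=0.0)


class TestEmpiricalProgenyVariance:
    def test_null_effects_zero_variance(self, rng):
        gmap = simdata.simulate_genetic_map(1, 1.0, 3)
        v = simdata.empirical_progeny_variance(
            [0, 0, 0], [2, 2, 2], gmap, np.zeros(3), 100, rng
        )
        assert v == 0.0

    def test_single_marker_closed_form(self, rng):
        # BC1S2 dosage distribution (11/16, 1/8, 3/16) -> Var = 5/8
        gmap = simdata.simulate_genetic_map(1, 1.0, 2)
        v = simdata.empirical_progeny_variance(
            [0, 0], [0, 2], gmap, np.array([0.0, 1.0]), 200_000, rng
        )
        assert v == pytest.approx(5 / 8, abs=0.01)

    def test_unlinked_markers_additive(self, rng):
        gmap = simdata.simulate_genetic_map(2, 1.0, 2)
        per_marker = np.array([1.0, 0, 1.0, 0])
        v = simdata.empirical_progeny_variance(
            np.zeros(4), np.array([2, 0, 2, 0]), gmap, per_marker, 200_000, rng
        )
        assert v == pytest.approx(2 * 5 / 8, rel=0.03)
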