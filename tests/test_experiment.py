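"""Tests of training-set construction, cross-validation and metrics."""

import numpy as np
import pandas as pd
import pytest

from ucbridge import experiment, simdata


def _toy_design():
    return pd.DataFrame(
        {
            "family_id": ["AxC", "AxD", "BxC", "BxE"],
            "recipient_id": ["A", "A", "B", "B"],
            "donor_id": ["C", "D", "C", "E"],
            "n_progeny": [2, 2, 2, 2],
        }
    )


def _toy_families(design):
    ids, fams = [], []
    for row in design.itertuples(index=False):
        for j in range(row.n_progeny):
            ids.append(f"{row.family_id}_{j}")
            fams.append(row.family_id)
    return pd.Series(fams, index=ids)


class TestBuildTrainingSet:
    def test_relatedness_subsets_by_definition(self):
        design = _toy_design()
        fams = _toy_families(design)
        got = {
            t: set(
                experiment.build_training_set(design, fams, "AxC", t, vs_ids=[]).families
            )
            for t in ("R", "D", "RD", "Disc", "OFO")
        }
        assert got["R"] == {"AxD"}
        assert got["D"] == {"BxC"}
        assert got["RD"] == {"AxD", "BxC"}
        assert got["Disc"] == {"BxE"}
        assert got["OFO"] == {"AxD", "BxC", "BxE"}

    def test_ofo_excludes_target_members(self):
        design = _toy_design()
        fams = _toy_families(design)
        spec = experiment.build_training_set(design, fams, "AxC", "OFO", vs_ids=[])
        assert set(spec.member_ids) == set(fams.index) - {"AxC_0", "AxC_1"}

    def test_family_fraction_augmentation(self):
        design = _toy_design()
        fams = _toy_families(design)
        spec = experiment.build_training_set(
            design, fams, "AxC", "Disc", vs_ids=["AxC_0"], with_family_fraction=True
        )
        assert "AxC_1" in spec.member_ids and "AxC_0" not in spec.member_ids

    def test_set_algebra_on_simulated_design(self, small_study):
        """RD = R u D; Disc disjoint from RD; OFO = R u D u Disc."""
        st = small_study
        for fam in st.design["family_id"]:
            sets = {}
            for t in ("R", "D", "RD", "Disc", "OFO"):
                try:
                    sets[t] = set(
                        experiment.build_training_set(
                            st.design, st.families, fam, t, vs_ids=[]
                        ).member_ids
                    )
                except ValueError:
                    sets[t] = set()
            assert sets["RD"] == sets["R"] | sets["D"]
            assert not sets["Disc"] & sets["RD"]
            assert sets["OFO"] == sets["RD"] | sets["Disc"]

    def test_empty_training_set_raises(self):
        design = pd.DataFrame(
            {
                "family_id": ["AxC", "BxD"],
                "recipient_id": ["A", "B"],
                "donor_id": ["C", "D"],
                "n_progeny": [2, 2],
            }
        )
        fams = _toy_families(design)
        with pytest.raises(ValueError, match="empty training set"):
            experiment.build_training_set(design, fams, "AxC", "R", vs_ids=[])


class TestMetrics:
    def test_predictive_ability_values(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert experiment.predictive_ability(obs, obs) == pytest.approx(1.0)
        assert experiment.predictive_ability(obs, -obs) == pytest.approx(-1.0)
        assert experiment.predictive_ability(obs, [1, 2, 4]) == pytest.approx(
            0.981980506, abs=1e-6
        )
        with pytest.raises(ValueError):
            experiment.predictive_ability(obs, np.ones(3))

    def test_nrmse(self):
        assert experiment.nrmse([0.0, 10.0], [0.0, 10.0]) == 0.0
        assert experiment.nrmse([1.0, 9.0], [0.0, 10.0]) == pytest.approx(0.1)
        a, b = np.array([1.0, 4.0, 2.0]), np.array([0.0, 5.0, 3.0])
        assert experiment.nrmse(3 * a, 3 * b) == pytest.approx(experiment.nrmse(a, b))
        with pytest.raises(ValueError):
            experiment.nrmse([1.0, 2.0], [5.0, 5.0])

    def test_uc_decomposition_limits(self, rng):
        s2 = rng.uniform(1, 2, 10)
        mu = rng.normal(size=10)
        assert experiment.uc_decomposition(mu, np.full(10, 1.3)) == pytest.approx(1.0)
        assert experiment.uc_decomposition(np.full(10, 2.0), s2) == pytest.approx(0.0)
        mu3 = np.array([0.0, 1.0, 2.0])
        assert experiment.uc_decomposition(mu3, mu3 / 2.07) == pytest.approx(0.5)

    def test_yield_index(self):
        assert experiment.yield_index(100.0, 30.0, 30.0) == pytest.approx(100.0)
        assert experiment.yield_index(100.0, 28.0, 30.0) == pytest.approx(105.0)
        assert experiment.yield_index(100.0, 34.0, 30.0) == pytest.approx(90.0)


class TestWithinFamilyCV:
    def test_determinism_and_partition_reuse(self, small_study):
        st = small_study
        fam = st.design["family_id"].iloc[0]
        y = st.trait_values("trait1").loc[st.family_members(fam)]
        a = experiment.within_family_cv(y, st.progeny, n_reps=3, seed=77)
        b = experiment.within_family_cv(y, st.progeny, n_reps=3, seed=77)
        pd.testing.assert_frame_equal(a, b)
        ids = st.family_members(fam)
        p1 = experiment.cv_partitions(ids, 4, seed=5)
        p2 = experiment.cv_partitions(ids, 4, seed=5)
        assert p1 == p2

    def test_strong_signal_high_pa(self):
        """Noiseless polygenic trait in a large family: mean PA near 1."""
        gmap = simdata.simulate_genetic_map(2, 1.5, 50)
        rng = np.random.default_rng(3)
        x_r = rng.choice([0, 2], 100)
        x_d = rng.choice([0, 2], 100)
        dos = simdata.simulate_bc1s2_family(x_r, x_d, gmap, 200, rng)
        beta = rng.normal(0, 0.3, 100)
        ids = pd.Index([f"i{j}" for j in range(200)])
        dosf = pd.DataFrame(dos, index=ids, columns=gmap["marker"])
        y = pd.Series(dos.astype(float) @ beta, index=ids)
        res = experiment.within_family_cv(y, dosf, n_reps=10, seed=1)
        assert res["pa"].mean() >= 0.95

    def test_shuffled_phenotypes_null_pa(self):
        gmap = simdata.simulate_genetic_map(2, 1.5, 30)
        rng = np.random.default_rng(4)
        x_r = rng.choice([0, 2], 60)
        x_d = rng.choice([0, 2], 60)
        dos = simdata.simulate_bc1s2_family(x_r, x_d, gmap, 150, rng)
        beta = rng.normal(0, 0.3, 60)
        y_vals = dos.astype(float) @ beta
        rng.shuffle(y_vals)  # break genotype-phenotype link
        ids = pd.Index([f"i{j}" for j in range(150)])
        dosf = pd.DataFrame(dos, index=ids, columns=gmap["marker"])
        res = experiment.within_family_cv(
            pd.Series(y_vals, index=ids), dosf, n_reps=20, seed=2
        )
        n_vs = int(round(2 / 3 * 150))
        assert abs(res["pa"].mean()) <= 3 / np.sqrt(n_vs)


class TestEvaluateTsTypes:
    def test_shared_partitions_across_types(self, small_study):
        st = small_study
        fam = st.design["family_id"].iloc[0]
        y = st.trait_values("trait1")
        tbl = experiment.evaluate_ts_types(
            st.design, st.families, y, st.progeny, fam,
            ts_types=("F", "OFO"), n_reps=2, seed=9,
        )
        assert set(tbl["ts_type"]) == {"F", "OFO"}
        assert len(tbl) == 4


class TestEvaluateCrossPredictions:
    def test_perfect_predictions(self):
        obs = pd.DataFrame(
            {"family_id": list("abcd"), "mu": [1.0, 2, 3, 4], "sigma2": [0.5, 1, 2, 1.5]}
        )
        pred = obs.assign(ts_type="F")
        out = experiment.evaluate_cross_predictions(obs, pred)
        assert np.allclose(out["correlation"], 1.0)
        assert np.allclose(out["nrmse"], 0.0)
        assert set(out["parameter"]) == {"mu", "sigma2", "uc"}

    def test_too_few_crosses(self):
        obs = pd.DataFrame({"family_id": ["a", "b"], "mu": [1.0, 2], "sigma2": [1.0, 2]})
        with pytest.raises(ValueError):
            experiment.evaluate_cross_predictions(obs, obs.assign(ts_type="F"))
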