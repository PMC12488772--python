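"""Tests of haplotype windows, HEBV and H-criterion donor selection."""

import numpy as np
import pandas as pd
import pytest

from ucbridge import hcriterion, simdata


def _hebv_frame(values: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(values, orient="index")


class TestWindows:
    def test_single_window_when_chromosome_fits(self):
        gmap = simdata.simulate_genetic_map(1, 1.0, 100)
        w = hcriterion.build_windows(gmap, 100, 20)
        assert w.n_windows == 1 + 4  # full window + truncated tails from starts 20..80
        assert len(w.indices[0]) == 100

    def test_window_starts_and_truncation(self):
        gmap = simdata.simulate_genetic_map(1, 2.0, 200)
        w = hcriterion.build_windows(gmap, 100, 20)
        full = [idx for idx in w.indices if len(idx) == 100]
        assert [idx[0] for idx in full] == [0, 20, 40, 60, 80, 100]
        tails = [idx for idx in w.indices if len(idx) < 100]
        assert [len(idx) for idx in tails] == [80, 60, 40, 20]
        covered = np.unique(np.concatenate(w.indices))
        assert len(covered) == 200  # no marker left out

    def test_windows_respect_chromosomes(self):
        gmap = simdata.simulate_genetic_map(2, 1.0, 150)
        w = hcriterion.build_windows(gmap, 100, 20)
        chrom = gmap["chromosome"].to_numpy()
        for idx in w.indices:
            assert len(set(chrom[idx])) == 1

    def test_lambda_is_step_over_size(self):
        gmap = simdata.simulate_genetic_map(1, 1.0, 100)
        assert hcriterion.build_windows(gmap, 100, 20).lam == pytest.approx(0.2)

    def test_bad_window_parameters(self):
        gmap = simdata.simulate_genetic_map(1, 1.0, 10)
        with pytest.raises(ValueError):
            hcriterion.build_windows(gmap, 5, 10)


class TestHEBV:
    def test_windowed_weighted_sum(self):
        gmap = simdata.simulate_genetic_map(1, 1.0, 3)
        w = hcriterion.build_windows(gmap, 3, 3)
        geno = pd.DataFrame([[2, 0, 2]], index=["L1"], columns=gmap["marker"])
        beta = np.array([0.5, 1.0, -0.25])
        out = hcriterion.hebv(geno, beta, w)
        assert out.loc["L1", 0] == pytest.approx(0.5)

    def test_zero_effects_and_duplicated_lines(self, rng):
        gmap = simdata.simulate_genetic_map(2, 1.0, 30)
        w = hcriterion.build_windows(gmap, 10, 5)
        geno = pd.DataFrame(
            rng.choice([0, 2], size=(3, 60)),
            index=["A", "B", "C"],
            columns=gmap["marker"],
        )
        geno.loc["C"] = geno.loc["A"]
        assert (hcriterion.hebv(geno, np.zeros(60), w) == 0).all().all()
        out = hcriterion.hebv(geno, rng.normal(size=60), w)
        assert np.allclose(out.loc["A"], out.loc["C"])


class TestHCriterion:
    def test_hand_computed_value(self):
        hv = _hebv_frame({"rec": [1.0, 2.0], "cand": [3.0, 1.0]})
        h = hcriterion.h_criterion("cand", "rec", [], hv, lam=0.2)
        assert h == pytest.approx(0.2 * (3 + 2))

    def test_candidate_identical_to_recipient_is_baseline(self):
        hv = _hebv_frame({"rec": [1.0, 2.0], "cand": [1.0, 2.0], "d0": [0.5, 2.5]})
        h = hcriterion.h_criterion("cand", "rec", ["d0"], hv, lam=0.2)
        baseline = 0.2 * np.maximum([1.0, 2.0], [0.5, 2.5]).sum()
        assert h == pytest.approx(baseline)

    def test_dominated_candidate_invariance(self, rng):
        lines = {f"L{i}": rng.normal(size=8) for i in range(4)}
        lines["dom"] = np.vstack(list(lines.values())).max(axis=0)
        lines["weak"] = np.vstack(list(lines.values())).min(axis=0) - 1.0
        hv = _hebv_frame(lines)
        base = hcriterion.h_criterion("dom", "L0", ["L1", "L2"], hv, 0.2)
        with_weak = hcriterion.h_criterion("weak", "L0", ["L1", "L2", "dom"], hv, 0.2)
        assert with_weak == pytest.approx(base)

    def test_candidate_already_incorporated_rejected(self):
        hv = _hebv_frame({"r": [1.0], "c": [2.0]})
        with pytest.raises(ValueError):
            hcriterion.h_criterion("c", "r", ["c"], hv, 0.2)


class TestForwardSelection:
    def test_single_candidate(self, rng):
        hv = _hebv_frame({"r": rng.normal(size=5), "c": rng.normal(size=5)})
        traj = hcriterion.forward_select_donors("r", [], ["c"], hv, 0.2)
        assert traj.order == ["c"]
        assert len(traj.table) == 1

    def test_dominant_candidate_selected_first(self):
        hv = _hebv_frame(
            {"r": [1.0, 1.0], "big": [3.0, 3.0], "small": [2.0, 2.0]}
        )
        traj = hcriterion.forward_select_donors("r", [], ["small", "big"], hv, 0.2)
        assert traj.order == ["big", "small"]

    def test_trajectory_nondecreasing_and_gains(self, rng):
        lines = {f"L{i}": rng.normal(size=20) for i in range(8)}
        hv = _hebv_frame(lines)
        traj = hcriterion.forward_select_donors(
            "L0", ["L1"], [f"L{i}" for i in range(2, 8)], hv, 0.2
        )
        hs = traj.table["h"].to_numpy()
        assert np.all(np.diff(hs) >= -1e-12)
        assert hs[0] >= traj.baseline_h - 1e-12

    def test_lambda_scaling_neutral_for_ranking(self, rng):
        lines = {f"L{i}": rng.normal(size=15) for i in range(6)}
        hv = _hebv_frame(lines)
        cands = [f"L{i}" for i in range(2, 6)]
        t1 = hcriterion.forward_select_donors("L0", ["L1"], cands, hv, 0.2)
        t2 = hcriterion.forward_select_donors("L0", ["L1"], cands, hv, 0.4)
        assert t1.order == t2.order
        assert np.allclose(2 * t1.table["h"], t2.table["h"])

    def test_deterministic_tie_break(self):
        hv = _hebv_frame({"r": [0.0], "b": [1.0], "a": [1.0]})
        traj = hcriterion.forward_select_donors("r", [], ["b", "a"], hv, 0.2)
        assert traj.order == ["a", "b"]


class TestUCRanking:
    def test_descending_order_and_divergence_from_h(self):
        ranked = hcriterion.rank_donors_by_uc({"d1": 1.0, "d2": 3.0, "d3": 2.0})
        assert list(ranked["donor"]) == ["d2", "d3", "d1"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_uc_and_h_orders_can_differ(self):
        """A candidate with high own performance but no windows beating the
        recipient ranks first by UC yet last by H."""
        hv = _hebv_frame(
            {
                "rec": [2.0, 2.0],
                "flat": [1.9, 1.9],  # good line, nothing complementary
                "spiky": [3.0, 0.0],  # weaker overall, one winning window
            }
        )
        h_flat = hcriterion.h_criterion("flat", "rec", [], hv, 0.2)
        h_spiky = hcriterion.h_criterion("spiky", "rec", [], hv, 0.2)
        assert h_spiky > h_flat
        uc_rank = hcriterion.rank_donors_by_uc({"flat": 5.0, "spiky": 4.0})
        assert list(uc_rank["donor"]) == ["flat", "spiky"]
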