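import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scle.core import (
    ScleProfile,
    _entropy_from_weights,
    detect_critical_stage,
    local_scle,
    pearson_abs,
    permutation_pvalue,
    stage_scle,
    _num_top,
)
from scle.network import LocalNetwork

from conftest import make_network, make_series, make_single_stage_series, random_instance
from naive_scle import naive_abs_pcc, naive_entropy, naive_local_score


class TestPearsonAbs:
    def test_perfect_linear(self):
        assert pearson_abs([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_anticorrelation_absolute(self):
        assert pearson_abs([1, 2, 3], [6, 4, 2]) == pytest.approx(1.0)

    def test_constant_convention(self):
        assert pearson_abs([1, 2, 3], [5, 5, 5]) == 0.0

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            assert pearson_abs(x, y) == pytest.approx(
                naive_abs_pcc(x, y), abs=1e-12
            )

    def test_length_errors(self):
        with pytest.raises(ValueError):
            pearson_abs([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_abs([1, 2, 3], [1, 2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_and_symmetric(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=12), r.normal(size=12)
        v = pearson_abs(x, y)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(pearson_abs(y, x), abs=1e-14)


class TestEntropy:
    def test_uniform_weights_are_maximal(self):
        assert _entropy_from_weights(np.array([0.3, 0.3, 0.3, 0.3]), 1.0) == (
            pytest.approx(1.0)
        )

    def test_skewed_weights(self):
        # brute-force value of -sum(p ln p)/ln 3 at p = (0.7, 0.2, 0.1)
        w = np.array([0.7, 0.2, 0.1])
        expected = naive_entropy(list(w))
        assert expected == pytest.approx(0.72985, abs=1e-4)
        assert _entropy_from_weights(w, 1.0) == pytest.approx(expected, abs=1e-12)
        # entropy depends only on the normalized weights
        assert _entropy_from_weights(5.0 * w, 1.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_degenerate_conventions(self):
        assert _entropy_from_weights(np.array([0.0, 0.0]), 1.0) == 0.0
        assert _entropy_from_weights(np.array([0.4]), 1.0) == 1.0
        assert _entropy_from_weights(np.array([0.4]), 0.0) == 0.0  # config alternative
        assert _entropy_from_weights(np.array([0.5, 0.0]), 1.0) == 0.0  # one-hot


class TestLocalScle:
    def test_constant_center_scores_zero(self, rng):
        vals = rng.normal(size=(3, 10))
        vals[0] = 2.5
        series = make_single_stage_series(vals)
        ln = LocalNetwork(center="g00", neighbors=("g01", "g02"))
        assert local_scle(series, ln, "S1").score == 0.0

    def test_identical_weights_give_entropy_one(self, rng):
        center = rng.normal(size=10)
        vals = np.vstack([center] + [center * k for k in (2.0, 3.0, 4.0, 5.0)])
        series = make_single_stage_series(vals)
        ln = LocalNetwork(center="g00", neighbors=("g01", "g02", "g03", "g04"))
        ls = local_scle(series, ln, "S1")
        assert ls.entropy == pytest.approx(1.0, abs=1e-12)
        assert ls.score == pytest.approx(ls.sd, abs=1e-12)
        assert ls.sd == pytest.approx(np.std(center, ddof=1))

    def test_matches_naive_oracle(self, rng):
        for _ in range(25):
            vals = rng.normal(size=(4, 9))
            series = make_single_stage_series(vals)
            ln = LocalNetwork(center="g01", neighbors=("g00", "g02", "g03"))
            ls = local_scle(series, ln, "S1")
            expected = naive_local_score(
                vals[1].tolist(), [vals[0].tolist(), vals[2].tolist(), vals[3].tolist()]
            )
            assert ls.score == pytest.approx(expected, abs=1e-12)

    def test_weights_form_simplex(self, rng):
        vals = rng.normal(size=(5, 12))
        series = make_single_stage_series(vals)
        ln = LocalNetwork(center="g00", neighbors=("g01", "g02", "g03", "g04"))
        ls = local_scle(series, ln, "S1")
        assert sum(ls.weights) == pytest.approx(1.0, abs=1e-12)

    def test_cell_permutation_invariance(self, rng):
        vals = rng.normal(size=(4, 20))
        series = make_series(vals, [10, 10])
        perm = np.concatenate([rng.permutation(10), 10 + rng.permutation(10)])
        shuffled = make_series(vals[:, perm], [10, 10])
        ln = LocalNetwork(center="g02", neighbors=("g00", "g01", "g03"))
        for stage in ("S1", "S2"):
            a, b = local_scle(series, ln, stage), local_scle(shuffled, ln, stage)
            assert a.score == pytest.approx(b.score, abs=1e-12)
            assert a.entropy == pytest.approx(b.entropy, abs=1e-12)

    def test_scale_equivariance(self, rng):
        vals = rng.normal(size=(4, 10))
        series = make_single_stage_series(vals)
        scaled_vals = vals.copy()
        scaled_vals[0] *= 3.7
        scaled = make_single_stage_series(scaled_vals)
        ln = LocalNetwork(center="g00", neighbors=("g01", "g02", "g03"))
        a, b = local_scle(series, ln, "S1"), local_scle(scaled, ln, "S1")
        assert b.score == pytest.approx(3.7 * a.score, rel=1e-10)


class TestStageScle:
    @pytest.mark.parametrize("m,frac,expected", [(40, 0.05, 2), (5200, 0.05, 260),
                                                 (10, 0.01, 1), (7, 1.0, 7)])
    def test_top_r_arithmetic(self, m, frac, expected):
        assert _num_top(frac, m) == expected

    def test_h_is_sum_of_top_r(self, rng):
        series, network = random_instance(rng, max_genes=8)
        profile = stage_scle(series, network, top_fraction=0.3)
        for stage in series.stage_order:
            sub = profile.local_scores.query("stage == @stage")
            top = sub.sort_values(["score", "gene"], ascending=[False, True]).head(
                profile.R
            )
            assert profile.stage_scores[stage] == pytest.approx(
                top["score"].sum(), abs=1e-12
            )

    def test_constant_stage_scores_zero(self):
        vals = np.ones((4, 16))
        series = make_series(vals, [8, 8])
        network = make_network([("g00", "g01"), ("g01", "g02"), ("g02", "g03")])
        profile = stage_scle(series, network)
        assert (profile.stage_scores == 0).all()

    def test_entropy_bounds_and_sd_cap(self, rng):
        for _ in range(10):
            series, network = random_instance(rng)
            profile = stage_scle(series, network)
            assert profile.local_scores["entropy"].between(0, 1).all()
            assert (
                profile.local_scores["score"]
                <= profile.local_scores["sd"] + 1e-12
            ).all()


def _profile_from_scores(h):
    stages = tuple(f"S{i}" for i in range(1, len(h) + 1))
    return ScleProfile(
        genes=("g",),
        stage_order=stages,
        local_scores=pd.DataFrame(),
        stage_scores=pd.Series(h, index=list(stages)),
        R=1,
        top_fraction=0.05,
        top_genes={s: ("g",) for s in stages},
    )


class TestDetectCriticalStage:
    def test_peak_and_fold_change(self):
        call = detect_critical_stage(_profile_from_scores([1, 1, 1, 5, 1, 1]))
        assert call.stage == "S4"
        assert call.fold_change == pytest.approx(5.0)
        assert not call.end_of_series_warning

    def test_tie_breaks_to_earliest(self):
        assert detect_critical_stage(_profile_from_scores([2, 2])).stage == "S1"

    def test_peak_at_first_stage_has_inf_fold(self):
        call = detect_critical_stage(_profile_from_scores([5, 1, 1]))
        assert call.stage == "S1" and math.isinf(call.fold_change)

    def test_monotone_rise_warns_at_series_end(self):
        call = detect_critical_stage(_profile_from_scores([1, 2, 3, 4]))
        assert call.stage == "S4" and call.end_of_series_warning


class TestPermutationPvalue:
    def test_determinism_and_range(self, rng):
        series, network = random_instance(rng, max_genes=6)
        profile = stage_scle(series, network)
        detect_critical_stage(profile)
        p1 = permutation_pvalue(series, network, profile, B=19, seed=11)
        p2 = permutation_pvalue(series, network, profile, B=19, seed=11)
        assert p1 == p2
        assert 1 / 20 <= p1 <= 1.0

    def test_strong_signal_reaches_floor(self):
        # one gene's variance explodes in stage 2: no permutation should match
        r = np.random.default_rng(5)
        vals = r.normal(size=(4, 30)) * 0.05
        vals[0, 10:20] = r.normal(size=10) * 50.0
        series = make_series(vals, [10, 10, 10])
        network = make_network([("g00", "g01"), ("g01", "g02"), ("g02", "g03")])
        profile = stage_scle(series, network, top_fraction=0.3)
        detect_critical_stage(profile)
        assert permutation_pvalue(series, network, profile, B=99, seed=0) == (
            pytest.approx(0.01)
        )

    def test_b_must_be_positive(self, rng):
        series, network = random_instance(rng, max_genes=6)
        profile = stage_scle(series, network)
        with pytest.raises(ValueError):
            permutation_pvalue(series, network, profile, B=0, seed=1)
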