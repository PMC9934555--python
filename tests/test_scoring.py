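import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mavemap import scoring
from mavemap.scoring import (ScoringConfig, ScoringError, adjust_frequencies,
                             enrichment_ratio, filter_wt_background,
                             functional_score, quality_filter, region_anchors,
                             regularize_errors, well_measured_flag)


class TestWtBackgroundFilter:
    def test_boundary_exactly_three_sd_is_retained(self):
        assert filter_wt_background(1e-4 + 3 * 1e-5, 1e-4, 1e-5)

    def test_zero_sd_retains_anything_above_mean(self):
        assert filter_wt_background(1.0001e-4, 1e-4, 0.0)

    def test_frequency_at_control_mean_is_flagged(self):
        assert not filter_wt_background(1e-4, 1e-4, 1e-5)


def test_adjust_frequencies_is_plain_subtraction():
    assert adjust_frequencies(1e-4, 1e-5) == pytest.approx(9e-5)
    assert adjust_frequencies(1e-4, 0.0) == 1e-4


def test_enrichment_ratio_examples():
    assert enrichment_ratio(1e-4, 2e-4) == pytest.approx(2.0)
    assert enrichment_ratio(1e-4, 1e-4) == pytest.approx(1.0)
    assert np.isnan(enrichment_ratio(0.0, 1e-4))


class TestRegionAnchors:
    phi = np.array([0.9, 1.0, 1.1, 0.01, 0.02, 0.03, 0.5])
    cls = np.array(["synonymous"] * 3 + ["nonsense"] * 3 + ["missense"])

    def test_median_anchors(self):
        pos = np.array([10, 20, 30, 40, 50, 60, 70])
        phi_stop, phi_syn = region_anchors(self.phi, self.cls, pos, 100)
        assert phi_syn == 1.0
        assert phi_stop == 0.02

    def test_terminal_nonsense_window_boundary(self):
        # L=100: position 86 included in the null anchor, 87 excluded
        pos = np.array([10, 20, 30, 86, 87, 60, 70])
        phi_stop, _ = region_anchors(self.phi, self.cls, pos, 100,
                                     min_anchor_variants=2)
        assert phi_stop == np.median([0.01, 0.03])  # position-87 variant dropped

    def test_too_few_anchors_aborts_region(self):
        with pytest.raises(ScoringError, match="anchor"):
            region_anchors([1.0, 0.01], ["synonymous", "nonsense"],
                           [10, 20], 100)


class TestFunctionalScore:
    def test_anchor_values(self):
        assert functional_score(0.01, 0.01, 1.0) == 0.0
        assert functional_score(1.0, 0.01, 1.0) == 1.0

    def test_closed_form(self):
        # ln(0.5/0.1)/ln(1.0/0.1) = ln 5 / ln 10
        assert functional_score(0.5, 0.1, 1.0) == pytest.approx(
            math.log(5) / math.log(10), abs=1e-12)

    @given(st.floats(0.02, 50), st.floats(0.02, 50))
    def test_monotone_in_phi(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert functional_score(lo, 0.01, 1.0) < functional_score(hi, 0.01, 1.0)


class TestErrorRegularization:
    def test_uniform_agreement_gives_sd_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        n = 200
        base = rng.normal(0.5, 0.2, n)
        fs = np.column_stack([base - 0.05, base + 0.05])  # every obs sd equal
        freq = np.full(n, 1e-4)
        se, nrep = regularize_errors(fs, freq)
        common_sd = np.std([-.05, .05], ddof=1)
        np.testing.assert_allclose(se, common_sd / np.sqrt(2), rtol=1e-9)
        assert (nrep == 2).all()

    def test_zero_observed_sd_is_pulled_toward_prior(self):
        fs = np.array([[0.5, 0.5]] + [[0.2, 0.6]] * 50)
        freq = np.full(51, 1e-4)
        se, _ = regularize_errors(fs, freq)
        assert se[0] > 0

    def test_single_replicate_uses_prior_only(self):
        fs = np.array([[0.5, np.nan]] + [[0.2, 0.6]] * 50)
        freq = np.full(51, 1e-4)
        se, nrep = regularize_errors(fs, freq)
        assert nrep[0] == 1
        obs_sd = np.std([0.2, 0.6], ddof=1)
        assert se[0] == pytest.approx(obs_sd, rel=0.05)

    def test_low_coverage_variants_get_larger_errors(self, default_maps):
        """Empirical check on synthetic data: mean se in the lowest
        pre-selection-frequency decile exceeds the highest decile's."""
        maps, _ = default_maps
        m = maps["ubiquitous"].dropna(subset=["score"])
        decile = pd.qcut(m["nonselect_freq"], 10, labels=False)
        by = m.groupby(decile)["se"].mean()
        assert by.iloc[0] > by.iloc[-1]


def test_quality_filter_boundaries_inclusive():
    assert not quality_filter(0.31, 1e-3)
    assert not quality_filter(0.1, 4e-5)
    assert quality_filter(0.3, 5e-5)


def test_well_measured_flag_boundaries():
    assert well_measured_flag(21, 2_000_000)      # 10.5 cpm
    assert not well_measured_flag(19, 2_000_000)  # 9.5 cpm
    assert well_measured_flag(20, 2_000_000)      # exactly 10 cpm


def test_missing_wt_control_condition_is_an_error(toy_tables):
    counts, wt, _ = toy_tables
    with pytest.raises(ScoringError, match="select"):
        scoring.score_map(counts, wt[wt["condition"] == "nonselect"], 100)


class TestScoreMapOnToyTable:
    def test_filter_bookkeeping_conserves_variants(self, toy_scores):
        scores, log = toy_scores
        assert log["n_variants_in"] == log["n_scored"] + \
            log["n_wt_indistinguishable"] + log["n_low_freq"]

    def test_exact_scores(self, toy_scores):
        scores, _ = toy_scores
        s = scores.set_index("variant")["score"]
        assert s["p.D5N"] == pytest.approx(0.5, abs=1e-12)
        assert s["p.K11R"] == pytest.approx(1.0, abs=1e-12)
        assert s["p.I9V"] == pytest.approx(-0.5, abs=1e-12)
        assert s["p.T90*"] == pytest.approx(math.log(50) / math.log(100),
                                            abs=1e-12)
        assert np.isnan(s["p.F7L"])

    def test_anchor_medians_exact(self, toy_scores):
        scores, _ = toy_scores
        syn = scores[scores["var_class"] == "synonymous"]["score"]
        stop = scores[(scores["var_class"] == "nonsense")
                      & (scores["position"] <= 86)]["score"]
        assert syn.median() == 1.0
        assert stop.median() == 0.0

    def test_depleted_variant_floored_not_dropped(self, toy_scores):
        scores, _ = toy_scores
        row = scores.set_index("variant").loc["p.I9V"]
        assert row["flag_select_floored"]
        assert np.isfinite(row["score"])


class TestParameterRecovery:
    def test_scores_track_true_fitness(self, default_experiment, default_maps):
        maps, _ = default_maps
        truth = default_experiment.ground_truth
        for isoform, m in maps.items():
            q = m[m["passes_quality"]].merge(truth[["variant", "w"]],
                                             on="variant")
            r = np.corrcoef(q["score"], q["w"])[0, 1]
            assert r >= 0.9, f"{isoform}: r={r:.3f}"

    def test_per_region_anchoring_exact(self, default_experiment, default_maps):
        maps, _ = default_maps
        L = default_experiment.config.protein_length
        for m in maps.values():
            scored = m.dropna(subset=["score"])
            for region, sub in scored.groupby("region"):
                syn = sub[sub["var_class"] == "synonymous"]["score"]
                stop = sub[(sub["var_class"] == "nonsense")
                           & (sub["position"] <= L - 14)]["score"]
                assert syn.median() == pytest.approx(1.0, abs=1e-12)
                assert stop.median() == pytest.approx(0.0, abs=1e-12)

    def test_synonymous_and_nonsense_recovered_medians(self, default_experiment,
                                                       default_maps):
        maps, _ = default_maps
        L = default_experiment.config.protein_length
        m = maps["ubiquitous"]
        q = m[m["passes_quality"]]
        assert 0.95 <= q[q["var_class"] == "synonymous"]["score"].median() <= 1.05
        stop = q[(q["var_class"] == "nonsense") & (q["position"] <= L - 14)]
        assert -0.05 <= stop["score"].median() <= 0.05
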