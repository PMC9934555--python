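import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mavemap import calibration as cal


# ---------------------------------------------------------------------------
# reference sets

def test_proxy_benign_rule():
    gnomad = pd.DataFrame({
        "variant": ["p.A5G", "p.A6G", "p.A7G", "p.A8G"],
        "maf": [4e-4, 4e-4, 6e-4, 4e-4],
        "n_homozygotes": [1, 0, 2, 3],
        "pathogenic_annotation": [False, False, False, True],
    })
    ref = cal.build_reference_sets(gnomad_records=gnomad)
    assert set(ref["variant"]) == {"p.A5G"}  # others fail hom/MAF/annotation
    assert (ref["provenance"] == "proxy_benign").all()


def test_clinvar_labels_and_conflict_exclusion():
    cv = pd.DataFrame({
        "variant": ["p.A5G", "p.A6G", "p.A7G"],
        "significance": ["Likely pathogenic", "Benign", "Benign"],
        "has_review_criteria": [True, True, True],
        "conflicting": [False, False, True],
    })
    ref = cal.build_reference_sets(clinvar_records=cv)
    d = ref.set_index("variant")
    assert d.loc["p.A5G", "label"] == "positive"
    assert d.loc["p.A6G", "label"] == "negative"
    assert "p.A7G" not in d.index  # conflicting interpretations excluded


def test_cross_source_overlap_resolves_positive_with_warning():
    cv = pd.DataFrame({"variant": ["p.A5G"], "significance": ["Pathogenic"],
                       "has_review_criteria": [True], "conflicting": [False]})
    expert = pd.DataFrame({"variant": ["p.A5G"], "label": ["non_disease"]})
    with pytest.warns(UserWarning, match="positive"):
        ref = cal.build_reference_sets(clinvar_records=cv,
                                       expert_records=expert)
    assert ref.set_index("variant").loc["p.A5G", "label"] == "positive"


def test_same_source_conflict_is_an_error():
    cv = pd.DataFrame({
        "variant": ["p.A5G", "p.A5G"],
        "significance": ["Pathogenic", "Benign"],
        "has_review_criteria": [True, True],
        "conflicting": [False, False]})
    with pytest.raises(ValueError, match="both"):
        cal.build_reference_sets(clinvar_records=cv)


# ---------------------------------------------------------------------------
# precision-recall

def _brute_force_curve(scores, labels):
    """Exhaustive confusion-matrix enumeration at each distinct threshold."""
    points = {}
    for t in sorted(set(scores)) + [float("inf")]:
        tp = sum(1 for s, l in zip(scores, labels) if s < t and l == "positive")
        fp = sum(1 for s, l in zip(scores, labels) if s < t and l == "negative")
        fn = sum(1 for s, l in zip(scores, labels) if s >= t and l == "positive")
        tn = sum(1 for s, l in zip(scores, labels) if s >= t and l == "negative")
        points[t] = (tp / (tp + fn), fp / (fp + tn),
                     tp / (tp + fp) if tp + fp else None)
    return points


def test_separated_sets_reach_perfect_precision_and_recall():
    curve = cal.precision_recall([0.1, 0.2, 0.8, 0.9],
                                 ["positive", "positive", "negative", "negative"])
    best = curve[(curve["recall"] == 1.0)]
    assert (best["precision"] == 1.0).any()


def test_hand_confusion_matrix():
    curve = cal.precision_recall([0.1, 0.2, 0.8, 0.9],
                                 ["positive", "positive", "negative", "negative"])
    at = curve[curve["threshold"] == 0.8].iloc[0]  # same calls as t=0.5
    assert at["precision"] == 1.0 and at["recall"] == 1.0 and at["fpr"] == 0.0


@settings(deadline=None, max_examples=150)
@given(st.lists(st.tuples(st.floats(-1, 2), st.booleans()),
                min_size=2, max_size=12))
def test_curve_matches_exhaustive_enumeration(items):
    scores = [round(s, 3) for s, _ in items]
    labels = ["positive" if b else "negative" for _, b in items]
    if "positive" not in labels or "negative" not in labels:
        return
    oracle = _brute_force_curve(scores, labels)
    curve = cal.precision_recall(scores, labels).set_index("threshold")
    for t, (rec, fpr, prec) in oracle.items():
        row = curve.loc[t]
        assert row["recall"] == pytest.approx(rec)
        assert row["fpr"] == pytest.approx(fpr)
        if prec is not None:
            assert row["precision"] == pytest.approx(prec)


def test_balanced_precision_examples():
    assert cal.balanced_precision(0.8, 0.2) == pytest.approx(0.8)
    assert cal.balanced_precision(0.5, 0.0) == 1.0
    assert np.isnan(cal.balanced_precision(0.0, 0.0))


def test_balanced_precision_invariant_to_negative_set_duplication():
    scores = [0.1, 0.2, 0.4, 0.8, 0.9]
    labels = ["positive", "positive", "negative", "negative", "negative"]
    c1 = cal.precision_recall(scores, labels)
    c2 = cal.precision_recall(scores + scores[2:], labels + labels[2:])
    merged = c1.merge(c2, on="threshold", suffixes=("_1", "_2"))
    np.testing.assert_allclose(merged["balanced_precision_1"],
                               merged["balanced_precision_2"])


def test_r90bp_and_aubprc_perfect_separation():
    curve = cal.precision_recall([0.0, 0.1, 0.8, 0.9],
                                 ["positive", "positive", "negative", "negative"])
    assert cal.r90bp(curve) == 1.0
    assert cal.aubprc(curve) == pytest.approx(1.0)


def test_r90bp_zero_when_unreachable():
    curve = pd.DataFrame({"threshold": [0, 1], "precision": [0.5, 0.5],
                          "recall": [0.5, 1.0], "fpr": [0.5, 1.0],
                          "balanced_precision": [0.5, 0.5]})
    assert cal.r90bp(curve) == 0.0


def test_aubprc_matches_hand_trapezoid():
    curve = pd.DataFrame({
        "threshold": [1, 2, 3, 4],
        "precision": [1, 1, 1, 1],
        "recall": [0.0, 0.4, 0.8, 1.0],
        "fpr": [0, 0, 0, 0],
        "balanced_precision": [1.0, 0.9, 0.8, 0.6],
    })
    # trapezoid by hand: 0.4*(1+.9)/2 + 0.4*(.9+.8)/2 + 0.2*(.8+.6)/2
    hand = 0.4 * 0.95 + 0.4 * 0.85 + 0.2 * 0.7
    assert cal.aubprc(curve) == pytest.approx(hand, abs=1e-12)


# ---------------------------------------------------------------------------
# densities and LLR

def test_gaussian_mle_closed_form():
    d = cal.fit_density_pair([0, 0, 1, 1], [2, 2, 3, 3])
    assert (d.mu_pos, d.sd_pos) == (0.5, 0.5)


def test_degenerate_density_rejected():
    with pytest.raises(ValueError):
        cal.fit_density_pair([1.0, 1.0], [0.0, 1.0])


def test_density_recovery_from_large_sample():
    rng = np.random.default_rng(0)
    d = cal.fit_density_pair(rng.normal(0.1, 0.2, 20_000),
                             rng.normal(1.0, 0.15, 20_000))
    assert d.mu_pos == pytest.approx(0.1, abs=0.01)
    assert d.sd_pos == pytest.approx(0.2, abs=0.01)
    assert d.mu_neg == pytest.approx(1.0, abs=0.01)


def test_llrp_zero_at_symmetric_point():
    d = cal.DensityPair(-1.0, 1.0, 1.0, 1.0)
    assert cal.llrp(0.0, d) == pytest.approx(0.0, abs=1e-12)


def test_llrp_gaussian_closed_form():
    # mu+=0, mu-=1, sigma=0.25, f=0: log10 exp(((1-0)^2)/(2*0.0625)) = 8/ln10
    d = cal.DensityPair(0.0, 0.25, 1.0, 0.25)
    assert cal.llrp(0.0, d) == pytest.approx(8 / math.log(10), abs=1e-10)


@settings(deadline=None)
@given(st.floats(-0.5, 0.5), st.floats(0.05, 0.5),
       st.floats(0.6, 1.5), st.floats(0.05, 0.5),
       st.floats(-1, 2))
def test_llrp_matches_analytic_log_ratio(mu_p, sd_p, mu_n, sd_n, f):
    d = cal.DensityPair(mu_p, sd_p, mu_n, sd_n)
    analytic = (math.log(sd_n / sd_p)
                - (f - mu_p) ** 2 / (2 * sd_p ** 2)
                + (f - mu_n) ** 2 / (2 * sd_n ** 2)) / math.log(10)
    assert cal.llrp(f, d) == pytest.approx(analytic, abs=1e-10)


def test_llrp_decreasing_when_damaging_scores_low():
    d = cal.DensityPair(0.1, 0.2, 1.0, 0.2)
    f = np.linspace(-0.5, 1.5, 50)
    assert (np.diff(cal.llrp(f, d)) < 0).all()


def test_posterior_odds():
    assert cal.posterior_odds(1.0, 0.5) == pytest.approx(10.0)
    assert cal.posterior_odds(0.0, 0.1) == pytest.approx(1 / 9)
    p = cal.odds_to_probability(cal.posterior_odds(0.5, 0.3))
    o = p / (1 - p)
    assert o == pytest.approx(cal.posterior_odds(0.5, 0.3))


# ---------------------------------------------------------------------------
# ACMG calibration

def test_halving_and_mirror_invariants():
    th = cal.calibrate_acmg_thresholds()
    assert th.pst == pytest.approx(th.pvst / 2, abs=1e-12)
    assert th.pm == pytest.approx(th.pvst / 4, abs=1e-12)
    assert th.psu == pytest.approx(th.pvst / 8, abs=1e-12)
    assert th.bsu == pytest.approx(-th.psu, abs=1e-12)
    assert th.bst == pytest.approx(-th.pst, abs=1e-12)


def test_all_posterior_constraints_hold_at_solution():
    th = cal.calibrate_acmg_thresholds()
    prior_odds = th.prior / (1 - th.prior)
    for rule in cal.DEFAULT_RULES:
        expo = sum(cal.EVIDENCE_EXPONENTS[k] * n
                   for k, n in rule["evidence"].items())
        post = cal.odds_to_probability(th.odds_pvst ** expo * prior_odds)
        op, bound = cal.DEFAULT_CONSTRAINTS[rule["category"]]
        if op == ">=":
            assert post >= bound - 1e-9, rule["name"]
        else:
            assert post <= bound + 1e-9, rule["name"]


def test_solution_is_minimal():
    th = cal.calibrate_acmg_thresholds()
    ok, _ = cal._rules_satisfied(th.odds_pvst * 0.999, th.prior,
                                 cal.DEFAULT_RULES, cal.DEFAULT_CONSTRAINTS)
    assert not ok


def test_pathogenic_constraints_relax_as_prior_rises():
    """With a larger prior the pathogenic-side combining rules are satisfied
    at smaller very-strong odds (posterior monotone in the prior).  The
    benign-side rules pull the other way, so only the pathogenic/likely-
    pathogenic subset is checked here."""
    path_rules = [r for r in cal.DEFAULT_RULES
                  if r["category"] in ("pathogenic", "likely_pathogenic")]
    xs = [cal.calibrate_acmg_thresholds(prior=p, rules=path_rules).odds_pvst
          for p in (0.05, 0.1, 0.2, 0.4)]
    assert all(a > b for a, b in zip(xs, xs[1:]))


def test_unsatisfiable_rules_report_binding_rule():
    rules = [{"name": "impossible", "category": "pathogenic",
              "evidence": {"BSu": 1}}]
    with pytest.raises(RuntimeError, match="impossible"):
        cal.calibrate_acmg_thresholds(rules=rules)


def test_evidence_assignment():
    th = cal.calibrate_acmg_thresholds()
    assert cal.assign_evidence(0.70, th) == "PM"
    assert cal.assign_evidence(0.0, th) == "indeterminate"
    assert cal.assign_evidence(-1.5, th) == "BSt"
    assert cal.assign_evidence(3.0, th) == "PVSt"
    assert cal.assign_evidence(-0.4, th) == "BSu"
    arr = cal.assign_evidence(np.array([1.5, 0.4]), th)
    assert list(arr) == ["PSt", "PSu"]
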