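"""Clinical calibration of variant-effect maps.

Three pieces live here:

* reference-set construction (pathogenic/benign/proxy-benign labeling from
  pre-extracted clinical and population tables);
* map evaluation against a reference set with precision-recall curves that
  are re-balanced to a 50/50 class prior (balanced precision
  BP = recall / (recall + FPR)), the area under the balanced curve
  (AUBPRC), and the recall at 90% balanced precision (R90BP);
* conversion of scores into log10 likelihood ratios of pathogenicity
  (LLRp) via Gaussian densities fitted to the reference scores, and a
  Tavtigian-style calibration of ACMG/AMP evidence-strength thresholds:
  evidence levels carry odds X^(1/2^k) (halving exponents, benign levels
  reciprocal), and the very-strong odds X is the smallest value for which
  every evidence-combining rule attains its required posterior probability
  of pathogenicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_reference_sets", "precision_recall", "balanced_precision",
    "r90bp", "aubprc", "evaluate_map", "DensityPair", "fit_density_pair",
    "llrp", "posterior_odds", "EvidenceThresholds",
    "calibrate_acmg_thresholds", "assign_evidence", "DEFAULT_RULES",
    "DEFAULT_CONSTRAINTS", "PROXY_BENIGN_MAX_MAF",
]

PROXY_BENIGN_MAX_MAF = 5e-4

#: Exponent of the very-strong odds X carried by each evidence level: the
#: odds of pathogenicity halve in exponent at each step down, and benign
#: evidence is the reciprocal of the matching pathogenic level.
EVIDENCE_EXPONENTS = {
    "PVS": 1.0, "PS": 0.5, "PM": 0.25, "PSu": 0.125,
    "BS": -0.5, "BSu": -0.125,
}

#: Posterior-probability constraint per rule category (inclusive).
DEFAULT_CONSTRAINTS = {
    "pathogenic": (">=", 0.99),
    "likely_pathogenic": (">=", 0.90),
    "likely_benign": ("<=", 0.10),
    "benign": ("<=", 0.01),
}

#: ACMG/AMP evidence-combining rules, encoded with the weakest qualifying
#: count for each ">= n" criterion.  The classical "two Strong lines =>
#: Pathogenic" combination cannot reach the pathogenic posterior constraint
#: anywhere in the halving framework (it is a known misfit of that
#: framework) and is therefore held to the likely-pathogenic constraint.
DEFAULT_RULES = [
    {"name": "P: 1 very strong + 1 strong", "category": "pathogenic",
     "evidence": {"PVS": 1, "PS": 1}},
    {"name": "P: 1 very strong + 2 moderate", "category": "pathogenic",
     "evidence": {"PVS": 1, "PM": 2}},
    {"name": "P: 1 very strong + 1 moderate + 1 supporting",
     "category": "pathogenic", "evidence": {"PVS": 1, "PM": 1, "PSu": 1}},
    {"name": "P: 1 very strong + 2 supporting", "category": "pathogenic",
     "evidence": {"PVS": 1, "PSu": 2}},
    {"name": "P: 1 strong + 3 moderate", "category": "pathogenic",
     "evidence": {"PS": 1, "PM": 3}},
    {"name": "P: 1 strong + 2 moderate + 2 supporting",
     "category": "pathogenic", "evidence": {"PS": 1, "PM": 2, "PSu": 2}},
    {"name": "P: 1 strong + 1 moderate + 4 supporting",
     "category": "pathogenic", "evidence": {"PS": 1, "PM": 1, "PSu": 4}},
    {"name": "P*: 2 strong (held to LP constraint)",
     "category": "likely_pathogenic", "evidence": {"PS": 2}},
    {"name": "LP: 1 very strong + 1 moderate", "category": "likely_pathogenic",
     "evidence": {"PVS": 1, "PM": 1}},
    {"name": "LP: 1 strong + 1 moderate", "category": "likely_pathogenic",
     "evidence": {"PS": 1, "PM": 1}},
    {"name": "LP: 1 strong + 2 supporting", "category": "likely_pathogenic",
     "evidence": {"PS": 1, "PSu": 2}},
    {"name": "LP: 3 moderate", "category": "likely_pathogenic",
     "evidence": {"PM": 3}},
    {"name": "LP: 2 moderate + 2 supporting", "category": "likely_pathogenic",
     "evidence": {"PM": 2, "PSu": 2}},
    {"name": "LP: 1 moderate + 4 supporting", "category": "likely_pathogenic",
     "evidence": {"PM": 1, "PSu": 4}},
    {"name": "B: 2 strong benign", "category": "benign",
     "evidence": {"BS": 2}},
    {"name": "LB: 1 strong benign + 1 supporting benign",
     "category": "likely_benign", "evidence": {"BS": 1, "BSu": 1}},
    {"name": "LB: 2 supporting benign", "category": "likely_benign",
     "evidence": {"BSu": 2}},
]


# ---------------------------------------------------------------------------
# reference sets

def build_reference_sets(clinvar_records: pd.DataFrame | None = None,
                         expert_records: pd.DataFrame | None = None,
                         gnomad_records: pd.DataFrame | None = None,
                         max_proxy_maf: float = PROXY_BENIGN_MAX_MAF,
                         ) -> pd.DataFrame:
    """Label reference variants as positive (pathogenic) or negative (benign).

    Parameters
    ----------
    clinvar_records : DataFrame, optional
        Columns: variant, significance (pathogenic / likely_pathogenic /
        benign / likely_benign / ...), has_review_criteria (bool),
        conflicting (bool).
    expert_records : DataFrame, optional
        Columns: variant, label ("disease" or "non_disease").
    gnomad_records : DataFrame, optional
        Columns: variant, maf, n_homozygotes, pathogenic_annotation (bool).
        Variants qualify as proxy-benign when MAF < ``max_proxy_maf``, at
        least one homozygote has been observed, and no pathogenic
        annotation exists.

    A variant labeled both ways across sources resolves to positive with a
    warning; both ways within one source is an error.
    """
    rows: list[tuple[str, str, str, float, int]] = []

    if expert_records is not None and len(expert_records):
        lab = expert_records.groupby("variant")["label"].nunique()
        dup = lab[lab > 1]
        if len(dup):
            raise ValueError(f"conflicting expert labels for {list(dup.index)}")
        for _, r in expert_records.iterrows():
            rows.append((r["variant"],
                         "positive" if r["label"] == "disease" else "negative",
                         "expert_center", np.nan, 0))

    if clinvar_records is not None and len(clinvar_records):
        cv = clinvar_records.copy()
        cv["sig"] = cv["significance"].str.lower().str.replace(" ", "_")
        is_path = cv["sig"].isin(["pathogenic", "likely_pathogenic"])
        is_ben = cv["sig"].isin(["benign", "likely_benign"])
        both = cv.groupby("variant").apply(
            lambda g: (g["sig"].isin(["pathogenic", "likely_pathogenic"]).any()
                       and g["sig"].isin(["benign", "likely_benign"]).any()),
            include_groups=False)
        if both.any():
            raise ValueError(
                f"variant labeled both ways in ClinVar: {list(both[both].index)}")
        for _, r in cv[is_path].iterrows():
            rows.append((r["variant"], "positive", "clinvar_pathogenic", np.nan, 0))
        ben = cv[is_ben]
        ben = ben[ben.get("has_review_criteria", pd.Series(True, index=ben.index)).astype(bool)
                  & ~ben.get("conflicting", pd.Series(False, index=ben.index)).astype(bool)]
        for _, r in ben.iterrows():
            rows.append((r["variant"], "negative", "clinvar_benign", np.nan, 0))

    if gnomad_records is not None and len(gnomad_records):
        g = gnomad_records
        ok = ((g["maf"] < max_proxy_maf) & (g["n_homozygotes"] >= 1)
              & ~g.get("pathogenic_annotation",
                       pd.Series(False, index=g.index)).astype(bool))
        for _, r in g[ok].iterrows():
            rows.append((r["variant"], "negative", "proxy_benign",
                         float(r["maf"]), int(r["n_homozygotes"])))

    out = pd.DataFrame(rows, columns=["variant", "label", "provenance",
                                      "maf", "n_homozygotes"])
    conflict = out.groupby("variant")["label"].nunique()
    for v in conflict[conflict > 1].index:
        warnings.warn(f"{v} labeled both positive and negative across "
                      f"sources; keeping positive")
        out = out[~((out["variant"] == v) & (out["label"] == "negative"))]
    return out.drop_duplicates(subset=["variant"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# balanced precision-recall

def balanced_precision(recall, fpr):
    """Precision under equal class priors: BP = recall / (recall + FPR)."""
    recall = np.asarray(recall, dtype=float)
    fpr = np.asarray(fpr, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(recall + fpr > 0, recall / (recall + fpr), np.nan)


def precision_recall(scores, labels, damaging_direction: str = "low",
                     ) -> pd.DataFrame:
    """Threshold-indexed precision/recall/FPR curve.

    A variant is called pathogenic when its score falls strictly below the
    threshold (``damaging_direction="low"``; scores are negated for
    ``"high"``).  One point per distinct score threshold, plus a final
    all-inclusive point so recall reaches 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = (labels == "positive") | (labels == 1) | (labels == True)  # noqa: E712
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("need at least one positive and one negative variant")
    if damaging_direction == "high":
        scores = -scores
    elif damaging_direction != "low":
        raise ValueError("damaging_direction must be 'low' or 'high'")
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    rows = []
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    for t in thresholds:
        called = scores < t
        tp = int((called & pos).sum())
        fp = int((called & ~pos).sum())
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / n_pos
        fpr = fp / n_neg
        rows.append((t, prec, rec, fpr))
    curve = pd.DataFrame(rows, columns=["threshold", "precision", "recall", "fpr"])
    curve["balanced_precision"] = balanced_precision(curve["recall"], curve["fpr"])
    return curve


def r90bp(curve: pd.DataFrame, bp_cutoff: float = 0.90) -> float:
    """Maximum recall over thresholds with balanced precision >= cutoff
    (0 if no threshold qualifies)."""
    ok = curve["balanced_precision"] >= bp_cutoff
    return float(curve.loc[ok, "recall"].max()) if ok.any() else 0.0


def aubprc(curve: pd.DataFrame) -> float:
    """Area under the balanced precision vs recall curve (trapezoid over
    recall-sorted points; undefined-BP points dropped)."""
    pts = curve.dropna(subset=["balanced_precision"])
    if len(pts) < 2:
        raise ValueError("need at least 2 curve points for an area")
    # at each recall level, the operating point is the best achievable BP
    best = pts.groupby("recall")["balanced_precision"].max().sort_index()
    recall = best.index.to_numpy(float)
    bp = best.to_numpy(float)
    if len(recall) < 2:
        recall = np.concatenate([recall, recall])
        bp = np.concatenate([bp, bp])
    if recall[0] > 0:
        # anchor at recall 0 with the first defined balanced precision
        recall = np.concatenate([[0.0], recall])
        bp = np.concatenate([[bp[0]], bp])
    return float(np.trapezoid(bp, recall))


def evaluate_map(score_map: pd.DataFrame, reference: pd.DataFrame,
                 masked_positions: list[tuple[int, int]] | None = None,
                 quality_only: bool = True) -> dict:
    """Score a map against a labeled reference set.

    ``masked_positions`` is a list of inclusive (start, stop) residue
    intervals excluded from evaluation (position-level masking).  Returns
    Pearson-free summary metrics: n, AUBPRC, R90BP and the curve itself.
    """
    m = score_map
    if quality_only and "passes_quality" in m.columns:
        m = m[m["passes_quality"]]
    joined = reference.merge(m[["variant", "score"]
                               + (["position"] if "position" in m.columns else [])],
                             on="variant", how="inner").dropna(subset=["score"])
    if masked_positions:
        if "position" not in joined.columns:
            raise ValueError("masking requires a position column")
        keep = np.ones(len(joined), dtype=bool)
        for start, stop in masked_positions:
            keep &= ~joined["position"].between(start, stop).to_numpy()
        joined = joined[keep]
    curve = precision_recall(joined["score"], joined["label"])
    return {
        "n_scored_reference": int(len(joined)),
        "n_positive": int((joined["label"] == "positive").sum()),
        "n_negative": int((joined["label"] == "negative").sum()),
        "aubprc": aubprc(curve),
        "r90bp": r90bp(curve),
        "curve": curve,
    }


# ---------------------------------------------------------------------------
# score densities and likelihood ratios

@dataclass
class DensityPair:
    """Gaussian score densities for pathogenic (+) and benign (-) variants."""

    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float

    def __post_init__(self) -> None:
        if not (self.sd_pos > 0 and self.sd_neg > 0):
            raise ValueError("density SDs must be strictly positive")


def fit_density_pair(positive_scores, negative_scores) -> DensityPair:
    """Maximum-likelihood Gaussian fits (mean, population SD) per class."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 scores per class")
    return DensityPair(float(pos.mean()), float(pos.std(ddof=0)),
                       float(neg.mean()), float(neg.std(ddof=0)))


def llrp(score, densities: DensityPair):
    """log10 likelihood ratio of pathogenicity at a functional score."""
    f = np.asarray(score, dtype=float)
    log_num = stats.norm.logpdf(f, densities.mu_pos, densities.sd_pos)
    log_den = stats.norm.logpdf(f, densities.mu_neg, densities.sd_neg)
    return (log_num - log_den) / np.log(10.0)


def posterior_odds(llr, prior: float):
    """Posterior odds of pathogenicity: 10^LLRp * P+/(1-P+)."""
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0,1)")
    return 10.0 ** np.asarray(llr, dtype=float) * prior / (1.0 - prior)


def odds_to_probability(odds):
    return np.asarray(odds, dtype=float) / (1.0 + np.asarray(odds, dtype=float))


# ---------------------------------------------------------------------------
# ACMG/AMP threshold calibration

@dataclass
class EvidenceThresholds:
    """The six log10 LLR cut-points produced by the calibration, with the
    prior and the very-strong odds they derive from."""

    pvst: float
    pst: float
    pm: float
    psu: float
    bsu: float
    bst: float
    prior: float
    odds_pvst: float
    binding_rule: str = ""

    @classmethod
    def from_odds(cls, odds_pvst: float, prior: float,
                  binding_rule: str = "") -> "EvidenceThresholds":
        pvst = float(np.log10(odds_pvst))
        return cls(pvst=pvst, pst=pvst / 2, pm=pvst / 4, psu=pvst / 8,
                   bsu=-pvst / 8, bst=-pvst / 2, prior=prior,
                   odds_pvst=odds_pvst, binding_rule=binding_rule)

    def as_dict(self) -> dict:
        return {"PVSt": self.pvst, "PSt": self.pst, "PM": self.pm,
                "PSu": self.psu, "BSu": self.bsu, "BSt": self.bst,
                "prior": self.prior, "odds_pvst": self.odds_pvst,
                "binding_rule": self.binding_rule}


def _rule_exponent(evidence: dict[str, int]) -> float:
    return sum(EVIDENCE_EXPONENTS[level] * int(n) for level, n in evidence.items())


def _rules_satisfied(x: float, prior: float, rules, constraints) -> tuple[bool, str]:
    """Check every combining rule's posterior constraint at very-strong
    odds ``x``; returns (ok, name-of-first-violated-rule)."""
    prior_odds = prior / (1.0 - prior)
    for rule in rules:
        op, bound = constraints[rule["category"]]
        post = odds_to_probability(x ** _rule_exponent(rule["evidence"]) * prior_odds)
        ok = post >= bound if op == ">=" else post <= bound
        if not ok:
            return False, rule["name"]
    return True, ""


def calibrate_acmg_thresholds(prior: float = 0.10, rules=None,
                              constraints=None,
                              x_range: tuple[float, float] = (1.0 + 1e-9, 1e6),
                              tol: float = 1e-10) -> EvidenceThresholds:
    """Find the most conservative very-strong odds X meeting all constraints.

    Evidence of level k carries odds X^(1/2^k) (PVS, PS, PM, PSu for
    k = 0..3; benign levels reciprocal), and each combining rule's posterior
    probability of pathogenicity (at the given prior) must satisfy its
    category constraint.  Satisfiability is monotone in X — pathogenic-side
    posteriors increase with X and benign-side decrease — so the smallest
    admissible X is located by bisection and the six log10 thresholds are
    derived from it by exponent halving and mirroring.
    """
    rules = DEFAULT_RULES if rules is None else rules
    constraints = DEFAULT_CONSTRAINTS if constraints is None else constraints
    lo, hi = x_range
    ok_hi, _ = _rules_satisfied(hi, prior, rules, constraints)
    if not ok_hi:
        _, name = _rules_satisfied(hi, prior, rules, constraints)
        raise RuntimeError(f"no admissible X in range; binding rule: {name}")
    ok_lo, _ = _rules_satisfied(lo, prior, rules, constraints)
    if ok_lo:
        hi = lo
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        ok, _ = _rules_satisfied(mid, prior, rules, constraints)
        if ok:
            hi = mid
        else:
            lo = mid
    # name the rule that binds just below the solution
    _, binding = _rules_satisfied(max(lo, x_range[0]), prior, rules, constraints)
    return EvidenceThresholds.from_odds(hi, prior, binding_rule=binding)


EVIDENCE_CATEGORIES = ("PVSt", "PSt", "PM", "PSu", "indeterminate", "BSu", "BSt")


def assign_evidence(llr, thresholds: EvidenceThresholds):
    """Map an LLRp value to the strongest evidence category it reaches."""
    arr = np.atleast_1d(np.asarray(llr, dtype=float))
    out = np.full(arr.shape, "indeterminate", dtype=object)
    out[arr >= thresholds.psu] = "PSu"
    out[arr >= thresholds.pm] = "PM"
    out[arr >= thresholds.pst] = "PSt"
    out[arr >= thresholds.pvst] = "PVSt"
    out[arr <= thresholds.bsu] = "BSu"
    out[arr <= thresholds.bst] = "BSt"
    if np.isscalar(llr) or np.ndim(llr) == 0:
        return str(out[0])
    return out
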