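"""Structure-aware descriptive analyses of a variant-effect map.

Residue-level classifiers (solvent accessibility, interface membership,
predicted thermostability change), moving-window score profiles,
per-residue medians for structure coloring, group comparisons, and the
amino-acid preference transforms used to ask whether above-wild-type
("hyper-complementing") variants behave as advantageous, neutral or
damaging across homologs.

ASA and ddG values are externally computed and ingested; nothing here
touches structure files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .variants import AMINO_ACIDS

__all__ = [
    "classify_residue", "classify_interface", "classify_ddg",
    "moving_window_profile", "median_score_per_residue", "compare_groups",
    "wt_normalize_scores", "transform_preferences", "read_residue_annotations",
]

PREFERENCE_MODELS = ("advantageous", "neutral", "damaging")


def classify_residue(asa_pct: float) -> str:
    """Solvent-accessibility class: exposed above 40% ASA, buried below 20%,
    intermediate otherwise (boundaries inclusive to intermediate)."""
    if asa_pct > 40.0:
        return "exposed"
    if asa_pct < 20.0:
        return "buried"
    return "intermediate"


def classify_interface(delta_asa: float) -> bool:
    """Interface residue: accessible surface area changes by more than
    1 A^2 between complex and monomer (strictly greater)."""
    return delta_asa > 1.0


def classify_ddg(ddg: float) -> str:
    """Stabilizing when ddG >= -1 kcal/mol, destabilizing below."""
    return "stabilizing" if ddg >= -1.0 else "destabilizing"


def read_residue_annotations(path) -> pd.DataFrame:
    """Ingest a residue-annotation TSV (position, asa_pct, delta_asa) and
    derive the class columns."""
    df = pd.read_csv(path, sep="\t")
    df["residue_class"] = df["asa_pct"].map(classify_residue)
    df["is_interface"] = df["delta_asa"].map(classify_interface)
    return df


def moving_window_profile(values_by_position: pd.Series, window: int = 5,
                          ) -> pd.Series:
    """Mean of available values in a centered window of residue positions.

    ``values_by_position`` is indexed by 1-based position (gaps allowed).
    Windows truncate at the termini; positions with no observed value in
    their whole window are absent from the output.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    lo, hi = int(values_by_position.index.min()), int(values_by_position.index.max())
    full = values_by_position.reindex(range(lo, hi + 1))
    prof = full.rolling(window, center=True, min_periods=1).mean()
    return prof.dropna()


def median_score_per_residue(score_map: pd.DataFrame,
                             quality_only: bool = True) -> pd.Series:
    """Median functional score of substitutions at each residue position
    (for structure coloring export)."""
    m = score_map
    if quality_only and "passes_quality" in m.columns:
        m = m[m["passes_quality"]]
    m = m.dropna(subset=["score"])
    return m.groupby("position")["score"].median()


def compare_groups(scores_a, scores_b) -> dict:
    """Difference in medians with a two-sided Mann-Whitney U test."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"delta_median": float(np.median(a) - np.median(b)),
            "u_statistic": float(u), "p_value": float(p),
            "n_a": len(a), "n_b": len(b)}


def wt_normalize_scores(score_map: pd.DataFrame,
                        quality_only: bool = True) -> pd.DataFrame:
    """Per-position wild-type-relative scores s_{r,a} = FS_{r,a} / FS_{r,wt}.

    The wild-type score at a position is its synonymous variant's score
    when measured, else 1; normalizing avoids penalizing the wild-type
    residue where its own score drifts slightly above 1.  Returns rows
    (position, alt_aa, s) for missense variants.
    """
    m = score_map
    if quality_only and "passes_quality" in m.columns:
        m = m[m["passes_quality"]]
    m = m.dropna(subset=["score"])
    wt = (m[m["var_class"] == "synonymous"]
          .groupby("position")["score"].median())
    mis = m[m["var_class"] == "missense"].copy()
    if "alt_aa" not in mis.columns:
        mis["alt_aa"] = mis["variant"].str.extract(r"(.)$")[0]
    mis["wt_score"] = mis["position"].map(wt).fillna(1.0)
    mis["s"] = mis["score"] / mis["wt_score"]
    out = mis[["position", "alt_aa", "s"]]
    if "ref_aa" in m.columns:
        # the wild-type residue itself scores 1 by construction
        wt_rows = (m.drop_duplicates("position")[["position", "ref_aa"]]
                   .rename(columns={"ref_aa": "alt_aa"}))
        wt_rows["s"] = 1.0
        out = pd.concat([out, wt_rows], ignore_index=True)
    return out.reset_index(drop=True)


def _apply_model(s: np.ndarray, model: str) -> np.ndarray:
    if model == "advantageous":
        return s
    if model == "neutral":
        return np.minimum(s, 1.0)
    if model == "damaging":
        return np.where(s > 1.0, 1.0 / s, s)
    raise ValueError(f"unknown preference model {model!r}; "
                     f"choose from {PREFERENCE_MODELS}")


def transform_preferences(normalized_scores: pd.DataFrame, model: str,
                          impute_missing: bool = True) -> pd.DataFrame:
    """Site-by-amino-acid preference table under one hyper-complementation
    model.

    ``normalized_scores`` holds (position, alt_aa, s) from
    :func:`wt_normalize_scores`.  Scores above 1 are kept (advantageous),
    clipped to 1 (neutral) or inverted to 1/s (damaging); each site's row
    is then normalized to sum to 1.  Missing amino acids are imputed with
    the site median score before transformation (configurable off; sites
    with no data at all get a uniform row).
    """
    wide = normalized_scores.pivot_table(index="position", columns="alt_aa",
                                         values="s", aggfunc="mean")
    wide = wide.reindex(columns=list(AMINO_ACIDS))
    if impute_missing:
        fill = wide.median(axis=1)
        wide = wide.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    wide = wide.fillna(1.0)  # sites with no measurements at all: uniform
    vals = _apply_model(wide.to_numpy(float), model)
    vals = np.clip(vals, 1e-9, None)  # preferences are strictly positive
    vals = vals / vals.sum(axis=1, keepdims=True)
    out = pd.DataFrame(vals, index=wide.index, columns=wide.columns)
    out.attrs["model"] = model
    return out
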