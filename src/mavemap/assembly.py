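"""Cross-isoform map harmonization and the combined variant-effect map.

Selection stringency differs between isoform screens, distorting the score
scale.  The erythroid map is therefore rescaled by the affine transform that
minimizes the mean squared score difference to the ubiquitous map over
shared quality-passing variants (ordinary least squares; a scale-only fit is
available).  Harmonized scores are then merged per variant by
inverse-variance weighting, and a delta score (erythroid minus ubiquitous)
is reported for isoform-difference screening.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rescale_isoform", "combine_scores", "combine_maps", "compare_maps"]


def _shared(map_a: pd.DataFrame, map_b: pd.DataFrame,
            quality_only: bool = True) -> pd.DataFrame:
    a = map_a.set_index("variant")
    b = map_b.set_index("variant")
    shared = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    if quality_only and "passes_quality_a" in shared.columns:
        shared = shared[shared["passes_quality_a"] & shared["passes_quality_b"]]
    return shared.dropna(subset=["score_a", "score_b"])


def rescale_isoform(map_a: pd.DataFrame, map_b: pd.DataFrame,
                    scale_only: bool = False,
                    quality_only: bool = True) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Affine-rescale ``map_a`` onto the scale of ``map_b``.

    Fits score_b ~ a*score_a + b over shared (quality-passing) variants by
    least squares and applies it to ``map_a`` scores; standard errors scale
    by ``|a|``.  With ``scale_only`` the offset is fixed at 0.  Returns the
    transformed copy of ``map_a`` and the fitted ``(a, b)``.
    """
    shared = _shared(map_a, map_b, quality_only)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared variants to rescale")
    x = shared["score_a"].to_numpy(float)
    y = shared["score_b"].to_numpy(float)
    if np.ptp(x) == 0:
        warnings.warn("degenerate shared set (constant scores); "
                      "applying identity transform")
        a, b = 1.0, 0.0
    elif scale_only:
        a, b = float(np.dot(x, y) / np.dot(x, x)), 0.0
    else:
        a, b = np.polyfit(x, y, 1)
        a, b = float(a), float(b)
    out = map_a.copy()
    out["score"] = a * out["score"] + b
    if "se" in out.columns:
        out["se"] = abs(a) * out["se"]
    return out, (a, b)


def combine_scores(fs_1, se_1, fs_2, se_2) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance weighted mean of two score estimates.

    FS = (FS1/se1^2 + FS2/se2^2) / (1/se1^2 + 1/se2^2), with combined
    variance 1/(1/se1^2 + 1/se2^2).  A missing estimate (NaN) passes the
    other through unchanged.  Symmetric in its arguments.
    """
    fs_1, se_1, fs_2, se_2 = (np.asarray(v, dtype=float)
                              for v in (fs_1, se_1, fs_2, se_2))
    has1 = np.isfinite(fs_1) & np.isfinite(se_1)
    has2 = np.isfinite(fs_2) & np.isfinite(se_2)
    if np.any((has1 & (se_1 <= 0)) | (has2 & (se_2 <= 0))):
        raise ValueError("standard errors must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = np.where(has1, 1.0 / se_1**2, 0.0)
        w2 = np.where(has2, 1.0 / se_2**2, 0.0)
        wsum = w1 + w2
        fs = (np.where(has1, fs_1 * w1, 0.0) + np.where(has2, fs_2 * w2, 0.0)) / wsum
        se = np.sqrt(1.0 / wsum)
    # exact passthrough when only one estimate is present
    fs = np.where(has1 & ~has2, fs_1, np.where(has2 & ~has1, fs_2, fs))
    se = np.where(has1 & ~has2, se_1, np.where(has2 & ~has1, se_2, se))
    fs = np.where(wsum > 0, fs, np.nan)
    se = np.where(wsum > 0, se, np.nan)
    return fs, se


def combine_maps(map_ery: pd.DataFrame, map_ubi: pd.DataFrame,
                 rescale: bool = True, scale_only: bool = False,
                 quality_only: bool = True) -> pd.DataFrame:
    """Build the combined cross-isoform map (variants in shared coordinates).

    The erythroid map is first rescaled onto the ubiquitous scale (see
    :func:`rescale_isoform`), then scores are merged by inverse-variance
    weighting.  Variants present in only one isoform keep that isoform's
    score and error.  The delta score is erythroid minus ubiquitous after
    rescaling.
    """
    if rescale:
        map_ery, _ = rescale_isoform(map_ery, map_ubi, scale_only, quality_only)
    cols = ["variant", "score", "se"]
    extra = [c for c in ("position", "var_class", "passes_quality")
             if c in map_ery.columns and c in map_ubi.columns]
    e = map_ery[cols + extra].rename(
        columns={"score": "score_ery", "se": "se_ery",
                 "passes_quality": "pass_ery"})
    u = map_ubi[cols + extra].rename(
        columns={"score": "score_ubi", "se": "se_ubi",
                 "passes_quality": "pass_ubi"})
    merged = e.merge(u, on="variant", how="outer", suffixes=("_ery", "_ubi"))
    for c in ("position", "var_class"):
        if f"{c}_ery" in merged.columns:
            merged[c] = merged[f"{c}_ery"].combine_first(merged[f"{c}_ubi"])
            merged = merged.drop(columns=[f"{c}_ery", f"{c}_ubi"])
    if quality_only and "pass_ery" in merged.columns:
        # only quality-passing single-map scores contribute
        for side in ("ery", "ubi"):
            bad = ~merged[f"pass_{side}"].astype("boolean").fillna(False).astype(bool)
            merged.loc[bad, [f"score_{side}", f"se_{side}"]] = np.nan
    fs, se = combine_scores(merged["score_ery"], merged["se_ery"],
                            merged["score_ubi"], merged["se_ubi"])
    merged["score"] = fs
    merged["se"] = se
    merged["delta"] = merged["score_ery"] - merged["score_ubi"]
    return merged.dropna(subset=["score"]).reset_index(drop=True)


def compare_maps(map_a: pd.DataFrame, map_b: pd.DataFrame,
                 quality_only: bool = True, segment_size: int = 50) -> dict:
    """Correlation report between two maps over shared variants.

    Returns Pearson r with p-value and n, plus per-segment summaries of the
    score difference (mean delta and its SD per block of ``segment_size``
    residue positions).  No segment-level difference is called significant
    here; the summaries are descriptive.
    """
    shared = _shared(map_a, map_b, quality_only)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared variants to compare maps")
    x = shared["score_a"].to_numpy(float)
    y = shared["score_b"].to_numpy(float)
    r, p = stats.pearsonr(x, y)
    report = {"pearson_r": float(r), "p_value": float(p), "n_shared": int(len(shared))}
    pos_col = next((c for c in ("position_a", "position") if c in shared.columns), None)
    if pos_col is not None:
        delta = pd.DataFrame({
            "segment": (shared[pos_col].to_numpy(int) - 1) // segment_size,
            "delta": x - y})
        seg = delta.groupby("segment")["delta"].agg(["mean", "std", "count"])
        report["segments"] = [
            {"segment_start": int(s * segment_size + 1),
             "mean_delta": float(row["mean"]),
             "sd_delta": float(row["std"]) if np.isfinite(row["std"]) else None,
             "n": int(row["count"])}
            for s, row in seg.iterrows()]
    return report
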