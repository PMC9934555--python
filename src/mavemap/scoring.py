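"""Count tables to functional impact scores with regularized errors.

The scoring chain per region, replicate and isoform:

1. depth-normalize counts to frequencies;
2. drop variants whose pre-selection frequency is indistinguishable from the
   wild-type-template control (below ``wt_mean + 3*wt_sd``);
3. subtract the control frequency from both conditions (post-selection
   values that fall to or below zero are floored to one pseudo-read so that
   fully depleted variants remain scoreable near 0);
4. enrichment ratio  phi = adjusted_select / adjusted_nonselect;
5. functional impact score
   FS = ln(phi/phi_stop) / ln(phi_syn/phi_stop),
   where phi_stop is the median enrichment of nonsense variants (excluding
   the last ``terminal_nonsense_window`` residues, where truncation may be
   tolerated) and phi_syn the median of synonymous variants, per region --
   so FS = 0 at the null anchor and 1 at the wild-type anchor;
6. replicate scores are averaged and re-anchored per region so the anchor
   medians are exact on the reported scale;
7. the standard error combines between-replicate spread with an
   empirical-Bayes prior predicted from the trend of replicate spread
   versus pre-selection frequency.

Quality filters: variants with se > 0.3 or pre-selection frequency below
0.005% are flagged as failing; a separate well-measured flag marks
variants at or above 10 reads per million.  All threshold comparisons are
inclusive on the retained side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .variants import parse_variant

__all__ = [
    "ScoringConfig", "ScoringError", "filter_wt_background",
    "adjust_frequencies", "enrichment_ratio", "region_anchors",
    "functional_score", "regularize_errors", "quality_filter",
    "well_measured_flag", "score_map",
]


class ScoringError(RuntimeError):
    """Raised when a region cannot be scored (missing controls/anchors)."""


@dataclass
class ScoringConfig:
    """Thresholds of the scoring chain; defaults are the assay's values."""

    wt_sd_multiplier: float = 3.0
    se_cutoff: float = 0.3
    min_nonselect_freq: float = 5e-5   # 0.005%
    cpm_cutoff: float = 10.0
    terminal_nonsense_window: int = 14
    min_anchor_variants: int = 3
    pseudo_reads: float = 1.0
    prior_weight_nu: float = 2.0
    smoothing_window: int = 51
    se_floor: float = 1e-6


def filter_wt_background(freq, wt_mean, wt_sd, multiplier: float = 3.0):
    """True where a frequency is distinguishable from the WT-control noise
    floor: freq >= wt_mean + multiplier * wt_sd (inclusive)."""
    freq = np.asarray(freq, dtype=float)
    return freq >= np.asarray(wt_mean, dtype=float) + multiplier * np.asarray(
        wt_sd, dtype=float)


def adjust_frequencies(raw_freq, wt_control_freq):
    """Subtract the WT-control (sequencing-error) frequency."""
    return np.asarray(raw_freq, dtype=float) - np.asarray(
        wt_control_freq, dtype=float)


def enrichment_ratio(adjusted_nonselect, adjusted_select):
    """phi = adjusted post-selection over adjusted pre-selection frequency.

    Non-positive pre-selection values yield NaN (the variant is excluded
    upstream with a low-frequency flag).
    """
    non = np.asarray(adjusted_nonselect, dtype=float)
    sel = np.asarray(adjusted_select, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(non > 0, sel / non, np.nan)
    return phi


def region_anchors(phi, var_class, position, protein_length: int,
                   terminal_window: int = 14, min_anchor_variants: int = 3,
                   ) -> tuple[float, float]:
    """Median nonsense and synonymous enrichment ratios for one region.

    Nonsense variants within ``terminal_window`` residues of the C-terminus
    are excluded from the null anchor.  Returns (phi_stop, phi_syn).
    """
    phi = np.asarray(phi, dtype=float)
    var_class = np.asarray(var_class)
    position = np.asarray(position)
    ok = np.isfinite(phi)
    stop_sel = ok & (var_class == "nonsense") & (
        position <= protein_length - terminal_window)
    syn_sel = ok & (var_class == "synonymous")
    if stop_sel.sum() < min_anchor_variants or syn_sel.sum() < min_anchor_variants:
        raise ScoringError(
            f"too few anchor variants (nonsense {int(stop_sel.sum())}, "
            f"synonymous {int(syn_sel.sum())}; need {min_anchor_variants})")
    phi_stop = float(np.median(phi[stop_sel]))
    phi_syn = float(np.median(phi[syn_sel]))
    if not (phi_stop > 0 and phi_syn > 0) or phi_syn == phi_stop:
        raise ScoringError(
            f"degenerate anchors phi_stop={phi_stop}, phi_syn={phi_syn}")
    return phi_stop, phi_syn


def functional_score(phi, phi_stop: float, phi_syn: float):
    """FS = ln(phi/phi_stop)/ln(phi_syn/phi_stop); 0 at the nonsense anchor,
    1 at the synonymous anchor."""
    phi = np.asarray(phi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = np.where(phi > 0,
                      np.log(phi / phi_stop) / np.log(phi_syn / phi_stop),
                      np.nan)
    return fs


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def regularize_errors(fs_by_replicate: np.ndarray, nonselect_freq: np.ndarray,
                      nu: float = 2.0, smoothing_window: int = 51,
                      se_floor: float = 1e-6,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes standard error of the replicate-mean score.

    ``fs_by_replicate`` is (n_variants, n_replicates) with NaN for missing
    replicates.  The prior SD for each variant is predicted from a
    running-median trend of observed replicate SD versus log pre-selection
    frequency, made monotone non-increasing in frequency (low-coverage
    variants are noisier).  Posterior variance blends prior and observed:

        var = (nu * prior^2 + (n-1) * obs^2) / (nu + n - 1)

    and the reported se is sqrt(var/n).  Variants observed in a single
    replicate get the prior SD directly.  Returns (se, n_replicates_used).
    """
    fs = np.asarray(fs_by_replicate, dtype=float)
    freq = np.asarray(nonselect_freq, dtype=float)
    n = np.sum(np.isfinite(fs), axis=1)
    obs_sd = pd.DataFrame(fs).std(axis=1, ddof=1).to_numpy()
    obs_sd = np.where(n >= 2, obs_sd, np.nan)

    # prior trend fitted on variants with an observed SD
    have = (n >= 2) & np.isfinite(freq) & (freq > 0)
    prior = np.full(len(fs), np.nan)
    if have.sum() >= 2:
        logf = np.log10(freq[have])
        order = np.argsort(logf)
        window = min(smoothing_window, have.sum())
        if window % 2 == 0:
            window = max(1, window - 1)
        med = _running_median(obs_sd[have][order], window)
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        iso.fit(logf[order], med)
        safe_f = np.where(freq > 0, freq, np.nanmin(freq[freq > 0])
                          if (freq > 0).any() else 1.0)
        prior = iso.predict(np.log10(safe_f))
    elif have.any():
        prior[:] = obs_sd[have][0]
    prior = np.where(np.isfinite(prior), prior, np.nanmax([se_floor]))
    prior = np.maximum(prior, se_floor)

    post_var = np.where(
        n >= 2,
        (nu * prior**2 + (n - 1) * np.where(np.isfinite(obs_sd), obs_sd, 0.0)**2)
        / (nu + n - 1),
        prior**2)
    se = np.where(n >= 2, np.sqrt(post_var / np.maximum(n, 1)),
                  np.where(n == 1, prior, np.nan))
    return np.maximum(se, se_floor), n


def quality_filter(se, nonselect_freq, se_cutoff: float = 0.3,
                   min_nonselect_freq: float = 5e-5):
    """True where a variant passes the high-quality filters
    (se <= 0.3 and pre-selection frequency >= 0.005%, inclusive)."""
    se = np.asarray(se, dtype=float)
    freq = np.asarray(nonselect_freq, dtype=float)
    return (se <= se_cutoff) & (freq >= min_nonselect_freq)


def well_measured_flag(count, depth, cpm_cutoff: float = 10.0):
    """True where pre-selection coverage is at or above ``cpm_cutoff`` reads
    per million."""
    count = np.asarray(count, dtype=float)
    depth = np.asarray(depth, dtype=float)
    return count / depth * 1e6 >= cpm_cutoff


def _variant_info(variants: pd.Series) -> pd.DataFrame:
    parsed = [parse_variant(v) for v in variants]
    return pd.DataFrame({
        "variant": variants.to_numpy(),
        "position": [p.position for p in parsed],
        "var_class": [p.var_class for p in parsed],
    })


def _wt_stats(wt_controls: pd.DataFrame) -> pd.DataFrame:
    """Per (variant, condition) mean and SD of the WT-control frequency
    across control replicates."""
    wt = wt_controls.copy()
    wt["freq"] = wt["count"] / wt["depth"]
    g = wt.groupby(["variant", "condition"])["freq"]
    stats = g.agg(wt_mean="mean", wt_sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
    return stats.reset_index()


def score_map(counts: pd.DataFrame, wt_controls: pd.DataFrame,
              protein_length: int,
              region_of: dict[str, str] | None = None,
              isoform: str | None = None,
              config: ScoringConfig | None = None,
              ) -> tuple[pd.DataFrame, dict]:
    """Run the full scoring chain on one isoform's count tables.

    Parameters
    ----------
    counts, wt_controls : DataFrame
        Count-table schema (variant, tile, condition, replicate, count,
        depth); ``wt_controls`` holds the wild-type-template sequencing of
        the same tiles.
    protein_length : int
        Length of the ORF in the coordinate frame of the variants.
    region_of : dict, optional
        Tile -> region map; defaults to a single region.
    config : ScoringConfig, optional

    Returns
    -------
    (scores, log) : per-variant DataFrame and a filter-bookkeeping dict.
    """
    cfg = config or ScoringConfig()
    for cond in ("nonselect", "select"):
        if not (wt_controls["condition"] == cond).any():
            raise ScoringError(f"missing WT control for condition {cond!r}")

    df = counts.copy()
    df["freq"] = df["count"] / df["depth"]
    df = df.merge(_wt_stats(wt_controls), on=["variant", "condition"], how="left")
    df[["wt_mean", "wt_sd"]] = df[["wt_mean", "wt_sd"]].fillna(0.0)
    if region_of is None:
        df["region"] = "all"
    else:
        df["region"] = df["tile"].map(region_of)

    info = _variant_info(df["variant"].drop_duplicates().reset_index(drop=True))
    df = df.merge(info, on="variant")

    # wide per (variant, replicate): nonselect / select side by side
    keys = ["variant", "position", "var_class", "region", "tile", "replicate"]
    wide = df.pivot_table(index=keys, columns="condition",
                          values=["freq", "wt_mean", "wt_sd", "count", "depth"],
                          aggfunc="first")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()

    ns_pass = filter_wt_background(wide["freq_nonselect"], wide["wt_mean_nonselect"],
                                   wide["wt_sd_nonselect"], cfg.wt_sd_multiplier)
    sel_pass = filter_wt_background(wide["freq_select"], wide["wt_mean_select"],
                                    wide["wt_sd_select"], cfg.wt_sd_multiplier)

    adj_non = adjust_frequencies(wide["freq_nonselect"], wide["wt_mean_nonselect"])
    adj_sel = adjust_frequencies(wide["freq_select"], wide["wt_mean_select"])
    floor = cfg.pseudo_reads / wide["depth_select"].to_numpy()
    floored = (~sel_pass) | (adj_sel <= 0)
    adj_sel = np.where(floored, floor, adj_sel)

    usable = ns_pass & (adj_non > 0)
    phi = np.where(usable, enrichment_ratio(adj_non, adj_sel), np.nan)
    wide["phi"] = phi
    wide["select_floored"] = floored & usable
    wide["rep_usable"] = usable

    # per-replicate functional scores with per (region, replicate) anchors
    wide["fs"] = np.nan
    for (region, rep), idx in wide.groupby(["region", "replicate"]).groups.items():
        sub = wide.loc[idx]
        phi_stop, phi_syn = region_anchors(
            sub["phi"], sub["var_class"], sub["position"], protein_length,
            cfg.terminal_nonsense_window, cfg.min_anchor_variants)
        wide.loc[idx, "fs"] = functional_score(sub["phi"], phi_stop, phi_syn)

    # aggregate replicates per variant
    per_var = wide.groupby("variant", sort=True).agg(
        position=("position", "first"),
        var_class=("var_class", "first"),
        region=("region", "first"),
        tile=("tile", "first"),
        nonselect_freq=("freq_nonselect", "mean"),
        nonselect_count=("count_nonselect", "sum"),
        nonselect_depth=("depth_nonselect", "sum"),
        phi=("phi", "mean"),
        select_floored=("select_floored", "any"),
        any_usable=("rep_usable", "any"),
    )
    fs_wide = wide.pivot_table(index="variant", columns="replicate",
                               values="fs", aggfunc="first")
    fs_mat = fs_wide.reindex(per_var.index).to_numpy()

    # re-anchor averaged scores per region so anchor medians are exact
    per_var["fs_raw"] = pd.DataFrame(
        fs_mat, index=per_var.index).mean(axis=1).to_numpy()
    for region, idx in per_var.groupby("region").groups.items():
        sub = per_var.loc[idx]
        ok = np.isfinite(sub["fs_raw"])
        stop_sel = ok & (sub["var_class"] == "nonsense") & (
            sub["position"] <= protein_length - cfg.terminal_nonsense_window)
        syn_sel = ok & (sub["var_class"] == "synonymous")
        if stop_sel.sum() < cfg.min_anchor_variants or \
                syn_sel.sum() < cfg.min_anchor_variants:
            raise ScoringError(f"too few anchors to re-scale region {region!r}")
        m_stop = float(sub.loc[stop_sel, "fs_raw"].median())
        m_syn = float(sub.loc[syn_sel, "fs_raw"].median())
        if m_syn == m_stop:
            raise ScoringError(f"degenerate anchor medians in region {region!r}")
        a = 1.0 / (m_syn - m_stop)
        sel = per_var.index.get_indexer(idx)
        fs_mat[sel] = (fs_mat[sel] - m_stop) * a

    per_var["score"] = pd.DataFrame(
        fs_mat, index=per_var.index).mean(axis=1).to_numpy()
    se, n_used = regularize_errors(
        fs_mat, per_var["nonselect_freq"].to_numpy(),
        cfg.prior_weight_nu, cfg.smoothing_window, cfg.se_floor)
    per_var["se"] = np.where(np.isfinite(per_var["score"]), se, np.nan)
    per_var["n_replicates"] = n_used

    per_var["flag_wt_indistinguishable"] = ~per_var["any_usable"]
    per_var["flag_low_freq"] = per_var["any_usable"] & ~np.isfinite(per_var["score"])
    per_var["flag_select_floored"] = per_var["select_floored"]
    per_var["flag_single_replicate"] = n_used == 1
    scored = np.isfinite(per_var["score"].to_numpy())
    per_var["flag_high_se"] = scored & (per_var["se"] > cfg.se_cutoff)
    per_var["flag_below_min_freq"] = scored & (
        per_var["nonselect_freq"] < cfg.min_nonselect_freq)
    per_var["passes_quality"] = scored & quality_filter(
        per_var["se"], per_var["nonselect_freq"],
        cfg.se_cutoff, cfg.min_nonselect_freq)
    per_var["well_measured"] = well_measured_flag(
        per_var["nonselect_count"], per_var["nonselect_depth"], cfg.cpm_cutoff)
    if isoform is not None:
        per_var["isoform"] = isoform

    flag_cols = [c for c in per_var.columns if c.startswith("flag_")]
    per_var["filter_flags"] = [
        ";".join(c[len("flag_"):] for c in flag_cols if row[c]) or "pass"
        for _, row in per_var[flag_cols].iterrows()]
    out = per_var.drop(columns=["select_floored", "any_usable"]).reset_index()
    log = {
        "n_variants_in": int(len(out)),
        "n_wt_indistinguishable": int(out["flag_wt_indistinguishable"].sum()),
        "n_low_freq": int(out["flag_low_freq"].sum()),
        "n_scored": int(np.isfinite(out["score"]).sum()),
        "n_select_floored": int(out["flag_select_floored"].sum()),
        "n_high_se": int(out["flag_high_se"].sum()),
        "n_below_min_freq": int(out["flag_below_min_freq"].sum()),
        "n_pass_quality": int(out["passes_quality"].sum()),
        "n_well_measured": int(out["well_measured"].sum()),
    }
    return out, log
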