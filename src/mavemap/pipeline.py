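"""End-to-end orchestration: simulate -> score -> assemble -> calibrate.

``run_pipeline`` drives the whole chain on synthetic data (or pre-existing
count tables), writing score maps, the combined map, an evaluation report,
an LLRp table and the calibrated evidence thresholds, together with a
JSON-lines run log recording every filter decision count.  All stages are
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, calibration, io as mio, scoring, simulate
from .variants import ERYTHROID, UBIQUITOUS


@dataclass
class RunConfig:
    """Pipeline settings; thresholds default to the assay's published values."""

    out_dir: str | Path = "mavemap_out"
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    scoring: scoring.ScoringConfig = field(default_factory=scoring.ScoringConfig)
    prior: float = 0.10
    masked_intervals: tuple[tuple[int, int], ...] = ((160, 215),)
    n_reference_positive: int = 53
    n_reference_negative: int = 13


@dataclass
class PipelineResult:
    maps: dict
    combined: pd.DataFrame
    comparison: dict
    evaluation: dict
    thresholds: calibration.EvidenceThresholds
    llr_table: pd.DataFrame
    log: list


def synthetic_reference_set(ground_truth: pd.DataFrame, n_positive: int,
                            n_negative: int, seed: int) -> pd.DataFrame:
    """Sample a labeled reference set from the generator's ground truth:
    clearly deleterious missense variants as positives, clearly neutral ones
    as (proxy-)benign negatives."""
    rng = np.random.default_rng(seed)
    mis = ground_truth[ground_truth["var_class"] == "missense"]
    pos_pool = mis[mis["w"] < 0.3]["variant"].to_numpy()
    neg_pool = mis[(mis["w"] >= 0.8) & (mis["w"] <= 1.2)]["variant"].to_numpy()
    pos = rng.choice(pos_pool, size=min(n_positive, len(pos_pool)), replace=False)
    neg = rng.choice(neg_pool, size=min(n_negative, len(neg_pool)), replace=False)
    return pd.DataFrame({
        "variant": np.concatenate([pos, neg]),
        "label": ["positive"] * len(pos) + ["negative"] * len(neg),
        "provenance": ["expert_center"] * len(pos) + ["proxy_benign"] * len(neg),
    })


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    cfg = config or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def _log(stage: str, **info):
        log.append({"stage": stage, **info})

    sim_cfg = cfg.simulation or simulate.SimulationConfig(rng_seed=cfg.seed)
    exp = simulate.simulate_experiment(sim_cfg)
    simulate.write_experiment(exp, out / "synthetic")
    _log("simulate", n_variants=len(exp.ground_truth),
         n_count_rows=len(exp.counts), seed=sim_cfg.rng_seed)

    region_of = dict(zip(exp.variant_table["tile"], exp.variant_table["region"]))
    maps: dict[str, pd.DataFrame] = {}
    for isoform in sim_cfg.isoforms:
        counts = exp.counts[exp.counts["isoform"] == isoform].drop(columns="isoform")
        wt = exp.wt_controls[exp.wt_controls["isoform"] == isoform].drop(
            columns="isoform")
        scores, slog = scoring.score_map(
            counts, wt, sim_cfg.protein_length, region_of,
            isoform=isoform, config=cfg.scoring)
        maps[isoform] = scores
        mio.write_score_map(scores, out / f"scores_{isoform}.tsv")
        _log("score", isoform=isoform, **slog)

    combined = assembly.combine_maps(maps[ERYTHROID], maps[UBIQUITOUS])
    comparison = assembly.compare_maps(maps[ERYTHROID], maps[UBIQUITOUS])
    mio.write_score_map(combined, out / "scores_combined.tsv")
    _log("combine", n_combined=len(combined),
         pearson_r=comparison["pearson_r"], n_shared=comparison["n_shared"])

    reference = synthetic_reference_set(
        exp.ground_truth, cfg.n_reference_positive, cfg.n_reference_negative,
        cfg.seed)
    mio.write_reference_set(reference, out / "reference_set.tsv")

    evaluation = {}
    for name, m in {"erythroid": maps[ERYTHROID], "ubiquitous": maps[UBIQUITOUS],
                    "combined": combined}.items():
        mm = m if "passes_quality" in m.columns else m.assign(passes_quality=True)
        res = calibration.evaluate_map(mm, reference)
        entry = {k: v for k, v in res.items() if k != "curve"}
        if cfg.masked_intervals:
            masked = calibration.evaluate_map(
                mm, reference, masked_positions=list(cfg.masked_intervals))
            entry["masked"] = {k: v for k, v in masked.items() if k != "curve"}
        evaluation[name] = entry
        _log("evaluate", map=name, **{k: v for k, v in entry.items()
                                      if not isinstance(v, dict)})

    scored_ref = reference.merge(combined[["variant", "score"]], on="variant")
    dens = calibration.fit_density_pair(
        scored_ref.loc[scored_ref["label"] == "positive", "score"],
        scored_ref.loc[scored_ref["label"] == "negative", "score"])
    thresholds = calibration.calibrate_acmg_thresholds(prior=cfg.prior)
    llr_table = combined[["variant", "score", "se"]].dropna(subset=["score"]).copy()
    llr_table["llrp"] = calibration.llrp(llr_table["score"], dens)
    llr_table["evidence"] = calibration.assign_evidence(
        llr_table["llrp"].to_numpy(), thresholds)
    llr_table.to_csv(out / "llrp.csv", index=False)
    mio.save_config(thresholds.as_dict(), out / "evidence_thresholds.yaml")
    _log("calibrate", **{k: (float(v) if isinstance(v, (int, float)) else v)
                         for k, v in thresholds.as_dict().items()})

    with open(out / "run_log.jsonl", "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec) + "\n")
    with open(out / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2)

    return PipelineResult(maps=maps, combined=combined, comparison=comparison,
                          evaluation=evaluation, thresholds=thresholds,
                          llr_table=llr_table, log=log)
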