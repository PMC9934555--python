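"""Synthetic TileSeq-style selection experiment with known ground truth.

Emulates a codon-randomized complementation screen: a mutagenized ORF library
(log-normal clone abundances, a configurable mean number of amino-acid
changes per clone) is grown competitively, and pre-/post-selection pools are
tile-sequenced at fixed depth together with a wild-type-template control that
shares the sequencing-error process.  True per-variant fitness is bimodal
(null vs. neutral) with a small hyper-complementing fraction scoring above
wild type, so every downstream scoring stage has a parameter-recovery
surface.

Two isoforms are generated, differing by a 17-residue N-terminal truncation;
both are emitted in the shared (ubiquitous) coordinate frame.  Selection
stringency differs slightly between isoforms, which is what the cross-isoform
rescaling step downstream has to undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .variants import (AMINO_ACIDS, ERYTHROID, N_TERMINAL_OFFSET, STOP,
                       SYNONYMOUS, UBIQUITOUS)

#: Nonsense changes this close to the C-terminus may retain function and are
#: excluded from the null anchor downstream; the generator mirrors that.
TERMINAL_NONSENSE_WINDOW = 14


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic selection experiment.

    Defaults follow the assayed enzyme: a 361-residue ubiquitous isoform,
    an average of 1.7 amino-acid changes per clone, two mutagenesis regions
    of five tiles each, two replicates, and 2.5% hyper-complementing
    missense variants.  ``reads_per_tile`` defaults to a scaled-down
    200,000 (the real assay sequenced ~2,000,000 reads per tile).
    """

    protein_length: int = 361
    mean_aa_changes_per_clone: float = 1.7
    n_regions: int = 2
    tiles_per_region: int = 5
    n_replicates: int = 2
    reads_per_tile: int = 200_000
    generations: float = 3.0
    erythroid_generations: float = 2.4
    growth_rate: float = 1.0
    sequencing_error_rate: float = 2e-6
    frac_deleterious: float = 0.35
    frac_hyper: float = 0.025
    sigma_log: float = 1.0
    rng_seed: int = 0
    isoforms: tuple[str, ...] = (UBIQUITOUS, ERYTHROID)

    def __post_init__(self) -> None:
        for name in ("frac_deleterious", "frac_hyper"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.frac_deleterious + self.frac_hyper > 1.0:
            raise ValueError("fitness-class fractions exceed 1")
        if self.mean_aa_changes_per_clone < 0:
            raise ValueError("mean_aa_changes_per_clone must be >= 0")
        if self.sequencing_error_rate < 0:
            raise ValueError("sequencing_error_rate must be >= 0")
        for name in ("protein_length", "n_regions", "tiles_per_region",
                     "n_replicates", "reads_per_tile"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticExperiment:
    """Count tables plus the ground truth that generated them."""

    config: SimulationConfig
    counts: pd.DataFrame        # variant, tile, condition, replicate, count, depth, isoform
    wt_controls: pd.DataFrame   # same schema; wild-type-template sequencing
    ground_truth: pd.DataFrame  # variant, position, var_class, w
    variant_table: pd.DataFrame


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    # one documented stream per key tuple so replicates/conditions/regions
    # are independent yet byte-reproducible
    return np.random.default_rng([config.rng_seed, *key])


def _wt_sequence(config: SimulationConfig) -> str:
    rng = _rng(config, 1)
    return "".join(rng.choice(list(AMINO_ACIDS), size=config.protein_length))


def enumerate_variants(config: SimulationConfig) -> pd.DataFrame:
    """All single amino-acid changes (19 missense + nonsense + synonymous
    per position) in ubiquitous coordinates, with tile/region assignment."""
    seq = _wt_sequence(config)
    n_tiles = config.n_regions * config.tiles_per_region
    positions = np.arange(1, config.protein_length + 1)
    tile_of = {}
    for t, chunk in enumerate(np.array_split(positions, n_tiles)):
        for p in chunk:
            tile_of[int(p)] = t
    rows = []
    for pos in positions:
        ref = seq[pos - 1]
        t = tile_of[int(pos)]
        region = t // config.tiles_per_region + 1
        alts = [a for a in AMINO_ACIDS if a != ref] + [STOP, SYNONYMOUS]
        for alt in alts:
            rows.append((f"p.{ref}{pos}{alt}", int(pos), ref, alt,
                         f"tile{t + 1}", f"region{region}"))
    df = pd.DataFrame(rows, columns=["variant", "position", "ref_aa",
                                     "alt_aa", "tile", "region"])
    df["var_class"] = np.where(
        df["alt_aa"] == STOP, "nonsense",
        np.where(df["alt_aa"] == SYNONYMOUS, "synonymous", "missense"))
    return df


def draw_true_fitness(config: SimulationConfig,
                      variant_table: pd.DataFrame) -> pd.DataFrame:
    """Assign a true relative fitness w to every variant.

    Missense fitness is a three-component mixture: deleterious (near 0),
    neutral (near 1), hyper-complementing (> 1, probability ``frac_hyper``).
    Synonymous variants are exactly 1; nonsense variants are exactly 0 except
    within the terminal window, where truncation may be tolerated.
    """
    rng = _rng(config, 2)
    n = len(variant_table)
    w = np.ones(n)
    cls = variant_table["var_class"].to_numpy()
    pos = variant_table["position"].to_numpy()

    mis = cls == "missense"
    u = rng.random(n)
    # neutral component sits at or just below 1 so that w > 1 identifies the
    # hyper-complementing class unambiguously
    neutral_draw = 1.0 - np.clip(np.abs(rng.normal(0.0, 0.04, n)), 0.0, 0.25)
    delet_draw = np.clip(np.abs(rng.normal(0.0, 0.03, n)), 0.0, 0.2)
    hyper_draw = 1.0 + np.abs(rng.normal(0.25, 0.10, n))
    w[mis] = neutral_draw[mis]
    is_delet = mis & (u < config.frac_deleterious)
    w[is_delet] = delet_draw[is_delet]
    is_hyper = mis & (u >= config.frac_deleterious) & (
        u < config.frac_deleterious + config.frac_hyper)
    w[is_hyper] = hyper_draw[is_hyper]

    non = cls == "nonsense"
    w[non] = 0.0
    terminal = non & (pos > config.protein_length - TERMINAL_NONSENSE_WINDOW)
    w[terminal] = neutral_draw[terminal]

    w[cls == "synonymous"] = 1.0

    out = variant_table[["variant", "position", "var_class"]].copy()
    out["w"] = w
    return out


def simulate_library_frequencies(config: SimulationConfig,
                                 ground_truth: pd.DataFrame,
                                 isoform_index: int = 0) -> np.ndarray:
    """Marginal pre-selection frequency of each variant among library clones.

    Clone abundances are log-normal; the vector is scaled so the expected
    number of amino-acid changes per clone matches the configured mean.  The
    remainder (1 - sum within any tile) is wild-type template.
    """
    rng = _rng(config, 3, isoform_index)
    n = len(ground_truth)
    if config.mean_aa_changes_per_clone == 0:
        return np.zeros(n)
    abundance = rng.lognormal(mean=0.0, sigma=config.sigma_log, size=n)
    # per-position share of the per-clone mutation budget
    n_positions = ground_truth["position"].nunique()
    lam = config.mean_aa_changes_per_clone * n_positions / config.protein_length
    return lam * abundance / abundance.sum()


def simulate_selection(pre_freqs: np.ndarray, ground_truth: pd.DataFrame,
                       generations: float,
                       growth_rate: float = 1.0) -> np.ndarray:
    """Deterministic competitive growth.

    Each variant grows as g(w)^generations with g(w) = exp(r*(w-1)), so
    wild-type-like variants (w=1) track the unmutated template exactly and
    enrichment is log-linear in w.  The pool is renormalized against the
    wild-type remainder.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    w = ground_truth["w"].to_numpy()
    g = np.exp(growth_rate * generations * (w - 1.0))
    wt_frac = 1.0 - pre_freqs.sum()
    z = (pre_freqs * g).sum() + wt_frac  # WT grows with g(1) = 1
    return pre_freqs * g / z


def _error_rates(config: SimulationConfig, n: int,
                 isoform_index: int) -> np.ndarray:
    """Per-variant spurious-call rate, fixed across conditions/replicates
    (sequencing error is a property of local sequence context)."""
    rng = _rng(config, 4, isoform_index)
    return config.sequencing_error_rate * rng.lognormal(0.0, 0.5, n)


def simulate_sequencing(freqs: np.ndarray, config: SimulationConfig,
                        variant_table: pd.DataFrame, condition: str,
                        replicate: int, isoform_index: int = 0,
                        error_rates: np.ndarray | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-tile read counts for the mutant pool and the WT control.

    Within each tile, reads are multinomial at ``reads_per_tile`` depth over
    the tile's variants plus the wild-type remainder.  A spurious-call
    component with per-variant rate epsilon enters the pool and the
    wild-type-template control identically, so the expected control
    frequency equals the error floor of the pool.
    """
    if condition not in mio.CONDITIONS:
        raise ValueError(f"condition must be one of {mio.CONDITIONS}")
    cond_idx = mio.CONDITIONS.index(condition)
    if error_rates is None:
        error_rates = _error_rates(config, len(freqs), isoform_index)

    pool_rows, ctrl_rows = [], []
    depth = config.reads_per_tile
    for t, (tile, idx) in enumerate(variant_table.groupby("tile").groups.items()):
        loc = variant_table.index.get_indexer(idx)
        rng = _rng(config, 5, isoform_index, t, replicate, cond_idx)
        f = freqs[loc] + error_rates[loc]
        p = np.append(f, max(0.0, 1.0 - f.sum()))
        counts = rng.multinomial(depth, p / p.sum())[:-1]
        rng_c = _rng(config, 6, isoform_index, t, replicate, cond_idx)
        fe = error_rates[loc]
        pe = np.append(fe, max(0.0, 1.0 - fe.sum()))
        ctrl = rng_c.multinomial(depth, pe / pe.sum())[:-1]
        for v, c, cc in zip(variant_table["variant"].to_numpy()[loc], counts, ctrl):
            pool_rows.append((v, tile, condition, replicate, int(c), depth))
            ctrl_rows.append((v, tile, condition, replicate, int(cc), depth))
    cols = mio.COUNT_COLUMNS
    return pd.DataFrame(pool_rows, columns=cols), pd.DataFrame(ctrl_rows, columns=cols)


def simulate_experiment(config: SimulationConfig | None = None) -> SyntheticExperiment:
    """Run the full generator for all configured isoforms.

    The same ground-truth fitness (drawn once in the shared coordinate
    frame) underlies both isoform libraries; library composition, selection
    stringency and sequencing noise are isoform-specific.
    """
    config = config or SimulationConfig()
    table_full = enumerate_variants(config)
    truth_full = draw_true_fitness(config, table_full)

    counts_parts, ctrl_parts = [], []
    for iso_idx, isoform in enumerate(config.isoforms):
        if isoform == ERYTHROID:
            keep = table_full["position"] > N_TERMINAL_OFFSET
        else:
            keep = pd.Series(True, index=table_full.index)
        table = table_full[keep].reset_index(drop=True)
        truth = truth_full[keep].reset_index(drop=True)
        gens = (config.erythroid_generations if isoform == ERYTHROID
                else config.generations)
        pre = simulate_library_frequencies(config, truth, iso_idx)
        post = simulate_selection(pre, truth, gens, config.growth_rate)
        eps = _error_rates(config, len(pre), iso_idx)
        for cond, f in (("nonselect", pre), ("select", post)):
            for rep in range(1, config.n_replicates + 1):
                pool, ctrl = simulate_sequencing(
                    f, config, table, cond, rep, iso_idx, eps)
                pool["isoform"] = isoform
                ctrl["isoform"] = isoform
                counts_parts.append(pool)
                ctrl_parts.append(ctrl)

    return SyntheticExperiment(
        config=config,
        counts=pd.concat(counts_parts, ignore_index=True),
        wt_controls=pd.concat(ctrl_parts, ignore_index=True),
        ground_truth=truth_full,
        variant_table=table_full,
    )


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> None:
    """Emit count tables, WT controls, ground truth (TSV) and config (YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for isoform in exp.config.isoforms:
        sel = exp.counts["isoform"] == isoform
        mio.write_count_table(
            exp.counts[sel].drop(columns="isoform"),
            outdir / f"counts_{isoform}.tsv")
        selc = exp.wt_controls["isoform"] == isoform
        mio.write_count_table(
            exp.wt_controls[selc].drop(columns="isoform"),
            outdir / f"wt_counts_{isoform}.tsv")
    exp.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    cfg = asdict(exp.config)
    cfg["isoforms"] = list(cfg["isoforms"])
    mio.save_config(cfg, outdir / "config.yaml")
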