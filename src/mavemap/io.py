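"""Tabular input/output for count tables, score maps and reference sets.

All on-disk formats are plain text: TSV for count tables and score maps
(MaveDB-style CSV also supported on export) and YAML for run configuration.
Variant identifiers are HGVS-p short form throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .variants import parse_variant

COUNT_COLUMNS = ["variant", "tile", "condition", "replicate", "count", "depth"]
COUNT_KEY = ["variant", "tile", "condition", "replicate"]
SCORE_COLUMNS = ["variant", "score", "se", "isoform", "region", "filter_flags"]

CONDITIONS = ("nonselect", "select")


class TableFormatError(ValueError):
    """Raised for schema violations in tabular inputs."""


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{what} is missing columns: {', '.join(missing)}")


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a per-variant read count table.

    Expected TSV columns: variant, tile, condition, replicate, count, depth.
    The key (variant, tile, condition, replicate) must be unique and counts
    cannot exceed depth.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "tile": str})
    _require_columns(df, COUNT_COLUMNS, f"count table {path}")
    dup = df.duplicated(subset=COUNT_KEY, keep=False)
    if dup.any():
        keys = df.loc[dup, COUNT_KEY].drop_duplicates().to_records(index=False)
        raise TableFormatError(
            "duplicate count-table keys: " + "; ".join(map(str, keys[:5]))
        )
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise TableFormatError(f"unknown conditions {sorted(bad_cond)}")
    if (df["count"] > df["depth"]).any():
        offending = df.loc[df["count"] > df["depth"], "variant"].iloc[0]
        raise TableFormatError(f"count exceeds depth for {offending}")
    # validate variant strings eagerly so malformed rows fail at ingest
    for v in df["variant"].unique():
        parse_variant(v)
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, COUNT_COLUMNS, "count table")
    df.to_csv(path, sep="\t", index=False)


def read_score_map(path: str | Path) -> pd.DataFrame:
    """Read a score map written by :func:`write_score_map` (TSV or CSV)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"variant": str})
    _require_columns(df, ["variant", "score"], f"score map {path}")
    return df


def write_score_map(df: pd.DataFrame, path: str | Path) -> None:
    """Write a score map as TSV (or MaveDB-style CSV if the path ends .csv).

    Core columns (variant, score, se, isoform, region, filter_flags) are
    written first; any extra columns are preserved after them.
    """
    _require_columns(df, ["variant", "score"], "score map")
    cols = [c for c in SCORE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    sep = "," if str(path).endswith(".csv") else "\t"
    df.loc[:, cols].to_csv(path, sep=sep, index=False)


def read_reference_set(path: str | Path) -> pd.DataFrame:
    """Read a labeled reference-variant table.

    Columns: variant, label (positive/negative), provenance; optional maf,
    n_homozygotes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant": str})
    _require_columns(df, ["variant", "label", "provenance"], f"reference set {path}")
    bad = set(df["label"]) - {"positive", "negative"}
    if bad:
        raise TableFormatError(f"unknown labels {sorted(bad)}")
    return df


def write_reference_set(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def sniff_coordinate_frame(positions: Iterable[int], protein_length: int,
                           n_terminal_offset: int = 17) -> str:
    """Guess whether erythroid-map positions use local or ubiquitous numbering.

    A map indexed in the shorter (erythroid-local) frame cannot contain
    positions above ``protein_length - n_terminal_offset``; one indexed in the
    shared ubiquitous frame typically does.  Returns ``"local"`` or
    ``"ubiquitous"``.
    """
    mx = max(positions)
    if mx > protein_length:
        raise TableFormatError(
            f"position {mx} exceeds protein length {protein_length}"
        )
    return "local" if mx <= protein_length - n_terminal_offset else "ubiquitous"
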