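"""Aggregate repository match tables with sample metadata and apply the
domain filter rules used for microbe/plant/food evidence.

A match table has one row per retrieved MS/MS spectrum (candidate, spectrum,
file, dataset, score); metadata maps file ids to controlled-vocabulary
attributes (taxon, body site, blank/QC/cell-line flags).  Filtering is
per candidate, not per row:

1. cell-line exclusion — drop candidates observed in human cell lines;
2. minimum evidence — drop candidates retrieved in fewer than 3 files;
3. contamination — drop candidates whose blank/QC fraction exceeds 5%.

Presets: ``microbe`` applies 1+2+3, ``plant`` 2+3, ``food`` 3 only (the food
reference data carries no blanks or QCs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import AcylChain

__all__ = [
    "FilterRules",
    "PRESETS",
    "join_metadata",
    "filter_matches",
    "chain_class",
    "occurrence_matrix",
]


@dataclass(frozen=True)
class FilterRules:
    exclude_cell_lines: bool = True
    min_occurrences: int = 3
    max_blank_fraction: float = 0.05
    apply_min_occurrences: bool = True
    apply_blank_fraction: bool = True


PRESETS: dict[str, FilterRules] = {
    "microbe": FilterRules(),
    "plant": FilterRules(exclude_cell_lines=False),
    "food": FilterRules(exclude_cell_lines=False, apply_min_occurrences=False),
}


def join_metadata(matches: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Left-join sample metadata onto a match table by ``file_id``.

    Row count is preserved; files without metadata keep NaN attributes.
    Duplicate file ids in the metadata are an error (they would fan out the
    join and silently inflate counts).
    """
    if "file_id" not in matches.columns or "file_id" not in meta.columns:
        raise ValueError("both tables need a 'file_id' column")
    if meta["file_id"].duplicated().any():
        dupes = meta.loc[meta["file_id"].duplicated(), "file_id"].tolist()
        raise ValueError(f"duplicate file ids in metadata: {dupes[:5]}")
    return matches.merge(meta, on="file_id", how="left")


def filter_matches(
    annotated: pd.DataFrame,
    rules: FilterRules | str = "microbe",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-candidate filter rules; returns (kept rows, removal log).

    Occurrences are counted per distinct file.  The blank/QC fraction
    denominator is all files in which the candidate occurs.  The removal log
    has one row per removed candidate naming the rule that removed it.
    """
    if isinstance(rules, str):
        rules = PRESETS[rules]
    required = {"candidate", "file_id"}
    if not required <= set(annotated.columns):
        raise ValueError(f"match table needs columns {sorted(required)}")

    def col_flag(name: str) -> pd.Series:
        if name not in annotated.columns:
            raise ValueError(f"rule requires metadata column {name!r}")
        return annotated[name].fillna(False).astype(bool)

    removal: list[tuple[str, str, float]] = []
    removed: set[str] = set()
    for candidate, grp in annotated.groupby("candidate", sort=True):
        candidate = str(candidate)
        if rules.exclude_cell_lines:
            cell = col_flag("is_cell_line").loc[grp.index]
            if cell.any():
                removal.append((candidate, "cell_line", float(cell.sum())))
                removed.add(candidate)
                continue
        n_files = grp["file_id"].nunique()
        if rules.apply_min_occurrences and n_files < rules.min_occurrences:
            removal.append((candidate, "min_occurrences", float(n_files)))
            removed.add(candidate)
            continue
        if rules.apply_blank_fraction:
            blank = col_flag("is_blank_or_qc").loc[grp.index]
            blank_files = grp.loc[blank.values, "file_id"].nunique()
            frac = blank_files / n_files if n_files else 0.0
            if frac > rules.max_blank_fraction:
                removal.append((candidate, "blank_fraction", frac))
                removed.add(candidate)
                continue
    kept = annotated[~annotated["candidate"].isin(removed)].copy()
    log = pd.DataFrame(removal, columns=["candidate", "rule", "value"])
    return kept, log


def chain_class(chain: AcylChain) -> str:
    """Fatty-acyl length class: short (<=C6), medium (C7-C12), long
    (C13-C20), very_long (>=C21)."""
    n = chain.n_carbons
    if n <= 6:
        return "short"
    if n <= 12:
        return "medium"
    if n <= 20:
        return "long"
    return "very_long"


def occurrence_matrix(
    filtered: pd.DataFrame,
    row_key: str,
    col_key: str,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Match counts per (row_key, col_key), optionally log10(count + 1)."""
    for key in (row_key, col_key):
        if key not in filtered.columns:
            raise ValueError(f"missing key column {key!r}")
    counts = (
        filtered.groupby([row_key, col_key], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    if log_scale:
        counts = np.log10(counts + 1)
    return counts
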