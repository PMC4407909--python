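"""qPCR fold-enrichment computation and per-pool summaries.

Relative qPCR compares enriched against unenriched libraries at a panel of
target amplicons.  Replicate crossing-point (Cp) values are averaged per
(library, amplicon, treatment), and fold enrichment is computed as
``efficiency ** abs(mean enriched Cp - mean unenriched Cp)`` with a default
amplification efficiency of 1.78.  Group summaries (e.g. per blocking-DNA
treatment) are arithmetic means of fold values; averaging on the Cp
difference scale is available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("enriched", "unenriched")
DEFAULT_EFFICIENCY = 1.78


@dataclass
class CpRecord:
    """Replicate crossing-point values for one library/amplicon/treatment."""

    library: str
    amplicon: str
    treatment: str  # enriched | unenriched
    blocker: str  # chicken | hymenoptera | none
    replicates: list[float]

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if not self.replicates:
            raise ValueError("at least one Cp replicate is required")
        if any(cp <= 0 for cp in self.replicates):
            raise ValueError("Cp values must be positive")

    @property
    def mean_cp(self) -> float:
        return float(np.mean(self.replicates))


@dataclass
class EnrichmentResult:
    library: str
    amplicon: str
    blocker: str
    delta_cp: float  # mean enriched Cp - mean unenriched Cp
    fold: float  # efficiency ** abs(delta_cp), >= 1


def fold_enrichment(
    enriched: CpRecord, unenriched: CpRecord, efficiency: float = DEFAULT_EFFICIENCY
) -> EnrichmentResult:
    """Fold enrichment of one library at one amplicon.

    ``fold = efficiency ** abs(mean(enriched Cp) - mean(unenriched Cp))``.
    The two records must describe the same library and amplicon.
    """
    if (enriched.library, enriched.amplicon) != (unenriched.library, unenriched.amplicon):
        raise ValueError(
            f"mismatched records: {enriched.library}/{enriched.amplicon} vs "
            f"{unenriched.library}/{unenriched.amplicon}"
        )
    if enriched.treatment != "enriched" or unenriched.treatment != "unenriched":
        raise ValueError("records must be one enriched and one unenriched")
    delta = enriched.mean_cp - unenriched.mean_cp
    return EnrichmentResult(
        library=enriched.library,
        amplicon=enriched.amplicon,
        blocker=enriched.blocker,
        delta_cp=delta,
        fold=efficiency ** abs(delta),
    )


def read_cp_table(source: str | Path | IO[str] | pd.DataFrame) -> list[CpRecord]:
    """Read a Cp CSV: library, amplicon, treatment, blocker, rep1..repK."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"library", "amplicon", "treatment", "blocker"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cp table lacks columns: {sorted(missing)}")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise ValueError("Cp table has no replicate (rep*) columns")
    records = []
    for _, row in df.iterrows():
        reps = [float(row[c]) for c in rep_cols if pd.notna(row[c])]
        records.append(
            CpRecord(str(row["library"]), str(row["amplicon"]), str(row["treatment"]),
                     str(row["blocker"]), reps)
        )
    return records


def compute_folds(
    records: Iterable[CpRecord], efficiency: float = DEFAULT_EFFICIENCY
) -> list[EnrichmentResult]:
    """Pair enriched/unenriched records by (library, amplicon, blocker)."""
    by_key: dict[tuple[str, str, str], dict[str, CpRecord]] = {}
    for rec in records:
        slot = by_key.setdefault((rec.library, rec.amplicon, rec.blocker), {})
        if rec.treatment in slot:
            raise ValueError(
                f"duplicate {rec.treatment} record for "
                f"{rec.library}/{rec.amplicon}/{rec.blocker}"
            )
        slot[rec.treatment] = rec
    results = []
    for key in sorted(by_key):
        slot = by_key[key]
        if set(slot) != set(TREATMENTS):
            warnings.warn(f"unpaired Cp records for {key}; skipped")
            continue
        results.append(fold_enrichment(slot["enriched"], slot["unenriched"], efficiency))
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "library": [r.library for r in results],
            "amplicon": [r.amplicon for r in results],
            "blocker": [r.blocker for r in results],
            "delta_cp": [r.delta_cp for r in results],
            "fold": [r.fold for r in results],
        }
    )


def summarize_pools(
    results: Sequence[EnrichmentResult],
    group_by: str = "blocker",
    mean_of: str = "fold",
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Mean fold enrichment per group (and per amplicon within group).

    ``mean_of="fold"`` averages fold values arithmetically;
    ``mean_of="delta"`` averages |delta Cp| first and reports
    ``efficiency ** mean|delta|``.
    """
    if group_by not in ("blocker", "library", "amplicon"):
        raise ValueError(f"group_by must be blocker/library/amplicon, got {group_by!r}")
    if mean_of not in ("fold", "delta"):
        raise ValueError(f"mean_of must be 'fold' or 'delta', got {mean_of!r}")
    if not results:
        raise ValueError("no enrichment results to summarize")
    df = results_table(results)
    rows = []
    for group, sub in sorted(df.groupby(group_by)):
        if sub.empty:
            warnings.warn(f"empty group {group!r} omitted")
            continue
        if mean_of == "fold":
            mean_fold = sub["fold"].mean()
        else:
            mean_fold = efficiency ** sub["delta_cp"].abs().mean()
        rows.append({group_by: group, "n": len(sub), "mean_fold": mean_fold})
    out = pd.DataFrame(rows)
    logger.info("stage=qc in=%d out=%d groups", len(results), len(out))
    return out
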