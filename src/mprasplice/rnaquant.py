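"""RNA-based splicing quantification from isoform-assigned read counts.

The splicing ratio is the log2 ratio of reads supporting the two possible
outcomes of the event (spliced/unspliced for retained introns,
included/skipped for cassette exons, downstream/upstream site for tandem
sites). Variants with fewer than 100 mapped reads are filtered; when all
reads support a single isoform, one read is added to both counts so the log
ratio stays finite (which also preserves antisymmetry under count swap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_READS = 100


@dataclass
class RatioResult:
    variant_id: str
    splicing_ratio: Optional[float]
    expression: Optional[float]
    pass_filter: bool


def assign_reads(read_table: pd.DataFrame, barcode_catalog: pd.DataFrame) -> pd.DataFrame:
    """Demultiplex a read table into per-variant isoform counts.

    ``read_table`` columns: ``barcode``, ``isoform`` ("up"/"down" or
    "cryptic"), optional ``mismatch`` flag and ``count``. Reads with unknown
    barcodes, any mismatch flag or an unrecognized junction are discarded.
    ``barcode_catalog`` columns: ``variant_id``, ``barcode`` (unique).
    """
    if barcode_catalog["barcode"].duplicated().any():
        dup = barcode_catalog.loc[barcode_catalog["barcode"].duplicated(), "barcode"]
        raise ValueError(f"duplicate catalog barcodes: {sorted(set(dup))}")
    reads = read_table.copy()
    if "count" not in reads.columns:
        reads["count"] = 1
    if "mismatch" in reads.columns:
        reads = reads[~reads["mismatch"].astype(bool)]
    reads = reads[reads["isoform"].isin(["up", "down"])]
    merged = reads.merge(barcode_catalog, on="barcode", how="inner")
    pivot = (
        merged.pivot_table(
            index="variant_id", columns="isoform", values="count", aggfunc="sum", fill_value=0
        )
        .reindex(barcode_catalog["variant_id"].unique(), fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
    )
    out = pd.DataFrame(
        {
            "variant_id": pivot.index,
            "count_iso_up": pivot["up"].to_numpy(dtype=np.int64),
            "count_iso_down": pivot["down"].to_numpy(dtype=np.int64),
        }
    ).reset_index(drop=True)
    return out


def compute_splicing_ratio(
    count_iso_up: int, count_iso_down: int, min_reads: int = DEFAULT_MIN_READS
) -> Optional[float]:
    """Log2 ratio of the two isoform counts, or None below the read filter.

    If one count is zero (and the filter is passed), one read is added to
    both counts before taking the ratio.
    """
    if count_iso_up < 0 or count_iso_down < 0:
        raise ValueError("isoform counts must be nonnegative")
    total = count_iso_up + count_iso_down
    if total < min_reads:
        return None
    if count_iso_up == 0 or count_iso_down == 0:
        count_iso_up += 1
        count_iso_down += 1
    # difference of logs keeps count-swap antisymmetry exact in floats
    return float(np.log2(count_iso_up) - np.log2(count_iso_down))


def compute_expression(rna_reads: int, dna_reads: int, pseudo: float = 0.5) -> float:
    """log2(RNA/DNA reads) with a half-read pseudo-count guarding zeros."""
    return float(np.log2((rna_reads + pseudo) / (dna_reads + pseudo)))


def quantify(
    counts: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS
) -> pd.DataFrame:
    """Apply the read filter and ratio computation to a whole counts table.

    ``counts`` columns: ``variant_id``, ``count_iso_up``, ``count_iso_down``
    and optionally ``rna_reads``/``dna_reads`` for the expression column.
    """
    ratios = [
        compute_splicing_ratio(int(u), int(d), min_reads)
        for u, d in zip(counts["count_iso_up"], counts["count_iso_down"])
    ]
    out = pd.DataFrame(
        {
            "variant_id": counts["variant_id"],
            "splicing_ratio": [r if r is not None else np.nan for r in ratios],
            "pass_filter": [r is not None for r in ratios],
        }
    )
    if {"rna_reads", "dna_reads"} <= set(counts.columns):
        out["expression"] = [
            compute_expression(int(r), int(d))
            for r, d in zip(counts["rna_reads"], counts["dna_reads"])
        ]
    return out


def normalize_to_wildtype(
    results: pd.DataFrame,
    manifest: pd.DataFrame,
    wt_label: str = "wt",
    value_col: str = "splicing_ratio",
) -> pd.DataFrame:
    """Subtract the per-context mean wild-type ratio from every variant.

    ``manifest`` columns: ``variant_id``, ``context_id``, ``subset``. Wild
    type replicates of each context (subset == ``wt_label``) are averaged;
    contexts without a passing wild-type measurement yield missing normalized
    values rather than being zero-filled.
    """
    merged = results.merge(
        manifest[["variant_id", "context_id", "subset"]], on="variant_id", how="left"
    )
    wt = merged[(merged["subset"] == wt_label) & merged[value_col].notna()]
    wt_means = wt.groupby("context_id")[value_col].mean()
    merged["normalized_ratio"] = merged[value_col] - merged["context_id"].map(wt_means)
    return merged[["variant_id", "context_id", "subset", value_col, "normalized_ratio"]]


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    iterations: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(iterations, values.size))
    boot = np.array([statistic(values[row]) for row in idx])
    alpha = (1 - level) / 2
    return float(np.quantile(boot, alpha)), float(np.quantile(boot, 1 - alpha))


def paired_group_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired effect comparisons."""
    res = stats.wilcoxon(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
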