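"""Descriptive statistics of a CNVR catalogue.

Per-chromosome distribution (count, unique bases covered, coverage
ratio), whole-genome coverage, size and carrier-frequency summaries,
and the correlations usually reported alongside them. Percentages are
printed at two decimals with half-up rounding; raw proportions are kept
in machine output.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import Genome, union_length
from .regions import Cnvr

__all__ = [
    "round_half_up",
    "pearson",
    "chromosome_summary",
    "chromosome_table_stats",
    "genome_coverage",
    "size_and_frequency_stats",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching how the
    percentage columns of published summary tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either input has zero
    variance or fewer than two points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("pearson: inputs must have equal length")
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def chromosome_summary(
    cnvrs: Sequence[Cnvr], genome: Genome
) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome CNVR distribution table plus genome-wide summary.

    One row per chromosome of the genome (chromosomes without CNVRs
    included with zero counts): chromosome length, CNVR count, unique
    bases covered, and coverage ratio. The summary holds the unweighted
    mean of per-chromosome coverage percentages, the Pearson r between
    chromosome length and CNVR count, the total unique coverage, and
    the genome-wide covered fraction.
    """
    for v in cnvrs:
        if v.chrom not in genome:
            raise ValueError(f"CNVR {v.id}: chromosome {v.chrom!r} not in genome")
    rows = []
    for c in genome:
        here = [v for v in cnvrs if v.chrom == c.name]
        rows.append(
            {
                "chrom": c.name,
                "chrom_length": c.length,
                "n_cnvr": len(here),
                "unique_bp": union_length([v.interval for v in here]) if here else 0,
            }
        )
    table = pd.DataFrame(rows)
    return chromosome_table_stats(table)


def chromosome_table_stats(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Derive ratio columns and genome-wide summary from a
    per-chromosome table with columns chrom, chrom_length, n_cnvr,
    unique_bp. Exposed separately so published per-chromosome tables
    can be fed in directly."""
    table = table.copy()
    if (table["unique_bp"] > table["chrom_length"]).any():
        raise ValueError("unique_bp exceeds chromosome length")
    table["ratio"] = table["unique_bp"] / table["chrom_length"]
    table["ratio_pct"] = [round_half_up(100 * r, 2) for r in table["ratio"]]
    total_unique = int(table["unique_bp"].sum())
    total_len = int(table["chrom_length"].sum())
    summary = {
        "n_cnvr_total": int(table["n_cnvr"].sum()),
        "total_unique_bp": total_unique,
        "genome_length_bp": total_len,
        "genome_fraction": total_unique / total_len,
        "genome_fraction_pct": round_half_up(100 * total_unique / total_len, 2),
        "mean_chrom_ratio": float(table["ratio"].mean()),
        "mean_chrom_ratio_pct": round_half_up(100 * float(table["ratio"].mean()), 2),
        "pearson_r_length_count": pearson(table["chrom_length"], table["n_cnvr"]),
    }
    return table, summary


def genome_coverage(cnvrs: Sequence[Cnvr], genome: Genome) -> tuple[int, float]:
    """(unique bp covered by CNVRs, fraction of the genome covered)."""
    unique = union_length([v.interval for v in cnvrs]) if cnvrs else 0
    return unique, unique / genome.total_length


def size_and_frequency_stats(cnvrs: Sequence[Cnvr]) -> dict:
    """Length summary, carrier-frequency spectrum, and per-type counts.

    The frequency spectrum maps carrier count -> number of CNVRs with
    that many carriers; its values sum to the total CNVR count, as do
    the gain/loss/mixed type counts.
    """
    if not cnvrs:
        raise ValueError("size_and_frequency_stats requires at least one CNVR")
    lengths = np.array([v.length for v in cnvrs])
    freqs = [v.frequency for v in cnvrs]
    spectrum: dict[int, int] = {}
    for f in freqs:
        spectrum[f] = spectrum.get(f, 0) + 1
    type_counts = {"gain": 0, "loss": 0, "mixed": 0}
    for v in cnvrs:
        type_counts[v.type] += 1
    return {
        "n_cnvr": len(cnvrs),
        "min_length": int(lengths.min()),
        "max_length": int(lengths.max()),
        "mean_length": float(lengths.mean()),
        "median_length": float(np.median(lengths)),
        "min_frequency": int(min(freqs)),
        "max_frequency": int(max(freqs)),
        "frequency_spectrum": dict(sorted(spectrum.items())),
        "type_counts": type_counts,
    }
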