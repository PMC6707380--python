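"""Reproduce a published swine CNVR survey's derived statistics from
its own printed tables: per-chromosome coverage, genome fraction, the
length-count correlation, and the cross-study overlap ratios."""

import numpy as np

from cnvreg import chromosome_table_stats, overlap_ratio_pct, round_half_up
from cnvreg.reference_tables import (
    TOTAL_CNVRS,
    TYPE_COUNTS,
    chromosome_distribution,
    external_comparison,
)

table, summary = chromosome_table_stats(chromosome_distribution())
print(table[["chrom", "chrom_length", "n_cnvr", "unique_bp", "ratio_pct"]]
      .head(3).to_string(index=False))
print(f"...\ntotal CNVRs:            {summary['n_cnvr_total']}")
print(f"total unique coverage:  {summary['total_unique_bp'] / 1e6:.1f} Mb")
print(f"genome fraction:        {summary['genome_fraction_pct']}%")
print(f"mean per-chromosome:    {summary['mean_chrom_ratio_pct']}%")
print(f"r(length, count):       {round_half_up(summary['pearson_r_length_count'], 2)}")

gain, loss, mixed = TYPE_COUNTS["gain"], TYPE_COUNTS["loss"], TYPE_COUNTS["mixed"]
print(f"type counts:            {gain} gain + {loss} loss + {mixed} mixed "
      f"= {gain + loss + mixed}")

ext = external_comparison()
recomputed = [overlap_ratio_pct(n, TOTAL_CNVRS) for n in ext["n_overlapped"]]
print(f"cross-study overlap:    mean of 20 printed ratios = "
      f"{round_half_up(float(np.mean(ext['printed_ratio_pct'])), 2)}% "
      f"(recomputed {round_half_up(float(np.mean(recomputed)), 2)}%)")
# the ratio column is (CNVRs of this catalogue touched by an earlier
# study) / 3538; low percentages reflect platform and breed differences
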