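"""Annotation overlap: genes, QTL, breed specificity, cross-study comparison.

Overlap is evaluated against each CNVR's union span (the merged region,
not its member calls) and counts from a single shared base upward by
default — deliberately looser than the reciprocal criterion used for
merging, matching how CNVR catalogues are usually intersected with
annotation tracks and with each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .intervals import Genome, Interval, Thresholds, overlap_bp
from .regions import Cnvr
from .stats import round_half_up
from .trios import PedigreeSample

__all__ = [
    "FeatureRecord",
    "FEATURE_CLASSES",
    "overlap_features",
    "breed_specific",
    "compare_external",
    "overlap_ratio_pct",
]

FEATURE_CLASSES = ("gene", "pseudogene", "ncRNA", "miscRNA", "QTL", "external_cnvr")


@dataclass(frozen=True)
class FeatureRecord:
    """A gene, QTL, or external-study CNVR interval.

    ``label`` carries the category used downstream: a gene biotype, a
    QTL trait name, or an external study name.
    """

    interval: Interval
    feature_id: str
    feature_class: str
    label: str = "."

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.feature_id}: class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def overlap_features(
    cnvrs: Sequence[Cnvr],
    features: Sequence[FeatureRecord],
    thresholds: Thresholds = Thresholds(),
    *,
    genome: Optional[Genome] = None,
) -> tuple[pd.DataFrame, dict]:
    """All (CNVR, feature) pairs sharing >= ``min_feature_overlap`` bases.

    Returns the pair table (cnvr_id, feature_id, feature_class, label,
    overlap_bp) and a rollup dict with distinct counts: CNVRs overlapped,
    features overlapped, and features overlapped per class.

    Raises if ``genome`` is given and a feature lies on a chromosome
    absent from it.
    """
    if genome is not None:
        for f in features:
            if f.chrom not in genome:
                raise ValueError(
                    f"feature {f.feature_id}: chromosome {f.chrom!r} "
                    "not in genome metadata"
                )

    min_ov = thresholds.min_feature_overlap
    by_chrom: dict[str, list[FeatureRecord]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for lst in by_chrom.values():
        lst.sort(key=lambda f: f.interval.start)

    rows = []
    for v in cnvrs:
        for f in by_chrom.get(v.chrom, ()):
            if f.interval.start >= v.end:
                break
            ov = overlap_bp(v.interval, f.interval)
            if ov >= min_ov:
                rows.append(
                    {
                        "cnvr_id": v.id,
                        "feature_id": f.feature_id,
                        "feature_class": f.feature_class,
                        "label": f.label,
                        "overlap_bp": ov,
                    }
                )
    pairs = pd.DataFrame(
        rows, columns=["cnvr_id", "feature_id", "feature_class", "label", "overlap_bp"]
    )
    per_class = (
        pairs.groupby("feature_class")["feature_id"].nunique().to_dict()
        if len(pairs)
        else {}
    )
    rollup = {
        "n_cnvrs_overlapped": int(pairs["cnvr_id"].nunique()) if len(pairs) else 0,
        "n_features_overlapped": int(pairs["feature_id"].nunique()) if len(pairs) else 0,
        "n_features_by_class": {k: int(n) for k, n in per_class.items()},
    }
    return pairs, rollup


def breed_specific(
    cnvrs: Sequence[Cnvr], samples: Sequence[PedigreeSample]
) -> tuple[pd.DataFrame, dict]:
    """CNVRs whose carriers all belong to a single breed.

    Returns the labelled subset (cnvr_id, breed, n_carriers) and a
    summary with the single-carrier fraction among breed-specific CNVRs
    (single-carrier regions are breed-specific by construction).
    """
    breed_of = {}
    for s in samples:
        if not s.breed or s.breed == ".":
            raise ValueError(f"sample {s.sample}: missing breed label")
        breed_of[s.sample] = s.breed
    rows = []
    for v in cnvrs:
        missing = [s for s in v.carriers if s not in breed_of]
        if missing:
            raise ValueError(
                f"CNVR {v.id}: carriers {sorted(missing)} have no breed label"
            )
        breeds = {breed_of[s] for s in v.carriers}
        if len(breeds) == 1:
            rows.append(
                {"cnvr_id": v.id, "breed": breeds.pop(), "n_carriers": v.frequency}
            )
    table = pd.DataFrame(rows, columns=["cnvr_id", "breed", "n_carriers"])
    n_specific = len(table)
    n_single = int((table["n_carriers"] == 1).sum()) if n_specific else 0
    summary = {
        "n_breed_specific": n_specific,
        "n_single_carrier": n_single,
        "single_carrier_fraction": (n_single / n_specific) if n_specific else float("nan"),
    }
    return table, summary


def overlap_ratio_pct(n_overlapped: int, n_total: int) -> float:
    """100 * overlapped / total, half-up rounded to 2 decimals — the
    cross-study comparison's ratio column."""
    return round_half_up(100.0 * n_overlapped / n_total, 2)


def compare_external(
    cnvrs: Sequence[Cnvr], external: Sequence[FeatureRecord]
) -> tuple[int, float]:
    """How many of this catalogue's CNVRs an external CNVR set touches.

    A CNVR counts as overlapped when it shares at least one base with
    any external region. Returns (count, percentage of all CNVRs,
    2-decimal half-up).
    """
    if not external:
        raise ValueError("external CNVR set is empty")
    by_chrom: dict[str, list[FeatureRecord]] = {}
    for f in external:
        by_chrom.setdefault(f.chrom, []).append(f)
    for lst in by_chrom.values():
        lst.sort(key=lambda f: f.interval.start)
    n = 0
    for v in cnvrs:
        for f in by_chrom.get(v.chrom, ()):
            if f.interval.start >= v.end:
                break
            if overlap_bp(v.interval, f.interval) >= 1:
                n += 1
                break
    return n, overlap_ratio_pct(n, len(cnvrs))
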