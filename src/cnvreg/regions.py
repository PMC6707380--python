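"""Merging CNV calls into population-level CNVRs.

Calls are first unioned within each genome (same sample, same type,
>= 1 bp overlap), then merged across samples: two calls join the same
copy-number variable region (CNVR) when their reciprocal overlap is at
least the configured fraction (default 0.50). Cross-sample merging is
defined as connected components of the resulting overlap graph, so a
region can grow by chaining — if call A links to B and B links to C,
all three form one CNVR spanning their union even if A and C themselves
fall below the threshold. A stricter clique mode (every pair must meet
the threshold) is available for sensitivity analysis.

A CNVR's type is ``gain`` if every member call is a gain, ``loss`` if
every member is a loss, and ``mixed`` otherwise (gains and losses at
the same locus in different individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .calls import CnvCall, sort_calls
from .intervals import Interval, Thresholds, overlap_bp, reciprocal_overlap

__all__ = [
    "Cnvr",
    "merge_within_sample",
    "build_cnvrs",
    "assign_type",
    "filter_min_length",
    "cnvr_presence",
]


@dataclass(frozen=True)
class Cnvr:
    """A merged copy-number variable region with its member calls."""

    id: str
    interval: Interval
    type: str  # gain | loss | mixed
    members: tuple[CnvCall, ...]
    carriers: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a CNVR must have at least one member call")
        object.__setattr__(self, "carriers", frozenset(m.sample for m in self.members))

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def frequency(self) -> int:
        """Number of distinct carrier samples."""
        return len(self.carriers)


def assign_type(members: Sequence[CnvCall]) -> str:
    """gain if all members gain, loss if all loss, mixed otherwise."""
    types = {m.type for m in members}
    if types == {"gain"}:
        return "gain"
    if types == {"loss"}:
        return "loss"
    return "mixed"


def merge_within_sample(calls: Sequence[CnvCall]) -> list[CnvCall]:
    """Union overlapping same-type calls of a single sample.

    Calls of different types never merge (a deletion and a duplication
    at one locus in one genome are distinct events). The merged call's
    copy number is the length-weighted mean of member copy numbers when
    every member reports one, otherwise absent; the caller label is kept
    when uniform, else set to ``merged``.
    """
    samples = {c.sample for c in calls}
    if len(samples) > 1:
        raise ValueError(f"merge_within_sample: calls from multiple samples {sorted(samples)}")
    if not calls:
        return []

    merged: list[CnvCall] = []
    by_group: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        by_group.setdefault((c.chrom, c.type), []).append(c)

    for (_, ctype), group in by_group.items():
        group.sort(key=lambda c: (c.start, c.end))
        cluster = [group[0]]
        for c in group[1:]:
            if c.start < max(m.end for m in cluster):  # >=1 bp overlap (half-open)
                cluster.append(c)
            else:
                merged.append(_union_call(cluster, ctype))
                cluster = [c]
        merged.append(_union_call(cluster, ctype))
    return sort_calls(merged)


def _union_call(cluster: list[CnvCall], ctype: str) -> CnvCall:
    if len(cluster) == 1:
        return cluster[0]
    start = min(c.start for c in cluster)
    end = max(c.end for c in cluster)
    if all(c.cn is not None for c in cluster):
        cn = sum(c.cn * c.length for c in cluster) / sum(c.length for c in cluster)
    else:
        cn = None
    callers = {c.caller for c in cluster}
    caller = callers.pop() if len(callers) == 1 else "merged"
    return CnvCall(
        interval=Interval(cluster[0].chrom, start, end),
        sample=cluster[0].sample,
        type=ctype,
        cn=cn,
        caller=caller,
    )


def build_cnvrs(
    calls: Sequence[CnvCall],
    thresholds: Thresholds = Thresholds(),
    *,
    clique: bool = False,
    id_prefix: str = "CNVR",
) -> list[Cnvr]:
    """Merge calls across samples into CNVRs.

    Component semantics (default): CNVRs are connected components of
    the graph joining call pairs with reciprocal overlap >= the
    threshold; order-independent. Clique semantics (``clique=True``):
    calls are processed in (chrom, start, end) order and a call joins
    a region only if it reciprocally overlaps *every* current member.

    Each CNVR spans min(start)..max(end) of its members; singleton
    components become single-member CNVRs. Output is sorted by
    (chromosome, start) with ids ``CNVR<zero-padded rank>`` assigned in
    that order.
    """
    ordered = sort_calls(calls)
    if not ordered:
        return []

    components: list[list[CnvCall]] = []
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in ordered:
        by_chrom.setdefault(c.chrom, []).append(c)

    frac = thresholds.reciprocal_fraction
    for chrom_calls in by_chrom.values():
        if clique:
            components.extend(_clique_merge(chrom_calls, frac))
        else:
            components.extend(_component_merge(chrom_calls, frac))

    components.sort(key=lambda ms: (ms[0].chrom, min(m.start for m in ms), max(m.end for m in ms)))
    pad = max(4, len(str(len(components))))
    cnvrs = []
    for rank, ms in enumerate(components, start=1):
        start = min(m.start for m in ms)
        end = max(m.end for m in ms)
        cnvrs.append(
            Cnvr(
                id=f"{id_prefix}{rank:0{pad}d}",
                interval=Interval(ms[0].chrom, start, end),
                type=assign_type(ms),
                members=tuple(sort_calls(ms)),
            )
        )
    return cnvrs


def _component_merge(chrom_calls: list[CnvCall], frac: float) -> list[list[CnvCall]]:
    """Union-find over pairs meeting the reciprocal threshold.

    Calls are sorted by start; each call is only compared against
    earlier calls that still overlap it, so the sweep is near-linear on
    realistic data.
    """
    n = len(chrom_calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # Edges require >=1 bp overlap, so a sweep keeping an active window
    # of intervals whose end exceeds the current start finds all pairs.
    active: list[int] = []
    for j in range(n):
        cj = chrom_calls[j]
        active = [i for i in active if chrom_calls[i].end > cj.start]
        for i in active:
            if reciprocal_overlap(chrom_calls[i].interval, cj.interval) >= frac:
                union(i, j)
        active.append(j)

    groups: dict[int, list[CnvCall]] = {}
    for i, c in enumerate(chrom_calls):
        groups.setdefault(find(i), []).append(c)
    return list(groups.values())


def _clique_merge(chrom_calls: list[CnvCall], frac: float) -> list[list[CnvCall]]:
    ordered = sorted(chrom_calls, key=lambda c: (c.start, c.end, c.sample))
    regions: list[list[CnvCall]] = []
    for c in ordered:
        placed = False
        for region in regions:
            if all(reciprocal_overlap(m.interval, c.interval) >= frac for m in region):
                region.append(c)
                placed = True
                break
        if not placed:
            regions.append([c])
    return regions


def filter_min_length(
    cnvrs: Sequence[Cnvr], thresholds: Thresholds = Thresholds()
) -> list[Cnvr]:
    """Drop CNVRs shorter than the minimum length (strictly-less-than
    removed; a CNVR of exactly the minimum length is kept)."""
    return [v for v in cnvrs if v.length >= thresholds.min_cnvr_length]


def cnvr_presence(cnvrs: Sequence[Cnvr], samples: Sequence[str]) -> pd.DataFrame:
    """Binary CNVR-by-sample carrier table.

    Row sums equal CNVR frequencies; column sums give per-sample CNVR
    counts. Raises if a carrier is missing from ``samples``.
    """
    sample_set = set(samples)
    for v in cnvrs:
        missing = v.carriers - sample_set
        if missing:
            raise ValueError(
                f"CNVR {v.id}: carrier sample(s) {sorted(missing)} not in sample list"
            )
    if not cnvrs:
        return pd.DataFrame(columns=list(samples), dtype=int)
    data = {
        v.id: [1 if s in v.carriers else 0 for s in samples] for v in cnvrs
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(samples), dtype=int)
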