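"""Per-sample CNV calls and the two-caller consensus filter.

A call set from a breakpoint-sensitive caller (split reads / paired-end
mapping) is intersected with an independent read-depth call set: a primary
call survives only if at least one single support call from the *same
sample* covers at least ``support_fraction`` of its length. Requiring
agreement between orthogonal detection signals is the pipeline's main
false-positive control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .intervals import Interval, Thresholds, overlap_fraction

__all__ = ["CnvCall", "filter_supported_calls", "sort_calls"]

CALL_TYPES = ("loss", "gain")


@dataclass(frozen=True)
class CnvCall:
    """One caller-emitted CNV on one sample's genome."""

    interval: Interval
    sample: str
    type: str  # "loss" or "gain"
    cn: Optional[float] = None  # estimated copy number, if the caller reports one
    caller: str = "."

    def __post_init__(self) -> None:
        if self.type not in CALL_TYPES:
            raise ValueError(f"call type must be loss|gain, got {self.type!r}")
        if self.cn is not None and self.cn < 0:
            raise ValueError(f"copy number must be >= 0, got {self.cn}")

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

    def with_interval(self, interval: Interval) -> "CnvCall":
        return replace(self, interval=interval)


def sort_calls(calls: Iterable[CnvCall]) -> list[CnvCall]:
    """Deterministic call order: (chromosome, start, end, sample)."""
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample))


def filter_supported_calls(
    primary: Sequence[CnvCall],
    support: Sequence[CnvCall],
    thresholds: Thresholds = Thresholds(),
    *,
    match_type: bool = False,
    known_samples: Optional[set[str]] = None,
) -> list[CnvCall]:
    """Retain primary calls corroborated by the support caller.

    A primary call is kept iff some single support call from the same
    sample covers >= ``thresholds.support_fraction`` of the primary
    call's length (one-way fraction, inclusive comparison). Retained
    calls are returned unmodified, sorted by (chrom, start, end, sample).

    Parameters
    ----------
    match_type
        If True, the support call must also have the same loss/gain
        type as the primary call. Off by default: the two callers'
        type assignments need not agree for corroboration.
    known_samples
        Optional sample-id vocabulary. Support calls naming a sample
        outside it are ignored with a warning.
    """
    if known_samples is not None:
        unknown = {c.sample for c in support if c.sample not in known_samples}
        if unknown:
            warnings.warn(
                f"support set references unknown samples {sorted(unknown)}; "
                "those calls are ignored",
                stacklevel=2,
            )
            support = [c for c in support if c.sample in known_samples]

    if not support:
        warnings.warn("empty support call set: no primary calls can be retained",
                      stacklevel=2)
        return []

    # index support calls per (sample, chrom), sorted by start, for a sweep
    by_key: dict[tuple[str, str], list[CnvCall]] = {}
    for c in support:
        by_key.setdefault((c.sample, c.chrom), []).append(c)
    for lst in by_key.values():
        lst.sort(key=lambda c: c.start)

    frac = thresholds.support_fraction
    retained = []
    for p in primary:
        candidates = by_key.get((p.sample, p.chrom), ())
        for s in candidates:
            if s.start >= p.end:  # sorted by start: nothing further can overlap
                break
            if s.end <= p.start:
                continue
            if match_type and s.type != p.type:
                continue
            if overlap_fraction(p.interval, s.interval) >= frac:
                retained.append(p)
                break
    return sort_calls(retained)
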