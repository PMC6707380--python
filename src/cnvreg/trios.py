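"""Trio-based CNVR validation: transmission, inheritance, and error rate.

With sequenced parent-offspring trios, Mendelian segregation stands in
for molecular validation. For a parent-child pair the *transmission
rate* is the fraction of the parent's CNVRs also called in the child;
for a trio the *inheritance rate* is the fraction of the child's CNVRs
present in at least one parent. In an ideal call set transmission would
be ~50% (each parental variant has a coin-flip chance of segregating,
more for common variants) and inheritance 100%. Assuming de-novo and
somatic events are rare relative to calling error, ``100% - mean
inheritance rate`` approximates the CNVR call error rate.

"Called in" a sample is evaluated at CNVR-carrier level by default: the
sample is a member of the population-level region. A looser mode counts
a CNVR as present in a sample when any of that sample's raw calls
overlaps it by >= 1 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calls import CnvCall
from .intervals import overlap_bp
from .regions import Cnvr

__all__ = [
    "PedigreeSample",
    "Trio",
    "derive_trios",
    "transmission_rate",
    "inheritance_rate",
    "trio_report",
    "summarize_trio_rates",
]


@dataclass(frozen=True)
class PedigreeSample:
    """One sample's pedigree record."""

    sample: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: str = "female"
    breed: str = "."
    coverage: Optional[float] = None  # mean sequencing depth, x-fold

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sample {self.sample}: sex must be male|female")


@dataclass(frozen=True)
class Trio:
    """A child with both parents present in the sample table."""

    child: str
    sire: str
    dam: str

    def __post_init__(self) -> None:
        if len({self.child, self.sire, self.dam}) != 3:
            raise ValueError(
                f"trio members must be distinct: {self.child}, {self.sire}, {self.dam}"
            )


def derive_trios(samples: Sequence[PedigreeSample]) -> list[Trio]:
    """All trios implied by the pedigree: children whose sire and dam are
    both themselves in the sample table."""
    ids = {s.sample for s in samples}
    by_id = {s.sample: s for s in samples}
    trios = []
    for s in samples:
        if s.sire in ids and s.dam in ids:
            if by_id[s.sire].sex != "male" or by_id[s.dam].sex != "female":
                raise ValueError(
                    f"sample {s.sample}: sire must be male and dam female"
                )
            trios.append(Trio(child=s.sample, sire=s.sire, dam=s.dam))
    return trios


def _carrier_index(
    cnvrs: Sequence[Cnvr],
    raw_calls: Optional[Sequence[CnvCall]] = None,
) -> dict[str, set[str]]:
    """sample -> set of CNVR ids the sample is considered to carry."""
    idx: dict[str, set[str]] = {}
    for v in cnvrs:
        for s in v.carriers:
            idx.setdefault(s, set()).add(v.id)
    if raw_calls is not None:
        # loose mode: any >=1 bp overlap of a sample's raw call with the CNVR
        by_sample: dict[str, list[CnvCall]] = {}
        for c in raw_calls:
            by_sample.setdefault(c.sample, []).append(c)
        for sample, calls in by_sample.items():
            hits = idx.setdefault(sample, set())
            for v in cnvrs:
                if v.id in hits:
                    continue
                if any(overlap_bp(v.interval, c.interval) > 0 for c in calls):
                    hits.add(v.id)
    return idx


def transmission_rate(cnvrs: Sequence[Cnvr], parent: str, child: str) -> float:
    """Fraction of the parent's CNVRs also carried by the child.

    Returns NaN when the parent carries no CNVR (undefined denominator).
    """
    idx = _carrier_index(cnvrs)
    parent_set = idx.get(parent, set())
    if not parent_set:
        return float("nan")
    child_set = idx.get(child, set())
    return len(parent_set & child_set) / len(parent_set)


def inheritance_rate(cnvrs: Sequence[Cnvr], trio: Trio) -> float:
    """Fraction of the child's CNVRs carried by at least one parent.

    Returns NaN when the child carries no CNVR.
    """
    idx = _carrier_index(cnvrs)
    child_set = idx.get(trio.child, set())
    if not child_set:
        return float("nan")
    parent_union = idx.get(trio.sire, set()) | idx.get(trio.dam, set())
    return len(child_set & parent_union) / len(child_set)


def trio_report(
    cnvrs: Sequence[Cnvr],
    trios: Sequence[Trio],
    *,
    raw_calls: Optional[Sequence[CnvCall]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-trio rate table plus unweighted column means and error rate.

    Each trio contributes one row (paternal transmission, maternal
    transmission, inheritance). Rows with an undefined rate carry NaN
    and are excluded from that column's mean, with a warning. The
    summary's ``error_rate`` is ``1 - mean inheritance`` — valid under
    the stated assumption that de-novo and somatic copy-number events
    are negligible relative to calling error.

    Passing ``raw_calls`` switches presence detection to the loose
    >=1 bp interval-overlap mode.
    """
    if not trios:
        raise ValueError("trio_report requires at least one trio")
    idx = _carrier_index(cnvrs, raw_calls=raw_calls)

    def _rate(numer_set: set, denom_set: set) -> float:
        if not denom_set:
            return float("nan")
        return len(numer_set & denom_set) / len(denom_set)

    rows = []
    for k, t in enumerate(trios, start=1):
        child = idx.get(t.child, set())
        sire = idx.get(t.sire, set())
        dam = idx.get(t.dam, set())
        rows.append(
            {
                "trio": k,
                "child": t.child,
                "sire": t.sire,
                "dam": t.dam,
                "paternal_transmission": _rate(child, sire),
                "maternal_transmission": _rate(child, dam),
                "inheritance": _rate(sire | dam, child),
            }
        )
    table = pd.DataFrame(rows)
    n_undefined = int(
        table[["paternal_transmission", "maternal_transmission", "inheritance"]]
        .isna()
        .any(axis=1)
        .sum()
    )
    if n_undefined:
        warnings.warn(
            f"{n_undefined} trio(s) have an undefined rate (zero denominator); "
            "excluded from the column means",
            stacklevel=2,
        )
    summary = summarize_trio_rates(table)
    return table, summary


def summarize_trio_rates(table: pd.DataFrame) -> dict:
    """Unweighted column means of a per-trio rate table and the derived
    error rate (1 - mean inheritance). NaN rows are skipped per column."""
    means = {
        col: float(table[col].mean(skipna=True))
        for col in ("paternal_transmission", "maternal_transmission", "inheritance")
    }
    return {
        "mean_paternal_transmission": means["paternal_transmission"],
        "mean_maternal_transmission": means["maternal_transmission"],
        "mean_inheritance": means["inheritance"],
        "error_rate": 1.0 - means["inheritance"]
        if np.isfinite(means["inheritance"])
        else float("nan"),
        "n_trios": int(len(table)),
        "assumes_negligible_de_novo_and_somatic": True,
    }
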