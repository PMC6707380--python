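"""File readers and writers for every format the pipeline touches.

Tabular conventions:

* call files — headered TSV ``chrom start end sample type cn caller``
  (``cn`` may be ``.``), 0-based half-open coordinates;
* genome metadata — headered TSV ``chrom length category``;
* pedigree — headered TSV ``sample sire dam sex breed coverage`` with
  ``.`` for unknown;
* feature tracks — header-less BED ``chrom start end id class label``
  or GFF3 (1-based inclusive, converted on read);
* CNVRs — header-less BED6+ ``chrom start end cnvr_id frequency .
  type n_members carriers`` (carriers comma-separated).

Malformed rows raise :class:`FileFormatError` naming the file, line
number, and offending field. Writing then reading any of these
round-trips to the identical record set.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .annotate import FEATURE_CLASSES, FeatureRecord
from .calls import CnvCall
from .intervals import CoordinateError, Genome, GenomeMeta, Interval
from .regions import Cnvr
from .trios import PedigreeSample, Trio

__all__ = [
    "FileFormatError",
    "read_calls",
    "write_calls",
    "read_genome",
    "write_genome",
    "read_pedigree",
    "write_pedigree",
    "read_trios",
    "read_features_bed",
    "read_features_gff3",
    "write_features_bed",
    "read_cnvrs_bed",
    "write_cnvrs_bed",
    "GFF3_TYPE_MAP",
]

PathLike = Union[str, Path]

# GFF3 record types mapped onto the four annotation classes used for
# gene-content summaries; anything absent from this table is skipped.
GFF3_TYPE_MAP = {
    "gene": "gene",
    "protein_coding_gene": "gene",
    "pseudogene": "pseudogene",
    "lnc_RNA": "ncRNA",
    "lncRNA": "ncRNA",
    "ncRNA": "ncRNA",
    "antisense_RNA": "ncRNA",
    "miRNA": "miscRNA",
    "snoRNA": "miscRNA",
    "snRNA": "miscRNA",
    "rRNA": "miscRNA",
    "tRNA": "miscRNA",
    "misc_RNA": "miscRNA",
}


class FileFormatError(ValueError):
    """A malformed input line, reported with file and line number."""


def _err(path: PathLike, lineno: int, msg: str) -> FileFormatError:
    return FileFormatError(f"{path}:{lineno}: {msg}")


def read_calls(path: PathLike) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["chrom", "start", "end", "sample", "type", "cn", "caller"]
    if list(df.columns) != expected:
        raise FileFormatError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            iv = Interval(row.chrom, int(row.start), int(row.end))
        except (ValueError, CoordinateError) as e:
            raise _err(path, i, f"bad coordinates {row.start!r}-{row.end!r}: {e}") from None
        cn = None if row.cn in (".", "", None) else float(row.cn)
        try:
            calls.append(
                CnvCall(interval=iv, sample=row.sample, type=row.type, cn=cn,
                        caller=row.caller)
            )
        except ValueError as e:
            raise _err(path, i, str(e)) from None
    return calls


def write_calls(calls: Sequence[CnvCall], path: PathLike) -> None:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "sample": c.sample,
            "type": c.type,
            "cn": "." if c.cn is None else repr(float(c.cn)),
            "caller": c.caller,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "type", "cn",
                                "caller"]).to_csv(path, sep="\t", index=False)


def read_genome(path: PathLike) -> Genome:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["chrom", "length", "category"]
    if list(df.columns) != expected:
        raise FileFormatError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    metas = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            metas.append(GenomeMeta(row.chrom, int(row.length), row.category))
        except ValueError as e:
            raise _err(path, i, str(e)) from None
    return Genome(metas)


def write_genome(genome: Genome, path: PathLike) -> None:
    pd.DataFrame(
        [{"chrom": c.name, "length": c.length, "category": c.category} for c in genome],
        columns=["chrom", "length", "category"],
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path: PathLike) -> list[PedigreeSample]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample", "sire", "dam", "sex", "breed", "coverage"]
    if list(df.columns) != expected:
        raise FileFormatError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    seen: set[str] = set()
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.sample in seen:
            raise _err(path, i, f"duplicated sample {row.sample!r}")
        seen.add(row.sample)
        try:
            samples.append(
                PedigreeSample(
                    sample=row.sample,
                    sire=None if row.sire == "." else row.sire,
                    dam=None if row.dam == "." else row.dam,
                    sex=row.sex,
                    breed=row.breed,
                    coverage=None if row.coverage == "." else float(row.coverage),
                )
            )
        except ValueError as e:
            raise _err(path, i, str(e)) from None
    return samples


def write_pedigree(samples: Sequence[PedigreeSample], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample": s.sample,
                "sire": s.sire or ".",
                "dam": s.dam or ".",
                "sex": s.sex,
                "breed": s.breed,
                "coverage": "." if s.coverage is None else repr(float(s.coverage)),
            }
            for s in samples
        ],
        columns=["sample", "sire", "dam", "sex", "breed", "coverage"],
    ).to_csv(path, sep="\t", index=False)


def read_trios(path: PathLike) -> list[Trio]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["child", "sire", "dam"]
    if list(df.columns) != expected:
        raise FileFormatError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    return [Trio(row.child, row.sire, row.dam) for row in df.itertuples(index=False)]


def read_features_bed(path: PathLike, default_class: str = "gene") -> list[FeatureRecord]:
    """Header-less 6-column BED: chrom start end id class label.

    Shorter BED lines are padded: a missing class falls back to
    ``default_class``, a missing label to ``.``.
    """
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _err(path, i, f"expected >= 3 BED columns, got {len(parts)}")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                iv = Interval(chrom, int(start), int(end))
            except (ValueError, CoordinateError) as e:
                raise _err(path, i, f"bad coordinates {start!r}-{end!r}: {e}") from None
            fid = parts[3] if len(parts) > 3 else f"feature{i}"
            fclass = parts[4] if len(parts) > 4 and parts[4] != "." else default_class
            label = parts[5] if len(parts) > 5 else "."
            if fclass not in FEATURE_CLASSES:
                raise _err(path, i, f"unknown feature class {fclass!r}")
            feats.append(FeatureRecord(iv, fid, fclass, label))
    return feats


def read_features_gff3(
    path: PathLike, type_map: Optional[dict[str, str]] = None
) -> list[FeatureRecord]:
    """GFF3 track: 1-based inclusive coordinates converted to 0-based
    half-open; record types mapped through ``type_map`` (default
    :data:`GFF3_TYPE_MAP`), unmapped types skipped. The feature id is
    taken from the ``ID=`` attribute (falling back to ``Name=``), the
    label from ``biotype=``/``gene_biotype=`` when present."""
    tmap = GFF3_TYPE_MAP if type_map is None else type_map
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise _err(path, i, f"expected 9 GFF3 columns, got {len(parts)}")
            chrom, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            if ftype not in tmap:
                continue
            try:
                iv = Interval(chrom, int(start) - 1, int(end))
            except (ValueError, CoordinateError) as e:
                raise _err(path, i, f"bad coordinates {start!r}-{end!r}: {e}") from None
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            fid = attrs.get("ID") or attrs.get("Name") or f"feature{i}"
            label = attrs.get("biotype") or attrs.get("gene_biotype") or "."
            feats.append(FeatureRecord(iv, fid, tmap[ftype], label))
    return feats


def write_features_bed(features: Sequence[FeatureRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.interval.start}\t{f.interval.end}\t"
                f"{f.feature_id}\t{f.feature_class}\t{f.label}\n"
            )


def write_cnvrs_bed(cnvrs: Sequence[Cnvr], path: PathLike) -> None:
    """BED6+: chrom start end cnvr_id frequency . type n_members carriers."""
    with open(path, "w") as fh:
        for v in cnvrs:
            carriers = ",".join(sorted(v.carriers))
            fh.write(
                f"{v.chrom}\t{v.start}\t{v.end}\t{v.id}\t{v.frequency}\t.\t"
                f"{v.type}\t{len(v.members)}\t{carriers}\n"
            )


def read_cnvrs_bed(path: PathLike) -> pd.DataFrame:
    """CNVR BED back as a DataFrame (member calls are not serialized;
    carriers come back as a comma-separated string)."""
    cols = ["chrom", "start", "end", "cnvr_id", "frequency", "strand", "type",
            "n_members", "carriers"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     dtype={"chrom": str, "cnvr_id": str, "carriers": str})
    if (df["start"] >= df["end"]).any():
        bad = df.index[(df["start"] >= df["end"])][0] + 1
        raise _err(path, int(bad), "start >= end")
    return df
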