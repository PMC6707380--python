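"""Pedigree-structured synthetic CNV call sets with known truth.

The generator emulates the study design the pipeline targets: a
multi-breed herd (purebred sires of two breeds mated to composite
dams), a dozen sequenced parent-offspring trios, diploid autosomes and
sex-appropriate X ploidy, and two imperfect callers observing the same
genomes — one breakpoint-sensitive ("splitread") and one read-depth
based ("readdepth"). True CNV loci are planted as mutually disjoint
intervals with log-normal lengths and per-breed Beta-distributed allele
frequencies; founders draw alleles from their breed's frequency and
descendants inherit them Mendelianly, so trio statistics have an exact
expected behaviour. Caller imperfection is modelled as boundary jitter,
coverage-dependent false negatives (a logistic curve in sequencing
depth: low-coverage genomes miss more events), and Poisson
false-positive calls per megabase.

Every run is fully determined by the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import FeatureRecord
from .calls import CnvCall
from .intervals import Genome, GenomeMeta, Interval, reciprocal_overlap
from .regions import Cnvr
from .trios import PedigreeSample, Trio, derive_trios

__all__ = [
    "SimulationConfig",
    "TruthLocus",
    "SimResult",
    "simulate",
    "evaluate_against_truth",
    "drop_calls",
    "inject_false_positive_cnvrs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulation run.

    Defaults describe a desk-scale herd: two autosomes (10 and 5 Mb)
    plus a 5 Mb X, 60 samples (12 purebred sires, 36 dams, 12 children
    forming 12 trios), and 300 true CNV loci with ~95% losses. Caller
    noise defaults are moderate: 100 bp boundary jitter, up to 30%
    false negatives at low coverage, 0.1 false positives per Mb.
    """

    seed: int = 17
    chromosomes: tuple[tuple[str, int, str], ...] = (
        ("chr1", 10_000_000, "autosome"),
        ("chr2", 5_000_000, "autosome"),
        ("chrX", 5_000_000, "X"),
    )
    sire_breeds: tuple[str, ...] = ("Duroc", "Landrace")
    dam_breed: str = "Composite"
    n_sires: int = 12
    n_dams: int = 36
    n_children: int = 12  # one per sire, mated to distinct dams -> 12 trios
    n_loci: int = 300
    locus_length_log_mean: float = math.log(2900.0)  # median ~2.9 kb
    locus_length_log_sd: float = 1.0
    min_locus_length: int = 300
    locus_gap: int = 2_000  # planted loci stay mutually disjoint by this margin
    allele_freq_beta: tuple[float, float] = (0.6, 2.4)  # per-breed, mean 0.2
    fraction_gain: float = 0.05
    coverage_log_mean: float = math.log(12.0)
    coverage_log_sd: float = 0.45
    coverage_range: tuple[float, float] = (1.0, 31.0)
    jitter_sd: float = 100.0
    fn_max: float = 0.30
    fn_midpoint_cov: float = 10.0
    fn_scale_cov: float = 4.0
    fp_per_mb: float = 0.10
    callers: tuple[str, str] = ("splitread", "readdepth")
    # annotation tracks
    n_random_genes: int = 80
    n_planted_genes: int = 30
    n_qtl_traits: int = 10
    qtl_per_trait: int = 8

    def noiseless(self) -> "SimulationConfig":
        """This config with all caller noise switched off: no jitter,
        no false negatives, no false positives."""
        return replace(self, jitter_sd=0.0, fn_max=0.0, fp_per_mb=0.0)


@dataclass(frozen=True)
class TruthLocus:
    """One planted CNV locus with its per-breed allele frequencies."""

    interval: Interval
    type: str  # loss | gain
    breed_freqs: tuple[tuple[str, float], ...]


@dataclass
class SimResult:
    """Everything one simulation produced.

    ``genotypes`` holds per-sample alternate-allele counts per locus
    (shape n_samples x n_loci); ``alleles`` the underlying 0/1 allele
    slots (n_samples x n_loci x 2, -9 where the ploidy slot is absent).
    ``calls`` maps each caller name to its emitted call list.
    """

    config: SimulationConfig
    genome: Genome
    samples: list[PedigreeSample]
    trios: list[Trio]
    loci: list[TruthLocus]
    alleles: np.ndarray
    genotypes: np.ndarray
    calls: dict[str, list[CnvCall]]
    genes: list[FeatureRecord] = field(default_factory=list)
    qtl: list[FeatureRecord] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample for s in self.samples]

    def carriers_of(self, locus_index: int) -> set[str]:
        idx = np.nonzero(self.genotypes[:, locus_index] > 0)[0]
        return {self.samples[i].sample for i in idx}

    def segregating_loci(self) -> list[int]:
        """Indices of loci carried by at least one sample."""
        return [j for j in range(len(self.loci)) if (self.genotypes[:, j] > 0).any()]

    def truth_bed(self) -> pd.DataFrame:
        rows = []
        for j, loc in enumerate(self.loci):
            rows.append(
                {
                    "chrom": loc.interval.chrom,
                    "start": loc.interval.start,
                    "end": loc.interval.end,
                    "locus": f"locus{j:04d}",
                    "type": loc.type,
                    "n_carriers": int((self.genotypes[:, j] > 0).sum()),
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        """Emit every file the pipeline reads, plus the truth BED."""
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_genome(self.genome, outdir / "genome.tsv")
        cio.write_pedigree(self.samples, outdir / "pedigree.tsv")
        for caller, calls in self.calls.items():
            cio.write_calls(calls, outdir / f"calls_{caller}.tsv")
        cio.write_features_bed(self.genes, outdir / "genes.bed")
        cio.write_features_bed(self.qtl, outdir / "qtl.bed")
        self.truth_bed().to_csv(outdir / "truth.bed", sep="\t", index=False,
                                header=False)


def _build_pedigree(cfg: SimulationConfig, rng: np.random.Generator) -> list[PedigreeSample]:
    if cfg.n_children > min(cfg.n_sires, cfg.n_dams):
        raise ValueError(
            "infeasible pedigree plan: need at least one distinct sire and dam "
            f"per child ({cfg.n_children} children, {cfg.n_sires} sires, "
            f"{cfg.n_dams} dams)"
        )
    samples: list[PedigreeSample] = []

    def cov() -> float:
        c = float(rng.lognormal(cfg.coverage_log_mean, cfg.coverage_log_sd))
        return float(np.clip(c, *cfg.coverage_range))

    for i in range(cfg.n_sires):
        breed = cfg.sire_breeds[i % len(cfg.sire_breeds)]
        samples.append(PedigreeSample(f"sire{i:02d}", None, None, "male", breed, cov()))
    for i in range(cfg.n_dams):
        samples.append(PedigreeSample(f"dam{i:02d}", None, None, "female",
                                      cfg.dam_breed, cov()))
    for i in range(cfg.n_children):
        sex = "male" if i % 2 == 0 else "female"
        samples.append(
            PedigreeSample(f"child{i:02d}", f"sire{i:02d}", f"dam{i:02d}",
                           sex, cfg.dam_breed, cov())
        )
    return samples


def _place_loci(cfg: SimulationConfig, genome: Genome, rng: np.random.Generator) -> list[Interval]:
    """Mutually disjoint loci (separated by >= locus_gap) so distinct
    truth events can never merge into one CNVR."""
    lengths = np.maximum(
        rng.lognormal(cfg.locus_length_log_mean, cfg.locus_length_log_sd, cfg.n_loci),
        cfg.min_locus_length,
    ).astype(int)
    chrom_names = genome.names()
    weights = np.array([genome[c].length for c in chrom_names], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    out = []
    for L in lengths:
        for attempt in range(2000):
            chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
            limit = genome[chrom].length - int(L)
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + int(L)
            ok = all(
                end + cfg.locus_gap <= s or start >= e + cfg.locus_gap
                for s, e in placed[chrom]
            )
            if ok:
                placed[chrom].append((start, end))
                out.append(Interval(chrom, start, end))
                break
        else:
            raise ValueError(
                "could not place all loci disjointly; reduce n_loci or locus "
                "lengths, or enlarge the genome"
            )
    return out


def simulate(cfg: SimulationConfig = SimulationConfig(), outdir=None) -> SimResult:
    """Run one simulation; optionally write all files to ``outdir``.

    Deterministic given ``cfg.seed``: the same config always yields the
    same truth set, pedigree, and emitted calls.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = Genome(GenomeMeta(n, l, c) for n, l, c in cfg.chromosomes)
    samples = _build_pedigree(cfg, rng)
    trios = derive_trios(samples)

    intervals = _place_loci(cfg, genome, rng)
    breeds = sorted({s.breed for s in samples})
    a, b = cfg.allele_freq_beta
    loci = []
    for iv in intervals:
        ltype = "gain" if rng.random() < cfg.fraction_gain else "loss"
        freqs = tuple((br, float(rng.beta(a, b))) for br in breeds)
        loci.append(TruthLocus(iv, ltype, freqs))

    alleles = _draw_genotypes(cfg, genome, samples, loci, rng)
    genotypes = (alleles == 1).sum(axis=2).astype(np.int16)

    calls = {
        caller: _emit_calls(cfg, genome, samples, loci, alleles, caller, rng)
        for caller in cfg.callers
    }
    genes, qtl = _make_tracks(cfg, genome, intervals, rng)

    result = SimResult(
        config=cfg, genome=genome, samples=samples, trios=trios, loci=loci,
        alleles=alleles, genotypes=genotypes, calls=calls, genes=genes, qtl=qtl,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def _ploidy_slots(meta: GenomeMeta, sex: str) -> tuple[bool, bool]:
    """(has paternal slot, has maternal slot) for a chromosome/sex."""
    p = meta.expected_ploidy(sex)
    if meta.category == "autosome":
        return True, True
    if meta.category == "X":
        return (sex == "female"), True if p >= 1 else False
    return (sex == "male"), False  # Y: paternal only, males only


def _draw_genotypes(
    cfg: SimulationConfig,
    genome: Genome,
    samples: Sequence[PedigreeSample],
    loci: Sequence[TruthLocus],
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele slots: 0 reference, 1 alternate, -9 absent (ploidy).

    Founders draw each present slot Bernoulli(breed frequency);
    children inherit slot-appropriate alleles from their parents
    (paternal slot from the sire, maternal from the dam; a son's X
    comes from the dam only)."""
    n_s, n_l = len(samples), len(loci)
    alleles = np.full((n_s, n_l, 2), -9, dtype=np.int8)
    sample_idx = {s.sample: i for i, s in enumerate(samples)}
    founders = [s for s in samples if s.sire is None and s.dam is None]
    children = [s for s in samples if not (s.sire is None and s.dam is None)]

    for j, loc in enumerate(loci):
        meta = genome[loc.interval.chrom]
        freq = dict(loc.breed_freqs)
        for s in founders:
            i = sample_idx[s.sample]
            has_pat, has_mat = _ploidy_slots(meta, s.sex)
            f = freq[s.breed]
            if has_pat:
                alleles[i, j, 0] = rng.random() < f
            if has_mat:
                alleles[i, j, 1] = rng.random() < f

    # children in pedigree order (parents are founders in the default
    # plan; deeper pedigrees must list parents before children)
    for s in children:
        i = sample_idx[s.sample]
        if s.sire not in sample_idx or s.dam not in sample_idx:
            raise ValueError(f"sample {s.sample}: parents not in sample table")
        si, di = sample_idx[s.sire], sample_idx[s.dam]
        for j, loc in enumerate(loci):
            meta = genome[loc.interval.chrom]
            has_pat, has_mat = _ploidy_slots(meta, s.sex)
            if has_pat:
                donor = alleles[si, j]
                present = donor[donor >= 0]
                if present.size == 0:
                    raise ValueError(
                        f"sample {s.sample}: sire has no transmissible allele at "
                        f"locus {j} on {meta.name}"
                    )
                alleles[i, j, 0] = present[rng.integers(present.size)]
            if has_mat:
                donor = alleles[di, j]
                present = donor[donor >= 0]
                if present.size == 0:
                    raise ValueError(
                        f"sample {s.sample}: dam has no transmissible allele at "
                        f"locus {j} on {meta.name}"
                    )
                alleles[i, j, 1] = present[rng.integers(present.size)]
    return alleles


def _fn_prob(cfg: SimulationConfig, coverage: float) -> float:
    """False-negative probability as a decreasing logistic in coverage;
    at the default shape a <5x genome misses roughly twice as many
    events as a 20x genome."""
    if cfg.fn_max == 0:
        return 0.0
    return cfg.fn_max / (1.0 + math.exp((coverage - cfg.fn_midpoint_cov) / cfg.fn_scale_cov))


def _emit_calls(
    cfg: SimulationConfig,
    genome: Genome,
    samples: Sequence[PedigreeSample],
    loci: Sequence[TruthLocus],
    alleles: np.ndarray,
    caller: str,
    rng: np.random.Generator,
) -> list[CnvCall]:
    calls: list[CnvCall] = []
    genotypes = (alleles == 1).sum(axis=2)
    for i, s in enumerate(samples):
        fn = _fn_prob(cfg, s.coverage if s.coverage is not None else 10.0)
        for j, loc in enumerate(loci):
            n_alt = int(genotypes[i, j])
            if n_alt == 0:
                continue
            if fn > 0 and rng.random() < fn:
                continue
            meta = genome[loc.interval.chrom]
            ploidy = meta.expected_ploidy(s.sex)
            cn = ploidy - n_alt if loc.type == "loss" else ploidy + n_alt
            iv = _jitter(cfg, loc.interval, meta.length, rng)
            calls.append(CnvCall(iv, s.sample, loc.type, float(max(cn, 0)), caller))
        # false positives, uniform over the genome
        if cfg.fp_per_mb > 0:
            lam = cfg.fp_per_mb * genome.total_length / 1e6
            for _ in range(rng.poisson(lam)):
                calls.append(_random_call(cfg, genome, s, caller, rng))
    return calls


def _jitter(cfg: SimulationConfig, iv: Interval, chrom_len: int,
            rng: np.random.Generator) -> Interval:
    if cfg.jitter_sd == 0:
        return iv
    start = int(round(iv.start + rng.normal(0, cfg.jitter_sd)))
    end = int(round(iv.end + rng.normal(0, cfg.jitter_sd)))
    start = max(0, min(start, chrom_len - 1))
    end = max(start + 1, min(end, chrom_len))
    return Interval(iv.chrom, start, end)


def _random_call(cfg: SimulationConfig, genome: Genome, s: PedigreeSample,
                 caller: str, rng: np.random.Generator) -> CnvCall:
    chroms = genome.names()
    weights = np.array([genome[c].length for c in chroms], dtype=float)
    weights /= weights.sum()
    chrom = chroms[rng.choice(len(chroms), p=weights)]
    meta = genome[chrom]
    L = int(
        max(
            cfg.min_locus_length,
            rng.lognormal(cfg.locus_length_log_mean, cfg.locus_length_log_sd),
        )
    )
    L = min(L, meta.length - 1)
    start = int(rng.integers(0, meta.length - L))
    ltype = "gain" if rng.random() < 0.5 else "loss"
    ploidy = meta.expected_ploidy(s.sex)
    cn = max(ploidy - 1, 0) if ltype == "loss" else ploidy + 1
    return CnvCall(Interval(chrom, start, start + L), s.sample, ltype, float(cn), caller)


def _make_tracks(
    cfg: SimulationConfig,
    genome: Genome,
    loci: Sequence[Interval],
    rng: np.random.Generator,
) -> tuple[list[FeatureRecord], list[FeatureRecord]]:
    genes: list[FeatureRecord] = []
    chroms = genome.names()
    weights = np.array([genome[c].length for c in chroms], dtype=float)
    weights /= weights.sum()

    def random_iv(min_len: int, max_len: int) -> Interval:
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = int(rng.integers(min_len, max_len))
        L = min(L, genome[chrom].length - 1)
        start = int(rng.integers(0, genome[chrom].length - L))
        return Interval(chrom, start, start + L)

    gid = 0
    for _ in range(cfg.n_random_genes):
        genes.append(FeatureRecord(random_iv(2_000, 20_000), f"gene{gid:04d}",
                                   "gene", "protein_coding"))
        gid += 1
    # planted genes sit inside true loci, guaranteeing CNVR-gene overlap
    for iv in list(loci)[: cfg.n_planted_genes]:
        span = max(iv.length // 2, 1)
        start = iv.start + (iv.length - span) // 2
        genes.append(FeatureRecord(Interval(iv.chrom, start, start + span),
                                   f"gene{gid:04d}", "gene", "protein_coding"))
        gid += 1

    qtl: list[FeatureRecord] = []
    qid = 0
    planted = list(loci)
    for t in range(cfg.n_qtl_traits):
        for k in range(cfg.qtl_per_trait):
            # half of the first trait's records are planted on true loci
            if t == 0 and k < cfg.qtl_per_trait // 2 and planted:
                anchor = planted[int(rng.integers(len(planted)))]
                pad = int(rng.integers(1_000, 50_000))
                start = max(0, anchor.start - pad)
                end = min(genome[anchor.chrom].length, anchor.end + pad)
                iv = Interval(anchor.chrom, start, end)
            else:
                iv = random_iv(5_000, 50_000)
            qtl.append(FeatureRecord(iv, f"qtl{qid:04d}", "QTL", f"trait{t:02d}"))
            qid += 1
    return genes, qtl


def evaluate_against_truth(cnvrs: Sequence[Cnvr], truth: SimResult) -> dict:
    """Precision/recall of CNVR recovery against the planted loci.

    A segregating truth locus is *recovered* when some CNVR overlaps it
    reciprocally by >= 0.5; a CNVR is a *true positive* when it matches
    some truth locus by the same criterion. Recall is over segregating
    loci only (a locus nobody carries is invisible to any caller).
    """
    seg = truth.segregating_loci()
    truth_ivs = [truth.loci[j].interval for j in seg]
    recovered = 0
    for tiv in truth_ivs:
        if any(reciprocal_overlap(tiv, v.interval) >= 0.5 for v in cnvrs):
            recovered += 1
    tp = 0
    for v in cnvrs:
        if any(reciprocal_overlap(tiv, v.interval) >= 0.5 for tiv in truth_ivs):
            tp += 1
    recall = recovered / len(truth_ivs) if truth_ivs else float("nan")
    precision = tp / len(cnvrs) if cnvrs else float("nan")
    return {
        "n_segregating_loci": len(truth_ivs),
        "n_cnvrs": len(cnvrs),
        "n_recovered": recovered,
        "recall": recall,
        "precision": precision,
    }


def drop_calls(calls: Sequence[CnvCall], rate: float,
               rng: np.random.Generator,
               samples: Optional[set[str]] = None) -> list[CnvCall]:
    """Thin a call set: drop each call with probability ``rate``
    (optionally only calls from the given samples). Models extra
    false negatives on top of a generated call set."""
    out = []
    for c in calls:
        if (samples is None or c.sample in samples) and rng.random() < rate:
            continue
        out.append(c)
    return out


def inject_false_positive_cnvrs(
    cnvrs: Sequence[Cnvr],
    target_samples: Sequence[str],
    proportion: float,
    genome: Genome,
    rng: np.random.Generator,
) -> list[Cnvr]:
    """Add spurious singleton CNVRs so that, for each target sample, a
    fraction ``proportion`` of its CNVR calls is false.

    For a sample carrying k genuine CNVRs, round(k * p / (1 - p)) fake
    regions carried only by that sample are appended at random
    positions, making false calls p of its total. Against trio
    validation this depresses the child's inheritance rate to ~(1 - p)
    while leaving transmission numerators intact.
    """
    if not (0 <= proportion < 1):
        raise ValueError("proportion must be in [0, 1)")
    out = list(cnvrs)
    chroms = genome.names()
    weights = np.array([genome[c].length for c in chroms], dtype=float)
    weights /= weights.sum()
    serial = 0
    for sample in target_samples:
        k = sum(1 for v in cnvrs if sample in v.carriers)
        n_fp = int(round(k * proportion / (1.0 - proportion)))
        for _ in range(n_fp):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            L = int(rng.integers(500, 5_000))
            start = int(rng.integers(0, genome[chrom].length - L))
            member = CnvCall(Interval(chrom, start, start + L), sample, "loss",
                             None, "injected")
            out.append(
                Cnvr(
                    id=f"FP{serial:05d}",
                    interval=member.interval,
                    type="loss",
                    members=(member,),
                )
            )
            serial += 1
    return out
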