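import math

import numpy as np
import pytest

from cnvreg.calls import CnvCall, filter_supported_calls
from cnvreg.intervals import Interval
from cnvreg.regions import build_cnvrs, filter_min_length, merge_within_sample
from cnvreg.simulate import SimulationConfig, simulate


def iv(chrom, start, end):
    return Interval(chrom, start, end)


def call(chrom, start, end, sample="s1", type="loss", cn=None, caller="A"):
    return CnvCall(Interval(chrom, start, end), sample, type, cn, caller)


def pipeline_cnvrs(sim, thresholds=None):
    """Consensus -> within-sample merge -> CNVR build -> length filter."""
    from cnvreg.intervals import Thresholds

    th = thresholds or Thresholds()
    retained = filter_supported_calls(
        sim.calls[sim.config.callers[0]], sim.calls[sim.config.callers[1]], th
    )
    by_sample = {}
    for c in retained:
        by_sample.setdefault(c.sample, []).append(c)
    merged = [m for cs in by_sample.values() for m in merge_within_sample(cs)]
    return filter_min_length(build_cnvrs(merged, th), th)


# --- independent oracles -------------------------------------------------

def union_length_bitmap(intervals):
    """Per-base bitmap count; only viable on tiny genomes."""
    total = 0
    by_chrom = {}
    for i in intervals:
        by_chrom.setdefault(i.chrom, []).append(i)
    for ivs in by_chrom.values():
        hi = max(i.end for i in ivs)
        mask = np.zeros(hi, dtype=bool)
        for i in ivs:
            mask[i.start:i.end] = True
        total += int(mask.sum())
    return total


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration at the
    observed margins: sum probabilities of tables no more likely than
    the observed one."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, r1)

    def prob(x):
        return math.comb(c1, x) * math.comb(n - c1, r1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(p for p in (prob(x) for x in range(lo, hi + 1))
               if p <= p_obs * (1 + 1e-9))


def components_bruteforce(intervals, frac):
    """O(n^2) pairwise graph + BFS connected components; returns a set
    of frozensets of interval indices."""
    from cnvreg.intervals import reciprocal_overlap

    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if (intervals[i].chrom == intervals[j].chrom
                    and reciprocal_overlap(intervals[i], intervals[j]) >= frac):
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = set()
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.add(frozenset(comp))
    return comps


# --- shared fixtures -----------------------------------------------------

@pytest.fixture(scope="session")
def noiseless_sim():
    return simulate(SimulationConfig(seed=3).noiseless())


@pytest.fixture(scope="session")
def noisy_sim():
    return simulate(SimulationConfig(seed=7))
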