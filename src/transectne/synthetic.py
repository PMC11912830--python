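"""Synthetic data: demographic scenarios, a fast model-based Poisson IBD
sampler, and an independent pairwise coalescent-with-recombination oracle.

The Poisson sampler draws binned segment counts directly from the observation
model (the exact inverse of the likelihood), which makes it the right tool
for parameter-recovery experiments.  The oracle simulates the ancestry of two
haplotypes backward through discrete generations — recombination as a Poisson
process along the chromosome, coalescence by Wright-Fisher parent choice —
and extracts IBD segments from the realized ancestral material, without ever
touching the model's segment-count x coalescence-probability factorization.
Agreement between the two is the package's central correctness check.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .core import ChromosomeMap, LengthGrid, NeTrajectory
from .errors import Segment
from .likelihood import IBDHistogram, PoissonIBDModel, SamplingScheme

__all__ = [
    "ScenarioSpec",
    "constant_scenario",
    "bottleneck_scenario",
    "growth_scenario",
    "build_scenario",
    "sample_ibd_from_model",
    "histogram_to_segments",
    "pairwise_arg_simulate",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one of the three study demographies."""

    name: str
    kind: str  # "constant" | "bottleneck" | "growth"
    params: tuple  # kind-specific, see the factory functions


def constant_scenario(ne: float = 25_000.0) -> ScenarioSpec:
    """A constant population."""
    if ne <= 1:
        raise ValueError("population size must exceed 1")
    return ScenarioSpec("constant", "constant", (float(ne),))


def bottleneck_scenario(pre: float = 50_000.0, post: float = 5_000.0,
                        time: int = 30, regrowth_to: float = 100_000.0) -> ScenarioSpec:
    """Instantaneous crash from ``pre`` to ``post`` at generation ``time``
    (backward), followed by steady exponential regrowth to ``regrowth_to``
    at generation 0."""
    if min(pre, post, regrowth_to) <= 1 or time < 1:
        raise ValueError("sizes must exceed 1 and the bottleneck time be >= 1")
    return ScenarioSpec("bottleneck", "bottleneck",
                        (float(pre), float(post), int(time), float(regrowth_to)))


def growth_scenario(start: float = 10_000.0, end: float = 250_000.0,
                    onset: int = 50) -> ScenarioSpec:
    """Exponential growth at a constant rate from ``start`` (at generation
    ``onset`` and deeper) to ``end`` at generation 0."""
    if min(start, end) <= 1 or onset < 1:
        raise ValueError("sizes must exceed 1 and the onset be >= 1")
    return ScenarioSpec("growth", "growth", (float(start), float(end), int(onset)))


def build_scenario(spec: ScenarioSpec, tmax: int) -> NeTrajectory:
    """Materialize a scenario on the integer generation grid 0..tmax-1."""
    t = np.arange(int(tmax), dtype=float)
    if spec.kind == "constant":
        (ne,) = spec.params
        vals = np.full(t.size, ne)
    elif spec.kind == "bottleneck":
        pre, post, btime, top = spec.params
        if tmax <= btime:
            raise ValueError("tmax must cover the bottleneck time")
        vals = np.where(t > btime, pre,
                        post * (top / post) ** ((btime - t) / btime))
    elif spec.kind == "growth":
        start, end, onset = spec.params
        if tmax <= onset:
            raise ValueError("tmax must cover the growth onset")
        vals = np.where(t >= onset, start,
                        start * (end / start) ** ((onset - t) / onset))
    else:
        raise ValueError(f"unknown scenario kind {spec.kind!r}")
    return NeTrajectory(vals)


def sample_ibd_from_model(ne: NeTrajectory, scheme: SamplingScheme,
                          grid: LengthGrid, chroms: ChromosomeMap, G: int,
                          seed=None) -> IBDHistogram:
    """Draw binned IBD counts: independent Poisson per (sample-set pair,
    chromosome, length bin) with the model's expected rates."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = PoissonIBDModel(IBDHistogram.empty(scheme, grid, chroms),
                            scheme, grid, chroms, G)
    hist = IBDHistogram.empty(scheme, grid, chroms)
    x = np.log(ne.values[: model.tmax])
    for p, entry in enumerate(model.pairs):
        gmin = entry["gmin"]
        phi, _ = model._phi(x[gmin : gmin + G + 1])
        lam, _ = model._pair_lambda(entry, phi)
        hist.counts[p] = rng.poisson(lam)
    return hist


def histogram_to_segments(hist: IBDHistogram) -> list[Segment]:
    """Expand binned counts into per-segment records at bin midpoints (cM)."""
    segs: list[Segment] = []
    mids_cm = hist.grid.midpoints * 100.0
    for p, (i, j) in enumerate(hist.pairs):
        for c, chrom in enumerate(hist.chromosomes):
            for k in np.nonzero(hist.counts[p, c])[0]:
                segs.extend([Segment(i, j, chrom, float(mids_cm[k]))]
                            * int(hist.counts[p, c, k]))
    return segs


# ---------------------------------------------------------------------------
# Pairwise discrete-generation coalescent-with-recombination oracle
# ---------------------------------------------------------------------------

def _split_meiosis(atoms, bps, phase, min_keep):
    """Partition interval atoms at crossover points; alternate regions go to
    the two parental haplotypes.  Every cut is a permanent segment boundary."""
    out0, out1 = [], []
    for (s, e) in atoms:
        i = bisect_right(bps, s)
        cur = s
        while cur < e:
            nxt = bps[i] if i < len(bps) else e
            end = nxt if nxt < e else e
            if end - cur >= min_keep:
                (out0 if (i + phase) % 2 == 0 else out1).append((cur, end))
            cur = end
            i += 1
    return out0, out1


def _subtract(atom, cuts, min_keep):
    """Remove sorted disjoint intervals from one atom; keep long remnants."""
    s, e = atom
    out = []
    for (cs, ce) in cuts:
        if cs > s and cs - s >= min_keep:
            out.append((s, cs))
        s = max(s, ce)
    if e > s and e - s >= min_keep:
        out.append((s, e))
    return out


def _merge_lineages(group, g, segments, min_keep):
    """Merge lineages sharing a parent haplotype; material ancestral to both
    sampled haplotypes at overlapping positions has found its MRCA here."""
    a1 = [iv for lin in group for iv in lin[0]]
    a2 = [iv for lin in group for iv in lin[1]]
    if a1 and a2:
        hits1 = {k: [] for k in range(len(a1))}
        hits2 = {k: [] for k in range(len(a2))}
        for k1, (s1, e1) in enumerate(a1):
            for k2, (s2, e2) in enumerate(a2):
                s, e = max(s1, s2), min(e1, e2)
                if e > s:
                    segments.append((e - s, g))
                    hits1[k1].append((s, e))
                    hits2[k2].append((s, e))
        new1 = []
        for k1, atom in enumerate(a1):
            if hits1[k1]:
                new1.extend(_subtract(atom, sorted(hits1[k1]), min_keep))
            else:
                new1.append(atom)
        new2 = []
        for k2, atom in enumerate(a2):
            if hits2[k2]:
                new2.extend(_subtract(atom, sorted(hits2[k2]), min_keep))
            else:
                new2.append(atom)
        a1, a2 = new1, new2
    if a1 or a2:
        return (a1, a2)
    return None


def _simulate_pair(rng, ne_vals, dt, L, horizon, min_keep):
    lineages = [([(0.0, L)], [])]
    if dt == 0:
        lineages.append(([], [(0.0, L)]))
    segments: list[tuple[float, int]] = []
    for g in range(1, horizon + 1):
        n_ind = max(1, int(round(ne_vals[g])))
        n = len(lineages)
        # batched randomness: crossover counts, parent individuals, phases
        ks = rng.poisson(L, n)
        ps = rng.integers(0, n_ind, n)
        phases = rng.integers(0, 2, n)
        pos = rng.random(int(ks.sum())) * L
        slots: dict[int, list] = {}
        off = 0
        for idx in range(n):
            lin = lineages[idx]
            k = int(ks[idx])
            p = int(ps[idx])
            if k == 0:
                slot = 2 * p + int(phases[idx])
                slots.setdefault(slot, []).append(lin)
            else:
                bps = sorted(pos[off : off + k])
                off += k
                phase = int(phases[idx])
                h0 = _split_meiosis(lin[0], bps, phase, min_keep)
                h1 = _split_meiosis(lin[1], bps, phase, min_keep)
                for h, (b1, b2) in enumerate(((h0[0], h1[0]), (h0[1], h1[1]))):
                    if b1 or b2:
                        slots.setdefault(2 * p + h, []).append((b1, b2))
        if g == dt:
            # the older haplotype is itself one of this generation's haplotypes
            slots.setdefault(0, []).append(([], [(0.0, L)]))
        lineages = []
        for slot, group in slots.items():
            if len(group) == 1:
                lineages.append(group[0])
            else:
                merged = _merge_lineages(group, g, segments, min_keep)
                if merged is not None:
                    lineages.append(merged)
        if g >= dt:
            if not any(lin[0] for lin in lineages):
                break
            if not any(lin[1] for lin in lineages):
                break
    return segments


def pairwise_arg_simulate(ne: NeTrajectory, dt: int, L: float, reps: int,
                          seed=None, min_length: float = 0.0,
                          horizon: int | None = None,
                          return_times: bool = False):
    """Simulate IBD segments between two haplotypes sampled ``dt``
    generations apart on one chromosome of length ``L`` Morgans.

    Ancestral material is tracked as intervals; each generation every lineage
    recombines (Poisson breakpoints, rate 1 per Morgan per meiosis) and picks
    a Wright-Fisher parent, so lineages landing on the same parental
    haplotype merge.  An IBD segment is a maximal interval on which the two
    sampled haplotypes reach the same most recent common ancestor along
    recombination-free paths.

    ``min_length`` prunes ancestral atoms too short to yield reportable
    segments (an exact optimization for analyses restricted to lengths >=
    ``min_length``).  Returns a list of per-replicate segment-length lists
    (Morgans), or (length, generation) tuples if ``return_times``.
    """
    if reps < 1:
        raise ValueError("need at least one replicate")
    if dt < 0 or L <= 0:
        raise ValueError("require dt >= 0 and L > 0")
    horizon = len(ne) - 1 if horizon is None else int(horizon)
    if horizon >= len(ne):
        raise ValueError("horizon exceeds trajectory length")
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    out = []
    for child in ss.spawn(reps):
        rng = np.random.default_rng(child)
        segs = _simulate_pair(rng, ne.values, dt, L, horizon, min_length)
        out.append(segs if return_times else [s[0] for s in segs])
    return out
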