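"""Binned Poisson composite likelihood of IBD sharing across sample sets.

Observed IBD segments are binned by length (left-closed, right-open bins) per
sample-set pair and per chromosome.  Within each (pair, chromosome, bin) cell
the count is modelled as Poisson with mean ``nhap * f(midpoint) * dl`` where
``f`` is the expected per-haplotype-pair IBD length density for that
chromosome under the Ne trajectory.  The composite log-likelihood sums the
cells over all within-set and cross-set pairs; the data-only ``log n!`` term
is dropped.

When an IBD detection-error model is supplied, the expected density is first
mapped to the observed scale (false positives, recall, length noise); because
the false-positive rate is a genome-wide quantity, the error-corrected
likelihood pools chromosomes within each sample-set pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ChromosomeMap, LengthGrid, NeTrajectory, PairContext

__all__ = [
    "SampleSet",
    "SamplingScheme",
    "IBDHistogram",
    "bin_segments",
    "haplotype_pair_count",
    "pair_loglik",
    "composite_loglik",
    "n_likelihood_components",
    "PoissonIBDModel",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class SampleSet:
    """A set of diploid individuals sampled at one time point."""

    time: int  # generations before the most recent set
    size: int  # diploid count
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("sampling time must be non-negative")
        if self.size < 1:
            raise ValueError("sample size must be >= 1")
        if self.members and len(self.members) != self.size:
            raise ValueError("member list inconsistent with size")


class SamplingScheme:
    """Ordered sample sets with distinct integer sampling times."""

    def __init__(self, sets) -> None:
        sets = list(sets)
        if not sets:
            raise ValueError("at least one sample set is required")
        times = [s.time for s in sets]
        if len(set(times)) != len(times):
            raise ValueError("sampling times must be distinct")
        if times != sorted(times):
            raise ValueError("sample sets must be sorted by time")
        self.sets: list[SampleSet] = sets
        self._member_to_set: dict[str, int] = {}
        for i, s in enumerate(sets):
            for m in s.members:
                if m in self._member_to_set:
                    raise ValueError(f"individual {m!r} appears in two sets")
                self._member_to_set[m] = i

    @property
    def times(self) -> list[int]:
        return [s.time for s in self.sets]

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def tmax(self, G: int) -> int:
        """Trajectory length needed for horizon G.

        The per-pair time summation runs from ``max(ti, tj)`` to
        ``G + max(ti, tj)`` inclusive, so generations 0 .. G + max(T) must
        all carry an Ne value: G + max(T) + 1 entries.
        """
        return G + max(self.times) + 1

    def set_index_of(self, individual: str) -> int | None:
        return self._member_to_set.get(individual)

    def pair_indices(self) -> list[tuple[int, int]]:
        """All (i, j) with i <= j: within-set pairs first criterion is i == j."""
        n = self.n_sets
        return [(i, j) for i in range(n) for j in range(i, n)]

    def context(self, i: int, j: int) -> PairContext:
        return PairContext(self.sets[i].time, self.sets[j].time)


def n_likelihood_components(n_sets: int) -> int:
    """Number of summed pair terms: n within-set + n(n-1)/2 cross-set."""
    return n_sets + n_sets * (n_sets - 1) // 2


def haplotype_pair_count(setA: SampleSet, setB: SampleSet | None = None, *,
                         within_individual: bool = False) -> int:
    """Number of haplotype pairs over which IBD rates are multiplied.

    Cross-set: ``4 * nA * nB``.  Within-set the default counts only
    inter-individual pairs, ``2 n (n - 1)``, matching empirical IBD callers
    that never report segments within an individual; ``within_individual=True``
    gives the literal C(2n, 2).
    """
    if setB is None or setB is setA or (setB.time == setA.time):
        n = setA.size
        if within_individual:
            return (2 * n) * (2 * n - 1) // 2
        return 2 * n * (n - 1)
    return 4 * setA.size * setB.size


@dataclass
class IBDHistogram:
    """Counts of observed IBD segments per (sample-set pair, chromosome, bin)."""

    counts: np.ndarray  # (n_pairs, n_chrom, n_bins) non-negative ints
    pairs: list[tuple[int, int]]
    chromosomes: list[str]
    grid: LengthGrid
    n_excluded: int = 0
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expected = (len(self.pairs), len(self.chromosomes), self.grid.n_bins)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        self._pair_index = {p: k for k, p in enumerate(self.pairs)}
        self._chrom_index = {c: k for k, c in enumerate(self.chromosomes)}

    @classmethod
    def empty(cls, scheme: SamplingScheme, grid: LengthGrid,
              chroms: ChromosomeMap) -> "IBDHistogram":
        pairs = scheme.pair_indices()
        labels = chroms.labels
        return cls(np.zeros((len(pairs), len(labels), grid.n_bins), dtype=int),
                   pairs, labels, grid)

    def pair_counts(self, i: int, j: int) -> np.ndarray:
        """(n_chrom, n_bins) counts for sample-set pair (i, j)."""
        return self.counts[self._pair_index[(min(i, j), max(i, j))]]

    def chrom_slice(self, labels) -> "IBDHistogram":
        idx = [self._chrom_index[str(c)] for c in labels]
        return IBDHistogram(self.counts[:, idx, :], list(self.pairs),
                            [str(c) for c in labels], self.grid,
                            self.n_excluded, self.n_unassigned)

    def total(self) -> int:
        return int(self.counts.sum())


def bin_segments(segments, grid: LengthGrid, scheme: SamplingScheme,
                 chroms: ChromosomeMap) -> IBDHistogram:
    """Bin IBD segments into an :class:`IBDHistogram`.

    ``segments`` is an iterable of either ``(set_i, set_j, chrom, length_morgans)``
    tuples (set indices into the scheme) or objects with ``id1``, ``id2``,
    ``chrom`` and ``length_cm`` attributes (caller-style records; individuals
    are mapped to sample sets through the scheme's member lists, and records
    involving unassigned individuals are skipped and counted).

    Segments with length outside ``[lmin, lmax)`` are excluded and counted in
    ``n_excluded``.  Unknown chromosome labels raise ``ValueError``.
    """
    hist = IBDHistogram.empty(scheme, grid, chroms)
    counts = hist.counts
    n_excluded = 0
    n_unassigned = 0
    for seg in segments:
        if hasattr(seg, "id1"):
            i = scheme.set_index_of(seg.id1)
            j = scheme.set_index_of(seg.id2)
            if i is None or j is None:
                n_unassigned += 1
                continue
            chrom, length = str(seg.chrom), seg.length_cm / 100.0
        elif hasattr(seg, "length_cm"):  # set-pair segment records
            i, j, chrom, length = seg.i, seg.j, str(seg.chrom), seg.length_cm / 100.0
        else:
            i, j, chrom, length = seg
            chrom = str(chrom)
        if length <= 0:
            raise ValueError("segment lengths must be positive")
        if chrom not in hist._chrom_index:
            raise ValueError(f"unknown chromosome label {chrom!r}")
        k = grid.bin_index(length)
        if k < 0:
            n_excluded += 1
            continue
        p = hist._pair_index[(min(i, j), max(i, j))]
        counts[p, hist._chrom_index[chrom], int(k)] += 1
    hist.n_excluded = n_excluded
    hist.n_unassigned = n_unassigned
    return hist


class PoissonIBDModel:
    """Composite-likelihood engine over log-Ne trajectories.

    Precomputes, for every sample-set pair, the linear map from the
    coalescence pmf to expected bin counts, so that repeated likelihood and
    gradient evaluations during optimization are dense matrix products.

    Parameters
    ----------
    chrom_mult:
        Optional per-chromosome multiplicities (bootstrap resampling over
        chromosomes; a duplicated chromosome contributes its counts and its
        expected rates twice).  Defaults to all ones.
    """

    def __init__(self, hist: IBDHistogram, scheme: SamplingScheme,
                 grid: LengthGrid, chroms: ChromosomeMap, G: int,
                 error_model=None, chrom_mult=None,
                 within_individual_pairs: bool = False) -> None:
        if G < 1:
            raise ValueError("G must be >= 1")
        for p in scheme.pair_indices():
            if p not in hist._pair_index:
                raise ValueError(f"histogram is missing sample-set pair {p}")
        self.scheme = scheme
        self.grid = grid
        self.chroms = chroms
        self.G = G
        self.error_model = error_model
        self.tmax = scheme.tmax(G)
        self.chrom_labels = hist.chromosomes
        self.n_chrom = len(self.chrom_labels)
        mult = np.ones(self.n_chrom) if chrom_mult is None else np.asarray(
            chrom_mult, dtype=float)
        if mult.shape != (self.n_chrom,):
            raise ValueError("chromosome multiplicity has wrong shape")
        self.chrom_mult = mult
        self._hist = hist
        self._within_individual = within_individual_pairs

        L = np.array([chroms[c] for c in self.chrom_labels])
        self._chrom_lengths = L
        self.pairs = []
        mids = grid.midpoints
        if error_model is not None:
            self._ext_grid = grid.extend(error_model.window_cm / 100.0)
            self._C = error_model.transfer_matrix(self._ext_grid, grid)
            self._fp_out = error_model.fp_on_grid(grid, chroms)
        for (i, j) in scheme.pair_indices():
            ctx = scheme.context(i, j)
            nhap = haplotype_pair_count(
                scheme.sets[i], scheme.sets[j] if i != j else None,
                within_individual=within_individual_pairs)
            g = np.arange(ctx.gmin, ctx.gmin + G + 1)
            tstar = ctx.total_branch_length(g).astype(float)
            pos = tstar > 0
            entry = {
                "ij": (i, j), "ctx": ctx, "nhap": nhap, "gmin": ctx.gmin,
                "counts": hist.pair_counts(i, j).astype(float),
            }
            # per-chromosome design tensor: fk[c, k, g]
            def design(mid_points):
                e = np.exp(-np.outer(mid_points, tstar[pos]))
                base1 = (2.0 * tstar[pos] - np.outer(mid_points, tstar[pos] ** 2)) * e
                base2 = tstar[pos] ** 2 * e
                fk = np.zeros((self.n_chrom, mid_points.size, G + 1))
                for c, Lc in enumerate(L):
                    block = base1 + Lc * base2
                    block[mid_points > Lc, :] = 0.0
                    fk[c][:, pos] = block
                return fk
            if error_model is None:
                entry["B"] = design(mids) * (nhap * grid.dl)
            else:
                entry["A_ext"] = design(self._ext_grid.midpoints)
            self.pairs.append(entry)

    def with_multiplicity(self, mult) -> "PoissonIBDModel":
        """Light copy sharing design tensors but with new chromosome weights."""
        import copy
        clone = copy.copy(self)
        clone.chrom_mult = np.asarray(mult, dtype=float)
        if clone.chrom_mult.shape != (self.n_chrom,):
            raise ValueError("chromosome multiplicity has wrong shape")
        return clone

    # -- coalescence pmf and its adjoint ------------------------------------

    @staticmethod
    def _phi(xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = 0.5 * np.exp(-xs)
        surv = np.concatenate(([0.0], np.cumsum(np.log1p(-q[:-1]))))
        return q * np.exp(surv), q

    @staticmethod
    def _phi_adjoint(u: np.ndarray, phi: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Gradient of sum_g u[g] * phi[g] with respect to x (log Ne)."""
        v = u * phi
        # suffix[i] = sum_{g > i} v[g]
        suffix = np.concatenate((np.cumsum(v[::-1])[::-1][1:], [0.0]))
        return -v + (q / (1.0 - q)) * suffix

    # -- likelihood ----------------------------------------------------------

    def _pair_lambda(self, entry, phi):
        """Expected counts and cached intermediates for one pair."""
        if self.error_model is None:
            lam = np.tensordot(entry["B"], phi, axes=([2], [0]))  # (c, k)
            return lam, None
        dens = np.tensordot(self.chrom_mult,
                            np.tensordot(entry["A_ext"], phi, axes=([2], [0])),
                            axes=([0], [0]))  # per-pair density on ext grid
        frac = float(self.chrom_mult @ self._chrom_lengths /
                     self._chrom_lengths.sum())
        lam = entry["nhap"] * self.grid.dl * (
            frac * self._fp_out + self._C @ dens)
        return lam, dens

    def neg_loglik_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative composite log-likelihood and gradient w.r.t. x = log Ne."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.tmax,):
            raise ValueError(f"expected x of length {self.tmax}")
        total = 0.0
        grad = np.zeros(self.tmax)
        for entry in self.pairs:
            gmin = entry["gmin"]
            sl = slice(gmin, gmin + self.G + 1)
            phi, q = self._phi(x[sl])
            lam, _ = self._pair_lambda(entry, phi)
            if self.error_model is None:
                n = entry["counts"]
                w = self.chrom_mult[:, None]
                safe = np.maximum(lam, 1e-300)
                total += float(np.sum(w * (n * np.log(safe) - lam)))
                dldlam = w * (n / safe - 1.0)
                u = np.tensordot(entry["B"], dldlam, axes=([0, 1], [0, 1]))
            else:
                n = self.chrom_mult @ entry["counts"]
                safe = np.maximum(lam, 1e-300)
                total += float(np.sum(n * np.log(safe) - lam))
                dldlam = n / safe - 1.0
                back = self._C.T @ dldlam * (entry["nhap"] * self.grid.dl)
                per_chrom = np.tensordot(entry["A_ext"], back, axes=([1], [0]))
                u = self.chrom_mult @ per_chrom
            grad[sl] += self._phi_adjoint(u, phi, q)
        return -total, -grad

    def loglik(self, ne: NeTrajectory) -> float:
        """Composite log-likelihood at a given trajectory (no penalties).

        Returns ``-inf`` if any cell with a positive count has zero expected
        rate (for example a segment longer than every resampled chromosome).
        """
        if len(ne) < self.tmax:
            raise ValueError("trajectory too short for this model")
        total = 0.0
        x = np.log(ne.values[: self.tmax])
        for entry in self.pairs:
            gmin = entry["gmin"]
            phi, _ = self._phi(x[gmin : gmin + self.G + 1])
            lam, _ = self._pair_lambda(entry, phi)
            if self.error_model is None:
                n = entry["counts"]
                w = np.broadcast_to(self.chrom_mult[:, None], lam.shape)
                if np.any((lam <= 0) & (n > 0) & (w > 0)):
                    return NEG_INF
                term = np.where(lam > 0,
                                n * np.log(np.maximum(lam, 1e-300)) - lam,
                                0.0)
                total += float(np.sum(w * term))
            else:
                n = self.chrom_mult @ entry["counts"]
                if np.any((lam <= 0) & (n > 0)):
                    return NEG_INF
                term = np.where(lam > 0,
                                n * np.log(np.maximum(lam, 1e-300)) - lam,
                                0.0)
                total += float(np.sum(term))
        return total


def pair_loglik(hist: IBDHistogram, i: int, j: int, ne: NeTrajectory,
                scheme: SamplingScheme, grid: LengthGrid,
                chroms: ChromosomeMap, G: int, error_model=None) -> float:
    """Poisson log-likelihood (log n! dropped) of the segments shared between
    sample sets ``i`` and ``j``."""
    sub = SamplingScheme([SampleSet(s.time, s.size) for s in scheme.sets])
    model = PoissonIBDModel(hist, sub, grid, chroms, G, error_model=error_model)
    for entry in model.pairs:
        if entry["ij"] == (min(i, j), max(i, j)):
            model.pairs = [entry]
            return model.loglik(ne)
    raise ValueError(f"pair ({i}, {j}) not in scheme")


def composite_loglik(hist: IBDHistogram, ne: NeTrajectory,
                     scheme: SamplingScheme, grid: LengthGrid,
                     chroms: ChromosomeMap, G: int, error_model=None) -> float:
    """Composite log-likelihood over all n + n(n-1)/2 sample-set pairs."""
    model = PoissonIBDModel(hist, scheme, grid, chroms, G,
                            error_model=error_model)
    assert len(model.pairs) == n_likelihood_components(scheme.n_sets)
    return model.loglik(ne)
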