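"""Coalescent model of IBD segment sharing between temporally offset haplotypes.

All lengths in this module are in Morgans; conversion to/from centimorgans
happens only at I/O boundaries (see :mod:`transectne.io`).

The model works on a single global integer generation clock: generation 0 is
the generation of the most recent sample set, and indices increase backward in
time.  A coalescence at global generation ``g`` between haplotypes sampled at
generations ``ti`` and ``tj`` implies a total branch length of
``t* = (g - ti) + (g - tj)`` meioses, which equals ``2t - dt`` when ``t`` is
measured from the younger sample and ``dt = |ti - tj|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeTrajectory",
    "ChromosomeMap",
    "PairContext",
    "LengthGrid",
    "TmrcaPosterior",
    "segment_count_density",
    "coalescent_pmf",
    "coalescent_pmf_vector",
    "expected_ibd_density",
    "constant_ne_density",
    "erlang2_length_density",
    "tmrca_posterior",
    "DEFAULT_AUTOSOME_LENGTHS_CM",
]

# Sex-averaged genetic lengths of the 22 human autosomes (cM), rounded from
# genome-wide linkage maps; used as the package default when no map is given.
DEFAULT_AUTOSOME_LENGTHS_CM: dict[str, float] = {
    "1": 286.3, "2": 268.6, "3": 223.4, "4": 214.6, "5": 204.1,
    "6": 192.0, "7": 187.2, "8": 168.0, "9": 166.4, "10": 181.1,
    "11": 158.2, "12": 174.7, "13": 125.9, "14": 120.2, "15": 141.8,
    "16": 134.0, "17": 128.5, "18": 117.9, "19": 107.9, "20": 108.3,
    "21": 62.8, "22": 74.1,
}


class NeTrajectory:
    """A diploid effective population size per discrete generation.

    Index 0 is the generation of the most recent sample set; indices increase
    backward in time.  Values must be finite and > 1.
    """

    __slots__ = ("values",)

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("trajectory must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 1.0):
            raise ValueError("all Ne values must be finite and > 1")
        self.values = arr

    @classmethod
    def constant(cls, ne: float, tmax: int) -> "NeTrajectory":
        return cls(np.full(int(tmax), float(ne)))

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, g):
        return self.values[g]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NeTrajectory(len={len(self)}, Ne[0]={self.values[0]:.1f})"


class ChromosomeMap:
    """Mapping of chromosome label to genetic length in Morgans."""

    def __init__(self, lengths: dict[str, float]) -> None:
        if not lengths:
            raise ValueError("chromosome map must not be empty")
        clean: dict[str, float] = {}
        for label, L in lengths.items():
            L = float(L)
            if not np.isfinite(L) or L <= 0:
                raise ValueError(f"chromosome {label!r} has non-positive length {L}")
            key = str(label)
            if key in clean:
                raise ValueError(f"duplicate chromosome label {key!r}")
            clean[key] = L
        self._lengths = clean

    @classmethod
    def default_autosomes(cls) -> "ChromosomeMap":
        """The 22 human autosomes with default genetic lengths."""
        return cls({k: v / 100.0 for k, v in DEFAULT_AUTOSOME_LENGTHS_CM.items()})

    @property
    def labels(self) -> list[str]:
        return list(self._lengths)

    @property
    def lengths(self) -> np.ndarray:
        return np.array(list(self._lengths.values()))

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def __getitem__(self, label: str) -> float:
        return self._lengths[str(label)]

    def __contains__(self, label: str) -> bool:
        return str(label) in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def items(self):
        return self._lengths.items()

    def subset(self, labels) -> "ChromosomeMap":
        return ChromosomeMap({lab: self._lengths[str(lab)] for lab in labels})


@dataclass(frozen=True)
class PairContext:
    """Sampling times (generations, global clock) of a pair of sample sets."""

    ti: int
    tj: int

    def __post_init__(self) -> None:
        if self.ti < 0 or self.tj < 0:
            raise ValueError("sampling times must be non-negative")

    @property
    def dt(self) -> int:
        return abs(self.ti - self.tj)

    @property
    def gmin(self) -> int:
        """Earliest global generation at which the pair can coalesce."""
        return max(self.ti, self.tj)

    def total_branch_length(self, g) -> np.ndarray:
        """t* = (g - ti) + (g - tj) for coalescence at global generation g."""
        return 2 * np.asarray(g) - self.ti - self.tj


@dataclass(frozen=True)
class LengthGrid:
    """Equally spaced, left-closed right-open length bins (Morgans)."""

    lmin: float
    lmax: float
    dl: float

    def __post_init__(self) -> None:
        if not (self.lmin < self.lmax):
            raise ValueError("lmin must be < lmax")
        if self.dl <= 0:
            raise ValueError("bin width must be positive")
        n = (self.lmax - self.lmin) / self.dl
        if abs(n - round(n)) > 1e-8:
            raise ValueError("bin width must evenly divide [lmin, lmax)")

    @classmethod
    def from_cm(cls, lmin_cm: float = 8.0, lmax_cm: float = 20.0,
                dl_cm: float = 0.25) -> "LengthGrid":
        return cls(lmin_cm / 100.0, lmax_cm / 100.0, dl_cm / 100.0)

    @property
    def n_bins(self) -> int:
        return int(round((self.lmax - self.lmin) / self.dl))

    @property
    def edges(self) -> np.ndarray:
        return self.lmin + self.dl * np.arange(self.n_bins + 1)

    @property
    def midpoints(self) -> np.ndarray:
        return self.lmin + self.dl * (np.arange(self.n_bins) + 0.5)

    def extend(self, pad: float) -> "LengthGrid":
        """A grid widened by ``pad`` on both sides, aligned on the same lattice."""
        k = int(np.ceil(pad / self.dl - 1e-9))
        lo = self.lmin - k * self.dl
        while lo <= 0:
            lo += self.dl
        return LengthGrid(lo, self.lmax + k * self.dl, self.dl)

    def bin_index(self, lengths) -> np.ndarray:
        """Bin index for each length; -1 for lengths outside [lmin, lmax)."""
        arr = np.atleast_1d(np.asarray(lengths, dtype=float))
        idx = np.floor((arr - self.lmin) / self.dl).astype(int)
        idx[(arr < self.lmin) | (arr >= self.lmax)] = -1
        return idx if idx.size > 1 or np.ndim(lengths) else int(idx[0])


def segment_count_density(l, tstar, L) -> np.ndarray:
    """Expected density (per Morgan) of chromosome segments of length ``l``
    after a total branch length of ``tstar`` meioses on a chromosome of
    genetic length ``L``.

    The first term counts segments abutting a chromosome end; the second
    counts interior segments delimited by two recombination events.
    """
    l = np.asarray(l, dtype=float)
    tstar = np.asarray(tstar, dtype=float)
    if np.any(l <= 0) or np.any(l > L):
        raise ValueError("require 0 < l <= L")
    if np.any(tstar <= 0):
        raise ValueError("total branch length must be positive")
    e = np.exp(-tstar * l)
    return 2.0 * tstar * e + (L - l) * tstar**2 * e


def coalescent_pmf(g: int, ctx: PairContext, ne: NeTrajectory) -> float:
    """Probability that the pair coalesces exactly at global generation ``g``.

    ``1/(2 Ne[g])`` times the probability of not coalescing in any generation
    from ``max(ti, tj)`` up to ``g - 1``; the survival product is empty at
    ``g = max(ti, tj)``, so the pmf is a proper (inhomogeneous-geometric)
    distribution over ``g >= max(ti, tj)``.
    """
    if g < ctx.gmin:
        raise ValueError("coalescence impossible before both lineages exist")
    if g >= len(ne):
        raise ValueError("generation beyond trajectory length")
    q = 1.0 / (2.0 * ne.values)
    surv = np.prod(1.0 - q[ctx.gmin : g])
    return float(q[g] * surv)


def coalescent_pmf_vector(ctx: PairContext, ne: NeTrajectory, G: int) -> np.ndarray:
    """Vector of coalescence probabilities for g = gmin .. gmin + G."""
    gmin = ctx.gmin
    if gmin + G >= len(ne):
        raise ValueError(
            f"trajectory of length {len(ne)} too short for gmin={gmin}, G={G}"
        )
    q = 1.0 / (2.0 * ne.values[gmin : gmin + G + 1])
    # phi[k] = q[k] * prod_{i=0}^{k-1} (1 - q[i])  (local index k = g - gmin)
    surv = np.concatenate(([0.0], np.cumsum(np.log1p(-q[:-1]))))
    return q * np.exp(surv)


def expected_ibd_density(l, ctx: PairContext, ne: NeTrajectory,
                         chroms: ChromosomeMap, G: int) -> np.ndarray:
    """Expected IBD segments per Morgan per haplotype pair, summed over
    chromosomes, for segment length(s) ``l``.

    Sums the per-generation product of the segment-count density and the
    coalescence probability from ``g = max(ti, tj)`` to ``G + max(ti, tj)``.
    Chromosomes shorter than ``l`` contribute nothing.
    """
    l = np.atleast_1d(np.asarray(l, dtype=float))
    if np.any(l <= 0):
        raise ValueError("segment length must be positive")
    if G < 1:
        raise ValueError("G must be >= 1")
    phi = coalescent_pmf_vector(ctx, ne, G)
    g = np.arange(ctx.gmin, ctx.gmin + G + 1)
    tstar = ctx.total_branch_length(g).astype(float)
    pos = tstar > 0  # t* = 0 at g = gmin when ti == tj: zero segment density
    out = np.zeros(l.shape)
    for L in chroms.lengths:
        ok = l <= L
        if not np.any(ok):
            continue
        e = np.exp(-np.outer(l[ok], tstar[pos]))
        fk = (2.0 * tstar[pos] + np.outer(L - l[ok], tstar[pos] ** 2)) * e
        out[ok] += fk @ phi[pos]
    return out if out.size > 1 else float(out[0])


def expected_ibd_density_time_averaged(l, ctx: PairContext, ne: NeTrajectory,
                                       chroms: ChromosomeMap, G: int,
                                       radius: int) -> np.ndarray:
    """EXPERIMENTAL: crude correction for heterogeneous sampling dates within
    one nominal sample set, averaging the expected density over integer
    offsets of the older sampling time within ``+-radius`` generations.

    This is a synthetic stand-in for a proper date-uncertainty model and
    should be treated as exploratory; the trajectory must extend ``radius``
    generations beyond the usual horizon.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    lo, hi = sorted((ctx.ti, ctx.tj))
    offsets = [o for o in range(-radius, radius + 1) if hi + o >= 0]
    vals = [expected_ibd_density(l, PairContext(lo, hi + o), ne, chroms, G)
            for o in offsets]
    return np.mean(vals, axis=0)


def constant_ne_density(l, dt, Ne, L) -> np.ndarray:
    """Closed-form expected IBD density for a constant population size.

    Continuous-time result of integrating the segment-count density against an
    exponential coalescence density with rate 1/(2 Ne) from ``dt`` to
    infinity.  Note the final term enters with a positive sign; this is what
    the integral evaluates to, and it keeps the density positive for all
    valid inputs.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0) or np.any(l > L) or Ne <= 0 or dt < 0:
        raise ValueError("require 0 < l <= L, Ne > 0, dt >= 0")
    a = 1.0 + 4.0 * Ne * l
    inner = (
        8.0 * Ne * (1.0 + 4.0 * Ne * L)
        + 2.0 * dt * (1.0 + 4.0 * Ne * L) * a
        + (L - l) * (dt + 4.0 * Ne * l * dt) ** 2
    )
    return np.exp(-l * dt) / a**3 * inner


def erlang2_length_density(l, g: int, ctx: PairContext) -> np.ndarray:
    """Erlang-2 approximation of the IBD length density at a focal marker,
    conditional on coalescence at global generation ``g``.

    The distance to the nearest recombination on either side of the marker is
    exponential with rate t*, hence the sum is Erlang-2: ``t*^2 l e^{-t* l}``.
    """
    tstar = float(ctx.total_branch_length(g))
    if tstar <= 0:
        raise ValueError("total branch length must be positive")
    l = np.asarray(l, dtype=float)
    return tstar**2 * l * np.exp(-tstar * l)


@dataclass
class TmrcaPosterior:
    """Posterior over the coalescence generation of an IBD segment."""

    generations: np.ndarray
    pmf: np.ndarray
    length: float = field(default=float("nan"))

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def quantile(self, q) -> np.ndarray:
        """Smallest generation with cumulative mass >= q."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile levels must be in [0, 1]")
        idx = np.searchsorted(self.cdf, q - 1e-12)
        idx = np.minimum(idx, self.generations.size - 1)
        out = self.generations[idx]
        return out if out.size > 1 else int(out[0])

    def mean(self) -> float:
        return float(np.sum(self.generations * self.pmf))


def tmrca_posterior(l: float, ctx: PairContext, ne: NeTrajectory,
                    G: int) -> TmrcaPosterior:
    """Posterior distribution of the coalescence generation of a segment of
    length ``l`` (Morgans), via Bayes' theorem: Erlang-2 length likelihood
    times the coalescence prior, normalized over
    ``g = max(ti, tj) .. G + max(ti, tj)``.
    """
    if l <= 0:
        raise ValueError("segment length must be positive")
    phi = coalescent_pmf_vector(ctx, ne, G)
    g = np.arange(ctx.gmin, ctx.gmin + G + 1)
    tstar = ctx.total_branch_length(g).astype(float)
    like = np.zeros_like(tstar)
    pos = tstar > 0
    like[pos] = tstar[pos] ** 2 * l * np.exp(-tstar[pos] * l)
    unnorm = like * phi
    total = unnorm.sum()
    if total <= 0:
        raise ValueError("degenerate trajectory: posterior mass is zero")
    return TmrcaPosterior(generations=g, pmf=unnorm / total, length=l)
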