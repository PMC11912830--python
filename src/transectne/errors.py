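"""IBD detection-error model: false positives, recall, length noise.

Empirical IBD callers miss short segments, hallucinate spurious ones, and
misreport lengths.  The forward model has three ingredients, all
parameterized in centimorgans (the unit of caller output):

* ``FP(y)`` — false-positive density per haplotype pair per cM;
* ``Recall(z)`` — probability that a true segment of length ``z`` is detected;
* ``R(y | z)`` — Gaussian length-noise kernel with mean ``z`` and standard
  deviation ``sigma_cm`` (default 1.5 cM).

The observed-scale rate is ``FP(y) + sum_z rate(z) Recall(z) R(y|z) dz`` with
the kernel truncated to a +-window (default 5 cM) around ``y`` and *not*
renormalized; at 5 cM ~ 3.3 sigma the truncated mass is <= 0.3%.
``inject_errors`` applies the same three processes generatively to
ground-truth segment lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .core import ChromosomeMap, LengthGrid, constant_ne_density

__all__ = [
    "Segment",
    "ErrorModel",
    "parametric_recall",
    "default_fp_density",
    "corrected_rate",
    "inject_errors",
]


@dataclass(frozen=True)
class Segment:
    """A simulated IBD segment between sample sets ``i`` and ``j``."""

    i: int
    j: int
    chrom: str
    length_cm: float


def parametric_recall(l_cm) -> np.ndarray:
    """Detection probability for a true segment of length ``l_cm`` (cM):
    ``1 - 1 / (1 + 0.025 l e^{0.25 l})``; zero at 0, monotone, -> 1."""
    l = np.asarray(l_cm, dtype=float)
    if np.any(l < 0):
        raise ValueError("segment length must be non-negative")
    out = 1.0 - 1.0 / (1.0 + 0.025 * l * np.exp(0.25 * l))
    return out if out.ndim else float(out)


def default_fp_density(l_cm, chroms: ChromosomeMap,
                       ne: float = 25_000.0) -> np.ndarray:
    """False-positive density (per haplotype pair per cM) equal to the
    expected sharing of a contemporaneous pair in a constant population of
    size ``ne``, summed over the chromosome map."""
    l = np.atleast_1d(np.asarray(l_cm, dtype=float)) / 100.0
    out = np.zeros(l.shape)
    for L in chroms.lengths:
        ok = l <= L
        if np.any(ok):
            out[ok] += constant_ne_density(l[ok], 0, ne, L)
    out /= 100.0  # per Morgan -> per cM
    return out if out.size > 1 else float(out[0])


@dataclass(frozen=True)
class ErrorModel:
    """Detection-error model consumed by the likelihood and the injector.

    ``fp_per_cm`` and ``recall`` are callables of length in cM.  The
    convolution grid step is ``step_cm`` and the kernel window ``window_cm``
    on each side.
    """

    fp_per_cm: Callable
    recall: Callable
    sigma_cm: float = 1.5
    window_cm: float = 5.0
    step_cm: float = 0.25

    def __post_init__(self) -> None:
        if self.sigma_cm < 0 or self.window_cm <= 0 or self.step_cm <= 0:
            raise ValueError("sigma >= 0 and positive window/step required")

    @classmethod
    def for_simulation(cls, chroms: ChromosomeMap, ne_fp: float = 25_000.0,
                       sigma_cm: float = 1.5) -> "ErrorModel":
        """The generative error model used in the simulation studies:
        constant-Ne false positives, parametric recall, 1.5 cM length noise."""
        return cls(fp_per_cm=lambda l: default_fp_density(l, chroms, ne_fp),
                   recall=parametric_recall, sigma_cm=sigma_cm)

    @classmethod
    def identity(cls) -> "ErrorModel":
        """No false positives, perfect recall, no length noise."""
        return cls(fp_per_cm=lambda l: np.zeros_like(np.asarray(l, float)),
                   recall=lambda l: np.ones_like(np.asarray(l, float)),
                   sigma_cm=0.0)

    @classmethod
    def from_table(cls, midpoints_cm, fp_per_cm, recall,
                   sigma_cm: float = 1.5, window_cm: float = 5.0) -> "ErrorModel":
        """Tabulated model (linear interpolation, clamped at the ends)."""
        mids = np.asarray(midpoints_cm, float)
        fp = np.asarray(fp_per_cm, float)
        rc = np.asarray(recall, float)
        if np.any(fp < 0) or np.any((rc < 0) | (rc > 1)):
            raise ValueError("require FP >= 0 and 0 <= recall <= 1")
        return cls(fp_per_cm=lambda l: np.interp(l, mids, fp),
                   recall=lambda l: np.interp(l, mids, rc),
                   sigma_cm=sigma_cm, window_cm=window_cm)

    # -- pieces used by the likelihood engine (Morgan-scale grids) ----------

    def fp_on_grid(self, grid: LengthGrid, chroms=None) -> np.ndarray:
        """False-positive density per haplotype pair per Morgan at the grid
        midpoints."""
        return np.atleast_1d(np.asarray(
            self.fp_per_cm(grid.midpoints * 100.0), float)) * 100.0

    def transfer_matrix(self, grid_in: LengthGrid,
                        grid_out: LengthGrid) -> np.ndarray:
        """Matrix mapping a true-scale density tabulated on ``grid_in`` to the
        recall-and-noise part of the observed-scale density on ``grid_out``.

        ``C[k, j] = Recall(z_j) N(y_k - z_j | 0, sigma) dz`` truncated to the
        window; with ``sigma == 0`` the kernel is a discrete delta on
        matching midpoints.
        """
        if abs(grid_in.dl - grid_out.dl) > 1e-12:
            raise ValueError("input and output grids must share the bin width")
        w = self.window_cm / 100.0
        need_lo = max(grid_out.lmin - w, grid_in.dl / 2.0)
        need_hi = grid_out.lmax + w
        if grid_in.lmin > need_lo + 1e-9 or grid_in.lmax < need_hi - 1e-9:
            raise ValueError(
                "input grid does not cover the convolution window "
                f"[{need_lo:.4f}, {need_hi:.4f}] Morgans; no silent zero-padding")
        z = grid_in.midpoints
        y = grid_out.midpoints
        rec = np.asarray(self.recall(z * 100.0), float)
        diff = y[:, None] - z[None, :]
        if self.sigma_cm == 0.0:
            kern = (np.abs(diff) < grid_in.dl / 2.0).astype(float) / grid_in.dl
        else:
            sig = self.sigma_cm / 100.0
            kern = np.exp(-0.5 * (diff / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
        kern[np.abs(diff) > w + 1e-12] = 0.0
        return kern * rec[None, :] * grid_in.dl


def corrected_rate(rate_true, model: ErrorModel, grid_in: LengthGrid,
                   grid_out: LengthGrid, chroms=None) -> np.ndarray:
    """Map a theoretical per-pair density (per Morgan, on ``grid_in``) to the
    observed scale on ``grid_out``: false positives plus the truncated
    recall/length-noise convolution."""
    rate_true = np.asarray(rate_true, float)
    if rate_true.shape != (grid_in.n_bins,):
        raise ValueError("rate must be tabulated on the input grid midpoints")
    C = model.transfer_matrix(grid_in, grid_out)
    return model.fp_on_grid(grid_out, chroms) + C @ rate_true


def inject_errors(segments, model: ErrorModel, cutoff_cm: float = 8.0,
                  chroms: ChromosomeMap | None = None, nhap: int = 1,
                  seed=None, pair: tuple[int, int] = (0, 0),
                  fp_max_cm: float = 30.0) -> list[Segment]:
    """Corrupt a ground-truth segment list for one sample-set pair.

    1. add ``Poisson(FP(mid) * dl * nhap)`` false positives at each grid
       midpoint between ``cutoff_cm`` and ``fp_max_cm``;
    2. keep each true segment with probability ``Recall(l)``;
    3. perturb kept lengths by ``N(0, sigma_cm)``;
    4. discard anything below ``cutoff_cm``.

    Deterministic given ``seed``.  False positives are assigned a chromosome
    proportional to map length (uniform label if no map is given).
    """
    rng = np.random.default_rng(seed)
    out: list[Segment] = []
    segments = list(segments)
    # (1) false positives
    mids = np.arange(cutoff_cm + model.step_cm / 2.0, fp_max_cm, model.step_cm)
    fp_rates = np.atleast_1d(np.asarray(model.fp_per_cm(mids), float))
    n_fp = rng.poisson(fp_rates * model.step_cm * nhap)
    if chroms is not None:
        labels = chroms.labels
        probs = chroms.lengths / chroms.total_length()
    for mid, n in zip(mids, n_fp):
        for _ in range(int(n)):
            lab = labels[rng.choice(len(labels), p=probs)] if chroms is not None else "1"
            out.append(Segment(pair[0], pair[1], lab, float(mid)))
    # (2)-(4) recall, length noise, cutoff
    for seg in segments:
        if rng.random() >= model.recall(seg.length_cm):
            continue
        newlen = seg.length_cm
        if model.sigma_cm > 0:
            newlen += rng.normal(0.0, model.sigma_cm)
        if newlen < cutoff_cm:
            continue
        out.append(replace(seg, length_cm=float(newlen)))
    return out
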