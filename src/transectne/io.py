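"""File formats and empirical-pipeline preprocessing.

Readers consume the tab-separated dialects emitted by aDNA IBD-calling
pipelines (segment tables in cM), simple metadata tables (individual, date,
unit, coverage), genetic-map tables (chromosome, length in Morgans) and
3-column error-model tables.  Preprocessing covers the relatedness filter
(remove the lower-coverage member of close pairs) and grouping individuals
into sample sets by generation windows.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ChromosomeMap, NeTrajectory
from .errors import ErrorModel
from .likelihood import SampleSet, SamplingScheme

__all__ = [
    "IBDSegmentRecord",
    "SampleMeta",
    "read_ibd_tsv",
    "write_ibd_tsv",
    "read_metadata_tsv",
    "read_chromosome_map",
    "write_chromosome_map",
    "read_error_model",
    "write_trajectory_tsv",
    "relatedness_filter",
    "group_by_generations",
    "read_config",
]


@dataclass(frozen=True)
class IBDSegmentRecord:
    """One called IBD segment between two individuals (lengths in cM)."""

    id1: str
    id2: str
    chrom: str
    length_cm: float
    start_cm: float | None = None
    end_cm: float | None = None

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ValueError("segment length must be positive")
        if self.id1 == self.id2:
            raise ValueError("a segment must join two distinct individuals")
        if self.start_cm is not None and self.end_cm is not None:
            if abs((self.end_cm - self.start_cm) - self.length_cm) > 0.01:
                raise ValueError("start/end inconsistent with length")


@dataclass(frozen=True)
class SampleMeta:
    """Individual id, date (with unit 'BP' or 'CE'), coverage in fold."""

    id: str
    date: float
    unit: str
    coverage: float = float("nan")
    include: bool = True

    def years_bp(self) -> float:
        if self.unit.upper() == "BP":
            return self.date
        if self.unit.upper() == "CE":
            return 1950.0 - self.date
        raise ValueError(f"unknown date unit {self.unit!r} (use BP or CE)")


_ALIASES = {
    "id1": ("id1", "iid1"),
    "id2": ("id2", "iid2"),
    "chrom": ("chrom", "ch", "chr", "chromosome"),
    "length_cm": ("length_cm", "length", "lengthcm"),
    "start_cm": ("start_cm", "start", "startcm"),
    "end_cm": ("end_cm", "end", "endcm"),
}


def _resolve_columns(df: pd.DataFrame, required, optional=()) -> dict[str, str]:
    lower = {c.lower(): c for c in df.columns}
    out = {}
    for name in (*required, *optional):
        for alias in _ALIASES.get(name, (name,)):
            if alias in lower:
                out[name] = lower[alias]
                break
        else:
            if name in required:
                raise ValueError(f"missing required column {name!r} "
                                 f"(have: {list(df.columns)})")
    return out


def read_ibd_tsv(path) -> list[IBDSegmentRecord]:
    """Read an IBD segment table (TSV with header; lengths in cM).

    Malformed rows (non-positive length, self-pair, inconsistent start/end)
    are rejected with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = _resolve_columns(df, ("id1", "id2", "chrom", "length_cm"),
                            ("start_cm", "end_cm"))
    records, problems = [], []
    for row_idx, row in df.iterrows():
        line_no = row_idx + 2  # 1-based, after the header line
        try:
            kwargs = dict(
                id1=str(row[cols["id1"]]), id2=str(row[cols["id2"]]),
                chrom=str(row[cols["chrom"]]),
                length_cm=float(row[cols["length_cm"]]))
            for opt in ("start_cm", "end_cm"):
                if opt in cols and pd.notna(row[cols[opt]]):
                    kwargs[opt] = float(row[cols[opt]])
            records.append(IBDSegmentRecord(**kwargs))
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ValueError("malformed IBD rows:\n" + "\n".join(problems))
    return records


def write_ibd_tsv(records, path) -> None:
    df = pd.DataFrame(
        [{"id1": r.id1, "id2": r.id2, "chrom": r.chrom,
          "length_cm": r.length_cm, "start_cm": r.start_cm,
          "end_cm": r.end_cm} for r in records])
    df.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> list[SampleMeta]:
    """Read sample metadata: columns id, date, unit (BP|CE), coverage."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(df, ("id", "date", "unit"), ("coverage",))
    metas = []
    for _, row in df.iterrows():
        metas.append(SampleMeta(
            id=str(row[cols["id"]]), date=float(row[cols["date"]]),
            unit=str(row[cols["unit"]]),
            coverage=float(row[cols["coverage"]]) if "coverage" in cols else float("nan")))
    if len({m.id for m in metas}) != len(metas):
        raise ValueError("duplicate individual ids in metadata")
    return metas


def read_chromosome_map(path) -> ChromosomeMap:
    """Read a genetic-map table: columns chrom, length_morgan."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(df, ("chrom", "length_morgan"))
    return ChromosomeMap({str(r[cols["chrom"]]): float(r[cols["length_morgan"]])
                          for _, r in df.iterrows()})


def write_chromosome_map(chroms: ChromosomeMap, path) -> None:
    pd.DataFrame([{"chrom": c, "length_morgan": L}
                  for c, L in chroms.items()]).to_csv(path, sep="\t", index=False)


def read_error_model(path, sigma_cm: float = 1.5,
                     window_cm: float = 5.0) -> ErrorModel:
    """Read a 3-column error-model table: bin_midpoint_cM,
    fp_density_per_pair_per_cM, recall."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    try:
        mid = df[cols["bin_midpoint_cm"]].to_numpy(float)
        fp = df[cols["fp_density_per_pair_per_cm"]].to_numpy(float)
        rec = df[cols["recall"]].to_numpy(float)
    except KeyError as exc:
        raise ValueError(f"error-model table missing column {exc}") from exc
    return ErrorModel.from_table(mid, fp, rec, sigma_cm=sigma_cm,
                                 window_cm=window_cm)


def write_trajectory_tsv(path, trajectory: NeTrajectory, ci_low=None,
                         ci_high=None) -> None:
    """Write generation, diploid Ne and optional CI columns (one row per
    generation; generation 0 = most recent sample set)."""
    n = len(trajectory)
    df = pd.DataFrame({
        "generation": np.arange(n),
        "ne_diploid": trajectory.values,
        "ci_low": np.full(n, np.nan) if ci_low is None else np.asarray(ci_low),
        "ci_high": np.full(n, np.nan) if ci_high is None else np.asarray(ci_high),
    })
    with open(path, "w") as fh:
        fh.write("# generation: generations before the most recent sample set\n"
                 "# ne_diploid: diploid effective population size\n"
                 "# ci_low/ci_high: bootstrap percentile envelope\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def relatedness_filter(records, metas, min_segments: int = 3,
                       seg_length_cm: float = 12.0,
                       total_cm: float = 100.0):
    """Remove the lower-coverage member of each closely related pair.

    A pair is flagged when it shares at least ``min_segments`` IBD segments
    longer than ``seg_length_cm`` or when the summed length of such segments
    exceeds ``total_cm``.  Filtering repeats until no flagged pair remains
    among the kept individuals; coverage ties are broken by keeping the
    lexicographically smaller id.

    Returns ``(kept_ids, removed_report)`` where the report lists
    ``(removed_id, kept_id, n_segments, total_length)`` tuples.
    """
    cov = {m.id: m.coverage for m in metas}
    stats: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if r.length_cm > seg_length_cm:
            key = (min(r.id1, r.id2), max(r.id1, r.id2))
            stats.setdefault(key, []).append(r.length_cm)
    flagged = {key: lens for key, lens in stats.items()
               if len(lens) >= min_segments or sum(lens) > total_cm}
    kept = {m.id for m in metas}
    removed = []
    while True:
        active = sorted(k for k in flagged if k[0] in kept and k[1] in kept)
        if not active:
            break
        a, b = active[0]
        ca, cb = cov.get(a, float("nan")), cov.get(b, float("nan"))
        if np.isnan(ca) or np.isnan(cb):
            drop, keep = (max(a, b), min(a, b))
        elif ca == cb:
            drop, keep = (max(a, b), min(a, b))
        else:
            drop, keep = (a, b) if ca < cb else (b, a)
        kept.discard(drop)
        lens = flagged[(a, b)]
        removed.append((drop, keep, len(lens), sum(lens)))
    return sorted(kept), removed


def group_by_generations(metas, window: int = 5,
                         generation_time: float = 29.0):
    """Assign individuals to sample sets by generation windows.

    Dates are converted to generations before the most recent individual
    (the window anchor) and floored into consecutive windows of ``window``
    generations; each non-empty window becomes a sample set whose time is
    ``window_index * window``.

    Returns ``(scheme, report)`` with per-set sizes in the report.
    """
    metas = [m for m in metas if m.include]
    if not metas:
        raise ValueError("empty metadata")
    ybp = np.array([m.years_bp() for m in metas])
    gens = (ybp - ybp.min()) / generation_time
    idx = np.floor(gens / window).astype(int)
    sets = []
    report = {}
    for w in sorted(set(idx.tolist())):
        members = tuple(sorted(m.id for m, k in zip(metas, idx) if k == w))
        sets.append(SampleSet(time=int(w * window), size=len(members),
                              members=members))
        report[int(w * window)] = len(members)
    return SamplingScheme(sets), report


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {line_no}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            out[key] = val
    return out


def log(msg: str) -> None:
    print(msg, file=sys.stderr)
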