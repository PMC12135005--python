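"""Exome interval masks and genetic-map coordinate conversion.

Coordinate conventions, fixed throughout the package:

* variant positions are 1-based bp (VCF dialect);
* BED intervals are 0-based half-open ``[start, end)``;
* a variant at 1-based position ``p`` falls in an interval iff
  ``start <= p - 1 < end``.

A :class:`GeneticMap` is a monotone piecewise-linear mapping from physical
position to cumulative genetic distance in cM (HapMap dialect: columns
``Position(bp)  Rate(cM/Mb)  Map(cM)``, the cumulative column being
authoritative). Positions outside the anchored range clamp to the terminal
cM values, i.e. zero recombination beyond the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .haplotypes import HaplotypeDataset

__all__ = [
    "ExomeMask",
    "GeneticMap",
    "read_bed",
    "read_genetic_map",
    "filter_to_exome",
    "flanking_exons",
    "regular_mask",
]

logger = logging.getLogger(__name__)


class MapRegionMismatchError(ValueError):
    """Genetic map does not span the simulated/estimated region."""


@dataclass
class ExomeMask:
    """Normalized exome intervals: sorted, overlap- and bookend-merged.

    ``starts``/``ends`` are parallel 0-based half-open coordinates. Touching
    intervals are merged as well so that every gap between consecutive
    intervals has positive width (the exome adjustment draws uniformly on
    open gaps).
    """

    starts: np.ndarray
    ends: np.ndarray
    chrom: str = "22"

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        if starts.shape != ends.shape or starts.ndim != 1:
            raise ValueError("starts and ends must be parallel 1-D arrays")
        if np.any(starts >= ends):
            raise ValueError("every interval must satisfy start < end")
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # merge overlapping or touching intervals
        m_starts: list[int] = []
        m_ends: list[int] = []
        for s, e in zip(starts, ends):
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(int(s))
                m_ends.append(int(e))
        self.starts = np.asarray(m_starts, dtype=np.int64)
        self.ends = np.asarray(m_ends, dtype=np.int64)

    def __len__(self) -> int:
        return self.starts.shape[0]

    @property
    def total_bp(self) -> int:
        return int((self.ends - self.starts).sum())

    def interval_index_of(self, pos) -> np.ndarray | int:
        """Index of the interval containing 1-based position(s); -1 if none."""
        p0 = np.asarray(pos, dtype=np.float64) - 1.0
        i = np.searchsorted(self.starts, p0, side="right") - 1
        inside = (i >= 0) & (p0 < self.ends[np.clip(i, 0, None)])
        out = np.where(inside, i, -1)
        return int(out) if np.isscalar(pos) or out.ndim == 0 else out

    def contains(self, positions) -> np.ndarray:
        """Boolean membership of 1-based positions (start <= p-1 < end)."""
        idx = self.interval_index_of(np.atleast_1d(positions))
        return np.asarray(idx) >= 0

    def interval(self, i: int) -> tuple[int, int]:
        return int(self.starts[i]), int(self.ends[i])


def read_bed(path, chrom: str | None = None, padding: int = 0) -> ExomeMask:
    """Load a 3+ column BED file into a normalized :class:`ExomeMask`.

    Rows from other chromosomes are dropped when ``chrom`` is given.
    ``padding`` symmetrically extends each interval before merging (clipped
    at 0). Malformed rows (non-numeric bounds, start >= end) are rejected
    with their line number.
    """
    starts: list[int] = []
    ends: list[int] = []
    seen_chrom = chrom
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            row_chrom = fields[0]
            if chrom is not None and row_chrom.removeprefix("chr") != chrom.removeprefix(
                "chr"
            ):
                continue
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric BED bounds") from err
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end ({s} >= {e})")
            if seen_chrom is None:
                seen_chrom = row_chrom
            starts.append(max(0, s - padding))
            ends.append(e + padding)
    if not starts:
        mask = ExomeMask.__new__(ExomeMask)
        mask.starts = np.empty(0, dtype=np.int64)
        mask.ends = np.empty(0, dtype=np.int64)
        mask.chrom = seen_chrom or "22"
        return mask
    return ExomeMask(np.array(starts), np.array(ends), chrom=seen_chrom or "22")


def regular_mask(
    seq_length_bp: int, exon_bp: int = 200, spacing_bp: int = 10_000, chrom: str = "22"
) -> ExomeMask:
    """A synthetic exome mask: ``exon_bp``-long exons every ``spacing_bp``.

    Used for tests and scaled benchmarks; coverage fraction is
    ``exon_bp / spacing_bp``.
    """
    starts = np.arange(0, seq_length_bp - exon_bp, spacing_bp, dtype=np.int64)
    return ExomeMask(starts, starts + exon_bp, chrom=chrom)


def write_bed(mask: ExomeMask, path) -> None:
    with open(path, "w") as fh:
        for s, e in zip(mask.starts, mask.ends):
            fh.write(f"{mask.chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear physical-to-genetic map (anchors in bp and cumulative cM)."""

    positions_bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.positions_bp.shape != self.cm.shape or self.positions_bp.ndim != 1:
            raise ValueError("anchor arrays must be parallel 1-D arrays")
        if self.positions_bp.size == 0:
            raise ValueError("a genetic map needs at least one anchor")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("anchor positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    @property
    def is_degenerate(self) -> bool:
        """True when there are < 2 anchors, so no rate can be interpolated."""
        return self.positions_bp.size < 2

    @classmethod
    def from_flat_rate(cls, rate_per_bp: float, seq_length_bp: int) -> "GeneticMap":
        """Flat map: ``rate_per_bp`` Morgans/bp/generation over the region."""
        if rate_per_bp < 0:
            raise ValueError("recombination rate must be >= 0")
        L = float(seq_length_bp)
        return cls(np.array([0.0, L]), np.array([0.0, rate_per_bp * 100.0 * L]))

    def phys_to_cm(self, pos):
        """Cumulative cM at physical position(s), clamped outside the anchors."""
        if self.is_degenerate:
            raise ValueError(
                "degenerate single-anchor map: supply a flat rate instead"
            )
        return np.interp(pos, self.positions_bp, self.cm)

    def span_bp(self) -> float:
        return float(self.positions_bp[-1])

    def to_msprime_ratemap(self, seq_length_bp: int):
        """An ``msprime.RateMap`` over [0, seq_length_bp] (M/bp rates).

        Raises :class:`MapRegionMismatchError` if the map ends before the
        region does.
        """
        import msprime

        if self.is_degenerate:
            raise ValueError("degenerate map cannot be converted to a rate map")
        if self.span_bp() < seq_length_bp:
            raise MapRegionMismatchError(
                f"genetic map ends at {self.span_bp():.0f} bp but the region is "
                f"{seq_length_bp} bp long"
            )
        pos = self.positions_bp.copy()
        cm = self.cm.copy()
        # restrict to the region and pin the boundary anchors
        keep = pos < seq_length_bp
        pos = np.append(pos[keep], float(seq_length_bp))
        cm = np.append(cm[keep], self.phys_to_cm(seq_length_bp))
        if pos[0] > 0:
            pos = np.insert(pos, 0, 0.0)
            cm = np.insert(cm, 0, cm[0])  # clamp: zero rate before first anchor
        rates = np.diff(cm) / 100.0 / np.diff(pos)
        return msprime.RateMap(position=pos, rate=rates)


def read_genetic_map(path) -> GeneticMap:
    """Read a HapMap-format genetic map.

    Accepts both the 3-column dialect ``Position(bp) Rate(cM/Mb) Map(cM)`` and
    the 4-column dialect with a leading chromosome label; the cumulative cM
    column is authoritative and the rate column is only cross-checked (a
    warning is logged when they disagree by more than 1%).
    """
    positions: list[float] = []
    rates: list[float] = []
    cms: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            try:
                vals = [float(x) for x in fields[-3:]]
            except ValueError:
                if lineno == 1 or not positions:
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: non-numeric map row")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 map columns")
            positions.append(vals[0])
            rates.append(vals[1])
            cms.append(vals[2])
    if not positions:
        raise ValueError(f"{path}: genetic map contains no data rows")
    gmap = GeneticMap(np.asarray(positions), np.asarray(cms))
    if not gmap.is_degenerate:
        d_bp = np.diff(gmap.positions_bp)
        d_cm = np.diff(gmap.cm)
        implied = np.asarray(rates[:-1]) * d_bp / 1e6
        denom = np.maximum(np.abs(d_cm), 1e-9)
        if np.any(np.abs(implied - d_cm) / denom > 0.01):
            logger.warning(
                "%s: rate column inconsistent with cumulative cM column; "
                "using the cM column",
                path,
            )
    return gmap


# ---------------------------------------------------------------------------
# WGS -> WES filtering and exon adjacency
# ---------------------------------------------------------------------------


def filter_to_exome(ds: HaplotypeDataset, mask: ExomeMask) -> HaplotypeDataset:
    """Keep only variants falling inside the mask (start <= p-1 < end).

    The sample set is unchanged; idempotent by construction.
    """
    if len(mask) == 0:
        return ds.subset_sites(np.zeros(ds.n_sites, dtype=bool))
    return ds.subset_sites(mask.contains(ds.positions))


def flanking_exons(
    mask: ExomeMask, focal_pos: float, query_pos: float
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int] | None]:
    """Exon containing ``query_pos``, its neighbor toward ``focal_pos``, and the gap.

    Returns ``(query_exon, adjacent_exon, gap)`` where ``gap`` is the open
    interval strictly between them (``None`` when both positions share one
    exon). The adjacent exon is the next mask interval from the query exon in
    the direction of the focal site — the focal site's own exon when the two
    are immediate neighbors.
    """
    qi = mask.interval_index_of(query_pos)
    fi = mask.interval_index_of(focal_pos)
    if qi < 0:
        raise ValueError(f"query position {query_pos} lies outside the exome mask")
    if fi < 0:
        raise ValueError(f"focal position {focal_pos} lies outside the exome mask")
    if qi == fi:
        return mask.interval(qi), mask.interval(fi), None
    ai = qi - 1 if qi > fi else qi + 1
    lo, hi = (ai, qi) if qi > fi else (qi, ai)
    gap = (int(mask.ends[lo]), int(mask.starts[hi]))
    return mask.interval(qi), mask.interval(ai), gap
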