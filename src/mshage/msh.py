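"""Maximum-shared-haplotype (msh) time-of-first-coalescence estimation.

Every copy of a derived allele descends from the haplotype on which the
mutation arose, so around the focal site all carriers share one ancestral
haplotype inherited from their most recent common ancestor. The time of
first coalescence t_c — the carriers' MRCA time, or for a singleton the time
at which its lineage first coalesces with any other sampled lineage — is
used as a proxy for allele age, and is estimated from the extent of that
shared haplotype:

* k >= 2: the msh extends from the focal position outward on each side to
  the nearest assayed site at which the carrier set is *not* monomorphic
  (some pair of carriers differs there); it is the maximal region over which
  all copies of the allele still share a single haplotype, and is identical
  for every copy.
* k = 1 (singleton): the msh is measured against the single best-matching
  partner among all other haplotypes — the tract to the nearest site where
  carrier and partner differ, maximized over partners.

The focal site itself is excluded from the comparison, and a side with no
discordant site before the region boundary is censored at the boundary.

Tract ends are produced by recombination or mutation events since the
common ancestor, which motivates a competing-risks likelihood. With
weighted tract exposure

    S = mu * (left_phys + right_phys) + (left_gen + right_gen)

(physical lengths in bp, genetic lengths in Morgans — both event classes
scale linearly with time depth t) and n observed (non-censored) ends,
events arrive at rate 2t per unit weighted length, so up to constants

    l(t) = n * ln t - 2 t * S      =>      t_c_hat = n / (2 S).

Censored sides contribute exposure but no event; with both sides censored
the likelihood is maximized at t -> 0 and the estimate is flagged undefined
rather than reported. Per-copy observation lists pool through a composite
rule (``pooled_mle`` sums n and S; ``min``/``mean`` reduce per-copy MLEs);
for k >= 2 the per-copy observations coincide, so the rules agree there.

Whole-exome mode: with assayed sites confined to exons, a tract appears to
end at the first discordant *exonic* site even though the terminating event
lies somewhere in the unassayed gap before it. The adjustment re-draws each
non-censored tract end uniformly on the open gap between the exon where the
tract was observed to end and the next exon toward the focal site, then
recomputes the tract lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from ._rng import rng_for, subseed
from .haplotypes import HaplotypeDataset
from .intervals import ExomeMask, GeneticMap, flanking_exons

__all__ = [
    "EstimatorConfig",
    "MshObservation",
    "AgeEstimate",
    "phase_singletons",
    "find_msh",
    "exome_adjust",
    "tc_mle",
    "loglik_tc",
    "estimate_all",
    "estimates_to_frame",
    "write_estimates",
]

logger = logging.getLogger(__name__)

ESTIMATE_COLUMNS = ["position", "k", "tc_hat_gen", "n_copies", "method", "flags"]


@dataclass
class EstimatorConfig:
    """Settings for the t_c estimator.

    ``genetic_map`` wins over ``flat_recomb_rate`` when both are given.
    ``k_range`` restricts estimation to variants with k_min <= k <= k_max
    (inclusive; None = unbounded above).
    """

    mu: float = 1e-8
    genetic_map: GeneticMap | None = None
    flat_recomb_rate: float | None = None
    exome_mode: bool = False
    mask: ExomeMask | None = None
    composite_rule: str = "pooled_mle"
    seed: int = 0
    k_range: tuple[int, int | None] | None = None

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.exome_mode and self.mask is None:
            raise ValueError("exome_mode requires an exome mask")
        if self.composite_rule not in ("pooled_mle", "min", "mean"):
            raise ValueError(f"unknown composite_rule: {self.composite_rule!r}")
        if self.genetic_map is None and self.flat_recomb_rate is None:
            raise ValueError(
                "either a genetic map or a flat recombination rate is required"
            )

    def resolve_map(self, seq_length_bp: int) -> GeneticMap:
        if self.genetic_map is not None:
            return self.genetic_map
        return GeneticMap.from_flat_rate(self.flat_recomb_rate, seq_length_bp)

    def k_bounds(self) -> tuple[int, float]:
        if self.k_range is None:
            return 1, np.inf
        lo, hi = self.k_range
        return max(1, int(lo)), (np.inf if hi is None else int(hi))


@dataclass(slots=True)
class MshObservation:
    """One msh tract: per-side lengths, censoring flags, and partner.

    Physical lengths are in bp (floats after exome adjustment), genetic
    lengths in Morgans. ``left_end_pos``/``right_end_pos`` record the
    terminating positions (the region boundary for censored sides).
    ``partner`` is the best-match haplotype index for singleton tracts and
    -1 for allele-level (k >= 2) tracts, which are bounded by the carrier
    set jointly rather than by one partner.
    """

    left_phys: float
    right_phys: float
    left_gen: float
    right_gen: float
    left_censored: bool
    right_censored: bool
    partner: int
    left_end_pos: float
    right_end_pos: float

    @property
    def n_end(self) -> int:
        """Number of observed (non-censored) tract ends, in {0, 1, 2}."""
        return int(not self.left_censored) + int(not self.right_censored)


@dataclass(slots=True)
class AgeEstimate:
    """One variant's t_c estimate in generations (NaN when undefined)."""

    position: int
    derived_count: int
    t_c_hat: float
    n_copies_used: int
    method: str
    flags: str = "ok"

    @property
    def defined(self) -> bool:
        return self.flags == "ok" and np.isfinite(self.t_c_hat) and self.t_c_hat > 0


# ---------------------------------------------------------------------------
# numba kernels: discordance scans
# ---------------------------------------------------------------------------


@njit(cache=True)
def _first_mismatch(H, a, b, f, step):
    """Nearest site index (excluding f, direction step) where rows a and b
    differ; -1 if none before the matrix edge."""
    j = f + step
    m = H.shape[1]
    while 0 <= j < m:
        if H[a, j] != H[b, j]:
            return j
        j += step
    return -1


@njit(cache=True)
def _tract_bp(positions, L, f, lj, rj):
    fpos = positions[f]
    lp = fpos - 1 if lj < 0 else fpos - positions[lj]
    rp = L - fpos if rj < 0 else positions[rj] - fpos
    return lp + rp


@njit(cache=True)
def _best_partner_all(H, positions, L, f, c, skip_a, skip_b):
    """Best partner for row c among all rows (minus c and the skip rows).

    Returns (partner, left_idx, right_idx, total_bp); ties go to the lowest
    row index because candidates are scanned in ascending order with a
    strict improvement test."""
    n = H.shape[0]
    best = np.int64(-1)
    bb = -1
    bl = -1
    br = -1
    for b in range(n):
        if b == c or b == skip_a or b == skip_b:
            continue
        lj = _first_mismatch(H, c, b, f, -1)
        rj = _first_mismatch(H, c, b, f, 1)
        tot = _tract_bp(positions, L, f, lj, rj)
        if tot > best:
            best, bb, bl, br = tot, b, lj, rj
    return bb, bl, br, best


@njit(cache=True)
def _allele_tract(H, f, carriers):
    """Per-side nearest site where the carriers are not monomorphic.

    Returns (left_idx, right_idx); -1 means no discordant site before the
    matrix edge (censored). This is the boundary of the haplotype shared by
    every copy of the allele."""
    m = H.shape[1]
    k = carriers.shape[0]
    lj = -1
    j = f - 1
    while j >= 0:
        v = H[carriers[0], j]
        poly = False
        for i in range(1, k):
            if H[carriers[i], j] != v:
                poly = True
                break
        if poly:
            lj = j
            break
        j -= 1
    rj = -1
    j = f + 1
    while j < m:
        v = H[carriers[0], j]
        poly = False
        for i in range(1, k):
            if H[carriers[i], j] != v:
                poly = True
                break
        if poly:
            rj = j
            break
        j += 1
    return lj, rj


# ---------------------------------------------------------------------------
# observation assembly
# ---------------------------------------------------------------------------


def _make_obs(
    positions: np.ndarray,
    pos_cm: np.ndarray,
    cm_lo: float,
    cm_hi: float,
    L: int,
    f: int,
    partner: int,
    lj: int,
    rj: int,
) -> MshObservation:
    fpos = float(positions[f])
    fcm = float(pos_cm[f])
    if lj < 0:
        left_end, left_phys, left_gen, left_cen = (
            1.0,
            fpos - 1.0,
            (fcm - cm_lo) / 100.0,
            True,
        )
    else:
        left_end = float(positions[lj])
        left_phys = fpos - left_end
        left_gen = (fcm - float(pos_cm[lj])) / 100.0
        left_cen = False
    if rj < 0:
        right_end, right_phys, right_gen, right_cen = (
            float(L),
            float(L) - fpos,
            (cm_hi - fcm) / 100.0,
            True,
        )
    else:
        right_end = float(positions[rj])
        right_phys = right_end - fpos
        right_gen = (float(pos_cm[rj]) - fcm) / 100.0
        right_cen = False
    return MshObservation(
        left_phys=left_phys,
        right_phys=right_phys,
        left_gen=left_gen,
        right_gen=right_gen,
        left_censored=left_cen,
        right_censored=right_cen,
        partner=int(partner),
        left_end_pos=left_end,
        right_end_pos=right_end,
    )


def _variant_index(ds: HaplotypeDataset, position: int) -> int:
    f = int(np.searchsorted(ds.positions, position))
    if f >= ds.n_sites or ds.positions[f] != position:
        raise KeyError(f"no variant at position {position}")
    return f


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def phase_singletons(ds: HaplotypeDataset, seed: int = 0) -> HaplotypeDataset:
    """Re-place every singleton on the longer of its carrier's two haplotypes.

    Singletons cannot be phased statistically, so each one is assigned to
    whichever of the heterozygous individual's two haplotypes shares the
    longer two-sided physical tract around the focal position with its best
    match among the other individuals' haplotypes. Exact ties are broken by
    a fair coin seeded per variant position. Non-singleton variants are
    untouched; the input is not modified.
    """
    if ds.ploidy != 2:
        logger.warning("phase_singletons: haploid data, nothing to phase")
        return ds
    out = ds.copy()
    H = ds.haplotypes  # decisions are made against the unmodified input,
    # so placements do not depend on the order singletons are visited
    positions = ds.positions
    L = np.int64(ds.seq_length_bp)
    singleton_cols = np.flatnonzero(ds.derived_counts == 1)
    n_flipped = 0
    for f in singleton_cols:
        carrier = int(np.flatnonzero(H[:, f] == 1)[0])
        ind = carrier // 2
        a, b = 2 * ind, 2 * ind + 1
        *_, tot_a = _best_partner_all(
            H, positions, L, np.int64(f), np.int64(a), np.int64(b), np.int64(-1)
        )
        *_, tot_b = _best_partner_all(
            H, positions, L, np.int64(f), np.int64(b), np.int64(a), np.int64(-1)
        )
        if tot_a > tot_b:
            target = a
        elif tot_b > tot_a:
            target = b
        else:
            target = a if rng_for(seed, "phase", positions[f]).random() < 0.5 else b
        if target != carrier:
            out.haplotypes[carrier, f] = 0
            out.haplotypes[target, f] = 1
            n_flipped += 1
    logger.info(
        "phase_singletons: %d singletons, %d re-placed (seed=%d)",
        singleton_cols.size,
        n_flipped,
        seed,
    )
    return out


def find_msh(
    ds: HaplotypeDataset, position: int, copy: int, config: EstimatorConfig
) -> MshObservation:
    """The msh observation for one carrier copy of the variant at ``position``.

    For k >= 2 this is the allele-level shared tract (identical for every
    carrier copy); for singletons, the tract to the best-matching partner
    among all other haplotypes.
    """
    f = _variant_index(ds, position)
    H = ds.haplotypes
    col = H[:, f]
    if col[copy] != 1:
        raise ValueError(
            f"haplotype {copy} does not carry the derived allele at {position}"
        )
    k = int(col.sum())
    L = np.int64(ds.seq_length_bp)
    gmap = config.resolve_map(ds.seq_length_bp)
    pos_cm = gmap.phys_to_cm(ds.positions)
    cm_lo = float(gmap.phys_to_cm(1))
    cm_hi = float(gmap.phys_to_cm(ds.seq_length_bp))
    if k == 1:
        bb, lj, rj, _ = _best_partner_all(
            H, ds.positions, L, np.int64(f), np.int64(copy), np.int64(-1), np.int64(-1)
        )
    else:
        carriers = np.flatnonzero(col).astype(np.int64)
        lj, rj = _allele_tract(H, np.int64(f), carriers)
        bb = -1
    return _make_obs(
        ds.positions, pos_cm, cm_lo, cm_hi, ds.seq_length_bp, f, bb, lj, rj
    )


def exome_adjust(
    obs: MshObservation,
    mask: ExomeMask,
    focal_pos: float,
    seed: int,
    genetic_map: GeneticMap | None = None,
) -> MshObservation:
    """Randomize exome tract ends into the preceding inter-exon gap.

    Each non-censored side whose terminating exon differs from the focal
    site's exon gets a new terminating position drawn uniformly on the open
    gap between that exon and the next exon toward the focal site; lengths
    are recomputed. Sides ending in the focal site's own exon (empty gap)
    and censored sides are unchanged. Draws are independent per side and
    deterministic given ``seed``.
    """
    new = replace(obs)
    for side in ("left", "right"):
        if getattr(obs, f"{side}_censored"):
            continue
        end = getattr(obs, f"{side}_end_pos")
        if mask.interval_index_of(end) < 0:
            raise ValueError(
                f"tract end {end} lies outside the exome mask: input is not "
                "exome-filtered but exome_mode is on"
            )
        _, _, gap = flanking_exons(mask, focal_pos, end)
        if gap is None:
            continue
        g0, g1 = gap
        u = float(rng_for(seed, side).uniform(g0, g1))
        phys = abs(u - focal_pos)
        setattr(new, f"{side}_end_pos", u)
        setattr(new, f"{side}_phys", phys)
        if genetic_map is not None:
            gen = (
                abs(
                    float(genetic_map.phys_to_cm(u))
                    - float(genetic_map.phys_to_cm(focal_pos))
                )
                / 100.0
            )
            setattr(new, f"{side}_gen", gen)
    return new


def _copy_stats(
    obs_list: Sequence[MshObservation], mu: float
) -> tuple[np.ndarray, np.ndarray]:
    n = np.array([o.n_end for o in obs_list], dtype=np.float64)
    s = np.array(
        [mu * (o.left_phys + o.right_phys) + o.left_gen + o.right_gen for o in obs_list],
        dtype=np.float64,
    )
    return n, s


def tc_mle(
    obs_list: Sequence[MshObservation],
    config: EstimatorConfig,
    position: int = -1,
    derived_count: int | None = None,
) -> AgeEstimate:
    """Maximum-likelihood t_c (generations) from one variant's observations.

    Closed form of the competing-risks likelihood: the pooled rule gives
    t = sum(n_i) / (2 * sum(S_i)); ``min``/``mean`` reduce per-copy MLEs.
    All-censored or zero-exposure inputs yield a flagged undefined estimate.
    """
    if not obs_list:
        raise ValueError("tc_mle needs at least one observation")
    method = "wes_msh_adjusted" if config.exome_mode else "wgs_msh"
    k = len(obs_list) if derived_count is None else derived_count
    n, s = _copy_stats(obs_list, config.mu)
    if config.composite_rule == "pooled_mle":
        n_tot, s_tot = n.sum(), s.sum()
        if n_tot == 0 or s_tot <= 0:
            return AgeEstimate(position, k, np.nan, len(obs_list), method, "undefined")
        t_hat = n_tot / (2.0 * s_tot)
    else:
        valid = (n > 0) & (s > 0)
        if not valid.any():
            return AgeEstimate(position, k, np.nan, len(obs_list), method, "undefined")
        per_copy = n[valid] / (2.0 * s[valid])
        t_hat = float(
            per_copy.min() if config.composite_rule == "min" else per_copy.mean()
        )
    return AgeEstimate(position, k, float(t_hat), len(obs_list), method)


def loglik_tc(t: float, obs_list: Sequence[MshObservation], mu: float) -> float:
    """Log-likelihood l(t) = sum(n_i) ln t - 2 t sum(S_i) (up to constants).

    Exposed so the closed-form MLE can be checked by numeric maximization.
    """
    n, s = _copy_stats(obs_list, mu)
    return float(n.sum() * np.log(t) - 2.0 * t * s.sum())


def estimate_all(ds: HaplotypeDataset, config: EstimatorConfig) -> list[AgeEstimate]:
    """t_c estimates for every variant whose k falls in ``config.k_range``.

    Singletons are assumed already phased when the range includes k = 1. In
    exome mode the (shared) tract is adjusted before the MLE; adjustment
    draws are seeded per variant position, so results are independent of
    iteration order.
    """
    if config.exome_mode and config.mask is None:
        raise ValueError("exome_mode requires a mask")
    H = ds.haplotypes
    positions = ds.positions
    L = np.int64(ds.seq_length_bp)
    gmap = config.resolve_map(ds.seq_length_bp)
    pos_cm = gmap.phys_to_cm(positions) if ds.n_sites else np.empty(0)
    cm_lo = float(gmap.phys_to_cm(1))
    cm_hi = float(gmap.phys_to_cm(ds.seq_length_bp))
    k_lo, k_hi = config.k_bounds()
    counts = ds.derived_counts
    estimates: list[AgeEstimate] = []
    n_undefined = 0
    for f in range(ds.n_sites):
        k = int(counts[f])
        if k < k_lo or k > k_hi or k >= ds.n_haplotypes:
            continue
        col = H[:, f]
        if k == 1:
            c = int(np.flatnonzero(col)[0])
            bb, lj, rj, _ = _best_partner_all(
                H, positions, L, np.int64(f), np.int64(c), np.int64(-1), np.int64(-1)
            )
        else:
            carriers = np.flatnonzero(col).astype(np.int64)
            lj, rj = _allele_tract(H, np.int64(f), carriers)
            bb = -1
        obs = _make_obs(positions, pos_cm, cm_lo, cm_hi, ds.seq_length_bp, f, bb, lj, rj)
        fpos = int(positions[f])
        if config.exome_mode:
            obs = exome_adjust(
                obs,
                config.mask,
                fpos,
                subseed(config.seed, "adjust", fpos),
                genetic_map=gmap,
            )
        # every copy contributes the same (shared) observation for k >= 2
        est = tc_mle([obs] * k, config, position=fpos, derived_count=k)
        if not est.defined:
            n_undefined += 1
        estimates.append(est)
    logger.info(
        "estimate_all: %d variants estimated (%d undefined) mode=%s seed=%d",
        len(estimates),
        n_undefined,
        "WES-adjusted" if config.exome_mode else "WGS",
        config.seed,
    )
    return estimates


# ---------------------------------------------------------------------------
# estimate table I/O
# ---------------------------------------------------------------------------


def estimates_to_frame(estimates: Iterable[AgeEstimate]) -> pd.DataFrame:
    rows = [
        (e.position, e.derived_count, e.t_c_hat, e.n_copies_used, e.method, e.flags)
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def write_estimates(estimates: Iterable[AgeEstimate], path) -> None:
    estimates_to_frame(estimates).to_csv(path, sep="\t", index=False)
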