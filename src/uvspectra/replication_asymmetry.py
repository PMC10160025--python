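"""Replicative (leading/lagging strand) mutation asymmetry.

Each mutation is placed fractionally between its two flanking replication
origins; assuming forks move outward from origins, positions in the first
half of an inter-origin interval are replicated by a rightward-moving fork
and positions in the second half by a leftward-moving fork. For a pair of
complementary substitution types read on the reference top strand (e.g.
C>T vs G>A — the pyrimidine collapse used for spectra is deliberately NOT
applied here, since it erases exactly the strand information this analysis
measures), a strand preference of mutagenic bypass shows up as opposite
linear trends of the two members' fractional abundance along the
inter-origin axis: the characteristic "cross".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MutationRecord, OriginMap

#: complementary top-strand substitution pairs (member 1 is pyrimidine-ref)
COMPLEMENTARY_PAIRS = (
    ("C>A", "G>T"),
    ("C>G", "G>C"),
    ("C>T", "G>A"),
    ("T>A", "A>T"),
    ("T>C", "A>G"),
    ("T>G", "A>C"),
)


@dataclass(frozen=True)
class InterOriginPlacement:
    record: MutationRecord
    left_origin: int
    right_origin: int
    fraction: float  # (pos - left) / (right - left), in [0, 1]

    @property
    def zone(self) -> str | None:
        """'rightward-fork' below the midpoint, 'leftward-fork' above, None at a tie."""
        if self.fraction < 0.5:
            return "rightward-fork"
        if self.fraction > 0.5:
            return "leftward-fork"
        return None


def place_between_origins(
    record: MutationRecord, origins: OriginMap
) -> InterOriginPlacement | None:
    """Fractional position of a mutation between its flanking origins.

    Returns None (exclusion, not failure) for mutations on chromosomes with
    fewer than two origins or outside the outermost origins.
    """
    if record.chrom not in origins:
        return None
    arr = origins.positions[record.chrom]
    if arr.size < 2:
        return None
    pos0 = record.pos - 1
    if pos0 < arr[0] or pos0 > arr[-1]:
        return None
    idx = int(np.searchsorted(arr, pos0, side="right"))
    if idx == arr.size:  # exactly on the last origin
        idx -= 1
    left, right = int(arr[idx - 1]), int(arr[idx])
    fraction = (pos0 - left) / (right - left)
    return InterOriginPlacement(record, left, right, float(fraction))


def top_strand_substitution(record: MutationRecord) -> str:
    """Uncollapsed substitution as read on the reference top strand."""
    if record.mclass != "single":
        raise ValueError("top-strand typing applies to single-base records")
    return f"{record.ref}>{record.alt}"


@dataclass
class CrossProfile:
    """Binned fractional abundance of a complementary pair with fitted slopes."""

    pair: tuple[str, str]
    bins: pd.DataFrame  # bin, midpoint, n_member1, n_member2, fraction1
    slope1: float
    intercept1: float
    slope2: float
    intercept2: float
    slope_diff: float
    slope_diff_ci: tuple[float, float]
    slope1_ci: tuple[float, float]
    n_mutations: int


def _fit_fraction(midpoints: np.ndarray, frac1: np.ndarray, valid: np.ndarray):
    """Unweighted least-squares line through per-bin member-1 fractions."""
    x, y = midpoints[valid], frac1[valid]
    if x.size < 2:
        return np.nan, np.nan
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def cross_profile(
    fractions: Sequence[float],
    members: Sequence[int],
    pair: tuple[str, str] = ("C>T", "G>A"),
    n_bins: int = 10,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
) -> CrossProfile:
    """Cross profile of one complementary pair along the inter-origin axis.

    ``fractions`` are inter-origin fractional positions in [0, 1];
    ``members`` is 0 for the pair's first member and 1 for the second as read
    on the top strand. Per bin (with nonzero total) the two members'
    fractions sum to one; each member's fraction is fit against the bin
    midpoint by unweighted least squares. Uncertainty of the member-1 slope
    (and the slope difference) comes from a seeded bootstrap that resamples
    mutations.
    """
    fractions = np.asarray(fractions, float)
    members = np.asarray(members, int)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if fractions.shape != members.shape:
        raise ValueError("fractions and members must align")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    midpoints = (edges[:-1] + edges[1:]) / 2
    bin_idx = np.clip(np.digitize(fractions, edges[1:-1]), 0, n_bins - 1)

    counts = np.zeros((n_bins, 2), dtype=float)
    np.add.at(counts, (bin_idx, members), 1.0)
    totals = counts.sum(axis=1)
    valid = totals > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac1 = np.where(valid, counts[:, 0] / np.where(valid, totals, 1), np.nan)

    slope1, intercept1 = _fit_fraction(midpoints, frac1, valid)
    slope2, intercept2 = _fit_fraction(midpoints, 1 - frac1, valid)

    n = fractions.size
    rng = np.random.default_rng(seed)
    boot_slopes = np.empty(n_bootstrap)
    cell_p = counts.ravel() / max(n, 1)
    for b in range(n_bootstrap):
        resampled = rng.multinomial(n, cell_p).reshape(n_bins, 2)
        t = resampled.sum(axis=1)
        v = t > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = resampled[:, 0] / np.where(v, t, 1)
        s, _ = _fit_fraction(midpoints, f1, v)
        boot_slopes[b] = s
    boot_slopes = boot_slopes[~np.isnan(boot_slopes)]
    if boot_slopes.size:
        lo, hi = np.percentile(boot_slopes, [2.5, 97.5])
    else:
        lo = hi = np.nan
    # member 2's fraction is 1 - member 1's, so the slope difference is 2*slope1
    slope1_ci = (float(lo), float(hi))
    diff_ci = (2 * float(lo), 2 * float(hi))

    table = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "midpoint": midpoints,
            "n_member1": counts[:, 0].astype(int),
            "n_member2": counts[:, 1].astype(int),
            "fraction1": frac1,
        }
    )
    return CrossProfile(
        pair=tuple(pair),
        bins=table,
        slope1=slope1,
        intercept1=intercept1,
        slope2=slope2,
        intercept2=intercept2,
        slope_diff=slope1 - slope2,
        slope_diff_ci=diff_ci,
        slope1_ci=slope1_ci,
        n_mutations=int(n),
    )


def replication_cross(
    records: Sequence[MutationRecord],
    origins: OriginMap,
    pair: tuple[str, str] = ("C>T", "G>A"),
    n_bins: int = 10,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
) -> CrossProfile:
    """Place single-base records between origins and profile one pair."""
    fractions, members = collect_pair(records, origins, pair)
    return cross_profile(fractions, members, pair, n_bins, n_bootstrap, seed)


def collect_pair(
    records: Sequence[MutationRecord],
    origins: OriginMap,
    pair: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-origin fractions and member indices for one complementary pair."""
    fractions, members = [], []
    for r in records:
        if r.mclass != "single":
            continue
        sub = top_strand_substitution(r)
        if sub not in pair:
            continue
        placement = place_between_origins(r, origins)
        if placement is None:
            continue
        fractions.append(placement.fraction)
        members.append(pair.index(sub))
    return np.asarray(fractions, float), np.asarray(members, int)
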