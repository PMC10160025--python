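"""Colony-count arithmetic for reversion-reporter and CAN1 assays.

Reversion frequency is revertants divided by viable (surviving) cells
plated. When no revertants are observed, the frequency of a single
revertant among the cells plated (1/N) is reported as a maximum estimated
reversion frequency and flagged as an upper bound; fold changes whose
numerator or denominator rests on such an estimate carry a bound flag
rather than pretending to be exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import mann_whitney


class InvalidExperimentError(ValueError):
    pass


@dataclass(frozen=True)
class ReversionExperiment:
    """One plating: revertant colonies vs viable cells plated."""

    strain: str
    revertant_count: int
    survivors_plated: float

    def __post_init__(self):
        if self.revertant_count < 0:
            raise InvalidExperimentError("negative revertant count")
        if self.survivors_plated <= 0:
            raise InvalidExperimentError("survivors_plated must be positive")

    @property
    def frequency(self) -> float:
        f, _ = reversion_frequency(self.revertant_count, self.survivors_plated)
        return f

    @property
    def is_upper_estimate(self) -> bool:
        return self.revertant_count == 0


def reversion_frequency(revertants: int, survivors: float) -> tuple[float, bool]:
    """(frequency, is_upper_estimate).

    revertants / survivors; with zero revertants, the maximum estimated
    frequency 1/survivors (one revertant among the cells plated) is returned
    and flagged as an upper estimate.
    """
    if survivors <= 0:
        raise InvalidExperimentError("survivors must be positive")
    if revertants < 0:
        raise InvalidExperimentError("negative revertant count")
    if revertants == 0:
        return 1.0 / survivors, True
    return revertants / survivors, False


DEFAULT_COUNTABLE = (30, 300)


def survivors_from_dilutions(
    plates: Sequence[tuple[int, float]],
    countable: tuple[int, int] = DEFAULT_COUNTABLE,
) -> float:
    """Viable cells plated, from a serial-dilution colony count series.

    Each plate is (colonies, dilution); each countable plate estimates
    colonies/dilution viable cells in the undiluted suspension, and the
    estimates are averaged. Plates outside the countable window
    (default 30-300 colonies) are ignored unless no plate is countable,
    in which case all plates with at least one colony are used.

    Assumes the same volume was plated at every dilution and on the
    selective plate.
    """
    if not plates:
        raise InvalidExperimentError("no dilution plates supplied")
    for colonies, dilution in plates:
        if colonies < 0 or not 0 < dilution <= 1:
            raise InvalidExperimentError(f"bad plate ({colonies}, {dilution})")
    lo, hi = countable
    usable = [(c, d) for c, d in plates if lo <= c <= hi]
    if not usable:
        usable = [(c, d) for c, d in plates if c > 0]
    if not usable:
        raise InvalidExperimentError("no plate with any colonies; titer undefined")
    return float(np.mean([c / d for c, d in usable]))


@dataclass(frozen=True)
class FoldChange:
    value: float
    #: 'exact' when neither group's median rests on a zero-revertant upper
    #: estimate; 'at_least' when the denominator does (true fold >= value),
    #: 'at_most' when the numerator does, 'bound_both' when both do.
    flag: str

    def __float__(self) -> float:
        return self.value


def _median_with_flag(exps: Sequence[ReversionExperiment]) -> tuple[float, bool]:
    freqs = np.array([e.frequency for e in exps], float)
    uppers = np.array([e.is_upper_estimate for e in exps], bool)
    order = np.argsort(freqs, kind="stable")
    n = len(freqs)
    if n % 2:
        mid = [order[n // 2]]
    else:
        mid = [order[n // 2 - 1], order[n // 2]]
    return float(np.median(freqs)), bool(uppers[mid].any())


def fold_change(
    group_a: Sequence[ReversionExperiment],
    group_b: Sequence[ReversionExperiment],
    summary: str = "median",
) -> FoldChange:
    """Ratio of group frequency summaries (a over b), default median.

    If the median of either group involves a zero-revertant upper estimate
    the result is a bound, flagged accordingly.
    """
    if not group_a or not group_b:
        raise InvalidExperimentError("both groups must be non-empty")
    if summary == "median":
        ma, ua = _median_with_flag(group_a)
        mb, ub = _median_with_flag(group_b)
    elif summary == "mean":
        ma = float(np.mean([e.frequency for e in group_a]))
        mb = float(np.mean([e.frequency for e in group_b]))
        ua = any(e.is_upper_estimate for e in group_a)
        ub = any(e.is_upper_estimate for e in group_b)
    else:
        raise ValueError(f"unknown summary {summary!r}")
    if mb == 0:
        raise InvalidExperimentError("denominator group summary is zero")
    flag = {(False, False): "exact", (False, True): "at_least",
            (True, False): "at_most", (True, True): "bound_both"}[(ua, ub)]
    return FoldChange(ma / mb, flag)


def compare_groups_mw(
    group_a: Sequence[ReversionExperiment | float],
    group_b: Sequence[ReversionExperiment | float],
) -> float:
    """Two-sided Mann-Whitney p on reversion frequencies (exact for n <= 8)."""
    a = [e.frequency if isinstance(e, ReversionExperiment) else float(e) for e in group_a]
    b = [e.frequency if isinstance(e, ReversionExperiment) else float(e) for e in group_b]
    if min(len(a), len(b)) < 2:
        warnings.warn("single-observation group: the rank test has no power", stacklevel=2)
    return mann_whitney(a, b)


@dataclass(frozen=True)
class CanavanineExperiment:
    canR_colonies: int
    dilution_can: float
    sc_colonies: int
    dilution_sc: float

    def __post_init__(self):
        if self.canR_colonies < 0 or self.sc_colonies < 0:
            raise InvalidExperimentError("negative colony count")
        for d in (self.dilution_can, self.dilution_sc):
            if not 0 < d <= 1:
                raise InvalidExperimentError("dilutions must be in (0, 1]")

    @property
    def frequency(self) -> float:
        return can1_frequency(self)[0]


def can1_frequency(exp: CanavanineExperiment) -> tuple[float, bool]:
    """Canavanine-resistance frequency: (canR x dilution_sc) / (sc x dilution_can).

    Returns (frequency, zero_count_flag); zero CanR colonies give frequency 0
    with the flag set (no upper-estimate rule is applied here).
    """
    if exp.sc_colonies == 0:
        raise InvalidExperimentError("zero SC colonies; titer undefined")
    freq = (exp.canR_colonies * exp.dilution_sc) / (exp.sc_colonies * exp.dilution_can)
    return freq, exp.canR_colonies == 0
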