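"""Strand-collapsed substitution spectra and spectrum-level statistics.

Single-base substitutions are collapsed onto the pyrimidine strand, giving
the standard 96 (substitution, trinucleotide-context) channels. Tandem
(doublet) substitutions are collapsed over reverse complement into the
standard 78-class space, using the conventional priority set of reference
dinucleotides so that the familiar labels (AC>TT, CC>TT, CT>TA) are the
canonical representatives.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dna import revcomp
from .io_formats import (
    ContextUnavailableError,
    Genome,
    MutationRecord,
    get_trinucleotide_context,
)

BASES = "ACGT"

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class SbsClass(NamedTuple):
    """One of the 96 pyrimidine-collapsed single-base substitution channels."""

    substitution: str  # e.g. "C>T"
    context: str  # 3-mer whose middle base is the substitution's ref base

    @property
    def label(self) -> str:
        l, m, r = self.context
        return f"{l}[{self.substitution}]{r}"

    def __str__(self) -> str:
        return self.label


class TandemClass(NamedTuple):
    """Canonical doublet-substitution class, e.g. AC>TT."""

    ref: str
    alt: str

    @property
    def label(self) -> str:
        return f"{self.ref}>{self.alt}"

    def __str__(self) -> str:
        return self.label


def _enumerate_sbs96() -> list[SbsClass]:
    classes = []
    for sub in SUBSTITUTIONS:
        ref = sub[0]
        for left, right in itertools.product(BASES, BASES):
            classes.append(SbsClass(sub, left + ref + right))
    return classes


#: reference dinucleotides chosen as canonical representatives of each
#: reverse-complement pair (the conventional doublet-signature priority set)
CANONICAL_TANDEM_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")

_PALINDROMIC_REFS = frozenset(r for r in CANONICAL_TANDEM_REFS if revcomp(r) == r)


def canonical_tandem(ref: str, alt: str) -> TandemClass:
    """Collapse a top-strand doublet substitution into its canonical class.

    Non-canonical reference dinucleotides are reverse-complemented (GT>AA
    becomes AC>TT); for palindromic references (AT, CG, GC, TA) the
    lexicographically smaller of alt and its reverse complement is kept.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref in _PALINDROMIC_REFS:
        return TandemClass(ref, min(alt, revcomp(alt)))
    if ref in CANONICAL_TANDEM_REFS:
        return TandemClass(ref, alt)
    return TandemClass(revcomp(ref), revcomp(alt))


def _enumerate_dbs78() -> list[TandemClass]:
    classes = set()
    for ref in CANONICAL_TANDEM_REFS:
        for a1, a2 in itertools.product(BASES, BASES):
            if a1 == ref[0] or a2 == ref[1]:
                continue  # both positions must be substituted
            classes.add(canonical_tandem(ref, a1 + a2))
    return sorted(classes)


SBS96_CLASSES: tuple[SbsClass, ...] = tuple(_enumerate_sbs96())
DBS78_CLASSES: tuple[TandemClass, ...] = tuple(_enumerate_dbs78())

assert len(SBS96_CLASSES) == 96
assert len(DBS78_CLASSES) == 78


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_single(record: MutationRecord, genome: Genome) -> SbsClass:
    """Pyrimidine-collapsed class of a single-base substitution.

    If the reference base is a purine, both the substitution and its
    trinucleotide context are reverse-complemented before classification.
    Raises :class:`ContextUnavailableError` at chromosome edges or N bases.
    """
    if record.mclass != "single":
        raise ValueError(f"classify_single got a {record.mclass} record")
    context = get_trinucleotide_context(genome, record.chrom, record.pos)
    ref, alt = record.ref, record.alt
    if ref in "AG":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return SbsClass(f"{ref}>{alt}", context)


def classify_tandem(record: MutationRecord, genome: Genome | None = None) -> TandemClass:
    """Canonical class of a tandem (adjacent doublet) substitution."""
    if record.mclass != "tandem":
        raise ValueError(f"classify_tandem got a {record.mclass} record")
    return canonical_tandem(record.ref, record.alt)


# ---------------------------------------------------------------------------
# Spectrum container
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """Count matrix (classes x isolates) with per-class summary statistics.

    ``mean`` and ``sd`` are taken across isolates; the SD is the sample
    (n-1) standard deviation.
    """

    counts: pd.DataFrame
    n_excluded_context: int = 0

    @property
    def isolates(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def class_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def per_isolate_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def mean(self) -> pd.Series:
        return self.counts.mean(axis=1)

    @property
    def sd(self) -> pd.Series:
        return self.counts.std(axis=1, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["mean"] = self.mean
        out["sd"] = self.sd
        return out


class EmptySpectrumError(ValueError):
    pass


def build_spectra(
    records: Sequence[MutationRecord], genome: Genome
) -> tuple[Spectrum, Spectrum, int]:
    """Build per-isolate SBS-96 and tandem-78 spectra.

    Returns ``(sbs, tandem, n_multi)`` where ``n_multi`` counts excluded
    runs of three or more adjacent substitutions. Singles whose context is
    unavailable are excluded and counted on the SBS spectrum.
    """
    isolates = sorted({r.isolate for r in records})
    if not isolates:
        raise EmptySpectrumError("no records, cannot build a spectrum")

    sbs_labels = [c.label for c in SBS96_CLASSES]
    dbs_labels = [c.label for c in DBS78_CLASSES]
    sbs = pd.DataFrame(0, index=sbs_labels, columns=isolates, dtype=int)
    dbs = pd.DataFrame(0, index=dbs_labels, columns=isolates, dtype=int)

    n_multi = 0
    n_ctx_excluded = 0
    for r in records:
        if r.mclass == "multi":
            n_multi += 1
            continue
        if r.mclass == "single":
            try:
                cls = classify_single(r, genome)
            except ContextUnavailableError:
                n_ctx_excluded += 1
                continue
            sbs.loc[cls.label, r.isolate] += 1
        else:
            dbs.loc[classify_tandem(r).label, r.isolate] += 1

    return Spectrum(sbs, n_ctx_excluded), Spectrum(dbs), n_multi


# ---------------------------------------------------------------------------
# Spectrum-level statistics
# ---------------------------------------------------------------------------


def median_density_fold(a: Sequence[float], b: Sequence[float]) -> float:
    """median(a) / median(b) — fold change in per-isolate substitution burden."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mb = float(np.median(b))
    if mb == 0:
        raise ZeroDivisionError("median of denominator group is zero; fold undefined")
    return float(np.median(a)) / mb


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    dof: int
    n_classes: int  # retained classes after zero-drop and low-expected merging


def compare_spectra_chi2(
    a: pd.Series | Sequence[float],
    b: pd.Series | Sequence[float],
    min_expected: float = 5.0,
) -> Chi2Result:
    """Two-sided chi-square comparison of two pooled class-count spectra.

    A 2 x K contingency test on the retained classes. Classes at zero in both
    groups are dropped; classes whose smaller expected count falls below
    ``min_expected`` are merged into a single "other" class to keep the
    asymptotic test valid.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("spectra must have identical class spaces")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size >= 2:
        table = np.vstack([a, b])
        expected = stats.contingency.expected_freq(table)
        low = expected.min(axis=0) < min_expected
        if low.any() and (~low).sum() >= 1:
            a = np.append(a[~low], a[low].sum())
            b = np.append(b[~low], b[low].sum())
    if a.size < 2:
        raise ValueError("fewer than 2 classes retained; chi-square undefined")
    stat, p, dof, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return Chi2Result(float(stat), float(p), int(dof), int(a.size))


def correlate_spectra(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (rho, two-sided p) between two class-count vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length over identical classes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a spectrum; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

EXACT_MAX_N = 8


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Groups of up to 8 per side are compared by exact enumeration of all
    rank assignments (midranks for ties, no continuity correction); larger
    groups use the normal approximation with tie correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if max(a.size, b.size) <= EXACT_MAX_N:
        return _exact_mw_p(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def _exact_mw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumerating all C(n_a+n_b, n_a) rank assignments.

    The p-value is the fraction of assignments whose U statistic is at least
    as far from its null mean as the observed one.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n = a.size, pooled.size
    mu = n_a * (n - n_a) / 2.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    d_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
        if abs(u - mu) >= d_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def compare_density_mw(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney comparison of per-isolate mutation burdens."""
    return mann_whitney(a, b)
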