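"""Transcriptional strand asymmetry of mutation classes.

Each genic mutation is assigned to the non-transcribed strand (NTS, the
coding / mRNA-like strand) or the transcribed strand (TS, the template) by
asking which strand carries the mutated pyrimidine after strand collapse.
Because the two strands of a gene do not contain equal numbers of every
trinucleotide, the observed NTS/TS split of each mutation class is tested
against the split expected from the per-strand context frequencies over all
gene bodies, with a 1-df chi-square goodness-of-fit test and Bonferroni
correction across the tested classes.

Regions covered by more than one annotated gene are masked from both the
mutation assignment and the context-frequency denominator: strand identity
is undefined there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dna import revcomp
from .io_formats import GeneInterval, Genome, MutationRecord
from .spectra import (
    BASES,
    CANONICAL_TANDEM_REFS,
    _PALINDROMIC_REFS,
    classify_single,
    classify_tandem,
    ContextUnavailableError,
)

DEFAULT_MIN_COUNT = 30


# ---------------------------------------------------------------------------
# Strand assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrandAssignment:
    record: MutationRecord
    gene: GeneInterval | None
    strand_call: str  # NTS | TS | intergenic | ambiguous


class GeneIndex:
    """Interval lookup over gene bodies, tracking multi-gene overlap."""

    def __init__(self, genes: Sequence[GeneInterval]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def hits(self, chrom: str, pos0: int) -> list[GeneInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[pos0]]


def _pyrimidine_strand(record: MutationRecord) -> str | None:
    """Strand ('+'/'-') carrying the canonical (pyrimidine-collapsed) allele.

    For tandems this is the strand on which the reference dinucleotide reads
    in its canonical orientation; palindromic tandem references (e.g. TA) are
    strand-ambiguous and return None.
    """
    if record.mclass == "single":
        return "+" if record.ref in "CT" else "-"
    if record.mclass == "tandem":
        if record.ref in _PALINDROMIC_REFS or revcomp(record.ref) == record.ref:
            return None
        return "+" if record.ref in CANONICAL_TANDEM_REFS else "-"
    return None


def assign_strand(record: MutationRecord, genes: GeneIndex | Sequence[GeneInterval]) -> StrandAssignment:
    """NTS/TS call for one mutation (tandems use their 5' position).

    A mutation is NTS when its collapsed pyrimidine lies on the gene's coding
    strand, TS when it lies on the template strand. Positions covered by more
    than one gene, or strand-undecidable tandems, are called ambiguous.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    hits = index.hits(record.chrom, record.pos - 1)
    if not hits:
        return StrandAssignment(record, None, "intergenic")
    if len(hits) > 1:
        return StrandAssignment(record, None, "ambiguous")
    gene = hits[0]
    pyr = _pyrimidine_strand(record)
    if pyr is None:
        return StrandAssignment(record, gene, "ambiguous")
    call = "NTS" if pyr == gene.strand else "TS"
    return StrandAssignment(record, gene, call)


# ---------------------------------------------------------------------------
# Per-strand context frequencies
# ---------------------------------------------------------------------------


@dataclass
class StrandContextFrequencies:
    """k-mer occurrence counts on the NTS (coding) and TS of all gene bodies."""

    nts: pd.Series
    ts: pd.Series

    def expected_nts_fraction(self, context: str) -> float:
        n, t = float(self.nts.get(context, 0)), float(self.ts.get(context, 0))
        if n + t == 0:
            raise ValueError(f"context {context!r} absent from gene bodies")
        return n / (n + t)


def strand_context_frequencies(
    genome: Genome, genes: Sequence[GeneInterval], k: int = 3
) -> StrandContextFrequencies:
    """Count k-mers on the coding strand (NTS) of every gene body.

    Windows overlapping a region covered by more than one gene, or containing
    N, are excluded. TS counts are the coding-strand counts of the reverse
    complement k-mer, so NTS[x] == TS[revcomp(x)] by construction.
    """
    kmers = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    nts = dict.fromkeys(kmers, 0)

    coverage: dict[str, np.ndarray] = {}
    for g in genes:
        cov = coverage.setdefault(g.chrom, np.zeros(genome.lengths[g.chrom], dtype=np.int32))
        cov[g.start : g.end] += 1

    for g in genes:
        seq = genome.slice(g.chrom, g.start, g.end)
        single = coverage[g.chrom][g.start : g.end] == 1
        if g.strand == "-":
            seq = revcomp(seq)
            single = single[::-1]
        for i in range(len(seq) - k + 1):
            if not single[i : i + k].all():
                continue
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            nts[kmer] += 1

    nts_series = pd.Series(nts, dtype=float)
    ts_series = pd.Series({km: nts[revcomp(km)] for km in kmers}, dtype=float)
    return StrandContextFrequencies(nts_series, ts_series)


# ---------------------------------------------------------------------------
# Asymmetry test
# ---------------------------------------------------------------------------


@dataclass
class StrandAsymmetryResult:
    label: str
    n_nts: int
    n_ts: int
    e_nts: float | None = None
    e_ts: float | None = None
    normalized_ratio: float | None = None
    chi2: float | None = None
    p_raw: float | None = None
    p_bonf: float | None = None
    tested: bool = False


def asymmetry_test(
    n_nts: int,
    n_ts: int,
    e_fraction_nts: float,
    m: int = 1,
    min_count: int = DEFAULT_MIN_COUNT,
    label: str = "",
) -> StrandAsymmetryResult:
    """1-df goodness-of-fit test of an NTS/TS split against its expected split.

    ``e_fraction_nts`` is the fraction of the class's genic sites on the NTS
    (from :func:`strand_context_frequencies`); ``m`` is the Bonferroni family
    size. Classes with fewer than ``min_count`` mutations are not tested.
    The normalized ratio (n_nts/e_nts)/(n_ts/e_ts) equals 1 whenever the
    observed split matches the composition-derived expectation.
    """
    if not 0 < e_fraction_nts < 1:
        raise ValueError("expected NTS fraction must be in (0, 1)")
    total = n_nts + n_ts
    if total < min_count:
        return StrandAsymmetryResult(label, n_nts, n_ts, tested=False)
    e_nts = total * e_fraction_nts
    e_ts = total - e_nts
    chi2 = (n_nts - e_nts) ** 2 / e_nts + (n_ts - e_ts) ** 2 / e_ts
    p_raw = float(stats.chi2.sf(chi2, df=1))
    ratio = (n_nts / e_nts) / (n_ts / e_ts) if n_ts > 0 else float("inf")
    return StrandAsymmetryResult(
        label=label,
        n_nts=n_nts,
        n_ts=n_ts,
        e_nts=float(e_nts),
        e_ts=float(e_ts),
        normalized_ratio=float(ratio),
        chi2=float(chi2),
        p_raw=p_raw,
        p_bonf=min(1.0, p_raw * m),
        tested=True,
    )


# ---------------------------------------------------------------------------
# Whole-dataset driver
# ---------------------------------------------------------------------------


def transcriptional_asymmetry(
    records: Sequence[MutationRecord],
    genome: Genome,
    genes: Sequence[GeneInterval],
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """NTS/TS asymmetry table over all (class, context) combinations.

    Singles are grouped by their pyrimidine-collapsed (substitution, context)
    class, tandems by their canonical doublet class. The Bonferroni family
    size is the number of classes reaching ``min_count`` genic mutations.
    """
    index = GeneIndex(genes)
    counts: dict[str, list[int]] = {}
    for r in records:
        if r.mclass == "multi":
            continue
        asg = assign_strand(r, index)
        if asg.strand_call not in ("NTS", "TS"):
            continue
        try:
            if r.mclass == "single":
                label = classify_single(r, genome).label
            else:
                label = classify_tandem(r).label
        except ContextUnavailableError:
            continue
        pair = counts.setdefault(label, [0, 0])
        pair[0 if asg.strand_call == "NTS" else 1] += 1

    freqs3 = strand_context_frequencies(genome, genes, k=3)
    freqs2 = strand_context_frequencies(genome, genes, k=2)

    m = sum(1 for n_nts, n_ts in counts.values() if n_nts + n_ts >= min_count)
    rows = []
    for label, (n_nts, n_ts) in sorted(counts.items()):
        if "[" in label:  # single-base class like "T[C>T]A"
            context = label[0] + label[2] + label[-1]
            e_frac = freqs3.expected_nts_fraction(context)
        else:  # tandem class like "AC>TT"
            e_frac = freqs2.expected_nts_fraction(label.split(">")[0])
        res = asymmetry_test(n_nts, n_ts, e_frac, m=m, min_count=min_count, label=label)
        rows.append(
            {
                "label": res.label,
                "n_nts": res.n_nts,
                "n_ts": res.n_ts,
                "e_nts": res.e_nts,
                "e_ts": res.e_ts,
                "normalized_ratio": res.normalized_ratio,
                "chi2": res.chi2,
                "p_raw": res.p_raw,
                "p_bonf": res.p_bonf,
                "tested": res.tested,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "n_nts", "n_ts", "e_nts", "e_ts",
            "normalized_ratio", "chi2", "p_raw", "p_bonf", "tested",
        ],
    )


def nts_fraction_profile(
    records: Sequence[MutationRecord],
    genome: Genome,
    genes: Sequence[GeneInterval],
) -> pd.DataFrame:
    """Per (substitution, context) fraction of genic singles on the NTS.

    All 96 channels are reported; contexts with no genic mutations are
    flagged n.d. (fraction NaN).
    """
    from .spectra import SBS96_CLASSES

    index = GeneIndex(genes)
    counts: dict[tuple[str, str], list[int]] = {
        (c.substitution, c.context): [0, 0] for c in SBS96_CLASSES
    }
    for r in records:
        if r.mclass != "single":
            continue
        asg = assign_strand(r, index)
        if asg.strand_call not in ("NTS", "TS"):
            continue
        try:
            cls = classify_single(r, genome)
        except ContextUnavailableError:
            continue
        pair = counts.setdefault((cls.substitution, cls.context), [0, 0])
        pair[0 if asg.strand_call == "NTS" else 1] += 1

    rows = []
    for (sub, ctx), (n_nts, n_ts) in sorted(counts.items()):
        total = n_nts + n_ts
        rows.append(
            {
                "substitution": sub,
                "context": ctx,
                "n_nts": n_nts,
                "n_ts": n_ts,
                "fraction_nts": n_nts / total if total else np.nan,
                "nd": total == 0,
            }
        )
    return pd.DataFrame(
        rows, columns=["substitution", "context", "n_nts", "n_ts", "fraction_nts", "nd"]
    )
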