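import itertools

import numpy as np
import pytest
from scipy import stats

import uvspectra as uv
from uvspectra.spectra import EXACT_MAX_N, _exact_mw_p


# independent reverse-complement oracle, deliberately not using uvspectra.dna
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(s):
    return "".join(_COMP[b] for b in reversed(s))


# ---------------------------------------------------------------------------
# single-base classification
# ---------------------------------------------------------------------------


def test_classify_purine_ref_is_reverse_complemented():
    genome = uv.make_genome({"chrT": "ACGTA"})
    cls = uv.classify_single(uv.MutationRecord("chrT", 3, "G", "T", "i"), genome)
    assert (cls.substitution, cls.context) == ("C>A", "ACG")


@pytest.mark.parametrize(
    "seq,ref,alt,sub,ctx",
    [("TTCAA", "C", "T", "C>T", "TCA"), ("AATAA", "T", "A", "T>A", "ATA")],
)
def test_classify_pyrimidine_ref_is_identity(seq, ref, alt, sub, ctx):
    genome = uv.make_genome({"chrT": seq})
    cls = uv.classify_single(uv.MutationRecord("chrT", 3, ref, alt, "i"), genome)
    assert (cls.substitution, cls.context) == (sub, ctx)


def test_classification_involution_all_96():
    """A channel and its reverse-complement description classify identically."""
    for cls in uv.SBS96_CLASSES:
        ref, alt = cls.substitution[0], cls.substitution[2]
        # forward orientation
        genome_f = uv.make_genome({"c": cls.context})
        got_f = uv.classify_single(uv.MutationRecord("c", 2, ref, alt, "i"), genome_f)
        # reverse-complement orientation of the same event
        genome_r = uv.make_genome({"c": _rc(cls.context)})
        got_r = uv.classify_single(
            uv.MutationRecord("c", 2, _rc(ref), _rc(alt), "i"), genome_r
        )
        assert got_f == got_r == cls


# ---------------------------------------------------------------------------
# tandem classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ref,alt,want", [("GT", "AA", "AC>TT"), ("CC", "TT", "CC>TT"), ("AG", "TA", "CT>TA")]
)
def test_canonical_tandem_examples(ref, alt, want):
    assert uv.canonical_tandem(ref, alt).label == want


def test_tandem_space_is_78_and_collapse_is_involutive():
    """Brute-force enumeration of all 144 doublets collapses onto 78 classes,
    and a doublet and its reverse complement always map to the same class."""
    seen = set()
    for ref in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
        for alt in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
            if alt[0] == ref[0] or alt[1] == ref[1]:
                continue
            cls = uv.canonical_tandem(ref, alt)
            assert cls == uv.canonical_tandem(_rc(ref), _rc(alt))
            assert cls in uv.DBS78_CLASSES
            seen.add(cls)
    assert len(seen) == 78 == len(uv.DBS78_CLASSES)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def _rec(chrom, pos, ref, alt, iso="i1", mclass="single"):
    return uv.MutationRecord(chrom, pos, ref, alt, iso, mclass)


def test_build_spectra_counts_and_sd():
    genome = uv.make_genome({"c1": "ACGTA", "c2": "TTCAA", "c3": "AATAA"})
    recs = [
        _rec("c1", 3, "G", "T"),  # C>A @ ACG
        _rec("c2", 3, "C", "T"),  # C>T @ TCA
        _rec("c3", 3, "T", "A"),  # T>A @ ATA
    ]
    sbs, dbs, n_multi = uv.build_spectra(recs, genome)
    assert n_multi == 0
    totals = sbs.class_totals
    assert totals["A[C>A]G"] == 1 and totals["T[C>T]A"] == 1 and totals["A[T>A]A"] == 1
    assert totals.sum() == 3

    # two isolates with identical records -> per-class SD of 0
    recs2 = recs + [_rec(r.chrom, r.pos, r.ref, r.alt, "i2") for r in recs]
    sbs2, _, _ = uv.build_spectra(recs2, genome)
    assert (sbs2.sd == 0).all()


def test_build_spectra_excludes_multi_and_edge_records():
    genome = uv.make_genome({"c1": "ACGTACGT"})
    recs = [
        _rec("c1", 1, "A", "T"),  # no 5' flank: excluded from context spectrum
        _rec("c1", 4, "T", "A"),
        _rec("c1", 6, "CGT", "TTA", mclass="multi"),
    ]
    sbs, dbs, n_multi = uv.build_spectra(recs, genome)
    assert n_multi == 1
    assert sbs.n_excluded_context == 1
    assert sbs.class_totals.sum() == 1


def test_spectrum_totals_conserve_classifiable_records(small_dataset):
    _, reference, records = small_dataset
    sbs, dbs, n_multi = uv.build_spectra(records, reference.genome)
    for iso in sbs.isolates:
        n_singles = sum(
            1 for r in records if r.isolate == iso and r.mclass == "single"
        )
        assert sbs.per_isolate_totals[iso] + _n_edge(records, reference, iso) == n_singles
        n_tandems = sum(1 for r in records if r.isolate == iso and r.mclass == "tandem")
        assert dbs.per_isolate_totals[iso] == n_tandems


def _n_edge(records, reference, iso):
    n = 0
    for r in records:
        if r.isolate != iso or r.mclass != "single":
            continue
        try:
            uv.get_trinucleotide_context(reference.genome, r.chrom, r.pos)
        except uv.ContextUnavailableError:
            n += 1
    return n


def test_build_spectra_requires_records():
    genome = uv.make_genome({"c1": "ACGT"})
    with pytest.raises(ValueError):
        uv.build_spectra([], genome)


# ---------------------------------------------------------------------------
# density fold change
# ---------------------------------------------------------------------------


def test_median_density_fold():
    assert uv.median_density_fold([10, 20, 30], [10, 20, 30]) == 1.0
    assert uv.median_density_fold([126], [100]) == pytest.approx(1.26)
    with pytest.raises(ZeroDivisionError):
        uv.median_density_fold([1.0], [0.0])


def test_median_fold_even_n_matches_sort_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a, b = rng.integers(1, 100, size=6), rng.integers(1, 100, size=8)
        med = lambda v: (sorted(v)[len(v) // 2 - 1] + sorted(v)[len(v) // 2]) / 2
        assert uv.median_density_fold(a, b) == pytest.approx(med(list(a)) / med(list(b)))


# ---------------------------------------------------------------------------
# chi-square spectrum comparison
# ---------------------------------------------------------------------------


def test_chi2_identical_spectra():
    res = uv.compare_spectra_chi2([50, 50], [50, 50])
    assert res.statistic == 0 and res.p_value == pytest.approx(1.0)


def test_chi2_matches_hand_computed_2x2():
    # expected 50/50 per cell; chi2 = 4 * (40^2 / 50) = 128
    res = uv.compare_spectra_chi2([90, 10], [10, 90])
    assert res.statistic == pytest.approx(128.0)


def test_chi2_symmetric_and_drops_empty_classes():
    a, b = [40, 0, 60, 0], [10, 0, 90, 0]
    assert uv.compare_spectra_chi2(a, b).statistic == pytest.approx(
        uv.compare_spectra_chi2(b, a).statistic
    )
    assert uv.compare_spectra_chi2(a, b).n_classes == 2


def test_chi2_merges_low_expected_classes():
    a = [500, 400, 2, 1]
    b = [480, 420, 1, 2]
    res = uv.compare_spectra_chi2(a, b, min_expected=5)
    assert res.n_classes == 3  # two sparse classes pooled into one


def test_chi2_undefined_below_two_classes():
    with pytest.raises(ValueError):
        uv.compare_spectra_chi2([5, 0], [3, 0])


def test_chi2_type_one_error_on_shared_spectrum():
    """Two groups drawn from one spectrum: ~5% rejections at alpha=0.05."""
    rng = np.random.default_rng(42)
    p = np.array(list(uv.default_uv_sbs_probs().values()))
    rejections = sum(
        uv.compare_spectra_chi2(rng.multinomial(2000, p), rng.multinomial(2000, p)).p_value
        < 0.05
        for _ in range(1000)
    )
    # binomial 99% band around 0.05 with 1000 replicates
    assert 0.032 <= rejections / 1000 <= 0.068


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def test_correlation_extremes_and_errors():
    a = np.array([1.0, 4.0, 2.0, 8.0])
    rho, _ = uv.correlate_spectra(a, a)
    assert rho == pytest.approx(1.0)
    rho_neg, _ = uv.correlate_spectra(a, -a + 10)
    assert rho_neg == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        uv.correlate_spectra(a, np.ones(4))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def test_mw_identical_tied_groups():
    assert uv.mann_whitney([5, 5, 5], [5, 5, 5]) == 1.0


def test_mw_extreme_ranking_small_n():
    # all 20 rank assignments enumerated; only the 2 extremes qualify
    assert uv.mann_whitney([1, 2, 3], [10, 20, 30]) == pytest.approx(0.1)


def test_mw_complete_separation_n6():
    assert uv.mann_whitney(range(6), range(10, 16)) == pytest.approx(2 / 924)


def test_mw_exact_agrees_with_normal_approximation_at_boundary():
    """At the n=8 exact/asymptotic boundary the two methods nearly agree."""
    rng = np.random.default_rng(7)
    diffs = []
    for _ in range(20):
        a, b = rng.normal(0, 1, EXACT_MAX_N), rng.normal(0.3, 1, EXACT_MAX_N)
        exact = _exact_mw_p(a, b)
        approx = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        diffs.append(abs(exact - approx))
    assert np.median(diffs) < 0.01 and max(diffs) < 0.02


def test_mw_large_groups_use_tie_corrected_normal_approximation():
    a = [1.0] * 6 + [2.0] * 6
    b = [1.5] * 12
    expected = float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )
    assert uv.mann_whitney(a, b) == pytest.approx(expected)
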