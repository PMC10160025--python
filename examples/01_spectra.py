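"""Build single and tandem substitution spectra from two simulated cohorts
and compare them.

Simulates a wild-type-like cohort and a second cohort with a 1.26-fold
higher mutation burden drawn from the same UV-like spectrum, then prints
the top spectrum channels, the median-burden fold change, the Mann-Whitney
p for the burden shift, and the chi-square spectrum comparison.
"""

import uvspectra as uv


def records_of(table):
    return uv.merge_tandems(
        [uv.MutationRecord(r.chrom, int(r.pos), r.ref, r.alt, r.isolate)
         for r in table.itertuples()]
    )


base = dict(n_chroms=2, chrom_length=100_000, n_genes=40, gene_length=1500,
            n_origins=6)
ref_a, table_a = uv.simulate_dataset(
    uv.SyntheticConfig(seed=1, n_isolates=20, mutations_per_isolate=600, **base))
ref_b, table_b = uv.simulate_dataset(
    uv.SyntheticConfig(seed=2, n_isolates=20, mutations_per_isolate=756, **base))

sbs_a, dbs_a, _ = uv.build_spectra(records_of(table_a), ref_a.genome)
sbs_b, dbs_b, _ = uv.build_spectra(records_of(table_b), ref_b.genome)

print("top 5 single channels, cohort A (mean +/- SD mutations per isolate):")
top = sbs_a.mean.sort_values(ascending=False).head(5)
for label in top.index:
    print(f"  {label}: {sbs_a.mean[label]:.1f} +/- {sbs_a.sd[label]:.1f}")

fold = uv.median_density_fold(sbs_b.per_isolate_totals, sbs_a.per_isolate_totals)
p_mw = uv.compare_density_mw(sbs_b.per_isolate_totals, sbs_a.per_isolate_totals)
print(f"\nmedian burden fold change (B / A): {fold:.3f}  (MW p = {p_mw:.2e})")
print("  -> the generator gave cohort B a 1.26-fold higher Poisson mean;")
print("     the pipeline re-measures that elevation from the mutation tables.")

chi2 = uv.compare_spectra_chi2(sbs_a.class_totals, sbs_b.class_totals)
print(f"\nchi-square spectrum comparison: stat = {chi2.statistic:.1f}, "
      f"p = {chi2.p_value:.3f} over {chi2.n_classes} classes")
print("  -> both cohorts share one spectrum, so p should be unremarkable.")

rho, p = uv.correlate_spectra(sbs_a.class_totals, sbs_b.class_totals)
print(f"Pearson concordance of the two spectra: rho = {rho:.3f} (p = {p:.1e})")
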