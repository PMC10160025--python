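# uvspectra

Mutation-spectrum and strand-asymmetry analysis for UV-irradiated yeast
genomes.

UV light forms bulky photoproducts (cyclobutane pyrimidine dimers,
6-4 photoproducts and rarer atypical lesions) whose error-prone bypass
leaves characteristic substitutions: C>T at dipyrimidines, tandem CC>TT and
AC>TT doublets, and T>A / T>C changes. `uvspectra` is a library for turning
per-isolate substitution calls from mutation-accumulation experiments into
the quantities that diagnose which lesion and which strand produced them:

* **Spectra** — strand-collapsed single-base substitution counts over the
  96 (substitution, trinucleotide-context) channels and tandem doublets over
  the canonical 78 classes, per isolate, with mean ± SD profiles, median
  burden fold changes, χ² spectrum comparisons, Pearson concordance and
  exact Mann–Whitney burden tests.
* **Transcriptional asymmetry** — assignment of each genic mutation to the
  non-transcribed (NTS, coding) or transcribed (TS, template) strand, tested
  against the NTS/TS split expected from per-strand trinucleotide
  frequencies of gene bodies: a 1-df goodness-of-fit χ² per class with
  Bonferroni correction, normalized ratios
  `(n_NTS/e_NTS)/(n_TS/e_TS)`, and per-context NTS fractions.
* **Replicative asymmetry** — each mutation placed fractionally between its
  flanking replication origins; complementary substitution types kept in
  top-strand orientation and binned along that axis, where a leading/lagging
  preference appears as the characteristic "cross" of opposite linear
  trends, with bootstrap confidence intervals on the fitted slopes.
* **Reversion statistics** — revertants / surviving cells, the
  maximum-estimated frequency `1/N` when zero revertants are seen among `N`
  plated cells, bound-aware fold changes, exact rank tests, and the CAN1
  canavanine-resistance frequency formula
  `(Can^R × dilution_SC) / (SC × dilution_Can)`.
* **Synthetic data** — seeded generation of toy genomes, gene/origin
  annotations and mutation tables with a chosen spectrum, NTS:TS odds and
  replicative slope, so every stage of the pipeline can be validated against
  known truth without any sequencing data.

Input formats are the plain ones a variant-calling pipeline emits: FASTA
reference, TSV (`chrom  pos  ref  alt  isolate`) or single-sample VCF
mutation tables, BED6 genes, TSV/BED origins. Positions in mutation tables
are 1-based; interval annotations are 0-based half-open. Mitochondrial
records are excluded by default and reference alleles are validated against
the genome, with mismatches collected into an explicit reject report.

## Worked example

```python
import uvspectra as uv

cfg = uv.SyntheticConfig(seed=11, n_chroms=2, chrom_length=100_000,
                         n_genes=40, gene_length=1500, n_origins=6,
                         n_isolates=5, mutations_per_isolate=2000,
                         poisson_counts=False, nts_odds=2.0)
reference, table = uv.simulate_dataset(cfg)
records = uv.merge_tandems(
    [uv.MutationRecord(r.chrom, int(r.pos), r.ref, r.alt, r.isolate)
     for r in table.itertuples()])

asym = uv.transcriptional_asymmetry(records, reference.genome, reference.genes)
print(asym[asym.tested][["label", "n_nts", "n_ts", "normalized_ratio", "p_bonf"]].head())
```

prints (see `examples/02_transcriptional_asymmetry.py`):

```
  label  n_nts  n_ts  normalized_ratio   p_bonf
T[C>T]T    318   157              1.99 2.62e-11
T[C>T]A    315   166              1.74 2.51e-07
T[C>T]G    311   172              1.78 3.02e-08
T[C>T]C    306   155              1.94 2.83e-10
C[C>T]A    303   142                 2 1.55e-10
```

The generator placed the mutated pyrimidine on the coding strand with 2:1
odds, and the normalized ratio — the observed/expected NTS rate over the
observed/expected TS rate — recovers values near 2 with vanishing
Bonferroni-corrected p-values. A ratio of 1 means any raw NTS/TS imbalance
is fully explained by the strands' trinucleotide composition.

The `examples/` directory has one short script per capability (spectra and
cohort comparison, transcriptional asymmetry, the replication "cross",
reversion-assay arithmetic, ingest validation); each prints the numbers it
computes and a line on what they mean. A thin command-line interface covers
the same pipeline for shell use:

```bash
uvspectra simulate --out-dir sim --seed 3
uvspectra ingest   --genome sim/genome.fa --mutations sim/mutations.tsv --out records.tsv
uvspectra spectrum --records records.tsv --genome sim/genome.fa --out-prefix wt
uvspectra tx-asym  --records records.tsv --genome sim/genome.fa --genes sim/genes.bed --out tx.tsv
uvspectra rep-asym --records records.tsv --genome sim/genome.fa --origins sim/origins.tsv --out-prefix rep
```

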