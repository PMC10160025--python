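"""Synthetic genomes, annotations and mutation tables with known structure.

The generator emulates the statistical structure the analysis modules
measure, nothing more: per-isolate mutation counts, a multinomial
substitution spectrum over the 96 single and 78 tandem classes, an NTS:TS
odds parameter governing which strand of a gene carries the mutated
pyrimidine, and a linear leading/lagging bias of complementary substitution
types along the inter-origin axis. It does not model lesion formation,
repair kinetics or polymerase choice.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dna import revcomp
from .io_formats import (
    GeneInterval,
    Genome,
    OriginMap,
    make_genome,
    make_origin_map,
    write_genes,
    write_genome,
    write_origins,
)
from .spectra import DBS78_CLASSES, SBS96_CLASSES

_BASE = "ACGT"


class ConfigError(ValueError):
    pass


def default_uv_sbs_probs() -> dict[str, float]:
    """A UV-photoproduct-like 96-channel spectrum.

    C>T at dipyrimidines (5' T or C neighbour) dominates, with smaller
    contributions from T>C, T>A and C>A channels and a low floor elsewhere,
    mirroring the qualitative shape of UV mutagenesis in repair-proficient
    yeast.
    """
    weights: dict[str, float] = {}
    for cls in SBS96_CLASSES:
        left = cls.context[0]
        if cls.substitution == "C>T" and left in "CT":
            w = 10.0
        elif cls.substitution == "C>T":
            w = 0.5
        elif cls.substitution == "T>C":
            w = 1.0
        elif cls.substitution == "T>A":
            w = 0.7
        elif cls.substitution == "C>A":
            w = 0.5
        else:
            w = 0.1
        weights[cls.label] = w
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def default_tandem_probs() -> dict[str, float]:
    """Tandem classes seen after UV: CC>TT dominant, with CT>TA and AC>TT."""
    return {"CC>TT": 0.6, "CT>TA": 0.2, "AC>TT": 0.2}


@dataclass
class SyntheticConfig:
    """Study-scale defaults: a small multi-chromosome genome, dense gene
    coverage, evenly spaced origins, tens of isolates with hundreds of
    substitutions each (the scale of a UV mutation-accumulation experiment),
    UV-like single and tandem spectra, and no strand bias unless asked for.
    """

    seed: int = 17
    n_chroms: int = 4
    chrom_length: int = 150_000
    gc_content: float = 0.38
    n_genes: int = 60  # per chromosome
    gene_length: int = 1200
    n_origins: int = 8  # per chromosome
    n_isolates: int = 46
    mutations_per_isolate: float = 600.0
    poisson_counts: bool = True
    sbs_probs: dict[str, float] = field(default_factory=default_uv_sbs_probs)
    tandem_probs: dict[str, float] = field(default_factory=default_tandem_probs)
    tandem_fraction: float = 0.06
    #: NTS:TS odds for the strand of the mutated pyrimidine inside genes;
    #: scalar, or dict keyed by substitution ("C>T") / tandem label ("CC>TT")
    nts_odds: float | dict[str, float] = 1.0
    #: linear replicative bias: member-1 (pyrimidine-on-top) probability is
    #: 0.5 + rep_slope * (fraction - 0.5); scalar or dict by substitution
    rep_slope: float | dict[str, float] = 0.0

    def __post_init__(self):
        self._check_simplex(self.sbs_probs, "sbs_probs")
        self._check_simplex(self.tandem_probs, "tandem_probs")
        if not 0 <= self.tandem_fraction <= 1:
            raise ConfigError("tandem_fraction must be in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ConfigError("gc_content must be in (0, 1)")
        for odds in self._odds_values():
            if odds <= 0:
                raise ConfigError("nts_odds must be positive")

    def _odds_values(self):
        if isinstance(self.nts_odds, dict):
            return self.nts_odds.values()
        return [self.nts_odds]

    @staticmethod
    def _check_simplex(probs: dict[str, float], name: str):
        if not probs:
            raise ConfigError(f"{name} is empty")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"{name} sums to {total}, not 1")
        if any(p < 0 for p in probs.values()):
            raise ConfigError(f"{name} has negative entries")

    def class_odds(self, key: str) -> float:
        if isinstance(self.nts_odds, dict):
            return self.nts_odds.get(key, 1.0)
        return self.nts_odds

    def class_slope(self, key: str) -> float:
        if isinstance(self.rep_slope, dict):
            return self.rep_slope.get(key, 0.0)
        return self.rep_slope


@dataclass
class Reference:
    genome: Genome
    genes: list[GeneInterval]
    origins: OriginMap

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.bed",
            "origins": outdir / "origins.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_genes(self.genes, paths["genes"])
        write_origins(self.origins, paths["origins"])
        return paths


def generate_reference(config: SyntheticConfig) -> Reference:
    """Toy genome with non-overlapping genes and jittered, even origins.

    Bases are drawn i.i.d. at the configured GC content. Genes are packed by
    distributing the free space between them uniformly (multinomial gaps), so
    placement never fails when the genes fit at all.
    """
    rng = np.random.default_rng([config.seed, 0])
    p = np.array(
        [(1 - config.gc_content) / 2, config.gc_content / 2,
         config.gc_content / 2, (1 - config.gc_content) / 2]
    )
    sequences: dict[str, str] = {}
    genes: list[GeneInterval] = []
    origins: dict[str, list[int]] = {}
    L, g = config.chrom_length, config.gene_length

    free = L - 2 - config.n_genes * g
    if free < 0:
        raise ConfigError(
            f"{config.n_genes} genes of {g} bp do not fit in a {L} bp chromosome"
        )

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        codes = rng.choice(4, size=L, p=p)
        sequences[chrom] = "".join(_BASE[c] for c in codes)

        gaps = rng.multinomial(free, np.full(config.n_genes + 1, 1 / (config.n_genes + 1)))
        start = 1
        for gi in range(config.n_genes):
            start += int(gaps[gi])
            strand = "+" if rng.integers(2) == 0 else "-"
            genes.append(GeneInterval(chrom, start, start + g, strand, f"{chrom}_g{gi}"))
            start += g

        spacing = L / (config.n_origins + 1)
        pos = []
        for oi in range(1, config.n_origins + 1):
            jitter = (rng.uniform(-0.2, 0.2)) * spacing
            pos.append(int(np.clip(round(oi * spacing + jitter), 0, L - 1)))
        origins[chrom] = sorted(set(pos))

    return Reference(make_genome(sequences), genes, make_origin_map(origins))


# ---------------------------------------------------------------------------
# Mutation simulation
# ---------------------------------------------------------------------------

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASE):
    _LUT[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


class MutationSimulator:
    """Samples mutation tables from a reference with configurable biases.

    Site lookup tables (every genomic occurrence of every trinucleotide and
    dinucleotide, with gene-strand annotation) are built once, so repeated
    sampling — e.g. across simulation replicates — is cheap.
    """

    def __init__(self, reference: Reference, config: SyntheticConfig):
        self.reference = reference
        self.config = config
        self._chroms = list(reference.genome.sequences)
        self._tri: dict[str, dict[str, np.ndarray]] = {}
        self._di: dict[str, dict[str, np.ndarray]] = {}
        self._gene_code: dict[str, np.ndarray] = {}
        self._origins = reference.origins
        self._pools: dict[str, tuple] = {}
        self._build_index()

    def _build_index(self):
        genome = self.reference.genome
        cov: dict[str, np.ndarray] = {}
        strand_sum: dict[str, np.ndarray] = {}
        for chrom, L in genome.lengths.items():
            cov[chrom] = np.zeros(L, dtype=np.int16)
            strand_sum[chrom] = np.zeros(L, dtype=np.int16)
        for gene in self.reference.genes:
            cov[gene.chrom][gene.start : gene.end] += 1
            strand_sum[gene.chrom][gene.start : gene.end] += 1 if gene.strand == "+" else -1
        for chrom, seq in genome.sequences.items():
            code = np.where(cov[chrom] == 0, 0, np.where(cov[chrom] > 1, 9, strand_sum[chrom]))
            self._gene_code[chrom] = code.astype(np.int8)
            b = _encode(seq)
            ok3 = (b[:-2] >= 0) & (b[1:-1] >= 0) & (b[2:] >= 0)
            k3 = b[:-2] * 16 + b[1:-1] * 4 + b[2:]
            tri: dict[str, np.ndarray] = {}
            for c0 in range(64):
                mids = np.nonzero(ok3 & (k3 == c0))[0] + 1  # 0-based middle base
                if mids.size:
                    kmer = _BASE[c0 >> 4] + _BASE[(c0 >> 2) & 3] + _BASE[c0 & 3]
                    tri[kmer] = mids
            self._tri[chrom] = tri
            ok2 = (b[:-1] >= 0) & (b[1:] >= 0)
            k2 = b[:-1] * 4 + b[1:]
            di: dict[str, np.ndarray] = {}
            for c0 in range(16):
                starts = np.nonzero(ok2 & (k2 == c0))[0]
                # need the downstream base to exist so the pair fits
                starts = starts[starts + 1 < len(seq)]
                if starts.size:
                    di[_BASE[c0 >> 2] + _BASE[c0 & 3]] = starts
            self._di[chrom] = di

    # -- pool construction ------------------------------------------------

    def _sites(self, motif: str, table: str) -> list[tuple[str, np.ndarray]]:
        src = self._tri if table == "tri" else self._di
        return [(chrom, src[chrom][motif]) for chrom in self._chroms if motif in src[chrom]]

    def _pool(self, motif: str, table: str):
        """(nts, ts, other) site pools for one pyrimidine-oriented motif.

        Each pool is an (n, 3) int array of [chrom_idx, pos0, orientation]
        where orientation is +1 when the canonical motif reads on the top
        strand and -1 when it reads on the bottom strand.
        """
        key = f"{table}:{motif}"
        if key in self._pools:
            return self._pools[key]
        rows = {"nts": [], "ts": [], "other": []}
        for orient, m in ((1, motif), (-1, revcomp(motif))):
            for chrom, positions in self._sites(m, table):
                ci = self._chroms.index(chrom)
                codes = self._gene_code[chrom][positions]
                coding = codes == orient
                template = codes == -orient
                other = ~(coding | template)
                for name, mask in (("nts", coding), ("ts", template), ("other", other)):
                    pos = positions[mask]
                    if pos.size:
                        rows[name].append(
                            np.column_stack(
                                [np.full(pos.size, ci), pos, np.full(pos.size, orient)]
                            )
                        )
        pools = tuple(
            np.concatenate(rows[name]) if rows[name] else np.empty((0, 3), dtype=np.int64)
            for name in ("nts", "ts", "other")
        )
        self._pools[key] = pools
        return pools

    # -- sampling ---------------------------------------------------------

    def _origin_fraction(self, chrom: str, pos0: int) -> float | None:
        if chrom not in self._origins:
            return None
        arr = self._origins.positions[chrom]
        if arr.size < 2 or pos0 < arr[0] or pos0 > arr[-1]:
            return None
        idx = int(np.searchsorted(arr, pos0, side="right"))
        if idx == arr.size:
            idx -= 1
        left, right = arr[idx - 1], arr[idx]
        return (pos0 - left) / (right - left)

    def _draw_site(self, rng, motif: str, table: str, odds: float, slope: float):
        nts, ts, other = self._pool(motif, table)
        n_genic = len(nts) + len(ts)
        total = n_genic + len(other)
        if total == 0:
            return None
        w_max = 0.5 + abs(slope) / 2
        for _ in range(1000):
            if rng.random() * total < n_genic and n_genic > 0:
                pick_nts = rng.random() < odds / (1 + odds)
                pool = nts if (pick_nts and len(nts)) or not len(ts) else ts
            else:
                pool = other if len(other) else (nts if len(nts) else ts)
            ci, pos0, orient = pool[rng.integers(len(pool))]
            if slope != 0.0:
                frac = self._origin_fraction(self._chroms[ci], pos0)
                if frac is None:
                    w = 0.5
                elif orient == 1:
                    w = 0.5 + slope * (frac - 0.5)
                else:
                    w = 0.5 - slope * (frac - 0.5)
                if rng.random() * w_max >= w:
                    continue
            return self._chroms[ci], int(pos0), int(orient)
        return None

    def sample_isolate(self, rng: np.random.Generator, isolate: str, n: int | None = None):
        """One isolate's mutation rows (chrom, 1-based pos, ref, alt, isolate).

        Tandems are emitted as two adjacent single-base rows so that ingest
        and tandem merging are exercised downstream. Collisions (a sampled
        site adjacent to or on an already-used site in the same isolate) are
        resampled so no unintended runs arise.
        """
        cfg = self.config
        if n is None:
            if cfg.poisson_counts:
                n = int(rng.poisson(cfg.mutations_per_isolate))
            else:
                n = int(cfg.mutations_per_isolate)
        sbs_labels = list(cfg.sbs_probs)
        sbs_p = np.array([cfg.sbs_probs[k] for k in sbs_labels])
        td_labels = list(cfg.tandem_probs)
        td_p = np.array([cfg.tandem_probs[k] for k in td_labels])

        used: set[tuple[str, int]] = set()
        rows = []
        for _ in range(n):
            for _attempt in range(200):
                if rng.random() < cfg.tandem_fraction:
                    label = td_labels[rng.choice(len(td_labels), p=td_p)]
                    ref, alt = label.split(">")
                    site = self._draw_site(rng, ref, "di", cfg.class_odds(label),
                                           cfg.class_slope(label))
                    if site is None:
                        break
                    chrom, pos0, orient = site
                    if orient == -1:
                        ref, alt = revcomp(ref), revcomp(alt)
                    span = [pos0, pos0 + 1]
                    if any((chrom, p) in used for p in range(pos0 - 1, pos0 + 3)):
                        continue
                    for off in (0, 1):
                        rows.append((chrom, pos0 + off + 1, ref[off], alt[off], isolate))
                else:
                    label = sbs_labels[rng.choice(len(sbs_labels), p=sbs_p)]
                    # label is "L[R>A]R2"
                    context = label[0] + label[2] + label[-1]
                    sub_ref, sub_alt = label[2], label[4]
                    site = self._draw_site(rng, context, "tri",
                                           cfg.class_odds(f"{sub_ref}>{sub_alt}"),
                                           cfg.class_slope(f"{sub_ref}>{sub_alt}"))
                    if site is None:
                        break
                    chrom, pos0, orient = site
                    ref, alt = (sub_ref, sub_alt) if orient == 1 else (revcomp(sub_ref), revcomp(sub_alt))
                    span = [pos0]
                    if any((chrom, p) in used for p in range(pos0 - 1, pos0 + 2)):
                        continue
                    rows.append((chrom, pos0 + 1, ref, alt, isolate))
                for p in span:
                    used.add((chrom, p))
                break
        return rows


def generate_mutations(
    config: SyntheticConfig, reference: Reference, simulator: MutationSimulator | None = None
) -> pd.DataFrame:
    """Per-isolate mutation table (TSV-ready, 1-based positions)."""
    sim = simulator or MutationSimulator(reference, config)
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    width = len(str(config.n_isolates))
    for i in range(config.n_isolates):
        rows.extend(sim.sample_isolate(rng, f"iso{i + 1:0{width}d}"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "isolate"])
    return df.sort_values(["isolate", "chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_dataset(config: SyntheticConfig) -> tuple[Reference, pd.DataFrame]:
    reference = generate_reference(config)
    return reference, generate_mutations(config, reference)


def generate_reversion_counts(
    true_freq: float, survivors: float, n_replicates: int, seed: int
) -> pd.DataFrame:
    """Simulated reversion assay: revertants ~ Poisson(true_freq * survivors)."""
    if not 0 <= true_freq <= 1:
        raise ConfigError("true_freq must be a frequency in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(true_freq * survivors, size=n_replicates)
    return pd.DataFrame(
        {
            "replicate": np.arange(1, n_replicates + 1),
            "revertants": counts,
            "survivors": np.full(n_replicates, float(survivors)),
        }
    )
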