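"""Input/output layer: genomes, mutation tables, gene and origin annotations.

Conventions enforced here and relied on by every downstream stage:

* mutation positions are 1-based (VCF convention);
* gene and origin intervals are 0-based half-open (BED convention);
* reference alleles are validated against the genome, mismatches are
  collected into a reject report rather than silently dropped;
* mitochondrial records are excluded by a configurable chromosome-name set.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .dna import revcomp

logger = logging.getLogger(__name__)

#: chromosome names dropped by default; the mitochondrial genome is excluded
#: from all nuclear mutation analyses.
DEFAULT_MITO_NAMES = frozenset({"chrM", "chrMito", "mitochondrion", "chrmt", "MT"})

VALID_BASES = frozenset("ACGTN")

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "isolate"]


class InputError(ValueError):
    """Malformed or inconsistent external input."""


class ValidationError(InputError):
    """Input parsed but violates a contract (alphabet, bounds, duplicates)."""


class ContextUnavailableError(Exception):
    """Trinucleotide context cannot be read (chromosome edge or N base)."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Genome:
    """Uppercase reference sequences keyed by chromosome name."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def slice(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice of a chromosome."""
        return self.sequences[chrom][start:end]


def make_genome(sequences: dict[str, str]) -> Genome:
    """Validate and uppercase raw sequences into a :class:`Genome`."""
    upper: dict[str, str] = {}
    for name, seq in sequences.items():
        s = seq.upper()
        bad = set(s) - VALID_BASES
        if bad:
            raise ValidationError(
                f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        upper[name] = s
    return Genome(upper)


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA reference.

    Chromosome names are taken verbatim from the headers up to the first
    whitespace. Sequences are uppercased and restricted to the ACGTN alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    for rec in records:
        name = rec.id
        if not name:
            raise InputError(f"{path}: record with empty header")
        if name in sequences:
            raise ValidationError(f"{path}: duplicate chromosome name {name!r}")
        sequences[name] = str(rec.seq)
    return make_genome(sequences)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Mutation records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRecord:
    """One called substitution; ``pos`` is 1-based.

    ``mclass`` distinguishes isolated single-base substitutions, merged
    adjacent pairs (tandems) and runs of three or more adjacent substituted
    positions (multi), which are excluded from both spectra.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    isolate: str
    mclass: str = "single"

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValidationError(f"{self}: ref equals alt")
        if len(self.ref) != len(self.alt):
            raise ValidationError(f"{self}: ref/alt length mismatch")
        if self.mclass not in {"single", "tandem", "multi"}:
            raise ValidationError(f"{self}: bad mclass {self.mclass!r}")

    @property
    def end(self) -> int:
        """1-based inclusive end of the substituted run."""
        return self.pos + len(self.ref) - 1


def _infer_mclass(ref: str) -> str:
    return {1: "single", 2: "tandem"}.get(len(ref), "multi")


@dataclass
class IngestResult:
    """Accepted records plus an explicit account of everything not accepted."""

    records: list[MutationRecord]
    rejected: list[tuple[dict, str]] = field(default_factory=list)
    n_excluded_chrom: int = 0
    n_dedup_dropped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _validate_record(row: dict, genome: Genome) -> MutationRecord:
    chrom, pos = str(row["chrom"]), int(row["pos"])
    ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
    if chrom not in genome:
        raise ValidationError(f"unknown chromosome {chrom!r}")
    L = genome.lengths[chrom]
    if not 1 <= pos <= L - (len(ref) - 1):
        raise ValidationError(f"position {pos} outside chromosome {chrom} (length {L})")
    observed = genome.slice(chrom, pos - 1, pos - 1 + len(ref))
    if observed != ref:
        raise ValidationError(
            f"ref mismatch at {chrom}:{pos}: table says {ref}, genome has {observed}"
        )
    return MutationRecord(chrom, pos, ref, alt, str(row["isolate"]), _infer_mclass(ref))


def read_mutations(
    path: str | Path,
    genome: Genome,
    exclude_chroms: Iterable[str] = DEFAULT_MITO_NAMES,
    dedup_shared: bool = False,
) -> IngestResult:
    """Read a mutation table (TSV with chrom/pos/ref/alt/isolate header, or VCF).

    Records on excluded chromosomes (default: common mitochondrial names) are
    dropped and counted; records whose reference allele disagrees with the
    genome are rejected into ``IngestResult.rejected``.

    ``dedup_shared`` optionally removes mutations observed at the same site
    with the same allele in more than one isolate (putative shared ancestral
    events). Off by default: the appropriate treatment depends on how the
    isolates were derived, so the caller must opt in.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        rows = _vcf_rows(path)
    else:
        table = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in MUTATION_COLUMNS if c not in table.columns]
        if missing:
            raise InputError(f"{path}: missing columns {missing}")
        rows = table[MUTATION_COLUMNS].to_dict("records")

    exclude = set(exclude_chroms)
    result = IngestResult(records=[])
    for row in rows:
        if str(row["chrom"]) in exclude:
            result.n_excluded_chrom += 1
            continue
        try:
            result.records.append(_validate_record(row, genome))
        except ValidationError as exc:
            result.rejected.append((dict(row), str(exc)))

    if dedup_shared:
        kept, dropped = _drop_shared_sites(result.records)
        result.n_dedup_dropped = dropped
        result.records = kept

    if result.n_excluded_chrom:
        logger.info("dropped %d record(s) on excluded chromosomes", result.n_excluded_chrom)
    if result.rejected:
        logger.warning("rejected %d record(s); see IngestResult.rejected", len(result.rejected))
    return result


def _vcf_rows(path: Path) -> list[dict]:
    """Minimal single-sample VCF reader; the sample name is the isolate ID."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        isolate = samples[0] if samples else path.stem
        for rec in vcf:
            for alt in rec.alts or ():
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "isolate": isolate,
                    }
                )
    return rows


def _drop_shared_sites(records: list[MutationRecord]) -> tuple[list[MutationRecord], int]:
    by_site: dict[tuple, set[str]] = {}
    for r in records:
        by_site.setdefault((r.chrom, r.pos, r.ref, r.alt), set()).add(r.isolate)
    shared = {site for site, isolates in by_site.items() if len(isolates) > 1}
    kept = [r for r in records if (r.chrom, r.pos, r.ref, r.alt) not in shared]
    return kept, len(records) - len(kept)


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    df = mutations_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def mutations_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt, "isolate": r.isolate}
            for r in records
        ],
        columns=MUTATION_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Tandem merging
# ---------------------------------------------------------------------------


def merge_tandems(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Merge runs of adjacent single-base substitutions within one isolate.

    Runs of exactly two consecutive positions become one ``tandem`` record,
    runs of three or more become one ``multi`` record (excluded from both
    spectra downstream); isolated substitutions stay ``single``. The multiset
    of genomic positions covered is conserved.
    """
    for r in records:
        if len(r.ref) != 1:
            raise ValueError("merge_tandems expects length-1 substitutions")
    out: list[MutationRecord] = []
    by_group: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in records:
        by_group.setdefault((r.isolate, r.chrom), []).append(r)
    for (_, _), group in sorted(by_group.items()):
        group = sorted(group, key=lambda r: r.pos)
        for a, b in zip(group, group[1:]):
            if a.pos == b.pos:
                raise ValidationError(
                    f"duplicate position {a.chrom}:{a.pos} in isolate {a.isolate}"
                )
        run: list[MutationRecord] = []
        for r in group + [None]:  # type: ignore[list-item]
            if run and (r is None or r.pos != run[-1].pos + 1):
                out.append(_collapse_run(run))
                run = []
            if r is not None:
                run.append(r)
    return out


def _collapse_run(run: list[MutationRecord]) -> MutationRecord:
    if len(run) == 1:
        return run[0]
    first = run[0]
    return MutationRecord(
        chrom=first.chrom,
        pos=first.pos,
        ref="".join(r.ref for r in run),
        alt="".join(r.alt for r in run),
        isolate=first.isolate,
        mclass="tandem" if len(run) == 2 else "multi",
    )


# ---------------------------------------------------------------------------
# Trinucleotide context
# ---------------------------------------------------------------------------


def get_trinucleotide_context(genome: Genome, chrom: str, pos: int) -> str:
    """3-mer centered on ``pos`` (1-based) as read on the reference top strand."""
    seq = genome.sequences[chrom]
    if pos < 2 or pos > len(seq) - 1:
        raise ContextUnavailableError(f"{chrom}:{pos}: flanking base outside chromosome")
    window = seq[pos - 2 : pos + 1]
    if "N" in window:
        raise ContextUnavailableError(f"{chrom}:{pos}: N base in context window {window}")
    return window


# ---------------------------------------------------------------------------
# Gene intervals and replication origins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneInterval:
    """0-based half-open gene body with transcription strand."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"gene {self.name}: start >= end")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.name}: strand must be + or -")


def read_genes(path: str | Path) -> list[GeneInterval]:
    """Read gene intervals from BED6 (chrom, start, end, name, score, strand)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InputError(f"{path}:{ln}: BED6 requires 6 columns")
            genes.append(
                GeneInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    strand=fields[5],
                )
            )
    return genes


def write_genes(genes: Sequence[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


@dataclass(frozen=True)
class OriginMap:
    """Per chromosome, strictly increasing replication-origin midpoints (0-based)."""

    positions: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, arr in self.positions.items():
            if np.any(np.diff(arr) <= 0):
                raise ValidationError(f"origins on {chrom} not strictly increasing")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.positions


def make_origin_map(positions: dict[str, Iterable[int]]) -> OriginMap:
    return OriginMap({c: np.asarray(sorted(set(p)), dtype=np.int64) for c, p in positions.items()})


def read_origins(path: str | Path) -> OriginMap:
    """Read origin coordinates from a headered TSV (chrom, position) or BED.

    BED intervals are reduced to their midpoints.
    """
    with open(path) as fh:
        text = fh.read()
    first = text.splitlines()[0] if text.strip() else ""
    positions: dict[str, list[int]] = {}
    if first.lower().startswith("chrom"):
        df = pd.read_csv(io.StringIO(text), sep="\t")
        if "position" not in df.columns:
            raise InputError(f"{path}: TSV origin file needs a 'position' column")
        for chrom, pos in zip(df["chrom"], df["position"]):
            positions.setdefault(str(chrom), []).append(int(pos))
    else:
        for ln, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{ln}: BED origin file needs >= 3 columns")
            positions.setdefault(fields[0], []).append((int(fields[1]) + int(fields[2])) // 2)
    return make_origin_map(positions)


def write_origins(origins: OriginMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\n")
        for chrom, arr in origins.positions.items():
            for p in arr:
                fh.write(f"{chrom}\t{int(p)}\n")
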