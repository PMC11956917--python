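"""Reading and writing of genomes, mutation catalogs and gene annotations.

All downstream analysis consumes the three in-memory containers defined here:

:class:`GenomeSequence`
    ordered chromosomes as uppercase nucleotide strings — the single source
    for every context lookup in the package;
:class:`MutationSet`
    a collection of :class:`MutationRecord` somatic calls with provenance;
:class:`GeneIntervals`
    stranded gene intervals (internally 0-based half-open).

I/O follows each format's native convention (VCF/GFF 1-based, BED 0-based);
everything internal is 0-based half-open, with converters at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from ._seq import revcomp

log = logging.getLogger("mutsig.io")

MUTATION_CLASSES = ("SBS", "INS", "DEL", "DBS", "MBS")

_TSV_COLUMNS = ("sample", "chrom", "pos", "ref", "alt", "vaf")


@dataclass
class GenomeSequence:
    """Named chromosomes with uppercase nucleotide strings."""

    chromosomes: dict[str, str]

    def __post_init__(self):
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-IUPAC residues {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def context(self, chrom: str, pos: int, radius: int) -> str:
        """Top-strand window of ±radius around 1-based *pos*, truncated at
        chromosome ends."""
        seq = self.chromosomes[chrom]
        i = pos - 1
        return seq[max(0, i - radius) : i + radius + 1]

    def trinucleotide(self, chrom: str, pos: int) -> str | None:
        """Top-strand trinucleotide centred on *pos*, or None at chromosome
        ends where a flank is missing."""
        seq = self.chromosomes[chrom]
        i = pos - 1
        if i < 1 or i > len(seq) - 2:
            return None
        return seq[i - 1 : i + 2]

    def reverse_complemented(self) -> "GenomeSequence":
        return GenomeSequence({n: revcomp(s) for n, s in self.chromosomes.items()})


def classify_alleles(ref: str, alt: str) -> str:
    """Assign SBS/INS/DEL/DBS/MBS from allele lengths."""
    if len(ref) == len(alt):
        if len(ref) == 1:
            return "SBS"
        if len(ref) == 2:
            return "DBS"
        return "MBS"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call (positions are 1-based, VCF style)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")

    @property
    def mclass(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity irrespective of sample."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MutationSet:
    """A collection of mutation calls plus how they were obtained."""

    records: list[MutationRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for r in self.records:
            k = (r.sample_id, *r.key)
            if k in seen:
                raise ValueError(f"duplicate record {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, predicate, note: str | None = None) -> "MutationSet":
        kept = [r for r in self.records if predicate(r)]
        prov = dict(self.provenance)
        if note:
            prov.setdefault("filters", []).append(note)
        return MutationSet(kept, prov)

    def of_class(self, *classes: str) -> "MutationSet":
        cs = set(classes)
        return MutationSet([r for r in self.records if r.mclass in cs],
                           dict(self.provenance))

    def samples(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.sample_id not in out:
                out.append(r.sample_id)
        return out

    def by_sample(self) -> dict[str, list[MutationRecord]]:
        d: dict[str, list[MutationRecord]] = {}
        for r in self.records:
            d.setdefault(r.sample_id, []).append(r)
        return d

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(sample=r.sample_id, chrom=r.chrom, pos=r.pos, ref=r.ref,
                     alt=r.alt, vaf=r.vaf, mclass=r.mclass)
                for r in self.records
            ],
            columns=["sample", "chrom", "pos", "ref", "alt", "vaf", "mclass"],
        )


@dataclass
class IngestConfig:
    """Call-level filters applied at load time.

    ``min_vaf`` defaults to 0.90: isolates are clonal expansions, so genuine
    somatic calls should be near-homozygous.  Records without a VAF pass the
    filter (upstream pipelines may omit it) and the count is logged.
    """

    min_vaf: float = 0.90
    drop_parental: bool = True
    drop_cross_sample_duplicates: bool = False

    def __post_init__(self):
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must be within [0, 1]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_fasta(path) -> GenomeSequence:
    """Load a multi-record FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; record order is preserved.  Empty files,
    duplicate headers and non-IUPAC residues are hard errors naming the
    offending record.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-IUPAC residues {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        chroms[rec.id] = seq
    if not chroms:
        raise ValueError(f"{path}: no FASTA records found")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Mutation catalogs (VCF / TSV)
# ---------------------------------------------------------------------------

def load_mutations(
    path,
    format: str = "tsv",
    config: IngestConfig | None = None,
    genome: GenomeSequence | None = None,
) -> MutationSet:
    """Load somatic calls from VCF 4.x or the package's TSV dialect.

    The TSV dialect is tab-separated with a mandatory header
    ``sample chrom pos ref alt vaf`` (vaf may be empty or ``.``).  VCF sample
    VAF is read from INFO key ``VAF`` (fraction) or a per-sample FORMAT field
    ``FREQ`` (percent, VarScan style); the sample column name is used as
    sample id, falling back to INFO key ``SAMPLE`` or the file stem.

    Records failing ``min_vaf`` are removed and the dropped count logged.
    When a genome is supplied, positions beyond the chromosome are errors.
    """
    config = config or IngestConfig()
    if format == "tsv":
        records = _read_tsv(path)
    elif format == "vcf":
        records = _read_vcf(path)
    else:
        raise ValueError(f"unknown mutation format {format!r}")

    if genome is not None:
        for r in records:
            if r.chrom not in genome:
                raise ValueError(f"{path}: unknown chromosome {r.chrom!r}")
            end = r.pos + len(r.ref) - 1
            if end > genome.lengths[r.chrom]:
                raise ValueError(
                    f"{path}: {r.chrom}:{r.pos} {r.ref}>{r.alt} beyond "
                    f"chromosome length {genome.lengths[r.chrom]}"
                )

    n_missing_vaf = sum(1 for r in records if r.vaf is None)
    kept = [r for r in records if r.vaf is None or r.vaf >= config.min_vaf]
    dropped = len(records) - len(kept)
    if dropped:
        log.info("%s: dropped %d/%d records below VAF %.2f",
                 path, dropped, len(records), config.min_vaf)
    if n_missing_vaf:
        log.info("%s: %d records without VAF passed the VAF filter",
                 path, n_missing_vaf)
    return MutationSet(
        kept,
        provenance={
            "source": str(path),
            "format": format,
            "filters": [f"min_vaf={config.min_vaf} (dropped {dropped})"],
        },
    )


def _read_tsv(path) -> list[MutationRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header] != list(_TSV_COLUMNS):
            raise ValueError(
                f"{path}: expected header {' '.join(_TSV_COLUMNS)!r}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_TSV_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(_TSV_COLUMNS)} columns, got {len(parts)}")
            sample, chrom, pos, ref, alt, vaf = parts
            try:
                records.append(
                    MutationRecord(
                        sample_id=sample,
                        chrom=chrom,
                        pos=int(pos),
                        ref=ref.upper(),
                        alt=alt.upper(),
                        vaf=None if vaf in ("", ".") else float(vaf),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: unparsable row: {exc}") from exc
    return records


def _read_vcf(path) -> list[MutationRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    fallback = Path(str(path)).stem
    records = []
    for var in vcf:
        vaf = var.INFO.get("VAF")
        if vaf is not None:
            vaf = float(vaf)
        elif vcf_samples:
            try:
                freq = var.format("FREQ")
            except KeyError:
                freq = None
            if freq is not None:
                vaf = float(str(freq[0]).strip("%")) / 100.0
        sample = var.INFO.get("SAMPLE") or (vcf_samples[0] if vcf_samples else fallback)
        for alt in var.ALT:
            records.append(
                MutationRecord(
                    sample_id=str(sample),
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF.upper(),
                    alt=str(alt).upper(),
                    vaf=vaf,
                )
            )
    return records


def write_mutations_tsv(mutations: MutationSet, path) -> None:
    """Write the TSV dialect; loading it back reproduces the set exactly."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in mutations:
            vaf = "." if r.vaf is None else f"{r.vaf:.6g}"
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{vaf}\n")


def write_mutations_vcf(mutations: MutationSet, path,
                        genome: GenomeSequence | None = None) -> None:
    """Minimal single-sample-per-record VCF 4.2 writer (INFO VAF + SAMPLE)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,'
                 'Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,'
                 'Description="Isolate label">\n')
        if genome is not None:
            for name, length in genome.lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(mutations, key=lambda r: (r.chrom, r.pos, r.sample_id)):
            info = f"SAMPLE={r.sample_id}"
            if r.vaf is not None:
                info += f";VAF={r.vaf:.6g}"
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


def subtract_parental(
    isolates: MutationSet,
    parent: MutationSet | None = None,
    drop_cross_sample_duplicates: bool = False,
) -> MutationSet:
    """Remove variants present in the untreated parent (matched normal).

    With ``drop_cross_sample_duplicates`` a variant shared by more than one
    isolate is treated as pre-existing and kept in none.  Idempotent.
    """
    parental = {r.key for r in parent} if parent is not None else set()
    kept = [r for r in isolates if r.key not in parental]
    if drop_cross_sample_duplicates:
        counts: dict[tuple, set[str]] = {}
        for r in kept:
            counts.setdefault(r.key, set()).add(r.sample_id)
        kept = [r for r in kept if len(counts[r.key]) == 1]
    prov = dict(isolates.provenance)
    prov.setdefault("filters", []).append(
        f"subtract_parental(n_parent={len(parental)}, "
        f"cross_sample_dupes={drop_cross_sample_duplicates})"
    )
    return MutationSet(kept, prov)


# ---------------------------------------------------------------------------
# Gene annotations (BED6 / GFF3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.gene_id}: {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class GeneIntervals:
    intervals: list[GeneInterval]

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_strand_trees(self):
        """Per-chromosome, per-strand interval trees for overlap queries."""
        from intervaltree import IntervalTree

        trees: dict[tuple[str, str], "IntervalTree"] = {}
        for g in self.intervals:
            trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
        return trees


def load_gene_annotation(path, format: str = "bed6") -> GeneIntervals:
    """Load genes from BED6 (0-based) or GFF3 (1-based, converted).

    A missing strand (``.``) is an error: strand-bias analysis needs it.
    """
    intervals: list[GeneInterval] = []
    if format == "bed6":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns "
                                     "(strand column required)")
                chrom, start, end, name, _score, strand = parts[:6]
                if strand not in "+-":
                    raise ValueError(f"{path}:{lineno}: missing strand {strand!r}")
                intervals.append(
                    GeneInterval(chrom, int(start), int(end), strand, name)
                )
    elif format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
                if ftype.lower() != "gene":
                    continue
                if strand not in "+-":
                    raise ValueError(f"{path}:{lineno}: missing strand {strand!r}")
                gid = f"{path}:{lineno}"
                for kv in attrs.split(";"):
                    if kv.startswith(("ID=", "Name=")):
                        gid = kv.split("=", 1)[1]
                        break
                intervals.append(
                    GeneInterval(chrom, int(start) - 1, int(end), strand, gid)
                )
    else:
        raise ValueError(f"unknown gene annotation format {format!r}")
    return GeneIntervals(intervals)


def write_genes_bed(genes: GeneIntervals, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
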