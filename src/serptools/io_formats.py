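"""Readers and writers for every on-disk artifact the pipeline touches.

Coordinate contracts
--------------------
Internal coordinates are 1-based inclusive, matching GTF on disk.  bedGraph
files (0-based, half-open) are converted at the parsing boundary and nowhere
else.  Count tracks are strandless: footprints live on genomic positions and
strand is applied only when a gene profile is extracted.

All readers reject invalid records instead of coercing them; errors carry the
file name and line number.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file could not be parsed (message carries file name and line)."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: strand, exon intervals, transposon flag.

    ``exons`` are 1-based inclusive genomic intervals, non-overlapping and
    sorted 5'->3' in *genomic* coordinates (ascending start) regardless of
    strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    is_transposon: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValidationError(f"{self.gene_id}: bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons overlap or are unsorted at ({start}, {end})"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the gene including introns, 1-based inclusive."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s + 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_codons(self) -> int:
        return self.exonic_length // 3

    def exon_mask(self) -> np.ndarray:
        """Boolean mask over the genomic span (True = exonic), genomic order."""
        s0, _ = self.span
        mask = np.zeros(self.span_length, dtype=bool)
        for s, e in self.exons:
            mask[s - s0 : e - s0 + 1] = True
        return mask


@dataclass
class GenomeAnnotation:
    """Gene models plus chromosome lengths."""

    genes: list[GeneModel]
    chrom_lengths: dict[str, int]

    def __post_init__(self):
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            length = self.chrom_lengths.get(g.chromosome)
            if length is None:
                raise ValidationError(f"{g.gene_id}: unknown chromosome {g.chromosome!r}")
            if g.span[1] > length:
                raise ValidationError(
                    f"{g.gene_id}: exon end {g.span[1]} beyond chromosome length {length}"
                )

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def coding_genes(self) -> list[GeneModel]:
        """Genes that enter quantification (transposon-related genes removed)."""
        return [g for g in self.genes if not g.is_transposon]


@dataclass
class CountTrack:
    """Per-nucleotide normalized footprint counts for one replicate of one condition.

    ``counts`` maps chromosome name to a dense float vector whose index 0 is
    genomic position 1.
    """

    condition: str
    bait: str
    replicate: int
    counts: dict[str, np.ndarray]

    def __post_init__(self):
        if self.condition not in ("ip", "total"):
            raise ValidationError(f"condition must be 'ip' or 'total', got {self.condition!r}")
        for chrom, vec in self.counts.items():
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValidationError(f"track {self.bait}/{self.condition}: chromosome "
                                      f"{chrom} has negative or non-finite values")


@dataclass(frozen=True)
class TruthSet:
    """Curated true-positive gene identifiers (an incomplete literature list)."""

    gene_ids: frozenset[str]

    def __post_init__(self):
        if not self.gene_ids:
            raise ValidationError("truth set is empty")


# ---------------------------------------------------------------------------
# GTF dialect
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_annotation(
    path,
    chrom_lengths: dict[str, int] | None = None,
    transposon_regex: str | None = None,
) -> GenomeAnnotation:
    """Read a GTF-dialect annotation into a :class:`GenomeAnnotation`.

    Exon features are grouped by their ``gene_id`` attribute.  A gene is
    flagged as transposon-related when its record carries the attribute
    ``transposon "true"`` or, if ``transposon_regex`` is given, when the
    regex matches the gene_id.  Coordinates are 1-based inclusive as on disk.

    When ``chrom_lengths`` is not supplied, each chromosome's length is taken
    as the maximum exon end observed on it.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, bool]] = {}
    pattern = re.compile(transposon_regex) if transposon_regex else None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields, "
                                  f"got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates "
                                  f"{start_s!r}/{end_s!r}") from None
            if start < 1 or end < start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end}]")
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: record has no gene_id attribute")
            is_tn = attrs.get("transposon", "").lower() == "true"
            if pattern is not None and pattern.search(gene_id):
                is_tn = True
            if gene_id in meta:
                prev_chrom, prev_strand, prev_tn = meta[gene_id]
                if prev_chrom != chrom or prev_strand != strand:
                    raise FormatError(f"{path}:{lineno}: gene {gene_id} spans multiple "
                                      f"chromosomes or strands")
                meta[gene_id] = (chrom, strand, prev_tn or is_tn)
            else:
                meta[gene_id] = (chrom, strand, is_tn)
            exons.setdefault(gene_id, []).append((start, end))

    genes = []
    for gene_id, ivals in exons.items():
        chrom, strand, is_tn = meta[gene_id]
        ivals.sort()
        for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValidationError(f"{path}: gene {gene_id} has overlapping exons "
                                      f"({s1},{e1}) and starting at {s2}")
        genes.append(GeneModel(gene_id, chrom, strand, tuple(ivals), is_tn))
    genes.sort(key=lambda g: (g.chromosome, g.span[0], g.gene_id))

    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chromosome] = max(chrom_lengths.get(g.chromosome, 0), g.span[1])
    return GenomeAnnotation(genes, dict(chrom_lengths))


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    """Write exon records in the GTF dialect that :func:`read_annotation` reads."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            for start, end in g.exons:
                attrs = f'gene_id "{g.gene_id}";'
                if g.is_transposon:
                    attrs += ' transposon "true";'
                fh.write("\t".join([
                    g.chromosome, "serptools", "exon", str(start), str(end),
                    ".", g.strand, ".", attrs,
                ]) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
    return sizes


def write_chrom_sizes(chrom_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_lengths):
            fh.write(f"{chrom}\t{chrom_lengths[chrom]}\n")


# ---------------------------------------------------------------------------
# bedGraph dialect
# ---------------------------------------------------------------------------

def read_count_track(
    path,
    condition: str,
    bait: str,
    replicate: int,
    chrom_lengths: dict[str, int],
) -> CountTrack:
    """Read a bedGraph-dialect file into a dense per-nucleotide track.

    bedGraph intervals are 0-based half-open; the dense vectors are 1-based
    (index 0 = position 1).  Positions not covered by any interval are 0.
    Overlapping intervals, intervals beyond the chromosome end and negative
    values are rejected.
    """
    counts = {chrom: np.zeros(length, dtype=float) for chrom, length in chrom_lengths.items()}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            chrom = fields[0]
            if chrom not in counts:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed interval or value") from None
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if end > chrom_lengths[chrom]:
                raise FormatError(f"{path}:{lineno}: interval end {end} beyond chromosome "
                                  f"length {chrom_lengths[chrom]}")
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"{path}:{lineno}: negative or non-finite value {value}")
            if start < last_end.get(chrom, 0):
                raise FormatError(f"{path}:{lineno}: overlapping or unsorted intervals")
            last_end[chrom] = end
            counts[chrom][start:end] = value
    return CountTrack(condition=condition, bait=bait, replicate=replicate, counts=counts)


def write_count_track(track: CountTrack, path) -> None:
    """Write a dense track as run-length-encoded bedGraph (zero runs omitted).

    Values are serialized with 17 significant digits so a write/read round
    trip is bit-identical for float64 data.
    """
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            vec = track.counts[chrom]
            if vec.size == 0:
                continue
            change = np.flatnonzero(np.diff(vec) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [vec.size]])
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


def track_filename(bait: str, condition: str, replicate: int) -> str:
    return f"{bait}.{condition}.rep{replicate}.bedgraph"


# ---------------------------------------------------------------------------
# Gene lists, FASTA, tables
# ---------------------------------------------------------------------------

def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(gene_ids, path) -> None:
    with open(path, "w") as fh:
        for gid in gene_ids:
            fh.write(f"{gid}\n")


def read_truth_set(path, annotation: GenomeAnnotation | None = None) -> TruthSet:
    """Read a plain-text truth set (one gene ID per line).

    Gene IDs absent from the annotation are reported with a warning but kept,
    so the caller can see exactly which records are problematic.
    """
    ids = read_gene_list(path)
    truth = TruthSet(frozenset(ids))
    if annotation is not None:
        known = {g.gene_id for g in annotation.genes}
        unknown = sorted(truth.gene_ids - known)
        if unknown:
            warnings.warn(
                f"{path}: {len(unknown)} truth-set gene(s) not in annotation: "
                + ", ".join(unknown[:10]),
                stacklevel=2,
            )
    return truth


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


HIT_TABLE_COLUMNS = [
    "gene_id", "bait", "auc_ip", "auc_total", "auc_fc", "auc_fc_wt",
    "coverage_ip", "coverage_total", "mean_replicate_corr", "scaled_auc",
    "coverage_ok", "auc_ok", "fc_ok", "corr_ok", "is_hit", "inspected",
]


def write_hit_table(scores, path) -> None:
    """Write per-gene decision records as TSV.

    Rows are ordered by descending scaled AUC with ties broken by gene_id, so
    repeated runs are byte-identical; floats carry 6 decimals.
    """
    rows = [{col: getattr(s, col) for col in HIT_TABLE_COLUMNS} for s in scores]
    df = pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["scaled_auc", "gene_id"], ascending=[False, True], na_position="last"
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def read_hit_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_go_map(path) -> pd.DataFrame:
    """Read a GO mapping TSV with columns gene_id, term_id, term_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id", "term_name"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: GO map lacks column(s) {sorted(missing)}")
    return df
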