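"""Readers/writers for the standard formats the pipeline touches.

All coordinates are internally 0-based half-open.  GFF3 (1-based inclusive)
is converted at the boundary; BED output is natively 0-based half-open.
Nucleotide sequences are normalized on read: uppercased, U->T, and any
remaining non-ACGT IUPAC code replaced by N (counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("ismorf")

BACTERIAL_TABLE = 11
#: start codons of the bacterial genetic code considered here
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: product keywords excluding an annotated protein from the positive set
EXCLUDED_PRODUCT_KEYWORDS = ("hypothetical", "putative", "uncharacterized")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration (unknown schema, bad parameter)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    contig_id: str
    sequence: str
    genome_id: str = ""
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    contig_id: str
    start: int            # 0-based
    end: int              # half-open
    strand: str           # '+' or '-'
    feature_id: str
    feature_type: str = "gene"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"feature {self.feature_id!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.feature_id!r}: strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    genome_id: str
    contigs: list[GenomeSequence]
    features: list[FeatureRecord]
    species_label: str = ""

    def __post_init__(self) -> None:
        if not self.species_label:
            self.species_label = self.genome_id.split("_")[0]
        known = {c.contig_id for c in self.contigs}
        for f in self.features:
            if f.contig_id not in known:
                raise FormatError(
                    f"feature {f.feature_id!r} references unknown contig {f.contig_id!r}"
                )
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.end))

    def contig(self, contig_id: str) -> GenomeSequence:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


# ---------------------------------------------------------------------------
# sequence normalization
# ---------------------------------------------------------------------------

_NORMALIZE = {c: c for c in "ACGTN"}
_NORMALIZE["U"] = "T"


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase, map U->T and any other non-ACGT letter to N.

    Returns the normalized sequence and the count of characters mapped to N
    that were not already N.
    """
    out = []
    n_ambiguous = 0
    for ch in seq.upper():
        mapped = _NORMALIZE.get(ch)
        if mapped is None:
            mapped = "N"
            n_ambiguous += 1
        out.append(mapped)
    return "".join(out), n_ambiguous


def read_fasta(path: str | Path, genome_id: str = "", circular: bool = False) -> list[GenomeSequence]:
    """Read a nucleotide FASTA into normalized :class:`GenomeSequence` records."""
    path = Path(path)
    records = []
    seen: set[str] = set()
    total_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        contig_id = rec.id
        if contig_id in seen:
            raise FormatError(f"{path}: duplicate contig id {contig_id!r}")
        seen.add(contig_id)
        seq, n_amb = normalize_sequence(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: empty sequence for contig {contig_id!r}")
        total_ambiguous += n_amb
        records.append(
            GenomeSequence(contig_id=contig_id, sequence=seq,
                           genome_id=genome_id or path.stem, circular=circular)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if total_ambiguous:
        logger.info("read_fasta(%s): %d ambiguous characters mapped to N",
                    path.name, total_ambiguous)
    return records


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff(path: str | Path, feature_types: Iterable[str] = ("gene",)) -> list[FeatureRecord]:
    """Read GFF3 features of the requested types.

    1-based inclusive coordinates are converted to 0-based half-open.
    ``product`` is taken from the ``product`` attribute, falling back to
    ``Name``.
    """
    wanted = set(feature_types)
    if not wanted:
        raise ConfigurationError("feature_types must be non-empty")
    path = Path(path)
    records: list[FeatureRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig_id, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype not in wanted:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            attrs = _parse_attributes(attr_s)
            feature_id = attrs.get("ID", f"{contig_id}:{start1}-{end1}")
            product = attrs.get("product", attrs.get("Name", ""))
            records.append(
                FeatureRecord(contig_id=contig_id, start=start1 - 1, end=end1,
                              strand=strand, feature_id=feature_id,
                              feature_type=ftype, product=product)
            )
    return records


def write_gff(features: Sequence[FeatureRecord], path: str | Path, source: str = "ismorf") -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            handle.write(
                f"{f.contig_id}\t{source}\t{f.feature_type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# translation and the annotated small-protein positive set
# ---------------------------------------------------------------------------

def translate_cds(cds: str, initiator_to_met: bool = True) -> str:
    """Translate a CDS with the bacterial code (table 11).

    A trailing stop codon is stripped.  When the first codon is a canonical
    bacterial start (ATG/GTG/TTG) the initiator residue is rendered as M.
    Raises ``ValueError`` if length is not a multiple of 3 or an internal
    stop is encountered.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate(table=BACTERIAL_TABLE))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    if initiator_to_met and protein and cds[:3] in START_CODONS:
        protein = "M" + protein[1:]
    return protein


def extract_feature_sequence(genome: AnnotatedGenome, feature: FeatureRecord) -> str:
    """Genomic sequence of a feature, reverse-complemented for '-' strand."""
    seq = genome.contig(feature.contig_id).sequence[feature.start:feature.end]
    if feature.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def select_small_proteins(
    features: Sequence[FeatureRecord],
    genome: AnnotatedGenome,
    max_len: int = 70,
) -> list[tuple[FeatureRecord, str]]:
    """Annotated small proteins (the positive-control set).

    Keeps coding features whose translated product is at most ``max_len``
    amino acids and whose product annotation does not contain
    "hypothetical", "putative" or "uncharacterized" (case-insensitive).
    Features whose length is not a codon multiple are skipped with a
    logged count.
    """
    kept: list[tuple[FeatureRecord, str]] = []
    n_skipped = 0
    for feat in features:
        product_lc = feat.product.lower()
        if any(word in product_lc for word in EXCLUDED_PRODUCT_KEYWORDS):
            continue
        cds = extract_feature_sequence(genome, feat)
        try:
            protein = translate_cds(cds)
        except ValueError:
            n_skipped += 1
            continue
        if 1 <= len(protein) <= max_len:
            kept.append((feat, protein))
    if n_skipped:
        logger.warning("select_small_proteins: skipped %d untranslatable features", n_skipped)
    return kept


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "ig_table": ("ig_id", "genome_id", "contig_id", "start", "end",
                 "left_gene", "right_gene"),
    "ismorf_table": ("orf_id", "ig_id", "genome_id", "contig_id", "start", "end",
                     "strand", "start_codon", "protein", "containment"),
    "cluster_table": ("cluster_id", "member_id", "is_representative"),
    "score_table": ("cluster_id", "dN", "dS", "Kd", "dnds",
                    "n_pairs_total", "n_pairs_used", "flags"),
    "synigs_table": ("synigs_id", "block_id", "genome_id", "ig_id",
                     "species_label", "cluster_id", "intact"),
    "context_table": ("orf_id", "strand", "upstream_relation", "downstream_relation",
                      "dist_upstream", "dist_downstream", "near_downstream",
                      "overlap_1_4"),
    "props_table": ("id", "length", "gravy", "gc_source"),
    "calibration_table": ("source", "statistic", "q_low", "q_high",
                          "q_low_spread_lo", "q_low_spread_hi",
                          "q_high_spread_lo", "q_high_spread_hi", "B", "n_values"),
    "classification_table": ("cluster_id", "label"),
    "turnover_table": ("synigs_id", "cluster_id", "n_genomes", "n_intact",
                       "fraction_intact"),
    "lcb_table": ("block_id", "genome_id", "contig_id", "start", "end", "strand"),
    "truth_table": ("orf_id", "cluster_id", "kind", "genome_id", "contig_id",
                    "start", "end", "strand"),
}


def _format_value(value) -> str:
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_tsv(records: Iterable[dict], path: str | Path, schema_name: str) -> None:
    """Write typed rows as TSV under a documented schema.

    Coordinates are emitted 0-based half-open; floats with 6 significant
    digits; booleans as 0/1.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise ConfigurationError(f"unknown table schema {schema_name!r}")
    columns = TABLE_SCHEMAS[schema_name]
    with open(path, "w") as handle:
        handle.write("\t".join(columns) + "\n")
        for rec in records:
            handle.write("\t".join(_format_value(rec.get(col, "")) for col in columns) + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str, float, str]], path: str | Path) -> None:
    """Write BED6 rows (contig, start, end, name, score, strand)."""
    with open(path, "w") as handle:
        for contig, start, end, name, score, strand in intervals:
            handle.write(f"{contig}\t{start}\t{end}\t{name}\t{_format_value(score)}\t{strand}\n")
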