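"""Readers/writers for genome inputs and the internal coordinate convention.

All genomic intervals are held internally as 0-based half-open ``[start,
end)``; GFF3 and the tabular feature dialect use 1-based inclusive
coordinates and are converted at the I/O boundary. Protein sequences are
restricted to the 20 canonical amino acids plus ``X``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import dendropy
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

HABITATS = ("freshwater", "open_ocean", "coastal", "terrestrial",
            "hot_spring", "salt_lake", "other")
SUBSECTIONS = ("I", "II", "III", "IV", "V", "unknown")

PathLike = Union[str, Path]


class GenomeIOError(ValueError):
    """Raised on malformed input files or contract violations."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence from an annotated proteome."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"empty sequence for protein {self.protein_id!r}")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise GenomeIOError(
                f"protein {self.protein_id!r} contains residues outside the "
                f"20-letter alphabet + X: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a replicon, in internal 0-based half-open coordinates.

    ``protein_id`` is ``None`` for features without a protein product
    (e.g. an xisC insertion element handled as a gene).
    """

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise GenomeIOError(
                f"feature {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(
                f"feature {self.gene_id!r}: unknown strand {self.strand!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    habitat: str = "other"
    subsection: str = "unknown"

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise GenomeIOError(f"unknown habitat label {self.habitat!r}")
        if self.subsection not in SUBSECTIONS:
            raise GenomeIOError(f"unknown subsection label {self.subsection!r}")


@dataclass
class Genome:
    """An annotated genome: proteome, gene features and strain metadata."""

    genome_id: str
    proteins: list[ProteinRecord] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)
    metadata: Optional[GenomeMetadata] = None

    def __post_init__(self) -> None:
        ids = [p.protein_id for p in self.proteins]
        if len(ids) != len(set(ids)):
            raise GenomeIOError(f"duplicate protein ids in genome {self.genome_id!r}")
        known = set(ids)
        for f in self.features:
            if f.protein_id is not None and f.protein_id not in known:
                raise GenomeIOError(
                    f"feature {f.gene_id!r} links unknown protein {f.protein_id!r}"
                )

    @property
    def protein_index(self) -> dict[str, ProteinRecord]:
        return {p.protein_id: p for p in self.proteins}

    @property
    def total_residues(self) -> int:
        return sum(len(p) for p in self.proteins)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: Union[PathLike, TextIO], genome_id: str = "") -> list[ProteinRecord]:
    """Parse a protein FASTA into records, in file order.

    Sequences are uppercased and trailing ``*`` terminators stripped. The
    first whitespace-delimited token of each header is the protein id.
    Duplicate ids or an empty/malformed file raise :class:`GenomeIOError`.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    stripped = text.lstrip()
    if not stripped:
        raise GenomeIOError("empty FASTA input")
    if not stripped.startswith(">"):
        raise GenomeIOError("malformed FASTA: first non-blank line must start with '>'")

    from io import StringIO

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        pid = rec.id
        if pid in seen:
            raise GenomeIOError(f"duplicate protein id {pid!r} in FASTA input")
        seen.add(pid)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(protein_id=pid, genome_id=genome_id, sequence=seq))
    if not records:
        raise GenomeIOError("FASTA input contains no records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Features (GFF3 + TSV dialect)

TSV_FEATURE_COLUMNS = ["gene_id", "replicon_id", "start", "end", "strand", "protein_id"]


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    from urllib.parse import unquote

    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GenomeIOError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[unquote(key)] = unquote(value)
    return attrs


def read_features(
    path: Union[PathLike, TextIO],
    dialect: str = "gff3",
    genome_id: str = "",
    protein_attribute: str = "protein_id",
) -> list[GeneFeature]:
    """Read gene features, converting to internal 0-based half-open coordinates.

    ``gff3``: only CDS rows are consumed; the protein link is taken from the
    ``protein_attribute`` attribute key (falling back to ``ID``). ``tsv``:
    header ``gene_id, replicon_id, start, end, strand, protein_id`` with
    1-based inclusive coordinates; empty protein_id means no product.
    """
    if dialect not in ("gff3", "tsv"):
        raise GenomeIOError(f"unknown feature dialect {dialect!r}")
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()

    feats: list[GeneFeature] = []
    if dialect == "gff3":
        for ln, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"GFF3 line {ln}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr_text = cols
            if ftype not in ("CDS", "gene"):
                continue
            attrs = _parse_gff3_attributes(attr_text)
            if ftype != "CDS":
                continue
            if strand not in ("+", "-"):
                raise GenomeIOError(f"GFF3 line {ln}: unsupported strand {strand!r} on a CDS")
            start_i, end_i = int(start) - 1, int(end)
            if end_i <= start_i:
                raise GenomeIOError(f"GFF3 line {ln}: end < start after conversion")
            pid = attrs.get(protein_attribute, attrs.get("ID"))
            gene_id = attrs.get("ID", pid or f"feature{ln}")
            if pid == "":
                pid = None
            feats.append(GeneFeature(gene_id=gene_id, genome_id=genome_id,
                                     replicon_id=seqid, start=start_i, end=end_i,
                                     strand=strand, protein_id=pid))
    else:
        if not lines:
            raise GenomeIOError("empty feature TSV")
        header = lines[0].rstrip("\n").split("\t")
        if header != TSV_FEATURE_COLUMNS:
            raise GenomeIOError(
                f"feature TSV header must be {TSV_FEATURE_COLUMNS}, got {header}")
        for ln, line in enumerate(lines[1:], 2):
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise GenomeIOError(f"feature TSV line {ln}: expected 6 columns")
            gene_id, replicon_id, start, end, strand, pid = cols
            if strand not in ("+", "-"):
                raise GenomeIOError(f"feature TSV line {ln}: unknown strand {strand!r}")
            start_i, end_i = int(start) - 1, int(end)
            if end_i <= start_i:
                raise GenomeIOError(f"feature TSV line {ln}: end < start after conversion")
            feats.append(GeneFeature(gene_id=gene_id, genome_id=genome_id,
                                     replicon_id=replicon_id, start=start_i, end=end_i,
                                     strand=strand, protein_id=pid or None))
    return feats


def write_features(features: Iterable[GeneFeature], path: PathLike,
                   dialect: str = "gff3", protein_attribute: str = "protein_id") -> None:
    """Write features, converting back to 1-based inclusive coordinates."""
    feats = list(features)
    with open(path, "w", newline="\n") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in feats:
                attrs = [f"ID={f.gene_id}"]
                if f.protein_id is not None:
                    attrs.append(f"{protein_attribute}={f.protein_id}")
                fh.write("\t".join([
                    f.replicon_id, "hydroscan", "CDS", str(f.start + 1), str(f.end),
                    ".", f.strand, "0", ";".join(attrs),
                ]) + "\n")
        elif dialect == "tsv":
            fh.write("\t".join(TSV_FEATURE_COLUMNS) + "\n")
            for f in feats:
                fh.write("\t".join([
                    f.gene_id, f.replicon_id, str(f.start + 1), str(f.end),
                    f.strand, f.protein_id or "",
                ]) + "\n")
        else:
            raise GenomeIOError(f"unknown feature dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Metadata


def read_metadata(path: Union[PathLike, TextIO]) -> dict[str, GenomeMetadata]:
    """Read strain metadata TSV (header: genome_id, habitat, subsection).

    Unrecognized habitat strings map to ``other`` with a logged warning;
    a missing subsection maps to ``unknown``. Duplicate genome rows error.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenomeIOError("empty metadata TSV")
    header = lines[0].split("\t")
    if header[:3] != ["genome_id", "habitat", "subsection"]:
        raise GenomeIOError("metadata TSV header must be genome_id, habitat, subsection")
    out: dict[str, GenomeMetadata] = {}
    for ln, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        cols = line.split("\t")
        gid = cols[0]
        habitat = cols[1] if len(cols) > 1 else ""
        subsection = cols[2] if len(cols) > 2 else ""
        if gid in out:
            raise GenomeIOError(f"duplicate genome_id {gid!r} in metadata (line {ln})")
        if habitat not in HABITATS:
            logger.warning("genome %s: unrecognized habitat %r mapped to 'other'",
                           gid, habitat)
            habitat = "other"
        if subsection not in SUBSECTIONS:
            subsection = "unknown"
        out[gid] = GenomeMetadata(genome_id=gid, habitat=habitat, subsection=subsection)
    return out


def write_metadata(metadata: Iterable[GenomeMetadata], path: PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("genome_id\thabitat\tsubsection\n")
        for m in metadata:
            fh.write(f"{m.genome_id}\t{m.habitat}\t{m.subsection}\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: Union[PathLike, TextIO]) -> dendropy.Tree:
    """Load a species tree whose leaf names are genome ids."""
    kwargs = dict(schema="newick", preserve_underscores=True,
                  suppress_internal_node_taxa=True)
    try:
        if hasattr(path, "read"):
            tree = dendropy.Tree.get(data=path.read(), **kwargs)
        else:
            tree = dendropy.Tree.get(path=str(path), **kwargs)
    except Exception as exc:  # dendropy raises several parse error types
        raise GenomeIOError(f"newick parse error: {exc}") from exc
    return tree


def tree_leaf_names(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]


# ---------------------------------------------------------------------------
# Whole-genome convenience loaders


def load_genome_dir(directory: PathLike, genome_id: str,
                    metadata: Optional[GenomeMetadata] = None) -> Genome:
    """Load ``<genome_id>.faa`` + ``<genome_id>.gff3`` from a cohort directory."""
    directory = Path(directory)
    proteins = read_fasta(directory / f"{genome_id}.faa", genome_id=genome_id)
    features = read_features(directory / f"{genome_id}.gff3", dialect="gff3",
                             genome_id=genome_id)
    return Genome(genome_id=genome_id, proteins=proteins, features=features,
                  metadata=metadata or GenomeMetadata(genome_id=genome_id))
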