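"""Readers, writers and validators for every file format the pipeline touches.

FASTA parsing goes through Biopython; the tabular side formats (domain
coordinates, expression, tRNA copy numbers) are plain TSV read with pandas.
The secondary-structure file is a simple stanza format: a ``>gene`` header
line, the sequence, the dot-bracket string, and an optional comma-separated
per-base pairing-probability line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STOP_CODONS

logger = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "DomainAnnotation",
    "StructureAnnotation",
    "SequenceIOError",
    "DuplicateIdError",
    "EmptySequenceError",
    "validate_cds",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_protein_alignment",
    "write_fasta",
    "pairwise_identity",
    "filter_ortholog_pairs",
    "read_domain_table",
    "write_domain_table",
    "read_structure_file",
    "write_structure_file",
    "read_expression_table",
    "write_expression_table",
    "read_trna_table",
    "write_trna_table",
]


class SequenceIOError(ValueError):
    """Malformed input file."""


class DuplicateIdError(SequenceIOError):
    pass


class EmptySequenceError(SequenceIOError):
    pass


@dataclass(frozen=True)
class CodingSequence:
    gene_id: str
    seq: str
    species: str = ""
    valid: bool = True
    invalid_reason: str | None = None

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self, drop_stop: bool = True) -> list[str]:
        end = len(self.seq) - (3 if drop_stop and self.seq[-3:] in STOP_CODONS else 0)
        return [self.seq[i : i + 3] for i in range(0, end, 3)]


@dataclass(frozen=True)
class DomainAnnotation:
    """Protein-coordinate domain intervals, 1-based inclusive."""

    gene_id: str
    intervals: tuple[tuple[str, int, int], ...]  # (domain id, start, end)

    def merged_mask(self, protein_length: int) -> list[bool]:
        """Per-residue in-domain mask; overlapping intervals are merged."""
        mask = [False] * protein_length
        for _dom, start, end in self.intervals:
            if not (1 <= start <= end <= protein_length):
                raise ValueError(
                    f"{self.gene_id}: domain interval ({start},{end}) outside "
                    f"protein of length {protein_length}"
                )
            for i in range(start - 1, end):
                mask[i] = True
        return mask


@dataclass(frozen=True)
class StructureAnnotation:
    """Dot-bracket secondary structure over CDS (or mature-mRNA) coordinates."""

    gene_id: str
    seq: str
    dotbracket: str
    pair_probs: tuple[float, ...] | None = None
    cds_offset: int = 0  # 0-based offset of CDS start within the structure

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.seq):
            raise SequenceIOError(
                f"{self.gene_id}: structure length {len(self.dotbracket)} != "
                f"sequence length {len(self.seq)}"
            )
        depth = 0
        for ch in self.dotbracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise SequenceIOError(f"{self.gene_id}: unbalanced dot-bracket")
            elif ch != ".":
                raise SequenceIOError(f"{self.gene_id}: bad structure char {ch!r}")
        if depth != 0:
            raise SequenceIOError(f"{self.gene_id}: unbalanced dot-bracket")
        if self.pair_probs is not None and len(self.pair_probs) != len(self.seq):
            raise SequenceIOError(f"{self.gene_id}: probability line length mismatch")


# ---------------------------------------------------------------------------
# CDS validation

_VALIDATION_RULES = ("no-start", "length-not-multiple-of-3", "no-stop", "internal-stop")


def validate_cds(seq: str, check_internal_stops: bool = True) -> tuple[bool, str | None]:
    """Check the canonical CDS rules: ATG start, full triplets, canonical
    stop, and (optionally) no in-frame internal stop.

    Returns ``(verdict, reason)`` where ``reason`` names the first failed
    rule, or ``None`` when valid. An empty sequence raises
    :class:`EmptySequenceError`.
    """
    if not seq:
        raise EmptySequenceError("empty sequence")
    seq = seq.upper()
    if not seq.startswith("ATG"):
        return False, "no-start"
    if len(seq) % 3:
        return False, "length-not-multiple-of-3"
    if seq[-3:] not in STOP_CODONS:
        return False, "no-stop"
    if check_internal_stops:
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in STOP_CODONS:
                return False, "internal-stop"
    return True, None


# ---------------------------------------------------------------------------
# FASTA

def read_cds_fasta(
    path: str | Path, species: str = "", check_internal_stops: bool = True
) -> list[CodingSequence]:
    """Read a CDS FASTA; invalid records are retained but flagged."""
    records: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        ok, reason = validate_cds(seq, check_internal_stops=check_internal_stops)
        records.append(CodingSequence(rec.id, seq, species, ok, reason))
    if not records:
        logger.warning("no records in %s", path)
    return records


def write_cds_fasta(path: str | Path, records: Iterable[CodingSequence]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.gene_id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_fasta(path: str | Path, named_seqs: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in named_seqs.items()),
        str(path),
        "fasta",
    )


def read_protein_alignment(path: str | Path) -> list[SeqRecord]:
    """Aligned protein FASTA (2 or 3 sequences, equal lengths, '-' gaps)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise SequenceIOError(f"{path}: alignment needs >=2 sequences")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise SequenceIOError(f"{path}: unequal aligned lengths {sorted(lengths)}")
    return records


def pairwise_identity(a: str, b: str, denominator: str = "ungapped") -> float:
    """Percent identity of two aligned sequences.

    ``denominator='ungapped'`` counts only columns where neither sequence
    has a gap (the conservative reading of an identity filter over
    alignment coverage); ``'columns'`` uses the full alignment length.
    """
    if len(a) != len(b):
        raise SequenceIOError("aligned sequences have different lengths")
    pairs = list(zip(a.upper(), b.upper()))
    if denominator == "ungapped":
        pairs = [(x, y) for x, y in pairs if x != "-" and y != "-"]
    elif denominator != "columns":
        raise ValueError(f"unknown denominator {denominator!r}")
    if not pairs:
        return 0.0
    same = sum(1 for x, y in pairs if x == y)
    return 100.0 * same / len(pairs)


def filter_ortholog_pairs(
    alignments: Sequence[Sequence[SeqRecord]],
    min_identity: float = 60.0,
    denominator: str = "ungapped",
) -> list[Sequence[SeqRecord]]:
    """Keep alignments whose minimum pairwise identity exceeds the threshold."""
    kept = []
    for aln in alignments:
        idents = [
            pairwise_identity(str(aln[i].seq), str(aln[j].seq), denominator)
            for i in range(len(aln))
            for j in range(i + 1, len(aln))
        ]
        if min(idents) > min_identity:
            kept.append(aln)
    return kept


# ---------------------------------------------------------------------------
# Tabular side files (TSV)

def read_domain_table(path: str | Path) -> dict[str, DomainAnnotation]:
    """TSV with columns gene, domain, start, end (protein coords, 1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "domain", "start", "end"}
    if not required.issubset(df.columns):
        raise SequenceIOError(f"{path}: domain table needs columns {sorted(required)}")
    out: dict[str, DomainAnnotation] = {}
    for gene, grp in df.groupby("gene", sort=True):
        ivals = tuple(
            (str(r.domain), int(r.start), int(r.end)) for r in grp.itertuples()
        )
        for _d, s, e in ivals:
            if not (1 <= s <= e):
                raise SequenceIOError(f"{path}: bad interval ({s},{e}) for {gene}")
        out[str(gene)] = DomainAnnotation(str(gene), ivals)
    return out


def write_domain_table(path: str | Path, annotations: Iterable[DomainAnnotation]) -> None:
    rows = [
        {"gene": ann.gene_id, "domain": dom, "start": s, "end": e}
        for ann in annotations
        for dom, s, e in ann.intervals
    ]
    pd.DataFrame(rows, columns=["gene", "domain", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_structure_file(path: str | Path) -> dict[str, StructureAnnotation]:
    """Read the stanza structure format (header/sequence/dot-bracket[/probs])."""
    out: dict[str, StructureAnnotation] = {}
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise SequenceIOError(f"{path}: expected '>' header at line {i + 1}")
        gene = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise SequenceIOError(f"{path}: truncated stanza for {gene}")
        seq, db = lines[i + 1], lines[i + 2]
        i += 3
        probs: tuple[float, ...] | None = None
        if i < len(lines) and not lines[i].startswith(">") and "," in lines[i]:
            probs = tuple(float(x) for x in lines[i].split(","))
            i += 1
        if gene in out:
            raise DuplicateIdError(f"duplicate structure for {gene}")
        out[gene] = StructureAnnotation(gene, seq.upper(), db, probs)
    return out


def write_structure_file(path: str | Path, annotations: Iterable[StructureAnnotation]) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            fh.write(f">{ann.gene_id}\n{ann.seq}\n{ann.dotbracket}\n")
            if ann.pair_probs is not None:
                fh.write(",".join(f"{p:.4g}" for p in ann.pair_probs) + "\n")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Long TSV (gene, experiment, value) -> gene x experiment frame.

    Absent (gene, experiment) cells become NaN, which is distinct from an
    explicit zero.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "experiment", "value"}
    if not required.issubset(df.columns):
        raise SequenceIOError(f"{path}: expression table needs columns {sorted(required)}")
    if (df["value"].dropna() < 0).any():
        raise SequenceIOError(f"{path}: negative expression values")
    return df.pivot_table(index="gene", columns="experiment", values="value", aggfunc="first")


def write_expression_table(path: str | Path, wide: pd.DataFrame) -> None:
    long = wide.stack().rename("value").reset_index()
    long.columns = ["gene", "experiment", "value"]
    long.to_csv(path, sep="\t", index=False)


def read_trna_table(path: str | Path) -> dict[str, int]:
    """TSV (codon, copies) -> codon -> tRNA gene copy count."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"codon", "copies"}.issubset(df.columns):
        raise SequenceIOError(f"{path}: tRNA table needs columns codon, copies")
    out: dict[str, int] = {}
    for r in df.itertuples():
        n = int(r.copies)
        if n < 0:
            raise SequenceIOError(f"{path}: negative copy count for {r.codon}")
        out[str(r.codon).upper()] = n
    return out


def write_trna_table(path: str | Path, counts: Mapping[str, int]) -> None:
    pd.DataFrame(
        sorted(counts.items()), columns=["codon", "copies"]
    ).to_csv(path, sep="\t", index=False)
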