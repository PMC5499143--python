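"""Codon alignments and per-site evolutionary classification.

A protein alignment plus the underlying coding sequences yields a codon
alignment; each column is then classified as conserved / variable /
excluded. Three dataset variants are supported:

* pairwise ("original"): conserved iff the two amino acids are identical;
* phylogeny-based: a three-species alignment on the fixed topology
  ((principal, sister), outgroup); only changes parsimony-assigned to the
  sister branch count as variable, so codon bias in the principal species
  cannot be an artefact of its own nonsynonymous substitutions;
* optimality-tied: variable sites are additionally filtered so that both
  codons (and every intermediate on every mutational pathway, for
  two-base amino-acid changes) share the same third base and the same
  favoured third base of their families.

Columns also carry protein-domain membership, mRNA stem/loop state of the
codon's third base, and the transcript third the codon falls in.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.SeqRecord import SeqRecord

from .genetic_code import CODON_TO_AA, family_of, is_sense_codon
from .sequence_io import CodingSequence, DomainAnnotation, StructureAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "GAP",
    "CodonAlignment",
    "SiteClassification",
    "TranslationMismatchError",
    "build_codon_alignment",
    "classify_pairwise",
    "classify_phylogeny",
    "optimality_tied_filter",
    "annotate_domain",
    "annotate_structure",
    "assign_thirds",
    "write_site_table",
]

GAP = "---"

CONSERVED = "conserved"
VARIABLE = "variable"
EXCLUDED = "excluded"


class TranslationMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon columns for 2 (principal, partner) or 3
    (principal, sister, outgroup) species.

    ``columns[i]`` holds one codon string (or :data:`GAP`) per species, in
    role order. ``principal_pos[i]`` is the 1-based ungapped position of
    column ``i`` in the principal protein (None at principal gaps).
    """

    gene_ids: tuple[str, ...]  # one id per role, principal first
    columns: tuple[tuple[str, ...], ...]
    principal_pos: tuple[int | None, ...]

    @property
    def n_species(self) -> int:
        return len(self.gene_ids)

    def __len__(self) -> int:
        return len(self.columns)

    def principal_codon(self, column: int) -> str:
        return self.columns[column][0]


@dataclass
class SiteClassification:
    """Per-column evolutionary state plus annotation flags."""

    gene_id: str
    state: list[str]  # conserved / variable / excluded
    lineage: list[str]  # sister / principal / outgroup-or-ancestral / ambiguous / none
    in_domain: list[bool] = field(default_factory=list)
    structure: list[str] = field(default_factory=list)  # S / L / unknown
    third: list[int] = field(default_factory=list)  # transcript third 1/2/3, 0 unknown

    def __post_init__(self) -> None:
        n = len(self.state)
        if not self.in_domain:
            self.in_domain = [False] * n
        if not self.structure:
            self.structure = ["unknown"] * n
        if not self.third:
            self.third = [0] * n

    def counts(self) -> dict[str, int]:
        out = {CONSERVED: 0, VARIABLE: 0, EXCLUDED: 0}
        for s in self.state:
            out[s] += 1
        return out


# ---------------------------------------------------------------------------
# Codon alignment construction

def build_codon_alignment(
    protein_alignment: Sequence[SeqRecord] | Sequence[tuple[str, str]],
    cds_by_role: Sequence[CodingSequence],
) -> CodonAlignment:
    """Back-translate a protein alignment onto the per-species CDS.

    ``protein_alignment`` entries may be Biopython records or plain
    ``(gene_id, aligned_seq)`` tuples, principal species first, in the same
    role order as ``cds_by_role``. Each CDS (minus its stop) must translate
    exactly to its ungapped protein sequence.
    """
    aligned: list[tuple[str, str]] = [
        (rec.id, str(rec.seq)) if isinstance(rec, SeqRecord) else (rec[0], str(rec[1]))
        for rec in protein_alignment
    ]
    if len(aligned) != len(cds_by_role):
        raise ValueError("one CDS per aligned protein is required")

    per_species_codons: list[list[str]] = []
    for (gene_id, aln_seq), cds in zip(aligned, cds_by_role):
        codons = cds.codons(drop_stop=True)
        ungapped = aln_seq.replace("-", "").upper()
        if len(codons) != len(ungapped):
            raise TranslationMismatchError(
                f"{gene_id}: {len(codons)} codons vs {len(ungapped)} residues"
            )
        for i, (codon, aa) in enumerate(zip(codons, ungapped)):
            trans = CODON_TO_AA.get(codon, "X")
            if trans != aa and trans != "X":
                raise TranslationMismatchError(
                    f"{gene_id}: codon {codon} at protein position {i + 1} "
                    f"translates to {trans}, alignment says {aa}"
                )
        per_species_codons.append(codons)

    length = len(aligned[0][1])
    columns: list[tuple[str, ...]] = []
    principal_pos: list[int | None] = []
    cursors = [0] * len(aligned)
    for col in range(length):
        row: list[str] = []
        for s, (_gid, aln_seq) in enumerate(aligned):
            if aln_seq[col] == "-":
                row.append(GAP)
            else:
                row.append(per_species_codons[s][cursors[s]])
                cursors[s] += 1
        columns.append(tuple(row))
        principal_pos.append(cursors[0] if row[0] != GAP else None)
    return CodonAlignment(
        gene_ids=tuple(gid for gid, _ in aligned),
        columns=tuple(columns),
        principal_pos=tuple(principal_pos),
    )


def _aa(codon: str) -> str | None:
    if codon == GAP:
        return None
    return CODON_TO_AA.get(codon, "X")


# ---------------------------------------------------------------------------
# Site classification

def classify_pairwise(aln: CodonAlignment) -> SiteClassification:
    """Original variant: conserved iff identical amino acids, variable iff
    both present and different, excluded at gaps or ambiguous codons."""
    if aln.n_species != 2:
        raise ValueError("pairwise classification needs a 2-species alignment")
    state, lineage = [], []
    for a, b in aln.columns:
        x, y = _aa(a), _aa(b)
        if x is None or y is None or "X" in (x, y):
            state.append(EXCLUDED)
            lineage.append("none")
        elif x == y:
            state.append(CONSERVED)
            lineage.append("none")
        else:
            state.append(VARIABLE)
            lineage.append("none")
    return SiteClassification(aln.gene_ids[0], state, lineage)


def classify_phylogeny(aln: CodonAlignment) -> SiteClassification:
    """Phylogeny-based variant on the fixed topology ((P, S), O).

    Single-column parsimony: a change is attributed to the sister branch
    only when aa(P) = aa(O) != aa(S); only those sites are variable.
    Changes on the principal branch, changes not placeable unambiguously
    (P = S != O can sit on the outgroup or the internal branch), and
    columns where all three differ are excluded.
    """
    if aln.n_species != 3:
        raise ValueError("phylogeny classification needs a (P, S, O) trio alignment")
    state, lineage = [], []
    for p, s, o in aln.columns:
        ap, as_, ao = _aa(p), _aa(s), _aa(o)
        if None in (ap, as_, ao) or "X" in (ap, as_, ao):
            state.append(EXCLUDED)
            lineage.append("none")
        elif ap == as_ == ao:
            state.append(CONSERVED)
            lineage.append("none")
        elif ap == ao != as_:
            state.append(VARIABLE)
            lineage.append("sister")
        elif as_ == ao != ap:
            state.append(EXCLUDED)
            lineage.append("principal")
        elif ap == as_ != ao:
            state.append(EXCLUDED)
            lineage.append("outgroup-or-ancestral")
        else:
            state.append(EXCLUDED)
            lineage.append("ambiguous")
    return SiteClassification(aln.gene_ids[0], state, lineage)


# ---------------------------------------------------------------------------
# Optimality-tied filter

def _favored_base(codon: str, favored: Mapping[str, str | None]) -> str | None:
    return favored.get(family_of(codon))


def mutation_pathways(codon_a: str, codon_b: str) -> list[list[str]]:
    """All stepwise single-base pathways from ``codon_a`` to ``codon_b``.

    Each pathway is the list of intermediate codons strictly between the
    endpoints (empty for 0- or 1-base differences). All orderings of the
    differing positions are enumerated.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    pathways: list[list[str]] = []
    for order in itertools.permutations(diff):
        cur = list(codon_a)
        steps: list[str] = []
        for pos in order:
            cur[pos] = codon_b[pos]
            steps.append("".join(cur))
        pathways.append(steps[:-1] if steps else [])
    # dedupe (permutations of a single position collapse)
    seen, out = set(), []
    for p in pathways:
        key = tuple(p)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def optimality_tied_filter(
    codon_a: str,
    codon_b: str,
    favored_base_by_family: Mapping[str, str | None],
) -> tuple[bool, str | None]:
    """Decide whether a variable-site codon pair enters the optimality-tied
    dataset.

    Kept iff (a) both codons carry the identical third (silent) base,
    (b) the favoured third base of both codons' families is defined and
    identical, and (c) for pairs differing at the first and second bases,
    every intermediate codon on every substitution ordering is a sense
    codon that also satisfies (a) and (b). Returns ``(keep, reason)`` with
    a reason code on drop.
    """
    for c in (codon_a, codon_b):
        if not is_sense_codon(c):
            raise ValueError(f"not a sense codon: {c!r}")
    if codon_a == codon_b:
        return True, None
    if codon_a[2] != codon_b[2]:
        return False, "silent-base-changed"
    fav_a = _favored_base(codon_a, favored_base_by_family)
    fav_b = _favored_base(codon_b, favored_base_by_family)
    if fav_a is None or fav_b is None:
        return False, "no-favored-base"
    if fav_a != fav_b:
        return False, "favored-base-differs"
    for pathway in mutation_pathways(codon_a, codon_b):
        for mid in pathway:
            if not is_sense_codon(mid):
                return False, "pathway-through-stop"
            fav_mid = _favored_base(mid, favored_base_by_family)
            if fav_mid is None:
                return False, "pathway-no-favored-base"
            if fav_mid != fav_a:
                return False, "pathway-favored-base-differs"
    return True, None


def apply_optimality_tied(
    aln: CodonAlignment,
    sites: SiteClassification,
    favored_base_by_family: Mapping[str, str | None],
) -> SiteClassification:
    """Demote variable sites failing the optimality-tied filter to excluded.

    Works on pairwise alignments (principal vs partner codons) and on trio
    alignments (principal vs sister codons at sister-lineage sites).
    """
    out = SiteClassification(
        sites.gene_id,
        list(sites.state),
        list(sites.lineage),
        list(sites.in_domain),
        list(sites.structure),
        list(sites.third),
    )
    partner = 1  # sister in trio mode, partner in pairwise mode
    for i, st in enumerate(sites.state):
        if st != VARIABLE:
            continue
        a = aln.columns[i][0]
        b = aln.columns[i][partner]
        keep, _reason = optimality_tied_filter(a, b, favored_base_by_family)
        if not keep:
            out.state[i] = EXCLUDED
    return out


# ---------------------------------------------------------------------------
# Annotation flags

def annotate_domain(
    sites: SiteClassification,
    aln: CodonAlignment,
    annotation: DomainAnnotation | None,
    protein_length: int,
) -> SiteClassification:
    """Flag columns whose ungapped principal position lies in any domain."""
    if annotation is None:
        sites.in_domain = [False] * len(sites.state)
        return sites
    mask = annotation.merged_mask(protein_length)
    flags = []
    for pos in aln.principal_pos:
        flags.append(bool(mask[pos - 1]) if pos is not None else False)
    sites.in_domain = flags
    return sites


def annotate_structure(
    sites: SiteClassification,
    aln: CodonAlignment,
    structure: StructureAnnotation,
    strong_pair_threshold: float = 0.9,
) -> SiteClassification:
    """Assign S (strongly paired third base) / L per column.

    Codon i (1-based, principal ungapped coordinates) has its third base at
    structure position ``cds_offset + 3*i`` (1-based). With pairing
    probabilities available, S additionally requires probability >= the
    threshold; without them, any paired third base is S.
    """
    n_codons = max((p for p in aln.principal_pos if p is not None), default=0)
    need = structure.cds_offset + 3 * n_codons
    if len(structure.dotbracket) < need:
        raise ValueError(
            f"{sites.gene_id}: structure length {len(structure.dotbracket)} "
            f"shorter than CDS extent {need}"
        )
    out = []
    for pos in aln.principal_pos:
        if pos is None:
            out.append("unknown")
            continue
        idx = structure.cds_offset + 3 * pos - 1  # 0-based third-base index
        paired = structure.dotbracket[idx] in "()"
        if paired and structure.pair_probs is not None:
            paired = structure.pair_probs[idx] >= strong_pair_threshold
        out.append("S" if paired else "L")
    sites.structure = out
    return sites


def assign_thirds(sites: SiteClassification, aln: CodonAlignment, n_codons: int) -> SiteClassification:
    """Label each column with the transcript third its codon falls in.

    The CDS is split into three contiguous blocks of ``n_codons // 3``
    codons; the remainder goes to the last block.
    """
    block = n_codons // 3
    if block == 0:
        logger.warning("%s: CDS of %d codons too short for thirds", sites.gene_id, n_codons)
    labels = []
    for pos in aln.principal_pos:
        if pos is None:
            labels.append(0)
        elif block and pos <= block:
            labels.append(1)
        elif block and pos <= 2 * block:
            labels.append(2)
        else:
            labels.append(3)
    sites.third = labels
    return sites


# ---------------------------------------------------------------------------
# Export

def write_site_table(path: str | Path, entries: Sequence[tuple[CodonAlignment, SiteClassification]]) -> None:
    """TSV pseudoalignment: gene, column, principal codon, state, lineage,
    domain flag, stem/loop class, transcript third."""
    with open(path, "w") as fh:
        fh.write("gene\tcolumn\tcodon\tstate\tlineage\tin_domain\tstructure\tthird\n")
        for aln, sites in entries:
            for i, st in enumerate(sites.state):
                fh.write(
                    f"{sites.gene_id}\t{i + 1}\t{aln.columns[i][0]}\t{st}\t"
                    f"{sites.lineage[i]}\t{int(sites.in_domain[i])}\t"
                    f"{sites.structure[i]}\t{sites.third[i]}\n"
                )
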