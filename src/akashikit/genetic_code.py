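"""Standard nuclear genetic-code tables and codon-family bookkeeping.

Every other module draws on the constants here: the 61 sense codons, the
three stops, the synonymous families (one family per amino acid by default,
with an optional split of the sixfold Leu/Ser/Arg families into their
two- and fourfold subfamilies), and the family degeneracy ``n`` that
normalises tRNA-RSCU values.

Sequences are handled in DNA alphabet (T, not U).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Seq import Seq

__all__ = [
    "BASES",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CODON_TO_AA",
    "InvalidCodonError",
    "StopCodonError",
    "family_of",
    "family_codons",
    "families",
    "degeneracy",
    "synonymous_peers",
    "translate_cds",
    "is_sense_codon",
]

BASES = "ACGT"

#: codon -> one-letter amino acid, '*' for stops (standard nuclear code)
CODON_TO_AA: dict[str, str] = {
    c: str(Seq(c).translate())
    for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
}

STOP_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TO_AA.items() if aa != "*"))

# Sixfold families split into their subfamilies (2-fold + 4-fold blocks);
# keys are the amino acid letter suffixed with the subfamily degeneracy.
_SIXFOLD_SPLIT = {
    "L": {"L2": ("TTA", "TTG"), "L4": ("CTA", "CTC", "CTG", "CTT")},
    "S": {"S2": ("AGC", "AGT"), "S4": ("TCA", "TCC", "TCG", "TCT")},
    "R": {"R2": ("AGA", "AGG"), "R4": ("CGA", "CGC", "CGG", "CGT")},
}


class InvalidCodonError(ValueError):
    """Raised for non-ACGT triplets or strings that are not a codon."""


class StopCodonError(InvalidCodonError):
    """Raised when a stop codon is supplied where a sense codon is required."""


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in BASES for b in codon.upper()):
        raise InvalidCodonError(f"not a valid ACGT codon: {codon!r}")
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise StopCodonError(f"stop codon not allowed here: {codon}")
    return codon


@lru_cache(maxsize=2)
def families(split_sixfold: bool = False) -> dict[str, tuple[str, ...]]:
    """Map family key -> lexicographically sorted codon tuple.

    With ``split_sixfold=False`` (default) each amino acid is one family,
    so Leu/Ser/Arg each form a single six-codon family. With
    ``split_sixfold=True`` those three are replaced by their 2+4 subfamilies
    (keys ``L2``, ``L4``, ...), a sensitivity-analysis variant.
    """
    fams: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        fams.setdefault(CODON_TO_AA[codon], []).append(codon)
    out: dict[str, tuple[str, ...]] = {}
    for aa, codons in sorted(fams.items()):
        if split_sixfold and aa in _SIXFOLD_SPLIT:
            for key, sub in _SIXFOLD_SPLIT[aa].items():
                out[key] = tuple(sorted(sub))
        else:
            out[aa] = tuple(sorted(codons))
    return out


@lru_cache(maxsize=2)
def _codon_to_family(split_sixfold: bool = False) -> dict[str, str]:
    return {
        codon: key
        for key, codons in families(split_sixfold).items()
        for codon in codons
    }


def family_of(codon: str, split_sixfold: bool = False) -> str:
    """Family key of a sense codon (amino acid letter, or e.g. ``L2``)."""
    return _codon_to_family(split_sixfold)[_check_codon(codon)]


def family_codons(codon: str, split_sixfold: bool = False) -> tuple[str, ...]:
    """All codons of the family containing ``codon`` (including itself)."""
    return families(split_sixfold)[family_of(codon, split_sixfold)]


def degeneracy(codon: str, split_sixfold: bool = False) -> int:
    """Family size n in {1, 2, 3, 4, 6} of a sense codon's family."""
    return len(family_codons(codon, split_sixfold))


def synonymous_peers(codon: str, split_sixfold: bool = False) -> list[str]:
    """Synonymous codons of ``codon``, excluding itself, in lexicographic order.

    Raises :class:`StopCodonError` for stops and :class:`InvalidCodonError`
    for non-ACGT triplets.
    """
    codon = _check_codon(codon)
    return [c for c in family_codons(codon, split_sixfold) if c != codon]


def is_sense_codon(codon: str) -> bool:
    return (
        isinstance(codon, str)
        and len(codon) == 3
        and codon.upper() in CODON_TO_AA
        and CODON_TO_AA[codon.upper()] != "*"
    )


def translate_cds(seq: str) -> str:
    """Translate an in-frame nucleotide sequence; stops appear as ``*``.

    Codons containing ambiguous bases translate to ``X`` and are excluded
    from all downstream counts rather than guessed.
    """
    if len(seq) % 3:
        raise InvalidCodonError("sequence length is not a multiple of 3")
    seq = seq.upper()
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)
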