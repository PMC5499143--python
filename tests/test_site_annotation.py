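import pytest
from hypothesis import given, settings, strategies as st

from akashikit import site_annotation as sa
from akashikit.genetic_code import SENSE_CODONS
from akashikit.sequence_io import (
    CodingSequence,
    DomainAnnotation,
    StructureAnnotation,
)

from oracles import AMINO_ACIDS, brute_force_tied, fitch_lineage


def _aln(columns, n_species=2, gene_ids=None):
    """Helper: build a CodonAlignment straight from codon columns."""
    principal_pos = []
    pos = 0
    for col in columns:
        if col[0] == sa.GAP:
            principal_pos.append(None)
        else:
            pos += 1
            principal_pos.append(pos)
    return sa.CodonAlignment(
        gene_ids=tuple(gene_ids or [f"s{i}" for i in range(n_species)]),
        columns=tuple(tuple(c) for c in columns),
        principal_pos=tuple(principal_pos),
    )


# ---------------------------------------------------------------------------
# build_codon_alignment

def test_build_codon_alignment_plain():
    aln = sa.build_codon_alignment(
        [("a", "MK"), ("b", "MK")],
        [CodingSequence("a", "ATGAAATAA"), CodingSequence("b", "ATGAAGTAA")],
    )
    assert aln.columns == ((("ATG"), ("ATG")), (("AAA"), ("AAG")))
    assert aln.principal_pos == (1, 2)


def test_build_codon_alignment_gap():
    aln = sa.build_codon_alignment(
        [("a", "M-K"), ("b", "MAK")],
        [CodingSequence("a", "ATGAAATAA"), CodingSequence("b", "ATGGCAAAGTAA")],
    )
    assert aln.columns[1] == (sa.GAP, "GCA")
    assert aln.principal_pos == (1, None, 2)


def test_build_codon_alignment_mismatch():
    with pytest.raises(sa.TranslationMismatchError, match="a"):
        sa.build_codon_alignment(
            [("a", "MK"), ("b", "MK")],
            [CodingSequence("a", "ATGCCCTAA"), CodingSequence("b", "ATGAAGTAA")],
        )


# ---------------------------------------------------------------------------
# pairwise / phylogeny classification

def test_classify_pairwise_states():
    aln = _aln([("AAA", "AAG"), ("AAA", "AGA"), (sa.GAP, "AAA")])
    sc = sa.classify_pairwise(aln)
    assert sc.state == ["conserved", "variable", "excluded"]
    assert sc.counts() == {"conserved": 1, "variable": 1, "excluded": 1}


@pytest.mark.parametrize(
    "codons, state, lineage",
    [
        (("AAA", "AAG", "AAA"), "conserved", "none"),  # K,K,K
        (("AAA", "AGA", "AAG"), "variable", "sister"),  # K,R,K
        (("AGA", "AAA", "AAG"), "excluded", "principal"),  # R,K,K
        (("AAA", "AAG", "AGA"), "excluded", "outgroup-or-ancestral"),  # K,K,R
        (("AAA", "AGA", "ACA"), "excluded", "ambiguous"),  # K,R,T
        ((sa.GAP, "AAA", "AAA"), "excluded", "none"),
    ],
)
def test_classify_phylogeny_cases(codons, state, lineage):
    sc = sa.classify_phylogeny(_aln([codons], n_species=3))
    assert (sc.state[0], sc.lineage[0]) == (state, lineage)


_CODON_BY_AA = {}
for c in SENSE_CODONS:
    from akashikit.genetic_code import CODON_TO_AA

    _CODON_BY_AA.setdefault(CODON_TO_AA[c], c)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(*[st.sampled_from(AMINO_ACIDS)] * 3))
def test_phylogeny_matches_fitch_oracle(aas):
    """Single-column lineage assignment equals exhaustive parsimony."""
    codons = tuple(_CODON_BY_AA[a] for a in aas)
    sc = sa.classify_phylogeny(_aln([codons], n_species=3))
    assert (sc.state[0], sc.lineage[0]) == fitch_lineage(*aas)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.tuples(*[st.sampled_from(sorted(_CODON_BY_AA.values()))] * 3), min_size=1, max_size=20))
def test_phylogeny_consistent_with_pairwise(columns):
    """Where aa(P) = aa(O), the trio classes collapse onto the (P, S)
    pairwise classes; conserved and sister-variable sites always satisfy
    aa(P) = aa(O)."""
    trio = _aln(columns, n_species=3)
    pair = _aln([(p, s) for p, s, _ in columns], n_species=2)
    sc3 = sa.classify_phylogeny(trio)
    sc2 = sa.classify_pairwise(pair)
    from akashikit.genetic_code import CODON_TO_AA

    for i, (p, s, o) in enumerate(columns):
        if CODON_TO_AA[p] == CODON_TO_AA[o]:
            assert sc3.state[i] == sc2.state[i]
        else:
            assert sc3.state[i] == "excluded"


# ---------------------------------------------------------------------------
# optimality-tied filter

_FAVOR_ALL_A = {aa: "A" for aa in AMINO_ACIDS}


def test_tied_filter_basic_cases():
    # Val -> Ile single base change, shared third base, shared favoured base
    assert sa.optimality_tied_filter("GTA", "ATA", _FAVOR_ALL_A) == (True, None)
    # identical codons: vacuously kept
    assert sa.optimality_tied_filter("GTA", "GTA", _FAVOR_ALL_A) == (True, None)
    # third base change
    keep, reason = sa.optimality_tied_filter("GTA", "GTC", _FAVOR_ALL_A)
    assert (keep, reason) == (False, "silent-base-changed")
    # favoured bases differ between the families
    favored = dict(_FAVOR_ALL_A, V="A", I="T")
    keep, reason = sa.optimality_tied_filter("GTA", "ATA", favored)
    assert (keep, reason) == (False, "favored-base-differs")
    # no favoured base for one family
    favored = dict(_FAVOR_ALL_A, I=None)
    keep, reason = sa.optimality_tied_filter("GTA", "ATA", favored)
    assert (keep, reason) == (False, "no-favored-base")


def test_tied_filter_pathway_through_stop():
    # AGA (Arg) -> TCA (Ser): the pos1-first ordering passes through TGA
    keep, reason = sa.optimality_tied_filter("AGA", "TCA", _FAVOR_ALL_A)
    assert keep is False
    assert reason == "pathway-through-stop"


def test_tied_filter_matches_brute_force_sample():
    favored = dict(_FAVOR_ALL_A)
    favored["W"] = None
    for a in ("GTA", "AGA", "TTA", "GGG", "ATG"):
        for b in SENSE_CODONS[::7]:
            keep, _ = sa.optimality_tied_filter(a, b, favored)
            assert keep == brute_force_tied(a, b, favored), (a, b)


# ---------------------------------------------------------------------------
# annotation flags

def test_annotate_domain():
    cols = [("AAA", "AAA")] * 8
    aln = _aln(cols)
    sc = sa.classify_pairwise(aln)
    ann = DomainAnnotation("s0", (("D1", 5, 7),))
    sa.annotate_domain(sc, aln, ann, protein_length=8)
    assert sc.in_domain == [False] * 4 + [True] * 3 + [False]
    sa.annotate_domain(sc, aln, None, protein_length=8)
    assert sc.in_domain == [False] * 8
    with pytest.raises(ValueError):
        sa.annotate_domain(sc, aln, DomainAnnotation("s0", (("D1", 5, 9),)), 8)


def test_annotate_structure_threshold_rule():
    cols = [("AAA", "AAA")] * 3
    aln = _aln(cols)
    sc = sa.classify_pairwise(aln)
    seq = "AAAAAAAAA"
    all_dots = StructureAnnotation("s0", seq, ".........")
    sa.annotate_structure(sc, aln, all_dots)
    assert sc.structure == ["L", "L", "L"]
    paired = StructureAnnotation("s0", seq, "..(..)...", (0, 0, 0.95, 0, 0, 0.30, 0, 0, 0))
    sa.annotate_structure(sc, aln, paired, strong_pair_threshold=0.9)
    assert sc.structure == ["S", "L", "L"]  # 0.95 strong, 0.30 weak, '.' loop
    # without probabilities, any paired third base is S
    paired_noprob = StructureAnnotation("s0", seq, "..(..)...")
    sa.annotate_structure(sc, aln, paired_noprob)
    assert sc.structure == ["S", "S", "L"]
    short = StructureAnnotation("s0", seq[:6], "......")
    with pytest.raises(ValueError):
        sa.annotate_structure(sc, aln, short)


@pytest.mark.parametrize(
    "n_codons, expected",
    [
        (9, [1, 1, 1, 2, 2, 2, 3, 3, 3]),
        (10, [1, 1, 1, 2, 2, 2, 3, 3, 3, 3]),
        (2, [3, 3]),  # degenerate: everything in the last block
    ],
)
def test_assign_thirds(n_codons, expected):
    cols = [("AAA", "AAA")] * n_codons
    aln = _aln(cols)
    sc = sa.classify_pairwise(aln)
    sa.assign_thirds(sc, aln, n_codons)
    assert sc.third == expected


def test_site_table_export(tmp_path):
    aln = _aln([("AAA", "AAG"), ("AAA", "AGA")])
    sc = sa.classify_pairwise(aln)
    path = tmp_path / "sites.tsv"
    sa.write_site_table(path, [(aln, sc)])
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("gene\tcolumn")
    assert len(lines) == 3
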