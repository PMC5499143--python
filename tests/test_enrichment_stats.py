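import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from akashikit import enrichment_stats as es
from akashikit.enrichment_stats import ContingencyStratum as CS

from oracles import naive_mh


# ---------------------------------------------------------------------------
# build_strata

def test_build_strata_worked_example():
    sites = {
        "g1": [("AAA", "conserved")] * 2
        + [("AAG", "conserved")]
        + [("AAA", "variable")]
        + [("AAG", "variable")] * 3
    }
    (stratum,) = es.build_strata(sites, "AAA", "conserved", "variable")
    assert (stratum.a, stratum.b, stratum.c, stratum.d) == (2, 1, 1, 3)


def test_build_strata_gene_without_family_omitted():
    sites = {"g1": [("AAA", "conserved")], "g2": [("CCC", "conserved")]}
    strata = es.build_strata(sites, "AAA", "conserved", "variable")
    assert [s.gene_id for s in strata] == ["g1"]
    assert not strata[0].informative  # variable margin empty


def test_build_strata_rejects_singleton_family():
    with pytest.raises(ValueError):
        es.build_strata({}, "ATG", "A", "B")


# ---------------------------------------------------------------------------
# mantel_haenszel

def test_mh_balanced_single_stratum():
    res = es.mantel_haenszel([CS("g", 2, 2, 2, 2)])
    assert res.odds_ratio == 1.0


def test_mh_worked_value():
    res = es.mantel_haenszel([CS("g1", 10, 5, 5, 10), CS("g2", 8, 2, 4, 6)])
    assert res.odds_ratio == pytest.approx(4.648648648648, rel=1e-9)
    assert res.p_value == pytest.approx(0.02541, abs=1e-4)


def test_mh_single_stratum_is_cross_product():
    res = es.mantel_haenszel([CS("g", 7, 3, 2, 9)])
    assert res.odds_ratio == pytest.approx((7 * 9) / (3 * 2))


def test_mh_invariances():
    strata = [CS("g1", 10, 5, 5, 10), CS("g2", 8, 2, 4, 6)]
    flipped = es.mantel_haenszel(strata[::-1])
    base = es.mantel_haenszel(strata)
    assert flipped.odds_ratio == base.odds_ratio
    assert flipped.chi2 == base.chi2
    padded = es.mantel_haenszel(strata + [CS("g3", 0, 0, 0, 0)])
    assert padded.odds_ratio == base.odds_ratio
    assert padded.chi2 == base.chi2


def test_mh_no_informative_strata():
    with pytest.raises(es.NoInformativeStrataError):
        es.mantel_haenszel([CS("g", 0, 0, 0, 0)])


def test_mh_undefined_and_continuity():
    strata = [CS("g", 3, 0, 2, 1)]  # pooled numerator ad = 3, denominator bc = 0
    res = es.mantel_haenszel(strata)
    assert math.isinf(res.odds_ratio)
    res2 = es.mantel_haenszel(strata, continuity_if_zero=True)
    assert res2.continuity_added and math.isfinite(res2.odds_ratio)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(*[st.integers(0, 10)] * 4),
        min_size=1,
        max_size=5,
    )
)
def test_mh_matches_naive_reference(cells):
    """OR, chi-square and p agree with a plain-loop textbook implementation
    on arbitrary small stratum sets, including degenerate ones."""
    strata = [CS(f"g{i}", *t) for i, t in enumerate(cells)]
    exp_or, exp_chi2, exp_p = naive_mh(cells)
    arr = np.array(cells, dtype=float)
    got_or, got_chi2, got_p = es.mantel_haenszel_arrays(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
    for got, exp in ((got_or, exp_or), (got_chi2, exp_chi2), (got_p, exp_p)):
        if math.isnan(exp):
            assert math.isnan(got)
        elif math.isinf(exp):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(exp, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# scans and averaging

def _two_class_sites(rng, n_genes=12, n_sites=60, p_a=0.5, p_b=0.5):
    """Random Lys-codon genes: AAA with class-dependent probability."""
    sites = {}
    for g in range(n_genes):
        rows = []
        for _ in range(n_sites):
            label = "A" if rng.random() < 0.5 else "B"
            p = p_a if label == "A" else p_b
            rows.append(("AAA" if rng.random() < p else "AAG", label))
        sites[f"g{g}"] = rows
    return sites


def test_scan_returns_59_results_and_label_swap_symmetry():
    rng = np.random.default_rng(0)
    sites = _two_class_sites(rng, p_a=0.7, p_b=0.4)
    fwd = es.codon_enrichment_scan(sites, "A", "B")
    rev = es.codon_enrichment_scan(sites, "B", "A")
    assert len(fwd) == len(rev) == 59
    assert fwd["AAA"].odds_ratio > 1
    assert rev["AAA"].odds_ratio == pytest.approx(1 / fwd["AAA"].odds_ratio)
    assert rev["AAA"].p_value == pytest.approx(fwd["AAA"].p_value)


def test_average_over_comparisons():
    def res(or_):
        return es.EnrichmentResult("AAA", or_, 1.0, 0.5, 3, "A")

    table = es.average_over_comparisons(
        {"c1": {"AAA": res(1.2)}, "c2": {"AAA": res(0.8)}, "c3": {"AAA": res(math.nan)}}
    )
    row = table.loc["AAA"]
    assert row["mean_or"] == pytest.approx(1.0)
    assert row["n_comparisons"] == 2
    assert row["n_undefined"] == 1
    assert row["mean_abs_deviation"] == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# optimal codons

def _expr(genes, values, n_exp=3):
    return pd.DataFrame(
        {f"e{j}": {g: v for g, v in zip(genes, values)} for j in range(n_exp)}
    )


def test_identify_optimal_codons_extreme_case():
    # strongly expressed genes use only AAA; weakly expressed only AAG
    genes = [f"h{i}" for i in range(5)] + [f"l{i}" for i in range(5)]
    cds = {g: ["AAA"] * 30 if g.startswith("h") else ["AAG"] * 30 for g in genes}
    expr = _expr(genes, [10_000] * 5 + [200] * 5)
    res = es.identify_optimal_codons(cds, expr, quantile=0.5, min_genes=4)
    assert res.table.loc["AAA", "optimal"]
    assert math.isfinite(res.table.loc["AAA", "or"])  # 0.5-continuity keeps it finite
    assert not res.table.loc["AAG", "optimal"]
    assert res.favored_base_map()["K"] == "A"


def test_identify_optimal_codons_null_and_filters():
    genes = [f"g{i}" for i in range(10)]
    cds = {g: ["AAA", "AAG"] * 15 for g in genes}
    expr = _expr(genes, [10_000, 9000, 8000, 7000, 6000, 500, 400, 300, 200, 150])
    res = es.identify_optimal_codons(cds, expr, quantile=0.3, min_genes=5)
    assert not res.table["optimal"].any()
    # a gene never expressed above threshold drops out of the ranking
    expr.loc["g0"] = 50.0
    ranked = es.mean_log_expression(expr)
    assert "g0" not in ranked.index
    with pytest.raises(ValueError):
        es.identify_optimal_codons(cds, expr, min_genes=50)


# ---------------------------------------------------------------------------
# Akashi test

def test_akashi_recovers_generative_or():
    rng = np.random.default_rng(42)
    p_c, p_v = 0.7, 0.5
    sites = {}
    for g in range(300):
        rows = []
        for _ in range(200):
            conserved = rng.random() < 0.6
            p = p_c if conserved else p_v
            codon = "AAG" if rng.random() < p else "AAA"  # AAG designated optimal
            rows.append((codon, "conserved" if conserved else "variable"))
        sites[f"g{g}"] = rows
    res = es.akashi_test(sites, ["AAG"])
    expected = (p_c / (1 - p_c)) / (p_v / (1 - p_v))
    assert res.odds_ratio == pytest.approx(expected, rel=0.08)
    assert res.p_value < 1e-6


def test_akashi_null_and_errors():
    rng = np.random.default_rng(1)
    sites = {}
    for g in range(100):
        rows = [
            ("AAG" if rng.random() < 0.5 else "AAA",
             "conserved" if rng.random() < 0.5 else "variable")
            for _ in range(100)
        ]
        sites[f"g{g}"] = rows
    res = es.akashi_test(sites, ["AAG"])
    assert res.odds_ratio == pytest.approx(1.0, abs=0.1)
    with pytest.raises(ValueError):
        es.akashi_test(sites, [])
    with pytest.raises(es.NoInformativeStrataError):
        es.akashi_test(sites, ["AAG"], site_filter=lambda i: False)


def test_akashi_masks_partition_counts():
    sites = {"g": [("AAA", "conserved"), ("AAG", "variable"), ("AAA", "variable")]}
    full = es.akashi_strata(sites, ["AAA"])[0]
    first = es.akashi_strata(sites, ["AAA"], site_filter=lambda i: i == 0)[0]
    rest = es.akashi_strata(sites, ["AAA"], site_filter=lambda i: i != 0)[0]
    assert first.n + rest.n == full.n


# ---------------------------------------------------------------------------
# tRNA-RSCU

def test_trna_rscu_examples():
    df = es.trna_rscu({"AAA": 3, "AAG": 1, "GGA": 2, "GGC": 2, "GGG": 2, "GGT": 2,
                       "CCG": 8})
    assert df.loc["AAA", "rscu"] == pytest.approx(1.5)
    assert df.loc["AAG", "rscu"] == pytest.approx(0.5)
    assert (df.loc[["GGA", "GGC", "GGG", "GGT"], "rscu"] == 1.0).all()
    assert df.loc["CCG", "rscu"] == pytest.approx(4.0)  # (0,0,0,8) fourfold
    assert df.loc["CCA", "rscu"] == 0.0
    # family with zero copies is undefined, flagged
    assert math.isnan(df.loc["TTT", "rscu"]) and not df.loc["TTT", "defined"]
    with pytest.raises(ValueError):
        es.trna_rscu({"AAA": -1})


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.dictionaries(st.sampled_from(es.SCANNABLE_CODONS), st.integers(0, 20), max_size=40))
def test_trna_rscu_family_sums(counts):
    df = es.trna_rscu(counts)
    for fam, grp in df.groupby("family"):
        if grp["defined"].any():
            assert grp["rscu"].sum() == pytest.approx(len(grp))


# ---------------------------------------------------------------------------
# correlation

def test_correlate_basics():
    x = np.arange(10.0)
    r, p = es.correlate(x, x)
    assert r == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    r, _ = es.correlate(rng.normal(size=2000), rng.normal(size=2000))
    assert abs(r) < 0.1
    with pytest.raises(ValueError):
        es.correlate([1, 2], [1, 2])


def test_permutation_p_matches_analytic():
    rng = np.random.default_rng(3)
    x = rng.normal(size=20)
    y = 0.6 * x + rng.normal(size=20)
    r, p_analytic = es.correlate(x, y)
    _, p_perm = es.correlate(x, y, permutations=10_000, seed=0)
    assert p_perm == pytest.approx(p_analytic, abs=3 * math.sqrt(p_analytic * (1 - p_analytic) / 10_000) + 1e-4)


def test_matrix_association_modes():
    rng = np.random.default_rng(7)
    a = pd.DataFrame(rng.normal(size=(4, 10)))
    b = a + rng.normal(scale=0.3, size=(4, 10))
    r_full, p_full = es.matrix_association(a, b, permutations=300, mode="full", seed=1)
    r_rows, p_rows = es.matrix_association(a, b, permutations=300, mode="rows", seed=1)
    assert r_full == pytest.approx(r_rows)
    assert p_full < 0.05
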