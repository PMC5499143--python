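"""Mantel-Haenszel codon-enrichment statistics and the Akashi test.

The unit of analysis is the gene: for a focal codon and a two-class site
partition (conserved vs variable, domain vs nondomain, stem vs loop, high
vs low expression, ...), each gene contributes one 2x2 table counting the
focal codon against its synonymous-family peers in the two classes.
Tables are pooled across genes with the Mantel-Haenszel estimator

    OR_MH = sum_i(a_i d_i / N_i) / sum_i(b_i c_i / N_i)

and significance comes from the MH chi-square with a 0.5 continuity
correction. Stratifying by gene removes between-gene differences in
expression level and mutational bias from the comparison, which is what
makes the Akashi design informative about within-gene synonymous choice.

The Akashi test itself is the same machinery with codons dichotomised as
optimal vs nonoptimal (restricted to families that contain at least one
optimal codon): OR > 1 means optimal codons are preferentially used at
conserved sites, the signature of selection for translational accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    SENSE_CODONS,
    degeneracy,
    families,
    family_of,
    synonymous_peers,
)

__all__ = [
    "ContingencyStratum",
    "EnrichmentResult",
    "OptimalCodonSet",
    "NoInformativeStrataError",
    "build_strata",
    "mantel_haenszel",
    "mantel_haenszel_arrays",
    "codon_enrichment_scan",
    "average_over_comparisons",
    "identify_optimal_codons",
    "akashi_test",
    "akashi_strata",
    "trna_rscu",
    "correlate",
    "matrix_association",
    "SCANNABLE_CODONS",
]

#: sense codons in degeneracy >= 2 families: the 59 focal codons of a scan
SCANNABLE_CODONS = tuple(c for c in SENSE_CODONS if degeneracy(c) > 1)


class NoInformativeStrataError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyStratum:
    """One gene's 2x2 table: (focal codon, peers) x (class A, class B)."""

    gene_id: str
    a: int  # focal codon, class A
    b: int  # synonymous peers, class A
    c: int  # focal codon, class B
    d: int  # synonymous peers, class B

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def informative(self) -> bool:
        return (
            self.a + self.b > 0
            and self.c + self.d > 0
            and self.a + self.c > 0
            and self.b + self.d > 0
        )


@dataclass(frozen=True)
class EnrichmentResult:
    focal: str  # focal codon, or a contrast label for pooled tests
    odds_ratio: float  # nan when undefined
    chi2: float
    p_value: float
    n_strata: int  # informative strata pooled
    class_a: str  # orientation: OR > 1 means enrichment in this class
    continuity_added: bool = False

    @property
    def defined(self) -> bool:
        return math.isfinite(self.odds_ratio)


# ---------------------------------------------------------------------------
# Strata construction and pooling

def build_strata(
    gene_sites: Mapping[str, Sequence[tuple[str, str]]],
    focal_codon: str,
    class_a: str,
    class_b: str,
) -> list[ContingencyStratum]:
    """One stratum per gene from per-site ``(codon, class_label)`` pairs.

    Sites with labels other than ``class_a``/``class_b`` are ignored.
    Genes containing no codon of the focal family are omitted; strata with
    an empty margin are retained (they contribute nothing to the pooled
    sums) and can be recognised via :attr:`ContingencyStratum.informative`.
    """
    peers = set(synonymous_peers(focal_codon))
    if not peers:
        raise ValueError(f"{focal_codon} has no synonymous peers (degeneracy-1 family)")
    strata = []
    for gene_id in sorted(gene_sites):
        a = b = c = d = 0
        for codon, label in gene_sites[gene_id]:
            if codon == focal_codon:
                if label == class_a:
                    a += 1
                elif label == class_b:
                    c += 1
            elif codon in peers:
                if label == class_a:
                    b += 1
                elif label == class_b:
                    d += 1
        if a + b + c + d > 0:
            strata.append(ContingencyStratum(gene_id, a, b, c, d))
    return strata


def mantel_haenszel_arrays(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[float, float, float]:
    """MH pooled OR, chi-square (0.5 continuity) and two-sided p on count
    arrays; vectorised workhorse shared by all contrasts.

    Returns ``(or, chi2, p)``; the OR is nan when the pooled numerator and
    denominator are both zero, inf when only the denominator is.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.where(n > 0, a * d / n, 0.0).sum()
        den = np.where(n > 0, b * c / n, 0.0).sum()
    if den > 0:
        or_mh = num / den
    elif num > 0:
        or_mh = math.inf
    else:
        or_mh = math.nan

    ok = n > 1
    e = np.where(ok, (a + b) * (a + c) / np.where(ok, n, 1), 0.0)
    v = np.where(
        ok,
        (a + b) * (c + d) * (a + c) * (b + d) / (np.where(ok, n, 1) ** 2 * np.where(ok, n - 1, 1)),
        0.0,
    )
    v_sum = v.sum()
    if v_sum > 0:
        chi2 = max(0.0, abs(a[ok].sum() - e.sum()) - 0.5) ** 2 / v_sum
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = math.nan, math.nan
    return float(or_mh), float(chi2), p


def mantel_haenszel(
    strata: Sequence[ContingencyStratum],
    focal: str = "",
    class_a: str = "A",
    continuity_if_zero: bool = False,
) -> EnrichmentResult:
    """Pool per-gene 2x2 strata into a cumulative odds ratio.

    The point estimate uses the raw MH sums; when a pooled sum is exactly
    zero and ``continuity_if_zero`` is set, 0.5 is added to every cell of
    every informative stratum to return a finite (flagged) estimate.
    Raises :class:`NoInformativeStrataError` when no stratum has both
    margins populated.
    """
    informative = [s for s in strata if s.informative]
    if not informative:
        raise NoInformativeStrataError("no informative strata to pool")
    arr = np.array([[s.a, s.b, s.c, s.d] for s in strata], dtype=float)
    or_mh, chi2, p = mantel_haenszel_arrays(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
    added = False
    if continuity_if_zero and not math.isfinite(or_mh):
        inf_arr = np.array([[s.a, s.b, s.c, s.d] for s in informative], dtype=float) + 0.5
        or_mh, _, _ = mantel_haenszel_arrays(*inf_arr.T)
        added = True
    return EnrichmentResult(focal, or_mh, chi2, p, len(informative), class_a, added)


def codon_enrichment_scan(
    gene_sites: Mapping[str, Sequence[tuple[str, str]]],
    class_a: str,
    class_b: str,
) -> dict[str, EnrichmentResult]:
    """MH enrichment of every focal codon (59 under the standard code) for
    one two-class partition; codons with no informative strata map to an
    undefined result rather than being dropped."""
    out: dict[str, EnrichmentResult] = {}
    for focal in SCANNABLE_CODONS:
        strata = build_strata(gene_sites, focal, class_a, class_b)
        try:
            out[focal] = mantel_haenszel(strata, focal, class_a)
        except NoInformativeStrataError:
            out[focal] = EnrichmentResult(focal, math.nan, math.nan, math.nan, 0, class_a)
    return out


def average_over_comparisons(
    results_by_comparison: Mapping[str, Mapping[str, EnrichmentResult]],
) -> pd.DataFrame:
    """Arithmetic mean OR per codon over comparisons (undefined ORs skipped
    and counted), plus the mean absolute deviation |OR - 1| summary used to
    compare overall enrichment strength between species."""
    rows = []
    codons = sorted({c for res in results_by_comparison.values() for c in res})
    for codon in codons:
        ors = [
            res[codon].odds_ratio
            for res in results_by_comparison.values()
            if codon in res and res[codon].defined
        ]
        n_skipped = sum(
            1
            for res in results_by_comparison.values()
            if codon in res and not res[codon].defined
        )
        mean = float(np.mean(ors)) if ors else math.nan
        rows.append(
            {
                "codon": codon,
                "mean_or": mean,
                "n_comparisons": len(ors),
                "n_undefined": n_skipped,
                "mean_abs_deviation": float(np.mean(np.abs(np.array(ors) - 1.0)))
                if ors
                else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("codon")


# ---------------------------------------------------------------------------
# Optimal codons

@dataclass(frozen=True)
class OptimalCodonSet:
    """Per-codon expression contrast and the derived optimal-codon calls."""

    tag: str  # species / subset label, e.g. "HGC"
    table: pd.DataFrame  # index codon; or, p_value, optimal columns
    alpha: float

    @property
    def optimal_codons(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["optimal"]])

    def favored_base_map(self) -> dict[str, str | None]:
        """family -> favoured third base: the shared third base of the
        family's optimal codons, or None when the family has no optimal
        codon or its optimal codons disagree on the third base."""
        out: dict[str, str | None] = {}
        for fam, codons in families().items():
            thirds = {c[2] for c in codons if c in self.optimal_codons}
            out[fam] = thirds.pop() if len(thirds) == 1 else None
        return out


def mean_log_expression(
    expression: pd.DataFrame, expressed_threshold: float = 100.0
) -> pd.Series:
    """Per-gene mean log10 expression over the experiments in which the
    gene is expressed (value > threshold); genes never expressed drop out."""
    expressed = expression.where(expression > expressed_threshold)
    means = np.log10(expressed).mean(axis=1, skipna=True)
    return means.dropna()


def identify_optimal_codons(
    cds_by_gene: Mapping[str, Sequence[str]],
    expression: pd.DataFrame,
    quantile: float = 0.20,
    alpha: float = 0.05,
    expressed_threshold: float = 100.0,
    min_genes: int = 10,
    tag: str = "",
) -> OptimalCodonSet:
    """Call optimal codons from a strong- vs weak-expression contrast.

    Genes are ranked by mean log10 expression over the experiments in which
    they are expressed; the top and bottom ``quantile`` form the high/low
    sets. For each focal codon a single pooled 2x2 table (focal vs peers x
    high vs low) is tested by chi-square; OR > 1 with p < alpha calls the
    codon optimal. ``cds_by_gene`` maps gene id -> codon list (stop
    removed). Ties in the ranking are broken by gene id so the split is
    reproducible.
    """
    ranked = mean_log_expression(expression, expressed_threshold)
    ranked = ranked[ranked.index.isin(cds_by_gene.keys())]
    if len(ranked) < min_genes:
        raise ValueError(f"only {len(ranked)} ranked genes; need >= {min_genes}")
    order = ranked.sort_index().sort_values(ascending=False, kind="stable")
    n_q = max(1, int(len(order) * quantile))
    high = list(order.index[:n_q])
    low = list(order.index[-n_q:])

    counts: dict[str, np.ndarray] = {
        codon: np.zeros(2) for codon in SENSE_CODONS
    }  # [high, low] occurrences
    for subset, col in ((high, 0), (low, 1)):
        for gene in subset:
            for codon in cds_by_gene[gene]:
                if codon in counts:
                    counts[codon][col] += 1

    rows = []
    for focal in SCANNABLE_CODONS:
        peers = synonymous_peers(focal)
        a, c = counts[focal]
        b = sum(counts[p][0] for p in peers)
        d = sum(counts[p][1] for p in peers)
        table = np.array([[a, b], [c, d]], dtype=float)
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            or_, p = math.nan, math.nan
        else:
            if (table == 0).any():
                ta = table + 0.5
            else:
                ta = table
            or_ = (ta[0, 0] * ta[1, 1]) / (ta[0, 1] * ta[1, 0])
            _, p, _, _ = stats.chi2_contingency(table, correction=True)
        rows.append({"codon": focal, "or": or_, "p_value": p})
    df = pd.DataFrame(rows).set_index("codon")
    df["optimal"] = (df["or"] > 1) & (df["p_value"] < alpha)
    return OptimalCodonSet(tag, df, alpha)


# ---------------------------------------------------------------------------
# Akashi test

def akashi_strata(
    gene_sites: Mapping[str, Sequence[tuple[str, str]]],
    optimal_codons: Iterable[str],
    class_a: str = "conserved",
    class_b: str = "variable",
    site_filter: Callable[[int], bool] | None = None,
) -> list[ContingencyStratum]:
    """Per-gene (optimal vs nonoptimal) x (class A vs class B) tables.

    Only codons from families containing at least one optimal codon are
    counted (codons of other families carry no optimal/nonoptimal
    information). ``site_filter`` receives the site's index within the
    gene's list and can restrict to a mask subset (domain-only, stem-only,
    a transcript third, ...).
    """
    optimal = set(optimal_codons)
    if not optimal:
        raise ValueError("empty optimal-codon set")
    opt_families = {family_of(c) for c in optimal}
    strata = []
    for gene_id in sorted(gene_sites):
        a = b = c = d = 0
        for i, (codon, label) in enumerate(gene_sites[gene_id]):
            if site_filter is not None and not site_filter(i):
                continue
            if family_of(codon) not in opt_families:
                continue
            is_opt = codon in optimal
            if label == class_a:
                a, b = a + is_opt, b + (not is_opt)
            elif label == class_b:
                c, d = c + is_opt, d + (not is_opt)
        if a + b + c + d > 0:
            strata.append(ContingencyStratum(gene_id, a, b, c, d))
    return strata


def akashi_test(
    gene_sites: Mapping[str, Sequence[tuple[str, str]]],
    optimal_codons: Iterable[str],
    class_a: str = "conserved",
    class_b: str = "variable",
    site_filter: Callable[[int], bool] | None = None,
    label: str = "akashi",
) -> EnrichmentResult:
    """Pooled Akashi test: do optimal codons concentrate at conserved sites?

    OR > 1 with a significant MH chi-square signals selection for
    translational accuracy. Raises :class:`NoInformativeStrataError` when
    the mask leaves no informative gene (e.g. an empty mask intersection).
    """
    strata = akashi_strata(gene_sites, optimal_codons, class_a, class_b, site_filter)
    if not strata:
        raise NoInformativeStrataError(f"{label}: no sites left after masking")
    return mantel_haenszel(strata, focal=label, class_a=class_a)


# ---------------------------------------------------------------------------
# tRNA-RSCU

def trna_rscu(copy_counts: Mapping[str, int], split_sixfold: bool = False) -> pd.DataFrame:
    """tRNA gene copy counts normalised like an RSCU.

    RSCU_i = n * copies_i / sum_family(copies), with n the family
    degeneracy, so a family with any copies sums to n. Families with zero
    total copies get NaN and are flagged undefined. Missing codons count 0.
    """
    for codon, cnt in copy_counts.items():
        if cnt < 0:
            raise ValueError(f"negative copy count for {codon}")
    rows = []
    for fam, codons in families(split_sixfold).items():
        n = len(codons)
        total = sum(copy_counts.get(c, 0) for c in codons)
        for c in codons:
            copies = copy_counts.get(c, 0)
            rscu = n * copies / total if total > 0 else math.nan
            rows.append(
                {"codon": c, "family": fam, "copies": copies, "rscu": rscu,
                 "defined": total > 0}
            )
    return pd.DataFrame(rows).set_index("codon").sort_index()


# ---------------------------------------------------------------------------
# Correlation with permutation support

def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    permutations: int | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pearson/Spearman correlation with analytic or permutation p-value.

    NaN entries are dropped pairwise. With ``permutations`` given, the
    p-value is the empirical two-sided tail of |r| under random relabelling
    of ``y`` (add-one correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    r, p = fn(x, y)
    r, p = float(r), float(p)
    if permutations:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            rp, _ = fn(x, rng.permutation(y))
            if abs(rp) >= abs(r) - 1e-15:
                hits += 1
        p = (hits + 1) / (permutations + 1)
    return r, p


def matrix_association(
    a: pd.DataFrame,
    b: pd.DataFrame,
    method: str = "pearson",
    permutations: int = 0,
    mode: str = "full",
    seed: int | None = None,
) -> tuple[float, float]:
    """Association between two species x codon matrices (e.g. mean MH odds
    ratios vs tRNA-RSCU values).

    ``mode='full'`` permutes all entries freely; ``mode='rows'`` permutes
    whole per-species rows of ``a`` jointly, preserving the internal
    correlation structure within each species vector.
    """
    a = a.loc[sorted(a.index), sorted(a.columns)]
    b = b.loc[a.index, a.columns]
    av = a.to_numpy(dtype=float).ravel()
    bv = b.to_numpy(dtype=float).ravel()
    keep = np.isfinite(av) & np.isfinite(bv)
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    r = float(fn(av[keep], bv[keep])[0])
    if not permutations:
        return r, float(fn(av[keep], bv[keep])[1])
    rng = np.random.default_rng(seed)
    am = a.to_numpy(dtype=float)
    hits = 0
    for _ in range(permutations):
        if mode == "rows":
            perm = am[rng.permutation(am.shape[0]), :].ravel()
        else:
            perm = rng.permutation(am.ravel())
        k = np.isfinite(perm) & np.isfinite(bv)
        rp = fn(perm[k], bv[k])[0]
        if abs(rp) >= abs(r) - 1e-15:
            hits += 1
    return r, (hits + 1) / (permutations + 1)
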