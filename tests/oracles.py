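"""Independent reference implementations used only as test oracles.

These are written from the textbook definitions with deliberately
different code paths from the package (plain loops, exhaustive
enumeration) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

from scipy.stats import chi2 as chi2_dist

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Mantel-Haenszel, plain-loop textbook version

def naive_mh(strata: list[tuple[int, int, int, int]]) -> tuple[float, float, float]:
    """Pooled OR, MH chi-square (0.5 continuity) and p from (a,b,c,d) tuples."""
    num = den = 0.0
    a_sum = e_sum = v_sum = 0.0
    for a, b, c, d in strata:
        n = a + b + c + d
        if n > 0:
            num += a * d / n
            den += b * c / n
        if n > 1:
            e_sum += (a + b) * (a + c) / n
            v_sum += (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1))
            a_sum += a
    if den > 0:
        or_mh = num / den
    elif num > 0:
        or_mh = math.inf
    else:
        or_mh = math.nan
    if v_sum > 0:
        chi2 = max(0.0, abs(a_sum - e_sum) - 0.5) ** 2 / v_sum
        p = float(chi2_dist.sf(chi2, 1))
    else:
        chi2 = p = math.nan
    return or_mh, chi2, p


# ---------------------------------------------------------------------------
# Exhaustive Fitch parsimony on the rooted topology ((P, S), O)

def fitch_lineage(ap: str, as_: str, ao: str) -> tuple[str, str]:
    """(state, lineage) for one amino-acid column by exhaustive enumeration.

    All assignments of the two internal nodes (the P/S ancestor X and the
    root R) are scored by the number of mutated branches among R-O, R-X,
    X-P, X-S; the optimal assignments' mutated-branch sets determine the
    lineage category.
    """
    best = None
    placements = set()
    for x in AMINO_ACIDS:
        for r in AMINO_ACIDS:
            branches = frozenset(
                name
                for name, (u, v) in {
                    "R-O": (r, ao),
                    "R-X": (r, x),
                    "X-P": (x, ap),
                    "X-S": (x, as_),
                }.items()
                if u != v
            )
            cost = len(branches)
            if best is None or cost < best:
                best = cost
                placements = {branches}
            elif cost == best:
                placements.add(branches)
    if best == 0:
        return "conserved", "none"
    if best == 1:
        branch_sets = {next(iter(p)) for p in placements}
        if branch_sets == {"X-S"}:
            return "variable", "sister"
        if branch_sets == {"X-P"}:
            return "excluded", "principal"
        if branch_sets <= {"R-O", "R-X"}:
            return "excluded", "outgroup-or-ancestral"
    return "excluded", "ambiguous"


# ---------------------------------------------------------------------------
# Brute-force optimality-tied pair check

def _aa(codon: str) -> str | None:
    from Bio.Seq import Seq

    if codon in _STOPS:
        return None
    return str(Seq(codon).translate())


def brute_force_tied(codon_a: str, codon_b: str, favored: dict[str, str | None]) -> bool:
    """Re-derive the optimality-tied keep/drop decision by brute force.

    Enumerates every ordering of the differing positions recursively and
    checks third-base identity plus favoured-base identity for the
    endpoints and every intermediate.
    """

    def fav(codon: str) -> str | None:
        aa = _aa(codon)
        return favored.get(aa) if aa else None

    if codon_a == codon_b:
        return True
    if codon_a[2] != codon_b[2]:
        return False
    fa, fb = fav(codon_a), fav(codon_b)
    if fa is None or fb is None or fa != fb:
        return False

    def paths(cur: str) -> bool:
        diff = [i for i in range(3) if cur[i] != codon_b[i]]
        if not diff:
            return True
        ok = True
        for i in diff:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if nxt != codon_b:
                if _aa(nxt) is None or fav(nxt) != fa:
                    ok = False
                    continue
            if not paths(nxt):
                ok = False
        return ok

    return paths(codon_a)


# ---------------------------------------------------------------------------
# Wright's ENC, second implementation

_FAMILIES: dict[str, list[str]] = {}
for _c in ("".join(t) for t in itertools.product(_BASES, repeat=3)):
    _a = _aa(_c)
    if _a:
        _FAMILIES.setdefault(_a, []).append(_c)

_GROUPS = {2: 9, 3: 1, 4: 5, 6: 3}


def enc_reference(codons: list[str]) -> float:
    """Effective number of codons from per-family homozygosity estimates."""
    tallies: dict[str, int] = {}
    for c in codons:
        c = c.upper()
        if c in _STOPS or any(b not in _BASES for b in c):
            continue
        tallies[c] = tallies.get(c, 0) + 1
    group_f: dict[int, list[float]] = {k: [] for k in _GROUPS}
    for aa, members in _FAMILIES.items():
        k = len(members)
        if k == 1:
            continue
        counts = [tallies.get(c, 0) for c in members]
        n = sum(counts)
        if n < 2:
            continue
        s = sum((x / n) ** 2 for x in counts)
        group_f[k].append((n * s - 1) / (n - 1))
    mean_f: dict[int, float] = {}
    for k, fs in group_f.items():
        mean_f[k] = sum(fs) / len(fs) if fs else math.nan
    if math.isnan(mean_f[3]) and not math.isnan(mean_f[2]) and not math.isnan(mean_f[4]):
        mean_f[3] = (mean_f[2] + mean_f[4]) / 2
    if any(math.isnan(mean_f[k]) for k in _GROUPS):
        return math.nan
    if any(mean_f[k] == 0 for k in _GROUPS):
        return 61.0
    if any(mean_f[k] < 0 for k in _GROUPS):
        return math.nan
    value = 2 + sum(cnt / mean_f[k] for k, cnt in _GROUPS.items())
    return min(61.0, max(20.0, value))
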