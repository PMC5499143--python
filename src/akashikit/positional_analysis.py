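"""Accuracy signal and Fop along the transcript in adjacent 5-codon windows.

Each gene's sites (in principal ungapped coordinates) are cut into
adjacent windows of five amino acids; window w of every gene long enough
contributes its sites to pool w (a "superalignment"), and the pooled
codons form the window's supersequence. Per window, the Akashi test runs
on the pool with genes as strata, and Fop is computed on the
supersequence, yielding a positional profile of translational accuracy
and efficiency.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition_metrics import fop
from .enrichment_stats import NoInformativeStrataError, akashi_test

__all__ = [
    "build_window_pools",
    "positional_profiles",
    "step_change_point",
]


def build_window_pools(
    gene_sites: Mapping[str, Sequence[tuple[str, str]]],
    window: int = 5,
) -> dict[int, dict[str, list[tuple[str, str]]]]:
    """Pool per-gene site lists into adjacent windows.

    ``gene_sites[gene]`` is the ordered list of ``(codon, state)`` pairs in
    principal ungapped coordinates (excluded sites may be present; they are
    carried through and ignored by the test). Window ``w`` (0-based) covers
    codons ``w*window+1 .. (w+1)*window``; trailing incomplete windows are
    dropped, so a gene stops contributing once it runs out of complete
    windows.
    """
    pools: dict[int, dict[str, list[tuple[str, str]]]] = {}
    for gene_id, sites in gene_sites.items():
        n_windows = len(sites) // window
        for w in range(n_windows):
            chunk = list(sites[w * window : (w + 1) * window])
            pools.setdefault(w, {})[gene_id] = chunk
    return pools


def positional_profiles(
    pools: Mapping[int, Mapping[str, Sequence[tuple[str, str]]]],
    optimal_codons: Sequence[str],
    window: int = 5,
    class_a: str = "conserved",
    class_b: str = "variable",
) -> pd.DataFrame:
    """Per-window pooled Akashi OR/p and supersequence Fop.

    Windows where no gene has an informative stratum get an undefined OR
    (NaN) but remain in the profile.
    """
    rows = []
    for w in sorted(pools):
        pool = pools[w]
        supersequence = [codon for sites in pool.values() for codon, _ in sites]
        try:
            res = akashi_test(pool, optimal_codons, class_a, class_b, label=f"window{w}")
            or_, p = res.odds_ratio, res.p_value
        except NoInformativeStrataError:
            or_, p = math.nan, math.nan
        rows.append(
            {
                "window": w,
                "start_codon": w * window + 1,
                "odds_ratio": or_,
                "p_value": p,
                "fop": fop(supersequence, optimal_codons),
                "n_genes": len(pool),
                "n_codons": len(supersequence),
            }
        )
    return pd.DataFrame(rows)


def step_change_point(values: Sequence[float]) -> int:
    """Least-squares single-step change point of a profile series.

    Returns the 0-based index of the first window of the second regime
    (the split minimising within-segment sum of squares); NaN entries are
    interpolated out before fitting. Requires at least 3 finite values.
    """
    y = np.asarray(values, dtype=float)
    idx = np.arange(len(y))
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite values")
    y = np.interp(idx, idx[ok], y[ok])
    best, best_sse = 1, math.inf
    for s in range(1, len(y)):
        left, right = y[:s], y[s:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best_sse:
            best, best_sse = s, sse
    return best
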