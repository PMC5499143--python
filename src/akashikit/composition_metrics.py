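"""Nucleotide-composition and codon-usage summary statistics.

GC/GC3, sliding windows across domain boundaries, Wright's effective
number of codons (ENC), the fraction of optimal codons (Fop), and the
high-GC / low-GC gene split used for grass genomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import STOP_CODONS, families, family_of
from .sequence_io import CodingSequence, DomainAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "gc_content",
    "gc3_content",
    "sliding_window_series",
    "DomainRegion",
    "extract_domain_regions",
    "compare_regions",
    "enc",
    "fop",
    "split_hgc_lgc",
]


def _gc_fraction(seq: str) -> float:
    counted = [b for b in seq.upper() if b in "ACGT"]
    if not counted:
        raise ValueError("no unambiguous bases")
    return sum(b in "GC" for b in counted) / len(counted)


def gc_content(seq: str) -> float:
    """G+C fraction; N and other ambiguity codes are excluded from both
    numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    return _gc_fraction(seq)


def gc3_content(cds: str) -> float:
    """G+C fraction at third codon positions of an in-frame sequence.

    Operates on the sequence as given; callers that want the stop codon
    excluded should trim it first (the per-gene pipeline does).
    """
    if not cds:
        raise ValueError("empty sequence")
    if len(cds) % 3:
        raise ValueError("length not a multiple of 3")
    return _gc_fraction(cds[2::3])


def sliding_window_series(seq: str, size: int = 9, step: int = 3) -> pd.DataFrame:
    """GC and GC3 in windows at offsets 0, step, 2*step, ...

    With the default step of one codon the windows stay in frame, so GC3
    is taken over the third-codon bases inside each window. Sequences
    shorter than one window yield an empty frame (with a warning).
    """
    rows = []
    if len(seq) < size:
        logger.warning("sequence of %d nt shorter than window size %d", len(seq), size)
    for w, off in enumerate(range(0, len(seq) - size + 1, step)):
        win = seq[off : off + size]
        rows.append({"window": w, "offset": off, "gc": _gc_fraction(win), "gc3": _gc_fraction(win[2::3])})
    return pd.DataFrame(rows, columns=["window", "offset", "gc", "gc3"])


# ---------------------------------------------------------------------------
# Domain / flank region extraction

@dataclass(frozen=True)
class DomainRegion:
    gene_id: str
    label: str  # "domain" or "nondomain"
    part: str  # domain-5p / domain-3p / flank-5p / flank-3p
    start: int  # protein coords, 1-based inclusive
    end: int
    seq: str  # the corresponding CDS slice


def extract_domain_regions(
    cds: CodingSequence,
    annotation: DomainAnnotation,
    region_codons: int = 100,
) -> tuple[list[DomainRegion], list[tuple[str, str]]]:
    """Extract the domain edges and flanking regions around each domain.

    Per domain of length >= ``region_codons``: its first and last
    ``region_codons`` codons (label "domain"), the last ``region_codons``
    codons of the 5' flank and the first ``region_codons`` of the 3' flank
    (label "nondomain"). Flanks shorter than ``region_codons`` or
    containing part of another domain are rejected. Returns the regions
    and a rejection log of ``(description, reason)`` pairs.
    """
    codons = cds.codons(drop_stop=True)
    plen = len(codons)
    mask = annotation.merged_mask(plen)

    def slice_cds(start: int, end: int) -> str:  # protein coords, 1-based
        return "".join(codons[start - 1 : end])

    regions: list[DomainRegion] = []
    rejected: list[tuple[str, str]] = []
    for dom_id, dstart, dend in annotation.intervals:
        dlen = dend - dstart + 1
        if dlen < region_codons:
            rejected.append((f"{cds.gene_id}:{dom_id}", "too-short"))
            continue
        regions.append(
            DomainRegion(cds.gene_id, "domain", "domain-5p", dstart,
                         dstart + region_codons - 1,
                         slice_cds(dstart, dstart + region_codons - 1))
        )
        regions.append(
            DomainRegion(cds.gene_id, "domain", "domain-3p",
                         dend - region_codons + 1, dend,
                         slice_cds(dend - region_codons + 1, dend))
        )
        # 5' flank: the region_codons codons immediately upstream
        fstart, fend = dstart - region_codons, dstart - 1
        if fstart < 1:
            rejected.append((f"{cds.gene_id}:{dom_id}:flank-5p", "too-short"))
        elif any(mask[fstart - 1 : fend]):
            rejected.append((f"{cds.gene_id}:{dom_id}:flank-5p", "contains-domain"))
        else:
            regions.append(
                DomainRegion(cds.gene_id, "nondomain", "flank-5p", fstart, fend,
                             slice_cds(fstart, fend))
            )
        # 3' flank
        fstart, fend = dend + 1, dend + region_codons
        if fend > plen:
            rejected.append((f"{cds.gene_id}:{dom_id}:flank-3p", "too-short"))
        elif any(mask[fstart - 1 : fend]):
            rejected.append((f"{cds.gene_id}:{dom_id}:flank-3p", "contains-domain"))
        else:
            regions.append(
                DomainRegion(cds.gene_id, "nondomain", "flank-3p", fstart, fend,
                             slice_cds(fstart, fend))
            )
    return regions, rejected


def compare_regions(
    domain_values: Sequence[float], nondomain_values: Sequence[float]
) -> tuple[float, float]:
    """Domain minus nondomain difference in percentage points plus a
    two-sided Wilcoxon rank-sum p-value (groups are unpaired windows)."""
    dv = np.asarray(domain_values, dtype=float)
    nv = np.asarray(nondomain_values, dtype=float)
    if dv.size == 0 or nv.size == 0:
        raise ValueError("both groups must be non-empty")
    delta = 100.0 * (dv.mean() - nv.mean())
    stat = stats.ranksums(dv, nv)
    return float(delta), float(stat.pvalue)


# ---------------------------------------------------------------------------
# ENC (Wright's effective number of codons)

# family groups of the standard code with unsplit sixfold families
_DEGENERACY_GROUPS = {2: 9, 3: 1, 4: 5, 6: 3}


def _codon_counts(codons: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in codons:
        cu = c.upper()
        if cu in STOP_CODONS or any(b not in "ACGT" for b in cu):
            continue
        counts[cu] = counts.get(cu, 0) + 1
    return counts


def enc(cds_codons: Iterable[str]) -> float:
    """Wright's effective number of codons of one gene.

    Per family, the homozygosity estimate F = (n * sum p_i^2 - 1)/(n - 1)
    over the n observed codons; families with n < 2 are skipped. ENC is
    2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk the mean over families of
    degeneracy k; a wholly missing threefold group is imputed from
    (F2 + F4)/2. The value is clamped to [20, 61]; NaN when any required
    group mean cannot be estimated.
    """
    counts = _codon_counts(cds_codons)
    f_by_group: dict[int, list[float]] = {k: [] for k in _DEGENERACY_GROUPS}
    for fam, codons in families().items():
        k = len(codons)
        if k == 1:
            continue
        obs = np.array([counts.get(c, 0) for c in codons], dtype=float)
        n = obs.sum()
        if n < 2:
            continue
        p = obs / n
        f_hat = (n * (p**2).sum() - 1) / (n - 1)
        f_by_group[k].append(f_hat)

    means: dict[int, float] = {}
    for k, fs in f_by_group.items():
        means[k] = float(np.mean(fs)) if fs else math.nan
    if math.isnan(means[3]) and not math.isnan(means[2]) and not math.isnan(means[4]):
        means[3] = (means[2] + means[4]) / 2.0
    if any(math.isnan(means[k]) or means[k] <= 0 for k in _DEGENERACY_GROUPS):
        # a group mean of exactly 0 means no detectable bias at the sample
        # size; treat as the no-bias limit rather than undefined when the
        # other groups are estimable
        if all(not math.isnan(means[k]) for k in _DEGENERACY_GROUPS) and any(
            means[k] == 0 for k in _DEGENERACY_GROUPS
        ):
            return 61.0
        return math.nan
    value = 2.0 + sum(
        n_fams / means[k] for k, n_fams in _DEGENERACY_GROUPS.items()
    )
    return float(min(61.0, max(20.0, value)))


# ---------------------------------------------------------------------------
# Fop and the HGC/LGC split

def fop(cds_codons: Iterable[str], optimal_codons: Iterable[str]) -> float:
    """Fraction of optimal codons.

    Denominator: codons belonging to families that contain at least one
    optimal codon (other families carry no signal). NaN when that
    denominator is zero.
    """
    optimal = {c.upper() for c in optimal_codons}
    if not optimal:
        raise ValueError("empty optimal-codon set")
    opt_families = {family_of(c) for c in optimal}
    num = den = 0
    for c in cds_codons:
        cu = c.upper()
        if cu in STOP_CODONS or any(b not in "ACGT" for b in cu):
            continue
        if family_of(cu) in opt_families:
            den += 1
            num += cu in optimal
    return num / den if den else math.nan


def split_hgc_lgc(
    records: Sequence[CodingSequence], boundary: float = 0.60
) -> tuple[list[CodingSequence], list[CodingSequence]]:
    """Partition genes into high-GC (GC >= boundary) and low-GC subsets,
    the split applied to grass genomes with bimodal GC distributions."""
    hgc, lgc = [], []
    for rec in records:
        (hgc if gc_content(rec.seq) >= boundary else lgc).append(rec)
    return hgc, lgc
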