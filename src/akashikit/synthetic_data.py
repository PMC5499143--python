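"""Synthetic ortholog-trio generator with known, configurable effects.

The generator emits everything the pipeline reads — three CDS FASTA
files, protein alignments (pairwise and trio), domain coordinates, a
dot-bracket structure file with pairing probabilities, an expression
table, and tRNA copy numbers — from a generative model whose ground
truth is recorded alongside:

* each gene is a run of amino-acid sites drawn from the 18 degenerate
  codon families; a site is conserved with probability ``f_conserved``;
* the principal species uses its family's designated optimal codon with
  probability ``p_conserved`` at conserved sites and ``p_variable`` at
  variable sites (nonoptimal codons are uniform over the peers), so the
  generative Akashi odds ratio is the closed form
  [p_c/(1-p_c)] / [p_v/(1-p_v)];
* variable sites change amino acid on the sister branch (and optionally
  on the principal/outgroup branches), so trio parsimony recovers the
  conserved mask;
* one domain spans the middle of each gene; inside it, third bases are
  tilted toward G/C so that the domain-vs-flank GC3 difference equals
  ``domain_gc3_shift`` in expectation;
* a fraction of codons sit in mRNA stems: their third bases are paired
  in the emitted dot-bracket, strongly (probability >= 0.9) with
  probability ``strong_pair_prob``;
* log10 expression is Normal(mu + beta * Fop, sigma) per experiment, so
  high-Fop genes are the strongly expressed ones and the optimal-codon
  caller can rediscover the designated set;
* tRNA copy numbers are Poisson, higher for designated optimal codons.

Each gene has its own random stream keyed by (seed, gene index), so
growing the gene set leaves earlier genes untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genetic_code import CODON_TO_AA, families
from .sequence_io import (
    CodingSequence,
    DomainAnnotation,
    StructureAnnotation,
    write_cds_fasta,
    write_domain_table,
    write_expression_table,
    write_fasta,
    write_structure_file,
    write_trna_table,
)
from .enrichment_stats import EnrichmentResult, mantel_haenszel_arrays

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "GeneRealization",
    "SimulationBundle",
    "designated_optimal_codons",
    "expected_akashi_or",
    "simulate",
    "simulate_count_strata",
    "truth_report",
]

_FAMS = {aa: codons for aa, codons in families().items() if len(codons) > 1}
_FAM_KEYS = tuple(sorted(_FAMS))  # the 18 degenerate families


def designated_optimal_codons() -> dict[str, str]:
    """family -> designated optimal codon: the C-ending codon when the
    family has one, else the G-ending codon (GC3-rich, as in most plant
    optimal-codon sets)."""
    out = {}
    for aa, codons in _FAMS.items():
        c_ending = [c for c in codons if c[2] == "C"]
        g_ending = [c for c in codons if c[2] == "G"]
        out[aa] = sorted(c_ending)[0] if c_ending else sorted(g_ending)[0]
    return out


_OPTIMAL = designated_optimal_codons()
_NONOPT = {aa: tuple(c for c in codons if c != _OPTIMAL[aa]) for aa, codons in _FAMS.items()}
# same-first-two-bases G/C-ending variants of each codon (for the GC3 tilt)
_GC_VARIANTS = {
    c: tuple(v for v in _FAMS[CODON_TO_AA[c]] if v[:2] == c[:2] and v[2] in "GC")
    for aa, codons in _FAMS.items()
    for c in codons
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 500
    len_min: int = 300  # body codons, excluding the start Met and stop
    len_max: int = 300
    f_conserved: float = 0.7
    sister_sub_prob: float = 1.0  # P(amino-acid change on the sister branch | variable site)
    principal_sub_prob: float = 0.0
    outgroup_sub_prob: float = 0.0
    p_conserved: float = 0.7  # P(optimal codon | conserved site)
    p_variable: float = 0.5
    # per-gene heterogeneity in codon bias: a Normal(0, sd) shift on the
    # log-odds of choosing the optimal codon, applied to both site classes.
    # It spreads gene Fop (coupling codon usage to expression) while leaving
    # every gene's conditional odds ratio — and hence the MH estimand —
    # untouched, which is exactly the property the gene-stratified design
    # relies on.
    gene_logodds_sd: float = 0.6
    # optional late-transcript regime for positional-gradient studies
    change_point_codon: int | None = None  # body codon index; later sites use *_late
    p_conserved_late: float | None = None
    p_variable_late: float | None = None
    domain_fraction: float = 1.0 / 3.0  # one central domain per gene
    domain_gc3_shift: float = 0.0  # expected GC3 excess (fraction) inside the domain
    stem_fraction: float = 0.4  # fraction of codons with a paired third base
    strong_pair_prob: float = 0.9  # P(pairing probability >= 0.9 | paired)
    expr_mu: float = 2.5  # log10 expression intercept
    expr_beta: float = 2.0  # log10 expression slope on gene Fop
    expr_sigma: float = 0.4
    n_experiments: int = 5
    trna_optimal_mean: float = 8.0  # Poisson means for tRNA gene copies
    trna_nonoptimal_mean: float = 2.0
    indel_rate: float = 0.0  # per-site sister deletion probability

    def validate(self) -> None:
        probs = dict(
            f_conserved=self.f_conserved,
            sister_sub_prob=self.sister_sub_prob,
            principal_sub_prob=self.principal_sub_prob,
            outgroup_sub_prob=self.outgroup_sub_prob,
            p_conserved=self.p_conserved,
            p_variable=self.p_variable,
            stem_fraction=self.stem_fraction,
            strong_pair_prob=self.strong_pair_prob,
            indel_rate=self.indel_rate,
        )
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.f_conserved < 1.0:
            raise ValueError("f_conserved must be strictly between 0 and 1: "
                             "both site classes are required")
        for p in (self.p_conserved, self.p_variable):
            if not 0.0 < p < 1.0:
                raise ValueError("codon-choice probabilities must be in (0, 1)")
        if self.gene_logodds_sd < 0:
            raise ValueError("gene_logodds_sd must be non-negative")
        if self.len_min < 6 or self.len_max < self.len_min:
            raise ValueError("bad codon-length range")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.domain_fraction <= 1.0:
            raise ValueError("domain_fraction outside [0, 1]")


def expected_akashi_or(p_c: float, p_v: float) -> float:
    """Closed-form generative odds ratio [p_c/(1-p_c)] / [p_v/(1-p_v)]."""
    return (p_c / (1 - p_c)) / (p_v / (1 - p_v))


@dataclass
class GeneRealization:
    gene_id: str
    length: int  # body codons
    principal_cds: str
    sister_cds: str
    outgroup_cds: str
    principal_aln: str  # aligned proteins (with '-' at sister deletions)
    sister_aln: str
    outgroup_aln: str
    conserved_mask: np.ndarray  # per body site, realized (all three aa equal)
    domain: DomainAnnotation | None
    structure: StructureAnnotation
    stem_strong_mask: np.ndarray  # per CDS codon (incl. Met), third base S
    fop: float


@dataclass
class SimulationTruth:
    config: SimulationConfig
    optimal_codons: tuple[str, ...]
    expected_or: float
    conserved_sites: dict[str, list[int]]  # gene -> 1-based body positions

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "optimal_codons": list(self.optimal_codons),
            "expected_or": self.expected_or,
            "n_conserved": {g: len(v) for g, v in self.conserved_sites.items()},
        }


@dataclass
class SimulationBundle:
    genes: list[GeneRealization]
    expression: pd.DataFrame  # gene x experiment, raw values
    trna_counts: dict[str, int]
    truth: SimulationTruth

    def principal_records(self) -> list[CodingSequence]:
        return [CodingSequence(g.gene_id, g.principal_cds, "principal") for g in self.genes]

    def trio_alignment(self, gene: GeneRealization) -> list[tuple[str, str]]:
        return [
            (f"{gene.gene_id}_P", gene.principal_aln),
            (f"{gene.gene_id}_S", gene.sister_aln),
            (f"{gene.gene_id}_O", gene.outgroup_aln),
        ]

    def pair_alignment(self, gene: GeneRealization) -> list[tuple[str, str]]:
        return [
            (f"{gene.gene_id}_P", gene.principal_aln),
            (f"{gene.gene_id}_S", gene.sister_aln),
        ]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        (out / "alignments" / "trio").mkdir(parents=True, exist_ok=True)
        (out / "alignments" / "pair").mkdir(parents=True, exist_ok=True)
        for role, attr in (("principal", "principal_cds"), ("sister", "sister_cds"),
                           ("outgroup", "outgroup_cds")):
            write_cds_fasta(
                out / f"{role}.cds.fasta",
                [CodingSequence(g.gene_id, getattr(g, attr), role) for g in self.genes],
            )
        for g in self.genes:
            write_fasta(out / "alignments" / "trio" / f"{g.gene_id}.fasta",
                        dict(self.trio_alignment(g)))
            write_fasta(out / "alignments" / "pair" / f"{g.gene_id}.fasta",
                        dict(self.pair_alignment(g)))
        write_domain_table(out / "domains.tsv",
                           [g.domain for g in self.genes if g.domain is not None])
        write_structure_file(out / "structures.txt", [g.structure for g in self.genes])
        write_expression_table(out / "expression.tsv", self.expression)
        write_trna_table(out / "trna.tsv", self.trna_counts)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.truth.config), fh, sort_keys=True)
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(self.truth.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# generation internals

def _logit_shift(p, u):
    """expit(logit(p) + u), elementwise over arrays or scalars."""
    return 1.0 / (1.0 + (1.0 - np.asarray(p)) / np.asarray(p) * np.exp(-np.asarray(u)))


def _mean_at3_probability(p_mix: float) -> float:
    """Expected fraction of A/T third bases before any domain tilt, given
    the marginal optimal-codon probability ``p_mix``."""
    total = 0.0
    for aa in _FAM_KEYS:
        opt = _OPTIMAL[aa]
        peers = _NONOPT[aa]
        p_at = (1 if opt[2] in "AT" else 0) * p_mix
        p_at += (1 - p_mix) * sum(1 for c in peers if c[2] in "AT") / len(peers)
        total += p_at
    return total / len(_FAM_KEYS)


def _site_probs(cfg: SimulationConfig, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-body-site (p_conserved, p_variable) vectors honouring the
    optional late-transcript change point."""
    p_c = np.full(length, cfg.p_conserved)
    p_v = np.full(length, cfg.p_variable)
    if cfg.change_point_codon is not None:
        late = np.arange(1, length + 1) > cfg.change_point_codon
        if cfg.p_conserved_late is not None:
            p_c[late] = cfg.p_conserved_late
        if cfg.p_variable_late is not None:
            p_v[late] = cfg.p_variable_late
    return p_c, p_v


def _draw_codons(rng, fam_idx: np.ndarray, optimal: np.ndarray) -> list[str]:
    out = []
    u = rng.random(len(fam_idx))
    for i, (fi, is_opt) in enumerate(zip(fam_idx, optimal)):
        aa = _FAM_KEYS[fi]
        if is_opt:
            out.append(_OPTIMAL[aa])
        else:
            peers = _NONOPT[aa]
            out.append(peers[int(u[i] * len(peers)) % len(peers)])
    return out


def _gene_fop(codons: Sequence[str]) -> float:
    opt = set(_OPTIMAL.values())
    fams = set(_FAM_KEYS)
    den = sum(1 for c in codons if CODON_TO_AA.get(c) in fams)
    num = sum(1 for c in codons if c in opt)
    return num / den if den else math.nan


def _simulate_gene(cfg: SimulationConfig, index: int) -> GeneRealization:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))
    gene_id = f"g{index:04d}"
    length = int(rng.integers(cfg.len_min, cfg.len_max + 1))
    conserved = rng.random(length) < cfg.f_conserved
    p_c, p_v = _site_probs(cfg, length)
    u_gene = float(rng.normal(0.0, cfg.gene_logodds_sd)) if cfg.gene_logodds_sd else 0.0
    p_site = _logit_shift(np.where(conserved, p_c, p_v), u_gene)

    fam_idx = rng.integers(0, len(_FAM_KEYS), size=length)
    optimal = rng.random(length) < p_site
    principal = _draw_codons(rng, fam_idx, optimal)

    # one central domain; protein coordinates are body + 1 (leading Met)
    domain = None
    dom_lo = dom_hi = 0  # 1-based body coords, inclusive; 0 = no domain
    if cfg.domain_fraction > 0:
        dom_len = max(1, round(length * cfg.domain_fraction))
        dom_lo = (length - dom_len) // 2 + 1
        dom_hi = dom_lo + dom_len - 1
        domain = DomainAnnotation(gene_id, (("DOM1", dom_lo + 1, dom_hi + 1),))

    if cfg.domain_gc3_shift > 0 and domain is not None:
        p_mix = float(
            _logit_shift(
                np.array([cfg.f_conserved * cfg.p_conserved
                          + (1 - cfg.f_conserved) * cfg.p_variable]),
                u_gene,
            )[0]
        )
        p_at = _mean_at3_probability(p_mix)
        s = min(1.0, cfg.domain_gc3_shift / p_at) if p_at > 0 else 0.0
        tilt = rng.random(length) < s
        pick = rng.random(length)
        for i in range(dom_lo - 1, dom_hi):
            c = principal[i]
            if tilt[i] and c[2] in "AT":
                variants = _GC_VARIANTS[c]
                if variants:
                    principal[i] = variants[int(pick[i] * len(variants)) % len(variants)]

    # sister and outgroup
    sister_fam = fam_idx.copy()
    outgroup_fam = fam_idx.copy()
    principal_fam = fam_idx.copy()
    variable = ~conserved
    n_fam = len(_FAM_KEYS)

    def _reassign(mask: np.ndarray, fams: np.ndarray) -> np.ndarray:
        shift = rng.integers(1, n_fam, size=len(fams))
        return np.where(mask, (fams + shift) % n_fam, fams)

    sister_fam = _reassign(variable & (rng.random(length) < cfg.sister_sub_prob), sister_fam)
    outgroup_fam = _reassign(variable & (rng.random(length) < cfg.outgroup_sub_prob), outgroup_fam)
    principal_change = variable & (rng.random(length) < cfg.principal_sub_prob)
    principal_fam = _reassign(principal_change, principal_fam)
    # re-draw principal codons where its own branch changed
    if principal_change.any():
        redraw = _draw_codons(
            rng, principal_fam[principal_change],
            rng.random(int(principal_change.sum())) < p_site[principal_change],
        )
        j = 0
        for i in np.flatnonzero(principal_change):
            principal[i] = redraw[j]
            j += 1

    sister = _draw_codons(rng, sister_fam, rng.random(length) < p_site)
    outgroup = _draw_codons(rng, outgroup_fam, rng.random(length) < p_site)

    # realized truth is what an observer of the trio sees: all three equal
    realized_conserved = (principal_fam == sister_fam) & (principal_fam == outgroup_fam)

    deletion = rng.random(length) < cfg.indel_rate  # sister-branch codon loss

    def _aa_of(fams: np.ndarray) -> str:
        return "".join(_FAM_KEYS[i] for i in fams)

    principal_prot = "M" + _aa_of(principal_fam)
    sister_body = _aa_of(sister_fam)
    outgroup_prot = "M" + _aa_of(outgroup_fam)
    sister_aln = "M" + "".join(
        "-" if deletion[i] else sister_body[i] for i in range(length)
    )
    stops = ("TAA", "TGA", "TAG")
    stop = stops[int(rng.integers(0, 3))]
    principal_cds = "ATG" + "".join(principal) + stop
    sister_cds = "ATG" + "".join(c for i, c in enumerate(sister) if not deletion[i]) + stop
    outgroup_cds = "ATG" + "".join(outgroup) + stop

    # secondary structure over the full principal CDS
    n_codons = length + 2  # incl. Met and stop
    stem = rng.random(n_codons) < cfg.stem_fraction
    stem[-1] = False  # leave the stop unpaired
    strong = rng.random(n_codons) < cfg.strong_pair_prob
    db = ["."] * (3 * n_codons)
    paired_pos = [3 * i + 2 for i in np.flatnonzero(stem)]
    if len(paired_pos) % 2:
        dropped = paired_pos.pop()
        stem[dropped // 3] = False
    half = len(paired_pos) // 2
    for p in paired_pos[:half]:
        db[p] = "("
    for p in paired_pos[half:]:
        db[p] = ")"
    probs = np.zeros(3 * n_codons)
    for i in np.flatnonzero(stem):
        lo, hi = (0.9, 1.0) if strong[i] else (0.2, 0.6)
        probs[3 * i + 2] = lo + (hi - lo) * rng.random()
    structure = StructureAnnotation(
        gene_id, principal_cds, "".join(db), tuple(np.round(probs, 4))
    )
    return GeneRealization(
        gene_id=gene_id,
        length=length,
        principal_cds=principal_cds,
        sister_cds=sister_cds,
        outgroup_cds=outgroup_cds,
        principal_aln=principal_prot,
        sister_aln=sister_aln,
        outgroup_aln=outgroup_prot,
        conserved_mask=realized_conserved,
        domain=domain,
        structure=structure,
        stem_strong_mask=stem & strong,
        fop=_gene_fop(principal),
    )


def simulate(config: SimulationConfig, outdir: str | Path | None = None) -> SimulationBundle:
    """Generate the full file bundle; optionally write it under ``outdir``.

    The same config (seed included) always yields a byte-identical bundle.
    """
    config.validate()
    genes = [_simulate_gene(config, i) for i in range(config.n_genes)]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 999_983]))
    expr = {}
    for g in genes:
        mu = config.expr_mu + config.expr_beta * (g.fop if math.isfinite(g.fop) else 0.0)
        logvals = rng.normal(mu, config.expr_sigma, size=config.n_experiments)
        expr[g.gene_id] = np.round(10.0 ** logvals, 3)
    expression = pd.DataFrame.from_dict(
        expr, orient="index",
        columns=[f"exp{i + 1}" for i in range(config.n_experiments)],
    )
    expression.index.name = "gene"

    optimal_set = set(_OPTIMAL.values())
    trna = {}
    for aa, codons in _FAMS.items():
        for c in codons:
            mean = config.trna_optimal_mean if c in optimal_set else config.trna_nonoptimal_mean
            trna[c] = int(rng.poisson(mean))
    for aa, codons in families().items():  # single-codon families too
        for c in codons:
            trna.setdefault(c, int(rng.poisson(config.trna_optimal_mean)))

    truth = SimulationTruth(
        config=config,
        optimal_codons=tuple(sorted(optimal_set)),
        expected_or=expected_akashi_or(config.p_conserved, config.p_variable),
        conserved_sites={
            g.gene_id: [int(i) + 1 for i in np.flatnonzero(g.conserved_mask)]
            for g in genes
        },
    )
    bundle = SimulationBundle(genes, expression, trna, truth)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


# ---------------------------------------------------------------------------
# count-level fast path for calibration studies

def simulate_count_strata(
    config: SimulationConfig, n_replicates: int, seed: int | None = None
) -> list[EnrichmentResult]:
    """Replicate Akashi tests on count-level draws from the generative model.

    Under the generator (without a domain GC3 tilt) each body site's
    optimal/nonoptimal outcome is an independent Bernoulli given its
    conservation class, so a gene's Akashi stratum is a pair of binomials.
    This draws those counts directly and pools them with the same MH
    machinery, which makes large calibration studies (hundreds of
    replicates of hundreds of genes) cheap while remaining distributionally
    identical to running the full pipeline on emitted files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = (n_replicates, config.n_genes)
    lengths = rng.integers(config.len_min, config.len_max + 1, size=shape)
    n_c = rng.binomial(lengths, config.f_conserved)
    n_v = lengths - n_c
    u = rng.normal(0.0, config.gene_logodds_sd, size=shape) if config.gene_logodds_sd else 0.0
    a = rng.binomial(n_c, _logit_shift(config.p_conserved, u))
    b = n_c - a
    c = rng.binomial(n_v, _logit_shift(config.p_variable, u))
    d = n_v - c
    out = []
    for r in range(n_replicates):
        or_, chi2, p = mantel_haenszel_arrays(a[r], b[r], c[r], d[r])
        n_inf = int(((a[r] + b[r] > 0) & (c[r] + d[r] > 0)
                     & (a[r] + c[r] > 0) & (b[r] + d[r] > 0)).sum())
        out.append(EnrichmentResult("akashi", or_, chi2, p, n_inf, "conserved"))
    return out


def truth_report(
    truth: SimulationTruth,
    estimates: Mapping[str, EnrichmentResult],
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tabulate estimated vs expected odds ratios per contrast."""
    if gene_ids is not None and set(gene_ids) != set(truth.conserved_sites):
        raise ValueError("gene sets of truth and results do not match")
    rows = []
    for label, res in estimates.items():
        rows.append(
            {
                "contrast": label,
                "expected_or": truth.expected_or,
                "estimated_or": res.odds_ratio,
                "bias": res.odds_ratio - truth.expected_or,
                "sign_agrees": (res.odds_ratio > 1) == (truth.expected_or > 1),
                "p_value": res.p_value,
                "n_strata": res.n_strata,
            }
        )
    return pd.DataFrame(rows).set_index("contrast")
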