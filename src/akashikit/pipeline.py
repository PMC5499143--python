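"""End-to-end orchestration over a compliant input bundle.

A run consumes the file layout the synthetic generator emits (and any
real data arranged the same way): per-species CDS FASTA, per-gene
protein alignments, domain/structure/expression/tRNA side tables. It
classifies sites (original, phylogeny-based, or optimality-tied mode),
calls optimal codons from the expression contrast, runs the Akashi test
overall and within each stratification (domain, stem/loop, transcript
thirds), scans per-codon enrichment, computes composition metrics, and
emits TSV reports. Deterministic given config + inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import composition_metrics as comp
from . import enrichment_stats as es
from . import positional_analysis as pos
from . import sequence_io as sio
from . import site_annotation as sa
from .sequence_io import CodingSequence

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "InputError", "run"]


class PipelineError(RuntimeError):
    pass


class InputError(PipelineError):
    pass


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    mode: str = "phylogeny"  # original | phylogeny | optimality-tied
    min_identity: float = 60.0
    hgc_boundary: float = 0.60
    expressed_threshold: float = 100.0
    expression_quantile: float = 0.20
    alpha: float = 0.05
    strong_pair_threshold: float = 0.9
    positional_window: int = 5
    check_internal_stops: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class GeneData:
    gene_id: str
    cds: CodingSequence
    alignment: sa.CodonAlignment
    sites: sa.SiteClassification


def _load_bundle(cfg: RunConfig) -> tuple[list[GeneData], pd.DataFrame | None, dict | None, dict]:
    root = Path(cfg.input_dir)
    if not (root / "principal.cds.fasta").exists():
        raise InputError(f"missing {root / 'principal.cds.fasta'}")
    principal = {
        r.gene_id: r
        for r in sio.read_cds_fasta(root / "principal.cds.fasta", "principal",
                                    cfg.check_internal_stops)
    }
    roles = {"principal": principal}
    for role in ("sister", "outgroup"):
        path = root / f"{role}.cds.fasta"
        if path.exists():
            roles[role] = {
                r.gene_id: r
                for r in sio.read_cds_fasta(path, role, cfg.check_internal_stops)
            }

    aln_dir = root / "alignments" / ("pair" if cfg.mode == "original" else "trio")
    if not aln_dir.is_dir():
        raise InputError(f"missing alignment directory {aln_dir}")
    needed_roles = ("principal", "sister") if cfg.mode == "original" else (
        "principal", "sister", "outgroup")
    for role in needed_roles:
        if role not in roles:
            raise InputError(f"mode {cfg.mode!r} needs {role}.cds.fasta")

    domains = {}
    if (root / "domains.tsv").exists():
        domains = sio.read_domain_table(root / "domains.tsv")
    structures = {}
    if (root / "structures.txt").exists():
        structures = sio.read_structure_file(root / "structures.txt")
    expression = None
    if (root / "expression.tsv").exists():
        expression = sio.read_expression_table(root / "expression.tsv")
    trna = None
    if (root / "trna.tsv").exists():
        trna = sio.read_trna_table(root / "trna.tsv")

    problems: list[str] = []
    rejects: dict[str, str] = {}
    genes: list[GeneData] = []
    alignments = []
    for path in sorted(aln_dir.glob("*.fasta")):
        records = sio.read_protein_alignment(path)
        gene_id = records[0].id.rsplit("_", 1)[0]
        cds_list = []
        for rec, role in zip(records, needed_roles):
            base = rec.id.rsplit("_", 1)[0]
            if base not in roles[role]:
                problems.append(f"{path.name}: no {role} CDS for {base}")
                continue
            cds_list.append(roles[role][base])
        if len(cds_list) != len(records):
            continue
        invalid = [c for c in cds_list if not c.valid]
        if invalid:
            rejects[gene_id] = f"invalid-cds:{invalid[0].invalid_reason}"
            continue
        alignments.append((gene_id, records, cds_list))
    if problems:
        raise InputError("cross-reference failures:\n" + "\n".join(problems))

    kept = sio.filter_ortholog_pairs([r for _, r, _ in alignments], cfg.min_identity)
    kept_ids = {id(r) for r in kept}
    for gene_id, records, cds_list in alignments:
        if id(records) not in kept_ids:
            rejects[gene_id] = "identity-below-threshold"
            continue
        aln = sa.build_codon_alignment(records, cds_list)
        if cfg.mode == "original":
            sites = sa.classify_pairwise(aln)
        else:
            sites = sa.classify_phylogeny(aln)
        plen = len(cds_list[0].codons(drop_stop=True))
        sa.annotate_domain(sites, aln, domains.get(gene_id), plen)
        if gene_id in structures:
            sa.annotate_structure(sites, aln, structures[gene_id], cfg.strong_pair_threshold)
        sa.assign_thirds(sites, aln, plen)
        genes.append(GeneData(gene_id, cds_list[0], aln, sites))
    return genes, expression, trna, rejects


def _gene_site_tuples(genes: Sequence[GeneData]):
    """gene -> ordered per-column (codon, state, in_domain, structure, third)
    restricted to non-gap principal columns."""
    out = {}
    for g in genes:
        rows = []
        for i, codon in enumerate(col[0] for col in g.alignment.columns):
            if codon == sa.GAP:
                continue
            rows.append(
                (codon, g.sites.state[i], g.sites.in_domain[i],
                 g.sites.structure[i], g.sites.third[i])
            )
        out[g.gene_id] = rows
    return out


def _masked(site_rows: Mapping[str, list], predicate) -> dict[str, list[tuple[str, str]]]:
    out = {}
    for gene_id, rows in site_rows.items():
        sel = [(codon, state) for (codon, state, dom, strct, third) in rows
               if predicate(dom, strct, third)]
        if sel:
            out[gene_id] = sel
    return out


_MASKS = {
    "all": lambda dom, strct, third: True,
    "domain": lambda dom, strct, third: dom,
    "nondomain": lambda dom, strct, third: not dom,
    "stem": lambda dom, strct, third: strct == "S",
    "loop": lambda dom, strct, third: strct == "L",
    "third1": lambda dom, strct, third: third == 1,
    "third2": lambda dom, strct, third: third == 2,
    "third3": lambda dom, strct, third: third == 3,
}


def run(cfg: RunConfig) -> dict:
    """Execute the full analysis graph; returns the in-memory results and
    writes TSV reports under ``cfg.output_dir``."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log_lines = [f"# config_hash={chash}"]

    genes, expression, trna, rejects = _load_bundle(cfg)
    for gid, reason in sorted(rejects.items()):
        log_lines.append(f"rejected\t{gid}\t{reason}")
    if not genes:
        raise InputError("no genes survived loading/filtering")
    site_rows = _gene_site_tuples(genes)

    results: dict = {"config_hash": chash, "n_genes": len(genes), "rejects": rejects}

    # site-count conservation bookkeeping
    counts = pd.DataFrame(
        [{"gene": g.gene_id, **g.sites.counts(), "columns": len(g.alignment)} for g in genes]
    ).set_index("gene")
    results["site_counts"] = counts

    # optimal codons from the expression contrast
    optimal_set = None
    if expression is not None:
        cds_by_gene = {g.gene_id: g.cds.codons(drop_stop=True) for g in genes}
        optimal_set = es.identify_optimal_codons(
            cds_by_gene, expression,
            quantile=cfg.expression_quantile, alpha=cfg.alpha,
            expressed_threshold=cfg.expressed_threshold,
        )
        results["optimal_codons"] = optimal_set
        optimal_set.table.to_csv(outdir / "optimal_codons.tsv", sep="\t")

    if cfg.mode == "optimality-tied":
        if optimal_set is None:
            raise InputError("optimality-tied mode needs an expression table "
                             "to derive the favoured-base map")
        favored = optimal_set.favored_base_map()
        for g in genes:
            g.sites = sa.apply_optimality_tied(g.alignment, g.sites, favored)
        site_rows = _gene_site_tuples(genes)

    # per-codon enrichment scan, conserved vs variable
    simple_sites = _masked(site_rows, _MASKS["all"])
    scan = es.codon_enrichment_scan(simple_sites, "conserved", "variable")
    scan_df = pd.DataFrame(
        [
            {"codon": c, "odds_ratio": r.odds_ratio, "chi2": r.chi2,
             "p_value": r.p_value, "n_strata": r.n_strata}
            for c, r in scan.items()
        ]
    ).set_index("codon")
    results["codon_scan"] = scan_df
    scan_df.to_csv(outdir / "codon_enrichment.tsv", sep="\t")

    # Akashi test overall and per stratum
    akashi_rows = []
    if optimal_set is not None and optimal_set.optimal_codons:
        opt = sorted(optimal_set.optimal_codons)
        results["akashi"] = {}
        for name, pred in _MASKS.items():
            subset = _masked(site_rows, pred)
            try:
                res = es.akashi_test(subset, opt, label=name)
            except es.NoInformativeStrataError:
                log_lines.append(f"akashi\t{name}\tno-informative-strata")
                continue
            results["akashi"][name] = res
            akashi_rows.append(
                {"stratum": name, "odds_ratio": res.odds_ratio, "chi2": res.chi2,
                 "p_value": res.p_value, "significant": res.p_value < cfg.alpha,
                 "n_strata": res.n_strata}
            )
        pd.DataFrame(akashi_rows).set_index("stratum").to_csv(
            outdir / "akashi_summary.tsv", sep="\t")

        # positional profile
        pools = pos.build_window_pools(simple_sites, cfg.positional_window)
        profile = pos.positional_profiles(pools, opt, cfg.positional_window)
        results["positional"] = profile
        profile.to_csv(outdir / "positional_profile.tsv", sep="\t", index=False)

    # composition metrics per gene
    comp_rows = []
    for g in genes:
        body = g.cds.seq[: len(g.cds.seq) - 3]  # stop excluded
        gc = comp.gc_content(body)
        row = {
            "gene": g.gene_id,
            "gc": gc,
            "gc3": comp.gc3_content(body),
            "enc": comp.enc(g.cds.codons(drop_stop=True)),
            "gc_class": "HGC" if gc >= cfg.hgc_boundary else "LGC",
        }
        if optimal_set is not None and optimal_set.optimal_codons:
            row["fop"] = comp.fop(g.cds.codons(drop_stop=True),
                                  optimal_set.optimal_codons)
        comp_rows.append(row)
    comp_df = pd.DataFrame(comp_rows).set_index("gene")
    results["composition"] = comp_df
    comp_df.to_csv(outdir / "gene_metrics.tsv", sep="\t")

    # domain vs nondomain sliding-window composition
    dom_gc3, nondom_gc3 = [], []
    domain_tbl = {}
    if (Path(cfg.input_dir) / "domains.tsv").exists():
        domain_tbl = sio.read_domain_table(Path(cfg.input_dir) / "domains.tsv")
    for g in genes:
        doms = domain_tbl.get(g.gene_id)
        if doms is None:
            continue
        regions, rejected = comp.extract_domain_regions(g.cds, doms)
        for _desc, reason in rejected:
            log_lines.append(f"region-rejected\t{_desc}\t{reason}")
        for region in regions:
            series = comp.sliding_window_series(region.seq)
            target = dom_gc3 if region.label == "domain" else nondom_gc3
            target.extend(series["gc3"].tolist())
    if dom_gc3 and nondom_gc3:
        delta, p = comp.compare_regions(dom_gc3, nondom_gc3)
        results["domain_composition"] = {
            "delta_gc3_points": delta, "wilcoxon_p": p,
            "n_domain_windows": len(dom_gc3), "n_nondomain_windows": len(nondom_gc3),
        }
        pd.DataFrame([results["domain_composition"]]).to_csv(
            outdir / "domain_composition.tsv", sep="\t", index=False)

    if trna:
        rscu = es.trna_rscu(trna)
        results["trna_rscu"] = rscu
        rscu.to_csv(outdir / "trna_rscu.tsv", sep="\t")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
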