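# Methods

## The question and the design

When a ribosome misreads a codon, the cell pays for a protein it cannot
use. If some synonymous codons are translated more accurately than
others, selection should concentrate those codons at amino-acid sites
where a mistranslation is most costly — sites that are evolutionarily
conserved. The Akashi test formalises this: within each gene, compare
how often an "optimal" codon (versus its synonymous peers) is used at
conserved versus variable sites, and pool the per-gene 2×2 tables. An
odds ratio above 1, with a significant test, is the signature of
selection for translational accuracy.

The per-gene stratification is the crux of the design. Expression
level, regional mutational bias and base composition differ enormously
*between* genes; by comparing conserved and variable sites *within*
each gene and only then pooling, those between-gene factors cancel and
cannot masquerade as an accuracy signal.

## Mantel–Haenszel machinery

For gene *i* with table (aᵢ, bᵢ; cᵢ, dᵢ) — rows focal codon / peers,
columns class A / class B, Nᵢ the table total — the pooled estimator is

    OR_MH = Σᵢ (aᵢdᵢ/Nᵢ) / Σᵢ (bᵢcᵢ/Nᵢ)

with significance from the MH chi-square,

    χ² = ( max(0, |Σaᵢ − ΣEᵢ| − ½) )² / ΣVᵢ ,
    Eᵢ = (aᵢ+bᵢ)(aᵢ+cᵢ)/Nᵢ ,
    Vᵢ = (aᵢ+bᵢ)(cᵢ+dᵢ)(aᵢ+cᵢ)(bᵢ+dᵢ) / (Nᵢ²(Nᵢ−1)) ,

two-sided against χ²₁. Numerical conventions:

* the continuity correction is clamped at zero (as in scipy's Yates
  correction for 2×2 tables); some libraries square a negative
  difference instead, which inflates the statistic when the observed
  and expected counts differ by less than ½;
* strata with Nᵢ ≤ 1 contribute nothing to the variance sum; all-zero
  strata are inert by construction;
* the point estimate is computed from the raw sums. When the pooled
  numerator or denominator is exactly zero the OR is reported as inf /
  NaN rather than silently corrected; callers that need a finite value
  can request a 0.5-cell addition, which is flagged on the result;
* a stratum is *informative* when both row and both column margins are
  positive; the informative count is reported with every result.

Per-codon significance is reported at α = 0.05 without multiple-testing
correction across the 59 scannable codons (each codon's test is of
separate interest); a Benjamini–Hochberg adjustment can be applied
downstream from the exported tables if a family-wise claim is needed.

## Site classification

Sites come from codon alignments built by back-translating a protein
alignment onto the CDS (verified column by column). Three dataset
variants:

* **original** (pairwise): conserved iff the aligned amino acids are
  identical; variable iff both are present and differ; gaps and
  ambiguous codons are excluded.
* **phylogeny-based**: on the fixed rooted topology ((P,S),O), a column
  is variable only when aa(P) = aa(O) ≠ aa(S) — single-column parsimony
  places the change on the sister branch, so codon bias at the site in
  the principal species cannot be a residue of the principal species'
  own nonsynonymous substitution. Changes on the principal branch,
  columns where P = S ≠ O (the change could sit on the outgroup or the
  internal branch), and columns with three states are excluded, as are
  gap columns. Conservation requires all three species identical. The
  implementation is checked exhaustively against Fitch parsimony over
  all 20³ amino-acid columns.
* **optimality-tied**: variable sites are kept only when the two codons
  share the same third (silent) base and their families share the same
  single favoured third base (taken from the optimal-codon set); for
  pairs differing at both first and second positions, every
  intermediate codon on both substitution orderings must be a sense
  codon satisfying the same two conditions. Families whose optimal
  codons disagree on the third base, or that have none, drop the site.

Each column additionally carries: protein-domain membership (1-based
protein intervals, overlaps merged), mRNA stem/loop state of the third
base (S when the dot-bracket shows it paired and, when pairing
probabilities are provided, the probability is ≥ 0.9 — the threshold is
configurable because "strongly paired" has no canonical numeric
definition), and the transcript third (blocks of ⌊L/3⌋ codons, the
remainder joining the last block).

## Optimal codons, Fop, tRNA-RSCU, ENC

Optimal codons are called from an expression contrast: per gene, the
mean log₁₀ expression over the experiments in which the gene is
expressed (value > 100); the top and bottom 20% of ranked genes form
the high/low sets (ties broken by gene id); per codon one pooled 2×2
(focal vs peers × high vs low) tested by chi-square; OR > 1 and
p < 0.05 ⇒ optimal. A single pooled table is used rather than per-gene
strata because genes are not paired across the two expression classes.

Fop is the fraction of optimal codons among codons of families
containing at least one optimal codon. tRNA-RSCU normalises tRNA gene
copy numbers so that each family sums to its degeneracy n. ENC follows
Wright's estimator with family groups 9×2-fold, 1×3-fold, 4-fold ×5 and
6-fold ×3 (sixfold families unsplit), a missing threefold group imputed
as (F̄₂+F̄₄)/2, and the value clamped to [20, 61] — mirroring the
behaviour of the classic codonw implementation. A family observed fewer
than twice is skipped; if an entire required group is missing the value
is undefined rather than guessed.

Sixfold families (Leu, Ser, Arg) are treated as single synonymous
families everywhere by default; a `split_sixfold` switch partitions
them into their 2+4 subfamilies for sensitivity analysis. Codons with
ambiguous bases are excluded from every count.

## Domain composition and positional profiles

Around each annotated domain of ≥ 100 aa, the first and last 100 codons
of the domain ("domain") and the adjacent 100-codon flanks
("nondomain") are extracted; flanks shorter than 100 aa or containing
part of another domain are rejected with a reason. GC and GC3 are
computed in sliding windows (size 9 nt, step 3 nt, in frame) within
each region; the domain-vs-nondomain contrast uses the unpaired
Wilcoxon rank-sum test, with the difference quoted in percentage
points. The stop codon is excluded from all per-gene composition and
codon counts; `gc3_content` itself operates on whatever in-frame
sequence it is given.

Positional profiles cut each gene into adjacent 5-codon windows in
principal ungapped coordinates (trailing partial windows dropped), pool
window *w* of all genes into a superalignment, and compute the Akashi
test (genes as strata) and Fop (on the pooled supersequence) per
window. A least-squares single-step fit locates change points in the
resulting series. Windows are indexed on the principal CDS, not on
alignment columns, so alignment gaps do not shift window boundaries.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not sequence evolution per se. Per gene: site count L (default 300
body codons), each site conserved with probability f_c = 0.7 (typical
of congeneric plant ortholog alignments); amino acids uniform over the
18 degenerate families; the principal species uses its family's
designated optimal codon with probability p_c = 0.7 at conserved and
p_v = 0.5 at variable sites (nonoptimal choices uniform over peers), so
the generative Akashi odds ratio is the closed form
[p_c/(1−p_c)]/[p_v/(1−p_v)] = 2.333 at the defaults. Variable sites
change amino acid on the sister branch (probability 1 by default;
principal/outgroup branch changes optional), so trio parsimony recovers
the conserved mask exactly under the defaults.

Designated optimal codons are the C-ending (else G-ending) codon of
each family, matching the GC3-rich optimal sets typical of plants. A
per-gene Normal(0, 0.6) shift on the log-odds of optimal-codon choice
models between-gene variation in codon bias; it moves gene Fop (and so
couples codon usage to the expression model,
log₁₀ expr ~ Normal(2.5 + 2·Fop, 0.4) over 5 experiments) while leaving
each gene's conditional odds ratio — the MH estimand — untouched, which
is precisely the robustness property of the stratified design.

Inside the single central domain (one third of the gene), third bases
of A/T-ending codons are switched to their same-prefix G/C variant with
a rate calibrated analytically so the expected domain-minus-flank GC3
difference equals `domain_gc3_shift` (default 0; +5 points in the
domain-effect studies). mRNA structure marks a fraction (0.4) of third
bases as paired, strongly (probability ≥ 0.9) with probability 0.9,
emitted as a balanced dot-bracket plus a per-base probability line.
tRNA copy numbers are Poisson(8) for designated optimal codons and
Poisson(2) otherwise. An optional late-transcript regime switches
(p_c, p_v) after a configurable body codon for positional-gradient
studies.

Each gene draws from its own stream keyed by (seed, gene index), so a
bundle is byte-reproducible and extending the gene count does not
perturb earlier genes. A count-level fast path draws each gene's Akashi
stratum directly as binomials — distributionally identical to running
the pipeline on emitted files in the no-tilt, no-indel case — and is
used for calibration studies of hundreds of replicates.

What the generator does *not* emulate: realistic codon substitution
processes (no transition/transversion structure, no rate variation),
linkage between neighbouring sites, realistic domain architectures or
RNA thermodynamics, and (by default) indels. Passing tests therefore
demonstrate the correctness and calibration of the statistical
machinery under its own assumptions, not that any particular real
genome shows an accuracy signal.

## Problem sizes and numerical choices

Calibration studies use 200 replicates (null) and 50 replicates
(recovery) of 500 genes × 300 codons via the count-level path;
positional recovery uses 250 genes × 150 codons through the full
classification path; the acceptance pipeline bundle is 150 genes × 300
codons with the +5-point domain tilt and branch substitution
probabilities 0.15 on the principal and outgroup lineages. These sizes
were chosen so Monte-Carlo error is small relative to the effects under
study. Identity filtering uses gap-free columns as the denominator
(configurable). All thresholds (identity 60%, HGC boundary 0.60
inclusive, expression 100, quantile 0.20, α 0.05, strong-pair 0.9) are
defaults that can be overridden by flags or arguments.

## Known limitations

* The MH test assumes a common odds ratio across strata; the summary it
  returns for heterogeneous effects is a weighted average, and no
  Breslow–Day heterogeneity test is provided.
* Single-column parsimony cannot use rate information; columns with
  P = S ≠ O are discarded although a minority of them are genuine
  outgroup-branch changes.
* The optimal-codon caller pools counts across genes within each
  expression class, so a few long biased genes can dominate the 2×2.
* Structure classification trusts the provided fold; predicted
  dot-brackets correlate only modestly with measured pairing in vivo.
* The CLI covers simulation, validation, tRNA-RSCU and the full
  pipeline (`run-all`); the individual stages are exposed as library
  functions rather than separate subcommands.
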