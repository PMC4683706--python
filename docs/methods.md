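# Methods

## The codon substitution model

All likelihood machinery rests on a GY94-style Markov process on the 61
sense codons of the standard genetic code. The instantaneous rate from
codon *i* to codon *j* is zero when they differ at more than one
nucleotide position and otherwise

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

where `pi` are the equilibrium codon frequencies, `kappa > 0` the
transition/transversion rate ratio, and `omega >= 0` the
nonsynonymous/synonymous rate ratio that measures selection intensity
(< 1 purifying, = 1 neutral, > 1 positive). The matrix is scaled so that
`-sum_i pi_i q_ii = 1`, making a branch length the expected number of
substitutions per codon. The chain is reversible, so trees are unrooted
for likelihood: a degree-two root's two branches are merged into one, and
branches are addressed by the leaf set of the clade below them (the "BMR"
branch means the same branch regardless of rooting).

Model classes: **one-ratio** (a single omega), **free-ratio** (one omega
per branch), **two-ratio** (foreground vs background omega), and the
**branch-site** pair — model A with site classes 0, 1, 2a, 2b
(proportions p0, p1, and the remainder split p0:p1), where class-2 sites
take omega2 on the foreground branch only, and its null with omega2
fixed at 1. In the mixture models the site classes share one clock: each
class matrix is rescaled so that a branch length is the expected
substitution count *averaged over classes*. Sites under omega2 > 1
therefore genuinely substitute faster, which is both the biologically
intended reading of "positive selection at a fraction of sites" and the
source of most of the power of the branch-site test.

Likelihoods are computed by Felsenstein pruning over site patterns
(duplicate columns collapsed) with per-node rescaling of partial vectors;
gap- or N-containing codons are fully ambiguous states, and columns that
are ambiguous in every taxon are dropped. Transition matrices come from
the symmetric eigendecomposition available for reversible chains; the
decompositions are cached per (kappa, omega), which makes the
finite-difference gradient sweeps of the optimizer cheap (perturbing one
branch length re-uses every cached decomposition).

### Fitting

Maximization uses L-BFGS-B on log-transformed rate parameters inside box
bounds — omega in [1e-4, 50], branch lengths in [1e-6, 20], kappa in
[0.05, 50]; branch-site class proportions use two softmax logits.
Estimates at a bound are flagged. Unless an explicit initial fit is
supplied, the nested simpler model is fitted first and seeds the search
(one-ratio seeds two-ratio/free-ratio/branch-site-null; the null seeds
model A); additional restarts perturb the start deterministically from
the fit seed. Convergence tolerance is ~1e-8 lnL units (`ftol = 1e-11`
relative). Scans default to a single restart — with nested seeding the
branch and branch-site likelihoods are well behaved at these data sizes,
and the restart knob remains available where it matters.

Equilibrium frequencies default to F3x4 estimated from each alignment
(uniform, F1x4 and F61 are selectable). Nucleotide frequencies are
floored at 1e-3 before forming codon products so unobserved states never
receive exactly zero mass. Because the frequency convention affects
absolute dS, per-year rates are convention-dependent; all comparisons in
the pipeline are within-convention, so paired contrasts are unaffected.

### Branch measures

From a free-ratio fit, per-branch quantities follow the flux partition of
the normalized rate matrix. With `rhoS(omega)` the synonymous fraction of
total flux and `pS1 = rhoS(1)` its neutral value: `S = 3 L pS1`,
`N = 3 L (1 - pS1)`, `dS = t rhoS / (3 pS1)`, `dN = t (1-rhoS)/(3 (1-pS1))`.
This makes dN/dS equal the fitted omega exactly (an identity the test
suite checks to 1e-8 over random parameter draws). A branch with dS = 0
has no defined omega and is excluded from omega comparisons but retained
for rN.

### Tests

LRTs use `stat = max(0, 2 dlnL)` against chi-square; degrees of freedom
default to the free-parameter difference (1 for one-ratio vs two-ratio
and branch-site null vs A, n_branches - 1 for one-ratio vs free-ratio).
The branch-site LRT is referred to chi-square(1) rather than the 50:50
boundary mixture; this is deliberately conservative, and the calibration
experiment confirms rejection at below the nominal rate under the null.

## Rate and pattern statistics

Genes are kept only if, on all six focal lineages (four terminals plus
the two subterranean/surface ancestral branches), dS <= 1 and
S·dS >= 1 — the first guards against saturation, the second against
branches with essentially no synonymous information. Per-year rates
divide dN or dS by the lineage's time span and multiply by 1000, giving
10^-9 substitutions/site/year; a terminal's span is its pair's split
date (47.4 Ma for BMR and mouse, 39.5 Ma for NMR and guinea pig) —
both sides of a split have evolved for the same absolute time, so e.g.
a guinea-pig dS of 0.021 gives 0.021 / 39.5 * 1000 = 0.53. Paired lineage comparisons use two-sided
Wilcoxon signed-rank tests (exact for <= 25 non-zero differences,
continuity-corrected normal approximation above); unpaired GC
comparisons use two-sided Mann–Whitney U. dN/dS strata split genes into
group 1 (omega < 1 in both lineages) and group 2 (omega > 1 in either);
genes exactly at 1 in one lineage and below in the other belong to
neither and are reported separately. Lineage summaries report both the
mean of per-gene omega values and the ratio of mean dN to mean dS — the
two differ and conflating them is a classic error. GC and GC3 are
computed on the trimmed alignment row of each gene, so all per-gene
statistics describe the same sites.

## GO analyses

Annotations are propagated through the DAG (true-path rule) before any
counting. Terms with >= 10 member genes are represented by the
concatenation of their members' alignments (members sorted by id for
determinism), and a free-ratio fit per term yields the per-lineage
omegas behind the log(omega-ratio) quadrant comparison; omegas are
floored at 1e-4 before logs. Terms with a zero log ratio are tallied
separately rather than assigned to a quadrant. The constrained-term scan
compares one-ratio vs two-ratio with *both* subterranean terminal
branches as one shared-omega foreground (direction "lower",
BH-adjusted alpha 0.01); a per-lineage variant is available behind a
configuration flag, since either reading of "lower in both lineages" is
defensible. Gene-level scans use the same LRT with direction "higher"
(alpha 0.05), and the PSG scan uses branch-site A vs null per terminal
branch. Each scan is its own multiple-testing family under
Benjamini–Hochberg. Enrichment is the classic one-sided Fisher 2x2 test
per term with BH correction; graph-decorrelation methods (elim/weight)
are intentionally out of scope.

## The synthetic study generator

The generator emulates the study design, not any particular genome. Its
defaults are the study conditions: the six-taxon topology
`((((BMR,mouse),kangaroo_rat),(guinea_pig,NMR)),rabbit)`; terminal branch
lengths chosen so expected dS lands in the regime these rodent
divergences show (BMR 0.175 vs mouse 0.26, NMR 0.125 vs guinea pig 0.18
expected substitutions per codon — the subterranean branches are
genuinely shorter per year); per-branch omega at the per-lineage mean
dN/dS values characteristic of the system (BMR 0.137, mouse 0.106,
NMR 0.178, guinea pig 0.143, background 0.11–0.12); kappa 2.5; uniform
codon frequencies. Genes are
i.i.d., indel-free (so a pass-through protein "aligner" is exact; an
indel mode deletes codons from single CDS records to exercise the
back-translation error paths), with lengths drawn uniformly from a
configurable range. A configurable fraction of genes carries a selection
effect: either a branch effect (foreground omega raised to 0.8) or a
branch-site effect (a fraction of sites at omega2 = 6 on the foreground
only, under the shared-clock convention above). GO labels are sampled
terms over genes with a shallow (depth <= 3) DAG, guaranteeing at least
one term above the concatenation threshold. Everything derives from one
seed via spawned substreams, and regeneration is bit-identical.

What the generator does *not* emulate: indel-rich alignments and
alignment error, GC/isochore heterogeneity and biased gene conversion,
rate variation among sites within a class, gene-tree discordance, and
codon-usage bias. Passing tests therefore demonstrate that the
*estimators and scans* behave correctly under the model family they
assume, at study-like parameter values — not that the biological
conclusions would survive every real-data artifact.

## Calibration experiments and problem sizes

The `experiments` module backs both the test suite and
`scripts/acceptance.py`; sizes were chosen as the smallest designs whose
statistical power makes the checks informative on one CPU.

* **Pruning oracle** — random 3-taxon, 2-codon instances against explicit
  root-state marginalization; agreement to 1e-10 relative.
* **Parameter recovery** — genes of 500 codons on the rodent tree with
  per-branch omega drawn from [0.05, 0.5]; the pooled median relative
  error of free-ratio omega estimates is required to be <= 0.2 (24 genes
  in the test suite). Short internal branches contribute most of the
  error, as their expected event counts are small.
* **LRT calibration** — 100 two-ratio nulls (200-codon one-ratio data):
  empirical type-I at alpha 0.05 must fall in [0.01, 0.10]; 20
  branch-site nulls under the study background: rejection rate must not
  exceed the nominal 0.05 (chi-square(1) is conservative here).
* **Gene-scan benchmark** — 120 genes of 150–300 codons, 10% carrying a
  foreground omega effect 0.1 -> 0.8 over a uniform 0.1 background;
  sensitivity >= 0.7 and observed FDR <= 0.15 at BH alpha 0.05. The
  uniform background isolates the scan: under the *study* background the
  subterranean lineages have genuinely (mildly) elevated omega, so a
  sharp scan correctly flags background genes and the truth-table "FDR"
  conflates model truth with annotation truth.
* **Lineage comparisons** — 100 background-only genes at CDS-realistic
  lengths (350–550 codons): paired Wilcoxon tests must find rN and rS
  significantly lower and omega significantly higher in both
  subterranean lineages. Selection effects are excluded from this bundle
  because branch-effect genes push foreground dN upward and work against
  the rate-pace contrast; gene length matters because per-branch omega
  estimates carry an upward finite-sample skew on branches flanking
  short internals (visible on the guinea pig terminal below ~300
  codons).

## Numerical and degenerate-input choices

Tiny negative transition-matrix entries from the eigendecomposition are
clamped to zero. Likelihood evaluations that raise or return non-finite
values inside the optimizer are treated as a very poor objective rather
than an error. A tie in a reciprocal-best-hit argmax disqualifies the
gene (no arbitrary winner). Alignment trimming rejects (a value, not an
exception) when fewer than 150 bp survive; "150 bp or codons" is read as
base pairs, with the codon reading behind a switch. All-zero Wilcoxon
differences give p = 1 with a warning. The pipeline caches stages by a
content signature over configuration and upstream outputs; a stage also
reruns whenever an upstream stage was re-executed in the same
invocation, so deleting one stage's outputs re-runs exactly that stage
and its descendants.

## Known limitations

Site-model scans (M1a/M2a, M7/M8), Bayes empirical Bayes site
identification, among-site rate heterogeneity within a class,
nonhomogeneous-model GC reconstruction, and divergence-time estimation
are out of scope. Absolute dS (hence rN/rS) depends on the frequency
convention as noted; cross-study comparisons of absolute per-year rates
should keep that in mind. The Smith–Waterman default scorer is exact but
quadratic — at genome scale one would swap in a heuristic search tool
through the pluggable scorer interface.
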