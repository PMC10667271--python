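# Methods

`desiccnet` analyses a gradual-versus-rapid drying experiment on a
modified desiccation-tolerant grass: physiology scoring, per-state
differential expression against the hydrated reference, per-tissue
thresholded Pearson co-expression networks with dehydration-state
overlays, metabolite fold-change/ordination analysis, and phytohormone
ANOVA with compact letter displays. This note records the models, the
parameters that matter, and the design choices made where the design
was genuinely open.

## The sampled design

Two tissues (shoot, root), six states — hydrated, ~80%, ~60%, ~40% and
<10% relative water content (RWC), and rehydrated — with three
biological replicates per tissue × state. RWC is
`100·(FW − DW)/(TW − DW)` from fresh, dry and turgid weights. Every
stage keys off a sample sheet (`sample_id`, `tissue`, `state`,
`replicate`).

## Physiology

- **RWC** is returned unclamped; values outside [0, 100] warn rather
  than fail because turgid-weight measurement error makes slight
  excursions real. `TW ≤ DW` is an error (RWC undefined).
- **Survival threshold**: pre-drying RWC bands ordered wettest to
  driest (`100-80`, `70-60`, `50-40`, `30-20`, `<10`); the summary
  returns the wettest band at and below which every band's resurrected
  fraction reaches `min_frac` (default 1.0 — resurrection at 72 h is
  scored all-or-nothing; fractional thresholds are exposed for other
  uses). The hydrated control row is ignored for thresholding.
- **Evans Blue cell-death index**: A600 readings are rescaled to
  `(mean(t) − mean(negative)) / (mean(positive) − mean(negative))`,
  clipped to [0, 1], with boiled tissue as the positive control and
  hydrated tissue as the negative. Raw A600 means are
  instrument-specific; this 0–1 normalisation is our definition, chosen so indices are instrument-independent. Degenerate
  controls (positive ≤ negative) raise an error.

## Differential expression

Expression is consumed on log2 scale. For each tissue × state, every
gene is tested against the hydrated reference of the same tissue with
a two-sided Welch t-test on log2 values — the minimal defensible
location test for triplicates, isolated as a swap point. A gene is
declared differentially expressed iff |fold change| ≥ 2 (i.e.
|log2FC| ≥ 1, boundary inclusive) **and** Benjamini–Hochberg adjusted
p < 0.05 (boundary strict). BH is applied within each tissue × state
contrast (one family per RWC percentage). Genes with zero variance in
both groups and equal means are flagged non-testable (p = NaN) and
excluded from the BH family rather than set to p = 1, so they do not
dilute the correction. The BH computation is delegated to
`statsmodels.stats.multitest.multipletests`; the test suite checks it
against a brute-force step-up oracle.

Note that BH is not idempotent: re-adjusting adjusted values can move a
value across the significance boundary (e.g. m = 2, p = (0.02, 1) →
(0.04, 1) → (0.08, 1)). Adjusted values must therefore be computed from
raw p values exactly once.

## Co-expression networks

Per tissue:

1. **CV ranking.** Coefficient of variation `sd/|mean|` per gene,
   computed across *all* samples of the tissue (states pooled — CV's
   purpose is to find dynamic-range genes, and pooling states maximises
   that signal; the scope is configurable). `|mean|` in the denominator
   handles negative log-scale means; genes with |mean| < 1e-8 are
   excluded with a warning (CV unstable). Ties break lexicographically
   by gene ID so ranking is deterministic and seed-free.
2. **Top-k selection** (default k = 10,000; if fewer genes exist, all
   are taken with a warning).
3. **All-pairs Pearson** on the selected genes (constant genes must be
   filtered first; one reaching this stage is an error naming the
   gene).
4. **Thresholding**: an unordered pair is an edge iff |r| > 0.964,
   strictly. Threshold 1.0 is legal and yields an empty network.
   Isolated genes are excluded from the node set — the graph an
   edge-list import into a viewer such as Cytoscape would produce.

**State overlays** colour nodes up/down/unchanged from the DEG tables;
nodes absent from a table are unchanged. **Summaries** report, per
state: up/down node counts, active edges (both endpoints sharing a
non-unchanged status), connected components of the active subgraph
(isolated active nodes count as singletons — distinct sections of a
state-active network are operationalised as connected components;
community detection is deliberately not used), and Jaccard similarity of active
node sets between states (two identical sets, including two empty
ones, score 1.0). Networks export as a sorted TSV edge list and as
GraphML with per-state node statuses, and round-trip losslessly
through the module's own reader.

## Metabolomics

Fold changes are ratios of raw-scale state means to the hydrated mean
per metabolite × tissue × state; significance uses the same
Welch-on-logs + per-contrast BH machinery as the transcript stage, for
internal consistency, with a raw-p mode exposed since significance
marks on reported panels do not always reflect adjustment. Zero abundances
are replaced by half the metabolite's minimum positive value before
logs (logged per replacement). Heatmap ordering is hierarchical
clustering with Euclidean distance on z-scored rows and average
linkage — a common default, configurable; a constant matrix returns
input order with a warning. PCA autoscales each metabolite to unit
variance by default (standard for GC–MS panels of mixed magnitudes;
center-only is available) and reports scores, loadings and the
variance-explained spectrum.

## Phytohormones

One-way ANOVA of concentration (pmol/mg) across states per hormone;
a panel in which every observation is equal returns F = 0, p = 1 by
convention. The recovery time point is an ordinary level of the state
factor. Letters come from Tukey's HSD (the standard generator of
letter displays; pairwise Welch + BH is offered as an alternative)
via the insert-and-absorb algorithm over states ordered by descending
mean: start with one column holding all states; split every column
containing a significantly different pair; absorb subset columns.
This guarantees exactly that two states share a letter iff their
pairwise comparison is non-significant, and the test suite asserts
that equivalence directly on every instance.

## Synthetic data

The generator is first-class, tested code; its defaults are the
conditions every recovery experiment runs under. All randomness flows
from one root seed through named substreams (CRC32 of the stream name),
so regenerating one table never perturbs the others.

**Expression.** Genes × samples on log2 scale (the upstream
normalisation of real matrices is out of scope, so the scale is
declared rather than inferred; the correlation and CV stages consume
whatever scale they are given). Background genes are independent
Gaussians around gene-specific baselines (Uniform(2, 12)) with residual
SD `noise_sd` (default 0.1 — realistic for well-expressed genes in
replicated bulk RNA-seq). A planted module is a block of `module_size`
genes sharing a latent N(0, 1) factor across its home tissue's samples,
with loading `a = noise_sd·√(ρ/(1−ρ))` so expected pairwise
within-module correlation is exactly `ρ = module_corr` (default 0.4).
On top, module genes shift by ±`deg_log2fc` (default 2.0) in the
module's active (tissue, state) cells only, so a gene can be down at
40% RWC and unchanged at 60%.

Two consequences shaped the defaults. First, the per-sample latent
factor is *within-group* variance for the DEG test: driving `ρ` high
makes planted DEGs undetectable at n = 3 (the factor draw is shared by
the whole module, so entire contrasts fail the BH step collectively).
Second, the planted state-specific shifts themselves induce
between-state covariance shared by co-regulated genes: with the default
design the pooled within-module sample correlation of *active* modules
is ≈ 0.98, comfortably above the 0.964 edge threshold, while
within-group SD stays ≈ 0.13 and Welch detection keeps power ≈ 1.
That is the biologically faithful mechanism — co-expression in a
dehydration series comes from genes moving together across states.
Pure-factor, high-ρ modules (e.g. target r = 0.99) remain available
per-experiment for correlation-recovery studies.

The default module plan encodes the tissue contrast the overlays are
designed to expose: two broad shoot modules (up and down in every
drying state — the shoot's response is broad and state-insensitive),
one root module down only at 40% RWC (the root's state-specific
response), and one root module up from 60% RWC on.

**Metabolites.** A named panel (sugars/polyols/proline; amino acids;
TCA-cycle organic acids) with multiplicative lognormal noise
(σ = 0.10, ~10% CV, typical of replicated GC–MS panels). The
early-accumulating set is elevated 4-fold in shoots from 60% RWC
onward; the late amino-acid set 4-fold in roots at <10% RWC and 2-fold
in rehydrated roots.

**Hormones.** Triplicate Gaussian measurements (SD 2 pmol/mg) around
fixed state-mean profiles: ABA 100 → 25 pmol/mg falling through
drying (highest hydrated), SA 10 → 60 rising from 60% RWC, JA-Ile
20 → 4 falling from 60% RWC; recovery values partially rebound.

**Physiology.** Weight triples are constructed by sampling a target
RWC inside the declared band (5% margin from the edges) and solving
for fresh weight, so the computed RWC of every record falls inside its
band exactly. A600 means are high (~1.0) for rapidly dried
unacclimated bands (≥ 80% RWC) and low (~0.3) once tolerance is
induced (≤ 60%), between boiled (1.2) and hydrated (0.1) controls.
Survival counts are deterministic: 0/5 for the hydrated control and
the 100–80 band, 5/5 for 70–60 and drier.

**What the generator does not emulate**: count-level overdispersion
(negative binomial), library-size artefacts, batch effects, missing
values, correlated noise between tissues, or metabolite/hormone
identification error. Passing recovery tests therefore demonstrates
that the *analysis rules* behave as specified under their stated
assumptions, not that those assumptions hold on any real dataset.

## Problem sizes and determinism

The bundled demo (`examples/demo_config.yaml`) simulates 1,200 genes
and builds networks on the top 400 by CV — large enough that every
stage is exercised with non-trivial multiplicity, small enough that
the full pipeline completes in seconds; the thresholds themselves
default to the full-scale values (top 10,000, |r| > 0.964).
The pipeline manifest records the config hash, seed and per-stage
counts and contains no timestamps, so identical config + seed gives a
byte-identical manifest; timings go to a separate log.

## Known limitations

- The Welch-on-logs test at n = 3 has heavy-tailed p-value behaviour
  (df ≈ 2–4); variance-moderated tests (limma/DESeq2-style) would be
  more powerful on real data and can be swapped in at the single test
  site.
- The 0.964 correlation cutoff is taken as given, not derived from a
  null model; at other sample sizes it implies a very different null
  edge rate.
- CV ranking on log-scale data with near-zero means is unstable; such
  genes are excluded rather than rescued.
- Compact letter displays are not unique; the insert-and-absorb order
  (descending means) fixes one deterministic choice.
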