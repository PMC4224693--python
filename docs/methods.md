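# Methods

## The model

`surf` scores a set of candidate SNPs jointly. For each of eight
annotation categories the variants are ranked among themselves (average
ranks for ties, so each column of the rank matrix is a tie-averaged
permutation of 1..n), and the final score of variant *i* is the rank of
`Σ_j r_ij · w_j` under a non-negative weight vector `w`. Two properties
follow directly and are enforced by tests: the ordering is invariant to
positive rescaling of `w`, and a category with weight 0 has no influence
(which is why a model with MAF weight 0 can be applied to variants with
no frequency data). Because ranks are relative, a variant's score is only
meaningful within the set it was ranked in; all evaluation therefore pools
positives and backgrounds *before* ranking.

Internally a larger rank value means "more functional", so the best
candidate maximises the weighted sum; the reported `final_rank` is the
presentation-order rank (1 = top). Remaining ties in `final_rank` are
fractional; sorting breaks them by input order, which is arbitrary and
documented as such.

### Category directionality and conventions

* **MAF** — rarer is more functional. An optional window `[lo, hi]`
  (tunable, e.g. for common-variant analyses) puts in-window variants
  strictly above all out-of-window ones, rarest-first within each tier.
  A missing MAF ranks worst: absence of frequency evidence is not
  rewarded.
* **Conservation** — negative RS scores are clamped to zero before
  ranking, so positive selection and alignment artefacts cannot distort
  the top of the ranking; clamped sites tie at the bottom.
* **Chromatin states** — each of nine cell-line segmentations contributes
  at most one state per position; the state earliest in the configured
  most-to-least-informative order represents the variant. The default
  order places promoter and strong-enhancer states first; the recommended
  practice is to fit the order to labelled data by logistic regression
  (`fit_state_order`). No coverage ranks below every named state.
* **Position** — one category per variant, chosen by precedence:
  splice site > exon > promoter (≤1 kb of a TSS, strand-ignoring) >
  CpG island > CpG shore > 10 kb upstream > 10 kb downstream > intron >
  intergenic. The order reflects the well-replicated enrichment of
  disease variants in coding and promoter sequence over intronic and
  intergenic sequence; it is a configuration list and can be overridden.
  Up/downstream flanks are oriented by gene-body strand.
* **DNase HS / TFBS** — maximum peak signal over any overlapping
  interval (any cell line / factor); 0 when none overlaps.
* **DNase footprints** — number of distinct cell lines with a footprint
  at the position.
* **Enhancers** — boolean overlap with transcribed-enhancer intervals.

Coordinates are BED-style 0-based half-open throughout; a SNP occupies
`[pos, pos+1)`. Indels are rejected at parse time. Chromosome labels
accept both `1` and `chr1` and are normalised internally; the engine is
otherwise assembly-agnostic.

## Training

Weights are small non-negative integers (default bounds 0–15 per
category, the span of the shipped models). `guided_grid_search`:

1. fits a multivariable logistic regression of the label on the eight
   rank columns (scaled to [0, 1]) of the full training/validation set;
   categories with non-positive coefficients have their upper bound cut
   to `guide_cap` (default 1). This shrinkage is what makes the integer
   lattice searchable; how exactly to translate regression output into
   bounds was a genuinely open design point, and the cap rule was chosen
   as the simplest scheme that cannot eliminate a weak-but-real category
   entirely.
2. enumerates the shrunken lattice exhaustively when it fits the budget
   (default 20,000 vectors), otherwise draws a uniform seeded sample.
3. scores every vector by stratified k-fold CV (default k = 10;
   stratification stabilises fold AUCs at small n). Within each fold,
   training-portion and validation-portion variants are each ranked
   among themselves; fold AUCs come from the weighted rank sums. AUC
   computation is vectorised across candidate vectors (rank matrix ×
   weight matrix, then column-wise Mann–Whitney), which keeps a
   20,000-vector × 10-fold search around half a minute at n = 1,000.
4. selects the maximum mean validation AUC subject to performance error
   `|mean training AUC − mean validation AUC| < 0.005`; if nothing
   qualifies, the best-AUC vector is returned flagged. Near-ties (within
   1e-9) resolve to the smallest L1 norm, then lexicographic order —
   determinism plus parsimony.

Perfect separation in any logistic fit is flagged and the fit falls back
to a lightly ridge-penalised estimate: coefficient *orderings* remain
usable, magnitudes are not interpreted. Reported errors: performance
error as above; generalisation error `|test AUC − mean validation AUC|`,
computed from unrounded AUCs. Train/validation and hold-out sets must
have disjoint variant ids; this is asserted, not assumed.

## Evaluation

AUC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counted half; ROC curves come from a threshold
sweep over unique scores. Benchmarks score with the continuous weighted
sum, not the integer final rank, so ties resolve exactly as in
prioritisation. Spike-in evaluation pools the positives with each
region's background variants, re-ranks jointly, and averages per-region
AUCs with equal weight per region (weighting by background count is the
obvious alternative; equal weighting was chosen so that small regions
are not drowned out). The negative control relabels `n_repeats` random
subsets of `subset_size` background variants as positives; since
relabelling changes no annotation, the background is prioritised once
and only labels vary per repeat — the expected AUC is 0.5 by
exchangeability, and the result carries a Monte-Carlo standard error.

## The synthetic generator

`FixtureSpec` → a toy genome: one chromosome per region (default 4
regions × 100 kb), each with 3 genes (stranded bodies, alternating
exons/introns, 2 bp splice sites at the boundaries, a TSS, a CpG island
with 1 kb shores cut to avoid island overlap), plus per-region scored
conservation (Normal(0, 2) RS scores, negatives included), DNase peaks
(Gamma(2, 2) signal), footprint loci shared by a random subset of eight
cell lines, enhancers, TFBS peaks (Gamma(2, 3), ten factors), and nine
chromatin-state segmentations that partition each region (regulatory
states rare, repressed states common).

Background variants are uniform within regions with MAF ~ U(0, 0.5).
Functional variants are rejection-sampled: a candidate's seven positional
annotation propensities are standardised against a uniform probe sample,
combined with the generating weight vector, normalised by its L2 norm,
and accepted with probability `expit(scale · (u − threshold))` (defaults
scale 4, threshold 1), which concentrates accepted variants in roughly
the upper sixth of the combined-annotation distribution — chosen once to
emulate the strong separation reported for curated functional variants
against genomic background (AUCs around 0.8–0.95 for a matched model, as
in the README example). Functional MAFs follow `0.5 · Beta(1, 1 + w_MAF/2)`.
With an all-zero generating vector the acceptance probability is constant,
so the generator is *analytically* null: functional and background
variants are exchangeable and any model's expected AUC is 0.5. Everything
is driven by one seed; identical specs produce byte-identical output.

What the generator does **not** emulate: linkage disequilibrium,
realistic genome composition or annotation co-occurrence structure
(beyond footprint/cell-line sharing), signal-strength distributions of
real assays, or coding-impact effects. Tests passing on these fixtures
demonstrate the correctness and calibration of the machinery — ranking,
aggregation, search, AUC arithmetic — not field performance on real
variant sets.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which the Monte-Carlo noise terms are clearly inside
the asserted tolerances: the negative control uses 3,200 background
variants × 100 subsets of 95 (SE of the mean AUC ≈ 0.003); parameter
recovery uses 1,000 train/validation + 400 hold-out variants with a
20,000-vector budget; the shuffled-label null uses 2,000 variants and a
400-vector budget, since the maximum of many correlated null AUCs is
biased upward and larger validation folds shrink that bias. Degenerate
inputs fail loudly: empty variant lists, single-class labels, all-zero
weight vectors, inverted MAF windows and multi-base records are errors,
not warnings.

## Limitations

Ordinal output only — no probabilities or p-values are attached to
ranks. SNPs only; indels and coding-impact scoring are out of scope.
Proximity-driven position weighting will discriminate against true
long-range enhancer variants. The shipped ALL/DM/DFP weights are
constants taken from their original derivation; this package reproduces
the machinery to train such models, not the licensed datasets behind
those particular values.
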