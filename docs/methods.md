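# Methods

This note records what `cfopt` computes, the assumptions behind it, and
the choices made where the underlying protocol leaves the design open.

## The composition grid

A buffer composition is a vector of level indices, one per variable
compound, over an ordered ladder of concentration fractions (default
10 / 30 / 50 / 100 % of each compound's maximum). The model-facing
representation is always the fraction vector in (0, 1]: compounds differ
in absolute concentration by three orders of magnitude (mM salts vs.
µM cofactors), and feeding raw concentrations to a neural network makes
optimization scale-dominated, so raw inputs are rejected outright.

The default 11-compound table (Mg-/K-glutamate, amino acids, NTPs,
spermidine, 3-PGA, tRNA, CoA, NAD, cAMP, folinic acid) ships with
**placeholder maximal concentrations** — protocol buffers differ between
labs and the table is meant to be edited (`cfopt init-space`). Maxima
are set to twice a typical protocol value so the reference buffer sits
at the 50 % level with room to move in both directions; Mg-/K-glutamate
maxima are treated as fixed configuration from a prior single-compound
calibration, not re-optimized here. HEPES (50 mM), PEG-8000 (2 %),
lysate fraction and plasmid (10 nM) are fixed components of every
reaction, carried through to dispenser instructions but invisible to the
model.

The reference composition defaults to the mid-grid (50 %) level of every
compound. This is a design choice: yields both above and below 1 must be
reachable, and the observed compound effects (raising some compounds and
lowering others both help) imply the reference is interior, not a grid
corner.

## Liquid handling

Acoustic dispensers transfer integer multiples of a 2.5 nL droplet with
a 12.5 nL (5-droplet) minimum. Requested volumes are quantized to the
*nearest* droplet multiple; a nonzero volume that quantizes below the
minimum raises an error naming the reagent and the highest stock
concentration that would make it dispensable — diluting the stock, not
silently clamping the volume, is the correct fix. Water absorbs the
residual to the 10.5 µL reaction volume and is reported unquantized,
because volumes above 1 µL (water, amino acids) are pipetted by hand and
routed to a separate manual sheet. Rows A and P of the 384-well plate
are reserved for the 13 triplicate controls (reference with and without
DNA among them); row P's control set is configurable per iteration.

## Ingestion and normalization

Each well is read five times as a reader QC; the five reads are
aggregated by their mean (no aggregation rule is prescribed upstream; a
configurable spread warning flags drifting wells). Triplicates with a
coefficient of variation strictly above 30 % lose the value farthest
from the median — for three points this equals "farthest from the other
two" — with ties dropping the larger value, inflated signal being the
likelier artefact. The CV uses the sample standard deviation (ddof = 1);
the estimator is pinned so the threshold is reproducible. Removed values
are persisted as −1.

Yields are computed per replicate and then averaged; computing them from
averaged fluorescence differs only through outlier handling, and the
per-replicate order keeps yield uncertainty directly interpretable.
Yield normalization is affine-invariant: a detector gain change cancels
exactly.

Plate QC compares control yields with every previous plate: squared
Pearson correlation must exceed 0.75 *and* the new plate must not be
strictly above or below a previous plate on every shared control (a pure
gain shift has perfect correlation and is exactly what the dominance
check catches).

## The ensemble surrogate

Twenty-five multilayer perceptrons, hidden layers (10, 100, 100, 20),
adam, adaptive learning rate, up to 20,000 iterations, early stopping;
each member is the best of 10 independently initialized fits, selected
by training R². Best-of-restarts selection on the training score is the
simpler of two readings ("highest regression score" could also mean the
early-stopping validation score); it is pinned and documented.
Unstated settings are fixed at one default set (L2 `alpha = 1e-4`,
validation fraction 0.1, auto batch size).

Two deliberate numerical choices:

- **Early stopping is skipped below 50 training rows.** A 10 %
  validation split of a 20-point training set is 2 points; stopping on
  it halts training essentially at initialization. Small sets are
  fitted to convergence instead. At campaign scale (≥ 102 rows) the
  rule changes nothing.
- **Uncertainty is the member standard deviation (ddof = 1), not the
  standard error of the mean.** With 25 members the SEM is 5× smaller
  and would all but silence the exploration term of the acquisition
  rule; a config switch provides the SEM variant.

Member seeds derive from a single base seed via `SeedSequence`, so
ensembles reproduce exactly while members differ. Cross-validation is
plain shuffled 5-fold (no yield stratification; folds are seeded), each
fold scored as the R² of the ensemble-mean prediction on the held-out
part. Test metrics follow the convention: R² over all points, Q²
(predictive R², 1 − PRESS/SS) and the observed-vs-predicted linear fit
over test points only.

## Acquisition

Candidates are drawn uniformly with rejection of seen or already-drawn
points (up to N = 100,000 per round); spaces small enough to enumerate
(≤ 2²⁰ points) are handled exactly, which also enables oracle tests.
Scores: `ucb = exploitation · μ̂ + exploration · σ̂` with weights 1 and
√2; pure-exploitation and pure-exploration rankings are emitted
alongside. Ties are broken lexicographically on the level tuple —
discrete grids with near-symmetric landscapes tie often, and the rule
makes rankings deterministic. How a 500-proposal list reduces to a
102-composition plate is an interpretation: the top 102 by UCB are
plated. Campaigns stop at 10 iterations or after two consecutive
iterations in which neither the best observed yield nor the CV score
improved by more than 1 % (the stagnation tolerance is a choice; no
numeric rule is prescribed upstream).

## Mutual information

Compound impact is ranked by mutual information between the discrete
concentration level (4 classes) and the continuous yield, estimated with
the nearest-neighbour discrete–continuous estimator
(`mutual_info_regression`, `discrete_features=True`, k = 3). Scores are
in **nats**; a deterministic invertible dependence on a uniform 4-level
compound scores ln 4 ≈ 1.386, which anchors the scale. Negative
estimates clip to zero; constant columns warn and score zero; a level
class smaller than k + 1 raises. Scores are descriptive rankings — no
multiple-testing correction is applied or needed.

## Informative-subset search ("one-step method")

Given the same composition panel measured on one or more lysates, the
search draws random subsets of size 20, trains the (reduced) ensemble on
the subset per lysate, scores R² on the complement, and keeps the best
mean score. Every subset is evaluated with the same model seeds so
candidates compete on equal footing — which also makes the exhaustive
mode (used automatically when the instance has at most 5000 subsets) an
exact argmax, testable against brute-force enumeration.

Because the cheap inner model ranks subsets noisily, selection is
two-stage in the benchmark preset: the random search keeps a top-10
shortlist which a stronger ensemble re-scores before the winner is
fixed. The 25-point extension keeps the 20 base compositions fixed and
searches only the 5 extras, on the low-quality (capped / weak) lysates'
data, so earlier measurements stay valid.

The 102-composition representative panel is reconstructed by yield
stratification: 102 evenly spaced targets across the observed yield
range, each matched to the nearest unused history point. The history it
stratifies is **exploitation-enriched** (the `sample_history` emulator:
~70 % of draws biased toward activator-high/inhibitor-low levels, ~30 %
uniform), because a real panel is distilled from an active-learning
campaign's history, which concentrates near the high-yield ridge. This
matters: from a uniform-random history, 20 points cannot anchor the
upper yield range and held-out accuracy collapses.

## The synthetic lysate model

Ground truth is a product of per-compound Hill responses on the fraction
scale — activating `(x/(x+h))^s`, inhibiting `(h/(x+h))^s`, neutral 1 —
normalized so the reference composition yields exactly 1, and optionally
clipped by a hard ceiling:

    yield(x) = min(cap, Π_j f_j(x_j) / Π_j f_j(ref_j))

Choices and what they model:

- **Multiplicative effects**: buffer components feed sequential steps of
  coupled transcription–translation, and fold-change yields spanning
  ~0–35× arise naturally from products of modest per-compound effects.
  This is a modelling choice of the simulator, not an empirical claim.
- **Effect-size balance**: the default landscape has 4 activators and 2
  inhibitors (6 influential compounds of 11) with *comparable*
  full-range effects (~6× each across the grid), so all six are
  recoverable by mutual information — matching the qualitative picture
  that all six influential compounds score in the same MI band. The
  original-lysate global maximum calibrates to ≈ 34.6× the reference.
- **Impairment dichotomy**: translation impairment is a hard yield cap
  (`min`), transcription impairment a reduced absolute signal
  (`quality`) with the relative landscape intact — reproducing the
  "low vs. high room for improvement" phenomenology. Sister profiles
  (`ps`, `ab`) share the influential set with shifted strengths,
  modeling lysate-dependent sensitivity.
- **Noise**: multiplicative lognormal per replicate (fluorescence stays
  positive) with configured CV (default 10 %), plus a gross-outlier
  mechanism (a replicate doubled with ~1 % probability) that exists
  specifically to exercise the 30 %-CV filter.

What the simulator does **not** model: plate-position (border) effects,
resource-competition kinetics, compound interactions beyond the
product structure, or day-to-day reagent drift. Passing the synthetic
suites therefore demonstrates that the machinery is correct and that the
statistical workflow recovers a landscape *of this family*; it does not
certify performance on any particular real lysate.

## Benchmark problem sizes

The standardized benchmarks (`cfopt.benchmarks`) run at desk scale on
one CPU:

- Campaigns use an 8-compound truncation (65,536 points) whose global
  optimum is found by exhaustive enumeration, a 10 × 102 measurement
  budget, 10,000 candidate draws per round, and a 3-member ensemble
  (architecture unchanged). The two compounds that are neutral in the
  full benchmark get weak effects here so the optimum is a unique grid
  point; with exactly neutral compounds the optimum is a 16-point
  degenerate set that uniform random querying ties on, which would make
  "beats random" comparisons meaningless.
- The one-step preset searches 150 random 20-subsets (2×2 inner
  ensembles), re-scores the top-10 shortlist with a 4×2 ensemble, and
  evaluates repeats with an 8×3 ensemble.
- Full-fidelity settings (25 members × 10 restarts, 100,000 draws,
  1000 search iterations) remain available through the config objects;
  they change runtimes, not interfaces.

## Known limitations

- The best-of-restarts selection uses training R², which favours
  interpolating members on small datasets; the ensemble mean tempers
  but does not remove this.
- Random-search subset selection offers no optimality guarantee at
  C(102, 20) scale; the exhaustive oracle only certifies the machinery
  on tiny instances.
- The kNN MI estimator is biased at small class counts; rankings are
  trustworthy, absolute nat values less so.
- With a well-selected 20-point base subset, the 5-point extension's
  marginal value on the pure-cap impaired lysate is small — on the
  order of the paired evaluation noise of small-sample MLP fits. The
  extension pays off chiefly when the base subset transfers poorly to
  the impaired lysate; the reproduction script reports the measured
  paired difference.
- `sample_unseen` on large spaces uses rejection sampling and assumes
  the seen set is sparse relative to the grid; near-exhausted large
  spaces would degrade (the enumerable path handles small spaces
  exactly).
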