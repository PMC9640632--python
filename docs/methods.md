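# Methods

## The model

`metcheck` models a deliberately lumped network of glucose and glutamine
metabolism: glycolysis (glucose → G6P → pyruvate), the branch points into
the pentose phosphate pathway, lactate, and acetyl-CoA, lipid synthesis, a
TCA cycle driven by glutaminolysis (citrate → aKG → malate → oxaloacetate,
with oxaloacetate + acetyl-CoA condensing back to citrate), a malic-enzyme
edge malate → pyruvate, and the neomorphic aKG → 2HG conversion that exists
only when mutant IDH is present. Thirteen reactions over fourteen species;
the network ships as an editable text file
(`src/metcheck/data/default_network.txt`), not hard-coded, so users can add
or remove edges.

Assumptions, in decreasing order of consequence:

* **Discreteness and stochasticity.** Amounts are small integers
  (fmol/cell scale), reactions fire stochastically with exponential waiting
  times, and the semantics is a continuous-time Markov chain. This is the
  natural regime for single-cell amounts of order 1–10; it also makes
  qualitative events such as "lactate reaches its cap" first-class objects.
* **Mass action, no enzymes.** The rate of a reaction is its rate constant
  times the product of substrate amounts. Enzymes, ATP/ADP, and
  Michaelis–Menten saturation are abstracted away; the rate constants are
  understood as lumped enzyme activities.
* **Saturation caps.** Every species has a maximum amount; a reaction that
  would push a product above its cap is disabled. Caps substitute for the
  unmodeled consumption of sink metabolites and bound the state space.
* **No compartments.** Cytosol and mitochondria are merged, so aKG is
  available to mutant IDH regardless of where it was produced, and
  transporters are not modeled.
* **Mutant IDH as an indicator.** `IDHmut` is a constant 0/1 species that is
  never consumed; it only guards the 2HG-producing command. Phenotypes with
  a positive neomorphic rate constant are run with the indicator set to 1.

### Network reconstruction choices

The lumping is a design choice where several topologies were defensible:

* Lower glycolysis is one reaction (G6P → Pyr), oxidative TCA is one
  reaction (aKG → Mal), and glutaminolysis is one reaction (Gln → aKG); each
  stands for a chain of measured steps and takes the chain's minimum
  (rate-limiting) flux as its constant.
* The malic-enzyme edge Mal → Pyr is included because the hypoxic
  IDH-mutant phenotype routes glutamine-derived carbon through the TCA
  cycle to pyruvate and lactate; without this edge no such route exists.
* A reductive carboxylation edge (aKG → citrate) is *not* included: the
  phenotypes modeled here do not require it, and its flux is not separately
  identifiable from the lumped tables we instantiate from. Users can add it
  as one line in the network file.
* PPP and lipid synthesis are absorbing sinks rather than multi-step
  subnetworks; only their entry fluxes matter for the queries asked here.
* Bimolecular mass action uses the plain product of substrate amounts
  (`amount^stoichiometry`), not the falling-factorial (combinatorial)
  convention; at amounts ≤ 5 the difference is a bounded rescaling of one
  rate constant, and the product form matches rate-proportional-to-
  concentration semantics.

### Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| species caps (`max_amount`) | 5 | fmol/cell | nutrients are initialized at 5; uniform caps keep the exhaustive state space desk-sized (~6·10⁴–6·10⁵ states) and are overridable per species |
| initial nutrients | caps (5) | fmol/cell | "maximum quantity" start; sweeps vary 1..cap |
| rate constants | from rate tables | dimensionless | normalized so the wild-type normoxia first-glycolysis constant is 1; all times are therefore in *normalized units* (1/k_R1 of the reference), with no absolute scale claimed |
| uniformization tolerance | 1e-10 | probability mass | Poisson tail truncated when the remaining mass is below this; configurable per call |
| saturation-surface horizon | 15 | normalized time | an explicit, required choice (no canonical value exists); 15 keeps all four phenotypes away from both the 0 and 1 plateaus |
| SSA event cap | 10⁶ | events | guards against runaway loops in user-edited networks |

## Algorithms

* **State space** is enumerated breadth-first from the initial state(s)
  with vectorized guard evaluation; several initial states (a nutrient grid)
  can share one enumeration, and a configurable bound aborts enumeration
  with advice to reduce caps. Commands whose rate constant is zero generate
  no transitions. Transitions of distinct commands between the same pair of
  states sum their rates in the rate matrix but keep per-command provenance
  for transition rewards. Self-transitions (identity updates) are dropped
  from the rate matrix — they do not change the law of a CTMC — but still
  accrue transition rewards through the provenance lists.
* **Transient analysis** uses uniformization: with uniformization rate `q`
  = max exit rate and `P = I + Q/q`, the distribution at `t` is the
  Poisson(qt)-weighted mixture of powers of `P`. Scalar expectations
  (species amounts, reward rates, reachability indicators) are propagated
  backward (`r ← P r`), so one pass serves every initial state and every
  time point on a grid; full distributions are propagated forward.
  Truncation uses the Poisson inverse survival function at the configured
  tolerance (plus a safety margin for cumulative weights).
* **Cumulative rewards** on `[0, t]` integrate the transient expectation of
  the reward accrual rate: state rewards accrue at their value per unit
  time, transition rewards at `ρ(c) ×` the command's current rate. The
  integral uses the standard survival-function weights `sf(k; qt)/q`.
* **Time-bounded reachability** zeroes the outgoing rates of goal states
  (making them absorbing) and reads the goal mass of the modified chain at
  `t`. A step-bounded variant on the embedded jump chain is provided for
  completeness; the time-bounded form is the primary semantics.

Degenerate inputs are defined rather than special-cased: `t = 0` returns
the point mass / initial amount / zero reward; a chain with no transitions
(all-zero start, or all rate constants zero) is a single absorbing state;
an initial state already in the goal set has reachability 1 at every `t`.

* **Gillespie simulation (SSA)** draws the waiting time from
  Exponential(total rate) and the firing command proportionally to its
  rate, up to `t_max` or absorption. One child seed per trajectory is
  spawned from the master seed (`numpy.random.SeedSequence.spawn`), so
  batches are independent but bit-reproducible. The simulator is kept
  deliberately independent of the uniformization engine — it shares only
  the compiled guard/rate arrays — so the two can serve as mutual oracles.

## Rate instantiation

Measured fluxes arrive as a tidy table (reaction, phenotype, condition,
flux in fmol/cell/hour). `normalize` divides everything by the reference
flux (first glycolysis reaction, wild-type, normoxia); `lump_chain` maps
measured reactions onto model rate keys via an editable YAML chain map and
takes the minimum over each chain. The chain membership shipped by default
(hexokinase; G6PD; PGI/PFK/lower-glycolysis; LDH; PDH; FASN; CS;
aconitase+IDH; aKG-dehydrogenase/SDH/FH; MDH; malic enzyme; GLS/GDH;
neomorphic IDH) is itself a reconstruction and is documented as such.

Patient-derived tables reuse the wild-type normoxia table as the Warburg
phenotype and divide each rate by the enzyme's Warburg/target expression
fold change. Fold changes are estimated per gene as the ratio of cohort
mean CPMs (counts per million, pseudocount 0.5 added to every count before
scaling) and averaged over isoenzymes *on the ratio scale* (arithmetic
mean; a geometric-mean flag exists because the choice of scale is a genuine
ambiguity). This estimator is intentionally simple and documented — it is
not a differential-expression model, performs no significance filtering,
and inherits the compositional limitations of total-count normalization.
The neomorphic 2HG rate is exempt from rescaling (no wild-type expression
proxy exists) and is copied from the measured mutant normoxia table, on the
same normalized scale as everything else.

## Synthetic data: what it does and does not emulate

The measured flux table and the patient count matrices are not
redistributable, so the package generates stand-ins.

`simulate_mfa_table` emits a four-phenotype flux table with the reference
flux fixed at 302 fmol/cell/hour and a seeded ±3% jitter on everything
else. It *enforces* the qualitative orderings that define the study
conditions: glycolytic fluxes rise under hypoxia (lactate flux most),
entry into the TCA cycle falls under hypoxia, the mutant under hypoxia
elevates glutaminolysis and oxidative TCA flux, carries the only positive
malic-enzyme flux, and is the only phenotype with a positive neomorphic
flux. The ordering margins (≥ 1.5×) dominate the jitter, so the orderings
hold for every seed. The *absolute* values are invented; consequently the
package's phenotype comparisons are structural claims (orderings,
sensitivities, monotonicities), not reproductions of any measured curve.

`simulate_counts` emits genes × samples negative-binomial counts with
cohort structure (defaults mirror 140 Warburg / 419 IDH-mutant / 5 normal
samples), lognormal per-gene baselines, uniform per-sample library factors
(0.7–1.3) and planted enzyme-level fold changes shared by all genes of an
enzyme; dispersion defaults to 0.1 (typical bulk RNA-seq overdispersion).
It does not emulate per-gene dispersion trends, GC/length bias, batch
effects, zero inflation, or correlated modules — so recovery tests certify
the estimator's arithmetic and its behavior under NB noise, not robustness
to those artifacts.

Recovery checks run at 20 samples per cohort with 2000 genes. The gene
count matters: planted fold changes on ~26 enzyme genes must remain a small
fraction of the library, as they are in genome-wide data, or total-count
CPM normalization itself shifts every estimate (a compositional artifact,
not an estimator defect). With NB dispersion 0.1 and n = 20, a per-enzyme
log2 estimate carries a standard error near 0.1, so the ±0.2 log2 recovery
bound is asserted on the mean of three replicate simulated cohorts (3–4
standard errors) while single replicates are held to the same bound only in
the median across enzymes.

## Problem sizes used by the tests and the acceptance script

Exhaustive engine checks run on the full default network at caps 5
(5.8·10⁴ reachable states for wild-type normoxia; 5.9·10⁵ for mutant
hypoxia, whose indicator opens the 2HG dimension and the malic-enzyme
route). Oracle comparisons use dense matrix exponentials on random chains
of up to 50 states and 10,000 Gillespie trajectories on the full network.
Experiment-orchestration tests reuse the same topology at caps 3, which
preserves every structural property while keeping state spaces in the
thousands. The saturation-surface analyses evaluate the full 5 × 5 nutrient
grid in one backward pass per phenotype.

## Known limitations

* Rates are time-homogeneous; no feedback from state to rate constants
  (e.g. hypoxia is a separate table, not a dynamic variable).
* The min-rule lumping makes a chain exactly as fast as its slowest member,
  ignoring intermediate pool effects.
* Expression fold changes proxy enzyme activity; post-translational
  regulation and phosphorylation are invisible to this estimator.
* Caps are a modeling device; results near the cap (saturation
  probabilities) depend on the cap value, which is why the surface horizon
  and caps are explicit, reported parameters.
* The PRISM-dialect export is best-effort syntax compatibility for external
  cross-checking and is not validated by automated tests.
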