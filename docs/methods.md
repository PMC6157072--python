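# Methods

## The optimization problem

A breeding or conservation program must decide, each cycle, (1) which
candidates become parents, (2) how many matings each parent contributes
and (3) which specific pairs are mated — and, when genome editing is on
the table, (4) which of the selected parents to edit. `matekit` treats
these as a single joint optimization over *mating plans*.

A plan for `M` matings is valid when it satisfies the user's mating
constraints: the number of matings, a per-role cap on the number of
parents, minimum / equal / maximum contributions per parent, and whether
selfing is allowed. Constraints are generic (one candidate pool filling
`2M` parent slots, monoecious species or unknown sex) or gendered (each
pair is male × female, `M` slots per role).

Three objectives are computed from the contribution proportions `x`
(`x >= 0`, `sum(x) = 1`; 0.5 per role when gendered) and the coancestry
matrix `C`:

* **genetic gain** `x'a`, with `a` the selection criterion standardized
  to mean 0, SD 1 over the candidates (raw-scale gain is also reported in
  the outputs);
* **group coancestry** `x'Cx`, the expected mean coancestry of the
  future cohort — its growth is the loss of genetic diversity;
* **mean expected progeny inbreeding**, the mean parental coancestry
  over the actual matings. Unlike `x'Cx` this depends on *who mates
  whom*, which is why contributions and allocation are optimized jointly.

`C` can be supplied directly, built from a 3-column pedigree by the
tabular method (reported as kinship, `theta = A/2`, founders non-inbred
and unrelated), or built from biallelic markers as identity-by-state
allele sharing: per locus `s(a,b) = (2 - |a-b|)/2` except `s(1,1) = 0.5`
(two heterozygotes share one random allele each in expectation), averaged
over loci. The IBS diagonal is *not* rescaled to the pedigree
`0.5(1+F)` convention — a fully heterozygous individual has
self-coancestry 0.5 — so gain/diversity trade-offs are scale-dependent
across sources and targets should be set per source.

## Plan encoding and decoding

The evolutionary search works on real-valued chromosomes with three
blocks:

1. **Contribution genes**, one per candidate per role. Candidates are
   ranked by gene value (ties by input order); the number of parents kept
   adapts to how many genes are positive, floored by what the
   contribution cap requires (`ceil(slots/max_contrib)`, and 2 in generic
   no-selfing mode), capped by `max_parents` and — when a contribution
   floor is set — by `slots // min_contrib`, since every kept parent is
   held at or above the floor and deselection is not a breach. Positive
   gene parts, normalized over the kept set (uniform if none is
   positive), are scaled to the slot count, trimmed to the contribution
   limits and rounded by largest remainder so per-role sums are exact.
   Decoding is scale-invariant: only ranks and signs matter.
2. **Mate-permutation keys.** Parent slots are laid out in candidate
   order and paired through the stable argsort of the keys: gendered mode
   keeps `M` keys permuting female slots against the fixed male slots;
   generic mode carries `2M` keys permuting the whole slot list before
   reading it off two slots per mating, so every perfect matching of the
   slot multiset is reachable (a permutation of only alternate slots
   cannot pair two even-positioned slots, which would hide some optima
   from the search).
3. **Edit-rank genes**, one per editable candidate, present when an
   editing budget is set.

The decoder is *total*: every real vector yields a plan with exact slot
sums. Repairs are deterministic — contributions are trimmed and rounded,
and a single left-to-right pass swaps away selfing pairs. Whatever cannot
be repaired (an irreparable selfing, limits that are jointly infeasible)
is counted in the plan's violation count and penalized, never raised, so
the optimizer's hot path cannot fail and invalid regions still carry a
gradient toward validity.

## Penalized scalarization and targets

Each mode maximizes a scalar: gain, `-x'Cx`, or `-` mean progeny
inbreeding, minus `w * violations / M` (default `w = 1e4`). Target mode
maximizes gain subject to a coancestry bound `C*` enforced as an exact
penalty `w * max(0, x'Cx - C*) / span`, normalized by the frontier span
so `w` is portable across problems.

`C*` can be given in four forms, all resolved against the objective-space
bounds found by two single-objective solves (max gain; min coancestry):

* absolute coancestry value;
* rate: `C* = C_cur + dC (1 - C_cur)` with `C_cur` the group coancestry
  under uniform contributions (overridable);
* percent of the span: `C* = C_min + (p/100)(C_at_Gmax - C_min)`;
* trigonometric degrees: `C* = C_min + cos(theta)(C_at_Gmax - C_min)`.

The degree convention is a documented design choice: `theta` is measured
from the gain axis, so 0° is the unconstrained max-gain solution and 90°
pure diversity; 35° is gain-leaning. The percent form is read on the
same normalized span (`p = 0` gives `C_min`); the alternative reading
`(1 + p/100) C_min` is noted here and not implemented. Resolved targets
are clamped into `[C_min, C_at_Gmax]`.

A frontier sweep solves a uniform degree grid over [0°, 90°]; endpoints
reuse the bound solutions (guaranteeing endpoint consistency and saving
two solves), each interior angle gets an independent seed derived as
`seed + round(1000 * theta)`, and a Pareto filter removes dominated
points. With elementwise-superior edited merits and an editing budget,
the optimum at any angle can only improve, so the edited frontier weakly
dominates the baseline — the property the acceptance suite asserts.

## The evolutionary engine

Classic DE/rand/1/bin, maximizing, with three anti-stagnation devices
suited to the plateau-heavy landscape that rank-based decoding produces:
the differential weight is dithered uniformly in `[0.1, 0.9]` per
generation; the crossover rate alternates between 0.2 and 0.9; and a
stall (best improvement < `tol = 1e-9` over a `window` of generations)
re-initializes the worst quarter of the population inside the
population's bounding box inflated two-fold, always keeping the
incumbent. Two consecutive restarts without improvement terminate. Trials
that *tie* the incumbent replace it so the population drifts across flat
regions instead of freezing. Chromosomes are unbounded; initialization is
uniform in [0, 1] per coordinate (the box only sets initial diversity
because decoding is rank/sign-based). All randomness flows from one
generator seeded once; runs are bit-reproducible and the seed is written
with every run's outputs.

Defaults (population `10 * dim` clipped to [8, 200]; 10 000 iterations;
window 500) are sized for production problems. The test and acceptance
suites configure the solver explicitly (population 30, 300 iterations,
window 60 on instances with at most 6 candidates and 4 matings; the toy
demo uses population 40 with half-effort bound solves, since the bounds
only set the target scale) — search effort sized so the suites run in
minutes while the search still recovers the enumerated global optimum
essentially always at these sizes.

## Synthetic data: what it emulates, what it does not

* **Marker populations**: independent per-locus `Binomial(2, p)`
  genotypes with `p ~ U(0.1, 0.9)`, standard-normal additive effects
  rescaled to genic variance 1, criterion = true merit `G a`. The edited
  criterion applies the improvement of flipping each individual's top
  `n_edit_loci` (default 5) unfavourable loci to the favourable
  homozygote. No linkage, no LD, no genotyping error, no estimation step
  (criteria are true merits, not GEBVs) — so passing tests demonstrate
  the optimizer's behaviour, not prediction accuracy on real data.
* **Pedigree populations**: founders `N(0, 1)`, children = parent mean
  plus Mendelian sampling `N(0, 0.5)`; the inbreeding adjustment of the
  sampling variance is deliberately omitted.
* **Brute-force oracle**: for instances with at most 6 candidates and 4
  matings, every valid contribution vector and every distinct mate
  pairing (and, with editing, every admissible edit subset) is
  enumerated and scored with the *same* penalized scalar the evolver
  sees. This is the independent optimum the search is required to match.
* **Toy recurrent selection**: cohorts of 16 crosses × 10 progeny (160
  candidates, the next cycle's pool of 32 parent slots), 200 unlinked
  loci, true-merit selection, at most 4 crosses per parent, no selfing.
  Schemes: truncation with one cross per parent (top 32), truncation
  with four (top 8), or a degree-targeted balanced solve per cycle.
  Conversion efficiency is the negated slope of a per-replicate
  regression of cohort genetic mean on genic SD
  (`sqrt(sum 2 p (1-p) a^2)`); a trajectory that lost essentially no
  genic SD has infinite efficiency by convention. At this toy scale the
  35° scheme reliably beats truncation-4 on efficiency; absolute
  percentages from full-scale simulation studies are outside what this
  generator can reproduce.

## Numerical choices and degenerate inputs

* Matrix symmetry tolerances: inputs are symmetrized as `(V + V')/2` when
  asymmetry is at most 1e-6, rejected above; internal checks use 1e-8.
* Largest-remainder ties prefer the higher-ranked parent on increments
  and drop the lowest-ranked on decrements; all ranking ties break by
  candidate input order, making decoding fully deterministic.
* Degenerate frontier span (< 1e-12) collapses the sweep to the single
  bound solution; span also guards the target penalty's normalization.
* Constant criterion vectors are rejected at standardization (gain is
  undefined); problems without any criterion support only the diversity
  modes.
* Candidate files with two columns are read as `Id Gender` when every
  second field is a literal 0/1/2, else `Id Criterion`; three columns are
  always `Id Gender Criterion`.
* Unknown parents in pedigrees are `0`/empty; ancestors that appear only
  as parents become implicit founders. Cycles (an individual its own
  ancestor) are rejected. Missing genotype values are rejected rather
  than imputed, keeping the IBS definition exact.

## Known limitations

* One optimization at a time: no simultaneous population-based
  multi-objective search; the frontier is traced sequentially by
  epsilon-constraint solves, as designed.
* No inbreeding-*rate* constraint distinct from the coancestry target;
  mating inbreeding enters as an objective (min_inbreeding mode) or
  implicitly through mate allocation.
* The generic-mode selfing repair is a single deterministic pass, not an
  exhaustive search; rare irreparable cases are penalized instead.
* Editing models *who* is edited, not how: edited merits are computed
  upstream (or by the synthetic generator); failure rates, off-target
  effects and per-locus budgets are out of scope.
* IBS and pedigree coancestry are on different diagonal conventions (see
  above); mixing sources across cycles of one program is not supported.
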