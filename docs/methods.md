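# Methods

## Model normalisation

A GEM is loaded from SBML (fbc) or COBRA JSON via cobrapy and converted to
an explicit stoichiometric container. GPR rules are parsed into boolean
trees accepting both `and/or` and `&/|` spellings (case-insensitive, `and`
binding tighter); an unparseable rule is logged and treated as empty rather
than aborting a genome-scale load. Unbounded or infinite flux bounds are
clipped to ±1000 model units (`vmax`), the usual COBRA convention, which
also serves as the finite big-M of the MILP.

Every reversible reaction (`lower < 0`) is split into two irreversible
forward copies `<id>_fwd` / `<id>_rev` sharing a `parent_id`. Splitting
preserves the feasible flux cone (net fluxes map 1:1 both ways; tested by
LP on toy models) and makes a per-direction binary indicator meaningful.
Positive lower bounds are clipped to 0 during normalisation: minimal-
network analysis asks which reactions *can* be silenced, so forced-flux
constraints are deliberately not carried into the MILP.

Thermodynamic or other directionality knowledge enters only as a
user-supplied table of (reaction, allowed direction); the forbidden split
copy is closed (`upper = 0`). No in-package ΔG estimation is attempted.
Exchange/medium bounds are taken from the model as-is: with no curated
medium the enumerated networks are an upper bound on the condition-specific
possibilities, and a bounds-override table is the supported way to impose
one.

## Tasks and the yield floor

A task is the synthesis of one target metabolite, realised as a demand
reaction `DM_<met>` consuming one unit of the target. The task table must
name the compartment explicitly — there is no default-to-cytosol guessing,
since a wrong compartment silently changes the answer. `V_max` is the LP
maximum of the demand flux; the MILP then requires `v_demand ≥ c·V_max`
with `c = 0.8` by default, i.e. minimal networks may sacrifice at most 20%
of the attainable yield for parsimony. A task with `V_max = 0` is reported
infeasible and skipped, not fatal to the run.

## MILP and enumeration

Decision variables are the fluxes plus one binary per non-demand reaction
with positive capacity; constraints are mass balance, big-M coupling
`v_i ≤ vmax_i·z_i`, the yield floor (as the demand's lower bound), and
`z_fwd + z_rev ≤ 1` per split pair, which excludes futile two-cycles from
inflating witnesses. The objective minimises the number of active *parent*
reactions; the demand reaction is scaffolding and never counted. Problems
are solved with HiGHS through `scipy.optimize.milp` at a relative MIP gap
of 0 — at the scale of the shipped studies exact optimality is cheap, and
the enumeration logic below depends on solutions arriving in
non-decreasing size order.

Alternatives are enumerated by adding, per found network `A`, the integer
cut `Σ_{p∈A} z_p ≤ |A| − 1` (parent level) and re-solving until the
objective exceeds `msize + max_rank` (`max_rank = 0` by default: strict
minimum size) or a cap (default 10,000) flags the result truncated.
Because cuts exclude supersets and solutions appear in size order, every
reported network is subset-minimal and its recomputed witness uses all of
its reactions. Each witness is re-derived by an LP restricted to the
active set — independent of the MILP's own variable values — and checked
against mass balance (1e-6) and the yield floor (1e-6); activity threshold
for fluxes is 1e-6. Networks are reported sorted lexicographically by
active-set ids, making the output a deterministic function of the inputs.

HFRs are the intersection of active sets over a task's alternatives;
phenotypic HFRs intersect further over all tasks sharing a phenotype
label. Both are computed at parent level.

## Regulation metric

A reaction's state is derived from the differential-expression calls on
the genes appearing anywhere in its GPR (set membership; the AND/OR
structure is intentionally ignored — a conservative reading that avoids
over-interpreting rule curation). Among the *called* genes: all up → up,
all down → down, mixed or none → unregulated. Both split directions
inherit the parent's state. The model census `(R, R_up, R_down, R_no)`
runs over parent reactions, excludes demand scaffolding, and is asserted
to partition `R`. Genes called in the table but absent from the model are
flagged and excluded from reaction states and, under the default
`gene_universe="model"`, from the gene test's universe (the universe is
all model genes; `"union"` widens it to include off-model calls).

## Significance

All tails are exact rational sums over `math.comb` (converted to float at
the API boundary; `exact=True` returns the `Fraction`): no normal
approximation, no continuity correction. The gene-mode density is
hypergeometric and the p-value is the upper tail `P(X ≥ k)` — the standard
over-representation convention; the density alone is not a p-value. The
reaction-mode tail treats drawing `T` of the model's `R` reactions without
replacement from the three regulation classes and sums the probability of
all outcomes at least as favourable to upregulation: at least `T_up` ups
*and* at most `T_down` downs (`i + j ≤ T`, terms with `T−i−j > R_no`
vanish). The down test swaps the roles. At the shipped problem sizes
(`R` a few thousand, `T` ≈ 150) the double sum is at most ~`T²/2` terms of
exact integer arithmetic — milliseconds.

No multiple-testing correction is applied when labelling significance
(raw thresholds: 0.05 gene mode, 0.005 reaction modes); BH-adjusted
columns are emitted alongside for the user but never drive AMiNF. A MiN's
up/down label comes from whichever reaction-mode p-value clears its
threshold, the smaller winning when both do and exact ties labelled
"both". AMiNF is the fraction of a task's alternatives with p below the
mode's threshold and requires a complete (untruncated) enumeration; DRP is
`k/K` over the MiN's genes (undefined, reported missing, when `K = 0`),
UPR/DnRP are `T_up/T` and `T_down/T`.

## Synthetic data and what it shows

`synth.make_parallel_gem` builds a source → staged-parallel-branches →
target model: each stage offers interchangeable unit-stoichiometry
branches, so the alternative count is exactly the product of branch counts
and the HFRs are the shared backbone. Decoy routes one reaction longer
than a branch are flux-capable but provably never minimal. A stage can be
cofactor-coupled, forcing a shared regeneration reaction into every
network — the mass-balance coupling that map-based enrichment cannot see.
`plant_regulation` calls every gene of one branch in a chosen direction
and backgrounds the rest independently at a given rate (direction
uniform); everything is bit-reproducible under a seed.

These fixtures have unit stoichiometry, no compartmental transport chains,
clean GPRs and planted, independent regulation — none of which holds in a
curated GEM. Passing tests therefore demonstrate algorithmic correctness
(enumeration completeness, exactness of the tails, detection of planted
signal, type-I control under permutation), not biological recovery on real
transcriptomes.

The planted-recovery study uses 3 branches of length 6, one gene per
reaction, two decoy routes and background rate 0.05: by the tail's own
arithmetic the planted network sits below 5×10⁻⁴ even with several
background-regulated reactions while null networks sit near 0.5, so the
α = 0.005 decision is insensitive to background draws. The oracle studies
use ≤ 14-reaction fixtures, where exhaustive subset search (ascending
cardinality, LP feasibility per subset) and full `C(R, T)` subset counting
are affordable; both oracles are implemented independently of the code
paths they check.

## Numerical choices and limitations

* MIP gap 0, integrality handled by HiGHS; flux-activity threshold 1e-6;
  yield-floor and balance tolerances 1e-6. The gap is configurable in
  principle for very large models, where proving exact optimality of every
  cut iteration may dominate runtime.
* Enumeration cost grows with the number of alternatives (one MILP solve
  per network plus one to prove exhaustion); the cap bounds runtime at the
  price of a flagged, HFR-approximate result.
* Genome-scale task sizes depend on the model's medium and directionality
  conventions; without the original bounds, absolute network sizes can
  shift by small constants (demand/transport conventions) or more (open
  vs closed exchanges).
* Gene-level calls are consumed as given: no DEG calling, normalisation or
  ortholog mapping is performed, and mRNA-level regulation is an imperfect
  proxy for flux regulation — the metric is deliberately conservative
  under mixed evidence.
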