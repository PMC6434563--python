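# Methods

## Scope and model summary

`fishweb` couples three layers: a stochastic structural layer (the
niche model), a static allometric layer (trophic positions → body
masses → metabolic rates → life-history stages), and a dynamic layer
(seasonal bioenergetic ODEs with an annual Leslie step). The ensemble
experiment compares three model types on identical webs, parameter
draws and initial conditions: *original* (one node per species),
*unlinked* (fish split into four independent stage nodes) and *linked*
(stages coupled by the Leslie matrix).

## Structural layer

Webs are drawn from the niche model with S species and target
connectance C: `n_i ~ U(0,1)`; range fraction `x_i ~ Beta(1, β)` with
`β = (1-2C)/(2C)` so that `E[x] = 2C`; `r_i = x_i n_i`;
`c_i ~ U(r_i/2, n_i)`. The diet interval is `[c_i - r_i/2, c_i + r_i/2]`
used exactly as drawn — the upper end may exceed `n_i` and no clamping
is applied. Consumption is pure range membership, so the adjacency is
a deterministic function of the niche triples (a tested invariant).

Validation rules: (a) no isolated node (self-links ignored); (b) every
node reaches an autotroph by following prey links (an autotroph has no
prey at all — a species eating only itself does not count, and
self-loops are ignored in the search); (c) the web is one undirected
component; (d) `|L/S² - C|/C ≤ tol`. Connectance counts directed
links, cannibalistic self-links included, over S² ordered pairs. The
tolerance defaults to 5% relative: tight enough to pin C, loose enough
for the discreteness of L at S = 30 (L must be an integer near
0.15 × 900 = 135). Rejection sampling repeats whole draws; the
acceptance rate at the defaults is roughly one in three, and the
report of a failed generation names the most frequent failing rule.

## Allometric layer

T1 is computed by breadth-first relaxation from the basal set; T2 by
solving the linear system `T2_i = 1 + mean_{j∈prey(i)} T2_j` with
`T2 = 1` fixed on basal nodes, which handles feeding loops and
cannibalism exactly. Cannibalistic self-links count as prey in T2's
average (they are links) but are ignored in T1's search, where a
self-loop can never shorten a path. Webs with a singular T2 system are
rejected and regenerated, never patched.

Guild assignment: basal nodes are autotrophs; the three non-basal nodes
with the highest short-weighted T are fish; the rest are invertebrates.
Ties at the fish cutoff break by higher niche value, then lower node
id — deterministic and seed-independent. Body mass is `M = Z^(T-1)`
(Z = 100 by default) and metabolic rates use the guild-switched
allometry (0, 0.314 M^-0.15, 0.88 M^-0.11 per day per unit mass).

## Life-history layer

Stage weights come from the isometric von Bertalanffy curve
`W_t = W_inf (1 - e^{-K(t-t0)})³`, t = 0..3, with `K = 3/t_max` and
adults at 90% of asymptotic weight. Those two constraints pin the age
offset in closed form, `t0 = t_max + ln(1 - 0.9^(1/3))/K ≈ -0.3667`
for t_max = 3, which puts newborns at ≈ 2.9% of `W_inf`.

Stage wiring is the one place the procedure is genuinely open, and the
choice here is: the adult stage keeps the species' node, niche triple
and hence diet (over the original nodes) unchanged; each younger stage
gets a niche value from the web's own least-squares linear fit of n on
T evaluated at `T_stage = 1 + log_Z(W_stage)` (clamped to (0,1)), a
range width reusing the species' range fraction `x = r/n`, and a range
center drawn `U(r_stage/2, n_stage)` from a sub-seed derived
deterministically from (master seed, species id) — so staging is
bit-reproducible given the web and seed. Adjacency is then rebuilt
from all niche triples uniformly: stages eat and are eaten strictly by
range membership, including other stages; conspecific stage predation
is allowed by default and removable by a switch. A staged web in which
any stage has an empty diet is rejected and the whole web regenerated
(default), because the experiment needs feedable fish; a permissive
mode lets such stages starve dynamically instead.

The annual transition is the 4×4 Leslie matrix with 0.1 on the
diagonal, 0.9 on the subdiagonal and 0.9 in the top-right corner
(reproduction). Columns sum to one, so the step conserves biomass to
machine precision — asserted as a property test.

## Dynamic layer

Seasonal ODEs are integrated with scipy's LSODA at rtol 1e-6 /
atol 1e-9, sampled daily (100 samples per 100-day season); the daily
grid reads as 100 time steps per year while keeping the integration
adaptive. Negative excursions are clamped to zero inside the
right-hand side and in the output. Extinction thresholding
(10⁻⁶ µgC/L) is applied at season boundaries only; in the linked model
the order at a year boundary is threshold first, then the Leslie step,
so aging can revive a zeroed stage and the revival survives to the
next season's start.

Parameter defaults: K = 540 µgC/L shared across autotrophs;
r ~ N(0.9, 0.2²) truncated to [0.6, 1.2] d⁻¹ per autotroph; y = 10 d⁻¹;
e = 0.45 on autotroph prey, 0.85 otherwise; Hill exponent 1.2;
f_a = 0.4; f_m = 0.1. Two constants are genuinely uncertain and are
therefore plain configuration with prominent defaults: the
half-saturation density (uniform B0 = 80 µgC/L, order-of-magnitude
consistent with K) and predator interference (c = 0). Every
quantitative conclusion of the ensemble, especially the stability
statistics, is conditional on this pair; see Limitations.

The assimilation efficiency multiplies the predation-loss term
(`... x_j y B_j F_ji e_ji`), which is the form the governing equations
print; because the conventional ATN formulation instead divides
consumption by efficiency, a config toggle
(`loss_efficiency_form="divide"`) provides that variant. Off-season,
nothing happens except the Leslie step.

Initial conditions: one draw `U(5, 500) µgC/L` per original species;
in staged variants a fish species' draw is split equally across its
four stages, so all three model types start from matched species
totals.

## Ensemble experiment

Per web: generate a valid, annotatable, stageable web (regenerating on
any structural rejection); run all three model types for 300 years
(200 burn-in + 100 analysis). Filters: *preliminary* keeps webs where
any variant kept any fish; *stringent* keeps webs where every variant
kept at least one fish species — stringent ⊆ preliminary by
construction (tested). "Fish biomass stabilized" has no standard
operational definition, so the one used here is explicit and
config-exposed: no solver failure, total fish biomass at the end of
burn-in at or above the extinction threshold, and no node above a
10¹⁰ µgC/L blow-up ceiling during burn-in (checked on the annual
summaries).

Stability statistics use the CV (sample standard deviation over mean,
reported in %) of annual season-mean biomass series over the 100
analysis years. Per-species mean and CV of biomass are pooled across
stringent-accepted linked-model runs and regressed by OLS on adult
(asymptotic-scale) mass after removing outliers (mass > 10¹⁰ or
CV > 800%); slope, t, df = n - 2 and two-sided p are reported, with n
whatever the harness produced rather than forced to any external
count. The stage-size ordering statistic — youngest stage of the
largest surviving species lighter than the oldest stage of the
smallest — is reported both conditional on ≥ 2 surviving species
(runs with fewer have no comparison) and over all accepted staged
runs, since the natural denominator is ambiguous. Any per-run solver
failure is logged and counted, never silently dropped.

Reproducibility: every random stream is derived from (master seed,
web id, purpose index) through numpy's seeding machinery, so runs are
independent of scheduling and ensembles are bit-reproducible; output
bundles carry SHA-256 hashes per file and every summary number is a
pure function of the archived per-run tables (tested).

## Problem sizes

The default configuration is 500 webs × 3 model types × 300 years.
The package's standing scaled rendition, used in the acceptance test
and recommended for exploratory work, is 50 webs × 3 × 300 years
(~10 minutes on one core); structural-only checks use 500 webs, which
take seconds because no ODEs are involved. The benchmark script's
single-autotroph equilibrium uses 50 seasons, far past convergence of
the seasonal logistic.

## What the generator emulates — and does not

Synthetic webs reproduce the degree structure, looping and trophic
organisation the niche model is known for, and the allometry ties all
rates to a single mass axis. They do not include empirical diet data,
within-guild physiological variation, environmental stochasticity,
off-season mortality, fishing, or demographic noise — the ODEs are
deterministic, so all ensemble variation comes from structure,
parameter draws and initial conditions. Passing tests therefore show
internal consistency of the method under these idealised conditions,
not agreement with any particular lake or ocean.

## Known limitations

- B0 and c (see above) dominate the quantitative behaviour of the
  dynamics. With the defaults (uniform B0 = 80, c = 0, Hill 1.2) fish
  persistence in the staged variants is high — the per-model-type
  persistence filter removes far fewer webs than a harsher,
  guild-structured B0/c parameterisation would — so headline fractions
  that depend on extinction frequency are sensitive to this pair.
  Both can be supplied through configuration.
- Every fish species has exactly four stages, one shared Leslie matrix
  and no maturity or fecundity schedule.
- The stage-diet construction (fitted n-on-T map plus reused range
  fraction) is one defensible rule among several; it is isolated
  behind configuration so alternatives can be swapped in.
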