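# Methods

## The design problem

A genetic control circuit for a metabolic pathway is specified by a discrete
architecture `p_d` (which pathway intermediate regulates which promoter, and
with what sign) together with continuous dose-response parameters `p_c` (the
maximal expression rate `k`, regulatory threshold `θ` and Hill coefficient `n`
of each controlled promoter). Given a performance objective `J`, the design
task is the mixed-integer program

    min_{p_c, p_d}  J(x, p_c, p_d)    s.t.   dx/dt = h(x; p_c, p_d),

where the state `x = (s, e)` splits into metabolite concentrations `s` (mM)
and protein concentrations `e` (µM) evolving as

    ds/dt = f(s, e) + influx/export,      de/dt = u(s, p_c, p_d) − λ e.

`f` collects irreversible Michaelis–Menten reaction rates, `u` is the vector
of metabolite-responsive expression rates (lumped Hill dose-response curves:
activation `k·sⁿ/(θⁿ+sⁿ)`, repression `k·θⁿ/(θⁿ+sⁿ)`, `n = 2` by default),
and `λ` (h⁻¹) is dilution by cell growth. Metabolism equilibrates within
seconds while expression takes hours, so the ODEs are stiff; they are solved
with LSODA (an implicit backward-differentiation integrator on stiff
segments; plain BDF is available via `simulate(..., method="bdf")`), at
`rtol = 1e-6`, `atol = 1e-9`. Halving both tolerances changes the toy-model
loss by well under 0.1%. Native metabolite levels are initialized at the
steady state of the model with all heterologous proteins clamped to zero
(relative residual < 1e-8, horizon capped at 1e4 h); heterologous protein and
mRNA states start at zero. Transient negative excursions within solver
tolerance are clipped inside rate laws; failed or non-finite integrations are
mapped to a large finite penalty loss (1e9) so the optimization loop is total.

## Feasible architectures

Architectures are signed ligand × promoter matrices with entries in
{−1, 0, +1} (repression / none / activation); a promoter is controlled by at
most one ligand. An edge is negative feedback when it represses a
ligand-producing (upstream) enzyme or activates a ligand-consuming
(downstream) enzyme; the opposite pairings create positive loops, which are
excluded because they are prone to multistability. Enumeration therefore
assigns each promoter either "uncontrolled" or "negatively controlled by one
ligand", giving `Π_p (1 + L_p)` architectures — 4 for one ligand and two
promoters, 27 (= 3³) for two ligands and three promoters. The fatty acid
model instead switches whole expression functions through a categorical label
(open_loop / NGL / NML / LNML).

The continuous decision vector uses a flat encoding: every dimension is
always sampled, and a dimension unused by the sampled architecture is ignored
by the objective. For uncontrolled promoters the `k` dimension doubles as the
constitutive expression rate.

## Objectives

**Cost-benefit:** `J = α₁·J_prod + α₂·J_cost` with
`J_prod = 1 / (mean production flux over the final 10% of the horizon + 1e-9)`
(minimizing `J_prod` maximizes late-culture flux) and `J_cost` the
time-integral of total heterologous protein divided by the culture time.
Because the two components have different magnitudes, `α₂/α₁` is calibrated
by sampling designs uniformly at random and matching the medians of the two
weighted components (`calibrate_weights`, deterministic under a fixed seed).
The calibrated weights ship on each model as `default_cost_weights`.

**Dynamic response:** `J = J_os + α·J_rt`, where `J_os` is the percent excess
of the product trajectory's maximum over its steady state (mean of the final
5% of the grid; floored at 0) and `J_rt` is the first grid time at which the
trajectory reaches 50% of that steady state, normalized by the horizon (1 if
never reached). `α` multiplies the rise time, so large `α` favors fast
circuits and small `α` accurate (low-overshoot) ones. Designs with sustained
oscillations — at least 2 peaks with prominence above 5% of the trajectory
mean in the final half of the trajectory (`scipy.signal.find_peaks`) — incur
a single additive penalty of 1e6, which dominates any feasible unpenalized
loss.

## The optimizer

The Bayesian optimization loop uses a tree-structured Parzen estimator (TPE)
surrogate with the Expected-Improvement-equivalent acquisition: observed
trials are split into a good set (the γ best losses; γ = 15 once at least 2γ
trials exist, otherwise the best ⌈25%⌉) and a bad set; each continuous
dimension gets a Gaussian Parzen density per set (kernel bandwidths from the
adjacent-spacing heuristic, truncated to the bounds, mixed with one uniform
prior component), and the architecture dimension gets re-weighted categorical
distributions with a uniform pseudo-count prior. Each iteration draws 24
candidates from the good densities and evaluates the one maximizing
`log l(x) − log g(x)`. The first 20 trials sample the uniform prior, as do
degenerate histories (all losses identical). `OptimizerConfig(conditional=True)`
switches the continuous densities to architecture-conditional fits (the
literal "tree" structure); the default pools them, matching the flat
encoding. A single integer seed makes entire runs bit-reproducible.

Baselines share the same trial bookkeeping: random search (prior draws), grid
search (per-architecture regular grid, with the budget rounded to the nearest
factorizable size), a generational GA (tournament selection of size 3,
uniform crossover, Gaussian mutation at 10% of each range, 10% categorical
architecture mutation, elitism 1), and multi-start L-BFGS-B per architecture,
which also counts local-search convergence failures.

## Robustness machinery

Latin hypercube sampling (`scipy.stats.qmc`, plain/maximin-free) places
exactly one point per equal-width stratum per dimension. A perturbation sweep
rebuilds the model at each sampled parameter set and re-runs the full
optimization; "±100% of nominal" is implemented as the interval
`[1e-6·nominal, 2·nominal]`, since a zero kinetic constant would break
positivity. Background ensembles re-run the optimizer at nominal parameters
with fresh derived seeds. Ensemble summaries report architecture win
fractions, loss statistics, per-architecture parameter means/SDs and mean
dose-response curves; `pca_project` gives a centered (optionally
unit-variance) top-2 principal-component projection with explained-variance
fractions, dropping zero-variance columns with a warning.

## The built-in model cards

All four models are synthetic fixtures: the structure follows the published
pathway descriptions, while rate laws are irreversible Michaelis–Menten with
first-order export/leak terms and the nominal constants are the package's own
choices (tagged `synthetic-nominal` in each `model_card()`), selected so the
models reproduce the qualitative behavior reported for the real systems.

- **toy** (4 ODEs): influx `V_in` into a branch-point metabolite X0 consumed
  by native metabolism (first-order) and by heterologous E1; E1 produces the
  regulatory intermediate X1; E2 converts X1 into the product. 4 continuous
  parameters, 4 architectures.
- **glucaric acid** (5 ODEs): g6p → MI (Ino1) → GA (MIOX), with first-order
  MI export and GA removal; SuhB is not rate-limiting and is lumped away.
  MIOX follows `v = Vm·e·s/(km+s)·(1 + a·s/(ka+s))` — Michaelis–Menten scaled
  by allosteric activation by its own substrate. The card makes MIOX the
  expensive rate-limiting step (Vm = 0.1) and Ino1 catalytically weak
  (kcat = 0.5) with substantial MI export (1.5 h⁻¹): under these conditions
  the dual-control architecture (MI represses Ino1, activates MIOX) is the
  strict optimum of the cost-benefit loss — repression trims the transient MI
  excess that would otherwise be exported while MIOX accumulates, and
  activation avoids expressing costly MIOX before substrate is available.
  The margins over the single-loop architectures are, however, below 1%:
  with static Hill feedback any control law coincides with some constitutive
  rate at steady state, so architectures separate only through transient
  shaping. Consequently repeated optimizations select dual control as the
  modal but not overwhelming winner (55–65% of perturbed-model runs at this
  scale, against the >80% reported for the original model, whose full kinetic
  description is not public).
- **fatty acid** (3 ODEs): fatty acid released by a thioesterase from a
  constant acyl-ACP pool, plus a repressor co-expressed on the enzyme's
  promoter. Architectures are categorical: constitutive (open loop), a
  metabolic loop (FA-responsive TF represses the enzyme, NML), a gene loop
  (co-expressed repressor represses its own promoter, NGL), and the layered
  combination (LNML). 2 continuous parameters; the repressor threshold is
  fixed at 1 µM.
- **p-aminostyrene** (23 ODEs): substrate → (PapA/PapB/PapC on the papABC
  operon) → p-AF → (E) → p-ACA → efflux pump → extracellular product, with a
  constitutive LAAO unit that drains p-AF and releases H₂O₂, and a first-order
  p-AF leak. Protein production is resolved per transcription unit as
  mRNA → unfolded → folded (4 mRNAs + 6 unfolded + 6 folded states), and a
  toxicity factor `τ = 1/(1 + t_l·v_LAAO + t_a·[p-ACA] + t_p·[pump])`
  (floored at 1e-6) multiplies all synthesis, degradation and folding rates.
  The 16 continuous parameters are 3 constitutive promoter rates, (k, θ) for
  each of the 6 ligand×promoter pairs, and the LAAO unit rate. Oscillatory
  regimes are permitted by the simulator and handled by the objective's
  oscillation penalty.

Default search bounds are uniform (per-model) over roughly
`k ∈ (10⁻³, 15) µM/h` and `θ ∈ (10⁻², 1–10) mM`, bracketing the ligand
concentration ranges the models actually visit.

## Problem sizes used by the test suite and acceptance script

Headline quantities are recomputed at desk scale: 20 optimization runs of 500
iterations each for the toy-model dispersion and for the glucaric LHS sweep
(N = 20 perturbations of the three MIOX allosteric constants), a 3-seed
GA (2,400 evaluations) vs BayesOpt (300) vs random (300) comparison, 5
reduced-budget (60-iteration) runs on the p-AS model, and 20-seed
TPE-vs-random comparisons at a 200-evaluation budget. These sizes keep full
reruns in the minutes range while leaving the measured quantities stable
across seeds.

## What the synthetic fixtures do and do not show

Passing tests demonstrate that the machinery — enumeration, stiff simulation,
objectives, the mixed-integer TPE loop, sweeps — behaves correctly and that
the qualitative design phenomenology (negative feedback beating open loop,
the overshoot/rise-time trade-off, architecture diversity on the large
model) emerges from the model class. They do not validate the kinetic
constants against experimental data: absolute losses, optimal parameter
values and architecture win margins depend on the synthetic cards and should
not be read as predictions for the real pathways.

## Known limitations

- Architecture win margins on the toy/glucaric models are intrinsically small
  (see above), so per-run winners among near-tied architectures are noisy.
- Dual regulators are lumped into signed Hill terms; no mechanistic TF
  binding, no multistability analysis of positive-feedback architectures.
- The GA and gradient baselines are deliberately simple reference
  implementations, not tuned metaheuristics.
- Simulation is deterministic; no stochastic gene expression.
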