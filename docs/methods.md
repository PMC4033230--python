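# Methods

This note records the modelling conventions the package implements, the
places where the published tables it was built around leave a choice open,
and which choice was made.  All flows are mgC m⁻² d⁻¹; there is no unit
conversion layer.

## 1. Model structure

A model declares compartments (`living` / `nonliving`, optional biomass in
mgC m⁻², tags such as `autotroph` or `parasite-sporangia`) and flows named
`src-dst`.  Three id patterns carry structural meaning: `gpp-<c>` is an
exogenous import (gross primary production), `<c>-res` a dissipation
(respiration), `<c>-los` an export (sinking, or consumption by trophic
levels outside the model).  Everything else is an internal transfer.

Compilation emits one mass balance per compartment (inputs − outputs = 0).
In the built-in models the DOC balance includes the bacterial release flow
`bac-doc` among the DOC inputs: both packaged flow tables balance the DOC
pool only under that reading, so the variant that omits it is treated as a
transcription slip in the source material.

Measured equalities and ecological constraints are written as linear
expression strings over flow ids and named aggregates, resolved at compile
time: `GPP` (sum of imports), `NPP` (GPP − autotroph respiration),
`NPP(c)`, `Ing(c)` (internal inflows of a consumer), `Det_total` (inputs to
`det`), `Los_total` (exports), `BP` (`doc-bac − bac-res`), `Biom(c)`.
Two-sided bounds compile to two one-sided rows of `G x ≥ h`.

### Constraint families (spring-bloom model)

GPP partition windows per size class; phytoplankton respiration 5–30 % of
own GPP (ph1, ph2) and 5–40 % (ph3); bacterial respiration ≥ 20 % of DOC
uptake; zooplankton respiration ≥ 20 % of ingestion; chytrid respiration
≤ 20 % of carbon input; phytoplankton exudation 10–55 % of own NPP;
zooplankton DOC excretion ≥ 10 % of ingestion and ≤ own respiration; net
growth efficiency 25–50 % for hnf/mic/mes and for bacteria (implemented in
loss form: respiration + excretion + detritus production between 50 % and
75 % of DOC uptake); assimilation efficiency 50–90 %; mesozooplankton
grazing on ph3 3–7 % of ph3 NPP; diet windows for mes, mic and hnf;
detritus-production caps (hnf, mes ≤ 20 % of ingestion; attached bacteria
1.2–5.6 % of BP; ph3 16–95 % of total detritus production; sporangia ≤ 5 %
of their carbon input); detritivory caps (≤ 40 % of detritus production);
detritus dissolution ≤ 10 % of NPP (upper-bound reading); zoospore grazing
by mic ≥ twice that by mes; parasitism ≥ 8 % of ph3 NPP; sinking shares
(ph3 ≥ 28 % and ≥ 0.2 mgC m⁻² d⁻¹; mes 45–65 %).  Where a printed equation
and its printed description disagree (respiration percentages, bacterial
growth efficiency, detritus dissolution direction), the description was
implemented; each choice is validated by the packaged spring-bloom flow
table, which satisfies every emitted row.

The sporangia→zoospore floor (`spg-zsp ≥ Biom(zsp)`) needs a zoospore
biomass that is not part of the packaged data; a constraint whose bound
references a missing biomass is skipped with a logged warning that also
appears in run manifests.

### Autumn-bloom (eutrophic) calibration

The cyanobacteria bloom concentrates production and sinking in ph3 far
beyond the spring-bloom windows, and the packaged autumn flow table
contradicts four families as printed for the spring web.  The autumn model
therefore carries lake-specific bounds, chosen as the package's own
calibration so that the measured-flow table is feasible with margin: ph3
GPP share 60–95 % (observed 89 %), ph2 2–12 %, ph1 0.5–20 % (observed
0.9 %); ph3 exudation floor 5 % of own NPP (observed 9.1 %); attached
bacteria 1.2–20 % of BP (observed 18 %); mesozooplankton sinking share
2–65 % (observed 6 % — autumn sedimentation is dominated by ungrazed
filaments, not zooplankton).  The spring model emits 78 ecological rows and
the autumn model 79; the difference from the cited counts (76/78) is
presumably a bookkeeping difference in how two-sided rows were tallied and
has no effect on the polytope.

The autumn model pins bacterivory at `bac-hnf = 63.02` and
`bac-mic = 109.40`, following the realized flow table; the published
equation list swaps the two labels, and `with_swapped_bacterivory` exposes
the alternative reading.

## 2. Feasibility checking

`evaluate_feasibility` reports equality residuals both absolutely and
relative to a per-row scale — the compartment's gross throughput for a mass
balance, the measured value for a pinned flow — and inequality slacks
absolutely.  The default tolerances (1 % relative, 0.5 mgC m⁻² d⁻¹) absorb
the two-decimal rounding of the packaged tables; sampler-generated vectors
are checked at 10⁻⁶/10⁻⁷.

## 3. Mirror sampler

`x = x0 + N q` with `N` an orthonormal null-space basis of `E`
(rank-revealing SVD, relative tolerance 10⁻¹⁰) and `x0` a strictly interior
start from a slack-maximising linear program (HiGHS).  Proposals add
zero-mean Gaussian noise with standard deviation `jump` per reduced
coordinate; while any inequality is violated the point is reflected across
the unit normal of the most-violated constraint; after 1,000 reflections the
move is rejected (the chain stays put; rejections are counted in the
ensemble).  Defaults — jump 10 mgC m⁻² d⁻¹, 100,000 iterations, no burn-in,
no thinning — are the study conditions of the built-in models; burn-in and
thinning are configurable because the published chains' treatment is
unknown, which is also why per-flow posterior means are validated
statistically rather than exactly.

Uniformity is verified in the tests against closed forms on an interval and
a simplex, and against a rejection-sampling oracle on generated problems
with ≤ 4 free dimensions (3 combined standard errors).  KS tests use
thinned chains, since raw MCMC output is autocorrelated.

Index ensembles (one index value per retained sample) are compared between
models with the classical two-sample, two-tailed t test.

## 4. Network indices

`to_flow_network` partitions a flow vector into imports Z, internal
transfers T, exports E and dissipations R.  Conventions, each pinned by the
packaged tables:

* **TST** = ΣZ + ΣT + ΣE + ΣR (the spring/autumn tables sum to 2625.2 and
  8888.6).
* **APL** = (TST − Z)/Z.
* **Information indices** on the extended matrix (compartments + one import
  source + one export sink + one dissipation sink), log base 2.
  `A = TST·AMI`.  The capacity is the *throughput-diversity* form
  `DC = TST · H(p)` with `p` the node **output** throughputs (import node
  included); `DCi` drops the import node's entropy term; `Ai` is the
  internal-transfer part of the ascendency sum; `Ri = DCi − Ai`.  This
  reproduces the published capacity/redundancy values to ~1 %, which the
  flow-entropy capacity `−Σ T log₂(T/TST)` does not (it overshoots DC by
  ~45 %).  Since mutual information is bounded by the source-margin entropy,
  `A ≤ DC` holds structurally; for a perfectly determinate web `A = DC`.
* **Connectance** `c = 2^(Hc/2)`, `Hc` the flow-weighted conditional
  entropy, on all transfers / internal transfers / living-living transfers.
  The intercompartmental and food-web values match the published ones to
  ±0.05; the "overall" value is sensitive to how the boundary nodes enter
  the matrix and the source's exact treatment could not be reconstructed —
  the packaged convention (full extended matrix) gives 2.60/2.20 against a
  published 2.2/1.9, so only the two better-defined bases should be
  compared across studies.
* **Diets, shares, mycoloop metrics** are simple ratios of the partitioned
  flows.  Parasitism (`ph3-spg`) counts as herbivory in D/H; detritivory is
  consumption of the non-living pools by living compartments (pool→pool
  dissolution excluded).  The microzooplankton efficiency is implemented
  literally as `mic-mes / mic throughput`; on the spring fixture this gives
  42.4 % where the source reports 36.7 % — the definition behind the
  reported figure could not be reconstructed, so the literal formula is
  kept and the discrepancy documented rather than patched.  Likewise the
  in-text "% of TST" figures for sporangia throughput use an unstated
  denominator and are not reproduced.

## 5. Cycling

Cycling uses the classical compartmental basis: denominator
`Σ_j T_j` over compartment input throughputs.  With
`n = diag((I − G)⁻¹)`, `G` the input-normalised internal transfer matrix:

* **FCI** = Σ T_j (n_jj − 1)/n_jj ÷ Σ T_j — flow weighted by the
  probability of at least one return.
* **CCI** = Σ T_j (n_jj − 1) ÷ Σ T_j — flow weighted by the *expected
  number* of returns, which also credits compound (multi-lap) cyclic
  pathways; hence CCI ≥ FCI, both zero on acyclic webs.  An alternative
  reading — total arc flow removed by weakest-arc cycle extraction over
  TST — was rejected because it yields cycling fractions of 12–19 % on the
  packaged webs, irreconcilable with the published 4–7 %.

`extract_cycles` enumerates simple cycles (networkx, budget 10⁶) and
removes circulation largest-weakest-arc-first (lexicographic tie-break),
leaving an acyclic residual; it backs the cycle listings, not the CCI.

## 6. Lindeman spine

Non-living pools are pinned to trophic level I together with the primary
producers (import recipients).  Each consumer's activity is apportioned
over integer levels one above its prey (fixed-point sweep, exact on
diet-acyclic webs, truncated at 12 levels).  Level-I input = imports +
flows into the pools weighted by the source's above-level-I apportionment
(autotroph exudation is level-I internal).  Input to level k+1 =
Σ T_ij · A_i(k) over living consumers j.  Transfer efficiency of level k =
input(k+1)/input(k) × 100; the grazing-chain efficiency at level k is the
cumulative form input(k+1)/Z × 100 — the share of exogenous input reaching
that level, which is what the published per-level "grazing chain" numbers
turn out to be; `Geff` is the geometric (logarithmic) mean of the first
four level efficiencies.  Levels above IV are computed but flagged
low-confidence.

## 7. Synthetic problems

`generate_problem` draws a feed-forward grazing web (imports only into
producer compartments, universal respiration, optional detrital pool,
guaranteed connectivity), routes the imports through Dirichlet-distributed
output shares so every balance holds exactly, then pins the total import
(plus a configurable number of individual flows) and windows every positive
flow at ±`window` around its true value.  The truth is strictly interior by
construction.  One seeded `numpy` generator drives all draws; identical
configs are bitwise-reproducible.  What the generator does *not* emulate:
diet-share constraints coupling several flows, measurement error on the
pinned values, and living-web cycles — so sampler recovery results on
synthetic problems speak to the geometry of box-windowed polytopes, not to
every feature of the lake webs.

`generate_bloom_like` scales a built-in model's equality constants and
biomasses by a bloom-intensity factor, leaving topology and relative
windows unchanged.

## 8. Problem sizes in the shipped tests

The test suite runs the full deterministic index battery on both packaged
webs, mirror chains of 10,000 iterations on the spring-bloom model (53
flows, 38 free dimensions), 2,000-iteration chains for the between-lake
throughput comparison, and 40,000–60,000-iteration chains on 1–4
dimensional analytic/synthetic polytopes; these lengths give Monte-Carlo
errors comfortably inside the 3-standard-error bands the tests assert while
keeping the whole suite around ten seconds.  Exact reproduction of the
published per-flow means is deliberately out of scope (unprinted
biomass-dependent bounds, unknown burn-in/thinning of the source chains).

## 9. Known limitations

* Steady state only; no time dynamics, no infection prevalence modelling.
* No fish or macrophyte compartments and no allochthonous detritus input.
* The "overall" connectance, the microzooplankton-efficiency figure and the
  sporangia %-of-TST figures discussed above are convention-sensitive; treat
  them as secondary.
* The mirror walk's most-violated-constraint reflection is the standard
  published recipe but no formal detailed-balance proof is attempted for
  pathological polytopes; the uniformity oracle tests cover the regime the
  package is used in.
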