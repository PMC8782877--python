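# Methods

This note records the models and procedures implemented in `petrisens`,
the assumptions behind them, the numerical choices, and what the bundled
synthetic fixtures do and do not establish about real pathway models.

## Petri nets and the invariant engine

Nets are classical (discrete) place/transition nets: bipartite directed
graphs with positive integer arc weights and a token marking.  Ordinary
nets are the default; weights are supported throughout.  Duplicate
same-direction arcs in input are summed into one weighted arc with a
warning, since they usually indicate a modelling slip.

The incidence matrix `A` (rows = places, columns = transitions) drives all
structural analysis.  Minimal semi-positive t-invariants — nonnegative
integer solutions of `A·x = 0` with support-minimal, gcd-normalized
vectors — are computed by Farkas-style elimination on the table
`[Aᵀ | I_m]`: one place column at a time, rows with opposite signs in that
column are combined with positive integer coefficients to cancel it, rows
still nonzero in the column are discarded, and rows whose support strictly
contains another row's support are pruned after every step.  p-invariants
reuse the same routine on `Aᵀ`.

Numerical choices:

- **Exact integer arithmetic** (Python arbitrary-precision ints) in the
  engine; `A·x = 0` holds exactly for every returned invariant and is
  asserted in tests.  No floating point touches the invariant path.
- **Elimination order**: the place column with the fewest nonzero rows is
  processed first.  This only limits intermediate table growth; the result
  is order-independent (tested under permuted place orderings).
- **Canonical form**: each invariant is divided by the gcd of its entries;
  the set is sorted lexicographically by support for reproducible output.

The engine is cross-validated against two independent oracles in
`petrisens.synthetic`:

- `brute_force_t_invariants` enumerates every nonnegative vector with
  entries up to a bound (guard `m·(bound+1)^m ≤ 10⁷`) and reduces to the
  minimal set.  It is exhaustive only when the true invariants respect the
  bound; random weighted nets routinely violate small bounds (entries
  above 60 were observed on 8×8 nets with weights ≤ 2), so it serves the
  hand-written examples and small-bound cases.
- `support_enumeration_t_invariants` enumerates candidate supports by
  increasing size with superset pruning and accepts a support iff the
  column-restricted incidence matrix has a one-dimensional exact rational
  nullspace spanned by a strictly positive vector — the standard
  characterization of minimal semiflows.  It has no entry bound and is the
  oracle used for the 200-net exact-equality check.

## Structural analyses

Significance, knockout and subset search operate on the invariant set, not
the net, so they are purely structural and independent of markings.

- Percentages (`S`, `E`) are rounded half-up to two decimals, matching the
  conventional report formatting of significance tables.
- **Knockout** is implemented as support filtering (drop every invariant
  whose support meets the knocked set).  For minimal invariants this
  coincides with recomputing the minimal invariants of the net with the
  knocked columns deleted — an invariant avoiding those columns solves the
  reduced system iff it solves the full one, and support-minimality is
  unaffected by deleting unused columns.  The equivalence is re-verified
  on random nets rather than assumed.
- **Subset search** has two modes because "a set contained in very many
  supports" and "a set whose removal excludes most subprocesses" are
  different questions.  Joint-containment mode runs a level-wise
  Apriori-style search over transitions whose individual frequency clears
  the threshold and returns the maximal sets at or above it (default 0.8).
  Union-knockout mode greedily adds the transition that maximizes the
  exclusion percentage, reporting the exclusion at each set size; it can
  be seeded with a starting set.  Ties break toward larger sets, then
  higher frequency, then lexicographic ids.  The original subset-search
  literature may use a different algorithm; no equivalence is claimed.

## Net I/O

PNML (ISO/IEC 15909-2 core model) is the format of record, read and
written with exact round-trip of structure and marking and deterministic
element order.  Snoopy `.spped` is read-only and best-effort for the
discrete place/transition dialect: graphics are ignored, and *logical
places* — multiple place nodes sharing one display name, a drawing
convenience in large published nets — are merged into one place with arcs
rewired and parallel arcs summed, which preserves the incidence matrix up
to row identification.  Other Snoopy net classes raise an explicit
unsupported-format error.  The Holmes `.project` format is not parsed
(undocumented); users can convert via Snoopy.  A minimal CSV arc-list
dialect (`source,target[,weight]`, ids prefixed `p`/`t`) covers quick
hand-written nets.

## Translation motifs and the p53 fragment

Classical nets have a single arc type, so three adaptations recur when
translating ODE rate terms into net fragments: catalysts are consumed and
returned to circulation by dedicated pool source transitions (read arcs
are deliberately not used); inhibition becomes a drain transition
competing for the inhibited reaction's pre-place tokens (weakening, with
complete inhibition delegated to knockout analysis); degradation is an
output transition with no post-places, which is also what makes source-fed
chains coverable by t-invariants.

`build_p53_fragment` composes the six balance terms of nuclear
phosphorylated p53 — spontaneous, ATM-dependent and Chk2-dependent
activation, Wip1-dependent inactivation, spontaneous and Mdm2-mediated
degradation — plus p53 synthesis and four catalyst pools (11 transitions,
6 places, 9 minimal t-invariants, fully covered).  Design choices that
were genuinely open:

- The Mdm2-mediated degradation consumes the Mdm2 token and replenishes
  it from a pool, mirroring the catalyst treatment; the alternative
  (non-consuming Mdm2) would need a read-arc emulation that classical
  nets do not have.  A consequence worth knowing: knocking out the
  mediated degradation *alone* strands its pool source (the pool loses
  coverage); knocking out degradation and pool together — a module
  knockout — keeps every remaining transition covered.  The tests assert
  this computed behavior.
- Marking is 1 token on each source-fed place, 0 elsewhere.  Markings do
  not affect invariant analysis; they are fixed only for reproducibility.

## The reduced ODE model and the protocol

`ODEModel` represents a pathway model as named additive rate terms
(expression strings over declared species, parameters and inputs, parsed
with sympy and compiled once).  A parameter that appears in no term is
accepted with a warning rather than rejected: such structurally inert
parameters are exactly what the sensitivity analysis must score as zero.

`reduced_fixture_model` is a closed six-species reduction of the nuclear
p53 module.  The phosphorylated-p53 balance carries the six canonical
terms (saturating Michaelis–Menten kinetics in each kinase, quadratic
Mdm2 dependence of the mediated degradation); the precursor mirrors the
conversion terms and adds synthesis and first-order decay; the four
regulators are first-order production/decay drivers, with production gated
by the radiation dose-rate input for ATM and Chk2.  Parameter values are
package defaults in arbitrary concentration units and hours: rates were
chosen once so that activation, inactivation and degradation compete at
comparable magnitudes, the unstressed steady state is reached well within
the 24 h equilibration phase, and a 4 Gy pulse produces a clear transient
(roughly 9-fold p53-phosphorylation rise) that relaxes back during
recovery.  They are deliberately not calibrated to measured kinetics, and
no full-pathway quantitative claim (published time courses, full-model
parameter rankings) is reproduced by this fixture.

The simulation protocol has three consecutive phases: equilibration with
no inputs (default 24 h), stimulation (default 1 h; TNF at 10 ng/ml and a
total radiation dose of 4 or 10 Gy applied as a rectangular dose-rate
pulse of amplitude dose/duration — only the total dose is specified
upstream, so the rectangular shape is this package's choice), and recovery
(default 240 h, TNF still on).  Integration uses a stiff-capable adaptive
solver (LSODA by default) with rtol 1e−6, atol 1e−9; halving the
tolerances moves the fixture trajectories by well under 0.1% sup-norm.
Equilibrium at the end of phase 1 is checked as
`‖dx/dt‖∞ < 1e−6·‖x‖∞ + 1e−9` and produces a warning, not an error,
because deliberately short equilibration phases are legitimate in
benchmarks.  Small negative excursions below ten times the absolute solver
tolerance are clipped to zero; larger ones remain visible as a modelling
error.

`settling_time` returns the earliest post-stimulus time after which a
trajectory stays inside a tolerance band around its final value.  The band
is a fraction (default 5%) of the post-stimulus excursion amplitude
`max|x(t) − x_final|` — the control-engineering convention of referencing
the step size — and a response whose settled tail is shorter than 5% of
the post-stimulus window (e.g. a sustained oscillation sampled near a
crossing) is reported as not settled (NaN) rather than trivially settled
at the last sample.

## OAT sensitivity analysis

Sampling follows the one-at-a-time scheme: each analyzed parameter is
redrawn uniformly in ±30% of nominal (configurable) for each run while all
others stay nominal; the reference study size is 1000 runs per parameter,
and the bundled benchmarks use 50 to keep the default test run fast.  Each
draw is keyed by (seed, parameter id, run index) through a counter-based
generator, so results are bit-for-bit reproducible and independent of
evaluation order.  Nonpositive nominals cannot be perturbed
multiplicatively and are skipped with a warning.

The index of a (parameter, variable) pair is a pluggable strategy.  The
default is the run-averaged normalized L1 deviation over the stimulation
and recovery phases,
`mean_r ∫|v_r − v̄| dt / (∫|v̄| dt + ε)` with `ε = 1e−12`; an inter-run
dispersion variant (time-averaged standard deviation across runs, scaled
by the nominal mean level) is provided.  The upstream index definition
based on response frequency distributions is not restated in the source
this package follows, so the L1 index is this package's own choice,
exposed as a strategy precisely so that variant can be added.  Per-variable
index columns are max-normalized to [0, 1] before the arithmetic mean
across variables — without normalization, variables on different scales
would dominate the mean — and the combined ranking sorts descending with
ties broken by parameter id.  Integration failures discard the run; more
than 10% failures for one parameter abort the analysis (the failure policy
is a package choice).

The analytic benchmark uses `dx/dt = a − b·x` from rest, where
`x(t) = (a/b)(1 − e^{−bt})` in closed form.  At first order the production
rate dominates the decay rate pointwise on any finite window, but with the
finite ±30% perturbation a convexity term in `b` can overturn that
near-asymptotic ties, so the benchmark's reference ordering is computed
per draw from the closed-form trajectories by quadrature (independent of
the ODE solver and the index pipeline) and the package ranking is required
to agree in at least 95% of seeded draws; in practice agreement is 100%.
A deterministic companion study, `perturbation_comparison`, scales one
parameter by fixed factors and tabulates recovery-phase mean level, final
level and settling time per variable, separating parameters that shift
response *levels* from parameters that shift response *timing*.

## Synthetic fixtures: what passing tests show

`random_invariant_net` composes disjoint cycles and source→place→sink
chains (one minimal t-invariant each, so the expected count is known by
construction) and can glue cycles on shared transitions, in which case the
expectation comes from the oracles.  `random_net` draws arbitrary random
bipartite nets (each direction of each place/transition pair independently
with probability 0.3, weights ≤ 2 — dense enough to produce nontrivial
invariant structure while staying within oracle reach).
`random_support_family` plants a jointly-frequent transition set at an
exact frequency inside random noise supports for subset-search tests.

These fixtures exercise correctness of the algorithms, not realism of
biology: random 8×8 nets do not mimic the topology, modularity or size of
a full DNA-damage-response network, and the reduced ODE fixture omits
transcription, feedback through Mdm2/Wip1 induction and the entire
NF-κB arm.  Passing tests therefore establish that the engines compute
what they claim on nets and models where the truth is independently
checkable — not that any specific biological conclusion transfers.  The
published full-model statistics (89 places, 170 transitions, 541
t-invariants, ~92% subset knockout) are checked by a dedicated test that
requires the externally distributed model file and reports failure until
it is supplied.

## Known limitations

- No reachability, liveness or boundedness analysis; no timed, colored,
  continuous or stochastic nets; no MCT-set/cluster decomposition of
  invariant sets.
- The Farkas engine is worst-case exponential; it is intended for models
  up to a few hundred transitions, not arbitrary nets.
- `.spped` reading is best-effort against the discrete dialect observed in
  published models; writing `.spped` and Holmes `.project` parsing are out
  of scope.
- Whole-model automatic ODE→net conversion is deliberately absent: the
  motif builders support the manual translation workflow.
- Global variance-based sensitivity (e.g. Sobol indices) is not
  implemented; the OAT scheme perturbs one parameter at a time and cannot
  detect interaction effects.
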