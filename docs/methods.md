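# Methods

## Model

A cargo carries `N` identical motors that can step along a one-dimensional
lattice of binding sites (lattice spacing = motor step size `dx`, 8 nm for
the kinesin and Ncd parameterizations).  A bound motor steps forward at
rate `p` and backward at rate `q` (s⁻¹); two motors never share a site
(simple exclusion), and a blocked step simply fails.  The cargo exerts its
entire load on the *leading* motor — the forwardmost bound motor — whose
rates acquire Boltzmann factors

    p1 = p exp(−f δ),      q1 = q exp(f (1−δ)),

where `f = F dx / kBT` is the dimensionless load and `δ ∈ [0, 1]` splits
the force between the forward and backward transition.  All presets use
δ = 0.5 and the conventional ratio `p = 10 q`.  ATP is assumed saturating:
one rate per step direction, no Michaelis–Menten substrate dependence.

For `n` bound motors the steady-state cluster velocity (steps/s) is

    V_n = p (1 − e^f r^n)(1 − r) / [ e^{fδ} (1 − r) + e^f (r − r^n) ],
    r = q/p,

which reduces to `p e^{−fδ}` for unidirectional motors (`q = 0`), collapses
to `p − q` at `f = 0`, and vanishes at the cluster stall `f_s(n) = n ln(p/q)`
— the stall force of a processive cluster is linear in the number of motors.

Non-processive motors unbind at rate `k_off` and rebind at rate `k_on`
(`k_on` quoted in the unlimited-binding-site convention; with `M`
accessible sites the per-site rate is `k_on/M`).  The number bound follows
a birth–death chain whose stationary law is binomial-like,

    P_n ∝ C(N, n) (k_on/k_off)^n                        (unlimited sites)
    P_n ∝ [N! M! / (n!(N−n)!(M−n)!)] (k_on/(M k_off))^n (M sites),

and the binding-averaged cluster velocity conditions on at least one motor
being bound:

    V̄ = Σ_{n≥1} P_n V_n / (1 − P_0).

This holds when stepping is fast compared with (un)binding so that each
`n`-motor configuration reaches its steady velocity; no quantitative
validity check is applied.  Distribution weights are accumulated in log
space and normalized by log-sum-exp, so factorial ratios do not overflow
even for clusters of hundreds of motors (exact to ~1e−12 relative for
N, M ≤ 200).  A direct linear solve of the master-equation generator is
kept as an internal cross-check; it reproduces the closed forms to 1e−10
total variation and satisfies detailed balance termwise.

## Simulators

### Fixed time-step engine

The production engine advances all motors with a fixed step `dt`
(default 1e−3 s).  Each step has two phases, each visiting the motors in a
fresh uniformly random permutation (a fixed sweep direction would bias
exclusion conflicts):

1. **Binding/unbinding** (non-processive runs).  A bound motor unbinds with
   probability `k_off dt`.  An unbound motor attempts to bind with
   probability `k_on dt`; where the attempt lands depends on the scenario
   (below).  Each motor makes at most one state transition per phase.
2. **Stepping.**  Each bound motor draws one uniform variate `u` and
   attempts a forward step if `u < p_μ dt`, otherwise a backward step if
   `u < (p_μ + q_μ) dt` (the two moves are mutually exclusive within a
   step, consistent with the small-`dt` limit).  The leader — recomputed
   after the binding phase and held fixed through the stepping phase —
   uses `p1, q1`; every other motor uses `p, q`.  Newly bound motors step
   in the same time step.

Two binding-window scenarios are implemented:

* **Scenario A — fixed window, swapping allowed.**  Binding is restricted
  to a window of `M_fixed` sites that co-moves with the cluster: its left
  edge tracks the rearmost bound motor, shifting forward only as needed to
  keep the leading bound motor inside (the closed forms depend only on the
  window *size*, so the anchoring is a convention).  A binding attempt
  succeeds with probability `(M − n)/M` — the per-motor rate implied by
  the per-site binding rate `k_on/M` of the limited-sites master
  equation — and the motor lands uniformly on a free window site, so the
  simulated occupancy realizes that equation's stationary law exactly.
  The "always succeed on any free site" alternative would instead produce
  a truncated unlimited binomial, which is not what a per-site binding
  rate means.  Motor identity is irrelevant here: a rebinding motor may
  take any free window site.
* **Scenario B — variable window, sequence preserved.**  A motor may bind
  only at an unoccupied site strictly between its nearest bound
  neighbours *by motor index*, plus one extension site behind the
  rearmost (ahead of the forwardmost) bound motor for motors at the ends,
  so the order of motors along the filament never changes.  The attempt
  succeeds at the full rate `k_on` whenever at least one admissible site
  exists, with the site drawn uniformly among the admissible ones; for
  `N = 2` a partner site is always available, which is why small clusters
  follow the unlimited binomial.  At the end of each step the window is
  recomputed as the bound extent plus one site on either side
  (`M(t) = extent + 2`); while every motor is detached it is retained
  from the positions last attached, so rebinding resumes where the
  cluster left off.

Processive runs (`k_on = k_off = 0`) skip phase 1; motors start bound at
distinct uniform sites within an initial cargo width of 10 sites for
`N < 10` and `N + 10` sites otherwise (results are insensitive to this
width).  Non-processive runs start with every motor unbound.

The first-order discretization error of the scheme is O(rate·dt).
Configurations are rejected when any `rate·dt > 1` and warned above 0.1.
At `rate·dt = 0.1` the bias is of order 1% — visible only when replicate
statistics are pushed well below that (the long-run comparisons here use
either moderate statistics at `dt = 1e−3` or `dt = 2.5e−4` where percent
accuracy matters).  The stall-force scanner shrinks `dt` automatically so
that `q1(f)·dt ≤ 0.1` and raises the step count to preserve total
simulated time, since the loaded leader's backward rate grows as
`e^{f(1−δ)}`.

### Event-driven engine

A continuous-time (Gillespie-type) sampler of the identical process serves
as the correctness oracle: exponential waiting times from the total
admissible rate, event selection proportional to rate, the same
admissibility rules and observable definitions.  The rate table is rebuilt
after every event — O(N) work that is entirely adequate at the cluster
sizes where the oracle runs.  Scenario A binding enters the table at rate
`k_on (free window sites)/M` per unbound motor; scenario B at `k_on` when
an admissible site exists.  The two engines agree within mutual error bars
on every observable; the fixed-step engine is roughly an order of
magnitude faster and is the default.

## Observables and estimators

* **Occupancy** — histogram of the number bound, accumulated every step
  (time-weighted in the event-driven engine), normalized to a
  distribution; compared against the closed forms above.
* **Episode velocities** — an episode is one motor's tenure as leader,
  opened when it becomes the forwardmost bound motor and closed when it
  unbinds or another motor binds in front of it; its velocity is
  displacement over duration.  Zero-duration episodes are discarded.  The
  headline non-processive cluster velocity is the *duration-weighted*
  episode mean — the time average of the leading motor's velocity while at
  least one motor is bound — which is the quantity the binding-averaged
  law V̄ predicts.  The unweighted mean over episodes is also exposed; it
  down-weights long episodes and sits a few percent lower.
* **End-to-end velocity** — `(x_lead(T) − x_lead(t_s))/(T − t_s)` after a
  burn-in `t_s`; the estimator for processive runs (5×10⁶ steps, burn-in
  1000 by default).  For non-processive runs it additionally counts the
  position jumps when leadership changes (forward on bind-in-front,
  backward on leader unbinding) and so differs from the episode average;
  both are reported.
* **Run lengths** — signed cargo displacement per contiguous attachment
  period, from the site where the first motor binds to the site where the
  last motor unbinds; periods still open at the horizon are dropped.  Net
  per-run velocities (run length / run duration) give the velocity
  distribution used for the in-vivo comparison.
* **Mean window** — time average of `M(t)` (scenario B); plugging its
  rounded value into the limited-sites distribution gives the analytic
  overlay for sequence-preserving runs.

Non-processive defaults are 5×10⁷ steps with burn-in 2500 (25 000 for
N ≥ 100) and 100 replicates; every control is overridable, and the test
suite and acceptance script run reduced lengths (10⁵–5×10⁶ steps, 3–20
replicates) chosen so that statistical resolution, discretization bias and
runtime stay balanced.  Replicates draw independent child seeds from one
root seed sequence, so results are reproducible and order-independent.

## Stall forces

Processive clusters: closed form `N ln(p/q)`.  Non-processive clusters:
the root of V̄(f) on the bracket `[0, N ln(p/q)]` (V̄ is continuous and
decreasing there, so the bracket is guaranteed), found by Brent's method to
1e−8.  Simulated stall: scan a force grid for the first point whose
measured velocity satisfies `|V_f/V_0| ≤ 1e−5` *or is non-positive* — with
finite sampling the long-run velocity near stall is dominated by noise of
either sign, so a sign change is accepted as crossing the stall — then
bisect to a resolution of 0.05 in `f`.

## What the simulations do and do not establish

The synthetic dynamics *are* the model: exclusion, leading-motor load and
the two binding-window scenarios, with preset rates taken from published
single-molecule measurements (kinesin-1 `p = 100, q = 10`; Ncd
`p = 22, q = 2.2, k_on = 20, k_off = 10`; weakly processive axonal
kinesin-1 `k_on = 5, k_off = 1`).  Real transport features deliberately
not represented: force-dependent unbinding, motor–motor interaction
potentials, elastic motor–cargo linkages, cargo diffusion, multiple
protofilaments and mixed motor species.  Agreement of the simulator with
the closed forms therefore validates the sampling and the estimators, not
those extra mechanisms.

Two emergent effects of the scenario-B rules are worth flagging because
they bound what "large clusters behave processively" means quantitatively.
At zero load a dense sequence-preserving cluster rectifies the leader's
motion — its backward steps are often blocked by the packed cluster while
forward steps never are — so the bound-state velocity of an N = 100 Ncd
cluster sits ~6% *above* `p − q`.  Under high load the leader carries the
full force, and each leader unbinding exposes the next motor to it (an
unbinding zipper), so measured velocities fall below the fully bound
`V_N` law well before its stall and the simulated stall force of large
sequence-preserving clusters is far below `N ln(p/q)`.  Both effects are
reproduced independently by the event-driven engine; at figure resolution
they are compatible with the qualitative plateau expected of large
clusters, but they are genuine, resolvable deviations from the fully bound
law at Monte Carlo precision.

## Motor-number inference

For in-vivo comparison the package simulates candidate motor numbers
(scenario B, by default the axonal kinesin-1 preset at `f = 2`,
i.e. ~1.1 pN at 310 K with `kBT = 4.28 pN nm` — the temperature is a
package choice, configurable) and ranks candidates by the sum of squared
z-distances of the simulated mean velocity and mean run length from the
observed pair, using the observed standard deviations as scale.  A formal
ranking metric is a necessary addition over by-eye comparison; candidates
whose simulation completes no attachment period are excluded with a
warning.  The zero-load in-vitro comparison uses different single-motor
and multi-motor stepping rates (`kinesin1-single`, `ncd-single` presets)
to absorb the scaffold-interaction effect seen experimentally; the
interaction itself is not modelled.
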