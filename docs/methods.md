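# Methods

## Problem

An outpatient clinic serves a cohort of scheduled patients. Each patient's
visit is a *care pathway*: an ordered chain of activities (Intake,
Radiology Tech, Provider, Ortho Tech, Discharge, ...), each requiring one
or more units of specific resource types and lasting a random number of
whole minutes. Resource units are heterogeneous and capacitated: unit `j`
can serve at most `k_j` activities simultaneously (a technician may
supervise several patients at once). The objective is to assign activities
to concrete units and fix a pairwise service sequence *before* durations
are realized, so that the expected total patient waiting time — the sum
over activities of (start time − release time), where the release is the
appointment time for a patient's first activity and the predecessor's
completion for the rest — is minimized.

## Two-stage stochastic MILP

First-stage binaries: assignment `x[a,j]`; sequencing indicators
`s1[a,a']` (`a` does not start before `a'`) and `s2[a,a']` (`a` starts
before `a'` ends), instantiated for ordered pairs of distinct activities
sharing at least one required resource type (both directions of a pair are
instantiated; the constraints are asymmetric); and concurrency indicators
`q[a,a',j]`. Second-stage continuous start times `b_a ≥ 0` are chosen per
duration scenario. Constraints:

- assignment counts: `Σ_{j∈J_g} x[a,j] = V[a,g]`;
- linkage: `q[a,a',j] ≥ s1 + s2 + x[a,j] + x[a',j] − 3`;
- capacity: `Σ_{a'} q[a,a',j] ≤ k_j − 1` for every unit `j` and activity
  `a` requiring `j`'s type — concurrency is controlled at activity start
  times only, which suffices because concurrency on a unit increases only
  at starts;
- releases and precedence on `b`;
- big-M disjunctions tying `(s1, s2)` to the start times, with a 1-minute
  strictness constant, replicated per scenario under the sample average
  approximation (SAA). The objective is the scenario-average total wait.

No time-indexed or rank-indexed variables are used, so model size is
independent of the horizon length. The horizon `u` is carried as metadata
for reporting and generator bounds; no `b ≤ u` constraint is added (the
formulation presumes the session is long enough to serve everyone).

Because `s1`/`s2` are first-stage, the *relative order* of any two
same-type activities is planned once and shared by all scenarios. A
consequence worth knowing: even with non-binding capacity, a stochastic
instance can have strictly positive optimal expected wait, because a
fixed order cannot track scenarios in which the natural (zero-wait) start
order flips. Zero wait is guaranteed for single-patient instances and for
ample-capacity instances whose natural start order is scenario-invariant
(e.g. zero-variance durations).

### Numerical choices

- Big-M default: `M = max_a t_a + Σ_a d_a^max + 1`, computed per instance
  and scenario set (`d_a^max` the largest sampled duration). Smallest
  easily-provable constant keeping all relaxed disjunctions slack; a
  doubling test confirms the optimum is M-invariant.
- Durations: continuous log-normal draws rounded half-up to whole minutes
  and clamped to ≥ 1. Mean-value durations use the same rule.
- Start times stay continuous; with integer data the optimal basis is
  integral, so optima coincide with integer-time schedules.
- Solver: HiGHS branch-and-cut via `scipy.optimize.milp`; default relative
  MIP gap 1e-4, default time limit 3600 s per model. Solutions carry the
  solver's gap rather than an assumed certificate. The evaluation stage
  (fixed binaries) decouples into one small LP per scenario, solved with
  `scipy.optimize.linprog`. The `threads` setting is accepted for
  configuration compatibility but this backend is single-threaded.

### Evaluating a fixed first stage on fresh scenarios

With binaries fixed, each scenario's model reduces to release, precedence,
order (`s1`) and separation/overlap (`s2`) constraints on `b`. A planned
overlap (`s2 = 1`, "a starts before a' ends") can clash with precedence
when the realized `d_{a'}` shrinks; the scenario would be infeasible. The
package then drops the overlap constraint for the offending pairs only
(found by an elastic LP) and marks the scenario as relaxed. Starting later
than planned can only reduce concurrency, so the capacity plan remains
safe; the independent audit re-checks every relaxed schedule. Scenarios
are never resampled, keeping all evaluations comparable.

## Monte Carlo Optimization (MCO)

The SAA optimum over N scenarios is a statistical lower bound on the true
optimum (in expectation); evaluating the resulting first stage on N' fresh
scenarios gives an upper bound. Per iteration, K independent replicates
each draw N+N' i.i.d. scenarios, solve the SAA on the first N and evaluate
on the last N'; the bound averages give the Approximate Optimality Index
`AOI = |v̄_N' − v̄_N| / v̄_N'` (defined as 0 when both vanish). The loop
stops when `AOI < ε`, else doubles N (geometric growth reaches an adequate
sample size in few expensive iterations; the growth rule and K are
genuinely open design choices — defaults K = 10, ε = 0.05). The retained
first stage is the replicate with the best simulation value; the final
iteration's simulation scenario sets are kept for the baseline comparison.

Replicate seeds derive from a master seed by `numpy` seed-sequence
spawning, so every reported number is recomputable from (config, seed).

## Value of the Stochastic Solution (VSS)

The mean-value baseline solves the deterministic model at rounded mean
durations and fixes its first stage. Both first stages are evaluated on
the *same* retained scenario sets, giving `v̄_base` and `v̄_sim`. We report
`VSS = v̄_base − v̄_sim` (positive = stochastic better; the literal
estimator with the opposite sign is included in the CLI summary metadata)
and the ratio `VSS / v̄_base`, the relative waiting-time reduction. In
finite samples VSS may be slightly negative; it should not fall below
about two standard errors of the paired difference.

## Synthetic RTLS generator

The generator emulates a two-stream RTLS export: patient room occupancies
(patient id, visit start/end, move start/end, room name/id) and resource
room presences (resource id, resource type, room name, room type,
start/end). The resource stream carries an explicit `resource_type`
column; deployments that keep type in a separate master table can join it
in before parsing. For each visit a pathway is sampled by proportion,
activity durations are drawn from the profile log-normals, activities are
laid out back-to-back alternating between two rooms dedicated to the
visit (so consecutive same-type activities remain separable), and one
resource row per required unit co-locates exactly with the activity.
Visits start at fixed arrival intervals (default 10 minutes — about six
arrivals per hour; stochastic arrivals and no-shows are out of scope).

What the generator does *not* emulate: localisation noise and wrong-room
records, patient time alone in rooms between activities, staff presence
not related to care, room contention, and overlapping visits sharing
rooms. Mining tests on synthetic logs therefore validate the segmentation
and grouping logic, not robustness to raw RTLS noise. Parsing drops rows
with inverted intervals or missing identifiers and reports counts, which
covers the gross error modes.

Mining defaults: co-location threshold 1 minute (segments shorter than
this are discarded); activity identity is the *type multiset* of
co-located resources, so a unit swap of the same type does not split an
activity; rooms are carried through mining but are not treated as
capacitated resources.

## Bundled pathway profiles

`careflow.profiles.ORTHO_CLINIC_PROFILES` ships five dominant orthopedics
pathways (proportions 38.03/24.55/13.93/13.78/9.71%, log-normal moments in
minutes) used as the default study conditions. The Ortho Tech activity is
the bottleneck: mean ≈ 11-12.5 min with variances ≈ 185-233 min², i.e. a
heavy right tail that drives the value of modelling uncertainty. In the
default resource pool, Radiology Tech, Provider and Ortho Tech are
capacitated (one unit, capacity 1 unless configured otherwise) while
Intake and Discharge get capacity equal to the cohort size so they never
bind.

## Problem sizes used in the test suite

The shipped tests and the reproduction script run at desk scale: tiny
randomized instances (2-3 patients, chains ≤ 3) against an exhaustive
oracle; a seeded 4-patient instance with N0 = 20, N' = 100, K = 5 for the
bound-sandwich check; 3-5 patient instances for AOI and VSS studies; and
100,000 synthetic visits for mining recovery. Larger cohorts (the 20-patient,
10-minute-interval setting) are supported by the same code paths but
require hours of branch-and-cut time per trial; the experiment driver
treats unit counts and capacities as sweep dimensions.

## Known limitations

- Arrivals are deterministic and equal-interval; no-shows, lateness and
  stochastic inter-arrival times are not modelled.
- No preemption, no overtime cost; the horizon is reporting metadata.
- The evaluation-stage relaxation (dropping clashing planned overlaps) is
  a modelling decision where the formulation is silent; it is conservative
  for capacity but makes the simulation bound slightly optimistic in
  heavily congested, high-variance settings.
- The brute-force oracle is exponential and restricted to ≤ 14 activities;
  it exists only to certify the MILP on tiny instances.
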