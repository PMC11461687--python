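# careflow

Care-pathway mining and stochastic multi-resource scheduling for
outpatient clinics.

Clinics that deploy Real-Time Location Systems (RTLS) collect time-stamped,
room-level traces of patients and staff. `careflow` turns those traces into
operational decisions in two steps:

1. **Pathway mining.** Patient and resource location logs are intersected
   into *co-location activities* (maximal intervals in which a patient
   shares a room with a fixed multiset of resource types). Visits with
   identical activity-type sequences are grouped into dominant pathways
   with occurrence proportions, and each activity's duration gets a
   log-normal model fitted by moment matching
   (`σ² = ln(1 + v/m²)`, `μ = ln m − σ²/2`).
2. **Stochastic scheduling.** Given a scheduled cohort, a heterogeneous
   resource pool with per-unit capacities `k_j`, and the mined duration
   models, a two-stage stochastic mixed-integer linear program assigns
   activities to units (`x`), fixes a pairwise service sequence
   (`s₁, s₂, q`) before durations are known, and chooses per-scenario
   start times `b` afterwards, minimizing the expected total waiting time

   ```
   min E[ Σ_{a∈A₀} (b_a − t_a) + Σ_{a∈A₁} (b_a − b_pre(a) − d_pre(a)) ]
   ```

   subject to assignment (`Σ_{j∈J_g} x_j^a = V_{a,g}`), capacity at
   activity starts (`Σ_{a'} q_{a,a'}^j ≤ k_j − 1` with
   `q ≥ s₁ + s₂ + x_j^a + x_j^{a'} − 3`), release, precedence, and big-M
   sequencing disjunctions. The expectation is handled by a Sample Average
   Approximation (SAA); a Monte Carlo Optimization (MCO) loop grows the
   sample size N until the relative gap between the statistical lower
   bound (average SAA optimum, `v̄_N`) and upper bound (average fixed
   first-stage simulation value, `v̄_N'`) — the Approximate Optimality
   Index, `AOI = |v̄_N' − v̄_N| / v̄_N'` — drops below a tolerance. The
   Value of the Stochastic Solution (VSS) compares the result against a
   deterministic mean-duration baseline on a common scenario set.

The MILP uses no time-indexed or rank-indexed variables, so model size is
independent of the session length. The solver backend is HiGHS via
`scipy.optimize.milp`. See `docs/methods.md` for the full model and the
design decisions.

## Worked example

```python
import careflow as cf

profiles = cf.ORTHO_CLINIC_PROFILES          # five dominant pathways
cohort   = cf.sample_cohort(profiles, n_patients=4, arrival_interval=10, seed=7)
pool     = cf.ResourcePool.clinic_default(4) # 1 unit each of Radiology Tech,
                                             # Provider, Ortho Tech (k=1)
inst     = cf.build_instance(cohort, profiles, pool)

mco = cf.run_mco(inst,
                 cf.MCOConfig(n0=20, n_prime=100, replicates=5,
                              epsilon=0.05, master_seed=11),
                 cf.SolverConfig(time_limit=600))
it = mco.final
print(f"N={it.n}  v_N={it.v_bar_opt:.2f}  v_N'={it.v_bar_sim:.2f}  AOI={it.aoi:.4f}")
vss = cf.compute_vss(inst, mco)
print(f"VSS={vss.vss:.2f} min  ratio={vss.ratio:.3f}")
```

Output:

```
N=20  v_N=33.83  v_N'=34.26  AOI=0.0126
VSS=-6.42 min  ratio=-0.230
```

Read: with 20 optimization scenarios the average SAA optimum predicts
33.8 minutes of total cohort waiting; simulating the fixed plan on 100
fresh scenarios gives 34.3 minutes, so the plan is within 1.3% of optimal
(AOI ≤ 0.05, converged in one iteration). The VSS here is negative —
at only 4 patients and 5 replicates, the paired difference between the
stochastic and the mean-value plan (−6.4 ± 6.4 minutes) is within
sampling noise; the stochastic advantage emerges as congestion grows.

The same pipeline is scriptable from the shell:

```bash
careflow synth-rtls --n-visits 2000 --seed 5 --out-prefix logs
careflow mine --patient-log logs_patients.csv --resource-log logs_resources.csv \
              --top-k 5 --out profiles.csv
careflow build-instance --profiles profiles.csv --out instance.json
careflow mco --instance instance.json --out-prefix run1
```

Every command writes a JSON run manifest (inputs, digests, seeds,
resolved configuration) sufficient to replay it.

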