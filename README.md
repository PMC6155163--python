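# shelfweb

Food-web modelling for exploited, invaded, warming shelf seas.

`shelfweb` implements the modelling chain used to project cumulative-stressor
futures for coastal ecosystems that are simultaneously fished, invaded by
warm-water alien species and exposed to rapid sea warming: a mass-balance
snapshot of the food web, foraging-arena temporal dynamics with temperature
response functions, an eleven-scenario stressor engine (fishing regulations ×
RCP warming × alien-biomass forcing), an ecological-indicator suite,
pedigree-based Monte Carlo uncertainty, and Spearman trend analysis. A
synthetic-web generator supplies balanced, locally stable test ecosystems so
the whole chain runs without any external data.

It is aimed at ecosystem modellers and fisheries scientists who want a
scriptable, tested, fully reproducible implementation of this workflow.

## The model

**Snapshot.** Each functional group i satisfies the trophic mass balance

    B_i · PB_i · EE_i = Σ_j B_j · QB_j · DC_ij + Y_i + BA_i + E_i

with biomass B (t km⁻²), production/biomass PB and consumption/biomass QB
(yr⁻¹), ecotrophic efficiency EE, diet composition DC, fisheries removals Y,
biomass accumulation BA and net export E. For each group one of {B, EE} is
unknown; the solve is linear and a model is balanced iff every EE ∈ [0, 1].

**Dynamics.** Biomass then evolves as

    dB_i/dt = (P/Q)_i Σ_j Q_ji − Σ_j Q_ij + I_i − (M_i + F_i + e_i) B_i

with each predator–prey flow following foraging-arena theory,

    Q_ij = a_ij v_ij B_i P_j T_i T_j M_ij / D_j
           ─────────────────────────────────────────── · f(Env, t)
           v_ij + v_ij T_i M_ij + a_ij M_ij P_j T_j / D_j

where v is the vulnerability exchange rate between the invulnerable and
vulnerable prey pools, a the effective search rate, and f ∈ [0, 1] a
trapezoidal temperature response (anchored at min/q10/q90/max) that limits a
group's foraging away from its thermal optimum. Calibration inverts the flow
equation at the balanced snapshot, so every simulation starts at an exact
equilibrium; vulnerability is exposed as a dimensionless multiplier k > 1
(default 2; 10 for newly arrived alien groups still far from capacity).

**Scenarios, indicators, uncertainty.** Eleven scenarios combine constant or
regulated fleet effort (trawl ×0.50, artisanal ×0.85, recreational ×0.80,
optionally a 3-year trawl closure), constant or RCP2.6/4.5/8.5 SST tracks,
and free, trend-forced or constant alien biomass, over a 50-year horizon.
Eleven indicators (TotalB, ForF, InvB, PredB, Kempton's Q, TotalC, mTLc,
mTLco, TST, FCI, PL) summarise each run; 500 Monte Carlo replicates drawn
from the parameter pedigree give 5%/95% envelopes; Spearman's rank
correlation against time flags significant trends (p ≤ 0.05).

## Worked example

```python
from shelfweb import (GeneratorConfig, generate_web, generate_baseline_forcing,
                      calibrate, simulate, build_scenario, compute_trophic_levels,
                      indicator_series, spearman_trend, new_alien_k_overrides)

cfg = GeneratorConfig(seed=1)                      # 12 groups, 3 fleets
model, responses, pedigree = generate_web(cfg)     # balanced snapshot
params, dyn = calibrate(model, k_overrides=new_alien_k_overrides(model))
baseline = generate_baseline_forcing(cfg, model=model)

forcing = build_scenario(3, baseline, horizon=50)  # regulations + trawl closure
result = simulate(model, params, dyn, forcing, years=50, responses=responses)
ind = indicator_series(result, model, dyn)
for name in ("PredB", "mTLco", "TotalC", "FCI"):
    t = spearman_trend(ind[name])
    print(f"{name:6s} 2011={ind[name].iloc[0]:8.3f}  2060={ind[name].iloc[-1]:8.3f}  "
          f"rho={t.rho:+.2f}  p={t.p_value:.3g}")
```

prints

```
PredB  2011=   0.405  2060=   0.611  rho=+1.00  p=0
mTLco  2011=   1.989  2060=   2.024  rho=+1.00  p=0
TotalC 2011=   1.757  2060=   0.572  rho=+0.66  p=1.74e-07
FCI    2011=   5.145  2060=   5.139  rho=+0.56  p=2.76e-05
```

Closing the trawl fishery lets predatory biomass (PredB, t km⁻²) rise
steadily and shifts the community toward higher trophic levels (mTLco),
while total catch drops to what the remaining fleets land — the classic
signature of an effort-reduction recovery.

The same pipeline is available from the shell:

```sh
shelfweb synth --seed 1 --out model/
shelfweb simulate model/ --scenario scn.yaml --out results/   # scn.yaml: {id: 3}
shelfweb trends results/
shelfweb montecarlo model/ --scenario scn.yaml -n 500 --seed 42 --out results/
```

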