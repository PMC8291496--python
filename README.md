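# amylokin

Analysis of amyloid aggregation kinetics and aggregation-inhibitor
screening assays: thioflavin-T (ThT) time courses, endpoint inhibition
and fibril-disaggregation plates, and bacterial (in cellulo) thioflavin-S
screens.

Amyloid-β fibrillation monitored by ThT fluorescence produces a
sigmoidal curve — a lag phase while nuclei form, a fast growth phase as
fibrils elongate, and a plateau.  `amylokin` models the fraction of
aggregated peptide *f*(*t*) as an autocatalytic two-step reaction,

```
df/dt = k (1 − f)(ρ + f),   f(0) = 0
⇒  f(t) = ρ (e^{(1+ρ)kt} − 1) / (1 + ρ e^{(1+ρ)kt})
```

where `k = k_e·a` combines the elongation rate constant `k_e`
(M⁻¹ s⁻¹) with the initial monomer concentration `a` (M), and
`ρ = k_n/k` is the dimensionless ratio of the nucleation rate constant
`k_n` (s⁻¹) to `k`.  Nonlinear regression of *f* against *t* yields
(ρ, k), hence `k_n = ρ·k` and `k_e = k/a`.  The tangent at the curve's
inflection point, extrapolated to *f* = 0 and to the plateau, defines
the lag time `t0` and the end time `t1`; `t_half` is the time at
*f* = 1/2.  Comparing fits with and without a compound quantifies
whether it acts on nucleation (fold decrease in `k_n`, longer lag) or on
elongation (fold decrease in `k_e`, shallower growth).

Endpoint screens reduce to a two-point normalization between controls:
percent inhibition in vitro (aggregated DMSO control = 0%, monomer
blank = 100%), fibril disaggregation (fibril control = 0%, monomer
control = 100%), and the in cellulo ThS screen in *E. coli*
overexpressing Aβ42 or tau (induced DMSO culture = 0%, non-induced
culture = 100%), each reported as mean ± SEM over replicates with an
OD620 growth-toxicity flag.

A synthetic-data module generates ThT traces (5-minute sampling,
multiplicative Gaussian noise, triplicates) and endpoint plates with
known true percentages, so every analysis step can be validated by
closure: simulate → analyze → recover.

## Worked example

Simulate triplicate ThT time courses for uninhibited Aβ40 aggregation
(`k_n = 3.09×10⁻⁵ s⁻¹`, `k_e = 486.9 M⁻¹s⁻¹`, 10 μM peptide) and for a
nucleation inhibitor (`k_n = 1.45×10⁻⁶ s⁻¹`, `k_e = 299.5 M⁻¹s⁻¹`) with
5% noise, then fit and compare:

```python
from amylokin import (KineticParameters, GeneratorConfig, generate_timecourse,
                      fit_condition, compare_kinetics, characteristic_times)

a = 1e-5  # 10 uM
control = KineticParameters(k_n=3.09e-5, k_e=486.9, a=a)
treated = KineticParameters(k_n=1.45e-6, k_e=299.5, a=a)

fits = {}
for name, params in [("control", control), ("compound", treated)]:
    span = 2 * characteristic_times(params).t1
    traces = generate_timecourse(GeneratorConfig(params=params, t_span=span,
                                                 noise_cv=0.05, seed=42))
    r = fits[name] = fit_condition(traces, a, "averaged")
    print(f"{name:9s} k_n = {r.params.k_n:.3g} 1/s   k_e = {r.params.k_e:.4g} 1/(M s)   "
          f"t0 = {r.times.t0:.0f} s   t_half = {r.times.t_half:.0f} s   t1 = {r.times.t1:.0f} s")

c = compare_kinetics(fits["control"], fits["compound"])
print(f"nucleation fold decrease: {c.k_n_fold:.1f}   lag extension: {c.delta_t0:.0f} s")
```

Output:

```
control   k_n = 3.68e-05 1/s   k_e = 462.4 1/(M s)   t0 = 615 s   t_half = 1040 s   t1 = 1466 s
compound  k_n = 1.42e-06 1/s   k_e = 303.7 1/(M s)   t0 = 1867 s   t_half = 2525 s   t1 = 3183 s
nucleation fold decrease: 26.0   lag extension: 1253 s
```

The fitted constants recover the generator values to within the noise
(the elongation constants within ~5%, the nucleation constant — the
hardest parameter under 5% noise — within a factor reflecting its small
leverage on the curve), and the comparison correctly identifies a
strong nucleation block: a >20-fold drop in `k_n` and a lag phase
extended by roughly 1300 s, while `k_e` changes by less than 2-fold.

The same pipeline is available from the shell:

```bash
amylokin simulate --config sim.yaml          # writes timecourse.csv
amylokin fit      --config fit.yaml          # writes kinetics.csv
amylokin screen   --config screen.yaml       # endpoint plate -> screen.csv
amylokin disagg   --config disagg.yaml       # disaggregation plate
amylokin report   --config report.yaml       # control-vs-treated comparison
```

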