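# nkassay

Quantification and Bayesian inference for in vitro NK-cell killing assays.

Natural killer (NK) cells regulate adaptive immunity partly by killing
activated CD4+ T cells. Flow-cytometry co-culture assays measure this:
dye-labelled conventional (Tconv) or regulatory (Treg) CD4+ T cells are
cultured with sorted CD56-bright or CD56-dim NK effectors, and the dead-cell
fraction is read out with a viability dye. `nkassay` implements the full
quantification chain for such assays, for immunologists and biostatisticians
who want the analysis reproducible and testable end to end:

1. **Generation deconvolution** — a proliferation dye halves its
   fluorescence each division, so the log10 intensity histogram is a
   Gaussian mixture with peaks at `mu0 - g*log10(2)` for generation *g*.
   `DyePeakMixture` fits this constrained mixture by EM (fixed spacing,
   shared SD, free weights) and assigns each cell its maximum-posterior
   generation.
2. **Proliferation indices** — from per-generation counts `n_g` and
   precursor counts `P_g = n_g / 2^g`: percent divided
   `sum_{g>=1} n_g / sum n_g`, division index
   `DI = sum g P_g / sum P_g`, proliferation index
   `PI = sum_{g>=1} g P_g / sum_{g>=1} P_g`, plus paired t-tests between
   matched populations.
3. **Specific killing** — dead fraction in co-culture minus the dead
   fraction of the same population cultured without NK cells, computed over
   all cells and stratified by proliferative state (high = ≥2 divisions at
   day 2.5, ≥3 at day 3.5) with matched-stratum background subtraction.
   All acquired cells are counted; dead cells are never gated out.
4. **Beta regression** — killing proportions are modelled as
   `y ~ Beta(mu*phi, (1-mu)*phi)` with
   `logit(mu) = alpha + beta_group + gamma_pair`, weakly informative priors,
   and MCMC sampling (4 chains, 2500 warmup + 2500 kept). Effects are
   reported as posterior medians, equal-tailed 95% credible intervals,
   per-draw fold changes between pair-marginalized group means, and the
   false sign rate (FSR): the posterior mass on the sign opposite the
   median.

A synthetic-data module (`nkassay.simulate`) generates event-level cohorts
with the paired-donor structure, dye-dilution physics, spontaneous death and
proliferation-dependent killing the analysis assumes, so every stage is
testable without instrument exports.

## Worked example

```python
import pandas as pd
from nkassay import (SimConfig, simulate_panel, build_killing_table,
                     BetaRegression)
from nkassay.pipeline import deconvolve_panel

cfg = SimConfig(n_donors=6, day_assignment=(2.5,)*4 + (3.5,)*2,
                cells_per_population=5_000, seed=7)
events = simulate_panel(cfg)

generations, models = deconvolve_panel(events)
m = models[("D01", "Tconv")]
print(f"D01/Tconv peaks: mu0={m.mu0_:.3f}, sigma={m.sigma_:.3f}")

records = build_killing_table(events, generations)
r = records[(records.effector == "CD56br") & (records.target == "Tconv")
            & records.stratum.isin(["high", "low"])]
model = BetaRegression(random_state=1).fit(
    pd.DataFrame({"group": r.stratum, "pair": r.donor_id}),
    r.specific_killing)
for level in ("high", "low"):
    s = model.group_summary(level)
    print(f"{level}: median {s.median:.1%} [{s.ci_low:.1%}, {s.ci_high:.1%}]")
fc = model.fold_change(("high", "low"))
print(f"fold change high:low = {fc.median:.2f} "
      f"[{fc.ci_low:.2f}, {fc.ci_high:.2f}], FSR = {fc.fsr:.2%}")
```

Output:

```
D01/Tconv peaks: mu0=4.501, sigma=0.080
high: median 24.3% [21.7%, 27.3%]
low: median 19.1% [16.7%, 21.9%]
fold change high:low = 1.27 [1.07, 1.53], FSR = 0.78%
```

The fitted peak model recovers the configured dye parameters (undivided peak
at 4.5, within-generation SD 0.08). Highly proliferative Tconv cells are
killed more than their lowly proliferative counterparts — the posterior
median specific killing is 24.3% vs 19.1% — and the fold change of 1.27
with FSR 0.78% says the posterior leaves under 1% probability that the
direction of the effect is reversed. (This small 6-donor example is noisier
than the default 14-donor cohort.)

The same stages are available as a CLI:

```sh
nkassay simulate --config sim.toml --out events.csv
nkassay prolif  --events events.csv --out prolif.json --assign-out gens.csv
nkassay killing --events events.csv --generations gens.csv --out records.csv
nkassay fit     --records records.csv --contrast high:low --out fitdir/
nkassay run     --config sim.toml --seed 1 --out outdir/   # end to end
```

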