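# mirharmonic

Statistical validation of growth-increment periodicity from marginal
increment ratio (MIR) data, for sclerochronologists and fisheries
biologists who need more than a plot of monthly means.

Counting growth bands in shells, otoliths or vertebrae gives an age only
if the bands' deposition period is known. The MIR — the forming increment
as a percentage of the last completed one, MIR = MI/PI × 100 — cycles
through that period, so a population sampled across the year encodes the
periodicity in its MIR-versus-month trajectory. `mirharmonic` fits that
trajectory with single- and second-order harmonic (Fourier) curves,

ψ(t) = β₀ + β₁ sin(2πt/γ) + β₂ cos(2πt/γ) [+ β₃ sin(4πt/γ) + β₄ cos(4πt/γ)],

by maximum likelihood under multiplicative lognormal error, with the
period γ **estimated**, not fixed: γ ≈ 12 months is the annual-deposition
conclusion. Parameter uncertainty comes from profile-likelihood intervals
at the χ²(1) threshold 3.84; the symmetric-versus-asymmetric choice
between the nested curves is a likelihood-ratio test. A companion module
checks the underlying assumption that band proportions are age-invariant
(increment ratio IR_i = GI_i/GI_{i−1} × 100 regressed on age).

## Worked example

Simulate a year of monthly sampling (25 individuals/month) around an
asymmetric annual cycle with realistic dispersion, then fit and compare
both models:

```
$ mirharmonic simulate --order 2 --beta 58 -22 -29 --beta2nd -8 -5 \
    --gamma 12 --n-per-month 25 --sigma-log 0.3 --seed 7 --out mir.csv
wrote 300 records to mir.csv

$ mirharmonic compare mir.csv --out-dir out
-2lnL: H1=290.79  H2=157.53  LRT=266.51 vs 3.84 -> prefer H2

$ mirharmonic profile mir.csv --order 2 --out-dir out
param  value  lower_LI  upper_LI
beta0  55.88     54.49     57.30
beta1 -20.68    -23.07    -18.28
beta2 -28.39    -30.71    -26.09
beta3  -8.27    -10.04     -6.49
beta4  -4.92     -6.50     -3.35
gamma  12.03     11.94     12.12
```

Reading the output: the second-order curve fits far better than the
symmetric one (the LRT statistic, twice the drop in −2 ln L, dwarfs the
3.84 criterion), every generating amplitude is inside its likelihood
interval, and the estimated period γ = 12.03 with likelihood interval
(11.94, 12.12) brackets 12 months — the analysis recovers the annual,
asymmetric deposition cycle it was given. On real data you would start
from `mirharmonic fit your_table.csv` (CSV or XLSX with columns
`sample_id, month, year, mir, age`; a differing MIR header is remapped
with `--mir-col "MIR %"`).

The same pipeline is available as a library:

```python
from mirharmonic import read_mir_table, fit, likelihood_ratio_test, interval_table

data = read_mir_table("mir.csv", species_label="demo")
h1, h2 = fit(data, 1), fit(data, 2)
print(likelihood_ratio_test(h1, h2).preferred_order)
print(interval_table(data, h2))
```

Fits apply the two-period replication convention (each record at month t
paired with a copy at t + 12) by default; disable with
`FitConfig(replicate=False)` or `--no-replicate`. The reported `n_used`
always states the count that entered the objective.

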