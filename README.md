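# cav3ephys

Quantitative electrophysiology of Cav3.3 (CACNA1I) T-type calcium channel
variants associated with hemiplegic migraine, plus the rare-variant allelic
burden analysis that links those variants to disease.

The package serves two audiences. For channel physiologists, it provides a
complete whole-cell voltage-clamp analysis pipeline — peak currents and
current densities, Boltzmann fits of activation and steady-state
inactivation, window-current areas, exponential-product kinetics fits, and
within-cell extracellular-pH modulation ratios — driven by its own
synthetic recording generator so that every stage of the analysis is
verifiable against known ground truth. For statistical geneticists, it
implements the aggregated allelic burden test of rare coding variants in
`CACNA1I` found in 187 hemiplegic-migraine probands against population
control cohorts.

## The models

**Channel gating.** The channel is a two-gate Hodgkin–Huxley model with an
activation gate m and an inactivation gate h, each relaxing first-order
toward voltage-dependent steady states

```
m∞(V) = 1 / (1 + exp((V05_act − V) / k_act))        (increasing)
h∞(V) = 1 / (1 + exp((V − V05_inact) / k_inact))    (decreasing)
```

with time constants τ_act and τ_inact, and ohmic current
I = g_max·m·h·(V − E_rev) (inward negative below the reversal potential).
Normalized conductance–voltage curves G/G_max and availability curves
I/I_max are fitted with the corresponding Boltzmann functions to recover
V0.5 and the slope factor k. Current transients at a depolarizing step are
fitted with the exponential product

```
I(t) = C · (1 − e^(−(t−t0)/τ_act)) · e^(−(t−t0)/τ_inact)
```

(C is the y-intercept scale; a small fitted sustained fraction lets the
decay end on the window-current plateau where availability does not reach
zero). The window current I_W is the area under the pointwise minimum of
the normalized activation and availability curves over [−90, +20] mV —
the voltage band of tonic Ca²⁺ influx — and variants are compared as
I_W(variant)/I_W(WT).

**Allelic burden.** Alternate alleles are aggregated across all rare
(MAF < 0.01) variants: per variant, round(MAF·2N) alleles out of 2N, so a
cohort contributes Σ round(MAF_i·2N) alternate alleles out of 2NV for V
variants. Case versus control aggregated frequencies form a 2×2 table
tested with the Pearson chi-square statistic (no continuity correction,
upper-tail χ²₁ p-value) and summarized by the aggregated-frequency odds
ratio.

## Worked example

Simulate a 12-cell wild-type cohort and recover its gating parameters:

```python
from cav3ephys import characterize_construct

df = characterize_construct("WT", n_cells=12, seed=42)
m, s = df.mean(numeric_only=True), df.sem(numeric_only=True)
for k in ("density", "act_v05", "act_slope", "inact_v05",
          "inact_slope", "tau_act", "tau_inact"):
    print(f"{k:12s} {m[k]:8.1f} +/- {s[k]:.1f}  (n={len(df)})")
```

```
density         207.7 +/- 36.5  (n=12)
act_v05         -20.2 +/- 0.3  (n=12)
act_slope         6.0 +/- 0.0  (n=12)
inact_v05       -47.6 +/- 0.4  (n=12)
inact_slope       6.8 +/- 0.0  (n=12)
tau_act           4.6 +/- 0.0  (n=12)
tau_inact        40.9 +/- 0.0  (n=12)
```

The cohort mean current density (207.7 pA/pF) and the fitted activation
(V0.5 ≈ −20.2 mV, k ≈ 6.0 mV), inactivation (V0.5 ≈ −47.6 mV, k ≈ 6.8 mV)
and kinetics (τ_act 4.6 ms, τ_inact 40.9 ms) recover the wild-type
generating parameters (208.4 pA/pF; −20.6/5.8; −47.1/6.9; 4.6/40.9).

The burden test against the UK Biobank control cohort (~43,000 subjects),
from the bundled 10-variant table:

```sh
cav3ephys burden --control-col ukbiobank_maf
```

```json
{
 "n_variants": 10,
 "case_alt": 17,
 "case_total": 3740,
 "ctrl_alt": 1687,
 "ctrl_total": 860000,
 "case_freq": 0.004545454545454545,
 "ctrl_freq": 0.0019616279069767442,
 "odds_ratio": 2.3231994326747922,
 "chi2": 12.62655384396153,
 "p_value": 0.0003803056273117036,
 "cohort": "ukbiobank_maf"
}
```

Seventeen alternate alleles among 187 cases (aggregated frequency 0.0045)
against 0.0020 in controls gives an odds ratio of 2.32 (χ² = 12.6,
P = 0.0004): a significantly increased rare-variant burden in cases.

Other entry points: `cav3ephys simulate` writes synthetic cohorts as
JSON + CSV recordings, `cav3ephys analyze` emits per-cell fit tables
(`gv_fits.tsv`, `ssi_fits.tsv`, `kinetics.tsv`, `density.tsv`), and
`cav3ephys report` runs the six-construct pipeline end to end into a
`summary.json` (optionally with `--plots`).

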