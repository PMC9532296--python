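# flscea

Individual-level Markov microsimulation for the cost-effectiveness of
**fracture liaison services (FLS)** versus usual care in Chinese patients
aged 65+ with a recent fragility fracture.

Fracture liaison services are coordinated post-fracture care programs that
identify patients after a fragility fracture, assess them for
osteoporosis, and improve the initiation of and adherence to
anti-osteoporosis treatment. This package implements a full
health-economic evaluation of that intervention from the healthcare
perspective, with a lifetime horizon: a decision tree assigns each
simulated patient a treatment pathway (gender → FLS attendance →
osteoporosis status → alendronate initiation → adherence class), and a
Markov model in 6-month cycles then simulates subsequent hip, clinical
vertebral, and wrist fractures, post-fracture states, and death, with
tracker variables recording every fracture.

Core quantities, in standard cost-utility notation:

- per-patient lifetime discounted cost C and quality-adjusted life years
  Q, discounted at 5%/year: cycle payoffs × (1+r)^(−t);
- incremental cost-effectiveness ratio **ICER = ΔC/ΔQ** (FLS − no-FLS),
  with the *dominant* label when ΔC < 0 and ΔQ > 0;
- fracture probabilities from published annual rates via
  p = 1 − exp(−rate × 0.5), after osteoporosis-status calibration
  (i_OP / i_nonOP consistent with prevalence and the osteoporosis RR),
  the subsequent-fracture RR (1.95 ♀ / 3.47 ♂), and treatment efficacy;
- post-fracture excess mortality 1 + 0.25(RR − 1) applied to the life
  table after a simulated hip/vertebral fracture;
- time-dependent medication persistence (56% at 6 months … 6% at 5 years)
  with a linear post-discontinuation efficacy offset;
- the maximum one-off FLS fee keeping FLS cost-saving (ΔC = 0) or
  cost-effective at the Chinese willingness-to-pay threshold of
  US$10,500/QALY, solved in closed form from the linearity of ΔC in the
  fee and confirmed by a same-seed rerun.

Both arms are simulated under **common random numbers** — identical
per-patient and per-cycle random streams, different thresholds — so
incremental results are variance-reduced and every run is bit-for-bit
reproducible from one seed. An exact cohort-expectation oracle
(`cohort_oracle`, exhaustive state-space enumeration over short horizons)
validates the Monte-Carlo engine in the test suite.

See `docs/methods.md` for the full model description, structural
conventions, and limitations.

## Worked example

```bash
flscea run --n 100000 --seed 1 --out results/
```

prints (abridged):

```json
{
  "attendance_realized": 0.6613,
  "delta_cost": 165.2713782564411,
  "delta_qaly": 0.0011371412978738362,
  "fractures_avoided_per_100": {
    "hip": 0.012000000000000455,
    "vertebral": 0.06400000000000361,
    "wrist": 0.036999999999999034
  },
  "icer": 145339.35102476392,
  "mean_fee_burden": 132.26,
  "se_delta_cost": 1.020696516828184,
  "se_delta_qaly": 0.00018208992469013552
}
```

Reading: with the published base-case parameters, FLS costs an extra
US$165 per patient over a lifetime (the US$200 fee falls on the 66% who
attend — realized burden US$132 — plus extra therapy costs for the
additional initiators, partly offset by avoided fracture costs) and gains
0.0011 QALYs, an ICER of ≈ US$145,000/QALY. Under this implementation's
osteoporosis-gated treatment initiation, only ≈ 3 extra patients per 100
ever start therapy, so avoided fractures per 100 patients are small
(≈ 0.1 across sites) and FLS is *not* cost-saving at a US$200 fee — see
`docs/methods.md` for the structural conventions behind these numbers.

```bash
flscea thresholds --n 100000 --seed 1 --out results/
```

```json
{
  "confirmed_delta_cost_at_fee_saving": 2.1100277081131935e-15,
  "fee_cost_effective": -31.86359387383311,
  "fee_cost_saving": -49.91891464757464
}
```

A *negative* break-even fee means FLS as modelled is not cost-saving at
any positive fee; the confirmatory same-seed rerun at the solved fee
reproduces ΔC = 0 to floating-point precision. The one-way sensitivity
grid (32 rows: base case + 8 FLS-related + 23 other) runs with

```bash
flscea dsa --n 20000 --seed 1 --out results/
# single row: flscea dsa --scenario "Starting age: 80" ...
```

Library use mirrors the CLI:

```python
from flscea import default_parameters, run_comparison

params = default_parameters()           # the published base case
result = run_comparison(params, n=100_000, seed=1)
result.delta_cost, result.delta_qaly, result.icer
```

Parameter files are YAML overrides merged onto the base case
(`flscea run --config my.yaml`), e.g. `costs: {fls_fee: 400}`.

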