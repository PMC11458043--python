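# ppi-deprescribing-cea

Decision-analytic cost-effectiveness model of a pharmacist-led
proton-pump-inhibitor (PPI) deprescribing service versus usual care in
ambulatory patients aged ≥ 65, for health-economics analysts and
pharmacy-service planners.

Long-term PPI use in older adults is often inappropriate and raises the
risk of pneumonia, Clostridium difficile infection and hypomagnesemia.  The
model is a one-year, two-strategy decision tree: the deprescribing arm
branches over inappropriate use, the recommendation mix (discontinue /
dose-reduce / switch to H2RA), prescriber acceptance and GERD rebound with
reinstatement; every resulting drug exposure then branches over adverse
events with hospitalization and mortality.  Outcomes are expected direct
medical cost *C* (USD) and expected QALY loss *L* per patient evaluated.
Adverse-event risks in PPI users come from non-user rates p₀ and odds
ratios: p = OR·p₀ / (1 − p₀ + OR·p₀).  Deaths lose
u·(1 − (1+r)^−LE)/r QALYs (utility u, remaining life expectancy LE from a
configurable life table, discount rate r = 3%).  Strategies are compared by
incremental cost ΔC, QALYs saved ΔE, ICER = ΔC/ΔE, dominance, and net
monetary benefit NMB = λ·ΔE − ΔC at a willingness-to-pay
λ = USD 49,023/QALY (1× GDP per capita, Hong Kong).  One-way sensitivity
analysis produces a tornado ranking with threshold detection; probabilistic
sensitivity analysis samples all uncertain inputs from beta / gamma /
triangular distributions (10,000 draws, common draws across arms).

Every input lives in a YAML configuration; the bundled defaults
(`src/ppicea/data/table1_defaults.yaml`) encode the published Hong Kong
input set, so the whole analysis is reproducible and portable to other
settings by editing one file.

## Worked example

```python
import ppicea as pp

params = pp.load_parameters()          # bundled defaults
ev = pp.evaluate_base_case(params)
print(ev.summary())
```

prints

```
Cost-effectiveness of PPI deprescribing vs usual care (1-year horizon)
========================================================================
Strategy              Cost (USD)  Incr. cost   QALY loss  QALY saved
------------------------------------------------------------------------
Usual care               1,264.7           -      0.0747           -
Deprescribing            1,066.3      -198.5      0.0660      0.0088
------------------------------------------------------------------------
ICER: -22,669 USD/QALY (dominant)
Cost-effective at WTP 49,023 USD/QALY: yes   NMB: 627.7 USD
```

Deprescribing costs USD 198.5 less and loses 0.0088 fewer QALYs per patient
than usual care — it *dominates* (saves both money and health), so the
negative ICER is reported only for completeness.  The probabilistic
analysis:

```python
psa = pp.run_psa(params, n_draws=10_000, seed=1)
print(psa.summary()["proportions"])
```

gives `{'qaly_saving': 0.9988, 'cost_saving': 1.0, 'cost_effective_at_wtp': 1.0}`:
at the default inputs the service saves QALYs in 99.9% of draws and is
cost-effective in 100%.

The same analyses are available from the shell:

```
ppi-cea base-case --out-dir results/
ppi-cea owsa --out-dir results/
ppi-cea psa --n 10000 --seed 1 --out-dir results/
ppi-cea paths --out-dir results/          # terminal-path table
ppi-cea validate --config my_region.yaml
```

Each run writes CSV/JSON tables plus a `run_report.json` (config digest,
seed, version) sufficient to reproduce it exactly.

## Layout

| module | contents |
|---|---|
| `ppicea.parameters` | config loading/validation, distribution fitting, sampling |
| `ppicea.tree` | decision-tree structure, odds conversion, enumeration, rollback |
| `ppicea.payoffs` | medication / adverse-event / service costs, QALY losses |
| `ppicea.cea` | strategy rollup, ICER, dominance, NMB, `ModelEvaluation.summary()` |
| `ppicea.sensitivity` | one-way (tornado) and probabilistic sensitivity analysis, CEAC |
| `ppicea.scenarios` | synthetic verification trees, parameter perturbation |
| `ppicea.cli` / `ppicea.io` | `ppi-cea` command line and table exports |
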