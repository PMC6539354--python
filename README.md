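# dndea — dynamic network SBM-DEA with undesirable outputs

`dndea` measures the relative efficiency of decision-making units (DMUs —
cities, firms, hospitals, regions) whose production runs through **several
internal divisions**, over **several time periods**, and produces both
desirable and **undesirable outputs**. It implements a non-oriented,
variable-returns-to-scale slacks-based measure (SBM) in which:

* each division k has inputs x, good outputs y⁺ and bad outputs y⁻;
* **link variables** (e.g. CO₂ emissions, air-quality index) are produced by
  one division and consumed *as inputs* by another within the same period;
* **good carry-overs** (e.g. fixed-asset stock) connect a division's period t
  to period t+1, with a continuity constraint between consecutive periods.

It is aimed at efficiency analysts studying, e.g., how the economic
production stage of a city passes pollution on to a health-treatment stage
that spends public money and media attention to protect population health.

## The model

For the evaluated unit *o*, with intensity vectors λₖᵗ ≥ 0 (eλₖᵗ = 1, VRS)
over the n observed units, the overall efficiency is

```
θ*₀ = min  Σₜ Wᵗ Σₖ Wᵏ [ 1 − (1/(mₖ+linkinₖ)) ( Σᵢ sᵢ⁻/xᵢₒ + Σₗ sₗⁱⁿ/zₗₒ ) ]
           ─────────────────────────────────────────────────────────────────
           Σₜ Wᵗ Σₖ Wᵏ [ 1 + (1/(r1ₖ+r2ₖ+ngoodₖ)) ( Σᵣ sᵣ⁺/yᵣₒ + Σᵣ sᵣᵇ⁻/yᵣₒᵇ + Σ꜀ s꜀/z꜀ₒ ) ]
```

subject to the balance equations x₀ = Xλ + s⁻, y₀⁺ = Y⁺λ − s⁺,
y₀⁻ = Y⁻λ + sᵇ⁻, z₀ⁱⁿ = Zⁱⁿλ + sⁱⁿ (links enter the *receiving* division's
block), carry-over balance z₀ = Σⱼ zⱼλⱼᵗ − s꜀ and continuity
Σⱼ zⱼλⱼᵗ = Σⱼ zⱼλⱼᵗ⁺¹. Input and link excesses shrink the numerator;
desirable-output shortfalls, undesirable-output excesses and carry-over
shortfalls enlarge the denominator, so θ*₀ ∈ (0, 1] with θ*₀ = 1 exactly on
undominated units. The ratio program is linear-fractional and is solved
exactly by the Charnes–Cooper transformation and one LP (HiGHS) per unit,
plus a lexicographic second LP that makes the reported slacks deterministic.

Period, division and division-period efficiencies are read off the same
optimal slack profile as weighted partial ratios, and per-variable
**total-factor indices** (labor efficiency, energy efficiency, GDP
efficiency, …) are target/actual ratios computed from the optimal slacks.

## Worked example

```python
from dndea import generate_two_stage_panel, run_two_stage

panel = generate_two_stage_panel(n_dmu=6, n_periods=2, seed=3)
res = run_two_stage(panel.data)
print(res.summary(precision=4))
```

```
Dynamic Network SBM (non-oriented, VRS, undesirable outputs)
============================================================
DMUs: 6    Periods: 2    Divisions: 2
Division order: production, health_treatment
Period weights: [0.5, 0.5]
Division weights: [0.5, 0.5]
Efficient DMUs: 2 of 6

     overall    2013    2014
E01   1.0000  1.0000  1.0000
E02   1.0000  1.0000  1.0000
U01   0.6121  0.6224  0.6020
U02   0.3687  0.3767  0.3610
U03   0.6580  0.6617  0.6544
U04   0.6815  0.6782  0.6848
```

The synthetic panel plants E01/E02 on the efficient frontier, and the model
recovers exactly them at θ* = 1. The `overall` column is the horizon-wide
score θ*₀; the year columns are the period efficiencies ∂*₀(t), whose
weighted mediant reproduces θ*₀. `res.division_scores`,
`res.division_period_scores` and `res.factor_indices` hold the stage-wise
decomposition and the per-variable indices (an index of 1.0 means that
variable sits on its benchmark; 0.8 for an input means the benchmark uses
only 80 % of the observed amount).

The same pipeline runs from the shell:

```bash
dndea simulate --mode two-stage --n 31 --periods 4 --seed 1 --out sim/
dndea two-stage --data sim/panel.csv --out results/
dndea verify --results results/results.json --data sim/panel.csv --spec sim/spec.json
```

writing `overall.csv` (DMU × year period scores), `stages.csv`
(`2013-I, 2013-II, …` division-period scores), `factors.csv` (per-variable
indices) and a machine-readable `results.json`. Custom topologies are
described by a JSON spec plus a long CSV
(`dmu,period,division,variable,role,value`) and solved with `dndea solve`.

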