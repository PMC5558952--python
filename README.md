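# dendrocarbon

Lifetime carbon-accumulation trajectories of tropical trees, reconstructed
from annual tree-ring widths.

Old tropical trees are usually credited for *storing* carbon a long time;
whether they keep *accumulating* it at high rates into old age is harder to
answer, because inventory plots cover only a slice of a tree's life. Tree
rings solve this retrospectively: each ring is one year of diameter growth,
so a stem disc contains the tree's whole growth history. `dendrocarbon`
turns per-radius ring-width series (Tucson/RWL files or long-form tables)
into:

- a mean tree-ring series per tree (wedge rings excluded from the mean) and
  a cross-dating coherence report,
- the diameter trajectory `D[t] = 2·Σ w̄[i]/10` and annual increments,
- aboveground biomass via the height-free pantropical allometry
  `AGB = exp(−1.803 − 0.976·E + 0.976·ln ρ + 2.673·ln D − 0.0339·ln²D)`
  (D in cm, wood density ρ in g cm⁻³, site stress factor E), carbon stocks
  `C = cf·AGB`, and annual accumulation `ΔC[t]`,
- the percent of lifetime carbon accumulated in each quarter of life,
- nonparametric inference implemented from first principles: Cox–Stuart
  trend test (exact binomial), Pettitt change-point test, Dunn's rank test
  with tie correction, one-way ANOVA with Holm-adjusted pooled-SD t-tests,
  Pearson correlation,
- a deterministic four-way classifier of lifetime growth patterns
  (sustained increase / increase with depression / plateau / rise then
  decline),
- a seeded synthetic cohort generator that emulates the study population
  this pipeline targets (61 trees of three Surinamese species, ages 84–255
  years, final diameters 36.7–99.2 cm, multi-radius discs with wedge
  rings), with ground truth retained for recovery testing.

The scientific background, model assumptions, parameter defaults and known
limitations are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
from dendrocarbon import (
    default_config, simulate_cohort, mean_tree_series,
    reconstruct_diameter, carbon_trajectory, quartile_shares,
    cox_stuart, classify_pattern,
)

cohort = simulate_cohort(default_config(seed=42))
tree = cohort.records[0]                      # TreeRecord: CO001, C. odorata
mean = mean_tree_series(tree.radii)           # 6 radii -> one mean series
traj = reconstruct_diameter(mean)
ct = carbon_trajectory(traj, tree.wood_density, tree.stress_E,
                       tree.carbon_fraction)
print(round(traj.final_diameter_cm, 1), round(ct.final_carbon_kg, 1))
print(quartile_shares(ct).shares_percent.round(1))
print(cox_stuart(ct.carbon_kg).p_value)
print(classify_pattern(ct.annual_c_kg, tree_id=tree.tree_id).label)
```

prints

```
49.5 611.0
[26.1 25.3 24.4 24.2]
2.842170943040401e-14
plateau
```

i.e. this 92-year-old *C. odorata* reached 49.5 cm diameter and 611 kg of
carbon, spread almost uniformly over its life (≈25 % per lifetime
quarter). Its *cumulative* stock shows a highly significant increasing
trend (exact binomial Cox–Stuart p ≈ 2.8e-14), as any growing tree's
does, while its *annual* accumulation pattern is classified as a plateau —
near-constant yearly carbon uptake with no trend.

The same analysis as a narrative sequence over the default cohort:

```bash
python analysis/01_simulate_cohort.py      # cohort -> results/cohort/
python analysis/02_reconstruct_carbon.py   # trajectories + tables -> results/run/
python analysis/03_growth_patterns.py      # trends, change points, confusion matrix
python analysis/04_species_comparison.py   # ANOVA/Holm, Dunn, age~carbon correlation
```

or through the CLI:

```bash
dendrocarbon simulate --config default --seed 42 --out data/
dendrocarbon run --in data/ --out run/
dendrocarbon report --in run/
```

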