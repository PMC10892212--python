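# qsarmlr

QSAR modelling toolkit for multiple-linear-regression activity models with
genetic-algorithm descriptor selection, built around a fully reproducible
case study: inhibition of α-glucosidase (a key enzyme in type-2 diabetes
control) by 1,2,4-triazole derivatives.

It is written for modellers who have a compounds × descriptors table
(e.g. PaDEL output) with measured activities and want the classical
GA-MLR workflow with all the validation machinery the OECD principles ask
for:

1. **Objective feature pruning** — descriptors that are virtually constant
   (modal value on > 95% of compounds) or highly collinear (pairwise
   Pearson |r| > 0.90) are removed before any model search.
2. **GA-MLR subset selection** — a seeded genetic algorithm searches
   descriptor subsets (default sizes 4–6) for the model
   `y = a₀ + a₁x₁ + … + a_k x_k` maximising the leave-one-out
   cross-validated coefficient
   `Q²_LOO = 1 − PRESS/TSS`, with an exhaustive-enumeration oracle for
   small pools.
3. **Validation** — internal (Q²_LOO via the exact hat-matrix PRESS
   shortcut), external (Q²_F1, Q²_F2, Q²_F3 and squared Pearson r on a
   held-out test set), and a Y-randomization permutation null with the
   corrected statistic `cRp² = R·√(R² − R̄_r²)`.
4. **Applicability domain** — leverages `hᵢ = xᵢᵀ(XᵀX)⁻¹xᵢ`, the warning
   leverage `h* = 3(k+1)/n`, standardized residuals, and Williams-plot
   classification.
5. **Screening** — predictions, domain flags and activity ranking for
   designed candidate compounds.

A synthetic-data generator with planted linear signal, decoy descriptors,
engineered collinear pairs and near-constant columns makes every stage
testable against known ground truth.

## The built-in study

The package ships the descriptor matrix of 33 synthesized triazole
α-glucosidase inhibitors (descriptors AATSC8s, VE3_Dzs, nHsOH, CIC1,
RotBFrac; activities as pIC₅₀ = −log₁₀ IC₅₀; fixed 27/6 train/test split)
plus 7 designed candidate compounds, together with the published model
statistics, predictions and leverages, so the complete study can be
re-run from in-package data.

## Worked example

```python
from qsarmlr import fit_ols, load_reference_data, q2_loo, screen_candidates

data = load_reference_data()
train = data.synthesized.training_set()

model = fit_ols(train)
print(model.equation())
# pIC50 = 6.403 + 0.760 AATSC8s + 0.022 VE3_Dzs - 0.112 nHsOH - 0.338 CIC1 - 1.803 RotBFrac
print(f"R2 = {model.stats.r2:.3f}, RMSE = {model.stats.rmse:.3f}")
# R2 = 0.767, RMSE = 0.082

q2, press = q2_loo(train)
print(f"Q2_LOO = {q2:.3f}")
# Q2_LOO = 0.633

report = screen_candidates(model, train, data.designed)
print(report.to_frame()[["compound_id", "predicted_pIC50", "in_domain"]].head(3))
#   compound_id  predicted_pIC50  in_domain
# 0          P3         5.779316       True
# 1          P4         5.737426       True
# 2          P6         5.740702       True
```

The refit equation and statistics agree with the published model to the
printed precision; every designed candidate is predicted more active than
the best synthesized compound (pIC₅₀ = 5.680) and lies inside the
applicability domain (all leverages below h* = 0.667).

The `analysis/` directory contains the study as numbered narrative
scripts (`01_fit_reference_model.py` … `06_synthetic_benchmarks.py`);
each writes its tables under `results/`. The same pipeline is exposed on
the command line:

```
qsarmlr reproduce-study --iterations 500 --seed 1
qsarmlr simulate --n-compounds 150 --seed 7 --out synth.csv
qsarmlr fit --input synth.csv --split split --subset-size 4:6 --out model.json
```

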