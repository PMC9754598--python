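# carindex

City-level analysis of municipal budget priorities as a structural
determinant of health: the **Carceral Resource Index (CRI)** computed from
classified budget ledgers, seven **Index of Concentration at the Extremes
(ICE)** variants computed from census-style demographic count tables, and
the correlation / polynomial-regression analysis that relates them —
plus a synthetic-city cohort generator so the entire pipeline is testable
end to end without restricted data.

## Who this is for

Researchers in social epidemiology and health equity who want a
reproducible, auditable implementation of budget-priority indexing:
classify departmental appropriations into carceral, health, and social
support categories; score each city; and test whether racialized economic
segregation (ICE) predicts fiscal prioritization of carceral systems,
including the U-shaped (convex) relationship predicted by the social
conflict model.

## The indices

**CRI.** For one city-year adopted budget,

```
CRI = ((health + support) − carceral) / total budget
```

with CRI ∈ [−1, 1]: −1 means total fiscal prioritization of carceral
systems (police, corrections, prosecution and public defense, courts,
sheriffs, probation/community supervision) to the exclusion of health
(public health, health and human services, parks and public spaces) and
support (housing, neighborhood development, employment, community
engagement, arts and culture); +1 the reverse. Departments that straddle
the carceral and health/support systems (medical examiners, environmental
protection, child and family services, education) are excluded from all
three numerator categories; they and all unmatched "other" departments
(fire, transit, utilities, …) still count in the denominator.

**ICE.** For a privileged count A, a deprived count P, and denominator T,

```
ICE = (A − P) / T    ∈ [−1, 1]
```

Seven variants are computed (income, education, race, race×income,
race×homeownership; the "wpc" variants contrast white non-Hispanic
households with all households of color), each with the denominator of
its source table (households, adults ≥25, persons, occupied units).

**Models.** ICE variables are z-transformed and CRI is regressed on z and
z² (ordinary least squares) with DAG-chosen demographic covariates (age
≥65 share, non-Hispanic-White share, >$100k income share); a positive,
significant z² coefficient indicates the convex relationship. Bivariate
screens use Pearson's r for variables that are plausibly Gaussian
(Shapiro–Wilk, with an a-priori override list) and Spearman's ρ otherwise.

## Worked example

Generate a 50-city synthetic cohort (planted link: CRI = −0.59 + 0.47·z +
0.58·z² + ε on the z-scored white/Black+income ICE, ε ~ N(0, 0.25²)),
then run the full study:

```sh
carindex simulate --n-cities 50 --seed 8 --out-dir data
cat > study.yaml <<EOF
ledger_path: data/ledger.csv
income_path: data/income.csv
education_path: data/education.csv
race_path: data/race.csv
tenure_path: data/tenure.csv
age_path: data/age.csv
crime_path: data/crime.csv
out_dir: out
EOF
carindex analyze --config study.yaml
```

which prints

```
50 cities; median CRI -0.1155 (IQR -0.2684, +0.1623)
Model 1 [ice_income]: adj R^2 = 0.311, quadratic +0.5137 (p = 0.0004)
Model 2 [ice_education]: adj R^2 = 0.316, quadratic +0.4028 (p = 0.0018)
Model 3 [ice_wb_income]: adj R^2 = 0.313, quadratic +0.6156 (p = 0.0000)
Model 4 [ice_wpc_income]: adj R^2 = 0.307, quadratic +0.5856 (p = 0.0000)
```

Reading this: the cohort median CRI and its interquartile range summarize
how far budgets tilt toward carceral spending (negative = carceral-
leaning). Each model regresses CRI on one z-scored ICE variant plus its
square and the model's covariates; Model 3's quadratic coefficient
+0.62 (p < 0.001) recovers the planted convexity of 0.58 — CRI is lowest
(most carceral-leaning) at intermediate ICE values and rises toward both
extremes. `out/` contains the per-city table, the median-split summary,
the bivariate correlation table, full coefficient tables, residual
diagnostics, and partial-residual point sets, and `data/truth.csv` holds
the generator's planted values for comparison.

The same machinery works on real inputs: a ledger CSV
(`city,fiscal_year,department,amount[,category_override]`), count-table
CSVs (`city,cell,count` with a controlled cell vocabulary), and a crime
CSV. `carindex cri` and `carindex ice` run the individual stages.

## Documentation

`docs/methods.md` describes the model, the synthetic-data generator and
its calibration, numerical conventions, and known limitations.
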