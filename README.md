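# droughtscreen

Multi-stage drought-tolerance screening analysis for balanced split-plot,
multi-environment crop trials.

Wheat breeders screen large genotype panels for water-shortage tolerance by
growing them under full and limited irrigation across seasons and combining
quantitative-genetic summaries with multivariate trait modelling. This
package implements that workflow as a tested, reusable library:

1. **Genetics** — combined split-plot ANOVA across seasons (sources S,
   rep(S), I, S×I, rep(I×S), G, S×G, I×G, S×I×G, Error), ANOVA
   variance-component estimates, and the genetic parameters

   - broad-sense heritability *h²* = σ²g / σ²p with
     σ²p = σ²g + σ²g×e/e + σ²re/(r·e),
   - genotypic / phenotypic coefficients of variation
     GCV = 100·σg/X̄, PCV = 100·σp/X̄ (so *h²* = (GCV/PCV)² exactly),
   - genetic advance GA = k·h²·σp and genetic gain GG = 100·GA/X̄, with
     k = 2.06 at 5% selection intensity.

2. **Screening** — tolerance/VIF multicollinearity diagnosis with iterative
   trait exclusion (VIF > 10), and correlation-matrix PCA with Kaiser
   retention and an |loading| > 0.27 trait-selection rule.

3. **Yield model** — forward stepwise regression (with removal check) of
   grain yield on the screened traits, and path-coefficient analysis solving
   R_x·p = r_xy to split each trait–yield correlation into direct and
   indirect effects, with residual effect √(1 − R²).

4. **Tolerance index** — per-trait stress/control ratios (orientation-inverted
   for traits such as canopy temperature that rise under stress), min–max
   membership scores Fij = (x − x_min)/(x_max − x_min), the tolerance index
   Fi = mean Fij, and the five-rank classification HT/T/I/S/HS at thresholds
   0.8/0.6/0.4/0.2.

5. **Group validation** — Euclidean distances, Ward/UPGMA clustering, PCoA,
   Mantel permutation tests, canonical discriminant functions (eigenvectors
   of W⁻¹B), Box's M with an equal-prior LDA/QDA resubstitution classifier,
   and one-way MANOVA (Wilks' Λ, Rao's F).

6. **Synthetic trials** — a generator for balanced split-plot data with known
   variance components, genetic correlations and stress directions, whose
   default design emulates a published 25-genotype × 2-season × 2-regime ×
   3-replicate bread-wheat screening trial. No plot-level data were deposited
   with that trial, so the generator is what makes every stage testable
   end to end.

Small digitizations of the trial's published summary tables (membership
scores, collinearity report, path table, genetic parameters, cell means,
mean squares) ship inside the package and drive the worked examples.

## Worked example

Score the published 25-genotype membership table and classify:

```python
from droughtscreen import datasets, tolerance_index as ti

fij = ti.fij_from_published(datasets.load_membership_scores())
table = ti.tolerance_table(fij)
print(table.loc[["DHL30", "Misr1", "DHL23", "KSU106"]].to_string())
summary = ti.classify_panel(table)
print("class counts:", summary["counts"])
print("season agreement:", summary["season_agreement"], "of", summary["n"])
```

prints

```
          Fi_S1 class_S1  Fi_S2 class_S2  Fi_combined class_combined
genotype
DHL30     0.908       HT  0.904       HT        0.906             HT
Misr1     0.907       HT  0.932       HT        0.920             HT
DHL23     0.591        I  0.601        T        0.596              I
KSU106    0.371        S  0.406        I        0.388              S
class counts: {'HT': 8, 'T': 6, 'I': 4, 'S': 7, 'HS': 0}
season agreement: 20 of 25
```

Each `Fi` is the mean of the genotype's per-trait membership scores (green
leaf area, leaf area index, relative water content, canopy temperature) in
that season; `Fi_combined` averages all eight trait × season scores. DHL30
and Misr1 are highly tolerant (Fi ≥ 0.8); 20 of the 25 genotypes keep the
same class in both seasons.

The full pipeline on a synthetic trial:

```bash
droughtscreen run --seed 1 --out report/
# or stage by stage:
droughtscreen simulate --seed 1 --out sim/
droughtscreen genetics --input sim/trial.csv
droughtscreen classify --input sim/trial.csv --traits GLA,LAI,RWC,CT
```

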