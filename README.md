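# eaccd — ordered prognostic grouping of censored survival data

`eaccd` builds TNM-style prognostic staging systems from censored,
cause-specific survival data. Given a case-level table stratified into
*combinations* — the subsets of cases sharing one level of every studied
prognostic factor (e.g. `T1aN0M0A0S1`) — it clusters combinations by
survival experience and returns a small number n\* of **ordered groups**
(group 1 = lowest risk) together with the assignment rule, so additional
factors such as age and sex can be folded into a staging system without
hand-crafted rules. It is aimed at biostatisticians and registry analysts
who need risk stratification that is simultaneously well separated and
predictive.

## The method

The fit is the four-step Ensemble Algorithm for Clustering Cancer Data:

1. **Initial dissimilarities.** Each combination's Kaplan–Meier curve is
   completed beyond a common horizon τ with an exponential tail e^(−λt),
   λ = −log Ŝ(τ)/τ. The Mann–Whitney parameter P(T₁ > T₂) is estimated
   from the completed curves as D\_e = A + B + C (Lebesgue–Stieltjes
   integral up to τ, horizon-gap term, joint tail mass
   λ₂/(λ₁+λ₂)·e^(−(λ₁+λ₂)τ)), and the dissimilarity is |D\_e − 0.5|.
2. **Learned dissimilarities.** A deterministic ensemble of Partitioning
   Around Medoids runs (k = 2 … M−1) turns the initial matrix into
   co-clustering frequencies: how often does each pair land in different
   clusters?
3. **Minimax-linkage clustering** of the learned matrix produces a
   dendrogram whose every internal node is a ball of its merge height
   centred at an actual combination (the prototype).
4. **C-index knee selection.** Cutting the dendrogram at each k and
   numbering clusters by decreasing 5-year survival gives a curve of
   Harrell's concordance C(k); n\* is its knee — the smallest k past which
   extra groups stop buying prediction accuracy.

Validation follows the standard internal/temporal pattern: adjacent-group
Cox hazard ratios and logrank tests, the C-index on held-out
later-diagnosed cases, a correlated C-index test for comparing two systems
on the same cases, contingency tables and mid-rank Spearman correlation
against an alternative staging, and risk-category distributions per factor
level. See `docs/methods.md` for the full account.

## Worked example

The package ships a synthetic-registry generator with planted structure:
24 combinations over 3 factors, 4 true risk groups with hazards
(0.002, 0.006, 0.02, 0.06) per month, 300 cases each, administrative
censoring at 150 months plus 20% random censoring.

```python
from eaccd import PrognosticGroupModel
from eaccd.simulate import standard_fixture

cohort, truth = standard_fixture()          # 7,200 cases, 24 combinations
res = PrognosticGroupModel(cohort).fit()    # four-step pipeline
print(res.summary())
```

```
Prognostic grouping system
====================================================
Factors:              T, N, M
Combinations:         24
Cases (training):     7200
Completion start tau: 76.4672 months
Groups (n*):          4
Training C-index:     0.7689

Group summaries (ordering horizon 60 months):
 group    n  events  survival_at_horizon
     1 1800     432             0.884659
     2 1800    1009             0.670940
     3 1800    1604             0.298847
     4 1800    1764             0.022571
```

The knee found n\* = 4 — the planted number of groups — and the 5-year
survival drops monotonically with the group number (88% → 2%), so the
ordering is respected. The training C-index of 0.7689 says a random
permissible case pair is correctly ordered by group number 77% of the
time. Internal validation confirms the stratification; the estimated
adjacent-group hazard ratios bracket the planted values of 3–3.3:

```python
print(res.validate()["table"].to_string(index=False))
```

```
groups_compared       hr    hr_lo    hr_hi          hr_p     logrank_p
         2 vs 1 3.115608 2.782384 3.488738  2.582723e-86  1.485200e-95
         3 vs 2 3.057688 2.819480 3.316021 1.172588e-160 3.020060e-175
         4 vs 3 3.102185 2.876310 3.345798 2.323942e-189 8.574031e-205
```

Applying the fitted rule to new cases is a lookup:
`res.apply(new_cohort)` returns their group numbers and counts cases whose
combination the system has never seen.

## Command line

The same workflow is available as a CLI for shell use:

```sh
eaccd simulate --out cohort.csv --truth-out truth.csv
eaccd fit cohort.csv --config config.yaml --out-dir out/      # system.json, matrices, dendrogram, plots
eaccd validate out/system.json cohort.csv --config config.yaml
eaccd compare  out/system.json cohort.csv --alternative alt.csv --config config.yaml
```

The YAML config declares the factor scheme (factors, admissible levels,
numeric recodes such as an age cutoff) and the column mapping; see
`tests/test_cli.py` for a minimal example.

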