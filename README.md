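# her2cua

A Markov cohort cost-utility and budget-impact model of neoadjuvant
HER2-targeted therapy for HER2-positive breast cancer, parameterised for the
Sri Lankan health system.

Adding a second HER2-targeted agent (pertuzumab or lapatinib) to neoadjuvant
trastuzumab plus chemotherapy improves event-free survival but at a steep
drug cost, which matters acutely in lower-middle-income settings where cancer
care is publicly funded. This package implements, as a tested and reusable
library, the full decision model used to weigh that trade-off: a five-state
Markov cohort model with deterministic and probabilistic sensitivity
analyses, a threshold (price-reduction) search, and a five-fiscal-year
budget impact analysis. It is written for health-economics analysts who want
to reproduce, audit or re-parameterise the evaluation.

## The model

Five health states: event free (EF), locoregional recurrence (LRR),
metastasis (MET), remission (REM) and death. A cohort enters at age 50
entirely event free and is propagated in 1-month cycles until age 100.
Per-cycle transitions:

- EF → event with probability *q(t)*, split 25% LRR / 75% MET; EF → death at
  the age-matched general-population rate *m(age)*.
- LRR exits every cycle (MET 0.02317, death 0.01064, remission 0.96619).
- REM → MET 0.0076, REM → death *m(age)*.
- MET → death 0.04672. Death is absorbing.

Treatment efficacy enters as a hazard ratio on the EF→event probability,
applied on the probability scale as `p' = 1 − (1 − p)^HR` for the first 12
years, after which all strategies revert to the comparator's event rate.
Five strategies are compared (neoadjuvant / adjuvant): TC/T (S1, comparator),
PTC/T (S2), LTC/T (S3), PTC/PT (S4), LTC/LT (S5), where T = trastuzumab,
P = pertuzumab, L = lapatinib, C = chemotherapy.

Outcomes are discounted life-years, QALYs (utilities 0.70–0.85 by state) and
lifetime costs in 2021 LKR (public perspective: direct medical costs;
societal: plus direct non-medical costs), all discounted at 3% per year.
Strategies are compared by incremental cost-effectiveness ratios (ICERs)
against a willingness-to-pay threshold of one 2021 GDP per capita
(LKR 758,680 ≈ USD 3,815). Uncertainty is handled by one-way (tornado) and
probabilistic (1,000-draw Monte Carlo, Beta/Gamma/LogNormal) sensitivity
analyses summarised as CE-plane points and acceptability curves.

See `docs/methods.md` for conventions, assumptions and design choices.

## Worked example

```python
from her2cua import (builtin_base_case, run_all_strategies,
                     incremental_analysis, Perspective)

params = builtin_base_case()
results = run_all_strategies(params, Perspective.SOCIETAL)
table = incremental_analysis(results, wtp=params.wtp_lkr)
print(table[["strategy_id", "total_ly", "total_qaly", "total_cost",
             "pairwise_icer_vs_comparator", "sequential_icer",
             "dominance"]].round(2).to_string(index=False))
```

```
strategy_id  total_ly  total_qaly  total_cost  pairwise_icer_vs_comparator  sequential_icer            dominance
         S1      8.98        7.37  3504924.86                          NaN              NaN                 none
         S3      9.55        7.87  3770133.87                    538040.01        538040.01                 none
         S5     10.06        8.30  4768141.67                   1364511.44       2305677.15 extendedly_dominated
         S2     11.06        9.17  5528834.14                   1127538.24        875148.10                 none
         S4     12.77       10.65 11416711.83                   2417501.18       3984401.12                 none
```

Rows are ordered by ascending discounted lifetime cost (societal
perspective, LKR). Only S3 (lapatinib dual therapy, single-agent adjuvant)
has an ICER versus the comparator below the LKR 758,680/QALY threshold; S2
buys the most QALYs per rupee among the pertuzumab strategies but still
exceeds it, and S5 is extendedly dominated (S2 delivers extra QALYs more
cheaply at the margin). The same API exposes the threshold search
(`threshold_reduction` reports that a 25% neoadjuvant price cut makes S2
cost-effective), the tornado analysis (`one_way_dsa`), the PSA
(`run_psa`/`ceac`/`ce_plane`) and the budget impact (`run_bia`).

A command-line interface mirrors the library:

```bash
her2cua basecase --perspective societal --out reports/
her2cua psa --n 1000 --seed 7 --out reports/
her2cua bia --coverage 0.6 --out reports/
```

Model configurations are plain JSON/YAML documents (optionally referencing
CSV tables for the life table and cost schedules); the packaged base case
lives at `src/her2cua/data/base_case.json` and `her2cua validate --params`
checks user-supplied files.

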