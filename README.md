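# dietopt

Least-cost, nutrient-constrained diet modeling for women and young
children in low-income, two-season market settings, with wild-food and
micronutrient-powder (MNP) intervention scenarios and wealth-group
affordability analysis.

The package is aimed at nutrition and food-security analysts who want a
reproducible, scriptable counterpart to cost-of-diet style modeling: it
takes a market price survey, food compositions, dietary-recall
frequencies, and requirement profiles, and answers three questions —
what does the cheapest nutritionally adequate diet cost per person and
season, how much does adding specific foods (e.g. wild vegetables
assigned an opportunity-cost price) change that cost and close nutrient
gaps, and can local households afford the result.

## The model

For one individual category and season, the diet is a vector of weekly
servings $x_f \ge 0$ over foods $f$, each with cost $c_f$ (KES per
serving, from the seasonal price per 100 g edible portion and a portion
size in grams) and per-serving nutrient supply $a_{kf}$. With weekly
requirement $r_k$ (7 × the daily recommended intake), the LP is

$$\min_x \; \sum_f c_f x_f + P \sum_{k \in \mathcal{M}} d_k
\quad \text{s.t.} \quad$$

- $\ell_f \le x_f \le u_f$  (weekly intake-frequency bounds, from the
  25th/75th percentiles of household recall counts, or fixed program
  bounds: wild foods 1–3/week, MNP sachets 3–4/week),
- $r_E \le \sum_f a_{Ef} x_f \le 1.1\, r_E$  (hard energy band),
- $\sum_f a_{kf} x_f \ge r_k$ for protein and fat (hard),
- $\sum_f a_{kf} x_f + r_k d_k \ge r_k,\; 0 \le d_k \le 1$ for each
  micronutrient $k \in \mathcal{M}$ (elastic),

where the penalty $P$ (10⁶ × the most expensive serving) makes total
normalized deficit lexicographically prior to money — the solver first
gets as close to adequacy as the food list allows, then minimizes cost,
so diets that cannot reach the iron or zinc requirement are reported
with their shortfall instead of being declared infeasible. Calcium and
iron are carried on an absorbed basis (bioavailability 0.48 and 0.05)
and vitamin A as retinol equivalents (β-carotene 12:1).

Scenario comparisons report the percent change in daily cost per season;
a reduction of at least 25 % in *both* seasons is flagged meaningful.
Affordability averages the cheapest diet's daily cost over the six
woman/child categories and both seasons, annualizes it (×365), and
compares it to each wealth group's food budget (annual income per
individual × food-expenditure share) and to total income.

## Worked example

Generate a synthetic two-season market survey (56 foods, 6 villages, 4
traders each, 180 recall households, 20 % lean-season mark-up), solve
the twelve baseline diets, run the intervention ladder, and check
affordability:

```bash
dietopt synth    --seed 7 --out data
dietopt optimize --data data --out results
dietopt ladder   --data data --out results
dietopt afford   --report results/scenario_report.csv \
                 --wealth data/wealth.csv --out results
```

`optimize` prints the baseline summary (KES per day; statuses show the
iron/zinc gap typical of these food lists):

```
       category season  daily_cost_kes  daily_cost_usd               status
     child_6_8m plenty            63.2            0.61 optimal_with_deficit
     child_6_8m   lean            75.8            0.73 optimal_with_deficit
   child_12_23m plenty            99.0            0.96 optimal_with_deficit
   child_12_23m   lean           118.9            1.15 optimal_with_deficit
     woman_NPNL plenty           176.8            1.71 optimal_with_deficit
     woman_NPNL   lean           212.2            2.05 optimal_with_deficit
...
```

Every lean-season cost exceeds its plenty-season counterpart (prices
rose ~20 %), and children's diets cost less than women's because their
energy floor is lower. `afford` then reports, for the cheapest scenario
("all wild vegetables"), the annual per-person cost against each wealth
group under both budget rules:

```
     group  budget_rule  budget_kes  annual_cost_kes  affordable  shortfall_kes
 very_poor   food_share      8014.5          39888.4       False        31873.9
 very_poor total_income     11786.0          39888.4       False        28102.4
    middle total_income     21875.0          39888.4       False        18013.4
...
```

No group can afford the optimized diet even spending its entire income —
the budget column never reaches the annual cost.

The same workflow is available as library calls
(`dietopt.build_problem` / `solve`, `dietopt.run_ladder`,
`dietopt.can_afford`); `dietopt.turkana` ships the reference inputs of
the northern-Kenya case study (wild-food compositions, MNP formulation,
wealth groups, published seasonal diet costs) used by the reproduction
checks.

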