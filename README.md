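# baltind

Zooplankton community indicators and control-chart based
environmental-status assessment for Baltic Sea monitoring series.

## What this is for

EU marine strategy assessments ask whether a sea area is in *Good
Environmental Status* (GES), and the "Food Webs" descriptor needs
simple, robust metrics of the plankton community to answer that.
`baltind` implements a complete assessment pipeline for long-term
zooplankton monitoring data, aimed at monitoring agencies and
researchers evaluating indicator behaviour:

1. **Indicators** — nine annual summer (June–September) community
   metrics from taxon-resolved abundance/biomass samples: total stock
   (TZA, TZB), copepod biomass absolute and relative (CB, CB%),
   microphagous mesozooplankton biomass (MMB, MMB%), community mean
   individual mass (MeanSize = TZB/TZA), and the Cla/Cop and
   RotCla/Cop biomass ratios.
2. **Preprocessing** — Box-Cox transformation (series are
   lognormal-like), Lilliefors-corrected KS normality checks,
   eigenvector-filtering imputation of missing years, and z-score
   standardisation *z* = (*x* − *μ*)/*σ* against a baseline: the whole
   series, or reference-condition year windows derived from
   chlorophyll-a quality ratios or fish feeding condition.
3. **Control charts** — Shewhart limits for sudden deviations and a
   decision-interval CuSum for persistent small shifts,
   S⁺ᵢ = max(0, S⁺ᵢ₋₁ + zᵢ − k), S⁻ᵢ = min(0, S⁻ᵢ₋₁ + zᵢ + k), with
   k = 0.5, h = 5; out-of-control period extraction (>3 consecutive
   years) and per-year in/out-of-control classification across the
   indicator suite.
4. **Trends & shifts** — Mann–Kendall monotonic trend tests,
   chronological clustering (temporally constrained, permutation-gated)
   for breakpoint years at sensitivities α ∈ {0.01, 0.05, 0.1}, and
   variance-shift F-tests.
5. **GES models** — exhaustive AIC search over logistic regressions
   predicting in/out-of-reference years from the indicators, with VIF
   screening, a nested-model parsimony rule, and in-sample
   classification accuracy; plus the two-dimensional **MSTS** status
   combining MeanSize with total stock (green / orange / red
   quadrants).
6. **Synthetic data** — a generator for multi-decadal summer datasets
   with group-structured lognormal biomass, trends, regime shifts and
   missing years, so the whole pipeline is testable without any
   monitoring-portal downloads.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a 35-year dataset whose community shifts in 1999 (copepods
down, small microphagous taxa up), then assess it against the pre-shift
reference window:

```python
import baltind
from baltind.synthetic_data import (
    GeneratorConfig, composite_shift, default_traits,
    generate_dataset, make_refcon_truth,
)
from baltind import preprocessing as prep, control_charts as cc

cfg = composite_shift(GeneratorConfig(seed=42), shift_year=1999)
samples, truth = generate_dataset(cfg)

wide = baltind.compute_indicators(samples, default_traits(cfg)).droplevel("dataset")
print(wide[["TZA", "TZB", "MeanSize"]].round(2).head(3))

window, _ = make_refcon_truth(cfg, truth)          # reference = 1980-1998
z, baselines, _, _ = prep.zscore_matrix(wide, window=window)
charts = {c: cc.control_chart(prep.ZScoreSeries(z[c], baselines[c]))
          for c in z.columns}
for name, res in charts.items():
    if res.periods:
        print(name, res.periods)
print(cc.classify_years_by_refcon(charts).value_counts().to_dict())
```

Output:

```
        TZA     TZB  MeanSize
year
1980  49.99   99.64      1.99
1981  45.65   93.43      2.05
1982  51.82  104.39      2.01
TZA [('upper', 2002, 2014)]
CB [('lower', 2002, 2014)]
CB_pct [('lower', 2000, 2014)]
MMB [('upper', 2000, 2014)]
MMB_pct [('upper', 2000, 2014)]
MeanSize [('lower', 2002, 2014)]
ClaCop [('upper', 2001, 2014)]
RotClaCop [('upper', 2001, 2014)]
{'in_control': 20, 'out_of_control': 15}
```

TZA is in thousands of individuals m⁻³, TZB in mg wet weight m⁻³ and
MeanSize in µg wet weight per individual.  The CuSum charts pick up the
1999 regime shift within one to three years: abundance and the
microphagous indicators run above their upper control limits while
copepod biomass and mean individual size run below — smaller organisms,
degraded fish-feeding conditions — and every year from 2000 onwards is
classified out of control.  The MSTS quadrant view condenses this:

```python
from baltind.ges_models import msts_classify
st = msts_classify(z.loc[2014, "MeanSize"], z.loc[2014, "TZB"])
print(f"2014: MeanSize z={st.z_size:+.2f}, TZB z={st.z_stock:+.2f} -> {st.status}")
```

```
2014: MeanSize z=-3.23, TZB z=-1.39 -> red
```

Both the mean size and the total stock fail the baseline in 2014, so the
community is in the red (sub-GES) quadrant.

The same pipeline is available from the shell:

```bash
baltind simulate --seed 42 --shift-year 1999 --out samples.csv \
    --traits traits.csv --truth truth.json
baltind indicators --samples samples.csv --traits traits.csv --out indicators.csv
baltind assess --samples samples.csv --traits traits.csv \
    --refcon refcon.csv --out charts.csv
```

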