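# aafscreen

Drug-sensitivity and combination-synergy analysis for high-throughput
viability screens of ovarian-cancer cell lines cultured with
patient-derived **acellular ascites fluid (AAF)**.

Malignant ascites bathes tumour cells in a signalling-rich fluid that can
blunt the response to standard-of-care chemotherapy (carboplatin,
paclitaxel).  Screens that expose cell-line panels to individual patients'
AAF ask two questions: *how much resistance does each ascites induce*, and
*which drug or combination still works in each (cell line × ascites)
condition*.  `aafscreen` implements the full analysis for such screens —
and, because raw patient screens of this kind are typically not publicly
deposited, ships a synthetic-screen generator with known ground truth so
that every stage is verifiable by recovery.

The pipeline:

* **Plate QC & normalisation** — Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| per plate;
  control-based normalisation (negative control → 100% viability, positive
  control → 0%) and vehicle-based normalisation for concentration-response
  experiments.
* **Dose-response** — four-parameter log-logistic fit on the inhibition
  scale, I(x) = c + (d−c)/(1+(e/x)^b) with the baseline c fixed at 0;
  closed-form ICp inversion; **DSS** (drug sensitivity score), the
  normalised area of the fitted inhibition curve above a 10% activity
  threshold over the tested log-concentration window, by closed-form
  integral (variants 1–3).
* **Combinations** — anchored designs (priming drug fixed at its average
  IC20, partner titrated) and full factorial grids; **CR** =
  (DSS_combo+100)/(DSS_mono+100); **ZIP** synergy deltas against the
  Bliss expectation from fitted marginals; **100−VUS** response-surface
  scores; synergy calls at the 95th percentile of each primer's ZIP
  population; deterministic per-condition treatment ranking.
* **Downstream statistics** — IgG-normalised phospho-marker fold-changes
  with Holm-corrected t-tests and Pearson correlation matrices; two-way
  ANOVA of DSS (cell line + AAF) with Tukey HSD; Ward-d2 hierarchical
  clustering with Newick export.

See `docs/methods.md` for the model, conventions and validation design.

## Worked example

```python
import numpy as np
from aafscreen import fit_ll4, ic_p, dss, combination_ratio

doses = 1e-8 * 10 ** (0.5 * np.arange(8))        # 8-point half-log grid
viab = 100 - 100 / (1 + (1e-6 / doses))          # midpoint 1 uM, slope 1

fit = fit_ll4(doses, viab)
print(f"e = {fit.e:.3g} M, d = {fit.d:.1f} %")
print(f"IC20 = {ic_p(fit, 20):.3g} M")
score = dss(fit, x_min=-8.0, x_max=-4.5, t=10, variant=2)
print(f"DSS = {score.dss:.2f}")
print(f"CR  = {combination_ratio(50.0, 0.0).cr:.2f}")
```

prints

```
e = 1e-06 M, d = 100.0 %
IC20 = 2.5e-07 M
DSS = 38.80
CR  = 1.50
```

`e` and `d` are the fitted midpoint and maximal inhibition (recovered
exactly from noiseless points), IC20 is the dose at 20% inhibition
(closed form: e·(20/80) at slope 1), the DSS is the fraction of the
attainable activity area the curve covers over the tested window, and a
CR of 1.5 says a combination scoring DSS 50 improves on a monotherapy
scoring 0.

## The analysis

Numbered drivers under `analysis/` run the study design end to end on the
synthetic screen and write their tables under `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_screen.py` | 30 conditions × 11 drugs × 3×2 replicates with ground truth; one ascites condition carries a strong resistance phenotype |
| `02_qc_normalize.py`    | per-plate Z′ and control normalisation |
| `03_fit_dss.py`         | LL4 fits, IC20/IC50, DSS table; ranks conditions by resistance |
| `04_combinations.py`    | anchored combination screen: CR, ZIP, 100−VUS, synergy calls, best-treatment nomination |
| `05_signalling_stats.py`| marker fold-changes, Holm-corrected tests and correlations, ANOVA + Tukey on DSS, Ward-d2 clustering |

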