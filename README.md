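# osmotrap

Osmotic fluid trapping in the small bowel after hyperosmolar drinks, and the
regulatory loop it drives: transient circulatory deficit → aldosterone/ADH →
slowly adapting colonic sodium absorption → ECF expansion and a
blood-pressure surrogate. Built for physiologists and modellers who want a
tested, reproducible implementation of this mechanism — beverage osmolarity
arithmetic, the static trapping model, a multi-day ODE simulator, and a
seeded virtual-cohort generator for qualitative dose–response studies of
habitual high-fructose (HFCS) soft-drink intake.

## The model

A drink of volume *V* at osmolarity *O* above the isotonic reference
*O*<sub>iso</sub> = 300 mosm/L is diluted to isotonicity by water drawn from
the circulation:

```
V_d = max(0, V·O/O_iso − V)        initially trapped volume
V_a = V + V_d                      total isotonic volume for absorption
```

Water returns with its solutes: the sodium-coupled share (glucose/galactose
via SGLT1, electrolytes) within 2 h, the fructose share (GLUT5, facilitated
diffusion along the whole small bowel) only by ~4 h — longer in fructose
malabsorbers. For a 0.5 L drink at 800 mosm/L (glucose 360 / fructose 440)
that is 0.83 L trapped, 1.33 L total, 45% back at 2 h. Because HFCS is
monosaccharide, it carries ~1.9× the osmoles of the same mass of sucrose
(molar masses 180.16 vs 342.3 g/mol), which is what pushes HFCS soft drinks
so far above isotonicity.

The repeated deficits drive aldosterone (gated off while luminal sodium from
a salty meal remains) and ADH; colonic sodium-absorption capacity relaxes,
with a days-scale time constant, toward a target set by the trailing-average
aldosterone exposure; retained sodium expands the ECF isotonically and a
linear coefficient maps ECF expansion to mean arterial pressure. All
dynamics gains are illustrative defaults in one YAML-round-trippable
parameter set; see `docs/methods.md`.

## Worked example

```python
from osmotrap import (analyze_beverage, absorption_timecourse,
                      circulatory_balance, preset_beverage)

hfcs = preset_beverage("hfcs_softdrink")     # 0.5 L, 800 mosm/L
res = analyze_beverage(hfcs)
print(f"trapped {res.V_d:.2f} L, total {res.V_a:.2f} L")
state = absorption_timecourse(res, 2.0)
print(f"at 2 h: {100*state.absorbed/res.V_a:.0f}% absorbed, "
      f"balance {circulatory_balance(res, 2.0):+.2f} L")
```

```
trapped 0.83 L, total 1.33 L
at 2 h: 45% absorbed, balance -0.23 L
```

0.83 L of body water is sequestered at ingestion; two hours later the
glucose-coupled water is back but the circulation is still 0.23 L down until
fructose absorption completes at 4 h (net +0.50 L, the ingested volume).

Multi-day dynamics and the four-beverage comparison, from the command line:

```sh
osmotrap preset-table                 # trapping table for the four presets
osmotrap simulate --drinks-per-day 3 --days 14
osmotrap cohort --n 200 --seed 1
```

`osmotrap simulate` prints a steady-state summary such as

```json
{"mean_map_mmHg": 95.84, "ecf_expansion_pct": 1.53,
 "mean_colon_capacity": 29.28, "mean_daily_aldo_exposure": 0.177}
```

— with the default physiology, three 0.5 L HFCS drinks a day settle ~3 mmHg
above the 93 mmHg baseline, while the same schedule pre-diluted to 300
mosm/L leaves aldosterone exposure and colon capacity exactly at baseline.

## Analysis scripts

Numbered drivers under `analysis/` reproduce the package's study narrative
and write tables to `results/`:

1. `01_osmolarity_survey.py` — dietary-fluid osmolarity ranges (soups
   305–435, sucrose drinks 292–365, monosaccharide drinks 555–694 mosm/L).
2. `02_trapping_comparison.py` — the four-beverage trapping table and the
   HFCS absorption timecourse.
3. `03_habitual_intake_dynamics.py` — dose–response over 0–4 drinks/day,
   dilution mitigation, salty-soup gating, impaired absorber.
4. `04_cohort_dose_response.py` — 200-individual virtual cohort; the
   flagged-hypertensive fraction rises monotonically across fructose-intake
   bins and malabsorbers carry higher aldosterone exposure.

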