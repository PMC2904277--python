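# Methods

## The model in one paragraph

A drink of volume *V* (L) with osmolarity *O* (mosm/L) above the
plasma-isotonic reference *O*<sub>iso</sub> = 300 mosm/L must be diluted to
isotonicity by water drawn out of the circulation into the small bowel:

> *V*<sub>d</sub> = max(0, *V·O*/*O*<sub>iso</sub> − *V*),  *V*<sub>a</sub> = *V* + *V*<sub>d</sub>

where *V*<sub>d</sub> is the initially trapped volume and *V*<sub>a</sub> the
total isotonic volume subsequently absorbed. Water returns with its solutes:
the sodium-coupled pool (glucose/galactose via SGLT1, plus electrolytes)
within 2 h, the fructose pool (GLUT5, facilitated diffusion along the entire
small bowel) by 4 h in normal absorbers. The transient circulatory deficit
stimulates aldosterone and ADH; colonic sodium-absorption capacity adapts to
the *average* hormone exposure over a few days (crypt cell renewal), so
habitual intake of hyperosmolar drinks biases the body toward sodium
retention, ECF expansion, and a higher mean arterial pressure.

## Osmolarity arithmetic

Ideal-solution osmolarity only: concentration (g/L) / molar mass ×
dissociation count × 1000, summed over components. This is deliberate — the
quantities this package is built to reproduce (soup 300–435 mosm/L from
8.9–12.7 g/L NaCl; sucrose 292–365 and monosaccharide 555–694 mosm/L from
100–125 g/L sugar) are themselves ideal-solution arithmetic. No osmotic
coefficients, pH/CO₂ or temperature corrections. NaCl uses 58.44 g/mol with
dissociation factor 2; sugars 180.16 (monosaccharides) and 342.3 g/mol
(sucrose, lactulose). Ethanol's effective osmolarity is far above the ideal
value, so ethanol drinks are representable only through a declared (measured)
osmolarity; the package never computes it from mass.

The shipped presets carry their quoted overall osmolarity as a declared
value together with a composition whose ideal arithmetic reproduces it
exactly (e.g. glucose 64.8576 + fructose 79.2704 g/L → 360 + 440 = 800
mosm/L). The HFCS preset's 800 mosm/L sits above the 555–694 mosm/L range
implied by 100–125 g/L sugar; we ship the canonical preset as quoted without
reconciling the two. Display rounds osmolarity to integers and truncates
volumes toward zero at two decimals (1/6 L shows as 0.16); computation is
always full precision.

## Absorption timecourse

Each pool absorbs at a constant (zero-order) rate over an absorption window:

- fast pool — [0 h, 2 h];
- slow (fructose) pool — [2 h, *T*<sub>f</sub>], default *T*<sub>f</sub> = 4 h;
- sucrose hydrolyses instantly to equimolar glucose + fructose, splitting its
  osmolar share 50/50 between the pools (no extra hydrolysis-generated
  osmole trapping — consistent with the static table this model reproduces);
- non-absorbed solutes (lactulose) keep their water until *T*<sub>f</sub> and
  then hand it to the colon; it never returns to the circulation.

The slow pool's delayed onset encodes that fructose-associated water stays
sequestered while fructose transits the whole small bowel: with it, the
fraction of *V*<sub>a</sub> absorbed at 2 h equals the fast osmolar share
exactly (45% for the 360/440 drink), and absorption completes at
*T*<sub>f</sub>. A plain zero-order rate from *t* = 0 for both pools would
instead put 72.5% into the body by 2 h, contradicting the 45% claim the
model is meant to embody; the delayed-onset choice is therefore deliberate.
Raising *T*<sub>f</sub> (default 4 h; 8 h in the impaired-absorber scenarios)
models fructose malabsorption. Dilution to isotonicity is instantaneous at
ingestion, so the circulatory balance steps to −*V*<sub>d</sub> at *t* = 0
and ends at +*V*.

## Regulatory-loop dynamics

State variables: colonic sodium-absorption capacity *C* (mmol/day), total
ECF sodium *Na* (mmol), ECF volume (L), luminal water (L), with cumulative
water-intake and urine ledgers. Fixed-step explicit Euler, event-aligned:
steps ≤ 1 min while any ingestion is being absorbed, ≤ 15 min otherwise —
chosen over adaptive stepping so trajectories are bit-reproducible; a
step-halving test bounds the discretisation error on steady-state MAP below
0.1%. Luminal water fluxes use the analytic timecourse differences per step,
so the water ledger closes to machine precision.

- **Hormone drive.** aldo = min(cap, k<sub>aldo</sub>·deficit/V<sub>circ</sub>),
  ADH likewise; the deficit is the trapped water not yet returned, summed
  over active ingestions. The aldosterone (not ADH) response is gated to
  zero while unabsorbed sodium from an electrolyte-rich beverage remains in
  the lumen — a salty meal blunts it.
- **Exposure memory.** The colon target follows the trailing boxcar mean of
  the aldosterone index over `window_days` (default 3 — "a few days" is not
  a quantified number), with first-order relaxation of time constant
  `tau_colon` (default 2 days).
- **Sodium balance.** d*Na*/dt = absorbed(*C*, diet) − k<sub>renal</sub>·max(0,
  *Na* − setpoint), where absorbed = diet − max(0, delivery − *C*): of 150
  mmol/day dietary sodium, 30 mmol/day reaches the colon, which absorbs up
  to its capacity (baseline 25 — stool loses the rest), so adapted capacity
  converts directly into retained sodium, capped by delivery. Aldosterone
  shifts the renal setpoint *upward* (sodium sparing; the sign is forced by
  the mechanism — hypovolemic hormones must retain, not shed, sodium).
  Beverage electrolyte sodium counts within the fixed daily intake: it gates
  aldosterone but is not an additional ledger load, because the renal model
  (no pressure natriuresis) would grossly over-retain a genuinely added
  sodium stream.
- **Water.** Urine volume relaxes ECF toward the isotonic target
  *Na*/[Na] with gain `k_water` (40 L/day per L, i.e. a ~36 min water
  diuresis time constant) and is damped by ADH; drinking is the fixed basal
  2 L/day plus ingestion events. ADH acts on urine volume only; a trophic
  ADH effect on the colon is a plausible extension for which the loop
  exposes no default pathway.
- **Pressure.** MAP = MAP₀·(1 + β·(ECF − ECF₀)/ECF₀), one linear
  coefficient; no autoregulation or pressure natriuresis.

The renal setpoint and baseline sodium are derived from the other constants
so that the no-ingestion state is an exact fixed point: an empty 30-day
simulation stays at baseline to better than 1e-9 in every state variable.

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| V_ecf0 / V_circ0 | 15 / 5 | L | textbook adult compartments |
| na_conc | 140 | mmol/L | ECF sodium concentration |
| Na_intake_basal | 150 | mmol/day | Western diet |
| colon_na_delivery / C0 | 30 / 25 | mmol/day | leaves 5 mmol/day adaptation headroom |
| C_gain | 25 | mmol/day per index | a sustained index of 0.2 recruits the headroom |
| tau_colon / window_days | 2 / 3 | days | "hours and days" adaptation; few-day memory |
| k_renal | 0.1 | /day | slow renal sodium equilibration |
| na_set_aldo | 100 | mmol per index | transient renal sparing |
| k_aldo, k_adh / cap | 6 / 2.0 | – | index ≈ 1 at the 0.83 L deficit of a 0.5 L, 800 mosm/L drink |
| k_water / s_adh | 40 / 0.5 | – | prompt water diuresis, ADH damping |
| beta_bp / MAP0 | 2.0 / 93 | – / mmHg | baseline 93 mmHg; 3 drinks/day ≈ +3 mmHg |

These gains are **illustrative, not calibrated**: the loop they implement is
qualitative, and the package's quantitative claims live entirely in the
static trapping/osmolarity layer. All values round-trip through one YAML
file (`PhysiologyParams.save`/`load`).

## Virtual cohorts

`CohortSpec` draws, from a single seeded stream in a fixed documented order
(malabsorber flags → completion times → drinks/day): a Bernoulli
malabsorber flag (default prevalence 0.30, completion 8 h — placeholders,
since no distributional data exist for malabsorption prevalence or
severity), a log-normal fructose completion time (median 4 h, σ = 0.15) for
normal absorbers, and drinks/day from a discrete distribution over 0–6 with
mean ≈ 2.5 drinks/day. At 2.5 drinks/day of the 0.5 L HFCS preset that is
≈ 99 g fructose/day; fructose exposure is always computed from the beverage
composition, never sampled separately, so exposure and physiology stay
consistent. Each individual runs a regular daily schedule for 14 days
(steady state is reached well within that: tau_colon = 2 d, window = 3 d)
and is summarised over the trailing 3 days; the hypertensive flag compares
mean MAP against a 95 mmHg surrogate threshold, ~2 mmHg above baseline,
chosen to discriminate within the conservative illustrative effect sizes.
The dose–response table is qualitative: no survey covariates (age, BMI,
salt habits) are emulated because the mechanism provides no pathway for
them, and no odds ratios from external epidemiology are targeted.

## What the synthetic cohort does and does not show

The generator emulates heterogeneous habits and absorption kinetics feeding
a shared deterministic physiology. Passing tests demonstrate internal
consistency — monotone dose–response, malabsorber excess exposure,
determinism — not external validity: real populations add covariate
structure, compensatory mechanisms (pressure natriuresis above all), and
measurement noise that this model deliberately omits.

## Numerical choices and degenerate inputs

- Truncation-toward-zero at 2 decimals is the display convention for
  volumes; comparisons against quoted values use truncated display values,
  full precision everywhere else.
- Hypotonic/isotonic drinks clamp *V*<sub>d</sub> to 0; pure water (zero
  osmolarity) has no osmolar partition and is routed through the fast pool.
- Zero-osmolarity beverages cannot be partitioned by osmolar share and
  raise a validation error in the partition primitive.
- Empty schedules are exact fixed points; events must lie inside the
  horizon and be time-sorted.
- The grid-search fit of (C_gain, tau_colon) replays the colon ODE against
  the recorded hormone exposure — valid because capacity does not feed back
  on the hormone drive.
- Simulation problem sizes used in the shipped analyses: 14-day schedules
  (≈ 11k steps) for dose–response, 200-individual cohorts for the synthetic
  survey; the test suite uses 3–10-day schedules and cohorts of ≤ 24.

## Known limitations

No gastric emptying, transport saturation, or bowel geometry; no potassium;
no pressure natriuresis or autoregulation (the pressure surrogate is
open-loop in ECF); sucrose hydrolysis generates no additional trapped
osmoles; the total intestinal volume is taken as exactly *V* + *V*<sub>d</sub>
although real dilution would settle slightly below that sum; hormone
indices are dimensionless and not mapped to plasma concentrations.
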