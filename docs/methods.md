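# Methods

## Genetic model

The engineered genotype space is four unlinked loci: the X-linked
female-lethal cassette (`FL`/`+`), the resistant *pyramus* promoter
(`res`/`wt`, chromosome 2), the programmable transcriptional activator
(`PTA`/`+`, chromosome 3), and an optional dominant-lethal locus
(`RIDL`/`+`) on a distinct autosome. The two tandem FL constructs of the
laboratory strain are collapsed into a single allele: the strain used
throughout carries both copies, so copy-number dosage never varies within a
simulation and modeling it would add parameters without data. A
mitochondrial marker present in the strain has no phenotype and is ignored.
Gametes form by independent assortment (all loci are on different
chromosomes; each engineered element is a single allele, so recombination
within cassettes does not arise), and crosses are exact outer products of
gamete distributions — the stochastic layers sample from these exact
distributions rather than approximating them.

Viability rules and their checkpoints:

- **EGI** — inviable iff ≥1 PTA copy and ≥1 `wt` promoter allele. Lethality
  acts at egg hatch: inviable zygotes are tallied as laid eggs but never
  instantiated as living individuals. Penetrance is modeled as absolute; no
  adult escapers have been observed in the underlying assays.
- **FL** — females carrying `FL` survive with probability `S(E)` (below),
  applied once at the larva→pupa boundary: doomed females live and compete
  as eggs and larvae but never pupate. Lethality is dominant (any `FL`
  copy); males are unaffected.
- **RIDL** — one copy kills either sex when food tetracycline is below the
  repression threshold (2 μg/ml, the same floor as the FL dose-response).
  Field and bottle food carry no tetracycline, so RIDL-sired zygotes die;
  the death is applied at egg hatch, like EGI. Placing RIDL lethality early
  (rather than at pupation) makes a RIDL release behave like a classical
  sterile-male programme without a larval-competition bonus, which is the
  behavior the strategy comparisons require; the checkpoint is a single
  code-level constant if a late-acting variant is wanted.

Genotypes serialize to a compact code (`XFL/Y;res,res;PTA,PTA;+,+`) that
round-trips losslessly; unordered allele pairs are normalised to sorted
order.

## Tetracycline dosimetry

Per-individual state is one scalar, the effective exposure `E`
(μg/ml-equivalent), with maternal deposition only (sperm carries none):

    E_child = C_food + κ · E_mother

whose fixed point under constant rearing is `C/(1−κ)`. FL-female survival is
a Hill curve with a hard floor:

    S(E) = 0 for E < E_floor;  otherwise S_max · E^h / (EC50^h + E^h).

Defaults: κ = 0.07, EC50 = 6 μg/ml-equiv, h = 2, S_max = 0.85 (the repressed
circuit stays slightly leaky, biasing adult sex ratios toward males even on
tetracycline), E_floor = 2 μg/ml-equiv. The floor makes the all-or-nothing
laboratory observations exact rather than asymptotic: a stock at the
10 μg/ml fixed point (E* = 10.75) passes E = 0.75 < 2 to tet-free offspring
(zero surviving females in F1), while a 100 μg/ml stock (E* = 107.5) passes
E = 7.53 (partial survival, predicted 34% adult females) and collapses only
in F2 (E = 0.53). The four anchor conditions cannot all be met exactly —
the recursion assigns similar exposures (7.5 vs 10.8) to conditions
observed at ~35% vs ~40% females — so the parameters were chosen once to
put every anchor within 7 percentage points, with two of the four exact;
`check_anchors` reports the residuals.

## Synthetic climatology

Daily mean temperature is the only weather driver (degree-day phenology
needs nothing finer). The generator is a sinusoidal annual cycle
(mean 8 °C, amplitude 16 °C, peak July 20) plus stationary AR(1) daily
anomalies (marginal s.d. 3 °C, lag-1 autocorrelation 0.6), giving a March
mean near 0 °C and a July mean near 23–24 °C. Real series load from CSV
(`date,tmean` or `date,tmin,tmax`), validated for strict day-by-day
contiguity with errors naming the offending row.

Season-level qualitative expectations (mid-summer peak and decline) are
properties of the seasonal envelope: with daily-noise realizations whose
July happens to be cool, the modeled population — like a real one — keeps
growing into late summer. Calibration checks therefore run on the
noise-free mean curve; noisy realizations are used wherever the property
under test is structural rather than climatic.

## Field agent-based model

Daily steps apply, in order: degree-day accrual and stage promotion (egg
20, larva 120, pupa 130 degree-days above 7.2 °C, with viability enforced
at the boundaries above), background and temperature-dependent mortality,
mating, oviposition, and larval density dependence (each egg survives the
day with probability `1/(1 + L/K)`, L = current larvae, K = 10,000).
Initial condition: 100 wild adults (even split, females pre-mated to wild
males) on March 1; releases recur every F days within their window.

Mating: a virgin female mates with probability 0.8/day when any adult male
is present; mated females remate at 0.03/day; sires are uniform over living
adult males (released males are fully competitive, per the competition
assays); sperm stores update with last-male precedence P2 = 0.8, and each
egg's sire is drawn independently from the store weights.

Vital-rate curves are implementer calibrations — the only quantitative
constraint available is that untreated populations should reach tens of
thousands by early July and then decline — and every constant is a config
knob. The calibrated defaults: adult mortality 0.03/day across 0–21 °C
(cold-tolerant overwintering adults), rising linearly to 0.40/day at
≥26 °C; fecundity trapezoid 0 at ≤7.2 °C, full lay of 12 eggs/day on
12–20 °C, zero at ≥23 °C; juvenile mortality 0.01/day plus a heat ramp to
0.26/day at ≥27 °C; adult senescence at 68 days.

| parameter | value | note |
|---|---|---|
| adult mortality, benign (10–21 °C) | 0.03 /day | ~1-month adult lifespan |
| adult mortality at ≤0 °C | 0.03 /day | overwintering adults are cold-tolerant; higher values extinguish the founder population before spring laying |
| adult mortality at ≥26 °C | 0.40 /day | midsummer heat stress |
| juvenile mortality | 0.01 /day + ramp to 0.26 at ≥27 °C | heat kills broods, not just adults |
| fecundity plateau | 12 eggs/♀/day on 12–20 °C | upper range of reported field fecundity; smaller values cannot build tens of thousands from ~10 overwintered founders by July |
| fecundity zero point | ≥23 °C | daily *means* above 23 °C proxy for afternoon extremes |
| carrying capacity K | 10,000 larvae | sets the peak scale |
| senescence | 68 days | bounds post-release persistence of released cohorts |

The heat thresholds look low against physiological limits because the model
runs on daily means: a 24 °C mean in continental summer implies afternoon
temperatures well past the reproductive optimum. The combination of heat
mortality on all stages and the fecundity cutoff produces the
boom-then-collapse season shape on the climatological curve; it is the
model's strongest structural assumption and the main thing to revisit if
published vital-rate tables become available (each value is a drop-in
config field).

Census semantics: the daily census counts living individuals by strain
class, sex, stage, and origin (wild / released / field-born); EGI- and
RIDL-inviable zygotes appear in the eggs-laid ledger only. The cumulative
wild-type count tallies every wild-type individual that ecloses to
adulthood during the season. Days-to-eradication is the first 1-based day
from which the wild-type count (all stages) stays at zero; internally days
are 0-based.

Release strategies fix genotype, sex composition, and carried exposure:
male-only SSIMS (reared at 10 μg/ml, hatched tet-free: females die before
release), single-amplification (reared and hatched at 10: bi-sex, E* =
10.75, field daughters die before pupation), double-amplification (100
μg/ml: E* = 107.5, one bi-sex field generation, then male-only), FL
(bi-sex, reared at 100 — the choice that maximises FL persistence), and
RIDL (bi-sex). Bi-sex cohorts use an exact ⌊n/2⌋ female split for
reproducibility.

The population is stored as flat numpy arrays (genotypes interned to
integer codes, sperm stores as a female × sire-genotype weight matrix);
cross distributions are cached per parental pair. A full season at peak
~10⁵ individuals runs in ~1–2 s, which keeps replicate-based property
checks cheap. The `Agent` dataclass is the user-facing record for cohorts
and conversions.

## Cage trial

Adults live in the cage; juveniles exist only inside weekly bottle cohorts
scheduled to eclose 10–13 days after the lay. The weekly cycle: SSIMS
addition (600 at 45% female, reared at 100 μg/ml, weeks 1–8), a 24-hour
reproduction bottle mid-week (Poisson 25 eggs per mated female; EGI, RIDL,
FL, a 0.90 egg-to-adult background survival, and an 800-emerger density cap
applied), and an end-of-week trap capturing each adult with probability
0.25 (trap estimate: total cage population was roughly three times larger
than weekly trapped counts). Trapped flies are killed except up to ten
wild-type females, which are assayed (Poisson 75-egg vial lay, sires from
their sperm stores, viability applied) and returned three days later.

Cage-specific defaults: constant 25 °C; adult mortality 0.05/day (crowded
cages run hotter attrition than the field optimum); remating 0.25/day and
P2 = 0.9, higher than the field defaults because males are permanently
abundant in the cage — the sperm-displacement assays show near-complete
displacement of resident sperm within days of cohabitation, which at cage
densities implies remating rates in this range.

## What the synthetic data do and do not show

The climatology and vital rates emulate the *shape* of an Upper-Midwest
season, not any particular year; all field-model outputs are therefore
qualitative (suppression orderings, persistence ladders, eradication
times), and none of the heatmap-style numbers should be read as predictions
for a real orchard. The dosimetry layer, by contrast, is anchored to
laboratory measurements and its outputs (sex-ratio anchors, the
one-generation collapse delay) are quantitative. Passing cage-trial
properties show that the protocol logic plus the genetics reproduce the
observed suppression dynamics; they cannot validate the trap-rate or
fecundity constants, which the protocol itself leaves unmeasured.

## Numerical choices

All randomness flows through `numpy.random.Generator` seeded per run;
identical seed and configuration give bit-identical outputs. Sweep cells
derive their seeds from the base seed and cell coordinates via
`SeedSequence`, so any CSV row can be reproduced in isolation. Genotype
pairs are compared after normalising unordered allele pairs; probabilities
are exact rationals accumulated in floats (the deepest product is 2⁻⁴·2⁻⁴,
well within double precision). The Hill fitter uses bounded least squares
with `p0 = (max response, median positive dose, 2)` and reports the Hill
coefficient's t-value from the fit covariance; constant responses are
rejected rather than fitted.

## Known limitations

No migration, spatial structure, resistance evolution, fruit-damage
economics, or photoperiod/diapause effects. Penetrance of both lethal
systems is absolute. The FL dose-response is driven by a single carryover
scalar; pharmacokinetics of tetracycline in food or field sprays are out of
scope. Strategy rankings at the smallest release sizes are sensitive to the
vital-rate calibration and should be re-examined against any published
parameter tables.
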