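# Methods

## The decision problem

People newly diagnosed with relapsing-remitting multiple sclerosis (RRMS)
usually face a choice among a dozen disease-modifying drugs (DMDs) or no
active treatment (best supportive care, BSC). Shared decision making (SDM)
— eliciting the patient's preferences and deciding together — plausibly
changes three things relative to usual care (CAU): the initial treatment
mix, persistence (fewer discontinuations), and adherence (more patients
with >80% of days covered). SDM itself costs money to deliver. This
package estimates the lifetime incremental costs and QALYs of an SDM
strategy against usual care for the Dutch setting, the headroom for the
delivery cost, and the uncertainty around the comparison.

## Model structure

A cohort state-transition model over 20 health states: RRMS at EDSS 0–9,
secondary-progressive MS (SPMS) at EDSS 1–9, and death. Cycles are
annual; the cohort enters at the mean onset age (37 years, 29% male) and
runs until age 100. In RRMS a patient can improve, stay, worsen, or
convert to SPMS (landing at the same EDSS, floored at the SPMS minimum
of 1); in SPMS only staying or worsening is possible; death is reachable
from every state.

Drug efficacy enters as two relative risks: one on worsening and
SPMS-conversion probabilities, one on the relapse rate. Relative-risk
scaling renormalizes each transition row through the stay-probability
only — improvement probabilities are never scaled, so a drug slows
deterioration without inventing recovery. By default the progression
relative risk keeps acting in SPMS while treatment continues, matching
the assumption that converters stay on treatment; a settings flag turns
this off.

Mortality is the sex-blended national life-table probability multiplied
by an EDSS-indexed hazard multiplier (identical for RRMS and SPMS at
equal EDSS), capped at 1. Within a cycle, death competes first; the
surviving mass then follows the progression row. This ordering is a
modelling choice (one of the two competing-risk orderings had to be
picked) and is localized in one function.

### Treatment pathways

The health-state space is expanded by treatment stage and adherence
class. Stages: initial BSC (absorbing — patients who choose no treatment
never start one), on first DMD, on second DMD, and BSC after treatment
(absorbing). Each cycle, in order: death, EDSS/SPMS transition, forced
stop for patients who progressed above EDSS 6 (straight to BSC, no new
choice), then voluntary discontinuation at the drug's real-world annual
rate times the strategy's persistence multiplier. Of voluntary
first-DMD discontinuers, 5% move to BSC; of the 95% who switch,
side-effect discontinuers (79%) of a first-line drug pick another
first-line drug and efficacy discontinuers (21%) escalate to second
line; a patient whose *first* drug was second-line stays within the
second line; after the second DMD everyone moves to BSC. Switch
destinations follow the strategy's own initiation shares over the
eligible set (current drug excluded), renormalized; two alternative
rules (equal split over second line, equal split over both lines) exist
for scenario analysis. A newly chosen drug takes effect the next cycle,
so the discontinuation year carries a full year of drug cost —
consistent with the >90-days-interruption definition of real-world
discontinuation, which implies substantial same-year exposure.

Adherence is a fixed two-class mixture decided at initiation: with the
strategy's per-drug adherent proportion a patient is optimally adherent
for the whole pathway, otherwise nonadherent. Infused drugs
(natalizumab, ocrelizumab, alemtuzumab) are always adherent.
Nonadherence inflates the total relapse rate by 1.42 and the severe
fraction by 1.075; it does not touch the progression relative risk,
because only the relapse consequences of nonadherence are quantified.
The class axis is carried through the engine, so patients mixing into
the same second-line stage from different first drugs keep their class.

Because transition dynamics do not depend on the adherence class, the
engine evolves both classes simultaneously; the per-cycle map factorizes
into an age-dependent survival scaling and an age-independent routing
operator over the expanded space (classes × stages × states). That
factorization is what makes a 10,000-iteration probabilistic analysis
affordable on one CPU.

### SDM delivery cost

Charged per decision epoch in the SDM arm only: once at initiation
(everyone decides, including BSC choosers) and once at each voluntary
first-DMD discontinuation (the second treatment is chosen through SDM
again). Forced stops and second-DMD stops involve no choice. The default
€100 per decision covers a 50% consultation-time extension (€51.77) plus
€48.23 of headroom for decision aids and training.

## Economics

Effects are discounted at 1.5%/year and costs at 4.0%/year (Dutch
guideline), cycle 0 undiscounted; undiscounted twins of every stream are
kept. Accrual happens on start-of-cycle occupancy; there is no half-cycle
correction by default (an optional flag provides one) because the model
this follows used none.

QALYs: state utility (EDSS-decreasing, SPMS below RRMS at equal EDSS)
minus an annualized disutility per expected relapse (severe/mild, relapse
duration folded into the decrement) minus a per-drug adverse-event
disutility per on-treatment year. Utilities are validated to [−1, 1] with
no extra floor, so negative QALY flows at high EDSS are representable.

Costs by category: drug price; administration (infused drugs only,
first-year vs subsequent); monitoring (annual, plus pretreatment in the
first treatment year, plus a one-off post-discontinuation contact charged
in the stopping year); pharmacy dispensing fees (€14 first prescription
of a treatment episode, €7 thereafter; 12 prescriptions/year for
self-administered drugs, none for infusions — monthly dispensing is the
conservative Dutch convention and is configurable); adverse-event costs
as a fixed proportion of health-state healthcare costs; relapse costs
(severe/mild); health-state costs by category (healthcare, community
services, equipment/aids, informal care, productivity losses); and SDM
delivery. Relapse costs are reported as their own category so that every
perspective total is exactly the sum of its categories.

Perspectives: healthcare only; limited societal with friction-cost
productivity losses (the base case); societal with human-capital
productivity losses. Health-state costs between published EDSS anchors
are linearly interpolated; beyond the outermost anchors the nearest
anchor is held constant, which cannot produce negative or exploding
costs.

## Analyses

* **Deterministic**: each SDM effect separately (choice only,
  discontinuation only, adherence only — each still paying the delivery
  cost) and combined; ICER or dominance classification on discounted
  totals. "Dominant" means cheaper and more effective.
* **One-way registry**: drug costs ±20%, progression relative risks
  scaled ±20/25% (a stand-in for unpublished per-drug ranges), SDM cost
  €0, discounting 0%/3%, healthcare and human-capital perspectives,
  onset age 29/45, proportion male 18%/40%, entry-distribution variants
  (all at EDSS 1; all at EDSS 4; uniform; −3.75 points from EDSS 0–3
  and +5 points to EDSS 4–6), initial-choice variants (equal first-line
  only, with and without 25% BSC), second-choice variants (equal second
  line; equal over both lines), transition probabilities ±10% with
  stay-probability renormalization.
* **Threshold**: the delivery cost enters totals linearly through the
  expected discounted decision count, so the maximum cost at which the
  ICER equals a willingness-to-pay threshold is a linear solve, verified
  by one re-run at the solution (relative error < 1e-6). Negative
  headroom means the arm is not cost-effective even with free delivery;
  "not achievable" means no QALY gain.
* **Probabilistic**: 10,000 replicates by default. Transition rows are
  Dirichlet (concentration 100 × the point probabilities, giving roughly
  10% relative uncertainty); relative risks lognormal; utilities,
  probabilities and proportions beta; costs gamma — each moment-matched
  to the point estimate with a 10% standard error, the standard default
  when a supplement does not specify distributions. Sampled utilities
  and healthcare costs are re-sorted to preserve their monotone EDSS
  shape. Outputs: the (ΔC, ΔQ) cloud, and the acceptability curve as
  the fraction of draws with non-negative net monetary benefit per
  willingness-to-pay point. Everything is reproducible from one seed.

## Synthetic inputs: what they are and are not

The strategy profiles are published and encoded verbatim: initiation
shares (usual-care column sums to exactly 100.0%; the SDM column as
printed carries a 0.1-point rounding residue and is renormalized for
use), per-drug real-world first-year discontinuation rates (10.4–30.1%),
adherent proportions (58.9% / 63.9% for self-administered drugs, 100%
for infused), the 50% relative discontinuation reduction under SDM, and
the €100 delivery cost.

Everything else the original model keeps in supplementary tables is a
*synthetic stand-in*, chosen once for field-plausible magnitude and the
documented structure: tridiagonal-plus-conversion RRMS rows with mild
seeded Dirichlet jitter; worsening-only SPMS rows; EDSS-increasing
mortality multipliers (1.0 → 4.5); a Gompertz–Makeham life table at a
Dutch-like level; utilities 0.87 at EDSS 0 declining to 0.10 at EDSS 9;
EDSS-increasing healthcare costs (€2,000 → €30,000/year) and the other
cost categories anchored at cost-of-illness magnitudes; relapse rates
0.65/year at low EDSS declining with disability; drug prices €4–20k/year
with second-line drugs dearer and more effective (progression relative
risks 0.55–0.75 second line, 0.75–0.95 first line). The generated cohort's
undiscounted life expectancy from entry (~37 years at onset age 37)
falls in the configured plausibility band of 25–42 years.

Consequences: all structural results (identities, conservation laws,
oracle equivalence, monotonicities, reproducibility) are fully tested on
these inputs, but the *numerical* cost-effectiveness results differ from
the published ones — with these stand-ins the combined-effects ICER is
around €70k/QALY rather than the published €17,875 — and reproducing the
published numbers requires transcribing the supplementary tables into
the parameter-directory format (see `data/published/` in the acceptance
test). Passing tests therefore demonstrate correctness of the machinery,
not calibration to Dutch data.

## Verification

* An independent individual-level microsimulation re-implements the
  event order with per-patient sampling and per-unit valuation functions
  (not the cohort algebra). At 200,000 patients the cohort engine agrees
  within 3 Monte-Carlo standard errors on QALYs, total costs, relapses
  and life years across 5 generator seeds. The microsimulation accrues
  expected relapses per state rather than sampling them, so its standard
  errors reflect trajectory variation only.
* Null-input identities: a dead cohort produces nothing; zero utilities
  give zero QALYs but unchanged life years; relative risk 1 with zero
  treatment costs makes any drug pathway identical to BSC; zero discount
  rates collapse discounted onto undiscounted streams.
* Mass is conserved to 1e-9 per cycle across the expanded space, and no
  treated occupancy above EDSS 6 survives a cycle start.

## Numerical and design notes

* Evaluation is linear in initiation shares when switch destinations are
  share-independent; with the default share-proportional destinations the
  routing operator itself depends on the shares, so linearity is exact
  only under the equal-split switch rules (and near-exact otherwise).
* Parameter files are plain CSV plus a YAML manifest; floats are written
  with `%.17g` and read with round-trip parsing, so a load/write cycle
  is bit-identical.
* The printed discontinuation rates are applied every cycle (a
  stationary annual rate), consistent with second-DMD rates being set
  equal to first-DMD rates.
* The SDM adherence effect is the printed 5-percentage-point absolute
  increase (58.9% → 63.9%), read directly from the published table.
* Dominance edge cases: ΔQ = 0 with ΔC < 0 is reported as dominant, with
  ΔC > 0 as dominated; the south-west quadrant keeps its ratio under a
  separate "cost-saving, QALY-losing" label.

## Problem sizes

The default runs use the full 14-drug portfolio (30 treatment stages ×
2 adherence classes × 20 health states, 63 annual cycles). A
deterministic two-arm comparison takes ~50 ms; the one-way registry
(24 scenarios) ~1 s; a 10,000-iteration probabilistic analysis ~10 min;
the 200,000-patient microsimulation ~2 s per run — all on one CPU.

## Known limitations

* Re-initiation after BSC, treatment holidays, waning efficacy, EDSS
  half-steps and more than two DMDs per pathway are out of scope.
* Nonadherence is constant over time and affects relapses only.
* Adverse events are an annual on-treatment disutility and a fixed cost
  proportion, not discrete events.
* The synthetic inputs are stand-ins; see above for what conclusions
  they do and do not support.
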