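# mscea

Cost-effectiveness modelling of **shared decision making (SDM) for
disease-modifying drug (DMD) choice in relapsing-remitting multiple
sclerosis (RRMS)**, for health economists and HTA analysts working on
the Dutch setting.

People with RRMS choose among ~14 DMDs or best supportive care. Shared
decision making may change the initial choice, halve treatment
discontinuation, and raise the share of adherent patients — at a
delivery cost per decision. This package implements an EDSS-based cohort
state-transition model (10 RRMS states, 9 secondary-progressive states,
death; annual cycles to age 100) with two-drug treatment sequencing,
forced stop above EDSS 6, an adherent/nonadherent mixture, Dutch
cost/QALY accounting (effects discounted at 1.5%, costs at 4.0%), and
the full analysis battery: deterministic effect decomposition, one-way
scenarios, delivery-cost threshold (headroom) analysis, and a seeded
probabilistic sensitivity analysis with CE-plane and CEAC outputs.

The model core, for a strategy arm *s* with initiation shares
*π*, per-drug discontinuation multiplier *m* and adherent proportions
*a*: drug efficacy enters as relative risks RR<sub>prog</sub> on
worsening/SPMS-conversion probabilities (rows renormalized through the
stay-probability) and RR<sub>rel</sub> on relapse rates; mortality is
the sex-blended life-table probability times an EDSS hazard multiplier;
and arm outcomes are the π- and a-weighted average of pathway outcomes,
compared by ICER = ΔC/ΔQ on discounted totals.

The published strategy profiles (initiation mixes, real-world
discontinuation rates of 10.4–30.1%/year, adherent proportions
58.9%/63.9%/100%) are encoded verbatim; the remaining inputs
(transitions, relative risks, utilities, unit costs, drug prices) are
clearly-labelled synthetic stand-ins generated from a seed — see
`docs/methods.md` for exactly what that implies about the numbers.

## Worked example

```python
import mscea

params = mscea.generate_parameter_set()          # 14-drug portfolio, seeded
cau, sdm = params.strategies["CAU"], params.strategies["SDM"]

out = mscea.evaluate_strategy(cau, params)
res = mscea.compare(mscea.evaluate_strategy(sdm, params), out)
print(f"CAU: cost {out.total_cost():,.0f}, QALYs {out.qalys:.2f}, "
      f"life expectancy {out.life_years_undiscounted:.1f} y")
print(f"SDM vs CAU: dC {res.delta_cost:+,.0f}, dQ {res.delta_qaly:+.3f} "
      f"-> {res.describe()}")
```

prints

```
CAU: cost 535,510, QALYs 14.33, life expectancy 37.4 y
SDM vs CAU: dC +26,608, dQ +0.376 -> ICER 70,792
```

Usual care costs €535,510 and yields 14.33 discounted QALYs per patient
over a lifetime (limited societal perspective, friction-cost method);
switching the cohort to shared decision making adds €26,608 and 0.376
QALYs, i.e. ≈€71k per QALY gained *on the synthetic stand-in inputs* —
the qualitative pattern (SDM gains QALYs at higher cost, driven by
increased drug utilization) is the substantive output here, not the
absolute ICER.

The numbered drivers under `analysis/` run the full study and write
tables under `results/`:

```bash
python analysis/01_build_inputs.py            # parameter-set directory
python analysis/02_base_case.py               # 3 effects separately + combined
python analysis/03_one_way_sensitivity.py     # 24-scenario registry
python analysis/04_threshold.py               # max SDM cost at WTP 20k/50k
python analysis/05_psa.py --n 2000 [--plot]   # CE plane + CEAC
```

Each script accepts `--seed` and `--params <dir>` (a parameter-set
directory, e.g. one with hand-transcribed published tables, replaces the
synthetic inputs everywhere).

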