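# frailsim

An individual-level, discrete-time microsimulation framework for
cost-effectiveness analysis of frailty interventions, built around a
consensus-derived model structure.

The package covers the full pipeline:

- **`frailsim.delphi`** — multi-round expert-panel (Delphi) classification of
  candidate health events and patient attributes into acceptable / moderate /
  unacceptable agreement bands and include / feed-back / reject decisions.
- **`frailsim.frailty`** — frailty measurement: the deficit-accumulation
  frailty index and the five-criterion frailty phenotype (non-frail /
  pre-frail / frail).
- **`frailsim.structure`** — the model structure (health events, patient
  attributes, dependency edges) with the consensus default: seven events
  (hip fracture, falls, residential care admission, hospital admission,
  physical disability, delirium, death) and eleven attributes; JSON
  serialisation and diagnostics.
- **`frailsim.synth`** — synthetic baseline cohorts (Gaussian-copula rank
  coupling of configurable marginals) and longitudinal multi-wave panels
  generated at known true risk parameters, so estimation and validation are
  fully testable offline.
- **`frailsim.risks`** — logistic per-cycle risk equations over attributes,
  event-history counters and frailty-category indicators; the frailty
  transition model with intervention modifiers; maximum-likelihood fitting
  from panels (statsmodels backend) with recovery guarantees.
- **`frailsim.engine`** — the microsimulation: per cycle, death first, then
  independent non-fatal events, frailty transition, history/state updates
  and utility/cost accrual. A scalar reference path and a vectorised cohort
  path share exact draw semantics; per-individual random substreams enable
  common random numbers for paired scenario comparisons.
- **`frailsim.econ`** — discounted QALYs and costs, incremental analysis
  (ICER and dominance labels), probabilistic sensitivity analysis and
  cost-effectiveness acceptability curves.
- **`frailsim.validation`** — exact Markov cohort oracle, microsimulation
  vs. oracle cross-model checks, and internal/external validation of
  simulated rates against observed panel rates.

Shipped utility, cost and coefficient defaults are illustrative fixtures,
not estimates from any dataset.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
classifier/measure/accounting invariants, and `tests/test_acceptance.py`
with one test per acceptance criterion (exhaustive 5^9 classifier
enumeration, geometric closed form, Markov-oracle equivalence at
n = 100,000, parameter recovery at n = 20,000, common-random-number
identities). Everything is generated programmatically; the whole suite runs
in well under a minute.

## CLI

```bash
frailsim structure build --out structure.json
frailsim structure validate --structure structure.json
frailsim synth cohort --n 10000 --seed 1 --out cohort.csv
frailsim synth panel --cohort cohort.csv --waves 5 --seed 2 --out panel.csv
frailsim fit --panel panel.csv --event falls --covariates age,frail
frailsim simulate --cohort cohort.csv --seed 3 --out results.csv --trace trace.csv
frailsim cea --cohort cohort.csv --scenario-b intervention.json --seed 4 --out cea.csv
frailsim validate --cohort cohort.csv --panel panel.csv --out validation.csv
frailsim delphi classify --responses responses.csv --out structure.json
```

Scenario JSON accepts the `ScenarioConfig` fields, e.g.

```json
{"name": "intervention", "intervention": true,
 "frailty_worsening_multiplier": 0.7,
 "event_hazard_multipliers": {"hip_fracture": 0.8},
 "one_off_cost": 250.0, "per_cycle_cost": 40.0}
```

## Example

```python
import frailsim as fs

structure = fs.default_structure()
params = fs.default_risk_params(structure)
cohort = fs.generate_cohort(fs.synth.default_cohort_spec(n=20_000, seed=1))

comparison = fs.run_comparison(
    cohort, structure, params,
    fs.ScenarioConfig(),
    fs.ScenarioConfig(name="intervention", intervention=True,
                      frailty_worsening_multiplier=0.7, one_off_cost=1_000.0),
    fs.SimConfig(seed=2),
    discount_rate=0.05,
)
print(comparison.ce.delta_qalys, comparison.ce.icer)
```
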