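# pavo2

Simulation and analysis of probabilistic Pavlovian learning with
haemodynamic (tissue-oxygen, T_O2) signals.

## The problem

In a two-cue probabilistic Pavlovian task, rats hear a 10-s auditory cue
(CS_High, rewarded 75% of the time, or CS_Low, rewarded 25%) followed
immediately by reward or omission, 56 trials per session over nine training
sessions plus a drug-challenge session. Two questions drive the analysis:

1. **Behaviour** — which variant of a Rescorla–Wagner learning model best
   describes each animal's cue-period magazine head entries? Candidate
   components: a cue-salience term β (cue-specific learning rate),
   split learning rates α⁺/α⁻, unconditioned responding k (shared or
   cue-specific) and a pre-cue baseline term (trial-specific or
   recency-weighted). Value updates as V ← V + α·β·(r − V); models are
   compared by BIC = k·ln n − 2·ln L̂.
2. **Signals** — do event-locked oxygen responses carry reward
   prediction errors? Trial-by-trial AUC responses (5–10 s post cue, 0–30 s
   post outcome) are regressed on model-derived latents: cue signal ~ V(t);
   outcome signal ~ r(t) + V(t−1) (an RPE signal needs β_r > 0 **and**
   β_V < 0); outcome signal ~ |r(t) − V(t−1)| (unsigned PE / salience).
   A nucleus-accumbens-like channel satisfies all three cardinal RPE
   criteria; an orbitofrontal-like channel instead carries the unsigned PE
   with a positive value effect at outcome. An amphetamine challenge
   collapses cue discrimination in behaviour and signals, tested by a
   permutation difference-of-differences contrast.

Since no recordings are public, the package includes a full synthetic-data
module (task schedules, a generative RW agent, HRF-convolved oxygen traces
with AR(1) noise) whose defaults encode the study conditions; every analysis
stage is tested by recovering that known structure. It is aimed at
computational-neuroscience users who want a tested, seedable reference
pipeline for RW model comparison and model-based analysis of event-related
haemodynamic signals.

## Worked example

```python
from pavo2 import simulate_cohort, CohortConfig
from pavo2.pipeline import fit_cohort_behaviour, cohort_auc_tables, electrode_glms
from pavo2.glm import rpe_criteria_check

cohort = simulate_cohort(n_animals=6, config=CohortConfig(), seed=1)
fits = fit_cohort_behaviour(cohort, n_restarts=10, seed=1)
print("population-preferred model:", fits["population_preferred"].label)
print(fits["bic_table"].round(1).iloc[:3, [0, -1]])

cue_auc, outcome_auc = cohort_auc_tables(cohort)
glms = electrode_glms(cohort, fits, cue_auc, outcome_auc)
nac_cue = [g for g in glms if g.region == "NAc" and g.design_kind == "cue_value"]
nac_out = [g for g in glms if g.region == "NAc" and g.design_kind == "outcome_rpe"]
print("NAc RPE criteria:", rpe_criteria_check(nac_cue, nac_out))
```

prints

```
population-preferred model: salience+k_cue_specific+recency_weighted
       standard  salience+k_cue_specific+recency_weighted
rat00    1567.6                                    1443.4
rat01    1980.5                                    1421.9
rat02    1587.2                                    1493.9
NAc RPE criteria: {'positive_cue_value': True, 'positive_outcome': True, 'negative_value_at_outcome': True}
```

The full model (salience + cue-specific k + recency-weighted baseline) —
the model generating the data — beats the plain single-α model by ~100–550
BIC points per animal and wins the population comparison, and the simulated
NAc channel passes all three cardinal RPE criteria: its cue response scales
positively with expected value, its outcome response scales positively with
reward delivery and negatively with expectation.

A command-line pipeline mirrors the library:

```bash
pavo2 simulate --n-animals 4 --seed 1 --out out/
pavo2 fit-behaviour --trials out/trials.csv --seed 1 --out out/
pavo2 epoch --traces out/traces --trials out/trials.csv --align cue --out out/auc_cue.csv
pavo2 run-all --seed 1 --out out/run    # everything, ending in the drug contrast
```

## Layout

- `pavo2.task` / `pavo2.agent` / `pavo2.o2sim` / `pavo2.cohort` — synthetic
  study: schedules, RW agent, oxygen traces, whole cohorts
- `pavo2.behaviour` — model grid, ML fitting, BIC comparison
- `pavo2.signals` — epoching, AUC, stage summaries, cross-region correlation
- `pavo2.glm` — model-based designs, OLS effect sizes, RPE criteria
- `pavo2.drug` — discrimination indices, permutation pre/drug contrast
- `pavo2.pipeline` / `pavo2.cli` / `pavo2.io` — end-to-end driver, CLI, I/O

Methodological details and design rationale: [docs/methods.md](docs/methods.md).
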