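# preycat

Virtual predator–prey categorization experiments as a tested, scriptable
pipeline. `preycat` rebuilds a human-foraging-game study in silico:

- **`preycat.communities`** — the five training communities of discrete prey
  phenotypes (36 prey, 1:1 good:bad). A *reliable* trait (2–8 values)
  predicts profitability perfectly; a binary *unreliable* key trait is right
  only 78% of the time. Richness and evenness of the reliable trait's values
  vary across designs; treatments shuffle which shapes/colors play which
  roles. Includes the fixed test community and Hill-number diversity stats.
- **`preycat.game`** — foraging-trial mechanics: sequential presentation of a
  permuted grid, a life bar with a 2:1 cost:benefit ratio (death after 8
  straight bad attacks in training, 4 in pretraining), an 18-attack training
  cap, compulsory pretraining sampling, and feedback-free test trials that
  provably never mutate agent state.
- **`preycat.agents`** — synthetic predators standing in for subjects, one
  archetype per categorization hypothesis: a Rescorla–Wagner compound-cue
  learner (relative validity), a key-trait-only categorizer, a rote
  phenotype memorizer with capacity limits, a random guesser, and a
  composite "humanlike" agent (capacity-limited reliable-value memory with a
  configurable fallback).
- **`preycat.analysis`** — the statistical pipeline: focal-prey filtering and
  good/bad recoding, the no-intercept binomial-logit model with subject fixed
  effects and centered trait/order terms, exact delta-method contrasts
  (per-experiment trait effects, their difference = relative use of the
  reliable trait, their sum = total discrimination), Bonferroni-adjusted
  pairwise comparisons with a compact letter display, and the split-vs-lumped
  likelihood-ratio test for distinct reliable-value coefficients.
- **`preycat.study`** — orchestration: subjects × experiments × treatments
  with balanced random assignment, counter-based per-subject RNG streams,
  tidy CSV persistence (with a column-mapping reader for externally
  deposited data), and end-to-end report generation.

## CLI

```bash
# the five designs and their diversity statistics
preycat communities --out communities.csv

# simulate a study (YAML config optional; every run writes a seed manifest)
preycat simulate --seed 1 --out records.csv

# fit the model, print contrast tables and letter groups, run the LRT
preycat analyze records.csv --out-dir analysis_out

# estimate tables + figure
preycat report records.csv --out-dir report_out
```

A config file can override any study setting, e.g.:

```yaml
n_subjects: 45
master_seed: 7
archetype_mix: {humanlike: 0.8, random: 0.2}
archetype_params:
  humanlike: {capacity: 3, epsilon: 0.05}
```

## Notes

- Agents are explicit models of the competing categorization hypotheses, not
  claims about any real predator; all parameters live in config.
- The model deliberately omits the intercept and trait main effects so the
  per-experiment trait effects are directly readable from the coefficients
  (a marginality violation by design, irrelevant to the nested LRT).
- Random-effect subject terms are out of scope by design; subjects enter as
  fixed effects.
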