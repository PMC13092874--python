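# rlwm-lba

Joint modeling of learning, choice dynamics and EEG decision signals for
the RLWM task — a stimulus-response association task in which
participants learn, block by block, which of three keys goes with each
of 2-5 stimuli under deterministic feedback.

The package is written for computational cognitive neuroscientists who
want a tested, end-to-end reference implementation of this analysis
family: a hybrid **reinforcement-learning / working-memory (RLWM)**
agent whose action policy is transformed into **linear ballistic
accumulator (LBA)** drift rates, fit hierarchically to choice + RT data,
extended with a trial-wise EEG regressor (the pre-response buildup rate
of the centro-parietal positivity, CPP) on drift scaling, plus the
single-trial mass-univariate ERP statistics that accompany such models.
Because raw cohort data of this kind is access-restricted, the package
ships a first-class synthetic-data generator that reproduces the task
design and the generative structure the analyses assume.

## Model

Two modules learn stimulus-action values `Q ∈ [0,1]` (init 1/3) from
reward `r ∈ {0,1}`:

- RL: `Q ← Q + α_eff (r − Q)`, with `α_eff = α_RL` for positive and
  `(1−bias)·α_RL` for negative prediction errors;
- WM: the same with learning rate 1, decaying each trial toward 1/3 at
  rate `φ`.

Softmax policies of the two modules are mixed with weight
`W_WM = ρ · min(1, C/n_s)` (capacity `C`, set size `n_s`), and the
block-average policy's Shannon entropy `H_prior` (bits, pre-stimulus)
quantifies mapping uncertainty.  Choices and RTs follow a 3-accumulator
LBA race with drift rates

```
v_a,t = η_t · π_a,t / H_prior,t ,     η_t = η + z(CPP slope)_t · β_slope
```

(`β_slope = 0` is the baseline model).  Fitting is hierarchical MAP with
Laplace draws; models are compared by PSIS-LOO expected log predictive
density (ELPD).  See `docs/methods.md` for assumptions, priors,
transforms and numerical conventions.

## Worked example

```python
from rlwm_lba.synth import GeneratorConfig, simulate_behavior
from rlwm_lba import fitting

cfg = GeneratorConfig(n_subjects=20, seed=101, beta_slope_true=0.094)
trials = simulate_behavior(cfg)          # ~390 trials/subject, with latents
fit = fitting.fit_neural(trials, rng_seed=2)
print({k: round(v, 4) for k, v in fit.beta_slope.items()
       if not isinstance(v, list)})
```

prints (exact numbers depend on seeds)

```
{'mean': 0.0947, 'se': 0.0106, 'ci_low': 0.0739, 'ci_high': 0.1154,
 'tau2': 0.0, 'group_mean': 0.0932}
```

i.e. the group-level CPP-slope coefficient recovered from a cohort
generated with `β_slope = 0.094` is 0.095 with a 95% interval
[0.074, 0.115] that excludes zero: trial-by-trial neural buildup
informs the drift scaling, and the fit can detect it at 20 subjects.

The same pipeline is scriptable from the shell:

```
rlwm-lba simulate      --seed 3 --out run/sim --set generator.n_subjects=6
rlwm-lba simulate-eeg  --seed 3 --trials run/sim/trials.tsv --out run/eeg
rlwm-lba cpp-slope     --epochs run/eeg/epochs_response.h5 --out run/slopes
rlwm-lba fit           --seed 3 --trials run/sim/trials.tsv --out run/fit_base
rlwm-lba fit-neural    --seed 3 --trials run/sim/trials.tsv --out run/fit_neural
rlwm-lba compare       --fit-a run/fit_neural --fit-b run/fit_base --out run/comp
rlwm-lba erp-glm       --trials run/sim/trials.tsv --epochs run/eeg/epochs_stimulus.h5 \
                       --lock stimulus --out run/glm
rlwm-lba slope-regression --trials run/sim/trials.tsv \
                       --slopes run/slopes/cpp_slopes.tsv --out run/sr
```

Artifacts are TSV (trial tables, coefficients), HDF5 (epochs, stat
maps) and JSON (fit and comparison summaries); every command echoes its
configuration and derives stage seeds from the global seed.

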