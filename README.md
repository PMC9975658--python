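# speechsync

Behavioural measures of auditory-motor coupling in speech, as a tested,
reusable Python pipeline — for researchers who study how listeners' own
speech-motor rhythms relate to their speech comprehension.

Experiments of this kind derive, per participant:

* **auditory-motor synchronization** — the phase-locking value (PLV) between
  the cochlear envelope of a syllable-train stimulus and the Hilbert
  envelope of the participant's whispered speech,

  `PLV = (1/T) | Σ_t exp(i (θ1(t) − θ2(t))) |`,

  computed in 5 s windows (2 s overlap) on 100 Hz envelopes bandpass
  filtered to 3.5–5.5 Hz, averaged within trial and across runs; k-means
  (k = 2) on the cohort's mean PLVs labels each participant a HIGH or LOW
  synchronizer;
* **spontaneous speech motor production rate** — syllable nuclei detected
  as intensity peaks, divided by the utterance duration excluding silent
  pauses (syl/s);
* **preferred auditory rate** — two-interval forced-choice (2IFC)
  preferences over syllabic rates 3.00–8.50 syl/s, aggregated into per-rate
  counts and fitted with a Gaussian; the peak is the preferred rate, the
  FWHM (= 2√(2 ln 2) σ) the specificity;
* **sentence predictability** — perplexity `(∏ p_i)^(−1/N)` from per-word
  probabilities (a pluggable provider; an add-k n-gram model is included);
* **comprehension scores** — word-identification percentages (multiset
  matching) and binary word-order judgements, plus a per-item word-order
  index from a control cohort.

Trial-level inference is a binomial-logit mixed model with crossed random
intercepts (participant, item) and a by-participant random slope for
syllabic rate, z-scored continuous predictors (so `OR = exp(β)` per SD),
Wald tests, likelihood-ratio model comparison, Benjamini–Hochberg FDR and
VIF collinearity checks. The fit uses a Laplace approximation of the
random-effects integral (the same approximation `lme4::glmer` uses) and is
cross-checked against `lme4` in the test suite.

Because speech recordings from such studies typically cannot be shared, the
package ships a first-class synthetic-data generator (`speechsync.synthetic`)
producing every input with known ground truth: ramping syllable trains
(4.3 → 4.7 syl/s every 60 syllables), von-Mises-coupled phase pairs whose
expected PLV is the Bessel ratio I₁(κ)/I₀(κ), bimodal synchronizer cohorts
(group means ≈ 0.73 / 0.36), burst speech with known nuclei, latent-Gaussian
2IFC choices and logit-model comprehension outcomes.

## Worked example

```python
from speechsync import synthetic as syn, sync

# a cohort of 10 high and 10 low synchronizers, 2 trials each
pop = syn.make_population(syn.PopulationSpec(n_high=10, n_low=10, seed=0))
plvs = [sync.participant_plv([sync.windowed_plv(t1, t2)
                              for t1, t2 in p.trials]) for p in pop]
cls = sync.classify_synchronizers(plvs, seed=0)
print(f"centers LOW {cls.cluster_centers[0]:.3f} "
      f"HIGH {cls.cluster_centers[1]:.3f}")
print("agreement:", sum(c == p.true_label
      for c, p in zip(cls.labels, pop)) / len(pop))
```

prints

```
centers LOW 0.387 HIGH 0.744
agreement: 0.95
```

— the k-means centers sit near the generating group means (≈ 0.36 / 0.73
PLV) and 19 of the 20 participants land in their true group (one low
synchronizer drew an individual coupling strong enough to cross over).

The full pipeline, from generators through the mixed model:

```sh
speechsync run-all --seed 0 --participants 20 --items 60 --outdir out/
```

which reports `label agreement 85.00%`, `motor-rate RMSE 0.032 syl/s`, and
the fitted odds ratio per term next to the generating one
(`OR[syllabic_rate] = 0.607 (true 0.65)`; estimates are noisy at this small
demo scale, tight at the full 82 × 240 scale used by the tests).

Each stage is also exposed as its own subcommand (`synth`, `envelope`,
`sync`, `classify`, `rates`, `predictability`, `score`, `infer`); see
`speechsync --help`.

## Documentation

`docs/methods.md` describes the models, defaults, numerical choices and
known limitations.
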