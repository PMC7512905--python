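# eegattn

Decoding **auditory object-specific attention** from single-trial EEG
with entropy features and machine learning.

When a listener attends to one of several concurrent sound sources, the
complexity of their ongoing cortical activity changes. `eegattn`
implements a complete pipeline that identifies which of three attention
states — `Rest` (eyes closed, no stimulus), `AOA1` (attending auditory
object 1) or `AOA2` (attending auditory object 2) — produced a single
60-second trial of 8-channel EEG (T7, T8, P7, P8, Cz, Fz, P3, P4 at
500 Hz), *without any access to the auditory stimulus itself*:

1. **Preprocessing** — per-channel linear detrending and 9-level db4
   wavelet denoising (drop D1, D2 and A9 ⇒ effective band 0.5–62.5 Hz);
2. **Entropy features** — approximate entropy (ApEn), sample entropy
   (SampEn), composite multiscale entropy (CmpMSE) and fuzzy entropy
   (FuzzyEn), one value per channel, with m = 2, t = 1, r = 0.15·STD
   and τ = 30 for CmpMSE (plus optional permutation entropy);
3. **Statistics** — per-channel comparison of the three conditions:
   Bartlett equal-variance and Shapiro–Wilk normality gates dispatching
   one-way ANOVA or Kruskal–Wallis, followed by pairwise contrasts at
   the Bonferroni threshold 0.05/3;
4. **Classification** — LDA (pooled covariance, equal priors) and an
   RBF-kernel SVM under leave-one-out cross-validation over the
   39 trials (13 subjects × 3 conditions), with per-class and average
   identification rates tested against the 33.3 % chance level by a
   chi-squared goodness-of-fit on the per-class correct counts
   (χ² = Σ(O_c − E)²/E, E = 13/3, df = 2).

Because no recordings are publicly deposited for this paradigm, the
package ships a first-class **synthetic-EEG generator** whose
per-condition complexity knob (a 1/f^α spectral exponent) injects the
qualitative effect the real study observed — higher signal complexity
under AOA1 than AOA2 than Rest — so that every stage of the pipeline is
testable end to end. See `docs/methods.md` for the model, its
parameters and its limits.

## Worked example

Simulate the default study (13 subjects × 3 conditions, here at 12 s
per trial to keep the example fast), extract whole-head SampEn features
and evaluate both classifiers:

```python
import eegattn as ea
from eegattn.classify import loocv
from eegattn.preprocess import preprocess_trial

config = ea.SimulationConfig(duration=12.0, seed=1)
trials = [preprocess_trial(t) for t in ea.generate_dataset(config)]
features = ea.extract_features(trials, "sampen")

for kind in ("lda", "svm"):
    res = loocv(features, kind)
    rates = {c: round(v, 1) for c, v in res.per_class_rate.items()}
    print(kind, rates, round(res.average_rate, 1), round(res.chi2_p, 4))
```

prints

```
lda {'Rest': 69.2, 'AOA1': 61.5, 'AOA2': 38.5} 56.4 0.0163
svm {'Rest': 69.2, 'AOA1': 76.9, 'AOA2': 61.5} 69.2 0.0004
```

Each classifier reports the percentage of held-out trials of each
condition identified correctly, their average (the *average
identification rate*), and the chi-squared p-value against random
guessing — here both classifiers decode the injected attention effect
far above the 33.3 % chance level, with the SVM ahead of LDA, mirroring
the qualitative pattern reported for the recorded data.

The same pipeline is available from the shell:

```bash
eegattn run-all --out results/ --subjects 13 --duration 12 --seed 1 \
    --measures sampen,cmpmse --tau 30
```

which writes feature tables (`features_*.tsv`), the statistical cascade
(`stats_*.tsv`/`.json`), the classification table
(`classification.tsv`) and a reproducibility manifest. Sub-commands
`simulate`, `preprocess`, `features`, `stats` and `classify` expose the
individual stages; `--sweep-tau`, `--sweep-r` and `--per-channel`
reproduce the scale-factor, tolerance and per-channel experiment grids.

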