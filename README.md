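# bp-affect

Psychoacoustic predictors and hierarchical Bayesian models of affective
responses to **Bohlen-Pierce triads** — chords from a microtonal system
that repeats at the tritave (3:1) instead of the octave and is unfamiliar
to virtually all listeners.

Because Bohlen-Pierce chords carry no cultural baggage, they are a clean
testbed for separating *intrinsic* drivers of musical affect
(psychoacoustics of the sound itself) from *extrinsic* ones (similarity
to the familiar 12-tone equal-tempered system).  The package provides the
full analysis chain for slider-rating experiments on such chords:

* **`bp_affect.scales`** — equal-tempered and just-intonation BP scales
  (13 steps per tritave), triad enumeration (78 with the tritave, 66
  without; 414 distinct just-intonation realizations), chord realization
  in continuous MIDI pitch, Scala `.scl` I/O.
* **`bp_affect.features`** — five chord-level predictors computed from an
  idealized 64-harmonic spectrum: roughness (summed pairwise sensory
  dissonance, Sethares or Hutchinson–Knopoff), harmonicity (lookup in a
  Gaussian-smoothed triad expectation matrix of the harmonic series),
  spectral entropy H(x) = −Σ xₙ log₂ xₙ of the smoothed composite
  spectrum, average pitch height (and its square), and 12-TET
  dissimilarity (minimal L1 distance to a freely transposed
  integer-semitone chord, solved in closed form via the median).
* **`bp_affect.simulate`** — a generative mirror of the experiment:
  60 participants × 4 blocks × 66 trials, consonance and valence blocks,
  random transposition, a 700-point slider, musical-sophistication
  (GMSI) moderation, correlated participant effects and response
  carry-over.
* **`bp_affect.models`** — Bayesian mixed-effects regressions (Gaussian
  likelihood, Student-t(3, 0, 2.5) population priors) fitted by a
  conjugate blocked Gibbs sampler with arviz diagnostics: the predictive
  model (predictors × GMSI), the descriptive chord-factor model, the
  exposure/learning model, directed hypothesis tests with evidence
  ratios, PSIS-LOO model comparison and Bayesian R².
* **`bp_affect.reporting` / `bp-affect` CLI** — predictor correlations,
  marginal-effects grids, figures, and an end-to-end pipeline with a
  reproducibility manifest.

See `docs/methods.md` for the models, priors, parameter defaults and
their rationale.

## Worked example

```python
from bp_affect import scales, features

et = scales.build_et_scale()
chord = scales.realize_chord(et, scales.ChordPattern(6, 10), root_step=0,
                             base_midi=60.0)
print(tuple(round(p, 2) for p in chord.pitches_midi))

matrix = features.build_triad_expectation_matrix()   # ~2 s, reusable
print(round(features.average_pitch(chord), 1))
print(round(features.tet12_dissimilarity(chord), 2))
print(round(features.roughness(chord), 4))
print(round(features.spectral_entropy(chord), 3))
```

prints

```
(60.0, 68.78, 74.63)
67.8
0.37
0.3415
11.318
```

This is the BP "major" chord 0 6 10 rooted on middle C.  Its average
pitch is 67.8 MIDI; the nearest freely-transposed 12-TET chord
(59.78, 68.78, 74.78) is 0.37 semitones away, so the chord is almost
Western; its roughness (0.34 in the Sethares metric, pooled over
3 × 64 partials) is among the lowest of the 66 BP triads, and it attains
the maximal harmonicity of all 66 because its intervals sit on harmonics
3:5:7 of a common fundamental.

A complete simulated study — features, ratings, model fit, hypothesis
table — in one call:

```python
from bp_affect.reporting import run_pipeline
manifest = run_pipeline("out/", scale="et", seed=1)
```

or from the shell: `bp-affect pipeline --outdir out --seed 1`.

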