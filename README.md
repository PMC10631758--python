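# wmmix

Mixture-model analysis of continuous-report (delayed-estimation) visual
working-memory experiments, built for studies that compare patient groups —
in particular multiple sclerosis subtypes (relapsing-remitting, RRMS, and
secondary progressive, SPMS) against healthy controls.

In a continuous-report task the subject reproduces a remembered feature on
an analog scale: the orientation of a colour-cued bar (sequential analog
report, one- or three-item load) or the position of a target circle after a
delay (memory-guided localization, MGL). Unlike change-detection paradigms,
the error distribution of these tasks can be decomposed into the sources of
recall failure. `wmmix` implements that full analysis chain:

* **Circular error metrics** — recall error as the wrapped angular
  difference (or Euclidean distance for MGL), recall precision as the
  reciprocal (circular) SD of recall error.
* **The three-source swap mixture.** The response θ̂ to a probed item with
  value θ among non-targets θ\*₁…θ\*ₘ is modelled as

  p(θ̂) = p_T · φ(θ̂; θ, κ) + (p_N / m) · Σᵢ φ(θ̂; θ\*ᵢ, κ) + p_U / 2π,

  where φ is the von Mises density with shared concentration κ. p_T is the
  target-response probability, p_N the swap (misbinding) probability and
  p_U the uniform-guessing probability. Fitted per subject by maximum
  likelihood (EM, 20 restarts); κ is reported as the circular SD
  √(−2 ln(I₁(κ)/I₀(κ))).
* **Nearest-neighbor rescoring** — error to the closest presented item,
  which removes the swap component.
* **Group statistics** — mixed-design ANOVA (between: group; within:
  distance / delay / serial order) with Tukey HSD post hoc, plus the
  3×IQR extreme-outlier exclusion rule.
* **ROC discrimination** — pairwise AUC for classifying group membership
  from recall error.
* **Paradigm simulators** — generative emulators of both tasks (block
  structure, balanced probes, 10° consecutive-orientation separation,
  published group-mean parameters), so the entire pipeline runs and is
  tested without any real data.

## Worked example

Simulate one healthy-control three-bar session (6 blocks × 30 trials) at
the group-mean generative parameters and fit the swap mixture:

```python
import numpy as np
from wmmix import GROUP_PROFILES, SequentialDesign, simulate_sequential_subject
from wmmix.mixture import em_fit, trials_from_frame

rng = np.random.default_rng(7)
subject = simulate_sequential_subject(
    GROUP_PROFILES["healthy"], SequentialDesign(), rng, heterogeneity=False
)
fit = em_fit(trials_from_frame(subject.trials, load=3))
print(f"p_target {fit.params.p_target:.3f}  p_nontarget {fit.params.p_nontarget:.3f}  "
      f"p_uniform {fit.params.p_uniform:.3f}  von Mises SD {fit.von_mises_sd:.3f} rad")
```

prints

```
p_target 0.899  p_nontarget 0.070  p_uniform 0.031  von Mises SD 0.515 rad
```

— a single 180-trial session recovers the generating values (0.88 / 0.07 /
0.05, SD 0.51 rad) up to single-subject sampling noise; averaging fits
across a 46-subject cohort pins them down to within ±0.01 (see below). The
full pipeline — simulation or CSV input, outlier exclusion, per-order and
whole-session fits, ANOVAs, ROC — is available programmatically via
`wmmix.run_pipeline` or from the shell:

```sh
wmmix simulate --seed 1 --paradigm sequential3 --out trials.csv
wmmix fit --trials trials.csv --out fits.json
wmmix analyze --seed 1 --out results/
```

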