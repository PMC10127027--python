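# hippoconn

Band-resolved functional-connectivity analysis of multichannel hippocampal
LFP recordings from goal-directed navigation experiments with a detour
(blocked-path) design, together with the behavioral indicators of the task
and the nonparametric statistics that compare task phases.

The package is written for systems-neuroscience analysts who record local
field potentials from a chronic electrode array (16 channels at 2 kHz in the
default configuration) while an animal learns a preferred maze route
(**acquisition**), has that route blocked and explores (**adjustment**), and
finally stabilizes on a new route (**recovery**). It is a library first —
the importable API plus the narrative scripts in `examples/` are the main
interface — with a thin `hippoconn` command for end-to-end runs.

## The analysis

For every trial and every frequency band, functional connectivity between
channels *x* and *y* is the magnitude-squared spectral coherence

$$\mathrm{Coh}_{x,y}(f) = \frac{|p_{x,y}(f)|^2}{p_x(f)\, p_y(f)},
\qquad
p_{x,y}(f) = \frac{1}{n}\sum_{i=1}^{n} x_i(f)\, y_i^{*}(f),$$

estimated from *n* Hann-tapered windowed FFTs of the trial's signal of
interest, averaged over the FFT bins of each band (delta 1–4, theta 5–12,
beta 13–30, slow gamma 31–45, fast gamma 55–80 Hz). The symmetric,
unit-diagonal coherence matrix is thresholded into a binary network whose
topology is summarized by the clustering coefficient and global efficiency

$$\mathrm{Coef} = \frac{1}{M}\sum_{i=1}^{M}\frac{2E_i}{k_i(k_i-1)},
\qquad
\mathrm{Eff} = \frac{1}{M}\sum_{i\in M}\frac{\sum_{j\in M} d_{ij}^{-1}}{M-1},$$

with $k_i$ the degree of node *i*, $E_i$ the number of edges among its
neighbours, and $d_{ij}$ the unweighted shortest-path length. Behavioral
indicators (trial duration, walked path length) and the network metrics are
compared across phases with two-sided Wilcoxon rank-sum tests
(\*&nbsp;p&nbsp;<&nbsp;0.05, \*\*&nbsp;p&nbsp;<&nbsp;0.01,
\*\*\*&nbsp;p&nbsp;<&nbsp;0.001).

Because raw recordings of this kind are rarely shareable, the package ships
a first-class synthetic-data generator that plants a known band- and
phase-specific coupling structure (depressed delta/theta and elevated gamma
coupling during adjustment; beta flat) and a known behavioral elongation of
the adjustment phase. Every downstream stage is validated against this
planted ground truth. See `docs/methods.md` for the generative model and
its limitations.

## Worked example

`examples/06_full_pipeline.py` runs the whole chain — simulate, low-pass,
channel screen, trial segmentation, per-band coherence, binarization,
topology metrics, distribution fits, rank-sum reports — on a reduced
session (8 trials per phase):

```
fitted coherence means (radar table):
band         delta  theta   beta  slow_gamma  fast_gamma
phase
acquisition  0.568  0.622  0.492       0.126       0.118
adjustment   0.130  0.124  0.498       0.648       0.642
recovery     0.590  0.622  0.493       0.126       0.123

theta clustering-coefficient contrasts:
    phase_a    phase_b  p_value mark
acquisition adjustment 0.000138  ***
acquisition   recovery 1.000000   ns
 adjustment   recovery 0.000138  ***
```

The radar table is the fitted mean of the pooled coherence values per phase
and band: theta and delta connectivity collapse during adjustment
(0.62 → 0.12) while both gamma bands rise (0.12 → 0.65), and beta does not
move — exactly the planted pattern. The contrasts show the corresponding
clustering-coefficient statistics: both adjustment comparisons are
significant at p < 0.001 and acquisition vs recovery is not. The other
examples exercise each stage in isolation and print what the numbers mean.

The same run is available from a shell:

```sh
hippoconn run --seed 5 --out out/            # full defaults (20 trials/phase)
hippoconn simulate --seed 1 --out session/   # write a raw synthetic session
hippoconn validate --config cfg.yaml         # check a configuration file
```

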