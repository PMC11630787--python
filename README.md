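# commonmap

**Data-driven discovery of common variables across heterogeneous sensor
streams — and of the functions that relate them.**

Two instruments watch the same process, but each also picks up unrelated
dynamics of its own: sensor 1 records variables of a system *X* together
with variables of a system *Y*; sensor 2 records other variables of *X*
together with variables of a system *Z*.  Before any cross-sensor
function can be learned, one must decide *what to relate*: which
combinations of channels carry the shared information, how many degrees
of freedom they span, and which channels are sensor-private and should be
left out.  `commonmap` answers those questions directly from simultaneous
time-series data, with no model of the underlying physics, and then
learns the cross-sensor observer functions — including present→future
maps, which turn common-variable discovery into a data-driven notion of
causality.

## Methods at its core

* **Alternating diffusion maps.**  Each sensor induces a Markov diffusion
  operator `P_i = D⁻¹ W_i` from a Gaussian affinity
  `W_ij = exp(−‖x_i − x_j‖²/ε)` on its own observation space (with
  density-correcting α-normalization, α = 1).  The eigenvectors of the
  product `P₁P₂` parameterize exactly the structure *both* sensors see:
  each sensor's private directions look like fast-mixing noise to the
  other and are averaged away.
* **LLR parsimony and identifiability.**  Successive eigenvectors are
  scored by leave-one-out local-linear-regression residuals against the
  ones already retained: a residual near 1 marks a genuinely new
  direction, near 0 a harmonic.  The retained set is the *parsimonious*
  common embedding, and the same residual applied to a sensor channel
  decides whether that channel is a function of the common variables
  (identifiable — predictable from the other sensor) or not.
* **Jointly smooth functions (JSF).**  An alternative route: take each
  sensor's leading `d` diffusion eigenfunctions as a basis of smooth
  functions, stack the two orthonormal bases as `[U₁ U₂]`, and read the
  common functions off its SVD — singular value `√2` means a function
  lies in both smooth subspaces.
* **Output-informed diffusion maps.**  To factor one sensor's geometry
  into common and *uncommon* coordinates, re-embed it with the kernel
  `w(y_i,y_j) = exp(−‖f(y_i)−f(y_j)‖²/ε² − ‖y_i−y_j‖²/ε)` using the
  common embedding as the output response `f`: level sets of the common
  variables are resolved last, so the sensor-private directions appear as
  separate eigenvectors.
* **Observers.**  Any regressor can then learn identifiable channels of
  one sensor from common coordinates of the other; k-nearest neighbors,
  geometric harmonics (Nyström extension) and a small feed-forward
  network are provided, scored by the normalized maximum deviation
  `ε = ‖truth − predicted‖_∞ / n_samples` with `n_samples = 200`.

Every experiment is fed by bundled simulators of three benchmark ODE
systems: a surface-reaction limit cycle (*X*, the common system), its
quasiperiodically forced variant (*Y*), and the Lorenz attractor (*Z*).

## Worked example

```python
from commonmap import AlternatingDiffusionMaps, make_experiment_streams, StreamConfig

s1, s2, truth = make_experiment_streams("clean", StreamConfig())
result = AlternatingDiffusionMaps(s1, s2).fit()
print(result.common_dimension)                       # 2
for j, name in enumerate(s1.channel_names):
    print(name, result.channel_identifiability(s1.samples[:, j], sensor=1))
```

or, end to end from the shell:

```bash
commonmap reproduce --experiment clean --out clean_report.json
```

which prints (abridged):

```
Experiment: clean
===============================================
common dimension        : 2
unique eigenvectors     : ['phi2', 'phi3']
jointly smooth functions: 7 of 10
channel identifiability (LLR residual vs common coords):
  S1[0] theta_A(X)(t)            0.0261
  S1[1] theta_A(Y)(t)            0.9744
  S1[2] theta_A(X)(t-200)        0.0172
  S1[3] theta_A(Y)(t-200)        0.9800
  S2[0] theta_B(X)(t)            0.1243
  S2[1] y(Z)(t)                  1.0029
  S2[2] theta_B(X)(t-200)        0.1335
  S2[3] y(Z)(t-200)              1.0021
observer test errors (max-dev / nsamples):
  knn                          4.78772e-05  (L_inf 0.00957543)
```

Reading it: the two sensors share exactly **two** common degrees of
freedom (the phase plane of the *X* limit cycle, parameterized by
eigenvectors φ₂, φ₃); the channels drawn from *X* have LLR residuals
near 0 (they are functions of the common variables, hence observable from
the other sensor), while the *Y*- and *Z*-derived channels score near 1
(sensor-private, unpredictable); seven of the first ten jointly smooth
functions are genuinely common; and a 5-nearest-neighbor observer
trained on 50 samples predicts the other sensor's clean *X* channel with
a worst-case error of ~0.01 coverage units over 200 test samples.

Other experiment tags: `causal1`, `causal2` (sensor 2 reads the common
system 200/250 time units into the future; the learned map is a
discrete-time evolution model), `mixed` (all channels are fixed linear
mixtures — the common embedding survives, but individual sensor-2
channels become structurally unidentifiable), and `factorize`
(output-informed splitting of sensor 1 into common and uncommon
coordinates).

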