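# medetect

Maximum-likelihood **event detection and classification from multimodal time
series** — simultaneous spike trains (point processes) and continuous field
signals (Gaussian) — as arises when decoding discrete behavioral events, such
as saccadic eye movements, from jointly recorded neuronal spiking and local
field potentials (LFPs) without knowing the event times in advance.

## The model and the detector

An event at time `t_s` with class `s ∈ {1..S}` (a direction, encoded one-hot)
drives each channel through a finite-support temporal response `r(t)` scaled
by a per-class spatial weight `φ[s]`:

* spike channel `i`: inhomogeneous Poisson with conditional intensity
  `log λ_i(t) = r_i(t − t_s) φ_iᵀs + α_i` (baseline rate `e^{α_i}`);
* field channel `j`: `y_j(t) = r_j(t − t_s) φ_jᵀs + w_j(t)`,
  `w_j ~ N(0, σ_j²)`.

Channels are conditionally independent given the event, so the joint
log-likelihood is a sum of per-channel terms. Maximizing it over `(t_s, s)`
reduces, after dropping terms constant in the candidates, to maximizing `S`
matched-filter traces

```
L_s(t) = Σ_i [ φ_iᵀs · (u_i * r_i(−·))(t) − Q_i(s) ]
       + k · Σ_j (1/σ_j²) [ φ_jᵀs · (y_j * r_j(−·))(t) − ½ (φ_jᵀs)² Σ_t r_j(t)² ]
```

where `u_i` is the binary spike train, `*` is convolution with the
time-reversed kernel, `Q_i(s)` is the integrated spike intensity given one
class-`s` event, and `k > 0` is a cross-modal scale that weighs the
continuous modality against the discrete one (a Gaussian likelihood is a
density, so it is scale-sensitive even at fixed SNR; `k` also absorbs model
mismatch). Peaks of `x(t) = max_s L_s(t)` are maximum-likelihood event
times; the argmax class at a peak is the class estimate. With `k = 1` the
traces reproduce exact joint log-likelihood differences, which is how the
implementation is tested. The traces can also be computed causally with a
fixed delay equal to the kernels' right edge.

The package provides, as separate modules:

| module | contents |
| --- | --- |
| `medetect.model` | model types and exact log-likelihoods (the brute-force oracle) |
| `medetect.simulate` | direction-tuned synthetic recordings with ground truth |
| `medetect.fit` | template learning (event-triggered averages / smoothed PSTHs + rank-1 factorization + Poisson ML refinement) and grid-search of `k` |
| `medetect.detect` | matched filters, offset terms, peak picking, causal mode |
| `medetect.evaluate` | tolerance-window ROC/AUC, class accuracy, timing NRMSE, channel-count sweeps |
| `medetect.cli` | `medetect simulate | fit | detect | evaluate | sweep` |

## Worked example

```python
from medetect import SimulationConfig, simulate_dataset, med_output, evaluate_output
from medetect.fit import fit_model

cfg = SimulationConfig(n_events=160, seed=1)   # SNR 0.1, 5+5 channels, 8 classes
model, events, rec = simulate_dataset(cfg)

fitted = fit_model(rec, events, window=(0.0, 0.3))   # learn r, phi, alpha, sigma^2
out = med_output(rec, fitted)                        # S per-class detector traces
report = evaluate_output(out, events, tol=0.2)

print(f"events: {len(events)} over {events.duration:.1f} s")
print(f"detection AUC:  {report.auc:.3f}")
print(f"accuracy:       {report.accuracy:.3f}  (chance 0.125)")
print(f"timing NRMSE:   {report.nrmse:.3f}")
```

prints

```
events: 160 over 321.9 s
detection AUC:  1.000
accuracy:       0.969  (chance 0.125)
timing NRMSE:   0.032
```

i.e. on a 5-minute continuous simulated recording at SNR 0.1, every one of
the 160 events is detected within the 200 ms tolerance (AUC 1.0), 96.9% are
assigned the correct direction out of 8 (chance 12.5%), and the RMS timing
error is ~3% of the tolerance window (~6 ms). The same pipeline runs from
the shell: `medetect simulate … | fit … | detect … | evaluate …`.

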