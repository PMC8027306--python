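# tempocode

**Does an event-camera dataset carry class information in spike *timing*,
or only in spike *counts*?**

Event (address-event representation, AER) datasets are the standard
benchmarks for spiking neural networks, whose selling point is computation
with precise spike times.  But a dataset recorded by sweeping a camera over
*static images* may contain no usable temporal information at all — in
which case it cannot tell a timing-sensitive learner from a rate-based one.
`tempocode` implements a battery of probes that measures this directly:

1. **Time-collapse baseline** — sum each pixel's events over the window,
   normalise per pattern (`C[x] = count(x) / max_y count(y)`), and train a
   purely spatial classifier.  Its accuracy bounds how much signal survives
   with timing removed.
2. **Rate-regime STDP (RD-STDP)** — a winner-take-all network of LIF
   neurons with lateral inhibition, adaptive thresholds
   (`V_th = v_thresh + θ`), trace STDP
   `Δw = η (x_pre − x_tar)(w_max − w)^μ` with a trace constant
   (τ = 215 ms) longer than the presentation, and an escalation protocol
   that re-presents silent patterns at higher input amplitude.  The trace
   approximates a spike *count*: an order-blind learner.
3. **STDP-tempotron** — the same network with tenth-of-presentation time
   constants, periodic state resets, a self-organising-map neighbourhood,
   and a tempotron classifying the output spike *sequences*: an
   order-sensitive learner.
4. **Fixed-t\* STDP** — re-train with the presynaptic trace evaluated at
   the *mean* postsynaptic spike time instead of the actual one.
5. **PSTH rule** — replace STDP with a kernel `h(t) = aH(t) + b` derived
   from the population event-rate histogram of the training data (LTD area
   > LTP area for stability), applied at the end of each presentation.

If probes 1, 2, 4 and 5 — none of which uses individual spike timing —
match or beat probe 3, the dataset's timing carries no class information.
The package ships synthetic AER generators with *controlled* temporal
content to exercise both outcomes: rate-coded data (Poisson events from
static templates under a shared saccade envelope) and order-coded data
(sweeps whose two classes differ only in activation order, with identical
expected collapsed frames).

## Worked example

```python
from tempocode.synth import (make_templates, raised_cosine_envelope,
                             RateCodedGenConfig, gen_rate_coded_dataset)
from tempocode.frames import collapse_dataset, train_frame_classifier, evaluate
from tempocode.pipelines import (prepare_dataset, default_rate_run_config,
                                 run_rdstdp)

templates = make_templates(4, 24, 24)          # four oriented-bar classes
env = raised_cosine_envelope(105)              # 105 ms saccade envelope
train = gen_rate_coded_dataset(templates, env, RateCodedGenConfig(n_per_class=100, seed=1))
test = gen_rate_coded_dataset(templates, env, RateCodedGenConfig(n_per_class=50, seed=2))

clf = train_frame_classifier(collapse_dataset(train), seed=1)
print(evaluate(clf, collapse_dataset(test)).accuracy)   # 1.0

res = run_rdstdp(prepare_dataset(train), prepare_dataset(test),
                 default_rate_run_config(seed=1))
print(res.accuracy)                                     # 1.0
```

The collapsed-frame classifier reaches 100% and unsupervised rate-regime
STDP 100% on this rate-coded data — timing is dispensable.  The
`analysis/` drivers run the full story; on the fixed study datasets they
print:

```
rate-coded:  rdstdp 100.0% vs tempotron 98.0%  ->  rate-regime STDP wins
order-coded: rdstdp  52.0% vs tempotron 98.0%  ->  STDP-tempotron wins
```

together with the collapse baseline (100% vs 50% — chance — on the two
datasets), the fixed-t\* run (99.5% vs 100.0% free), and the PSTH rule
(99.0%, histogram/envelope correlation 0.9996).  Order-coded data needs the
temporal machinery; rate-coded data does not.

## Layout

```
src/tempocode/       the library: events, synth, frames, network,
                     plasticity, readout, pipelines
analysis/01..06      numbered drivers: generate data, collapse baseline,
                     STDP contrast, fixed-t*, PSTH rule, DSE protocol
docs/methods.md      model equations, parameter defaults, design rationale
tests/               unit, property and end-to-end acceptance tests
```

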