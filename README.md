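# grandloop

A closed-loop spiking-network simulator of cortico–basal-ganglia–thalamic
exchange, with an information-theoretic measurement suite.

## The problem

Models of single neural tissues need naturalistic inputs, which in real
brains come from millions of upstream neurons.  `grandloop` sidesteps that
by closing the loop: four small component networks drive each other with no
external input, so every signal a tissue receives is generated by the rest
of the modeled brain.  The package is for computational neuroscientists who
want a seeded, configurable sandbox for studying *system set points* —
firing rates, burst statistics, transition rates, population entropy and
mutual information — and how neuromodulation shifts them.

## The model

Four component networks are coupled through eight interfaces around a ring
of four cortical areas (M1 → M_sup → S_sec → S1 → M1 in the feedback
direction; feed-forward relays run the reverse):

* **Cortical layer 5** — a self-organizing recurrent network of N_E = 400
  binary units: x_i(t+1) = H[U_i·(W_EE x)_i − (W_EI y)_i + ξ_i − T_E,i],
  with pair STDP, inhibitory STDP, intrinsic plasticity toward a target
  rate μ_IP = 0.1 (→ 100 spikes/s at 1-ms steps), row normalization,
  pruning and synaptogenesis.  Development self-organizes a closed ring of
  propagation layers (the four areas) that carries synfire "traversals".
* **Cortical layer 2/3** — per-area Infomax: y = σ(C x_I + w0), with
  ΔC = β_C[(Cᵀ)⁻¹ + (1 − 2y) x_Iᵀ], Δw0 = β_w0(1 − 2y), and a lateral
  network (Q̂, v) that can estimate the anti-redundancy term (Cᵀ)⁻¹ locally.
  Its outputs set the layer-5 gain U_j = [1 − Ach(1 − y_j)]/[1 − Ach/2],
  where Ach ∈ [0, 1] models cholinergic modulation.
* **Striatum** — 100 medium spiny neurons (50 D1, 50 D2) as
  FitzHugh–Nagumo units with weak asymmetric lateral inhibition
  (winnerless competition): τ₁ẋ = x − x³/3 − y − z(x − ν) + I,
  ẏ = x − by + a, τ₂ż = ΣW_Str H(x) − z.  Burst output P = max(x, 0);
  corticostriatal synapses undergo STDP gated by the sign of P′ and
  modulated by MSN type, dopamine presence, and GABA level (high z flips
  the sign), normalized so each MSN's input sum never exceeds 0.1.
* **Dopamine neurons** — 20 adaptive-threshold integrate-and-fire cells
  with two spike-induced currents.  Sustained striatal inhibition
  (I_e = −2.25 ΣP) drags the threshold down; release triggers a rebound
  burst of exactly four spikes, which stamps dopamine-present windows
  (τ_DA) onto assigned corticostriatal synapses.

The basal ganglia gate feed-forward thalamic relay to the frontal areas:
Ĝ = H[D·P(x_f)], where D holds +1 for direct-pathway (D1) and −1 for
indirect-pathway (D2) inputs.

## Worked example

```python
import numpy as np
from grandloop import DopamineConfig, StriatumConfig
from grandloop.dopamine import init_dopamine, step_dopamine
from grandloop.striatum import init_striatum, step_striatum
from grandloop.measure import all_transient_durations

# dopamine rebound burst
da = init_dopamine(DopamineConfig(N_DA=1), seed=0)
spike_times = []
for t in range(2000):                      # 2 s at 1-ms steps
    I_e = -4.5 if 100 <= t < 600 else 0.0  # 500 ms of striatal inhibition
    _, spikes = step_dopamine(da, I_e)
    if spikes[0]:
        spike_times.append(t)
print("rebound spikes at t =", spike_times, "ms")

# striatal winnerless network burst statistics
st = init_striatum(StriatumConfig(), seed=1)
x_f = np.empty((60_000, st.n))             # 60 s of model time
for t in range(60_000):
    step_striatum(st)
    x_f[t] = st.x_f
durs = all_transient_durations(x_f)
print(f"{durs.size} MSN bursts, mean duration {durs.mean():.0f} ms")
```

prints

```
rebound spikes at t = [636, 640, 644, 650] ms
484 MSN bursts, mean duration 340 ms
```

The four spikes 36–50 ms after release from inhibition are the rebound
burst, terminated intrinsically by the accumulating hyperpolarizing
spike-induced current.  The striatal bursts are the ~350-ms positive
transients of the burst potential under winnerless turn-taking.

A full closed-loop run (development → bias adjustment → main phase) from
the shell:

```bash
grandloop run --seed 7 --ach 0.5 --tau-da 100 --steps 350000 --out runs/demo
grandloop measure --artifacts runs/demo
grandloop sweep --seed 7 --out runs/sweep     # all (Ach x tau_DA) conditions
```

`run` writes spike events (`spikes.csv`), continuous traces and weight
matrices (`traces.h5`), and a manifest with the config hash and seed;
`measure` computes rates, burst durations, dwell times, population entropy
and cortex–dopamine mutual information from those artifacts.

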