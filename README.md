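# cx36mg

Kinetic modelling of Mg²⁺ regulation of Cx36 gap-junction channels.

Connexin36 (Cx36) gap junctions — the channels of electrical synapses in
the CNS — are uniquely sensitive to cytosolic Mg²⁺: raising intracellular
Mg²⁺ closes them over minutes. This package implements the modelling side
of that problem for electrophysiologists and modellers: a catalogue of
candidate 3-state hemichannel gating schemes, a coupled two-cell simulator
of junctional conductance (g_j) and transjunctional Mg²⁺ flux, simultaneous
least-squares fitting of conductance + fluorescence traces, AIC-based model
selection with Akaike weights, and a synthetic-data generator that emulates
dual whole-cell recording protocols so the whole pipeline is testable
without raw recordings.

## The model

Each hemichannel follows a linear 3-state chain

```
S0  <->(k1/k2)  S1  <->(k3/k4)  S2
```

where either transition may carry a ligand factor, `k · [Mg²⁺]ⁿ` (Hill
binding; mass action is n = 1 fixed). Enumerating which transition binds
Mg²⁺ and whether the intermediate state conducts — and discarding schemes
with no Mg²⁺ dependence plus the redundant open–open gating scheme — gives
five basic schemes × two binding laws = ten candidate models. The preferred
candidate ("Model 5, Hill") is

```
O  <-k1/k2->  C  <-k3·[Mg²⁺]ⁿ / k4->  C·Mg²⁺
```

i.e. ligand-independent stochastic gating followed by Mg²⁺ binding to, and
stabilisation of, the closed conformation, with single-hemichannel ODEs

```
d[O]/dt    = −k1·[O] + k2·[C]
d[C]/dt    =  k1·[O] − (k2 + k3·[Mg²⁺]ⁿ)·[C] + k4·[C·Mg]
d[C·Mg]/dt =  k3·[Mg²⁺]ⁿ·[C] − k4·[C·Mg]
```

and conservation `[O] + [C] + [C·Mg] = 1`. Two hemichannels in series give
`g_j = [O]₁·[O]₂`, and cytosolic Mg²⁺ in an unclamped cell evolves by
Fickian exchange through the junction, `d[Mg]ᵢ/dt = +P·g_j·([Mg]ⱼ − [Mg]ᵢ)
− P_leak·[Mg]ᵢ`. Model ranking uses `AIC = 2(k+1) + n·ln(SSE) − n·ln(n)`
and Akaike weights `wᵢ = exp(−ΔAICᵢ/2) / Σⱼ exp(−ΔAICⱼ/2)`.

Fitting and selection are exposed as scikit-learn-style estimators
(`GatingModelFitter`, `SchemeSelector`) with `fit`/`predict` and fitted
attributes (`params_`, `sse_`, `comparison_`, ...); `fit_global` and
`compare_models` are functional wrappers.

## Worked example

```python
import cx36mg as m

scheme = m.get_scheme("Model 5, Hill")
wt = m.VARIANT_PARAMS["WT"]          # built-in Cx36 wild-type estimates

# symmetric 5 mM Mg2+ in both pipettes, 5 minutes
trace = m.simulate_pair(scheme, wt, m.symmetric_protocol(5.0))
print(m.trace_summary(trace))
# {'gj_ss_over_init': 0.227, 'gj_final_over_init': 0.220, 'fi_final_over_init': 1.0}

# asymmetric: donor pipette 10 mM, recipient read out by Mag-Fluo-4 proxy
asym = m.simulate_pair(scheme, wt, m.asymmetric_protocol(10.0))
print(m.trace_summary(asym))
# {'gj_ss_over_init': 0.256, 'gj_final_over_init': 0.252, 'fi_final_over_init': 1.288}

# deep-closed trapping: absorbing trap once both hemichannels are Mg-bound
joint = m.simulate_pair_joint_trap(
    scheme, wt, m.symmetric_protocol(1.0, duration=180.0, sample_interval=1.0),
    eps=0.0,
)
print(joint.extras["p_double_closed"][-1])   # 0.902
```

The first two calls show the Mg²⁺-response index g_j,ss/g_j,init: symmetric
5 mM and one-sided 10 mM produce similar ~4-fold conductance drops, while
the recipient-cell fluorescence proxy rises only in the asymmetric case
(Mg²⁺ flows through the junction). The trapping run shows that slowing
Mg²⁺ unbinding in the doubly-bound state drives >90% of channels into a
long-lived double-closed configuration within 3 hours at 1 mM Mg²⁺.

A command-line pipeline wraps the same library:

```
cx36mg simulate --variant WT --protocol sym_5 --out-dir results/sim
cx36mg make-data --seed 1 --out-dir results/dataset
cx36mg fit --data-dir results/dataset --variant WT --scheme "Model 5, Hill"
cx36mg select --data-dir results/dataset --variant WT
cx36mg recover --variant WT --n-seeds 3
```

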