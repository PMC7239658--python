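# wtanet

A firing-rate simulator and assay toolkit for the circuit basis of
**competitive selection** (winner-take-all choice among options). The package
implements a canonical four-population selection network — input, inhibitory,
amplifier, and output units, one channel per option — in which each circuit
motif can be switched on or off independently:

| Motif | Computational role | Behavioral assay |
|---|---|---|
| global feedforward inhibition | comparison across options | CRP response reduction |
| donut-like inhibition (zero self-inhibition) | categorical selection boundary | categorization index of the CRP |
| reciprocal inhibition-of-inhibition feedback | flexible (norm-tracking) boundary | transition-norm shift ratio |
| point-to-point recurrent amplifiers | unitary output generation | first-to-threshold choice statistics |

An exact winner-take-all **oracle** (`wtanet.ideal`) provides ground truth:
the circuit's steady-state winner is verified against the argmax rule on
randomly sampled norm vectors, and perturbation operations
(`add_self_inhibition`, `silence_feedback`, `set_amplifier_gain`) implement
the corresponding experimental predictions.

The `wtanet.cosmi` module covers the combinatorial inhibitory-coding problem:
multilobe receptive-field codes that serve every ordered channel pair with
fewer inhibitory units than channels, scored by metabolic + wiring cost and
searched exhaustively (globally optimal for L ≤ 6) or greedily, against the
copy-and-paste baseline.

## Library quick start

```python
import numpy as np
import wtanet as w

net = w.build_network(w.default_config(2))        # full circuit, 2 channels
w.steady_state(net, (10, 2)).rates                # channel 0 wins

crp = w.measure_crp(net, norm_A=8, competitor_norms=np.arange(2, 16.1, 1),
                    n_trials=50, seed=0)
w.categorization_index(crp)                       # ~0.85: step-like
w.transition_norm(crp)                            # ~8: boundary at the winner's norm

res = w.flexibility_assay(net, 8, 12, np.arange(2, 16.1, 1), seed=0)
res.shift_ratio                                   # ~1 with feedback on
w.flexibility_assay(w.silence_feedback(net), 8, 12,
                    np.arange(2, 16.1, 1), seed=0).shift_ratio   # ~0

stats = w.unitary_choice_assay(net, (10, 2), threshold=15, n_trials=200, seed=0)
stats.p_unitary, stats.accuracy                   # both ~1.0

code, cost = w.search_min_cost_code(6, max_units=6)   # 4-unit multilobe code
```

## Command line

```bash
wtanet build --config net.yaml --out edges.tsv        # construct + validate
wtanet simulate --config net.yaml --norms 10,2 --duration 300 --seed 1 --out trace.tsv
wtanet assay --config experiment.yaml --seed 1 --out results/
wtanet cosmi-search --channels 6 --max-units 6 --out code.json
```

`net.yaml` mirrors `NetworkConfig` field names (write one with
`wtanet.default_config(2).to_yaml("net.yaml")`); an experiment YAML bundles a
network config with an assay name (`crp`, `flexibility`, `multi_option`,
`unitary_choice`), its parameters, and a master seed. Result bundles carry
full provenance (config hash, seed, package version) and deterministic
reruns are byte-identical.

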