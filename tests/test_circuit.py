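import dataclasses

import numpy as np
import pytest

import wtanet as w
from wtanet.circuit import build_network, to_edgelist, validate_network
from wtanet.cosmi import sperner_code


class TestBuildNetwork:
    def test_two_channel_full_circuit_layout(self, full_net):
        assert full_net.n_channels == 2
        assert full_net.n_inhibitory == 2
        w_io = full_net.weight("inhibitory", "output")
        # donut: inhibition strictly off-channel
        assert w_io[0, 0] == 0 and w_io[1, 1] == 0
        assert w_io[0, 1] < 0 and w_io[1, 0] < 0

    def test_single_channel_degenerate(self):
        net = build_network(w.default_config(1))
        assert not np.any(net.weight("inhibitory", "output"))
        assert not np.any(net.weight("inhibitory", "amplifier"))

    def test_all_motifs_off_is_pure_feedforward(self, bare_net):
        for key in bare_net.weights:
            assert key == ("input", "output"), key
        assert np.allclose(
            bare_net.weight("input", "output"),
            bare_net.config.gains.w_in * np.eye(2),
        )

    def test_multilobe_code_covers_all_ordered_pairs(self):
        code = sperner_code(6, 4)
        cfg = w.default_config(6, cosmi_code=code.rfs)
        net = build_network(cfg)
        w_ei = net.weight("input", "inhibitory")
        w_io = net.weight("inhibitory", "output")
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                served = any(
                    w_ei[i, u] > 0 and w_io[u, j] < 0 for u in range(net.n_inhibitory)
                )
                assert served, f"ordered pair ({i},{j}) not served"

    def test_uncovering_code_rejected_with_named_pair(self):
        with pytest.raises(ValueError, match="coverage"):
            build_network(w.default_config(3, cosmi_code=((0,),)))

    def test_construction_is_deterministic(self, full_cfg):
        a, b = build_network(full_cfg), build_network(full_cfg)
        assert a.weights.keys() == b.weights.keys()
        for key in a.weights:
            assert np.array_equal(a.weights[key], b.weights[key])

    @pytest.mark.parametrize(
        "flag,blocks",
        [
            ("feedback_inhibition", {("inhibitory", "inhibitory")}),
            (
                "amplifiers",
                {
                    ("output", "amplifier"),
                    ("amplifier", "output"),
                    ("inhibitory", "amplifier"),
                },
            ),
        ],
    )
    def test_motif_toggle_touches_only_its_blocks(self, full_cfg, flag, blocks):
        net_on = build_network(full_cfg)
        net_off = build_network(
            full_cfg.replace(motifs=dataclasses.replace(full_cfg.motifs, **{flag: False}))
        )
        shared = set(net_on.weights) & set(net_off.weights)
        for key in shared - blocks:
            assert np.array_equal(net_on.weights[key], net_off.weights[key]), key
        for key in (set(net_on.weights) ^ set(net_off.weights)) | (
            {k for k in shared if not np.array_equal(net_on.weights[k], net_off.weights[k])}
        ):
            assert key in blocks

    def test_indirect_feedback_variant_routes_through_outputs(self, full_cfg):
        net = build_network(full_cfg.replace(feedback_variant="indirect"))
        assert ("inhibitory", "inhibitory") not in net.weights
        assert np.any(net.weight("output", "inhibitory") > 0)


class TestValidateNetwork:
    def test_built_network_passes(self, full_net, full_net6, bare_net):
        for net in (full_net, full_net6, bare_net):
            report = validate_network(net)
            assert report.passed, str(report)

    def test_self_inhibition_flags_donut_violation(self, full_net):
        report = validate_network(w.add_self_inhibition(full_net, 0.5))
        by_name = {c.name: c for c in report.checks}
        assert not by_name["donut_zero_diagonal"].passed
        assert by_name["donut_zero_diagonal"].offenders

    def test_hand_edited_positive_inhibitory_weight_names_edge(self, full_cfg):
        net = build_network(full_cfg)
        bad = net.weight("inhibitory", "output").copy()
        bad[0, 1] = +0.5
        net = dataclasses.replace(
            net, weights={**net.weights, ("inhibitory", "output"): bad}
        )
        report = validate_network(net)
        by_name = {c.name: c for c in report.checks}
        assert not by_name["sign_consistency"].passed
        assert ("inh0", "out1", 0.5) in by_name["sign_consistency"].offenders


class TestAddSelfInhibition:
    def test_zero_fraction_is_identity(self, full_net):
        net = w.add_self_inhibition(full_net, 0.0)
        for key in full_net.weights:
            assert np.array_equal(net.weights[key], full_net.weights[key])

    def test_full_fraction_matches_mean_off_channel_weight(self, full_net):
        net = w.add_self_inhibition(full_net, 1.0)
        w_io = net.weight("inhibitory", "output")
        assert w_io[0, 0] == w_io[0, 1]
        assert w_io[1, 1] == w_io[1, 0]

    def test_half_fraction_adds_exactly_two_entries(self, full_net):
        before = np.count_nonzero(full_net.weight("inhibitory", "output"))
        after = np.count_nonzero(
            w.add_self_inhibition(full_net, 0.5).weight("inhibitory", "output")
        )
        assert after - before == 2

    def test_off_channel_weights_unchanged(self, full_net):
        net = w.add_self_inhibition(full_net, 0.7)
        w0 = full_net.weight("inhibitory", "output")
        w1 = net.weight("inhibitory", "output")
        assert w1[0, 1] == w0[0, 1] and w1[1, 0] == w0[1, 0]

    def test_provenance_recorded(self, full_net):
        net = w.add_self_inhibition(full_net, 0.5)
        assert any("add_self_inhibition" in p for p in net.provenance)

    def test_fraction_out_of_range(self, full_net):
        with pytest.raises(ValueError):
            w.add_self_inhibition(full_net, 1.5)

    def test_requires_donut(self, full_cfg):
        cfg = full_cfg.replace(
            motifs=dataclasses.replace(full_cfg.motifs, donut=False)
        )
        with pytest.raises(ValueError):
            w.add_self_inhibition(build_network(cfg), 0.5)


class TestSilenceFeedback:
    def test_zeroes_inhibitory_block_only(self, full_net):
        net = w.silence_feedback(full_net)
        assert not np.any(net.weight("inhibitory", "inhibitory"))
        for key in net.weights:
            if key != ("inhibitory", "inhibitory"):
                assert np.array_equal(net.weights[key], full_net.weights[key])

    def test_idempotent(self, full_net):
        once = w.silence_feedback(full_net)
        twice = w.silence_feedback(once)
        for key in once.weights:
            assert np.array_equal(once.weights[key], twice.weights[key])

    def test_single_option_steady_state_unchanged(self, full_net):
        before = w.steady_state(full_net, (9.0, 0.0)).rates
        after = w.steady_state(w.silence_feedback(full_net), (9.0, 0.0)).rates
        assert np.allclose(before, after, atol=1e-9)

    def test_requires_feedback_enabled(self, bare_net):
        with pytest.raises(ValueError):
            w.silence_feedback(bare_net)


class TestSetAmplifierGain:
    def test_unit_multiplier_is_identity(self, full_net):
        net = w.set_amplifier_gain(full_net, 0, 1.0)
        for key in full_net.weights:
            assert np.array_equal(net.weights[key], full_net.weights[key])

    def test_zero_multiplier_matches_disabled_amplifiers(self, full_net, full_cfg):
        net = w.set_amplifier_gain(w.set_amplifier_gain(full_net, 0, 0.0), 1, 0.0)
        cfg_off = full_cfg.replace(
            motifs=dataclasses.replace(full_cfg.motifs, amplifiers=False)
        )
        net_off = w.build_network(cfg_off)
        assert np.allclose(
            w.steady_state(net, (10.0, 6.0)).rates,
            w.steady_state(net_off, (10.0, 6.0)).rates,
            atol=1e-9,
        )

    def test_boosting_weaker_option_raises_its_output(self, full_net):
        # near-threshold norms keep the weaker channel partially active
        before = w.steady_state(full_net, (4.3, 4.1)).rates
        boosted = w.set_amplifier_gain(full_net, 1, 3.0)
        after = w.steady_state(boosted, (4.3, 4.1)).rates
        assert after[1] > before[1]

    def test_invalid_channel(self, full_net):
        with pytest.raises(ValueError):
            w.set_amplifier_gain(full_net, 5, 2.0)


class TestExportAndConfig:
    def test_edgelist_signs(self, full_net):
        edges = to_edgelist(full_net)
        assert set(edges.columns) == {"source", "target", "weight", "sign"}
        inh = edges[edges.source.str.startswith("inh")]
        assert (inh.sign == -1).all()
        exc = edges[~edges.source.str.startswith("inh")]
        assert (exc.sign == 1).all()

    def test_config_yaml_round_trip(self, tmp_path, full_cfg):
        path = tmp_path / "cfg.yaml"
        cfg = full_cfg.replace(cosmi_code=((0,), (1,)))
        cfg.to_yaml(path)
        assert w.NetworkConfig.from_yaml(path) == cfg

    def test_config_hash_stable_and_sensitive(self, full_cfg):
        assert full_cfg.config_hash() == w.default_config(2).config_hash()
        assert full_cfg.config_hash() != full_cfg.replace(n_channels=3).config_hash()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            w.NetworkConfig(n_channels=0)
        with pytest.raises(ValueError):
            w.default_config(2, combination_rule="mean")
        with pytest.raises(ValueError):
            w.default_config(2, self_inhibition_fraction=1.2)
        with pytest.raises(ValueError):
            w.default_config(2, gains=w.Gains(w_ie=-1.0))

    def test_softmax_weighted_alias(self):
        cfg = w.default_config(2, combination_rule="softmax-weighted")
        assert cfg.combination_rule == "softmax"
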