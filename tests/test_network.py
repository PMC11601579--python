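"""Network structure, constraints, dynamics, persistence."""

import dataclasses

import numpy as np
import pytest

from sahnet.network import (
    Network,
    NetworkFormatError,
    NetworkSpec,
    activation,
    build_network,
    load_network,
    run_episode,
    save_network,
    step,
)
from sahnet.task import TaskConfig, generate_episode


class TestStructure:
    def test_default_dual_task_network_has_946_weights(self, fresh_default_net):
        assert fresh_default_net.count_weights() == 946
        assert fresh_default_net.count_live_units() == 32

    def test_tiny_network_weight_enumeration(self):
        # 1 task input, 1 excitatory hidden, 1 output, bias:
        # input->hidden (1) + bias->hidden,output (2) + hidden->output (1) = 4
        spec = NetworkSpec(n_task_inputs=1, n_excitatory=1, n_inhibitory=0, n_outputs=1)
        assert build_network(spec, rng_state=0).count_weights() == 4

    def test_no_inhibitory_units_means_no_negative_hidden_weights(self):
        spec = NetworkSpec(n_inhibitory=0)
        net = build_network(spec, rng_state=0)
        hidden = net.hidden_slice
        assert np.all(net.weights[hidden, :] >= 0.0)

    def test_forbidden_connections_absent(self, fresh_default_net):
        net = fresh_default_net
        m = net.mask
        assert not np.diagonal(m).any()
        hid = net.hidden_slice
        inh = slice(hid.start + net.spec.n_excitatory, hid.stop)
        assert not m[inh, inh].any()  # no inhibitory cross-coupling
        out = net.output_slice
        assert not m[out, :].any()  # outputs project nowhere
        task_inputs = slice(0, net.spec.n_task_inputs)
        assert not m[task_inputs, out].any()  # only bias reaches outputs directly

    def test_validator_catches_violations(self, fresh_default_net):
        net = fresh_default_net
        net.validate()
        bad = net.copy()
        hid_start = bad.hidden_slice.start
        # flip an excitatory outgoing weight negative
        cols = np.flatnonzero(bad.mask[hid_start])
        bad.weights[hid_start, cols[0]] = -0.5
        with pytest.raises(AssertionError):
            bad.validate()

    def test_init_weights_within_class_bounds(self, fresh_default_net):
        net = fresh_default_net
        lo, hi = net.bound_matrices()
        w = net.weights[net.mask]
        assert np.all(w >= lo[net.mask]) and np.all(w <= hi[net.mask])
        assert np.all(net.weights[~net.mask] == 0.0)


class TestActivation:
    def test_midpoint(self):
        assert activation(4.0, 4.0, 1.0) == pytest.approx(0.5)

    def test_closed_form_tails(self):
        assert activation(0.0, 4.0, 1.0) == pytest.approx(1 / (1 + np.exp(4)), rel=1e-12)
        assert activation(8.0, 4.0, 1.0) == pytest.approx(1 / (1 + np.exp(-4)), rel=1e-12)

    def test_strictly_increasing_and_temperature_scales_slope(self):
        x = np.linspace(-5, 13, 50)
        y1 = activation(x, 4.0, 1.0)
        assert np.all(np.diff(y1) > 0)
        y_steep = activation(x, 4.0, 0.25)
        # steeper sigmoid crosses the midpoint faster
        assert (y_steep > 0.9).sum() > (y1 > 0.9).sum()

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            activation(1.0, 4.0, 0.0)


class TestStep:
    def test_zero_weights_give_offset_leak(self, fresh_default_net):
        net = fresh_default_net.copy()
        net.weights[:] = 0.0
        a = step(net, np.zeros(net.n_units), np.zeros(net.spec.n_inputs))
        expected = 1 / (1 + np.exp(4))
        np.testing.assert_allclose(a[net.spec.n_inputs:], expected)

    def test_input_units_take_input_row_verbatim(self, fresh_default_net):
        row = np.array([1.0, 0.3, 0.7, 1.0])
        a = step(fresh_default_net, np.zeros(38), row)
        np.testing.assert_array_equal(a[:4], row)

    def test_saturated_bias_drive(self):
        spec = NetworkSpec(n_task_inputs=1, n_excitatory=1, n_inhibitory=0, n_outputs=1)
        net = build_network(spec, rng_state=0)
        net.weights[net.mask] = 0.001
        bias_idx, hid_idx = 1, 2
        net.weights[bias_idx, hid_idx] = 8.0
        prev = np.zeros(net.n_units)
        prev[bias_idx] = 1.0
        a = step(net, prev, np.array([0.0, 1.0]))
        assert a[hid_idx] == pytest.approx(1 / (1 + np.exp(-4)), abs=1e-6)

    def test_dimension_mismatch_raises(self, fresh_default_net):
        with pytest.raises(ValueError):
            step(fresh_default_net, np.zeros(10), np.zeros(4))
        with pytest.raises(ValueError):
            step(fresh_default_net, np.zeros(38), np.zeros(2))


class TestRunEpisode:
    def test_zero_length_episode(self, fresh_default_net):
        ep = generate_episode(TaskConfig(epoch_length=0, target_delay=0), 0)
        trace = run_episode(fresh_default_net, ep)
        assert trace.shape == (0, 38)

    def test_trace_strictly_inside_unit_interval(self, fresh_default_net):
        ep = generate_episode(TaskConfig(alpha=0.3), 1)
        trace = run_episode(fresh_default_net, ep)
        non_input = trace[:, fresh_default_net.spec.n_inputs:]
        assert np.all(non_input > 0.0) and np.all(non_input < 1.0)

    def test_determinism(self, fresh_default_net):
        ep = generate_episode(TaskConfig(alpha=0.3), 2)
        t1 = run_episode(fresh_default_net, ep)
        t2 = run_episode(fresh_default_net, ep)
        np.testing.assert_array_equal(t1, t2)

    def test_one_step_propagation_delay(self, fresh_default_net):
        """Input change at step t first reaches hidden units at t+1 and
        outputs at t+2 -- the reason targets are delayed two steps."""
        cfg = TaskConfig(alpha=0.0, epoch_length=10)
        ep1 = generate_episode(cfg, 3)
        ep2 = generate_episode(cfg, 3)
        t_change = 4
        ep2.inputs[t_change, 1] = 1.0 - ep2.inputs[t_change, 1]
        tr1 = run_episode(fresh_default_net, ep1)
        tr2 = run_episode(fresh_default_net, ep2)
        hid = fresh_default_net.hidden_slice
        out = fresh_default_net.output_slice
        assert np.array_equal(tr1[: t_change + 1, hid], tr2[: t_change + 1, hid])
        assert not np.array_equal(tr1[t_change + 1, hid], tr2[t_change + 1, hid])
        assert np.array_equal(tr1[: t_change + 2, out], tr2[: t_change + 2, out])
        assert not np.array_equal(tr1[t_change + 2, out], tr2[t_change + 2, out])

    def test_wrong_input_count_rejected(self, fresh_default_net):
        ep = generate_episode(TaskConfig(n_signals=1), 0)
        with pytest.raises(ValueError):
            run_episode(fresh_default_net, ep)


class TestPersistence:
    def test_round_trip_lossless(self, tmp_path, fresh_default_net):
        path = tmp_path / "net.json"
        save_network(fresh_default_net, path)
        loaded = load_network(path)
        np.testing.assert_array_equal(loaded.weights, fresh_default_net.weights)
        np.testing.assert_array_equal(loaded.mask, fresh_default_net.mask)
        np.testing.assert_array_equal(loaded.alive, fresh_default_net.alive)
        assert loaded.spec == fresh_default_net.spec

    def test_missing_field_rejected(self, tmp_path, fresh_default_net):
        import json

        path = tmp_path / "net.json"
        save_network(fresh_default_net, path)
        doc = json.loads(path.read_text())
        del doc["connections"]["weight"]
        path.write_text(json.dumps(doc))
        with pytest.raises(NetworkFormatError, match="weight"):
            load_network(path)

    def test_version_mismatch_rejected(self, tmp_path, fresh_default_net):
        import json

        path = tmp_path / "net.json"
        save_network(fresh_default_net, path)
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(NetworkFormatError, match="version"):
            load_network(path)

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "net.json"
        path.write_text("not json {")
        with pytest.raises(NetworkFormatError):
            load_network(path)
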