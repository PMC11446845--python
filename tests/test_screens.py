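"""Screen orchestration logic on planted circuits."""

import itertools

import numpy as np
import pandas as pd
import pytest

import connlif as cl
from connlif.errors import CalibrationError
from connlif.screens import ScreenResult

from conftest import FAST, triplet_weights

P = cl.DEFAULT_PARAMS


@pytest.fixture(scope="module")
def relay_chain():
    """sensory(3) -> relay -> readout, all excitatory, decisive weights."""
    trips = [(f"s{i}", "relay", 10.0) for i in range(3)]
    trips += [("relay", "readout", 60.0)]
    trips += [("s0", "bystander", 0.5)]   # weakly driven side neuron
    return triplet_weights(trips)


SENSORY = ("s0", "s1", "s2")


class TestActivationScreen:
    def test_output_rate_monotone_in_drive(self, relay_chain):
        res = cl.activation_screen(relay_chain, P, SENSORY,
                                   [30, 60, 120], seed=1, **FAST)
        out = res.matrix("neuron_id", "stim_rate_hz").loc["readout"]
        assert out.iloc[-1] > 0
        assert (np.diff(out.values) >= -1.0).all()  # sampling-noise slack

    def test_zero_rate_grid_gives_silence(self, relay_chain):
        res = cl.activation_screen(relay_chain, P, SENSORY, [0.0],
                                   seed=1, **FAST)
        assert (res.data["rate_hz"] == 0).all()

    def test_disconnected_component_stays_silent(self, params):
        w = triplet_weights([("s", "m", 10.0), ("x", "y", 10.0)])
        res = cl.activation_screen(w, params, ["s"], [100], seed=1, **FAST)
        sub = res.data.set_index("neuron_id")["rate_hz"]
        assert sub["m"] > 0 and sub["x"] == 0 and sub["y"] == 0

    def test_empty_stim_set_rejected(self, relay_chain):
        with pytest.raises(ValueError):
            cl.activation_screen(relay_chain, P, [], [100], **FAST)


class TestResponderSet:
    def test_strictly_positive_rule(self, relay_chain):
        res = cl.activation_screen(relay_chain, P, SENSORY, [100],
                                   seed=1, **FAST)
        hits = cl.responder_set(res, 100)
        assert {"s0", "s1", "s2", "relay", "readout"} <= hits

    def test_rate_not_in_grid_rejected(self, relay_chain):
        res = cl.activation_screen(relay_chain, P, SENSORY, [100],
                                   seed=1, **FAST)
        with pytest.raises(ValueError):
            cl.responder_set(res, 55)

    def test_all_zero_table_gives_empty_set(self):
        data = pd.DataFrame({"neuron_id": ["a", "b"],
                             "stim_rate_hz": [50.0, 50.0],
                             "rate_hz": [0.0, 0.0]})
        res = ScreenResult("activation", data, {"rate_grid": [50.0]})
        assert cl.responder_set(res, 50) == set()

    def test_single_spike_in_one_trial_counts(self):
        # mean rate > 0 even for one spike across trials: strict rule
        data = pd.DataFrame({"neuron_id": ["a"], "stim_rate_hz": [50.0],
                             "rate_hz": [1 / 30]})
        res = ScreenResult("activation", data, {"rate_grid": [50.0]})
        assert cl.responder_set(res, 50) == {"a"}


class TestSufficiencyScreen:
    def test_reachability(self, relay_chain):
        res = cl.sufficiency_screen(relay_chain, P,
                                    ["relay", "bystander"], [100, 150],
                                    ["readout"], seed=2, **FAST)
        m = res.data.set_index(["candidate", "stim_rate_hz"])["rate_hz"]
        assert m.loc[("relay", 150.0)] > 0          # sole strong exciter
        assert m.loc[("bystander", 150.0)] == 0     # no path to readout

    def test_inhibitory_candidate_on_silent_network(self, params):
        w = triplet_weights([("inh", "m", -20.0), ("m", "out", 10.0)])
        res = cl.sufficiency_screen(w, params, ["inh"], [100], ["out"],
                                    seed=2, **FAST)
        assert (res.data["rate_hz"] == 0).all()

    def test_unit_activation_drives_all_members(self, relay_chain):
        units = {"sensory_type": list(SENSORY)}
        res = cl.sufficiency_screen(relay_chain, P, ["sensory_type"], [100],
                                    ["readout"], units=units, seed=2, **FAST)
        assert res.data["rate_hz"].iloc[0] > 0


class TestSilencingScreen:
    def test_relay_silencing_zeroes_readout(self, relay_chain):
        res = cl.silencing_screen(relay_chain, P, SENSORY,
                                  ["relay", "bystander"], "readout",
                                  stim_rates=[80, 120], seed=3, **FAST)
        m = res.data.set_index(["candidate", "stim_rate_hz"])["normalized"]
        assert (m.loc["relay"] == 0).all()
        labels = cl.classify_silencing_phenotype(res)
        assert bool(labels["relay"])

    def test_outputless_candidate_normalizes_to_one(self, relay_chain):
        res = cl.silencing_screen(relay_chain, P, SENSORY, ["bystander"],
                                  "readout", stim_rates=[100], seed=3, **FAST)
        assert (res.data["normalized"] == 1.0).all()

    def test_readout_excluded_from_candidates(self, relay_chain):
        res = cl.silencing_screen(relay_chain, P, SENSORY,
                                  ["relay", "readout"], "readout",
                                  stim_rates=[100], seed=3, **FAST)
        assert "readout" not in set(res.data["candidate"])

    def test_all_zero_control_rejected(self, relay_chain):
        with pytest.raises(ValueError, match="control"):
            cl.silencing_screen(relay_chain, P, SENSORY, ["relay"],
                                "readout", stim_rates=[0.0], seed=3, **FAST)


class TestClassifySilencingPhenotype:
    def _result(self, normalized_by_rate):
        rows = [{"candidate": "c", "stim_rate_hz": r, "normalized": v}
                for r, v in normalized_by_rate.items()]
        return ScreenResult("silencing", pd.DataFrame(rows))

    def test_single_dip_below_threshold_is_phenotype(self):
        res = self._result({50.0: 1.0, 60.0: 0.79, 70.0: 1.0})
        assert bool(cl.classify_silencing_phenotype(res)["c"])

    def test_above_threshold_everywhere_is_no_phenotype(self):
        res = self._result({50.0: 0.81, 60.0: 0.95, 70.0: 1.0})
        assert not bool(cl.classify_silencing_phenotype(res)["c"])

    def test_exact_threshold_counts(self):
        res = self._result({50.0: 0.8})
        assert bool(cl.classify_silencing_phenotype(res)["c"])

    def test_empty_candidates_empty_labels(self):
        res = ScreenResult("silencing", pd.DataFrame(
            columns=["candidate", "stim_rate_hz", "normalized"]))
        assert cl.classify_silencing_phenotype(res).empty


class TestCoactivation:
    def test_zero_rate_marginal_matches_single_screen(self, relay_chain):
        co = cl.coactivation_matrix(relay_chain, P, SENSORY, [60, 120],
                                    ("bystander",), [0, 100], "readout",
                                    seed=4, **FAST)
        single = cl.activation_screen(relay_chain, P, SENSORY, [60, 120],
                                      seed=4, **FAST)
        marg = co.data[co.data["rate_b_hz"] == 0].set_index("rate_a_hz")
        ref = single.data[single.data["neuron_id"] == "readout"] \
            .set_index("stim_rate_hz")
        for r in (60.0, 120.0):
            assert marg.loc[r, "rate_hz"] == ref.loc[r, "rate_hz"]

    def test_overlapping_sets_rejected(self, relay_chain):
        with pytest.raises(ValueError):
            cl.coactivation_matrix(relay_chain, P, SENSORY, [50],
                                   ("s0",), [50], "readout", **FAST)

    def test_convergent_inhibition_suppresses(self, params):
        trips = [("a0", "relay", 10.0), ("a1", "relay", 10.0),
                 ("relay", "out", 60.0),
                 ("b0", "relay", -12.0), ("b1", "relay", -12.0)]
        w = triplet_weights(trips)
        co = cl.coactivation_matrix(w, params, ("a0", "a1"), [120],
                                    ("b0", "b1"), [0, 60, 150], "out",
                                    seed=5, n_trials=5, duration_ms=500)
        col = co.data.sort_values("rate_b_hz")["rate_hz"].values
        assert col[0] > 0
        assert col[-1] < col[0]
        assert (np.diff(col) <= 1.0).all()  # monotone up to sampling noise


class TestCalibration:
    def test_already_at_target_returns_zero(self, relay_chain):
        rate = cl.calibrate_input_rate(relay_chain, P, SENSORY, "readout",
                                       target_rate=0.0, grid=[0, 50],
                                       seed=6, **FAST)
        assert rate == 0.0

    def test_matches_brute_force_sweep(self, relay_chain):
        grid = [0, 40, 80, 120, 160]
        target = 10.0
        rate = cl.calibrate_input_rate(relay_chain, P, SENSORY, "readout",
                                       target_rate=target, grid=grid,
                                       seed=6, **FAST)
        # independent exhaustive sweep with the same seeds
        sweep = {}
        for r in grid:
            res = cl.activation_screen(relay_chain, P, SENSORY, [r],
                                       seed=6, **FAST)
            sweep[r] = res.data.set_index("neuron_id").loc["readout",
                                                           "rate_hz"]
        expected = min(r for r in grid if sweep[r] >= target)
        assert rate == expected

    def test_unreachable_target_brackets_error(self, relay_chain):
        with pytest.raises(CalibrationError, match="unreachable"):
            cl.calibrate_input_rate(relay_chain, P, SENSORY, "readout",
                                    target_rate=1e6, grid=[0, 50],
                                    seed=6, **FAST)

    def test_suppress_mode_finds_inhibitory_rate(self, params):
        trips = [("app", "relay", 20.0), ("relay", "out", 60.0),
                 ("av", "relay", -40.0)]
        w = triplet_weights(trips)
        rate = cl.calibrate_input_rate(
            w, params, ("av",), "out", target_rate=1.0, mode="suppress",
            opposing=(("app",), 150.0), grid=[0, 50, 100, 150, 200],
            seed=7, **FAST)
        assert rate > 0


class TestOverlapAnalysis:
    def test_identical_and_disjoint_sets(self):
        s = {"a", "b", "c"}
        out = cl.overlap_analysis({"x": s, "y": set(s)})
        assert out[("x", "y")] == 3 and out[("x",)] == 0
        out = cl.overlap_analysis({"x": {"a"}, "y": {"b"}})
        assert out[("x", "y")] == 0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(12)
        universe = list(range(60))
        sets = {n: set(rng.choice(universe, size=rng.integers(5, 40),
                                  replace=False)) for n in "ABC"}
        out = cl.overlap_analysis(sets)
        for r in range(1, 4):
            for names in itertools.combinations("ABC", r):
                inside = set.intersection(*(sets[n] for n in names))
                outside = set.union(*(sets[n] for n in sets
                                      if n not in names), set())
                assert out[tuple(names)] == len(inside - outside)
        # inclusion-exclusion: region counts sum to |union|
        assert out.sum() == len(set.union(*sets.values()))

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            cl.overlap_analysis({"only": {1}})


class TestShuffleControl:
    def test_unshuffled_pathway_active_and_deterministic(self, relay_chain):
        res = cl.shuffle_control(relay_chain, P, SENSORY, 120.0, "readout",
                                 n_shuffles=2, base_seed=1, n_trials=2,
                                 duration_ms=300)
        control = res.data[res.data["shuffle"] == -1]
        assert bool(control["active"].iloc[0])
        res2 = cl.shuffle_control(relay_chain, P, SENSORY, 120.0, "readout",
                                  n_shuffles=2, base_seed=1, n_trials=2,
                                  duration_ms=300)
        pd.testing.assert_frame_equal(res.data, res2.data)


class TestRobustnessSweep:
    def test_variant_predictions_and_agreement(self, params):
        # glutamatergic relay gates the pathway: prediction flips when
        # glutamate is treated as excitatory
        from conftest import make_sites
        rows = []
        rows += [("s", "relay", 100.0, "ach")] * 80
        rows += [("relay", "out", 100.0, "glut")] * 150
        sites = make_sites(rows)

        def predict(w, p):
            res = cl.activation_screen(w, p, ["s"], [150], seed=8,
                                       n_trials=2, duration_ms=300)
            r = res.data.set_index("neuron_id")["rate_hz"]
            return {"out_active": bool(r["out"] > 0)}

        table = cl.robustness_sweep(sites, params, predict)
        assert not table.loc["default", "out_active"]
        assert table.loc["glutamate_excitatory", "out_active"]
        assert table.loc["default", "agreement"] == 1.0
        assert table.loc["glutamate_excitatory", "agreement"] == 0.0

    def test_wsyn_increase_does_not_lose_activity(self, relay_chain, params):
        def predict(w, p):
            res = cl.activation_screen(w, p, ["s"], [120], seed=8,
                                       n_trials=2, duration_ms=300)
            r = res.data.set_index("neuron_id")["rate_hz"]
            return {"m_active": bool(r["m"] > 0)}

        from conftest import make_sites
        sites = make_sites([("s", "m", 100.0, "ach")] * 80)
        table = cl.robustness_sweep(
            sites, params, predict, variants=("default", "wsyn_plus30"))
        assert table.loc["default", "m_active"]
        assert table.loc["wsyn_plus30", "m_active"]
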