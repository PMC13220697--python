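"""Training regimes: aggregation rules, oracle equivalences, ledgers."""

import numpy as np
import pytest

from fedsplitsim.cost import DeviceSpec, make_fleet
from fedsplitsim.errors import AggregationError, ConfigurationError, ProtocolStallError
from fedsplitsim.nn import SmashedData, build_reference_model, init_params
from fedsplitsim.protocols import (
    ClientState,
    TrainingConfig,
    add_dp_noise,
    async_update,
    fedavg_aggregate,
    run_fedavg,
    run_hfedsl,
    run_split_learning,
    select_clients,
    train_centralized,
)
from fedsplitsim.synth import (
    ClientSilo,
    GeneratorConfig,
    PartitionConfig,
    SegmentSet,
    generate_dataset,
    split_and_partition,
    zscore_apply,
    zscore_fit,
)

DEVICE = DeviceSpec(flops_per_second=1e8, active_power_w=0.07,
                    idle_power_w=0.01, link_bytes_per_second=1e5,
                    link_energy_per_byte_j=1e-6)
SERVER = DeviceSpec(flops_per_second=1e10, active_power_w=3.0)


@pytest.fixture(scope="module")
def spec():
    return build_reference_model()


@pytest.fixture(scope="module")
def federated_data():
    """3 scaled silos plus a global test set (shared z-score scaling)."""
    data = generate_dataset(
        GeneratorConfig(n_users=10, segments_per_user=40, arrhythmia_prevalence=0.3, seed=21)
    )
    pc = PartitionConfig(n_clients=3, test_fraction=0.2, dirichlet_alpha=0.5,
                        local_val_fraction=0.0, seed=21)
    global_test, silos = split_and_partition(data, pc)
    pooled = SegmentSet.concat([s.train for s in silos])
    scaler = zscore_fit(pooled)
    global_test = zscore_apply(scaler, global_test)
    for s in silos:
        s.train = zscore_apply(scaler, s.train)
    return global_test, silos, zscore_apply(scaler, pooled)


def cfg(rounds=2, epochs=2, seed=5):
    return TrainingConfig(learning_rate=0.001, batch_size=32,
                          local_epochs=epochs, global_rounds=rounds, seed=seed)


class TestFedAvgAggregate:
    def test_idempotent_on_identical_inputs(self, spec):
        p = init_params(spec, 0)
        out = fedavg_aggregate([p, p], [1.0, 1.0])
        for k in p:
            np.testing.assert_array_equal(out[k], p[k])

    def test_equal_weight_mean(self):
        out = fedavg_aggregate(
            [{"w": np.array([0.0])}, {"w": np.array([2.0])}], [1.0, 1.0]
        )
        assert out["w"][0] == 1.0

    def test_weighted_mean(self):
        out = fedavg_aggregate(
            [{"w": np.array([0.0])}, {"w": np.array([4.0])}], [1.0, 3.0]
        )
        assert out["w"][0] == 3.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(AggregationError):
            fedavg_aggregate(
                [{"w": np.zeros(2)}, {"w": np.zeros(3)}], [1.0, 1.0]
            )

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(AggregationError):
            fedavg_aggregate([{"w": np.zeros(2)}], [0.0])


class TestAsyncUpdate:
    def test_fresh_update_full_replacement(self):
        g = {"w": np.array([1.0])}
        c = {"w": np.array([5.0])}
        assert async_update(g, c, staleness=0, alpha0=1.0)["w"][0] == 5.0

    def test_stale_update_discounted(self):
        g = {"w": np.array([0.0])}
        c = {"w": np.array([4.0])}
        # alpha = 0.5 / (1 + 1) = 0.25
        assert async_update(g, c, staleness=1, alpha0=0.5)["w"][0] == 1.0

    def test_mixing_weight_nonincreasing_in_staleness(self):
        g = {"w": np.array([0.0])}
        c = {"w": np.array([1.0])}
        vals = [async_update(g, c, s, 0.8)["w"][0] for s in range(5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            async_update({"w": np.zeros(1)}, {"w": np.zeros(1)}, 0, 0.0)


class TestSelection:
    def _states(self, batteries):
        silo = ClientSilo(0, SegmentSet(np.zeros((1, 187)), np.zeros(1, dtype=int)),
                          SegmentSet(np.zeros((0, 187)), np.zeros(0, dtype=int)))
        return [
            ClientState(client_id=i, silo=silo, device=DEVICE, battery_fraction=b)
            for i, b in enumerate(batteries)
        ]

    def test_battery_threshold_excludes_exactly_subthreshold(self):
        states = self._states([0.5, 0.19, 0.21])
        chosen = select_clients(states, "resource_aware", battery_threshold=0.20)
        assert [s.client_id for s in chosen] == [0, 2]

    def test_zero_threshold_selects_all(self):
        states = self._states([0.5, 0.19, 0.21])
        assert len(select_clients(states, "resource_aware", battery_threshold=0.0)) == 3

    def test_selection_stable_subset(self):
        states = self._states([0.9, 0.8, 0.7, 0.1])
        chosen = select_clients(states, "resource_aware")
        assert [s.client_id for s in chosen] == [0, 1, 2]

    def test_link_floor(self):
        states = self._states([0.9, 0.9])
        floor = DEVICE.link_bytes_per_second + 1
        assert select_clients(states, "resource_aware",
                              link_floor_bytes_per_second=floor) == []


class TestDpNoise:
    def test_sigma_zero_is_identity(self):
        smashed = SmashedData(np.arange(12.0).reshape(3, 4))
        out = add_dp_noise(smashed, 0.0, np.random.default_rng(0))
        assert out is smashed

    def test_noise_sd_matches_sigma(self):
        rng = np.random.default_rng(17)
        clean = SmashedData(np.zeros(100_000))
        noisy = add_dp_noise(clean, 2.5, rng)
        assert np.std(noisy.activations - clean.activations) == pytest.approx(2.5, rel=0.02)

    def test_overwhelming_noise_destroys_learning(self, spec):
        """Split training with sigma >> activation scale collapses to chance
        on a balanced test set, while the clean run learns."""
        data = generate_dataset(GeneratorConfig(
            n_users=5, segments_per_user=60, arrhythmia_prevalence=0.5, seed=31))
        gt, silos = split_and_partition(
            data, PartitionConfig(n_clients=1, test_fraction=0.2,
                                  local_val_fraction=0.0, seed=31))
        scaler = zscore_fit(silos[0].train)
        silos[0].train = zscore_apply(scaler, silos[0].train)
        gt = zscore_apply(scaler, gt)
        c = cfg(rounds=4, epochs=5, seed=9)
        clean = run_split_learning(silos[0], DEVICE, SERVER, gt, spec, c)
        noisy = run_split_learning(silos[0], DEVICE, SERVER, gt, spec, c,
                                   dp_sigma=1e3)
        assert clean.final_accuracy > 0.8
        assert abs(noisy.final_accuracy - 0.5) <= 0.15


class TestCentralized:
    def test_zero_rounds_gives_untrained_accuracy(self, spec, federated_data):
        test, _, pooled = federated_data
        hist = train_centralized(pooled, test, spec, cfg(rounds=0), server=SERVER)
        assert len(hist.accuracies) == 1  # untrained evaluation only

    def test_raw_upload_bytes(self, spec, federated_data):
        test, _, pooled = federated_data
        hist = train_centralized(pooled, test, spec, cfg(rounds=1, epochs=1), server=SERVER)
        assert hist.ledger.bytes_by_kind["raw"] == len(pooled) * 187 * 4
        assert hist.ledger.client_uplink_raw_bytes > 0

    def test_noiseless_data_reaches_high_accuracy(self, spec):
        """Separable noiseless classes: 20 epochs of SGD exceed 95% accuracy."""
        data = generate_dataset(GeneratorConfig(
            n_users=2, segments_per_user=100, arrhythmia_prevalence=0.4,
            noise_sd=0.0, seed=3))
        allseg = SegmentSet.concat(list(data.values()))
        train, test = allseg.take(np.arange(0, 150)), allseg.take(np.arange(150, 200))
        hist = train_centralized(train, test, spec, cfg(rounds=4, epochs=5, seed=1),
                                 server=SERVER)
        assert hist.final_accuracy >= 0.95


@pytest.fixture(scope="module")
def one_silo(federated_data):
    _, silos, _ = federated_data
    return max(silos, key=lambda s: len(s.train))


@pytest.fixture(scope="module")
def central_params(spec, federated_data, one_silo):
    test, _, _ = federated_data
    hist = train_centralized(one_silo.train, test, spec, cfg(), server=SERVER,
                             stream_id=one_silo.client_id)
    return hist.params


class TestOracleEquivalences:
    """Bitwise oracle chain: split on one silo == centralized on that silo;
    one-client FedAvg == centralized; one-client H-FedSL == centralized."""

    def test_split_learning_matches_centralized(self, spec, federated_data,
                                                one_silo, central_params):
        test, _, _ = federated_data
        hist = run_split_learning(one_silo, DEVICE, SERVER, test, spec, cfg())
        for k in central_params:
            assert np.array_equal(hist.params[k], central_params[k]), k

    def test_one_client_fedavg_matches_centralized(self, spec, federated_data,
                                                   one_silo, central_params):
        test, _, _ = federated_data
        hist = run_fedavg([one_silo], [DEVICE], test, spec, cfg())
        for k in central_params:
            assert np.array_equal(hist.params[k], central_params[k]), k

    @pytest.mark.parametrize("mode", ["relay", "parallel"])
    def test_one_client_hfedsl_matches_centralized(self, spec, federated_data,
                                                   one_silo, central_params, mode):
        test, _, _ = federated_data
        hist = run_hfedsl([one_silo], [DEVICE], [SERVER], test, spec, cfg(), mode=mode)
        for k in central_params:
            assert np.array_equal(hist.params[k], central_params[k]), k

    @pytest.mark.parametrize("cut", [1, 2, 3, 4])
    def test_split_equivalence_any_cut(self, spec, federated_data, one_silo,
                                       central_params, cut):
        test, _, _ = federated_data
        hist = run_split_learning(one_silo, DEVICE, SERVER, test,
                                  spec.with_cut(cut), cfg())
        for k in central_params:
            assert np.array_equal(hist.params[k], central_params[k]), k


class TestLedgers:
    def test_privacy_no_raw_bytes_on_federated_uplink(self, spec, federated_data):
        test, silos, _ = federated_data
        fleet = [DEVICE] * len(silos)
        for hist in (
            run_fedavg(silos, fleet, test, spec, cfg(rounds=1, epochs=1)),
            run_hfedsl(silos, fleet, [SERVER], test, spec, cfg(rounds=1, epochs=1)),
        ):
            assert hist.ledger.client_uplink_raw_bytes == 0
            assert "raw" not in hist.ledger.bytes_by_kind

    def test_ledger_conservation_every_protocol(self, spec, federated_data):
        test, silos, pooled = federated_data
        fleet = [DEVICE] * len(silos)
        for hist in (
            train_centralized(pooled, test, spec, cfg(rounds=1, epochs=1), server=SERVER),
            run_fedavg(silos, fleet, test, spec, cfg(rounds=1, epochs=1)),
            run_hfedsl(silos, fleet, [SERVER], test, spec, cfg(rounds=1, epochs=1)),
        ):
            led = hist.ledger
            assert led.total_j == pytest.approx(led.compute_j + led.comm_j + led.idle_j)

    def test_smashed_payload_per_batch(self, spec, federated_data):
        """Each batch ships B x 2,976 features x 4 bytes of smashed data."""
        test, silos, _ = federated_data
        silo = max(silos, key=lambda s: len(s.train))
        n = len(silo.train)
        hist = run_split_learning(silo, DEVICE, SERVER, test, spec,
                                  cfg(rounds=1, epochs=1))
        assert hist.ledger.bytes_by_kind["smashed"] == n * 2976 * 4
        assert hist.ledger.bytes_by_kind["cut_gradient"] == n * 2976 * 4


class TestStragglers:
    def test_straggler_inflates_sync_wall_clock_and_async_removes_idle(
        self, spec, federated_data
    ):
        test, silos, _ = federated_data
        homogeneous = [DEVICE] * len(silos)
        straggled = make_fleet(len(silos), DEVICE, seed=0, speed_spread=1.0,
                               slow_factors={0: 5.0})
        h_homo = run_fedavg(silos, homogeneous, test, spec, cfg(rounds=1, epochs=1))
        h_slow = run_fedavg(silos, straggled, test, spec, cfg(rounds=1, epochs=1))
        assert h_slow.wall_clock_s >= h_homo.wall_clock_s
        assert h_slow.ledger.idle_j > 0
        h_async = run_fedavg(silos, straggled, test, spec, cfg(rounds=1, epochs=1),
                             aggregation="async")
        added_idle = h_slow.ledger.idle_j - h_homo.ledger.idle_j
        assert h_async.ledger.idle_j <= 0.5 * added_idle

    def test_async_aggregates_every_update(self, spec, federated_data):
        test, silos, _ = federated_data
        fleet = [DEVICE] * len(silos)
        rounds = 2
        hist = run_fedavg(silos, fleet, test, spec, cfg(rounds=rounds, epochs=1),
                          aggregation="async")
        assert len(hist.accuracies) == rounds * len(silos)


class TestStalls:
    def test_empty_selection_raises(self, spec, federated_data):
        test, silos, _ = federated_data
        drained = DeviceSpec(flops_per_second=1e8, active_power_w=0.07,
                             link_bytes_per_second=1.0)
        fleet = [drained] * len(silos)
        with pytest.raises(ProtocolStallError):
            run_fedavg(silos, fleet, test, spec, cfg(rounds=1, epochs=1),
                       policy="resource_aware",
                       link_floor_bytes_per_second=2.0)
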