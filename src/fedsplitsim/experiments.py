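"""Pre-wired study configurations.

The desk-scale trade-off study reproduces the qualitative centralized vs
FedAvg vs H-FedSL comparison at a size a laptop core finishes in minutes:
10 client silos of roughly 500 heartbeat segments each under strong
Dirichlet label skew, the canonical wearable/edge model, per-role energy
constants calibrated from the published comparison table, and one client
slowed 5x to act as the straggler.  Absolute accuracies on real ECG are out
of reach of synthetic data; the study targets the *directions* of the
published trade-off (federated saves energy, loses wall-clock to the
straggler, loses accuracy to label skew) and the hierarchical recovery
property (H-FedSL tracking centralized accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cost import (
    DeviceSpec,
    calibrate_from_reference,
    link_energy_per_byte,
    make_fleet,
    wearable_device,
)
from .nn import build_reference_model, init_params, params_payload_bytes
from .profiler import training_flops_per_sample
from .protocols import (
    RAW_BYTES_PER_SAMPLE,
    RunHistory,
    TrainingConfig,
    run_fedavg,
    run_hfedsl,
    train_centralized,
)
from .synth import (
    GeneratorConfig,
    PartitionConfig,
    SegmentSet,
    generate_dataset,
    split_and_partition,
    zscore_apply,
    zscore_fit,
)


@dataclass
class TradeoffStudyConfig:
    """Scaled-down study conditions (see docs/methods.md for the rationale)."""

    n_users: int = 25
    segments_per_user: int = 250
    arrhythmia_prevalence: float = 0.15
    noise_sd: float | None = None  # None -> generator default
    n_clients: int = 10
    test_fraction: float = 0.2
    dirichlet_alpha: float = 0.5
    global_rounds: int = 10
    local_epochs: int = 2
    batch_size: int = 32
    learning_rate: float = 0.001
    straggler_client: int = 0
    straggler_slowdown: float = 5.0
    n_edges: int = 2
    wearable_flops_per_second: float = 50e6
    server_flops_per_second: float = 5e9
    idle_power_w: float = 0.01


@dataclass
class TradeoffStudyResult:
    centralized: RunHistory
    fedavg: RunHistory
    hfedsl: RunHistory
    test_size: int = 0
    train_size: int = 0


def _prepare_data(sc: TradeoffStudyConfig, seed: int):
    gen_kwargs = dict(
        n_users=sc.n_users,
        segments_per_user=sc.segments_per_user,
        arrhythmia_prevalence=sc.arrhythmia_prevalence,
        seed=seed,
    )
    if sc.noise_sd is not None:
        gen_kwargs["noise_sd"] = sc.noise_sd
    dataset = generate_dataset(GeneratorConfig(**gen_kwargs))
    pc = PartitionConfig(
        n_clients=sc.n_clients,
        test_fraction=sc.test_fraction,
        dirichlet_alpha=sc.dirichlet_alpha,
        seed=seed,
    )
    global_test, silos = split_and_partition(dataset, pc)
    # one public standardisation, fitted on the pooled client training data,
    # applied everywhere so every regime sees identical inputs
    pooled_train = SegmentSet.concat([s.train for s in silos])
    scaler = zscore_fit(pooled_train)
    global_test = zscore_apply(scaler, global_test)
    for s in silos:
        s.train = zscore_apply(scaler, s.train)
        s.validation = zscore_apply(scaler, s.validation)
    return global_test, silos, zscore_apply(scaler, pooled_train)


def run_tradeoff_study(seed: int, sc: TradeoffStudyConfig | None = None) -> TradeoffStudyResult:
    """Run centralized, straggled FedAvg, and relay H-FedSL on one data draw."""
    sc = sc or TradeoffStudyConfig()
    global_test, silos, pooled_train = _prepare_data(sc, seed)
    spec = build_reference_model()
    cfg = TrainingConfig(
        learning_rate=sc.learning_rate,
        batch_size=sc.batch_size,
        local_epochs=sc.local_epochs,
        global_rounds=sc.global_rounds,
        seed=seed,
    )
    costs = calibrate_from_reference()
    fps_full = training_flops_per_sample(spec, convention="hybrid")

    # calibrated per-byte link energies: each regime's published communication
    # budget spread over that regime's deterministic byte total
    raw_bytes = len(pooled_train) * RAW_BYTES_PER_SAMPLE
    payload = params_payload_bytes(init_params(spec, seed))
    fed_bytes = sc.global_rounds * sc.n_clients * 2 * payload
    e_byte_raw = link_energy_per_byte(costs.comm_budget_centralized_j, raw_bytes)
    e_byte_update = link_energy_per_byte(costs.comm_budget_federated_j, fed_bytes)

    server = DeviceSpec(
        flops_per_second=sc.server_flops_per_second,
        active_power_w=costs.e_flop_centralized_j * sc.server_flops_per_second,
        idle_power_w=sc.idle_power_w,
        link_energy_per_byte_j=e_byte_raw,
    )
    wearable = wearable_device(
        costs.e_flop_federated_j,
        flops_per_second=sc.wearable_flops_per_second,
        idle_power_w=sc.idle_power_w,
        link_energy_per_byte_j=e_byte_update,
    )
    # raw-segment uplink in the centralized regime: same wearable radio, but
    # priced under the centralized regime's calibrated communication budget
    raw_uplink = wearable_device(
        costs.e_flop_federated_j,
        flops_per_second=sc.wearable_flops_per_second,
        idle_power_w=sc.idle_power_w,
        link_energy_per_byte_j=e_byte_raw,
    )
    fleet = make_fleet(
        sc.n_clients,
        wearable,
        seed=seed,
        speed_spread=2.0,
        slow_factors={sc.straggler_client: sc.straggler_slowdown},
    )
    edge = DeviceSpec(
        flops_per_second=sc.server_flops_per_second,
        active_power_w=costs.e_flop_centralized_j * sc.server_flops_per_second,
        idle_power_w=sc.idle_power_w,
        link_energy_per_byte_j=e_byte_update,
    )
    edge_fleet = [edge] * sc.n_edges

    central = train_centralized(
        pooled_train, global_test, spec, cfg, server=server,
        client_link=raw_uplink, flops_per_sample=fps_full,
    )
    fed = run_fedavg(
        silos, fleet, global_test, spec, cfg, flops_per_sample=fps_full
    )
    hf = run_hfedsl(silos, fleet, edge_fleet, global_test, spec, cfg, mode="relay")
    return TradeoffStudyResult(
        centralized=central,
        fedavg=fed,
        hfedsl=hf,
        test_size=len(global_test),
        train_size=len(pooled_train),
    )


def sweep_tradeoff_study(
    seeds: list[int], sc: TradeoffStudyConfig | None = None
) -> dict[str, np.ndarray]:
    """Seed-swept study; returns per-seed final accuracies, energies, times."""
    rows = {
        "centralized_acc": [], "fedavg_acc": [], "hfedsl_acc": [],
        "centralized_kj": [], "fedavg_kj": [], "hfedsl_kj": [],
        "centralized_s": [], "fedavg_s": [], "hfedsl_s": [],
    }
    for seed in seeds:
        r = run_tradeoff_study(seed, sc)
        for name, hist in (
            ("centralized", r.centralized), ("fedavg", r.fedavg), ("hfedsl", r.hfedsl)
        ):
            rows[f"{name}_acc"].append(hist.final_accuracy)
            rows[f"{name}_kj"].append(hist.ledger.total_kj)
            rows[f"{name}_s"].append(hist.wall_clock_s)
    return {k: np.array(v) for k, v in rows.items()}
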