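"""Training regimes: centralized SGD, synchronous/asynchronous FedAvg, split
learning, and hierarchical federated split learning (H-FedSL).

Every regime drives the same per-layer engine with the same child-seeded
shuffle streams, which makes the protocol stack exactly testable: split
learning on one silo reproduces centralized SGD on that silo bit-for-bit,
and H-FedSL with a single client does too (composition of the split- and
aggregation-equivalences).

H-FedSL runs in two modes.  In ``relay`` mode (default) the clients attached
to one edge server share that edge's weights within a round: the edge
multiplexes their mini-batches round-robin through a single relayed model
(a batch-interleaved split-learning weight relay), and the cloud averages
the per-edge results each round.  Because every edge's weights see all of
its clients' data finely mixed within a round, label skew is largely
neutralised and the trajectory tracks centralized training closely; this is
the mechanism by which the hierarchical design recovers the accuracy that
naive FedAvg loses on non-IID silos.  In ``parallel`` mode every client
trains against a
private copy of the server half and the cloud averages everything, which is
algorithmically identical to FedAvg (useful as an oracle, not as a fix).

Energy and time go through the cost module: device-side FLOPs are charged to
the wearable, server-side FLOPs to the edge; the only client-uplink payloads
in federated regimes are parameters and smashed data/cut gradients — never
raw segments (asserted by the ledger).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from ._seeding import STREAM_DP, STREAM_SHUFFLE, child_rng
from .cost import (
    DeviceSpec,
    EnergyLedger,
    battery_drain,
    compute_time,
    idle_seconds,
    sync_round_time,
)
from .errors import AggregationError, ConfigurationError, ProtocolStallError
from .nn import (
    ModelSpec,
    ParamSet,
    SmashedData,
    backward,
    forward,
    init_params,
    params_payload_bytes,
    predict,
    sgd_step,
    split_backward,
    split_forward_device,
    split_forward_server,
)
from .profiler import training_flops_per_sample
from .synth import ClientSilo, SegmentSet

RAW_BYTES_PER_SAMPLE = 187 * 4  # single-precision wire convention


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters shared by all regimes."""

    learning_rate: float = 0.001
    batch_size: int = 32
    local_epochs: int = 5
    global_rounds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ConfigurationError("learning_rate and batch_size must be positive")
        if self.local_epochs < 0 or self.global_rounds < 0:
            raise ConfigurationError("epochs and rounds must be nonnegative")


@dataclass
class ClientState:
    """Mutable per-client bookkeeping across rounds."""

    client_id: int
    silo: ClientSilo
    device: DeviceSpec
    battery_fraction: float = 1.0
    consumed_j: float = 0.0
    staleness: int = 0

    def drain(self, joules: float) -> None:
        self.consumed_j += joules
        self.battery_fraction = battery_drain(self.consumed_j, self.device)

    @property
    def available(self) -> bool:
        return self.battery_fraction > 0.0


@dataclass
class RunHistory:
    """One regime's trajectory: accuracy per evaluation, costs, timings."""

    protocol: str
    accuracies: list[float] = field(default_factory=list)
    ledger: EnergyLedger = field(default_factory=EnergyLedger)
    round_times: list[float] = field(default_factory=list)
    wall_clock_s: float = 0.0
    params: ParamSet | None = None

    @property
    def final_accuracy(self) -> float:
        return self.accuracies[-1] if self.accuracies else float("nan")

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "accuracies": self.accuracies,
            "final_accuracy": self.final_accuracy,
            "round_times_s": self.round_times,
            "wall_clock_s": self.wall_clock_s,
            "ledger": self.ledger.to_dict(),
        }


# ---------------------------------------------------------------------------
# shared machinery


def shuffle_rng(seed: int, stream_id: int) -> np.random.Generator:
    """The data-order stream for one client (or the pooled run)."""
    return child_rng(seed, STREAM_SHUFFLE, stream_id)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start : start + batch_size]


def _sgd_epochs(
    params: ParamSet,
    spec: ModelSpec,
    data: SegmentSet,
    cfg: TrainingConfig,
    rng: np.random.Generator,
    epochs: int,
) -> ParamSet:
    """Plain mini-batch SGD with per-epoch reshuffling (the unsplit engine)."""
    for _ in range(epochs):
        for idx in _batches(len(data), cfg.batch_size, rng):
            probs, tape = forward(params, spec, data.X[idx])
            grads = backward(params, tape, data.y[idx])
            params = sgd_step(params, grads, cfg.learning_rate)
    return params


def add_dp_noise(
    smashed: SmashedData, sigma: float, rng: np.random.Generator
) -> SmashedData:
    """Gaussian noise on the smashed activations (sigma = 0 is the identity)."""
    if sigma < 0:
        raise ConfigurationError("sigma must be nonnegative")
    if sigma == 0:
        return smashed
    return SmashedData(
        activations=smashed.activations + rng.normal(0.0, sigma, smashed.activations.shape)
    )


def _split_sgd_epochs(
    params: ParamSet,
    spec: ModelSpec,
    data: SegmentSet,
    cfg: TrainingConfig,
    rng: np.random.Generator,
    epochs: int,
    on_batch=None,
    dp_sigma: float = 0.0,
    dp_rng: np.random.Generator | None = None,
) -> ParamSet:
    """Split-learning SGD: device half and server half exchange smashed data
    and cut gradients per batch.  With dp_sigma = 0 the parameter trajectory
    is bit-identical to :func:`_sgd_epochs` on the same data order."""
    for _ in range(epochs):
        for idx in _batches(len(data), cfg.batch_size, rng):
            smashed, dev_tape = split_forward_device(params, spec, data.X[idx])
            payload = add_dp_noise(smashed, dp_sigma, dp_rng) if dp_sigma else smashed
            _, srv_tape = split_forward_server(params, spec, payload)
            srv_g, cut_grad, dev_g = split_backward(params, srv_tape, dev_tape, data.y[idx])
            if on_batch is not None:
                on_batch(payload.byte_size, cut_grad.size * 4)
            params = sgd_step(params, {**srv_g, **dev_g}, cfg.learning_rate)
    return params


def evaluate_accuracy(params: ParamSet, spec: ModelSpec, test: SegmentSet) -> float:
    probs, _ = forward(params, spec, test.X)
    return float((predict(probs) == test.y).mean())


# ---------------------------------------------------------------------------
# aggregation rules


def fedavg_aggregate(params_list: list[ParamSet], weights: list[float]) -> ParamSet:
    """Sample-size-weighted elementwise mean of parameter sets."""
    if not params_list or len(params_list) != len(weights):
        raise AggregationError("need one positive weight per parameter set")
    if any(w <= 0 for w in weights):
        raise AggregationError("weights must be positive")
    keys = set(params_list[0])
    for p in params_list[1:]:
        if set(p) != keys or any(p[k].shape != params_list[0][k].shape for k in keys):
            raise AggregationError("parameter sets are not shape-compatible")
    if len(params_list) == 1:
        return {k: v.copy() for k, v in params_list[0].items()}
    total = float(sum(weights))
    alphas = [w / total for w in weights]
    # mean computed as base + sum(alpha_i * (p_i - base)): identical inputs
    # aggregate to themselves exactly, whatever the weights
    base = params_list[0]
    return {
        k: base[k]
        + sum(a * (p[k] - base[k]) for a, p in zip(alphas[1:], params_list[1:]))
        for k in keys
    }


def async_update(
    global_params: ParamSet, client_params: ParamSet, staleness: int, alpha0: float
) -> ParamSet:
    """Staleness-discounted mixing: g <- (1-a) g + a c with a = alpha0/(1+s)."""
    if not 0.0 < alpha0 <= 1.0:
        raise ConfigurationError("alpha0 must lie in (0, 1]")
    if staleness < 0:
        raise ConfigurationError("staleness must be nonnegative")
    a = alpha0 / (1.0 + staleness)
    return {
        k: (1.0 - a) * g + a * client_params[k] for k, g in global_params.items()
    }


def select_clients(
    states: list[ClientState],
    policy: str = "all",
    battery_threshold: float = 0.20,
    link_floor_bytes_per_second: float = 0.0,
) -> list[ClientState]:
    """Admission control for a round; deterministic and order-stable."""
    if policy == "all":
        return list(states)
    if policy == "resource_aware":
        return [
            s
            for s in states
            if s.battery_fraction > battery_threshold
            and s.device.link_bytes_per_second >= link_floor_bytes_per_second
        ]
    raise ConfigurationError(f"unknown selection policy {policy!r}")


# ---------------------------------------------------------------------------
# regimes


def train_centralized(
    train: SegmentSet,
    test: SegmentSet,
    spec: ModelSpec,
    cfg: TrainingConfig,
    server: DeviceSpec,
    client_link: DeviceSpec | None = None,
    flops_per_sample: float | None = None,
    stream_id: int = 0,
) -> RunHistory:
    """Pooled mini-batch SGD with all data shipped to one server.

    The ledger charges the one-off raw-segment upload (187 samples x 4 bytes
    each) to the client link and all training compute to the server; training
    runs ``global_rounds`` blocks of ``local_epochs`` epochs so the
    evaluation cadence matches the federated regimes.
    """
    if len(train) == 0:
        raise ConfigurationError("training data is empty")
    fps = flops_per_sample if flops_per_sample is not None else training_flops_per_sample(spec)
    hist = RunHistory(protocol="centralized")
    link = client_link if client_link is not None else server
    _, t_up = hist.ledger.add_comm(
        len(train) * RAW_BYTES_PER_SAMPLE, link, kind="raw", client_uplink=True
    )
    hist.wall_clock_s += t_up
    params = init_params(spec, cfg.seed)
    rng = shuffle_rng(cfg.seed, stream_id)
    if cfg.global_rounds == 0:
        hist.accuracies.append(evaluate_accuracy(params, spec, test))
    for _ in range(cfg.global_rounds):
        params = _sgd_epochs(params, spec, train, cfg, rng, cfg.local_epochs)
        round_flops = fps * len(train) * cfg.local_epochs
        hist.ledger.add_compute(round_flops, server)
        t = compute_time(round_flops, server)
        hist.round_times.append(t)
        hist.wall_clock_s += t
        hist.accuracies.append(evaluate_accuracy(params, spec, test))
    hist.params = params
    return hist


def run_fedavg(
    silos: list[ClientSilo],
    fleet: list[DeviceSpec],
    test: SegmentSet,
    spec: ModelSpec,
    cfg: TrainingConfig,
    policy: str = "all",
    battery_threshold: float = 0.20,
    link_floor_bytes_per_second: float = 0.0,
    aggregation: str = "sync",
    alpha0: float = 0.5,
    flops_per_sample: float | None = None,
) -> RunHistory:
    """Federated averaging over client silos (synchronous or asynchronous)."""
    if not silos:
        raise ConfigurationError("need at least one silo")
    if len(fleet) != len(silos):
        raise ConfigurationError("need one device per silo")
    fps = flops_per_sample if flops_per_sample is not None else training_flops_per_sample(spec)
    states = [
        ClientState(client_id=s.client_id, silo=s, device=d)
        for s, d in zip(silos, fleet)
    ]
    rngs = {s.client_id: shuffle_rng(cfg.seed, s.client_id) for s in silos}
    global_params = init_params(spec, cfg.seed)
    hist = RunHistory(protocol=f"fedavg-{aggregation}")
    if aggregation == "sync":
        _fedavg_sync(hist, states, rngs, global_params, test, spec, cfg, fps,
                     policy, battery_threshold, link_floor_bytes_per_second)
    elif aggregation == "async":
        _fedavg_async(hist, states, rngs, global_params, test, spec, cfg, fps,
                      policy, battery_threshold, link_floor_bytes_per_second, alpha0)
    else:
        raise ConfigurationError(f"unknown aggregation mode {aggregation!r}")
    return hist


def _client_round_cost(
    hist: RunHistory, st: ClientState, fps: float, cfg: TrainingConfig, payload: int
) -> float:
    """Charge one client's local round (compute + up/down parameters) and
    return its completion time."""
    flops = fps * len(st.silo.train) * cfg.local_epochs
    e_c = hist.ledger.add_compute(flops, st.device)
    e_up, t_up = hist.ledger.add_comm(payload, st.device, kind="params", client_uplink=True)
    e_dn, t_dn = hist.ledger.add_comm(payload, st.device, kind="params")
    st.drain(e_c + e_up + e_dn)
    return compute_time(flops, st.device) + t_up + t_dn


def _fedavg_sync(hist, states, rngs, global_params, test, spec, cfg, fps,
                 policy, battery_threshold, link_floor):
    payload = params_payload_bytes(global_params)
    for _ in range(cfg.global_rounds):
        selected = [
            s for s in select_clients(states, policy, battery_threshold, link_floor)
            if len(s.silo.train) > 0
        ]
        if not selected:
            raise ProtocolStallError("no eligible clients this round")
        updates, weights, times = [], [], []
        for st in selected:
            local = _sgd_epochs(
                global_params, spec, st.silo.train, cfg, rngs[st.client_id], cfg.local_epochs
            )
            updates.append(local)
            weights.append(float(len(st.silo.train)))
            times.append(_client_round_cost(hist, st, fps, cfg, payload))
        round_t = sync_round_time(times)
        for st, wait in zip(selected, idle_seconds(times)):
            st.drain(hist.ledger.add_idle(wait, st.device))
        global_params = fedavg_aggregate(updates, weights)
        hist.round_times.append(round_t)
        hist.wall_clock_s += round_t
        hist.accuracies.append(evaluate_accuracy(global_params, spec, test))
    hist.params = global_params


def _fedavg_async(hist, states, rngs, global_params, test, spec, cfg, fps,
                  policy, battery_threshold, link_floor, alpha0):
    payload = params_payload_bytes(global_params)
    selected = [
        s for s in select_clients(states, policy, battery_threshold, link_floor)
        if len(s.silo.train) > 0
    ]
    if not selected:
        raise ProtocolStallError("no eligible clients")
    version = 0
    client_version = {st.client_id: 0 for st in selected}
    rounds_done = {st.client_id: 0 for st in selected}
    client_params = {st.client_id: global_params for st in selected}
    queue: list[tuple[float, int]] = []
    now = 0.0
    for st in selected:
        t = _start_async_round(hist, st, rngs, client_params, global_params, spec, cfg, fps, payload)
        heapq.heappush(queue, (now + t, st.client_id))
    by_id = {st.client_id: st for st in selected}
    while queue:
        now, cid = heapq.heappop(queue)
        st = by_id[cid]
        staleness = version - client_version[cid]
        st.staleness = staleness
        global_params = async_update(global_params, client_params[cid], staleness, alpha0)
        version += 1
        rounds_done[cid] += 1
        hist.accuracies.append(evaluate_accuracy(global_params, spec, test))
        hist.round_times.append(now)
        if rounds_done[cid] < cfg.global_rounds:
            client_version[cid] = version
            t = _start_async_round(hist, st, rngs, client_params, global_params, spec, cfg, fps, payload)
            heapq.heappush(queue, (now + t, cid))
    hist.wall_clock_s = now
    hist.params = global_params


def _start_async_round(hist, st, rngs, client_params, global_params, spec, cfg, fps, payload):
    client_params[st.client_id] = _sgd_epochs(
        global_params, spec, st.silo.train, cfg, rngs[st.client_id], cfg.local_epochs
    )
    return _client_round_cost(hist, st, fps, cfg, payload)


def run_split_learning(
    silo: ClientSilo,
    device: DeviceSpec,
    edge: DeviceSpec,
    test: SegmentSet,
    spec: ModelSpec,
    cfg: TrainingConfig,
    dp_sigma: float = 0.0,
    flops_device: float | None = None,
    flops_server: float | None = None,
) -> RunHistory:
    """Single-client split learning against one edge server.

    Per batch: device forward -> smashed data uplink -> server forward +
    backward -> cut-gradient downlink -> device backward and step.  With
    dp_sigma = 0 the parameter trajectory is bit-identical to centralized
    SGD on the same silo and shuffle stream.
    """
    if not 0 <= spec.cut_layer <= spec.n_layers:
        raise ConfigurationError("invalid cut layer")
    f_dev = (
        flops_device
        if flops_device is not None
        else training_flops_per_sample(spec, start=0, stop=spec.cut_layer)
    )
    f_srv = (
        flops_server
        if flops_server is not None
        else training_flops_per_sample(spec, start=spec.cut_layer)
    )
    hist = RunHistory(protocol="split")
    params = init_params(spec, cfg.seed)
    rng = shuffle_rng(cfg.seed, silo.client_id)
    dp_rng = child_rng(cfg.seed, STREAM_DP, silo.client_id)
    n = len(silo.train)

    def on_batch(smashed_bytes: int, grad_bytes: int) -> None:
        _, t1 = hist.ledger.add_comm(smashed_bytes, device, kind="smashed", client_uplink=True)
        _, t2 = hist.ledger.add_comm(grad_bytes, device, kind="cut_gradient")
        hist.wall_clock_s += t1 + t2

    for _ in range(cfg.global_rounds):
        t0 = hist.wall_clock_s
        params = _split_sgd_epochs(
            params, spec, silo.train, cfg, rng, cfg.local_epochs,
            on_batch=on_batch, dp_sigma=dp_sigma, dp_rng=dp_rng,
        )
        dev_flops = f_dev * n * cfg.local_epochs
        srv_flops = f_srv * n * cfg.local_epochs
        hist.ledger.add_compute(dev_flops, device)
        hist.ledger.add_compute(srv_flops, edge)
        hist.wall_clock_s += compute_time(dev_flops, device) + compute_time(srv_flops, edge)
        hist.round_times.append(hist.wall_clock_s - t0)
        hist.accuracies.append(evaluate_accuracy(params, spec, test))
    hist.params = params
    return hist


def run_hfedsl(
    silos: list[ClientSilo],
    fleet: list[DeviceSpec],
    edge_fleet: list[DeviceSpec],
    test: SegmentSet,
    spec: ModelSpec,
    cfg: TrainingConfig,
    mode: str = "relay",
    policy: str = "all",
    battery_threshold: float = 0.20,
    link_floor_bytes_per_second: float = 0.0,
    dp_sigma: float = 0.0,
    aggregate_scope: str = "full",
) -> RunHistory:
    """Hierarchical federated split learning.

    Clients are paired with edge servers round-robin (client k -> edge
    k mod n_edges).  Each round the selected clients train split-fashion
    against their edge; the cloud then FedAvg-aggregates parameters across
    the hierarchy and re-broadcasts.  ``aggregate_scope`` is "full" (device +
    server halves, default) or "device" (device half only; each edge keeps
    its own deep layers).  See the module docstring for relay vs parallel.
    """
    if not silos:
        raise ConfigurationError("need at least one silo")
    if len(fleet) != len(silos) or not edge_fleet:
        raise ConfigurationError("need one device per silo and at least one edge server")
    if mode not in ("relay", "parallel"):
        raise ConfigurationError(f"unknown H-FedSL mode {mode!r}")
    if aggregate_scope not in ("full", "device"):
        raise ConfigurationError(f"unknown aggregate_scope {aggregate_scope!r}")
    f_dev = training_flops_per_sample(spec, start=0, stop=spec.cut_layer)
    f_srv = training_flops_per_sample(spec, start=spec.cut_layer)
    states = [
        ClientState(client_id=s.client_id, silo=s, device=d)
        for s, d in zip(silos, fleet)
    ]
    rngs = {s.client_id: shuffle_rng(cfg.seed, s.client_id) for s in silos}
    dp_rngs = {s.client_id: child_rng(cfg.seed, STREAM_DP, s.client_id) for s in silos}
    global_params = init_params(spec, cfg.seed)
    dev_payload = params_payload_bytes(
        {k: v for k, v in global_params.items() if int(k[1 : k.index("_")]) < spec.cut_layer}
    )
    full_payload = params_payload_bytes(global_params)
    hist = RunHistory(protocol=f"hfedsl-{mode}")
    n_edges = len(edge_fleet)

    for _ in range(cfg.global_rounds):
        selected = [
            s for s in select_clients(states, policy, battery_threshold, link_floor_bytes_per_second)
            if len(s.silo.train) > 0
        ]
        if not selected:
            raise ProtocolStallError("no eligible clients this round")
        updates, weights, client_times = [], [], {}
        if mode == "relay":
            groups: dict[int, list[ClientState]] = {}
            for st in selected:
                groups.setdefault(st.client_id % n_edges, []).append(st)
            edge_times = []
            for e_idx, members in sorted(groups.items()):
                edge = edge_fleet[e_idx]
                chain, times = _relay_edge_round(
                    hist, members, edge, global_params, spec, cfg, rngs,
                    dp_rngs, f_dev, f_srv, dp_sigma, dev_payload,
                )
                client_times.update(times)
                updates.append(chain)
                weights.append(float(sum(len(s.silo.train) for s in members)))
                _, t_up = hist.ledger.add_comm(full_payload, edge, kind="edge_params")
                _, t_dn = hist.ledger.add_comm(full_payload, edge, kind="edge_params")
                edge_times.append(sum(times.values()) + t_up + t_dn)
            round_t = sync_round_time(edge_times)
        else:  # parallel: per-client private server half (FedAvg-equivalent)
            times = []
            for st in selected:
                edge = edge_fleet[st.client_id % n_edges]
                local, t = _hfedsl_client_pass(
                    hist, st, edge, global_params, spec, cfg, rngs, dp_rngs,
                    f_dev, f_srv, dp_sigma, dev_payload,
                )
                updates.append(local)
                weights.append(float(len(st.silo.train)))
                client_times[st.client_id] = t
                times.append(t)
            round_t = sync_round_time(times)
        for st in selected:
            wait = round_t - client_times[st.client_id]
            st.drain(hist.ledger.add_idle(wait, st.device))
        new_global = fedavg_aggregate(updates, weights)
        if aggregate_scope == "device":
            for k in list(new_global):
                if int(k[1 : k.index("_")]) >= spec.cut_layer:
                    new_global[k] = global_params[k]
        global_params = new_global
        hist.round_times.append(round_t)
        hist.wall_clock_s += round_t
        hist.accuracies.append(evaluate_accuracy(global_params, spec, test))
    hist.params = global_params
    return hist


def _relay_edge_round(
    hist, members, edge, params, spec, cfg, rngs, dp_rngs, f_dev, f_srv,
    dp_sigma, dev_payload
):
    """One edge's round in relay mode: the edge's deep layers (and the
    relayed device weights) process its clients' batches interleaved
    round-robin, so within a round the shared weights see every attached
    silo's data finely mixed — the hierarchy's defence against label skew.
    With a single client this reduces to plain sequential SGD.

    Returns the updated parameters and per-client active times."""
    times = {st.client_id: 0.0 for st in members}
    for _ in range(cfg.local_epochs):
        queues = [
            (st, list(_batches(len(st.silo.train), cfg.batch_size, rngs[st.client_id])))
            for st in members
        ]
        pos = 0
        while any(q for _, q in queues):
            st, q = queues[pos % len(queues)]
            pos += 1
            if not q:
                continue
            idx = q.pop(0)
            data = st.silo.train
            smashed, dev_tape = split_forward_device(params, spec, data.X[idx])
            payload = (
                add_dp_noise(smashed, dp_sigma, dp_rngs[st.client_id])
                if dp_sigma else smashed
            )
            _, srv_tape = split_forward_server(params, spec, payload)
            srv_g, cut_grad, dev_g = split_backward(
                params, srv_tape, dev_tape, data.y[idx]
            )
            e1, t1 = hist.ledger.add_comm(
                payload.byte_size, st.device, kind="smashed", client_uplink=True
            )
            e2, t2 = hist.ledger.add_comm(
                cut_grad.size * 4, st.device, kind="cut_gradient"
            )
            st.drain(e1 + e2)
            b = len(idx)
            e_dev = hist.ledger.add_compute(f_dev * b, st.device)
            hist.ledger.add_compute(f_srv * b, edge)
            st.drain(e_dev)
            times[st.client_id] += (
                compute_time(f_dev * b, st.device)
                + compute_time(f_srv * b, edge)
                + t1 + t2
            )
            params = sgd_step(params, {**srv_g, **dev_g}, cfg.learning_rate)
    for st in members:
        e_up, t_up = hist.ledger.add_comm(dev_payload, st.device, kind="params", client_uplink=True)
        e_dn, t_dn = hist.ledger.add_comm(dev_payload, st.device, kind="params")
        st.drain(e_up + e_dn)
        times[st.client_id] += t_up + t_dn
    return params, times


def _hfedsl_client_pass(
    hist, st, edge, params, spec, cfg, rngs, dp_rngs, f_dev, f_srv, dp_sigma, dev_payload
):
    """One client's split-learning pass within an H-FedSL round; returns the
    updated parameters and the client's active time."""
    comm_t = [0.0]

    def on_batch(smashed_bytes: int, grad_bytes: int) -> None:
        e1, t1 = hist.ledger.add_comm(smashed_bytes, st.device, kind="smashed", client_uplink=True)
        e2, t2 = hist.ledger.add_comm(grad_bytes, st.device, kind="cut_gradient")
        comm_t[0] += t1 + t2
        st.drain(e1 + e2)

    new_params = _split_sgd_epochs(
        params, spec, st.silo.train, cfg, rngs[st.client_id], cfg.local_epochs,
        on_batch=on_batch, dp_sigma=dp_sigma, dp_rng=dp_rngs[st.client_id],
    )
    n = len(st.silo.train)
    dev_flops = f_dev * n * cfg.local_epochs
    srv_flops = f_srv * n * cfg.local_epochs
    e_dev = hist.ledger.add_compute(dev_flops, st.device)
    hist.ledger.add_compute(srv_flops, edge)
    e_up, t_up = hist.ledger.add_comm(dev_payload, st.device, kind="params", client_uplink=True)
    e_dn, t_dn = hist.ledger.add_comm(dev_payload, st.device, kind="params")
    st.drain(e_dev + e_up + e_dn)
    t = (
        compute_time(dev_flops, st.device)
        + compute_time(srv_flops, edge)
        + comm_t[0]
        + t_up
        + t_dn
    )
    return new_params, t
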