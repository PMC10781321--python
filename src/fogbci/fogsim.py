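"""Discrete-event simulation of fog versus cloud command latency.

Models the three-layer control loop of a BCI-driven cyber-physical system:
an EEG sensor emits fixed-size messages; a processing node (either a nearby
fog node or a distant cloud node) runs the filter-encode-classify pipeline
as a single-server FIFO queue; the resulting command is delivered to the
actuator. Per-message end-to-end latency is

    sum over traversed links (propagation + size / bandwidth)
    + sum over nodes (queueing wait + service time),

measured from sensor emission to actuator delivery. Links are pure delay
pipes (no contention); nodes are single-server FIFO queues, the simplest
discipline consistent with one classifier per node.

The default topology places the fog node 2 ms from the sensor/actuator and
the cloud 50 ms away with equal compute, so any latency gap between the two
routings comes from proximity alone.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import numpy as np

from .errors import TopologyError, ValidationError

ROUTINGS = ("fog", "cloud_only")


@dataclass
class Node:
    """A network node: single-server FIFO queue with fixed service time."""

    id: str
    kind: str  # sensor | fog | cloud | actuator
    service_time: float = 0.0  # ms per message

    def __post_init__(self) -> None:
        if self.kind not in ("sensor", "fog", "cloud", "actuator"):
            raise ValidationError(f"unknown node kind {self.kind!r}")
        if self.service_time < 0:
            raise ValidationError("service_time must be >= 0")


@dataclass
class Link:
    """Directed link with propagation delay (ms) and bandwidth (bits/ms)."""

    source: str
    destination: str
    propagation_delay: float  # ms
    bandwidth: float  # bits/ms

    def __post_init__(self) -> None:
        if self.propagation_delay < 0:
            raise ValidationError("propagation_delay must be >= 0")
        if self.bandwidth <= 0:
            raise ValidationError("bandwidth must be positive")

    def transit_time(self, message_size: float) -> float:
        return self.propagation_delay + message_size / self.bandwidth


@dataclass
class FogTopology:
    """Node/link graph with the two routing paths of interest."""

    nodes: dict[str, Node]
    links: dict[tuple[str, str], Link]

    def path(self, routing: str) -> list[str]:
        if routing == "fog":
            return ["sensor", "fog", "actuator"]
        if routing == "cloud_only":
            return ["sensor", "cloud", "actuator"]
        raise ValidationError(f"routing must be one of {ROUTINGS}, got {routing!r}")

    def validate_path(self, path: list[str]) -> None:
        for node_id in path:
            if node_id not in self.nodes:
                raise TopologyError(f"node {node_id!r} missing from topology")
        for src, dst in zip(path[:-1], path[1:]):
            if (src, dst) not in self.links:
                raise TopologyError(f"link {src!r} -> {dst!r} missing from topology")

    @classmethod
    def from_dict(cls, config: dict) -> "FogTopology":
        nodes = {n["id"]: Node(**n) for n in config["nodes"]}
        links = {
            (l["source"], l["destination"]): Link(**l) for l in config["links"]
        }
        return cls(nodes=nodes, links=links)

    def to_dict(self) -> dict:
        return {
            "nodes": [vars(n) for n in self.nodes.values()],
            "links": [vars(l) for l in self.links.values()],
        }


@dataclass
class Workload:
    """Message stream emitted by the sensor."""

    message_size: float = 1e4  # bits: one EEG window
    n_messages: int = 1000
    inter_arrival: float = 20.0  # ms (fixed) or 1/rate for exponential
    arrival_process: str = "exponential"  # or "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_messages < 1:
            raise ValidationError("n_messages must be >= 1")
        if self.message_size <= 0:
            raise ValidationError("message_size must be positive")
        if self.inter_arrival <= 0:
            raise ValidationError("inter_arrival must be positive")
        if self.arrival_process not in ("fixed", "exponential"):
            raise ValidationError("arrival_process must be 'fixed' or 'exponential'")

    def emission_times(self) -> np.ndarray:
        """Sensor emission times in ms, seed-reproducible."""
        if self.arrival_process == "fixed":
            gaps = np.full(self.n_messages, self.inter_arrival)
        else:
            rng = np.random.default_rng(self.seed)
            gaps = rng.exponential(self.inter_arrival, size=self.n_messages)
        return np.cumsum(gaps)


@dataclass
class LatencyResult:
    """Per-message end-to-end latencies (ms) for one simulation run."""

    latencies: np.ndarray
    routing: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.latencies))

    @property
    def median(self) -> float:
        return float(np.median(self.latencies))

    @property
    def max(self) -> float:
        return float(np.max(self.latencies))

    def summary(self) -> dict:
        return {
            "routing": self.routing,
            "n_messages": int(len(self.latencies)),
            "mean_ms": self.mean,
            "median_ms": self.median,
            "max_ms": self.max,
        }


def default_topology(
    fog_delay_ms: float = 2.0,
    cloud_delay_ms: float = 50.0,
    bandwidth: float = 1e4,
    fog_service_ms: float = 5.0,
    cloud_service_ms: float = 5.0,
) -> FogTopology:
    """Proximate fog node vs distant cloud, equal compute."""
    nodes = {
        "sensor": Node("sensor", "sensor", 0.0),
        "fog": Node("fog", "fog", fog_service_ms),
        "cloud": Node("cloud", "cloud", cloud_service_ms),
        "actuator": Node("actuator", "actuator", 0.0),
    }
    links = {}
    for src, dst, delay in [
        ("sensor", "fog", fog_delay_ms),
        ("fog", "actuator", fog_delay_ms),
        ("sensor", "cloud", cloud_delay_ms),
        ("cloud", "actuator", cloud_delay_ms),
    ]:
        links[(src, dst)] = Link(src, dst, delay, bandwidth)
    return FogTopology(nodes=nodes, links=links)


def default_workload(seed: int = 0) -> Workload:
    """1000 messages of 10^4 bits, exponential arrivals at rate 0.05/ms."""
    return Workload(
        message_size=1e4,
        n_messages=1000,
        inter_arrival=20.0,
        arrival_process="exponential",
        seed=seed,
    )


def simulate(topology: FogTopology, workload: Workload, routing: str) -> LatencyResult:
    """Event-driven run of one routing; returns per-message latencies.

    Events (time-ordered heap): message arrival at a node, and service
    completion at a node. Each node serves one message at a time in FIFO
    order; completed messages travel the next link after propagation plus
    transmission delay. Deterministic for fixed inter-arrivals and
    seed-reproducible for exponential ones.
    """
    path = topology.path(routing)
    topology.validate_path(path)
    emissions = workload.emission_times()
    n = workload.n_messages

    counter = itertools.count()  # tie-break: preserves FIFO insertion order
    events: list[tuple[float, int, str, int, int]] = []
    # event = (time, tiebreak, kind, message_id, path_position)
    for msg, t in enumerate(emissions):
        heapq.heappush(events, (float(t), next(counter), "arrive", msg, 0))

    queues: dict[str, list[int]] = {node_id: [] for node_id in path}
    busy: dict[str, bool] = {node_id: False for node_id in path}
    position: dict[int, int] = {}
    delivered = np.full(n, np.nan)
    last_completion = np.full(n, -np.inf)

    def start_service(node_idx: int, now: float) -> None:
        node_id = path[node_idx]
        queue = queues[node_id]
        if busy[node_id] or not queue:
            return
        msg = queue.pop(0)
        busy[node_id] = True
        finish = now + topology.nodes[node_id].service_time
        heapq.heappush(events, (finish, next(counter), "finish", msg, node_idx))

    while events:
        now, _, kind, msg, node_idx = heapq.heappop(events)
        if kind == "arrive":
            position[msg] = node_idx
            queues[path[node_idx]].append(msg)
            start_service(node_idx, now)
        else:  # finish
            node_id = path[node_idx]
            busy[node_id] = False
            # causality bookkeeping: completions strictly ordered per message
            last_completion[msg] = max(last_completion[msg], now)
            if node_idx == len(path) - 1:
                delivered[msg] = now
            else:
                link = topology.links[(node_id, path[node_idx + 1])]
                arrival = now + link.transit_time(workload.message_size)
                heapq.heappush(
                    events, (arrival, next(counter), "arrive", msg, node_idx + 1)
                )
            start_service(node_idx, now)

    if np.any(np.isnan(delivered)):
        raise TopologyError("not every message was delivered")  # pragma: no cover
    return LatencyResult(latencies=delivered - emissions, routing=routing)


def compare_architectures(
    topology: FogTopology | None = None, workload: Workload | None = None
) -> dict:
    """Run fog and cloud-only routings on the same workload and seed.

    Returns the two mean latencies and their ratio (fog / cloud).
    """
    topology = topology or default_topology()
    workload = workload or default_workload()
    fog = simulate(topology, workload, "fog")
    cloud = simulate(topology, workload, "cloud_only")
    return {
        "fog_mean_ms": fog.mean,
        "cloud_mean_ms": cloud.mean,
        "ratio": fog.mean / cloud.mean if cloud.mean > 0 else np.nan,
        "fog": fog,
        "cloud": cloud,
    }
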