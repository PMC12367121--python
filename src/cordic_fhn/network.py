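"""Random pulse-coupled populations of original vs CORDIC FHN neurons.

A population of ``n_neurons`` (default 1000) is wired so that every neuron
receives exactly ``degree`` (default 100) presynaptic connections sampled
uniformly without replacement, self-connections excluded; 80% of neurons
are excitatory, the rest inhibitory.  The synapse model — unspecified in
the hardware literature this emulates — is the minimal current-based
coupling consistent with an E/I split: a presynaptic spike injects a
rectangular current pulse (weight ``w_exc``/``w_inh``, duration
``pulse_width``) into each of its targets.

Both model variants are run on the *same* seeded topology and initial
conditions, so the spike-raster discrepancy between them measures the
CORDIC approximation alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _kernels
from .cordic import DEFAULT_SCHEDULE, CordicSchedule
from .models import DriveSpec, FHNParams, _validate_model

__all__ = [
    "NetworkConfig",
    "Network",
    "SpikeRaster",
    "build_network",
    "simulate_network",
    "raster_discrepancy",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Population, coupling and run settings for the network comparison."""

    n_neurons: int = 1000
    degree: int = 100            # presynaptic inputs per neuron
    frac_excitatory: float = 0.8
    w_exc: float = 0.05
    w_inh: float = -0.25
    pulse_width: float = 1.0     # ms
    seed: int = 42
    duration: float = 1200.0     # ms
    crop: float = 1000.0         # analysis window: last `crop` ms
    drive: DriveSpec = field(default_factory=lambda: DriveSpec.constant(0.5))
    v_th: float = 1.0
    refractory: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.degree < self.n_neurons:
            raise ValueError("degree must satisfy 0 < degree < n_neurons")
        if not 0.0 <= self.frac_excitatory <= 1.0:
            raise ValueError("frac_excitatory must be in [0, 1]")
        if self.duration < self.crop:
            raise ValueError("duration must be >= crop window")


@dataclass
class Network:
    """Seeded topology + initial conditions shared by both model variants."""

    pre: np.ndarray          # (n, degree) presynaptic indices of each neuron
    excitatory: np.ndarray   # (n,) bool labels
    weights: np.ndarray      # (n,) outgoing weight of each neuron
    V0: np.ndarray
    W0: np.ndarray
    config: NetworkConfig

    def out_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR (indptr, targets) of outgoing connections per neuron."""
        n = self.config.n_neurons
        src = self.pre.ravel()
        tgt = np.repeat(np.arange(n), self.config.degree)
        order = np.argsort(src, kind="stable")
        targets = tgt[order].astype(np.int64)
        counts = np.bincount(src, minlength=n)
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return indptr, targets


def build_network(config: NetworkConfig = NetworkConfig()) -> Network:
    """Sample the seeded random topology, E/I labels and initial state.

    Initial membrane states are drawn uniformly over the tonic-orbit range
    to desynchronize the population (identical parameters would otherwise
    make every neuron fire in lockstep).
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_neurons, config.degree
    n_exc = int(round(config.frac_excitatory * n))
    excitatory = np.zeros(n, dtype=bool)
    excitatory[rng.permutation(n)[:n_exc]] = True
    weights = np.where(excitatory, config.w_exc, config.w_inh)
    pre = np.empty((n, k), dtype=np.int64)
    others = np.arange(n)
    for i in range(n):
        pool = np.delete(others, i)
        pre[i] = rng.choice(pool, size=k, replace=False)
    V0 = rng.uniform(-1.5, 1.5, size=n)
    W0 = rng.uniform(-0.1, 0.3, size=n)
    return Network(pre, excitatory, weights, V0, W0, config)


@dataclass
class SpikeRaster:
    """Per-neuron ordered spike times (ms) inside the analysis window."""

    spike_times: list  # list of np.ndarray, one per neuron
    config: NetworkConfig
    model: str

    @property
    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spike_times))

    def to_json(self) -> str:
        cfg = asdict(self.config)
        return json.dumps(
            {
                "config": cfg,
                "model": self.model,
                "spike_times": [list(map(float, s)) for s in self.spike_times],
            },
            indent=None,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SpikeRaster":
        obj = json.loads(text)
        cfg = obj["config"]
        cfg["drive"] = DriveSpec(**cfg["drive"])
        return cls(
            [np.asarray(s, dtype=float) for s in obj["spike_times"]],
            NetworkConfig(**cfg),
            obj["model"],
        )


def simulate_network(
    net: Network,
    model: str,
    params: FHNParams = FHNParams(),
    sched: CordicSchedule = DEFAULT_SCHEDULE,
    record: bool = False,
):
    """Euler co-integration of the population; returns a cropped SpikeRaster.

    With ``record=True`` additionally returns the full (V, W) histories
    (shape ``(n_steps+1, n)``) before cropping — intended for small
    diagnostic networks only.
    """
    use_cordic = _validate_model(model)
    cfg = net.config
    if cfg.drive.is_sin:
        raise NotImplementedError("network runs use constant drive")
    dt = params.dt
    n_steps = int(round(cfg.duration / dt))
    pulse_steps = max(1, int(round(cfg.pulse_width / dt)))
    refr_steps = int(round(cfg.refractory / dt))
    indptr, targets = net.out_csr()
    max_spikes = cfg.n_neurons * (int(cfg.duration / max(cfg.refractory, dt)) + 2)
    neurons, steps, n_spikes, V_hist, W_hist = _kernels.network_sim(
        use_cordic, params.a, params.b, params.T, dt,
        sched.i_min, sched.i_max, cfg.drive.I_in, n_steps,
        indptr, targets, net.weights.astype(float),
        cfg.v_th, refr_steps, pulse_steps,
        net.V0.astype(float), net.W0.astype(float),
        record, max_spikes,
    )
    t_min = cfg.duration - cfg.crop
    times = steps * dt
    spike_times = []
    for i in range(cfg.n_neurons):
        ti = times[(neurons == i) & (times > t_min)]
        spike_times.append(np.sort(ti))
    raster = SpikeRaster(spike_times, cfg, model)
    if record:
        return raster, V_hist, W_hist
    return raster


def _match_trains(a: np.ndarray, b: np.ndarray, window: float):
    """Greedy one-to-one nearest-time matching of two spike trains."""
    pairs = [
        (abs(ta - tb), i, j)
        for i, ta in enumerate(a)
        for j, tb in enumerate(b)
        if abs(ta - tb) <= window
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    diffs = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        diffs.append(d)
    return diffs


def raster_discrepancy(
    raster_a: SpikeRaster,
    raster_b: SpikeRaster,
    match_window: float = 20.0,
) -> tuple[float, float]:
    """Mean |spike-time difference| (ms) and matched fraction across models.

    Per neuron, spikes are paired greedily by nearest time within
    ``match_window``; the mean is over all matched pairs, the fraction is
    matched pairs over the larger per-pair spike count (unmatched spikes
    count against it).  Returns ``(nan, 0.0)`` when both rasters are empty.
    """
    if len(raster_a.spike_times) != len(raster_b.spike_times):
        raise ValueError("rasters must have the same neuron count")
    diffs: list[float] = []
    n_total = 0
    n_matched = 0
    for a, b in zip(raster_a.spike_times, raster_b.spike_times):
        d = _match_trains(np.asarray(a), np.asarray(b), match_window)
        diffs.extend(d)
        n_matched += len(d)
        n_total += max(len(a), len(b))
    if n_total == 0:
        return math.nan, 0.0
    mean_dt = float(np.mean(diffs)) if diffs else math.nan
    return mean_dt, n_matched / n_total
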