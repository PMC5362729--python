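"""Synthetic LSPS circuits, stimulation grids, and patch-clamp recordings.

Everything downstream (event detection, Z-score maps, FI fitting) is
validated against recordings generated here, where the ground truth —
which interneurons are connected, when each IPSC occurred, what the FI
parameters were — is known exactly.

The generative model: GABAergic interneurons are scattered as a spatial
Poisson process over the slice field.  Each is connected to the recorded
(target) cell with a probability that decays exponentially with somatic
distance, and carries a fixed evoked-IPSC peak amplitude.  A light flash
at a grid site fires every connected interneuron whose soma lies within
the activation radius of the spot, producing an inward IPSC after a
Gaussian-distributed latency.  Spontaneous IPSCs arrive as a homogeneous
Poisson process, and Gaussian baseline noise is added.  All generators
are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from lspsmap.trace import Trace, InfeasibleConstraintError

__all__ = [
    "CircuitConfig",
    "StimGrid",
    "Population",
    "MapRecording",
    "generate_hex_grid",
    "order_pseudorandom",
    "ipsc_kernel",
    "simulate_circuit",
    "simulate_map_recording",
    "simulate_fi_observations",
    "simulate_step_response",
    "spike_waveform",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class CircuitConfig:
    """Generative parameters for a synthetic inhibitory circuit + acquisition.

    Geometry is in µm with the recorded (target) cell at the origin;
    +x runs along the layer (dorsal), +y is depth from the pia.  IPSCs are
    inward (negative) in raw traces; amplitudes here are magnitudes in pA.

    Parameters
    ----------
    interneuron_density : float
        Light-excitable interneurons per mm² of slice field.
    field_width, field_depth : float
        Extent of the simulated field (µm), centered on the target cell.
    activation_radius : float
        A flash fires every connected interneuron with soma within this
        distance of the spot (µm); on the order of the laser spot size.
    connect_prob0, connect_lambda : float
        Connection probability at distance 0 and its exponential decay
        length (µm).
    strength_mean, strength_sd : float
        Evoked IPSC peak amplitude distribution (pA, magnitudes).
    close_in_gain, close_in_radius : float
        Multiplier on connection strength for presynaptic somata within
        ``close_in_radius`` µm of the target; > 1 models selectively
        strengthened perisomatic inhibition.
    tau_rise, tau_decay : float
        IPSC kinetics (ms); decay must exceed rise.
    spont_rate : float
        Spontaneous IPSC rate (Hz) per trace.
    latency_mean, latency_sd : float
        Flash-to-IPSC latency (ms).
    noise_sd : float
        Gaussian baseline noise (pA).
    spikes_per_activation : int
        Presynaptic spikes per activation (1 = single spike; > 1 a short
        burst at ``burst_interval_ms``).
    """

    interneuron_density: float = 6000.0
    field_width: float = 850.0
    field_depth: float = 1200.0
    activation_radius: float = 50.0
    connect_prob0: float = 0.9
    connect_lambda: float = 110.0
    strength_mean: float = 60.0
    strength_sd: float = 15.0
    close_in_gain: float = 1.0
    close_in_radius: float = 50.0
    tau_rise: float = 1.0
    tau_decay: float = 15.0
    spont_rate: float = 8.0
    latency_mean: float = 17.0
    latency_sd: float = 2.0
    noise_sd: float = 2.0
    spikes_per_activation: int = 1
    burst_interval_ms: float = 10.0
    pre_ms: float = 100.0
    post_ms: float = 300.0
    sample_rate_hz: float = 10000.0
    flash_duration_ms: float = 5.0
    power_density_mw_mm2: float = 42.0
    genotype_label: str = "WT"
    seed: int = 0

    def __post_init__(self):
        positive = [
            ("interneuron_density", self.interneuron_density),
            ("field_width", self.field_width),
            ("field_depth", self.field_depth),
            ("activation_radius", self.activation_radius),
            ("connect_lambda", self.connect_lambda),
            ("strength_mean", self.strength_mean),
            ("strength_sd", self.strength_sd),
            ("tau_rise", self.tau_rise),
            ("tau_decay", self.tau_decay),
            ("latency_mean", self.latency_mean),
            ("latency_sd", self.latency_sd),
            ("pre_ms", self.pre_ms),
            ("post_ms", self.post_ms),
            ("sample_rate_hz", self.sample_rate_hz),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.noise_sd < 0 or self.spont_rate < 0:
            raise ValueError("noise_sd and spont_rate must be non-negative")
        if not self.tau_decay > self.tau_rise:
            raise ValueError("tau_decay must exceed tau_rise")
        if not 0.0 <= self.connect_prob0 <= 1.0:
            raise ValueError("connect_prob0 must lie in [0, 1]")
        if self.close_in_gain < 0:
            raise ValueError("close_in_gain must be >= 0")
        if self.spikes_per_activation < 1:
            raise ValueError("spikes_per_activation must be >= 1")

    @property
    def sample_interval(self) -> float:
        return 1.0 / self.sample_rate_hz

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def _rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named random stream."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass
class StimGrid:
    """Hexagonal stimulation grid in slice coordinates (µm)."""

    sites: np.ndarray  # (n, 2)
    spacing: float
    bounds: tuple  # (width, depth)
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=float).reshape(-1, 2)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    def distances(self, point=(0.0, 0.0)) -> np.ndarray:
        return np.hypot(self.sites[:, 0] - point[0], self.sites[:, 1] - point[1])


@dataclass
class Population:
    """Simulated interneuron somata and their connectivity to the target."""

    x: np.ndarray  # µm
    y: np.ndarray  # µm
    connected: np.ndarray  # bool
    strength: np.ndarray  # pA (magnitude, close-in gain applied)

    @property
    def n_cells(self) -> int:
        return self.x.size

    def distance_to_target(self) -> np.ndarray:
        return np.hypot(self.x, self.y)


@dataclass
class MapRecording:
    """One repetition of a full-grid voltage-clamp map.

    ``traces`` is an (n_sites, n_samples) array in pA, one row per grid
    site (row order matches ``sites``); every trace shares the sampling
    and the flash at t = 0 ms.  ``truth`` carries the simulator's
    ground-truth events (columns: site, time_ms, amp_pA, kind).
    """

    repetition_index: int
    sites: np.ndarray  # (n, 2) µm
    traces: np.ndarray  # (n, T) pA
    sample_interval: float  # s
    t0: float  # s (negative: pre-flash baseline)
    flash_onset_ms: float
    flash_duration_ms: float
    power_density: float
    stimulus_order: np.ndarray
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_sites(self) -> int:
        return self.traces.shape[0]

    def trace(self, site_index: int) -> Trace:
        return Trace(
            self.traces[site_index],
            sample_interval=self.sample_interval,
            t0=self.t0,
            units="pA",
        )


# ---------------------------------------------------------------------------
# grid + ordering

def generate_hex_grid(width, depth, spacing, origin=(0.0, 0.0)) -> StimGrid:
    """All points of a hexagonal lattice inside a width × depth rectangle.

    Rows are pitched spacing·√3/2 apart with alternate rows offset by
    spacing/2; the rectangle is centered on ``origin``.  Edge sites are
    included (|coordinate| up to half-extent, with a small tolerance).
    """
    if not (width > 0 and depth > 0 and spacing > 0):
        raise ValueError("width, depth and spacing must be strictly positive")
    ox, oy = origin
    pitch = spacing * np.sqrt(3.0) / 2.0
    tol = 1e-9 * max(width, depth, spacing)
    half_w, half_d = width / 2.0 + tol, depth / 2.0 + tol
    jmax = int(np.floor(half_d / pitch))
    points = []
    for j in range(-jmax, jmax + 1):
        y = j * pitch
        offset = (spacing / 2.0) if (j % 2) else 0.0
        imin = int(np.ceil((-half_w - offset) / spacing))
        imax = int(np.floor((half_w - offset) / spacing))
        for i in range(imin, imax + 1):
            points.append((ox + offset + i * spacing, oy + y))
    return StimGrid(np.array(points), spacing=spacing, bounds=(width, depth), origin=origin)


def order_pseudorandom(grid: StimGrid, min_separation: float, seed: int,
                       max_restarts: int = 1000) -> np.ndarray:
    """Permutation of site indices with consecutive sites >= min_separation apart.

    Random permutations with greedy repair: on a violation at position k,
    swap in the first later site that satisfies both junctions; restart
    with a fresh shuffle when no repair exists (cap ``max_restarts``).
    """
    if grid.n_sites == 0:
        raise ValueError("grid is empty")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    sites = grid.sites
    n = grid.n_sites
    rng = np.random.default_rng(seed)
    if min_separation == 0 or n == 1:
        return rng.permutation(n)

    def dist(a, b):
        return np.hypot(*(sites[a] - sites[b]))

    for _ in range(max_restarts):
        perm = list(rng.permutation(n))
        ok = True
        for k in range(1, n):
            if dist(perm[k - 1], perm[k]) >= min_separation:
                continue
            repaired = False
            for m in range(k + 1, n):
                if dist(perm[k - 1], perm[m]) < min_separation:
                    continue
                perm[k], perm[m] = perm[m], perm[k]
                # the swapped-out site must still fit around position m
                bad = dist(perm[m - 1], perm[m]) < min_separation if m - 1 > k else False
                if not bad and m + 1 < n:
                    bad = dist(perm[m], perm[m + 1]) < min_separation
                if bad:
                    perm[k], perm[m] = perm[m], perm[k]
                    continue
                repaired = True
                break
            if not repaired:
                ok = False
                break
        if ok:
            out = np.asarray(perm)
            d = np.hypot(*np.diff(sites[out], axis=0).T)
            if np.all(d >= min_separation):
                return out
    raise InfeasibleConstraintError(
        f"no ordering with consecutive separation >= {min_separation} µm found "
        f"after {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# waveforms

def ipsc_kernel(duration, sample_interval, amplitude, tau_rise, tau_decay) -> Trace:
    """Difference-of-exponentials IPSC waveform (inward: negative-going).

    w(t) = exp(-t/τ_decay) − exp(-t/τ_rise) for t >= 0, normalized so the
    peak magnitude equals ``amplitude`` (pA).  All times in ms.
    """
    if not (tau_rise > 0 and tau_decay > tau_rise):
        raise ValueError("requires tau_decay > tau_rise > 0")
    if not (duration > 0 and sample_interval > 0):
        raise ValueError("duration and sample_interval must be positive")
    t = np.arange(0.0, duration, sample_interval)
    w = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = _doe_peak(tau_rise, tau_decay)
    samples = -amplitude * w / peak
    return Trace(samples, sample_interval=sample_interval * 1e-3, t0=0.0, units="pA")


def _doe_peak(tau_rise, tau_decay) -> float:
    """Analytic peak of exp(-t/τd) − exp(-t/τr)."""
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    return np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)


def spike_waveform(sample_interval_ms, peak_mV=35.0, threshold_mV=-40.0,
                   rise_ms=0.25, fall_ms=0.45, ahp_mV=8.0, ahp_tau_ms=4.0) -> np.ndarray:
    """Stereotyped action-potential shape (relative to resting/step voltage).

    Piecewise-linear depolarization from 0 to ``peak_mV`` − baseline over
    ``rise_ms``, linear fall over ``fall_ms`` to an afterhyperpolarization
    of depth ``ahp_mV`` that relaxes exponentially.  Values are offsets in
    mV added onto the membrane trajectory.
    """
    up = np.arange(0.0, rise_ms, sample_interval_ms)
    down = np.arange(0.0, fall_ms, sample_interval_ms)
    tail_t = np.arange(0.0, 6 * ahp_tau_ms, sample_interval_ms)
    height = peak_mV - threshold_mV
    rise = height * up / rise_ms
    fall = height - (height + ahp_mV) * down / fall_ms
    tail = -ahp_mV * np.exp(-tail_t / ahp_tau_ms)
    return np.concatenate([rise, fall, tail])


# ---------------------------------------------------------------------------
# circuit + recordings

def simulate_circuit(config: CircuitConfig) -> Population:
    """Scatter interneurons over the field and draw their connectivity.

    Soma count ~ Poisson(density × area); positions uniform.  A soma at
    distance d from the target is connected with probability
    connect_prob0·exp(−d/connect_lambda) and carries strength
    |N(strength_mean, strength_sd)|, multiplied by ``close_in_gain``
    when d < close_in_radius.
    """
    rng = config._rng(0)
    area_mm2 = config.field_width * config.field_depth * 1e-6
    n = rng.poisson(config.interneuron_density * area_mm2)
    x = rng.uniform(-config.field_width / 2, config.field_width / 2, n)
    y = rng.uniform(-config.field_depth / 2, config.field_depth / 2, n)
    d = np.hypot(x, y)
    p = config.connect_prob0 * np.exp(-d / config.connect_lambda)
    connected = rng.uniform(size=n) < p
    strength = np.abs(rng.normal(config.strength_mean, config.strength_sd, n))
    strength = np.where(d < config.close_in_radius,
                        strength * config.close_in_gain, strength)
    return Population(x=x, y=y, connected=connected, strength=strength)


def simulate_map_recording(population: Population, grid: StimGrid,
                           ordering, config: CircuitConfig,
                           n_repetitions: int = 1) -> list[MapRecording]:
    """Voltage-clamp traces for every grid site, one per repetition.

    Each flash fires the connected interneurons whose somata lie within
    ``activation_radius`` of the site; each emits ``spikes_per_activation``
    spikes, every spike adding one IPSC at flash + latency (latency drawn
    per event from N(latency_mean, latency_sd), clipped at 0.5 ms).
    Spontaneous IPSCs are a homogeneous Poisson process over the full
    trace; Gaussian noise is added last.  Bit-identical for a given
    (config.seed, grid, ordering).
    """
    ordering = np.asarray(ordering, dtype=int)
    if ordering.size != grid.n_sites or set(ordering.tolist()) != set(range(grid.n_sites)):
        raise ValueError("ordering must be a permutation of all site indices")
    dt_ms = 1e3 * config.sample_interval
    n_samples = int(round((config.pre_ms + config.post_ms) / dt_ms))
    t0 = -config.pre_ms * 1e-3
    kernel = ipsc_kernel(
        duration=min(10 * config.tau_decay, config.post_ms),
        sample_interval=dt_ms, amplitude=1.0,
        tau_rise=config.tau_rise, tau_decay=config.tau_decay,
    ).samples
    # per-site activated presynaptic cells (geometry is repetition-independent)
    active_cells = []
    for s in range(grid.n_sites):
        dx = population.x - grid.sites[s, 0]
        dy = population.y - grid.sites[s, 1]
        within = (np.hypot(dx, dy) <= config.activation_radius) & population.connected
        active_cells.append(np.flatnonzero(within))

    recordings = []
    for rep in range(n_repetitions):
        rng = config._rng(1 + rep)
        traces = np.zeros((grid.n_sites, n_samples))
        truth_rows = []
        for s in range(grid.n_sites):
            tr = traces[s]
            for cell in active_cells[s]:
                amp = population.strength[cell]
                for k in range(config.spikes_per_activation):
                    lat = max(0.5, rng.normal(config.latency_mean, config.latency_sd))
                    onset = lat + k * config.burst_interval_ms
                    _add_kernel(tr, kernel, onset, config.pre_ms, dt_ms, amp)
                    truth_rows.append((s, onset, amp, "evoked"))
            n_spont = rng.poisson(config.spont_rate * n_samples * config.sample_interval)
            for _ in range(n_spont):
                onset = rng.uniform(-config.pre_ms, config.post_ms)
                amp = np.abs(rng.normal(config.strength_mean, config.strength_sd))
                _add_kernel(tr, kernel, onset, config.pre_ms, dt_ms, amp)
                truth_rows.append((s, onset, amp, "spontaneous"))
            if config.noise_sd > 0:
                tr += rng.normal(0.0, config.noise_sd, n_samples)
        truth = pd.DataFrame(truth_rows, columns=["site", "time_ms", "amp_pA", "kind"])
        truth = truth.sort_values(["site", "time_ms"], ignore_index=True)
        recordings.append(MapRecording(
            repetition_index=rep,
            sites=grid.sites.copy(),
            traces=traces,
            sample_interval=config.sample_interval,
            t0=t0,
            flash_onset_ms=0.0,
            flash_duration_ms=config.flash_duration_ms,
            power_density=config.power_density_mw_mm2,
            stimulus_order=ordering.copy(),
            truth=truth,
        ))
    return recordings


def _add_kernel(trace, kernel, onset_ms, pre_ms, dt_ms, amplitude):
    """Add an IPSC kernel (scaled by amplitude) at onset_ms (flash = 0 ms)."""
    i0 = int(round((onset_ms + pre_ms) / dt_ms))
    if i0 >= trace.size:
        return
    if i0 < 0:
        clip = -i0
        n = min(kernel.size - clip, trace.size)
        if n > 0:
            trace[:n] += amplitude * kernel[clip:clip + n]
        return
    n = min(kernel.size, trace.size - i0)
    trace[i0:i0 + n] += amplitude * kernel[:n]


# ---------------------------------------------------------------------------
# current-clamp fixtures

def simulate_fi_observations(fit, currents, noise_sd=0.0, seed=0):
    """Firing rates at each current from the FI model, plus truncated noise.

    Returns (currents, rates) as float arrays; rates are clipped at 0.
    """
    from lspsmap.intrinsic import eval_fi

    currents = np.asarray(currents, dtype=float)
    rates = eval_fi(fit, currents)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = rates + rng.normal(0.0, noise_sd, currents.shape)
    return currents, np.clip(rates, 0.0, None)


def simulate_step_response(passive, current, duration, fi=None, seed=0,
                           sample_rate_hz=10000.0, adaptation=1.0,
                           first_spike_ms=10.0) -> Trace:
    """Current-clamp step response of a passive RC cell, optionally spiking.

    ``passive`` is a mapping with V_rest (mV), R (MΩ) and tau (ms).
    Subthreshold: V(t) = V_rest + I·R·(1 − e^(−t/τ)).  If ``fi`` is given
    and the model rate at ``current`` is positive, stereotyped spike
    waveforms are superimposed at the model rate; ``adaptation`` > 1
    lengthens successive interspike intervals linearly so the train's
    adaptation ratio is approximately that value.  Times in ms.
    """
    from lspsmap.intrinsic import eval_fi

    if not duration > 0:
        raise ValueError("duration must be positive")
    dt_ms = 1e3 / sample_rate_hz
    t = np.arange(0.0, duration, dt_ms)
    v_rest = float(passive["V_rest"])
    deflect = current * float(passive["R"]) / 1000.0  # pA·MΩ → mV
    v = v_rest + deflect * (1.0 - np.exp(-t / float(passive["tau"])))
    if fi is not None:
        rate = float(eval_fi(fi, current))
        if rate > 0:
            n_spikes = int(round(rate * duration * 1e-3))
            if n_spikes >= 1:
                spike_times = _spike_train(n_spikes, duration, first_spike_ms, adaptation)
                wf = spike_waveform(dt_ms)
                for st in spike_times:
                    i0 = int(round(st / dt_ms))
                    n = min(wf.size, v.size - i0)
                    if n > 0:
                        v[i0:i0 + n] += wf[:n]
    return Trace(v, sample_interval=dt_ms * 1e-3, t0=0.0, units="mV")


def _spike_train(n_spikes, duration_ms, first_spike_ms, adaptation):
    """Spike times with ISIs ramping linearly by the adaptation factor."""
    if n_spikes == 1:
        return np.array([first_spike_ms])
    weights = np.linspace(1.0, max(adaptation, 1e-6), n_spikes - 1)
    span = duration_ms - first_spike_ms - 1.0
    # mean ISI targets the requested count over the step
    isis = weights / weights.mean() * (span / n_spikes)
    times = first_spike_ms + np.concatenate([[0.0], np.cumsum(isis)])
    return times[times < duration_ms - 1.0]
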