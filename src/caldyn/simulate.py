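"""Synthetic calcium-imaging data with planted brain-state and activity-class structure.

The generator emulates a wide-field GCaMP6f recording of cortical layer 2/3
neurons across an awake -> anesthesia -> recovery session: a fixed schedule of
brain states, three planted activity classes (low / moderate / high) whose
membership evolves between states through planted transition matrices, event
times drawn from a refractory renewal process, and calcium transients rendered
with a double-exponential kernel plus Gaussian noise.

Because every event time, class label, and state boundary is known, each
downstream stage (event detection, temporal segmentation, neuron
classification, transition estimation) can be tested as a parameter-recovery
problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Mapping

import numpy as np

from .traces import TraceMatrix

#: Activity classes, ordered from least to most active.
CLASSES: tuple[str, ...] = ("low", "moderate", "high")

#: Cortical regions used for the synthetic region labels.
REGIONS: tuple[str, ...] = ("M1", "V1", "S1", "RSP")

#: Hard refractory period (s) between events; matches the detection rule that
#: admits at most one event per 0.8-s interval, so detection can in principle
#: recover every planted event.
REFRACTORY_S: float = 0.8

#: Default brain-state schedule (name, duration s). The 600-s anesthetic
#: inhalation period is split into induction + maintenance, and the 700-s
#: recovery into early + late, giving the five phases the temporal
#: segmentation is expected to find. Total 1400 s.
DEFAULT_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("awake", 100.0),
    ("induction", 100.0),
    ("maintenance", 500.0),
    ("early_recovery", 350.0),
    ("late_recovery", 350.0),
)

#: Awake-state class composition (low, moderate, high).
DEFAULT_INITIAL_FRACTIONS: tuple[float, float, float] = (0.10, 0.25, 0.65)

#: Planted class transition matrices, one per consecutive state pair; rows =
#: from-class, cols = to-class, order (low, moderate, high). Cells that the
#: anesthesia literature reports for this paradigm are used where available;
#: the rest are filled in to produce the characteristic trajectory: high
#: activity collapses entering anesthesia and rebounds through recovery.
DEFAULT_TRANSITIONS: tuple[tuple[tuple[float, ...], ...], ...] = (
    # awake -> induction
    ((0.80, 0.15, 0.05), (0.70, 0.20, 0.10), (0.53, 0.17, 0.30)),
    # induction -> maintenance
    ((0.95, 0.03, 0.02), (0.75, 0.20, 0.05), (0.50, 0.30, 0.20)),
    # maintenance -> early recovery
    ((0.55, 0.20, 0.25), (0.13, 0.30, 0.57), (0.14, 0.20, 0.66)),
    # early recovery -> late recovery
    ((0.50, 0.20, 0.30), (0.20, 0.30, 0.50), (0.07, 0.20, 0.73)),
)

#: Mean event rate (events/s) per class; constant across states by default
#: (class membership, not within-class rate, carries the state dependence).
DEFAULT_CLASS_RATES: dict = {
    "low": 0.002,
    "moderate": {"awake": 0.113, "induction": 0.053, "maintenance": 0.127,
                 "early_recovery": 0.09, "late_recovery": 0.152},
    "high": {"awake": 0.47, "induction": 0.22, "maintenance": 0.53,
             "early_recovery": 0.375, "late_recovery": 0.63},
}

#: Peak amplitude (dF/F units) of the coherent up-state waveform per state:
#: slow-wave up-states are largest under deep anesthesia and smallest in the
#: desynchronized awake state.
DEFAULT_BACKGROUND_GAIN: dict[str, float] = {
    "awake": 0.6,
    "induction": 1.3,
    "maintenance": 1.3,
    "early_recovery": 0.7,
    "late_recovery": 0.6,
}

#: Per-state population synchrony: the fraction of each neuron's events that
#: are locked to shared population bursts (up-states). Isoflurane slow-wave /
#: burst-suppression activity is highly synchronized; awake cortex fires more
#: independently but retains substantial population coupling.
DEFAULT_SYNC: dict[str, float] = {
    "awake": 0.85,
    "induction": 0.90,
    "maintenance": 0.95,
    "early_recovery": 0.80,
    "late_recovery": 0.95,
}

#: Rate (bursts/s) of the shared population burst rhythm per state. Up-states
#: recur quasi-periodically with a state-specific frequency: slow sparse
#: bursts while entering anesthesia (burst-suppression-like), ~0.5 Hz slow
#: waves at maintenance, faster shallower rhythms through recovery, and a
#: sparse infra-slow arousal rhythm awake. The rhythm's frequency is the
#: state signature that time warping cannot absorb: windows with different
#: burst counts can never be fully aligned.
DEFAULT_BURST_RATES: dict[str, float] = {
    "awake": 0.4,
    "induction": 0.2,
    "maintenance": 0.5,
    "early_recovery": 0.3,
    "late_recovery": 0.6,
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    Rates are events/s and must respect the refractory bound
    ``rate <= 1/REFRACTORY_S``; kernel time constants are seconds.
    ``class_rates`` maps class -> rate, or class -> {state: rate} for
    state-dependent rates. ``baseline_f`` sets the raw-fluorescence baseline;
    ``None`` renders traces directly on the dF/F scale.
    """

    n_neurons: int = 300
    n_mice: int = 5
    sampling_rate: float = 10.0
    phase_schedule: tuple[tuple[str, float], ...] = DEFAULT_SCHEDULE
    initial_class_fractions: tuple[float, float, float] = DEFAULT_INITIAL_FRACTIONS
    class_transitions: tuple = DEFAULT_TRANSITIONS
    class_rates: Mapping = field(default_factory=lambda: dict(DEFAULT_CLASS_RATES))
    transition_noise: float = 0.0
    kernel_rise_s: float = 0.08
    kernel_decay_s: float = 0.5
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.25
    noise_sd: float = 0.05
    baseline_f: float | None = 100.0
    sync: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SYNC))
    burst_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BURST_RATES)
    )
    burst_jitter_sd: float = 0.03
    background_gain: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_GAIN)
    )
    background_floor: float = 0.0
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.25 for r in REGIONS}
    )
    mouse_rate_multipliers: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def states(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.phase_schedule)

    @property
    def state_bounds(self) -> list[tuple[str, float, float]]:
        """(state, start_s, end_s) for each scheduled state."""
        bounds, t = [], 0.0
        for name, dur in self.phase_schedule:
            bounds.append((name, t, t + dur))
            t += dur
        return bounds

    @property
    def total_duration_s(self) -> float:
        return float(sum(dur for _, dur in self.phase_schedule))

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate))

    @property
    def class_fractions(self) -> dict[str, tuple[float, float, float]]:
        """Marginal class fractions per state implied by the transition chain."""
        p = np.asarray(self.initial_class_fractions, float)
        out = {self.states[0]: tuple(p)}
        for state, T in zip(self.states[1:], self.class_transitions):
            p = p @ np.asarray(T, float)
            out[state] = tuple(p)
        return out

    def rate(self, cls: str, state: str) -> float:
        r = self.class_rates[cls]
        if isinstance(r, Mapping):
            r = r[state]
        return float(r)

    def sync_of(self, state: str) -> float:
        return float(self.sync.get(state, 0.0))

    def burst_rate(self, state: str) -> float:
        return float(self.burst_rates.get(state, 0.0))

    def bg_gain_of(self, state: str) -> float:
        g = self.background_gain
        if isinstance(g, Mapping):
            return float(g.get(state, 0.0))
        return float(g)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.n_neurons < 1 or self.n_mice < 1:
            raise ValueError("n_neurons and n_mice must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if any(dur <= 0 for _, dur in self.phase_schedule):
            raise ValueError("all state durations must be positive")
        if len(set(self.states)) != len(self.states):
            raise ValueError("state names must be unique")
        fr = np.asarray(self.initial_class_fractions, float)
        if fr.shape != (3,) or abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
            raise ValueError("initial_class_fractions must be 3 nonnegative values summing to 1")
        if len(self.class_transitions) != len(self.states) - 1:
            raise ValueError(
                f"need {len(self.states) - 1} transition matrices for "
                f"{len(self.states)} states, got {len(self.class_transitions)}"
            )
        for T in self.class_transitions:
            T = np.asarray(T, float)
            if T.shape != (3, 3) or (T < 0).any():
                raise ValueError("each class transition matrix must be 3x3 nonnegative")
            if np.abs(T.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("class transition matrix rows must sum to 1")
        if not 0.0 <= self.transition_noise <= 1.0:
            raise ValueError("transition_noise must be in [0, 1]")
        if not self.kernel_decay_s > self.kernel_rise_s > 0:
            raise ValueError("require kernel_decay_s > kernel_rise_s > 0")
        if self.amplitude_mean <= 0 or self.amplitude_cv < 0 or self.noise_sd < 0:
            raise ValueError("amplitude_mean must be > 0; amplitude_cv, noise_sd >= 0")
        if self.burst_jitter_sd < 0:
            raise ValueError("burst_jitter_sd must be nonnegative")
        for state in self.states:
            if self.bg_gain_of(state) < 0:
                raise ValueError("background gain must be nonnegative")
        if not 0.0 <= self.background_floor <= 1.0:
            raise ValueError("background_floor must be in [0, 1]")
        for state in self.states:
            sy = self.sync_of(state)
            if not 0.0 <= sy <= 1.0:
                raise ValueError(f"sync for state {state!r} must be in [0, 1]")
            lam = self.burst_rate(state)
            if lam < 0 or lam > 1.0 / REFRACTORY_S:
                raise ValueError(
                    f"burst rate for state {state!r} must be in [0, 1/{REFRACTORY_S}]"
                )
            if sy > 0 and lam <= 0:
                raise ValueError(f"state {state!r} has sync > 0 but no burst rate")
        rp = np.asarray([self.region_probs[r] for r in self.region_probs], float)
        if abs(rp.sum() - 1.0) > 1e-9 or (rp < 0).any():
            raise ValueError("region_probs must be nonnegative and sum to 1")
        mults = self.mouse_rate_multipliers
        if mults is not None and len(mults) != self.n_mice:
            raise ValueError("mouse_rate_multipliers must have one entry per mouse")
        bound = 1.0 / REFRACTORY_S
        for cls in CLASSES:
            for state in self.states:
                r = self.rate(cls, state)
                if r < 0:
                    raise ValueError("rates must be nonnegative")
                eff = r * (max(mults) if mults else 1.0)
                if eff > bound:
                    raise ValueError(
                        f"rate {eff:g} events/s for class {cls!r} in state {state!r} "
                        f"exceeds the refractory bound 1/{REFRACTORY_S} = {bound:g} events/s"
                    )



@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    event_times: list[np.ndarray]  # per neuron, sorted seconds
    class_by_state: np.ndarray  # (n_neurons, n_states) of class names
    states: tuple[str, ...]
    state_bounds: list[tuple[str, float, float]]
    regions: np.ndarray  # per-neuron region label
    mouse: np.ndarray  # per-neuron mouse id
    burst_times: dict = None  # state -> shared population burst times (s)

    @property
    def n_neurons(self) -> int:
        return len(self.event_times)

    def window_states(self, window_s: float) -> list[str]:
        """State name of each consecutive analysis window of length window_s.

        A window is attributed to the state containing its midpoint; with the
        default schedule every state duration is a multiple of the window, so
        no window straddles a boundary.
        """
        total = self.state_bounds[-1][2]
        n_win = int(total // window_s)
        out = []
        for w in range(n_win):
            mid = (w + 0.5) * window_s
            for name, s, e in self.state_bounds:
                if s <= mid < e:
                    out.append(name)
                    break
        return out

    def class_at_time(self, t: float) -> np.ndarray:
        for i, (_, s, e) in enumerate(self.state_bounds):
            if s <= t < e or (t == e and i == len(self.state_bounds) - 1):
                return self.class_by_state[:, i]
        raise ValueError(f"time {t} outside recording")

    def to_json(self, path) -> None:
        obj = {
            "states": list(self.states),
            "state_bounds": [[n, s, e] for n, s, e in self.state_bounds],
            "event_times": [list(map(float, ev)) for ev in self.event_times],
            "class_by_state": self.class_by_state.tolist(),
            "regions": self.regions.tolist(),
            "mouse": self.mouse.tolist(),
            "burst_times": {k: list(map(float, v))
                            for k, v in (self.burst_times or {}).items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            event_times=[np.asarray(ev, float) for ev in obj["event_times"]],
            class_by_state=np.asarray(obj["class_by_state"], dtype=object),
            states=tuple(obj["states"]),
            state_bounds=[(n, float(s), float(e)) for n, s, e in obj["state_bounds"]],
            regions=np.asarray(obj["regions"], dtype=object),
            mouse=np.asarray(obj["mouse"], int),
            burst_times={k: np.asarray(v, float)
                         for k, v in obj.get("burst_times", {}).items()},
        )


def _renewal_times(rng: np.random.Generator, rate: float, start: float, end: float,
                   t_prev: float) -> list[float]:
    """Events of a refractory renewal process on [start, end).

    Gaps between events are REFRACTORY_S plus an exponential with mean
    (1/rate - REFRACTORY_S). The first event after the state onset waits only
    the exponential part (the onset acts as a virtual event without its
    refractory period), while still respecting the refractory tail of the
    previous state's last event.
    """
    if rate <= 0:
        return []
    mean_exp = 1.0 / rate - REFRACTORY_S
    times = []
    t0 = max(start, t_prev + REFRACTORY_S)
    while True:
        t = t0 + rng.exponential(mean_exp) if mean_exp > 0 else t0
        if t >= end:
            return times
        times.append(t)
        t0 = t + REFRACTORY_S


def _enforce_refractory(times: np.ndarray) -> np.ndarray:
    """Greedy left-to-right thinning so consecutive events are >= REFRACTORY_S
    apart (earlier event wins)."""
    if len(times) < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= REFRACTORY_S:
            kept.append(t)
    return np.asarray(kept)


def simulate_events(config: SimulationConfig) -> GroundTruth:
    """Draw per-neuron class schedules and event times. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, states = config.n_neurons, config.states
    n_states = len(states)

    # neurons partitioned evenly across mice, in blocks
    mouse = np.repeat(np.arange(config.n_mice), int(np.ceil(n / config.n_mice)))[:n]
    region_names = list(config.region_probs)
    probs = np.asarray([config.region_probs[r] for r in region_names], float)
    regions = np.asarray(region_names, dtype=object)[rng.choice(len(region_names), size=n, p=probs)]

    # scheduled class per (neuron, state): Markov chain over the planted
    # transition matrices, then optional label noise per state
    cls_idx = np.empty((n, n_states), dtype=int)
    p0 = np.asarray(config.initial_class_fractions, float)
    cls_idx[:, 0] = rng.choice(3, size=n, p=p0)
    for s, T in enumerate(config.class_transitions, start=1):
        T = np.asarray(T, float)
        u = rng.random(n)
        cum = np.cumsum(T, axis=1)
        cls_idx[:, s] = (u[:, None] > cum[cls_idx[:, s - 1]]).sum(axis=1)
    if config.transition_noise > 0:
        flip = rng.random((n, n_states)) < config.transition_noise
        alt = rng.integers(1, 3, size=(n, n_states))
        cls_idx = np.where(flip, (cls_idx + alt) % 3, cls_idx)

    mults = (np.asarray(config.mouse_rate_multipliers, float)
             if config.mouse_rate_multipliers is not None
             else np.ones(config.n_mice))

    bounds = config.state_bounds

    # shared population burst rhythm, one quasi-periodic train per state:
    # a grid at the state's burst rate, anchored to the state onset, with a
    # small shared timing jitter per burst. All neurons see the same bursts:
    # the synthetic recording represents one cortical population, and this
    # up-state backbone is what makes each brain state's population dynamics
    # recognizable.
    bursts = {}
    for state, start, end in bounds:
        lam = config.burst_rate(state)
        if lam <= 0:
            bursts[state] = np.empty(0)
            continue
        period = 1.0 / lam
        grid = start + (np.arange(int((end - start) * lam)) + 0.5) * period
        grid = grid + rng.normal(0.0, 0.05 * period, size=len(grid))
        bursts[state] = np.sort(np.clip(grid, start, np.nextafter(end, start)))

    event_times: list[np.ndarray] = []
    jit = config.burst_jitter_sd
    for i in range(n):
        t_prev = -np.inf
        times: list[float] = []
        for s, (state, start, end) in enumerate(bounds):
            rate = config.rate(CLASSES[cls_idx[i, s]], state) * mults[mouse[i]]
            sy = config.sync_of(state)
            lam = config.burst_rate(state)
            # burst-locked component: participate in each population burst
            # with probability min(1, rate*sync/lambda) (capped: a neuron can
            # fire at most once per burst), with small per-neuron jitter
            ev_b: np.ndarray = np.empty(0)
            p_part = 0.0
            bs = bursts[state]
            if sy > 0 and lam > 0 and rate > 0 and len(bs):
                p_part = min(1.0, rate * sy / lam)
                take = rng.random(len(bs)) < p_part
                jitter = rng.normal(0.0, jit, size=len(bs)) if jit > 0 else 0.0
                ev_b = np.clip(bs + jitter, start, np.nextafter(end, start))[take]
            # independent component: refractory renewal at the residual rate
            ev_i = np.asarray(_renewal_times(rng, rate - p_part * lam, start, end,
                                             t_prev))
            ev = np.sort(np.concatenate([ev_b, ev_i]))
            if t_prev > -np.inf and len(ev):
                ev = ev[ev >= t_prev + REFRACTORY_S] if ev[0] < t_prev + REFRACTORY_S else ev
            ev = _enforce_refractory(ev)
            if len(ev):
                times.extend(ev.tolist())
                t_prev = ev[-1]
        event_times.append(np.asarray(times, float))

    class_by_state = np.asarray(CLASSES, dtype=object)[cls_idx]
    return GroundTruth(
        event_times=event_times,
        class_by_state=class_by_state,
        states=states,
        state_bounds=bounds,
        regions=regions,
        mouse=mouse,
        burst_times=bursts,
    )


def calcium_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Double-exponential calcium impulse response, zero for t < 0, unnormalized."""
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    k[t < 0] = 0.0
    return k


def render_traces(truth: GroundTruth, config: SimulationConfig) -> TraceMatrix:
    """Render fluorescence traces from planted events.

    Each event contributes an amplitude-scaled double-exponential transient,
    normalized to unit peak at the sampled frame resolution; amplitudes are
    log-normal with the configured mean and CV; Gaussian noise of sd
    ``noise_sd`` is added on the dF/F scale. With ``baseline_f`` set the
    output is raw fluorescence ``baseline_f * (1 + signal + noise)``.
    """
    if truth.n_neurons != config.n_neurons:
        raise ValueError(
            f"truth has {truth.n_neurons} neurons but config specifies {config.n_neurons}"
        )
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    fs = config.sampling_rate
    n_frames = config.n_frames
    sig = np.zeros((config.n_neurons, n_frames), dtype=np.float64)

    # kernel support: long enough that the tail is < 1e-4 of peak
    support = int(np.ceil(10.0 * config.kernel_decay_s * fs))
    cv = config.amplitude_cv
    sigma2 = np.log1p(cv * cv)
    mu = np.log(config.amplitude_mean) - sigma2 / 2.0

    for i, events in enumerate(truth.event_times):
        if len(events) == 0:
            continue
        amps = rng.lognormal(mu, np.sqrt(sigma2), size=len(events)) if cv > 0 \
            else np.full(len(events), config.amplitude_mean)
        for t_e, a in zip(events, amps):
            f0 = int(np.floor(t_e * fs))
            f1 = min(f0 + support, n_frames)
            if f1 <= f0:
                continue
            tt = np.arange(f0, f1) / fs - t_e
            k = calcium_kernel(tt, config.kernel_rise_s, config.kernel_decay_s)
            peak = k.max()
            if peak > 0:
                sig[i, f0:f1] += a * k / peak

    # coherent up-state depolarization: every population burst also carries a
    # subthreshold calcium waveform (the kernel at unit peak scaled by
    # background_gain) shared across neurons, weighted per neuron by its
    # firing engagement in that state (population coupling is empirically
    # rate-dependent) with mild log-normal heterogeneity. Burst-aligned and
    # sparse, it rides under the event transients rather than creating
    # spurious peaks, and gives each brain state a deterministic population
    # signature over and above the stochastic event trains.
    if truth.burst_times:
        state_idx = {st: i for i, st in enumerate(truth.states)}
        for state, s0, e0 in truth.state_bounds:
            bs = truth.burst_times.get(state)
            gain = config.bg_gain_of(state)
            if bs is None or len(bs) == 0 or gain <= 0:
                continue
            wave = np.zeros(n_frames)
            for b in bs:
                f0 = int(np.floor(b * fs))
                f1 = min(f0 + support, n_frames)
                if f1 <= f0:
                    continue
                tt = np.arange(f0, f1) / fs - b
                k = calcium_kernel(tt, config.kernel_rise_s, config.kernel_decay_s)
                pk = k.max()
                if pk > 0:
                    wave[f0:f1] += k / pk
            wave *= gain
            si = state_idx[state]
            rmax = max(config.rate(c, state) for c in CLASSES)
            rel = np.asarray([
                config.rate(truth.class_by_state[i, si], state)
                for i in range(config.n_neurons)
            ]) / (rmax if rmax > 0 else 1.0)
            # even near-silent neurons receive up-state synaptic input, so
            # their subthreshold co-modulation has a floor
            rel = np.maximum(rel, config.background_floor)
            cv_c = 0.3
            s2 = np.log1p(cv_c * cv_c)
            coupling = rel * np.clip(
                rng.lognormal(-s2 / 2.0, np.sqrt(s2), size=config.n_neurons), None, 2.0)
            f0 = int(round(s0 * fs))
            f1 = min(int(round(e0 * fs)) + support, n_frames)
            sig[:, f0:f1] += coupling[:, None] * wave[None, f0:f1]

    if config.noise_sd > 0:
        sig += rng.normal(0.0, config.noise_sd, size=sig.shape)

    if config.baseline_f is None:
        values, is_dff = sig, True
    else:
        values, is_dff = config.baseline_f * (1.0 + sig), False
    return TraceMatrix(
        values=values,
        sampling_rate=fs,
        is_dff=is_dff,
        regions=truth.regions.copy(),
        mouse=truth.mouse.copy(),
    )


def simulate(config: SimulationConfig) -> tuple[TraceMatrix, GroundTruth]:
    """Convenience wrapper: events + traces in one call."""
    truth = simulate_events(config)
    return render_traces(truth, config), truth


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["phase_schedule"] = [[n, float(s)] for n, s in config.phase_schedule]
    d["class_transitions"] = [np.asarray(T, float).tolist() for T in config.class_transitions]
    d["initial_class_fractions"] = list(config.initial_class_fractions)
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    known = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "phase_schedule" in d:
        d["phase_schedule"] = tuple((n, float(s)) for n, s in d["phase_schedule"])
    if "class_transitions" in d:
        d["class_transitions"] = tuple(tuple(map(tuple, T)) for T in d["class_transitions"])
    if "initial_class_fractions" in d:
        d["initial_class_fractions"] = tuple(d["initial_class_fractions"])
    if "mouse_rate_multipliers" in d and d["mouse_rate_multipliers"] is not None:
        d["mouse_rate_multipliers"] = tuple(d["mouse_rate_multipliers"])
    return SimulationConfig(**d)
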