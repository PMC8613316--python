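"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure its downstream stage
assumes and emits the ground truth alongside the data, so every stage has a
parameter-recovery test surface:

* ``generate_population`` — GCaMP6f-like ROI traces at 10 fps: a drifting
  baseline, homogeneous-Poisson event times, instantaneous-rise /
  exponential-decay transients (default tau 0.4 s, amplitude 1.0 dF/F0 —
  a fast-indicator proxy; the kinetics are configurable, not a biophysical
  model), Gaussian noise.
* ``generate_whisking_session`` — whisking bouts at 30 fps coupled to a
  10 fps whole-field activity trace with configurable gain and delay.
* ``generate_texture_session`` — a population with planted novel/familiar
  texture selectivity receiving response pulses during matching contacts.
* ``generate_spine_history`` — longitudinal protrusion tables with
  configurable formation / elimination / survival probabilities and
  positional re-emergence near prior elimination sites.
* ``generate_frame_pair`` — a translated, noisy frame pair as the optic-flow
  fixture.

All randomness flows through per-call ``numpy`` Generators seeded from the
config, so identical configs give bit-identical outputs and modules can be
tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._validate import InvalidConfigError
from .spines import SPINE_CLASSES
from .texture import TEXTURES, Contact, ContactSchedule

__all__ = [
    "PopulationConfig",
    "SelectivityGroundTruth",
    "SpineHistoryConfig",
    "generate_population",
    "generate_whisking_session",
    "generate_texture_session",
    "generate_spine_history",
    "generate_frame_pair",
    "make_texture_image",
    "make_selectivity",
    "alternating_contact_schedule",
    "regular_bout_schedule",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth parameters of a synthetic ROI population.

    Amplitudes (kernel, noise, drift) are in dF/F0 units relative to
    ``baseline_level``; the raw trace is
    ``F = baseline_level * (1 + drift + transients + noise)``.
    """

    n_neurons: int = 20
    duration_s: float = 600.0
    fps: float = 10.0
    firing_rate_hz: float = 0.1
    kernel_amplitude: float = 1.0
    kernel_decay_tau_s: float = 0.4
    noise_sd: float = 0.05
    baseline_drift_amplitude: float = 0.05
    drift_period_s: float = 120.0
    baseline_level: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0:
            raise InvalidConfigError("fps and duration_s must be positive")
        n_frames = self.duration_s * self.fps
        if abs(n_frames - round(n_frames)) > 1e-9 or round(n_frames) < 2:
            raise InvalidConfigError("duration_s * fps must be an integer >= 2")
        if self.noise_sd < 0 or self.firing_rate_hz < 0:
            raise InvalidConfigError("noise_sd and firing_rate_hz must be >= 0")
        if self.kernel_decay_tau_s <= 0:
            raise InvalidConfigError("kernel_decay_tau_s must be positive")
        if self.n_neurons < 1:
            raise InvalidConfigError("need at least one neuron")
        if self.drift_period_s < 100.0:
            raise InvalidConfigError("drift_period_s must be >= 100 s (slow drift)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


def _transient_component(
    times: np.ndarray, amplitudes: np.ndarray, n_frames: int, fps: float, tau_s: float
) -> np.ndarray:
    """Sum of instantaneous-rise, exponential-decay pulses sampled at frames."""
    t = np.arange(n_frames) / fps
    out = np.zeros(n_frames)
    for ti, ai in zip(times, amplitudes):
        start = int(np.ceil(ti * fps))
        if start >= n_frames:
            continue
        out[start:] += ai * np.exp(-(t[start:] - ti) / tau_s)
    return out


def generate_population(
    config: PopulationConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Raw trace matrix (neurons x frames) and ground-truth event table
    (neuron_id, time_s).

    Event times are a homogeneous Poisson process at ``firing_rate_hz`` per
    neuron; the drift is a slow sinusoid with a random phase per neuron.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_neurons, config.n_frames
    t = np.arange(T) / config.fps
    F = np.empty((n, T))
    events = []
    for i in range(n):
        n_ev = rng.poisson(config.firing_rate_hz * config.duration_s)
        ev_times = np.sort(rng.uniform(0, config.duration_s, size=n_ev))
        phase = rng.uniform(0, 2 * np.pi)
        drift = config.baseline_drift_amplitude * np.sin(
            2 * np.pi * t / config.drift_period_s + phase
        )
        transients = _transient_component(
            ev_times,
            np.full(ev_times.size, config.kernel_amplitude),
            T,
            config.fps,
            config.kernel_decay_tau_s,
        )
        noise = rng.normal(0, config.noise_sd, size=T) if config.noise_sd > 0 else 0.0
        F[i] = config.baseline_level * (1.0 + drift + transients + noise)
        events.extend({"neuron_id": f"n{i}", "time_s": float(ts)} for ts in ev_times)
    truth = pd.DataFrame(events, columns=["neuron_id", "time_s"])
    return F, truth


@dataclass(frozen=True)
class SelectivityGroundTruth:
    """Planted per-neuron selectivity labels and response amplitudes.

    Labels partition the population into NTS (novel-only response), FTS
    (familiar-only), non-selective (both), and non-responsive (neither).
    """

    labels: tuple[str, ...]
    amp_novel: np.ndarray
    amp_familiar: np.ndarray

    def __post_init__(self):
        an = np.asarray(self.amp_novel, dtype=float)
        af = np.asarray(self.amp_familiar, dtype=float)
        if not (len(self.labels) == an.size == af.size):
            raise InvalidConfigError("labels and amplitude arrays must align")
        if (an < 0).any() or (af < 0).any():
            raise InvalidConfigError("amplitudes must be >= 0")
        for lbl, a_n, a_f in zip(self.labels, an, af):
            if lbl == "NTS" and a_f != 0:
                raise InvalidConfigError("NTS neurons must have familiar amplitude 0")
            if lbl == "FTS" and a_n != 0:
                raise InvalidConfigError("FTS neurons must have novel amplitude 0")
            if lbl == "non-responsive" and (a_n != 0 or a_f != 0):
                raise InvalidConfigError("non-responsive neurons must have zero amplitudes")
            if lbl not in ("NTS", "FTS", "non-selective", "non-responsive"):
                raise InvalidConfigError(f"unknown label {lbl!r}")
        object.__setattr__(self, "amp_novel", an)
        object.__setattr__(self, "amp_familiar", af)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": [f"n{i}" for i in range(len(self.labels))],
                "label": self.labels,
                "amp_novel": self.amp_novel,
                "amp_familiar": self.amp_familiar,
            }
        )


def make_selectivity(
    n_neurons: int,
    frac_nts: float,
    frac_fts: float,
    amplitude: float,
    frac_nonselective: float = 0.0,
    seed: int = 0,
) -> SelectivityGroundTruth:
    """Random population with the given planted category fractions (rounded
    to counts) and a common response amplitude."""
    n_nts = int(round(frac_nts * n_neurons))
    n_fts = int(round(frac_fts * n_neurons))
    n_ns = int(round(frac_nonselective * n_neurons))
    if n_nts + n_fts + n_ns > n_neurons:
        raise InvalidConfigError("category fractions exceed 1")
    labels = (
        ["NTS"] * n_nts
        + ["FTS"] * n_fts
        + ["non-selective"] * n_ns
        + ["non-responsive"] * (n_neurons - n_nts - n_fts - n_ns)
    )
    rng = np.random.default_rng(seed)
    labels = list(rng.permutation(labels))
    amp_n = np.array([amplitude if l in ("NTS", "non-selective") else 0.0 for l in labels])
    amp_f = np.array([amplitude if l in ("FTS", "non-selective") else 0.0 for l in labels])
    return SelectivityGroundTruth(tuple(labels), amp_n, amp_f)


def alternating_contact_schedule(
    n_per_texture: int,
    contact_s: float = 2.0,
    gap_s: float = 4.0,
    first_start_s: float = 5.0,
    phase: str = "testing",
) -> ContactSchedule:
    """Alternating novel/familiar contacts of fixed duration and spacing."""
    contacts = []
    t = first_start_s
    for k in range(2 * n_per_texture):
        tex = TEXTURES[k % 2]
        contacts.append(Contact(tex, t, t + contact_s))
        t += contact_s + gap_s
    return ContactSchedule(tuple(contacts), phase=phase)


def generate_texture_session(
    selectivity: SelectivityGroundTruth,
    schedule: ContactSchedule,
    config: PopulationConfig,
) -> tuple[np.ndarray, ContactSchedule]:
    """Population traces with planted texture responses.

    Selective neurons receive an added rectangular dF/F0 pulse of their
    amplitude throughout every matching-texture contact; non-responsive
    neurons receive none.  Returns (raw F matrix, the schedule).
    """
    if not schedule.contacts:
        raise InvalidConfigError("empty contact schedule")
    for tex in TEXTURES:
        if not schedule.for_texture(tex):
            raise InvalidConfigError(f"schedule has no {tex} contacts")
    if len(selectivity.labels) != config.n_neurons:
        raise InvalidConfigError("selectivity and population sizes differ")
    last_end = max(c.end_s for c in schedule.contacts)
    if last_end > config.duration_s:
        raise InvalidConfigError("schedule extends past the recording")
    F, _ = generate_population(config)
    T = config.n_frames
    t = np.arange(T) / config.fps
    masks = {}
    for tex in TEXTURES:
        m = np.zeros(T, dtype=bool)
        for c in schedule.for_texture(tex):
            m |= (t >= c.start_s) & (t < c.end_s)
        masks[tex] = m
    added = (
        selectivity.amp_novel[:, None] * masks["novel"][None, :]
        + selectivity.amp_familiar[:, None] * masks["familiar"][None, :]
    )
    F = F + config.baseline_level * added
    return F, schedule


def regular_bout_schedule(
    n_bouts: int, bout_s: float = 2.0, gap_s: float = 4.0, first_start_s: float = 5.0, amplitude: float = 1.0
) -> list[tuple[float, float, float]]:
    """(start_s, end_s, amplitude) whisking bouts, evenly spaced."""
    return [
        (first_start_s + k * (bout_s + gap_s), first_start_s + k * (bout_s + gap_s) + bout_s, amplitude)
        for k in range(n_bouts)
    ]


def generate_whisking_session(
    bouts: list[tuple[float, float, float]],
    gain: float = 0.5,
    delay_s: float = 0.3,
    noise_sd: float = 0.05,
    duration_s: float = 300.0,
    behavior_fps: int = 30,
    imaging_fps: int = 10,
    whisk_noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Coupled whisking-magnitude (behavior fps) and whole-field activity
    (imaging fps) traces.

    The whole-field trace is ``gain`` x the delayed, block-mean-downsampled
    whisking magnitude plus Gaussian noise of ``noise_sd`` (dF/F0 units).
    ``delay_s`` is rounded to the behavior-frame grid; the effective value is
    recorded in the ground truth.  Bouts must not overlap; delay >= 0.
    """
    if delay_s < 0:
        raise InvalidConfigError("delay_s must be >= 0")
    if behavior_fps % imaging_fps != 0:
        raise InvalidConfigError("behavior_fps must be a multiple of imaging_fps")
    ivs = sorted((b[0], b[1]) for b in bouts)
    for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise InvalidConfigError(f"overlapping bouts at {s1} s")
    rng = np.random.default_rng(seed)
    n_b = int(round(duration_s * behavior_fps))
    t_b = np.arange(n_b) / behavior_fps
    whisk = np.zeros(n_b)
    for start, end, amp in bouts:
        if end > duration_s:
            raise InvalidConfigError("bout extends past the recording")
        whisk[(t_b >= start) & (t_b < end)] = amp
    if whisk_noise_sd > 0:
        whisk = np.abs(whisk + rng.normal(0, whisk_noise_sd, size=n_b))
    delay_frames = int(round(delay_s * behavior_fps))
    delayed = np.concatenate([np.zeros(delay_frames), whisk])[:n_b]
    factor = behavior_fps // imaging_fps
    down = delayed[: (n_b // factor) * factor].reshape(-1, factor).mean(axis=1)
    noise = rng.normal(0, noise_sd, size=down.size) if noise_sd > 0 else 0.0
    ca_wf = gain * down + noise
    return {
        "whisking": whisk,
        "behavior_fps": behavior_fps,
        "ca_wf": ca_wf,
        "imaging_fps": imaging_fps,
        "truth": {
            "gain": gain,
            "delay_s": delay_frames / behavior_fps,
            "bout_onsets_s": [b[0] for b in bouts],
            "mean_bout_amplitude": float(np.mean([b[2] for b in bouts])) if bouts else 0.0,
        },
    }


@dataclass(frozen=True)
class SpineHistoryConfig:
    """Stochastic model of a longitudinal protrusion table.

    Per inter-session interval, each existing protrusion is eliminated with
    ``p_eliminate`` — except spines in their first interval after formation,
    which survive it with ``p_survive`` — and ``Binomial(n_prev, p_form)``
    new spines form.  A fraction ``reemergence_fraction`` of new spines is
    placed strictly within ``reemergence_radius_um`` of a recorded
    elimination site; the rest land uniformly on the dendrite.
    """

    n_sessions: int = 3
    n_spines_initial: int = 150
    p_eliminate: float = 0.05
    p_form: float = 0.05
    p_survive: float = 0.5
    dendrite_length_um: float = 100.0
    reemergence_fraction: float = 0.0
    reemergence_radius_um: float = 2.0
    filopodium_fraction: float = 0.1
    class_probs: tuple[float, ...] = (0.3, 0.25, 0.3, 0.15)  # mushroom/stubby/thin/other
    dendrite_id: str = "d0"
    seed: int = 0

    def __post_init__(self):
        probs = (
            self.p_eliminate,
            self.p_form,
            self.p_survive,
            self.reemergence_fraction,
            self.filopodium_fraction,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise InvalidConfigError("all probabilities must lie in [0, 1]")
        if self.dendrite_length_um <= 0:
            raise InvalidConfigError("dendrite_length_um must be positive")
        if self.n_sessions < 2:
            raise InvalidConfigError("need at least 2 sessions")
        if abs(sum(self.class_probs) - 1) > 1e-9 or len(self.class_probs) != 4:
            raise InvalidConfigError("class_probs must be 4 probabilities summing to 1")


def generate_spine_history(config: SpineHistoryConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(long-format SpineTable, per-protrusion ground truth).

    Presence obeys conservation — spines at session s are the survivors from
    s-1 plus that interval's formations — and a protrusion never resurrects:
    a re-emerged spine near an old site is a new identity.
    """
    rng = np.random.default_rng(config.seed)
    L = config.dendrite_length_um
    spine_classes = list(SPINE_CLASSES)

    protrusions: list[dict] = []

    def new_protrusion(birth: int, position: float, cls: str, reemerged: bool) -> dict:
        p = {
            "id": f"p{len(protrusions)}",
            "birth": birth,
            "death": None,  # first session absent, None = alive at end
            "position": float(np.clip(position, 0, L)),
            "class": cls,
            "reemerged": reemerged,
        }
        protrusions.append(p)
        return p

    n0 = config.n_spines_initial
    n_filo = int(round(config.filopodium_fraction * n0))
    for k in range(n0):
        cls = (
            "filopodium"
            if k < n_filo
            else spine_classes[rng.choice(4, p=config.class_probs)]
        )
        new_protrusion(0, rng.uniform(0, L), cls, False)

    elimination_sites: list[float] = []
    for s in range(1, config.n_sessions):
        # site pool snapshot: new spines re-emerge near sites eliminated in
        # *earlier* intervals, matching the lost-then-recovered accounting
        site_pool = list(elimination_sites)
        alive = [p for p in protrusions if p["death"] is None]
        n_prev_spines = sum(p["class"] != "filopodium" for p in alive)
        n_prev_filo = len(alive) - n_prev_spines
        for p in alive:
            first_interval = p["birth"] == s - 1 and p["birth"] > 0
            p_gone = (1 - config.p_survive) if first_interval else config.p_eliminate
            if rng.random() < p_gone:
                p["death"] = s
                if p["class"] != "filopodium":
                    elimination_sites.append(p["position"])
        # spine and filopodium formation are separate binomials on their own
        # previous-session counts, so each recovered rate has a clean oracle
        n_new_spines = rng.binomial(n_prev_spines, config.p_form) if n_prev_spines else 0
        n_new_filo = rng.binomial(n_prev_filo, config.p_form) if n_prev_filo else 0
        for _ in range(n_new_spines):
            reemerge = bool(site_pool) and rng.random() < config.reemergence_fraction
            if reemerge:
                site = site_pool[rng.integers(len(site_pool))]
                r = config.reemergence_radius_um
                pos = site + rng.uniform(-0.9 * r, 0.9 * r)
            else:
                pos = rng.uniform(0, L)
            cls = spine_classes[rng.choice(4, p=config.class_probs)]
            new_protrusion(s, pos, cls, reemerge)
        for _ in range(n_new_filo):
            new_protrusion(s, rng.uniform(0, L), "filopodium", False)

    rows = []
    for p in protrusions:
        for s in range(config.n_sessions):
            present = p["birth"] <= s and (p["death"] is None or s < p["death"])
            rows.append(
                {
                    "protrusion_id": p["id"],
                    "session_index": s,
                    "dendrite_id": config.dendrite_id,
                    "position_um": p["position"],
                    "class": p["class"],
                    "present": present,
                }
            )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "protrusion_id": [p["id"] for p in protrusions],
            "birth_session": [p["birth"] for p in protrusions],
            "death_session": [p["death"] for p in protrusions],
            "position_um": [p["position"] for p in protrusions],
            "class": [p["class"] for p in protrusions],
            "reemerged": [p["reemerged"] for p in protrusions],
        }
    )
    return table, truth



def make_texture_image(shape: tuple[int, int] = (128, 128), smooth_px: float = 2.0, seed: int = 0) -> np.ndarray:
    """Smoothed random texture with structure at the block-matching scale."""
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(size=shape), smooth_px)
    img -= img.min()
    return img / img.max()


def generate_frame_pair(
    shift: tuple[int, int],
    texture: np.ndarray | None = None,
    noise_sd: float = 0.0,
    search_radius: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame pair where frame 2 is frame 1 translated by (dy, dx) plus noise.

    The translation is circular (wrap-around); block matching is evaluated at
    interior grid points where wrap effects cannot reach.
    """
    dy, dx = shift
    if abs(dy) > search_radius or abs(dx) > search_radius:
        raise InvalidConfigError(
            f"shift {shift} exceeds the block-search radius {search_radius}"
        )
    if texture is None:
        texture = make_texture_image(seed=seed)
    rng = np.random.default_rng(seed + 1)
    frame_a = np.asarray(texture, dtype=float)
    frame_b = np.roll(frame_a, (dy, dx), axis=(0, 1))
    if noise_sd > 0:
        frame_a = frame_a + rng.normal(0, noise_sd, frame_a.shape)
        frame_b = frame_b + rng.normal(0, noise_sd, frame_b.shape)
    return frame_a, frame_b
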