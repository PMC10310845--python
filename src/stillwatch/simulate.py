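"""Synthetic audience cohorts with known ground truth.

The generator emulates a remote audience watching a 30-minute performance
through a webcam face tracker. Each participant's momentary engagement
state follows a sticky 4-state Markov chain over {distracted, engaged,
reflecting, immersed}; per-second head movement is drawn from a lognormal
family whose location depends on the state (distracted > reflecting ≈
engaged > immersed), scaled by a per-participant fidgetiness trait.
Stimulus-locked shared events briefly boost every participant's hazard of
becoming distracted, which is what induces positive inter-subject
correlation — the coupling is behavioural, not additive noise. In the
experience-sampling condition each probe adds a short keypress movement
spike, and probe responses read out the state at probe onset with a
configurable confusion rate. Retrospective questionnaire scores follow a
negative link from mean movement to engagement, with enjoyment tracking
engagement except in a planted "discordant" subgroup (low engagement, high
enjoyment, inflated movement) that attenuates the movement–enjoyment
correlation. Landmark rendering inverts the head-movement metric, so the
pipeline can be exercised end-to-end from raw frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .analysis import RetrospectiveScores, write_retrospective_csv
from .errors import ConfigError
from .landmarks import LandmarkFrame, LandmarkSeries, N_LANDMARKS
from .movement import REFERENCE_IOD_CM, MovementSeries
from .probes import (
    CATEGORIES,
    EngagementCategory,
    ProbeResponseSeries,
    ProbeSchedule,
    write_probe_responses_csv,
)

STATE_NAMES = tuple(c.value for c in CATEGORIES)  # distracted, engaged, reflecting, immersed
_DISTRACTED = 0


@dataclass
class SimulationConfig:
    """Study-condition parameters for cohort generation.

    Defaults emulate the study design: 132 participants (58 control, 74
    experience-sampling), 1800 s of content, 23 probes ~1 min apart with
    ±5 s jitter. Movement is lognormal with shape σ = 1 (skewness ≈ 6) and
    state means chosen so that the pooled per-second mean lands near
    0.67 cm/s once the discordant subgroup's inflation is included; base
    state occupancy (.10, .41, .245, .245) plus the shared distraction
    events (whose sticky aftermath extends each event's effect by roughly
    the chain's ~20 s dwell time) yields response marginals near
    17/36/23/24%.
    """

    n_participants: int = 132
    duration_s: int = 1800
    control_fraction: float = 58 / 132

    # probe schedule
    probe_count: int = 23
    probe_start_s: float = 75.0
    probe_spacing_s: float = 60.0
    probe_jitter_s: float = 5.0

    # engagement-state chain (base marginals; shared events add distraction,
    # bringing realised distracted occupancy to ~0.17)
    state_marginals: tuple = (0.10, 0.41, 0.245, 0.245)
    state_persistence: float = 0.95  # per-second stay probability
    transition_matrix: np.ndarray | None = None  # overrides marginals/persistence

    # shared stimulus events (the ISC-inducing component)
    shared_event_rate_per_s: float = 1 / 180
    shared_event_duration_s: int = 3
    shared_event_hazard: float = 0.25  # per-second probability of forced distraction

    # movement model
    state_mean_movement: tuple = (1.15, 0.50, 0.52, 0.29)  # cm/s per state
    movement_sigma: float = 1.0  # lognormal shape (skewness ≈ 6.2)
    participant_scale_sigma: float = 0.35  # fidgetiness trait, lognormal
    spike_amplitude_cm: float = 2.0  # keypress spike after each probe
    spike_duration_s: int = 3

    # landmark rendering
    iod_px_mean: float = 63.0
    iod_px_sd: float = 8.0
    landmark_jitter_px: float = 0.0
    frame_rate_hz: float = 1.0

    # probe responses
    confusion_rate: float = 0.1
    missing_response_rate: float = 0.1

    # retrospective links
    engagement_intercept: float = 4.2
    engagement_slope: float = 1.2  # negative link: engagement drops with movement
    engagement_noise_sd: float = 0.5
    enjoyment_noise_sd: float = 8.0
    discordant_fraction: float = 0.25
    discordant_movement_inflation: float = 1.8
    discordant_enjoyment_boost: float = 25.0  # enjoyment offset, 0–100 scale
    intention_center: float = 3.0
    intention_slope: float = 2.0
    condition_effect: float = 0.0  # engagement shift in the sampling condition

    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0 or self.duration_s <= 0:
            raise ConfigError("n_participants must be >= 0 and duration positive")
        m = np.asarray(self.state_marginals, dtype=float)
        if m.shape != (4,) or not math.isclose(m.sum(), 1.0, abs_tol=1e-9) or np.any(m < 0):
            raise ConfigError("state_marginals must be 4 non-negative values summing to 1")
        for name in (
            "control_fraction",
            "state_persistence",
            "shared_event_hazard",
            "confusion_rate",
            "missing_response_rate",
            "discordant_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            if t.shape != (4, 4) or np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0):
                raise ConfigError("transition matrix rows must be probabilities summing to 1")
            self.transition_matrix = t

    def effective_transition_matrix(self) -> np.ndarray:
        """Sticky chain: ``p·I + (1−p)·1⊗marginals``; its stationary
        distribution equals ``state_marginals`` exactly."""
        if self.transition_matrix is not None:
            return self.transition_matrix
        m = np.asarray(self.state_marginals, dtype=float)
        p = self.state_persistence
        return p * np.eye(4) + (1 - p) * np.tile(m, (4, 1))

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["transition_matrix"] is not None:
            d["transition_matrix"] = np.asarray(d["transition_matrix"]).tolist()
        d["state_marginals"] = list(d["state_marginals"])
        d["state_mean_movement"] = list(d["state_mean_movement"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for key in ("state_marginals", "state_mean_movement"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticParticipant:
    participant_id: str
    condition: str
    true_states: np.ndarray  # per-second state indices (ground truth)
    true_movement: np.ndarray  # per-second cm/s, spike included (ground truth)
    movement_scale: float
    iod_px: float
    is_discordant: bool
    movement: MovementSeries  # truth-backed series (bypasses rendering)
    landmarks: LandmarkSeries | None = None
    responses: ProbeResponseSeries | None = None
    retrospective: RetrospectiveScores | None = None


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    schedule: ProbeSchedule
    event_seconds: np.ndarray
    participants: list[SyntheticParticipant] = field(default_factory=list)

    def movement_by_id(self, condition: str | None = None) -> dict[str, MovementSeries]:
        return {
            p.participant_id: p.movement
            for p in self.participants
            if condition is None or p.condition == condition
        }

    def responses_by_id(self) -> dict[str, ProbeResponseSeries]:
        return {
            p.participant_id: p.responses
            for p in self.participants
            if p.responses is not None
        }

    def retrospective_scores(self) -> list[RetrospectiveScores]:
        return [p.retrospective for p in self.participants if p.retrospective]


def _event_mask(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Shared stimulus events: cohort-random onset seconds, each lasting
    ``shared_event_duration_s``. Random placement avoids systematic phase
    locking with the probe grid."""
    t = config.duration_s
    n_events = int(round(config.shared_event_rate_per_s * t))
    mask = np.zeros(t, dtype=bool)
    if n_events == 0 or config.shared_event_hazard == 0:
        return mask
    onsets = np.sort(rng.choice(t, size=min(n_events, t), replace=False))
    for o in onsets:
        mask[o : o + config.shared_event_duration_s] = True
    return mask


def simulate_state_sequence(
    config: SimulationConfig,
    rng: np.random.Generator,
    event_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One participant's per-second engagement-state sequence.

    A first-order Markov chain at 1 Hz; at shared-event seconds the
    participant is forced into the distracted state with probability
    ``shared_event_hazard`` (otherwise transitions normally)."""
    return _simulate_states(config, rng, event_mask, n=1)[0]


def _simulate_states(
    config: SimulationConfig,
    rng: np.random.Generator,
    event_mask: np.ndarray | None,
    n: int,
) -> np.ndarray:
    """Vectorised chain simulation for ``n`` participants sharing one RNG."""
    t_mat = config.effective_transition_matrix()
    cum = np.cumsum(t_mat, axis=1)
    marg_cum = np.cumsum(np.asarray(config.state_marginals, dtype=float))
    duration = config.duration_s
    if event_mask is None:
        event_mask = np.zeros(duration, dtype=bool)
    states = np.empty((n, duration), dtype=np.int64)
    cur = np.searchsorted(marg_cum, rng.random(n), side="right").clip(max=3)
    for t in range(duration):
        if t > 0:
            u = rng.random(n)
            cur = (cum[cur] < u[:, None]).sum(axis=1).clip(max=3)
        if event_mask[t] and config.shared_event_hazard > 0:
            forced = rng.random(n) < config.shared_event_hazard
            cur = np.where(forced, _DISTRACTED, cur)
        states[:, t] = cur
    return states


def simulate_movement(
    states: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    scale: float = 1.0,
    probe_onsets: np.ndarray | None = None,
) -> np.ndarray:
    """Per-second true movement (cm/s) for one state sequence.

    Lognormal with shared shape σ and state-dependent mean (the lognormal
    location is ``log(mean) − σ²/2``), multiplied by the participant's
    fidgetiness ``scale``. When ``probe_onsets`` is given (the
    experience-sampling condition), a keypress spike of configured
    amplitude and duration is added from each probe onset. The first
    second is 0, matching the metric's first-sample convention."""
    means = np.asarray(config.state_mean_movement, dtype=float)
    sigma = config.movement_sigma
    mu = np.log(means) - 0.5 * sigma**2
    mov = rng.lognormal(mean=mu[states], sigma=sigma) * scale
    if probe_onsets is not None:
        mov = add_probe_spikes(mov, probe_onsets, config)
    mov[0] = 0.0
    return mov


def add_probe_spikes(
    movement: np.ndarray, probe_onsets: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Overlay the keypress response spike on a movement sequence (returns a
    copy). The spike is a measurement artifact of responding, distinct from
    the fidgeting tendency the retrospective links operate on."""
    out = np.array(movement, dtype=float)
    for onset in np.asarray(probe_onsets, dtype=int):
        out[onset : onset + config.spike_duration_s] += config.spike_amplitude_cm
    return out


def _face_template(iod_px: float) -> np.ndarray:
    """A rigid 68-point face with the requested interocular distance.

    Only the eye clusters (markers 37–48) and the nose tip (31) feed the
    metric; the remaining points are placed on simple parametric curves and
    move rigidly with the head."""
    pts = np.zeros((N_LANDMARKS, 2))
    half = iod_px / 2.0
    r_eye = 0.12 * iod_px
    angles = np.arange(6) * (2 * np.pi / 6)
    hexagon = np.column_stack([np.cos(angles), np.sin(angles)]) * r_eye
    pts[36:42] = hexagon + [-half, 0.0]  # markers 37–42, left eye
    pts[42:48] = hexagon + [half, 0.0]  # markers 43–48, right eye
    pts[30] = [0.0, 0.45 * iod_px]  # marker 31, nose tip
    # jaw 1–17 on a lower arc
    jaw = np.linspace(0, np.pi, 17)
    pts[0:17] = np.column_stack([-np.cos(jaw), np.sin(jaw) * 1.1]) * iod_px
    # brows 18–27 on an upper arc
    brow = np.linspace(0.2 * np.pi, 0.8 * np.pi, 10)
    pts[17:27] = np.column_stack([-np.cos(brow), -np.sin(brow) * 0.5]) * iod_px
    # nose bridge 28–30 and base 32–36
    pts[27:30] = np.column_stack([np.zeros(3), np.linspace(0.05, 0.35, 3) * iod_px])
    base = np.linspace(-0.2, 0.2, 5)
    pts[31:36] = np.column_stack([base, np.full(5, 0.52)]) * iod_px
    # mouth 49–68 on an ellipse
    mouth = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    pts[48:68] = (
        np.column_stack([np.cos(mouth) * 0.35, np.sin(mouth) * 0.15 + 0.75]) * iod_px
    )
    return pts


def render_landmarks(
    true_movement: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    participant_id: str = "P000",
    condition: str = "control",
    iod_px: float | None = None,
) -> LandmarkSeries:
    """Synthesise a landmark stream realising the given movement.

    The head (a rigid face template yielding the participant's pixel IOD)
    performs a random-direction walk: each second it is displaced by
    ``movement_cm × iod_px / 6.3`` pixels, so the head-movement metric
    inverts the rendering exactly when ``landmark_jitter_px`` is 0. With
    ``frame_rate_hz`` > 1, extra within-second frames (identical head
    position, timestamps offset by 1/rate) exercise 1 Hz downsampling."""
    if iod_px is None:
        iod_px = max(config.iod_px_mean + config.iod_px_sd * rng.standard_normal(), 10.0)
    template = _face_template(iod_px)
    t = len(true_movement)
    pos = np.zeros((t, 2))
    pos[0] = [320.0, 240.0]
    theta = rng.uniform(0, 2 * np.pi, size=t)
    step_px = true_movement * iod_px / REFERENCE_IOD_CM
    for k in range(1, t):
        pos[k] = pos[k - 1] + step_px[k] * np.array([np.cos(theta[k]), np.sin(theta[k])])
    # keep coordinates in a plausible pixel range without changing steps
    pos -= pos.min(axis=0) - 2.0 * iod_px

    rate = max(int(round(config.frame_rate_hz)), 1)
    frames = []
    for k in range(t):
        for j in range(rate):
            pts = template + pos[k]
            if config.landmark_jitter_px > 0:
                pts = pts + rng.normal(0, config.landmark_jitter_px, size=pts.shape)
            frames.append(LandmarkFrame(timestamp=k + j / rate, points=pts))
    return LandmarkSeries(participant_id, condition, frames)


def simulate_probe_responses(
    states: np.ndarray,
    schedule: ProbeSchedule,
    config: SimulationConfig,
    rng: np.random.Generator,
    participant_id: str = "P000",
) -> ProbeResponseSeries:
    """Readout of the true state at each probe onset, flipped uniformly to
    another category with the confusion rate and dropped with the
    missingness rate."""
    responses: dict[int, EngagementCategory] = {}
    for p in range(len(schedule)):
        if rng.random() < config.missing_response_rate:
            continue
        onset = schedule.onset_second(p)
        state = int(states[onset]) if onset < len(states) else int(states[-1])
        if rng.random() < config.confusion_rate:
            others = [s for s in range(4) if s != state]
            state = others[rng.integers(len(others))]
        responses[p] = CATEGORIES[state]
    return ProbeResponseSeries(participant_id, responses, n_probes=len(schedule))


def simulate_retrospective(
    participant_id: str,
    condition: str,
    mean_movement: float,
    is_discordant: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> RetrospectiveScores:
    """Questionnaire outcomes from the negative movement→engagement link.

    ``engagement = clip(intercept − slope·mean_movement + noise, 1, 5)``;
    enjoyment tracks engagement linearly (mapped to 0–100) with noise, and
    discordant participants receive an additive enjoyment boost on top of
    the same link — they end up low-engagement/high-enjoyment (with their
    inflated movement) while the cohort-level engagement–enjoyment
    correlation stays high; intention is a logistic draw on engagement."""
    eng = (
        config.engagement_intercept
        - config.engagement_slope * mean_movement
        + rng.normal(0, config.engagement_noise_sd)
    )
    if condition == "experience_sampling":
        eng += config.condition_effect
    eng = float(np.clip(eng, 1.0, 5.0))
    enj = 25.0 * (eng - 1.0) + rng.normal(0, config.enjoyment_noise_sd)
    if is_discordant:
        enj += config.discordant_enjoyment_boost
    enj = float(np.clip(enj, 0.0, 100.0))
    p_yes = 1.0 / (1.0 + np.exp(-config.intention_slope * (eng - config.intention_center)))
    return RetrospectiveScores(
        participant_id, condition, eng, enj, bool(rng.random() < p_yes)
    )


def default_schedule(config: SimulationConfig, rng: np.random.Generator) -> ProbeSchedule:
    """Probes at ``start + k·spacing`` with uniform ±jitter, trimmed to the
    performance duration."""
    base = config.probe_start_s + config.probe_spacing_s * np.arange(config.probe_count)
    times = base + rng.uniform(-config.probe_jitter_s, config.probe_jitter_s, base.size)
    times = times[(times >= 1) & (times < config.duration_s - 1)]
    return ProbeSchedule(np.sort(times), duration_s=config.duration_s)


def simulate_cohort(config: SimulationConfig, render: bool = False) -> SyntheticCohort:
    """Generate a full cohort, deterministically from ``config.seed``.

    Per-participant RNG streams are spawned from the master seed, so any
    prefix of the cohort is reproducible. With ``render=True``, landmark
    streams are synthesised for every participant (the slow, end-to-end
    path); otherwise participants carry only the truth-backed movement
    series, which is what the statistical analyses consume."""
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *participant_ss = root.spawn(config.n_participants + 1)
    cohort_rng = np.random.default_rng(cohort_ss)

    schedule = default_schedule(config, cohort_rng)
    event_mask = _event_mask(config, cohort_rng)
    event_seconds = np.flatnonzero(event_mask)
    probe_onsets = np.array(
        [schedule.onset_second(p) for p in range(len(schedule))], dtype=int
    )

    n = config.n_participants
    n_control = int(round(config.control_fraction * n))
    n_discordant = int(round(config.discordant_fraction * n))
    discordant = np.zeros(n, dtype=bool)
    if n_discordant:
        discordant[cohort_rng.choice(n, size=n_discordant, replace=False)] = True

    cohort = SyntheticCohort(config, schedule, event_seconds)
    width = max(3, len(str(max(n, 1))))
    for i in range(n):
        rng = np.random.default_rng(participant_ss[i])
        pid = f"P{i + 1:0{width}d}"
        condition = "control" if i < n_control else "experience_sampling"
        scale = float(
            rng.lognormal(-0.5 * config.participant_scale_sigma**2,
                          config.participant_scale_sigma)
        )
        if discordant[i]:
            scale *= config.discordant_movement_inflation
        states = simulate_state_sequence(config, rng, event_mask)
        # keypress spikes go into the observed movement only; the
        # retrospective link runs on the spike-free behavioural tendency
        base_mov = simulate_movement(states, config, rng, scale=scale)
        true_mov = (
            add_probe_spikes(base_mov, probe_onsets, config)
            if condition == "experience_sampling"
            else base_mov
        )
        iod_px = max(config.iod_px_mean + config.iod_px_sd * rng.standard_normal(), 10.0)
        movement = MovementSeries(
            pid,
            condition,
            np.arange(config.duration_s),
            true_mov,
            np.full(config.duration_s, iod_px),
        )
        landmarks = (
            render_landmarks(true_mov, config, rng, pid, condition, iod_px)
            if render
            else None
        )
        responses = (
            simulate_probe_responses(states, schedule, config, rng, pid)
            if condition == "experience_sampling"
            else None
        )
        retro = simulate_retrospective(
            pid, condition, float(base_mov.mean()), bool(discordant[i]), config, rng
        )
        cohort.participants.append(
            SyntheticParticipant(
                pid, condition, states, true_mov, scale, iod_px,
                bool(discordant[i]), movement, landmarks, responses, retro,
            )
        )
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a cohort to disk in the pipeline's file formats.

    Layout: ``manifest.csv``, ``landmarks/<pid>.jsonl`` (rendered on demand
    when the cohort was generated without rendering), ``probes.csv``,
    ``retrospective.csv``, ``ground_truth.csv``. Returns the manifest path.
    """
    import pandas as pd

    from .landmarks import write_landmark_series

    out = Path(out_dir)
    (out / "landmarks").mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        lm = p.landmarks
        if lm is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([cohort.config.seed, 7_777, int(p.participant_id[1:])])
            )
            lm = render_landmarks(
                p.true_movement, cohort.config, rng, p.participant_id, p.condition, p.iod_px
            )
        lm_path = out / "landmarks" / f"{p.participant_id}.jsonl"
        write_landmark_series(lm, lm_path)
        rows.append(
            (
                p.participant_id,
                p.condition,
                str(lm_path.relative_to(out)),
                "probes.csv" if p.responses is not None else "",
                "retrospective.csv",
            )
        )
    pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "landmark_path", "probes_path", "retrospective_path"],
    ).to_csv(out / "manifest.csv", index=False)
    write_probe_responses_csv(cohort.responses_by_id(), cohort.schedule, out / "probes.csv")
    write_retrospective_csv(cohort.retrospective_scores(), out / "retrospective.csv")
    gt = []
    for p in cohort.participants:
        gt.append(
            pd.DataFrame(
                {
                    "participant_id": p.participant_id,
                    "second": np.arange(cohort.config.duration_s),
                    "true_state": [STATE_NAMES[s] for s in p.true_states],
                    "true_movement_cm": p.true_movement,
                }
            )
        )
    if gt:
        pd.concat(gt, ignore_index=True).to_csv(out / "ground_truth.csv", index=False)
    else:
        pd.DataFrame(
            columns=["participant_id", "second", "true_state", "true_movement_cm"]
        ).to_csv(out / "ground_truth.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    return out / "manifest.csv"
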