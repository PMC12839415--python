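"""Synthetic OCAT session and cohort generator.

The OCAT presents sequences of three numbers (position 1/2/3 carrying
low/medium/high cognitive workload) at targets laid out so that consecutive
saccades cover horizontal, vertical and diagonal planes; the participant
clicks to advance after mentally adding each number.  This module generates
a forward model of such sessions: a task script (target layout), a
participant profile (latent oculomotor parameters, age, DRS score), and a
raw gaze recording at 120 Hz with fixation jitter, main-sequence-shaped
saccades, blinks as validity gaps, and workload-dependent pupil dynamics.

Group structure: participants are Cognitively Normal (CN, DRS >= 140) or
Possible MCI (PMCI, DRS < 140).  PMCI profiles are slower and noisier by
configurable effect sizes (longer saccadic latency and fixation time, larger
fixation jitter, higher blink rate, larger pupil variability, slower
completion).  The effect magnitudes are design defaults of this generator,
not empirical claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry, px_to_deg
from .recording import EVENT_COLUMNS, GazeRecording

PLANES = ("horizontal", "vertical", "diagonal")
WORKLOADS = ("low", "medium", "high")


class ConfigurationError(ValueError):
    """A cohort specification violates the label rule or another contract."""


def _draw_trunc(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size=None):
    """Draw from a normal truncated to [lo, hi] (inverse-CDF sampling)."""
    if sd <= 0:
        return np.full(size, mean) if size is not None else mean
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size=size)
    return mean + sd * ndtri(u)


# ---------------------------------------------------------------------------
# Task script
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stimulus:
    seq_idx: int
    pos_idx: int  # 1-based position within the sequence (workload level)
    target_x_px: float
    target_y_px: float
    digit: int
    plane: str | None  # planned transition plane from the previous stimulus


@dataclass
class TaskScript:
    sequences: list[list[Stimulus]]

    @property
    def stimuli(self) -> list[Stimulus]:
        return [s for seq in self.sequences for s in seq]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def validate(self, geometry: ScreenGeometry = DEFAULT_GEOMETRY) -> None:
        for seq in self.sequences:
            if len(seq) != 3:
                raise ValueError("every sequence must contain exactly 3 stimuli")
        for s in self.stimuli:
            if not (0 <= s.target_x_px < geometry.width_px and 0 <= s.target_y_px < geometry.height_px):
                raise ValueError("target coordinates must lie on the screen")
        planes = {s.plane for s in self.stimuli if s.plane is not None}
        # Three planes need at least three transitions (n_sequences >= 2).
        if len(self.stimuli) >= 4 and planes != set(PLANES):
            raise ValueError("script must cover horizontal, vertical and diagonal planes")


_PLANE_BASE_ANGLES = {
    "horizontal": (0.0, 180.0),
    "vertical": (90.0, 270.0),
    "diagonal": (45.0, 135.0, 225.0, 315.0),
}


def generate_task_script(
    n_sequences: int = 3,
    layout_policy: str = "cycle",
    rng: np.random.Generator | None = None,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    margin_px: float = 150.0,
) -> TaskScript:
    """Generate a task script whose consecutive targets cycle through the
    horizontal, vertical and diagonal saccadic planes.

    ``layout_policy='cycle'`` cycles the three planes in a seed-dependent
    order, which guarantees full plane coverage whenever the script has at
    least three transitions (``n_sequences >= 2``).
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if layout_policy != "cycle":
        raise ValueError(f"unknown layout policy {layout_policy!r}")
    rng = np.random.default_rng(rng)

    w, h = geometry.width_px, geometry.height_px
    lo_x, hi_x = margin_px, w - margin_px
    lo_y, hi_y = margin_px, h - margin_px

    plane_order = list(PLANES)
    rng.shuffle(plane_order)

    n_stimuli = 3 * n_sequences
    x = rng.uniform(w * 0.25, w * 0.75)
    y = rng.uniform(h * 0.3, h * 0.7)
    points: list[tuple[float, float]] = [(x, y)]
    planes: list[str | None] = [None]
    for i in range(1, n_stimuli):
        plane = plane_order[(i - 1) % 3]
        dist = rng.uniform(300.0, 600.0)
        placed = False
        while not placed:
            bases = list(_PLANE_BASE_ANGLES[plane])
            rng.shuffle(bases)
            for base in bases:
                theta = math.radians(base + rng.uniform(-15.0, 15.0))
                nx = x + dist * math.cos(theta)
                ny = y - dist * math.sin(theta)  # screen y grows downward
                if lo_x <= nx <= hi_x and lo_y <= ny <= hi_y:
                    x, y = nx, ny
                    placed = True
                    break
            if not placed:
                dist *= 0.7  # shrink until a candidate fits
        points.append((x, y))
        planes.append(plane)

    digits = rng.integers(1, 10, size=n_stimuli)
    sequences: list[list[Stimulus]] = []
    for seq in range(n_sequences):
        stimuli = []
        for pos in range(3):
            i = seq * 3 + pos
            stimuli.append(
                Stimulus(
                    seq_idx=seq,
                    pos_idx=pos + 1,
                    target_x_px=points[i][0],
                    target_y_px=points[i][1],
                    digit=int(digits[i]),
                    plane=planes[i],
                )
            )
        sequences.append(stimuli)
    script = TaskScript(sequences)
    script.validate(geometry)
    return script


# ---------------------------------------------------------------------------
# Participant profiles and cohort specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent generative parameters for one participant."""

    group: str  # 'CN' | 'PMCI'
    age: float  # years
    drs: int  # Dementia Rating Scale score, 0-144
    latency_ms: float  # mean saccadic latency
    fixation_duration_ms: float  # mean sub-fixation duration
    jitter_px: float  # fixation jitter SD
    blink_rate_per_min: float
    blink_duration_ms: float
    pupil_mm: float  # pupil baseline
    pupil_noise_sd_mm: float
    workload_multipliers: tuple[float, float, float]  # positions 1..3, >= 1, non-decreasing
    think_time_ms: float  # base onset-to-click think time (position 1)
    seed: int

    def __post_init__(self) -> None:
        if self.group not in ("CN", "PMCI"):
            raise ValueError("group must be 'CN' or 'PMCI'")
        if (self.drs >= 140) != (self.group == "CN"):
            raise ConfigurationError(f"DRS {self.drs} inconsistent with group {self.group} (cutoff 140)")
        positives = (
            self.latency_ms, self.fixation_duration_ms, self.jitter_px,
            self.blink_rate_per_min, self.blink_duration_ms, self.pupil_mm,
            self.pupil_noise_sd_mm, self.think_time_ms,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("latent parameters must be strictly positive")
        m = self.workload_multipliers
        if len(m) != 3 or m[0] < 1 or any(m[i] > m[i + 1] for i in range(2)):
            raise ValueError("workload multipliers must be >= 1 and non-decreasing")

    @property
    def think_times_ms(self) -> tuple[float, float, float]:
        """Per-position mean think time (onset to click)."""
        return tuple(self.think_time_ms * m for m in self.workload_multipliers)


@dataclass(frozen=True)
class GroupParams:
    """Population (mean, sd) of each latent oculomotor parameter for one group.

    Truncation bounds keep draws physiologically sensible and strictly
    positive.
    """

    latency_ms: tuple[float, float] = (200.0, 20.0)
    fixation_duration_ms: tuple[float, float] = (400.0, 80.0)
    jitter_px: tuple[float, float] = (8.0, 1.5)
    blink_rate_per_min: tuple[float, float] = (15.0, 7.0)
    blink_duration_ms: tuple[float, float] = (150.0, 30.0)
    pupil_mm: tuple[float, float] = (3.5, 0.4)
    pupil_noise_sd_mm: tuple[float, float] = (0.10, 0.025)
    think_time_ms: tuple[float, float] = (2000.0, 400.0)
    workload_multipliers: tuple[float, float, float] = (1.0, 1.2, 1.5)
    age: tuple[float, float] = (64.9, 8.9)

    BOUNDS = {
        "latency_ms": (80.0, 500.0),
        "fixation_duration_ms": (150.0, 1200.0),
        "jitter_px": (2.0, 30.0),
        "blink_rate_per_min": (3.0, 40.0),
        "blink_duration_ms": (80.0, 450.0),
        "pupil_mm": (2.0, 6.0),
        "pupil_noise_sd_mm": (0.02, 0.5),
        "think_time_ms": (800.0, 6000.0),
        "age": (21.0, 99.0),
    }


@dataclass(frozen=True)
class GroupEffects:
    """PMCI-vs-CN effect sizes applied to the CN population parameters.

    Defaults are generator design choices sized for stable pipeline recovery;
    they are configurable and make no empirical claim.
    """

    latency_shift_ms: float = 40.0
    fixation_time_mult: float = 1.3
    jitter_mult: float = 1.4
    blink_rate_shift_per_min: float = 4.0
    pupil_noise_mult: float = 1.5
    think_time_mult: float = 1.25

    @classmethod
    def null(cls) -> "GroupEffects":
        """Zero effect on every latent parameter (null configuration)."""
        return cls(0.0, 1.0, 1.0, 0.0, 1.0, 1.0)

    def apply(self, cn: GroupParams, age: tuple[float, float] = (67.9, 9.1)) -> GroupParams:
        def shift(p, d):
            return (p[0] + d, p[1])

        def scale(p, m):
            return (p[0] * m, p[1] * m)

        return replace(
            cn,
            latency_ms=shift(cn.latency_ms, self.latency_shift_ms),
            fixation_duration_ms=scale(cn.fixation_duration_ms, self.fixation_time_mult),
            jitter_px=scale(cn.jitter_px, self.jitter_mult),
            blink_rate_per_min=shift(cn.blink_rate_per_min, self.blink_rate_shift_per_min),
            pupil_noise_sd_mm=scale(cn.pupil_noise_sd_mm, self.pupil_noise_mult),
            think_time_ms=scale(cn.think_time_ms, self.think_time_mult),
            age=age,
        )


@dataclass(frozen=True)
class SimConfig:
    """Signal-level constants of the forward model (within-participant)."""

    sampling_rate_hz: float = 120.0
    settle_ms: float = 1000.0  # pre-task fixation at screen centre
    tail_ms: float = 500.0  # recording continues past the last click
    latency_event_sd_ms: float = 30.0  # trial-to-trial latency noise
    think_lognorm_sigma: float = 0.15  # trial-to-trial think-time noise
    saccade_dur_intercept_ms: float = 21.0  # main-sequence duration model
    saccade_dur_slope_ms_per_deg: float = 2.2
    refix_jump_px: tuple[float, float] = (85.0, 12.0)  # sub-fixation shift (mean, sd)
    refix_max_offset_px: float = 140.0  # max sub-fixation centre offset from target
    fixation_gamma_shape: float = 4.0
    blink_event_sd_ms: float = 20.0
    blink_bounds_ms: tuple[float, float] = (80.0, 450.0)
    pupil_dilation_per_level_mm: float = 0.06  # load-dependent dilation step
    isolated_invalid_rate: float = 0.01  # per-sample dropout probability


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and group-wise parameter distributions.

    Defaults reproduce the study conditions: 166 CN / 40 PMCI, with DRS drawn
    from group-wise truncated normals (CN N(142.1, 1.5) on [140, 144], PMCI
    N(135.9, 3.2) on [100, 139]) so that the DRS >= 140 label rule holds by
    construction.
    """

    n_cn: int = 166
    n_pmci: int = 40
    cn_params: GroupParams = field(default_factory=GroupParams)
    effects: GroupEffects = field(default_factory=GroupEffects)
    pmci_age: tuple[float, float] = (67.9, 9.1)
    drs_cn: tuple[float, float, float, float] = (142.1, 1.5, 140.0, 144.0)
    drs_pmci: tuple[float, float, float, float] = (135.9, 3.2, 100.0, 139.0)
    n_sequences: int = 3
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cn < 0 or self.n_pmci < 0:
            raise ValueError("group counts must be >= 0")
        if self.drs_cn[2] < 140:
            raise ConfigurationError("CN DRS truncation admits scores below the 140 cutoff")
        if self.drs_pmci[3] >= 139.5:
            raise ConfigurationError("PMCI DRS truncation admits scores at or above the 140 cutoff")

    @property
    def pmci_params(self) -> GroupParams:
        return self.effects.apply(self.cn_params, age=self.pmci_age)

    def params_for(self, group: str) -> GroupParams:
        return self.cn_params if group == "CN" else self.pmci_params


def null_cohort_spec(n_cn: int = 166, n_pmci: int = 40, seed: int = 0, **kwargs) -> CohortSpec:
    """Cohort with zero group effect: every group-conditional distribution
    except DRS (the label source) is identical between CN and PMCI."""
    cn = kwargs.pop("cn_params", GroupParams())
    return CohortSpec(
        n_cn=n_cn,
        n_pmci=n_pmci,
        cn_params=cn,
        effects=GroupEffects.null(),
        pmci_age=cn.age,
        seed=seed,
        **kwargs,
    )


def sample_participant(
    group: str,
    cohort_spec: CohortSpec,
    rng: np.random.Generator,
    seed: int | None = None,
) -> ParticipantProfile:
    """Draw one participant profile from the group's distributions."""
    if group not in ("CN", "PMCI"):
        raise ValueError("group must be 'CN' or 'PMCI'")
    params = cohort_spec.params_for(group)
    drs_mean, drs_sd, drs_lo, drs_hi = cohort_spec.drs_cn if group == "CN" else cohort_spec.drs_pmci
    drs = int(round(_draw_trunc(rng, drs_mean, drs_sd, drs_lo, drs_hi)))

    def draw(name: str) -> float:
        mean, sd = getattr(params, name)
        lo, hi = GroupParams.BOUNDS[name]
        return float(_draw_trunc(rng, mean, sd, lo, hi))

    if seed is None:
        seed = int(rng.integers(0, 2**31 - 1))
    return ParticipantProfile(
        group=group,
        age=draw("age"),
        drs=drs,
        latency_ms=draw("latency_ms"),
        fixation_duration_ms=draw("fixation_duration_ms"),
        jitter_px=draw("jitter_px"),
        blink_rate_per_min=draw("blink_rate_per_min"),
        blink_duration_ms=draw("blink_duration_ms"),
        pupil_mm=draw("pupil_mm"),
        pupil_noise_sd_mm=draw("pupil_noise_sd_mm"),
        workload_multipliers=params.workload_multipliers,
        think_time_ms=draw("think_time_ms"),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Gaze signal synthesis
# ---------------------------------------------------------------------------


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 position profile (velocity peaks mid-saccade)."""
    return 0.5 - 0.5 * np.cos(np.pi * u)


def simulate_gaze(
    profile: ParticipantProfile,
    script: TaskScript,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    config: SimConfig = SimConfig(),
    participant_id: str = "P000",
) -> GazeRecording:
    """Render a raw 120 Hz gaze recording of one OCAT session.

    The eye fixates the screen centre, then for each stimulus: waits the
    participant's saccadic latency (plus trial noise), performs a
    main-sequence saccade to the target, and dwells there -- broken into
    sub-fixations of gamma-distributed duration whose centres shift by
    ~1.3 degrees between samples -- until the click.  The next stimulus
    onset coincides with the click, so per-position response times add up
    exactly to the total test time.  Blinks arrive as a Poisson process and
    appear as validity gaps; pupil size is baseline plus a workload-dependent
    increment plus Gaussian noise.
    """
    rng = np.random.default_rng(profile.seed)
    dt = 1000.0 / config.sampling_rate_hz
    stimuli = script.stimuli
    cx, cy = geometry.width_px / 2.0, geometry.height_px / 2.0

    # --- event timeline ---------------------------------------------------
    onsets, clicks, saccades = [], [], []  # saccades: (t0, t1, from_xy, to_xy)
    t = config.settle_ms
    pos = np.array([cx, cy])
    for s in stimuli:
        onset = t
        latency = max(80.0, rng.normal(profile.latency_ms, config.latency_event_sd_ms))
        target = np.array([s.target_x_px, s.target_y_px])
        amp_deg = float(px_to_deg(np.linalg.norm(target - pos), geometry))
        sacc_dur = config.saccade_dur_intercept_ms + config.saccade_dur_slope_ms_per_deg * amp_deg
        think = profile.think_times_ms[s.pos_idx - 1] * rng.lognormal(0.0, config.think_lognorm_sigma)
        click = onset + max(think, latency + sacc_dur + 400.0)
        onsets.append((onset, s))
        clicks.append((click, s))
        saccades.append((onset + latency, onset + latency + sacc_dur, pos.copy(), target.copy()))
        pos = target
        t = click  # next onset coincides with this click

    total_ms = t + config.tail_ms
    n = int(math.floor(total_ms / dt)) + 1
    ts = np.arange(n) * dt

    # --- gaze path: saccade segments + sub-fixation centres ---------------
    # Dwell intervals are the gaps between consecutive saccades (plus the
    # initial settle and the final tail); each dwell is split into
    # sub-fixations with instantaneous centre shifts between samples.
    seg_t0, seg_t1, seg_from, seg_to = [], [], [], []  # saccade segments
    fix_t0, fix_cx, fix_cy = [], [], []  # sub-fixation start times and centres

    def add_dwell(t0: float, t1: float, anchor: np.ndarray) -> None:
        tcur = t0
        centre = anchor.copy()
        while tcur < t1:
            fix_t0.append(tcur)
            fix_cx.append(centre[0])
            fix_cy.append(centre[1])
            dur = rng.gamma(config.fixation_gamma_shape,
                            profile.fixation_duration_ms / config.fixation_gamma_shape)
            tcur += max(dur, 2 * dt)
            # next sub-fixation centre: jump ~N(mean, sd) px, stay near anchor
            for _ in range(20):
                ang = rng.uniform(0, 2 * np.pi)
                d = rng.normal(*config.refix_jump_px)
                cand = centre + d * np.array([np.cos(ang), np.sin(ang)])
                if np.linalg.norm(cand - anchor) <= config.refix_max_offset_px:
                    break
            else:
                cand = anchor.copy()
            centre = cand

    prev_end = 0.0
    prev_anchor = np.array([cx, cy])
    for (t0, t1, p_from, p_to) in saccades:
        add_dwell(prev_end, t0, prev_anchor)
        seg_t0.append(t0)
        seg_t1.append(t1)
        seg_from.append(p_from)
        seg_to.append(p_to)
        prev_end = t1
        prev_anchor = p_to
    add_dwell(prev_end, total_ms + dt, prev_anchor)

    seg_t0 = np.array(seg_t0)
    seg_t1 = np.array(seg_t1)
    seg_from = np.array(seg_from)
    seg_to = np.array(seg_to)
    fix_t0 = np.array(fix_t0)
    fix_c = np.column_stack([fix_cx, fix_cy])

    # vectorised sample positions
    x = np.empty(n)
    y = np.empty(n)
    # which saccade window (if any) each sample falls into
    idx = np.searchsorted(seg_t0, ts, side="right") - 1
    in_sacc = (idx >= 0) & (ts < seg_t1[np.clip(idx, 0, None)])
    si = idx[in_sacc]
    u = (ts[in_sacc] - seg_t0[si]) / (seg_t1[si] - seg_t0[si])
    w = _raised_cosine(u)
    x[in_sacc] = seg_from[si, 0] + w * (seg_to[si, 0] - seg_from[si, 0])
    y[in_sacc] = seg_from[si, 1] + w * (seg_to[si, 1] - seg_from[si, 1])
    # dwell samples take the active sub-fixation centre plus jitter
    dwell = ~in_sacc
    fi = np.clip(np.searchsorted(fix_t0, ts[dwell], side="right") - 1, 0, len(fix_t0) - 1)
    x[dwell] = fix_c[fi, 0] + rng.normal(0.0, profile.jitter_px, dwell.sum())
    y[dwell] = fix_c[fi, 1] + rng.normal(0.0, profile.jitter_px, dwell.sum())
    np.clip(x, 0, geometry.width_px - 1, out=x)
    np.clip(y, 0, geometry.height_px - 1, out=y)

    # --- pupil -------------------------------------------------------------
    onset_times = np.array([o[0] for o in onsets])
    click_times = np.array([c[0] for c in clicks])
    levels = np.array([o[1].pos_idx - 1 for o in onsets])
    stim_i = np.searchsorted(onset_times, ts, side="right") - 1
    active = (stim_i >= 0) & (ts < click_times[np.clip(stim_i, 0, None)])
    level = np.zeros(n)
    level[active] = levels[stim_i[active]]
    pupil = profile.pupil_mm + config.pupil_dilation_per_level_mm * level
    pupil = pupil + rng.normal(0.0, profile.pupil_noise_sd_mm, n)

    # --- validity: blinks + isolated dropouts ------------------------------
    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(profile.blink_rate_per_min * total_ms / 60000.0)
    starts = np.sort(rng.uniform(0.0, total_ms, n_blinks))
    lo_b, hi_b = config.blink_bounds_ms
    prev_close = -np.inf
    for b0 in starts:
        dur = float(np.clip(rng.normal(profile.blink_duration_ms, config.blink_event_sd_ms), lo_b, hi_b))
        if b0 < prev_close + 50.0:  # drop overlapping draws
            continue
        valid[(ts >= b0) & (ts < b0 + dur)] = False
        prev_close = b0 + dur
    if config.isolated_invalid_rate > 0:
        valid &= rng.random(n) >= config.isolated_invalid_rate

    x[~valid] = np.nan
    y[~valid] = np.nan
    pupil[~valid] = np.nan

    samples = pd.DataFrame({"t_ms": ts, "x_px": x, "y_px": y, "pupil_mm": pupil, "valid": valid})
    rows = []
    for (onset, s) in onsets:
        rows.append(("onset", onset, s.seq_idx, s.pos_idx, s.target_x_px, s.target_y_px))
    for (click, s) in clicks:
        rows.append(("click", click, s.seq_idx, s.pos_idx, np.nan, np.nan))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values(
        ["t_ms", "kind"], kind="stable").reset_index(drop=True)

    return GazeRecording(
        participant_id=participant_id,
        samples=samples,
        events=events,
        sampling_rate_hz=config.sampling_rate_hz,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def sample_cohort_profiles(spec: CohortSpec) -> tuple[list[ParticipantProfile], pd.DataFrame]:
    """Draw all participant profiles (no gaze synthesis) and the metadata
    table (id, age, group, drs).  Fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    profiles: list[ParticipantProfile] = []
    records = []
    groups = ["CN"] * spec.n_cn + ["PMCI"] * spec.n_pmci
    for i, group in enumerate(groups):
        pid = f"P{i:03d}"
        profile = sample_participant(group, spec, rng)
        profiles.append(profile)
        records.append({"id": pid, "age": round(profile.age, 1), "group": group, "drs": profile.drs})
    metadata = pd.DataFrame(records, columns=["id", "age", "group", "drs"])
    return profiles, metadata


def generate_cohort(spec: CohortSpec) -> tuple[list[GazeRecording], pd.DataFrame]:
    """Generate a full cohort of gaze recordings plus the metadata table."""
    profiles, metadata = sample_cohort_profiles(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    recordings = []
    for pid, profile in zip(metadata["id"], profiles):
        script = generate_task_script(spec.n_sequences, rng=rng)
        recordings.append(simulate_gaze(profile, script, config=spec.sim, participant_id=pid))
    return recordings, metadata
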