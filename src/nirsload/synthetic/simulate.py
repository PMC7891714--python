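"""Synthetic multi-distance fNIRS cohort generator.

Per channel the oxyhemoglobin trace follows the mixing model

    dHbO(t) = w_c(sep) * A(region, hemi) * g_cer * x(t)
            + w_s(sep) * g_sup * s_sup(t)
            + drift(t) + noise(t)

where ``x`` is a task regressor (episode boxcar plus a within-task event
train, convolved with a canonical HRF), ``s_sup`` is a subject-level sum of
systemic oscillations (Mayer ~0.1 Hz, respiration ~0.3 Hz, cardiac ~1 Hz),
and the cerebral mixing weight ``w_c`` grows with source-detector separation
while the superficial weight ``w_s`` shrinks.  dHbR is an anticorrelated
scaled copy of the cerebral part plus its own noise.  Optical densities are
produced by the forward Beer-Lambert relation; motion events add decaying
spikes and baseline steps directly to the optical densities and simultaneous
bumps to the accelerometer/gyroscope traces.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..constants import (
    DPF_DEFAULT,
    EXTINCTION_DEFAULT,
    FS_DEFAULT,
    REGIONS,
    WAVELENGTHS,
)
from .hrf import double_gamma_hrf
from .layout import ChannelLayout, LayoutConfig, build_layout


class SimulationError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# protocol schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Episode:
    name: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered rest/task episodes plus the sampling rate."""

    episodes: tuple[Episode, ...]
    fs: float = FS_DEFAULT

    def validate(self) -> None:
        if self.fs <= 0:
            raise SimulationError("sampling rate must be positive")
        prev_end = 0.0
        for ep in self.episodes:
            if ep.start_s < prev_end or ep.end_s <= ep.start_s:
                raise SimulationError(f"episode {ep.name} overlaps or is empty")
            if ep.name.startswith("task") and ep.duration_s > 360.0 + 1e-9:
                raise SimulationError(f"task episode {ep.name} exceeds 6 minutes")
            prev_end = ep.end_s

    @property
    def total_s(self) -> float:
        return self.episodes[-1].end_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.fs))

    def episode(self, name: str) -> Episode:
        for ep in self.episodes:
            if ep.name == name:
                return ep
        raise KeyError(f"episode {name!r} not in schedule")

    def task_names(self) -> list[str]:
        return [ep.name for ep in self.episodes if ep.name.startswith("task")]

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def make_schedule(task_s: float = 240.0, rest_s: float = 60.0,
                  fs: float = FS_DEFAULT) -> ProtocolSchedule:
    """rest1 / task1 / rest2 / task2 schedule (rests 60 s, tasks <= 6 min)."""
    t = 0.0
    eps = []
    for name, dur in (("rest1", rest_s), ("task1", task_s),
                      ("rest2", rest_s), ("task2", task_s)):
        eps.append(Episode(name, t, t + dur))
        t += dur
    sched = ProtocolSchedule(tuple(eps), fs=fs)
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysioConfig:
    """Mixing weights, systemic oscillations, drift, noise and motion shapes."""

    mixing_cerebral: dict[float, float] = field(
        default_factory=lambda: {1.5: 0.05, 2.12: 0.15, 3.0: 0.50, 3.35: 0.65}
    )
    mixing_superficial: dict[float, float] = field(
        default_factory=lambda: {1.5: 1.0, 2.12: 0.9, 3.0: 0.7, 3.35: 0.6}
    )
    osc_freqs_hz: tuple[float, ...] = (0.1, 0.3, 1.0)
    osc_rel_amps: tuple[float, ...] = (1.0, 0.6, 0.8)
    osc_freq_jitter: float = 0.08  # relative per-subject jitter
    channel_gain_jitter: float = 0.3  # per-channel multiplicative spread
    drift_amp_um: float = 0.3
    drift_freq_hz: float = 0.002
    noise_sd_um: float = 0.15
    hbr_noise_sd_um: float = 0.05
    hbr_ratio: float = 1.0 / 3.0
    # task event train: regular cadence of sub-task events inside task episodes
    event_interval_s: float = 15.0
    event_rel_amp: float = 1.0
    hrf_duration_s: float = 30.0
    # motion artifacts
    motion_spike_tau_s: float = 0.5
    motion_amp_od_logmu: float = -3.912  # ln of ~0.02 OD
    motion_amp_od_logsd: float = 0.6
    motion_shift_prob: float = 0.3
    motion_shift_frac: float = 0.3
    accel_noise_sd: float = 0.02

    def validate(self, fs: float) -> None:
        vals = (
            list(self.mixing_cerebral.values())
            + list(self.mixing_superficial.values())
            + list(self.osc_freqs_hz)
            + list(self.osc_rel_amps)
            + [self.drift_amp_um, self.noise_sd_um, self.hbr_noise_sd_um]
        )
        if not np.all(np.isfinite(vals)):
            raise SimulationError("non-finite physiological configuration value")
        nyq = fs / 2.0
        for f in (*self.osc_freqs_hz, self.drift_freq_hz):
            if f >= nyq:
                raise SimulationError(
                    f"component frequency {f} Hz is not below Nyquist ({nyq} Hz)"
                )

    def w_c(self, sep: float) -> float:
        return self._lookup(self.mixing_cerebral, sep)

    def w_s(self, sep: float) -> float:
        return self._lookup(self.mixing_superficial, sep)

    @staticmethod
    def _lookup(table: dict[float, float], sep: float) -> float:
        for k, v in table.items():
            if np.isclose(k, sep):
                return v
        raise SimulationError(f"no mixing weight configured for separation {sep} cm")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject latent parameters (the generator's ground truth)."""

    subject_id: str
    group: str  # "student" | "attending"
    latent_load: float
    cerebral_amplitude: dict[tuple[str, str], float]  # (region, hemisphere) -> uM
    superficial_amplitude: float  # uM
    motion_rate_per_min: float

    @property
    def tlx_link_sign(self) -> int:
        return 1 if self.group == "student" else -1

    def validate(self) -> None:
        if any(a < 0 for a in self.cerebral_amplitude.values()):
            raise SimulationError("cerebral amplitudes must be non-negative")

    @property
    def mean_cerebral_amplitude(self) -> float:
        return float(np.mean(list(self.cerebral_amplitude.values())))


@dataclass(frozen=True)
class TLXLink:
    """Affine latent-load -> subscale link used by the TLX generator."""

    base: float = 10.5
    slope: float = 3.5
    noise_sd: float = 1.0


@dataclass(frozen=True)
class StudyConfig:
    """Cohort-level composition and planted effect sizes."""

    n_students: int = 17
    n_attendings: int = 11
    student_amp_um: float = 1.0
    attending_amp_um: float = 0.4
    amp_subject_sd_um: float = 0.05
    load_gain_um: float = 0.25
    student_left_mult: float = 1.3
    region_mults: dict[str, float] = field(
        default_factory=lambda: {
            "dorsolateral": 1.2,
            "ventrolateral": 1.1,
            "medial": 1.0,
            "orbitofrontal": 0.9,
        }
    )
    superficial_amp_um: float = 0.5
    superficial_student_ratio: float = 1.0
    superficial_subject_sd: float = 0.0
    motion_rate_per_min: float = 0.5
    motion_rate_student_ratio: float = 1.0
    task_s: float = 240.0
    rest_s: float = 60.0
    fs: float = FS_DEFAULT
    physio: PhysioConfig = field(default_factory=PhysioConfig)
    tlx: TLXLink = field(default_factory=TLXLink)
    layout: LayoutConfig = field(default_factory=LayoutConfig)

    def schedule(self) -> ProtocolSchedule:
        return make_schedule(self.task_s, self.rest_s, self.fs)

    def zero_effect(self) -> "StudyConfig":
        """Null configuration: no group, load, or subject-level amplitude effects.

        Channel-paired tests are anti-conservative under any subject-level
        variance that is shared across channels, so the null configuration
        removes subject amplitude heterogeneity along with the group effects.
        """
        return replace(
            self,
            student_amp_um=self.attending_amp_um,
            amp_subject_sd_um=0.0,
            load_gain_um=0.0,
            student_left_mult=1.0,
            superficial_student_ratio=1.0,
            superficial_subject_sd=0.0,
            motion_rate_student_ratio=1.0,
        )


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Additive components of a simulated recording (uM except motion_od)."""

    cerebral_hbo: np.ndarray  # (T, C)
    superficial_hbo: np.ndarray  # (T, C)
    drift_hbo: np.ndarray  # (T, C)
    noise_hbo: np.ndarray  # (T, C)
    noise_hbr: np.ndarray  # (T, C)
    motion_od: np.ndarray  # (T, C, 2)
    hbr_ratio: float
    profile: SubjectProfile


@dataclass
class RawRecording:
    subject_id: str
    layout: ChannelLayout
    od: np.ndarray  # (T, C, 2), wavelengths 780/850 nm
    motion: np.ndarray  # (T, 6): 3 accelerometer + 3 gyroscope
    schedule: ProtocolSchedule
    ground_truth: GroundTruth | None = None

    def validate(self) -> None:
        if not np.all(np.isfinite(self.od)):
            raise SimulationError("optical densities contain non-finite values")
        if self.motion.shape[0] != self.od.shape[0]:
            raise SimulationError("motion traces must match od length")


@dataclass(frozen=True)
class TLXRecord:
    subject_id: str
    episode: str
    subscales: tuple[float, ...]  # six scores, each on 1..20
    group: str = ""

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.subscales))


# ---------------------------------------------------------------------------
# forward optics
# ---------------------------------------------------------------------------

def forward_mbll(
    hbo: np.ndarray,
    hbr: np.ndarray,
    separation_cm: float | np.ndarray,
    dpf: dict[float, float] | None = None,
    extinction: np.ndarray | None = None,
) -> np.ndarray:
    """Forward Beer-Lambert relation: concentration changes -> dOD per wavelength.

    ``hbo``/``hbr`` are (T,) or (T, C) in uM; ``separation_cm`` is scalar or
    per-channel.  Returns dOD stacked on a trailing wavelength axis.
    """
    dpf = DPF_DEFAULT if dpf is None else dpf
    extinction = EXTINCTION_DEFAULT if extinction is None else np.asarray(extinction)
    if np.linalg.matrix_rank(extinction) < 2:
        raise SimulationError("extinction matrix is singular")
    sep = np.asarray(separation_cm, dtype=float)
    if np.any(sep <= 0):
        raise SimulationError("source-detector separation must be positive")
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    out = np.empty(hbo.shape + (len(WAVELENGTHS),))
    for j, lam in enumerate(WAVELENGTHS):
        out[..., j] = (extinction[j, 0] * hbo + extinction[j, 1] * hbr) * sep * dpf[lam]
    return out


# ---------------------------------------------------------------------------
# per-subject simulation
# ---------------------------------------------------------------------------

def subject_seed_sequence(root_seed: int, subject_id: str) -> np.random.SeedSequence:
    """Stable per-subject stream: hash of (root seed, subject id)."""
    return np.random.SeedSequence([int(root_seed), zlib.crc32(subject_id.encode())])


def task_regressor(schedule: ProtocolSchedule, physio: PhysioConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Boxcar plus within-task event train, convolved with the canonical HRF.

    A pure boxcar convolved with the HRF is nearly flat during a sustained
    task, which a windowed-SD feature cannot see; the regular sub-task event
    cadence (phase-jittered per subject) supplies amplitude-proportional
    in-band variability.
    """
    fs = schedule.fs
    n = schedule.n_samples
    stick = np.zeros(n)
    for name in schedule.task_names():
        ep = schedule.episode(name)
        i0, i1 = int(round(ep.start_s * fs)), int(round(ep.end_s * fs))
        stick[i0:i1] += 1.0  # boxcar
        phase = rng.uniform(0.0, physio.event_interval_s)
        t_ev = np.arange(ep.start_s + phase, ep.end_s, physio.event_interval_s)
        idx = np.round(t_ev * fs).astype(int)
        idx = idx[idx < n]
        stick[idx] += physio.event_rel_amp * fs * 2.0  # impulse area ~2 s boxcar
    h = double_gamma_hrf(fs, physio.hrf_duration_s)
    x = np.convolve(stick, h)[:n] / fs
    return x


def simulate_subject(
    profile: SubjectProfile,
    layout: ChannelLayout,
    schedule: ProtocolSchedule,
    physio: PhysioConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> RawRecording:
    """Simulate one subject's two-wavelength recording with stored ground truth."""
    physio = physio or PhysioConfig()
    schedule.validate()
    physio.validate(schedule.fs)
    profile.validate()

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    (ss_task, ss_osc, ss_gain, ss_drift, ss_noise, ss_motion) = ss.spawn(6)

    fs = schedule.fs
    t = schedule.time()
    n = t.size
    C = layout.n_channels
    sep = layout.separations

    # cerebral component: shared regressor, channel-specific amplitude
    x = task_regressor(schedule, physio, np.random.default_rng(ss_task))
    wc = np.array([physio.w_c(s) for s in sep])
    amp = np.array(
        [profile.cerebral_amplitude[(c.region, c.hemisphere)] for c in layout.channels]
    )
    rng_gain = np.random.default_rng(ss_gain)
    g_cer = 1.0 + physio.channel_gain_jitter * rng_gain.standard_normal(C)
    g_sup = 1.0 + physio.channel_gain_jitter * rng_gain.standard_normal(C)
    cerebral = x[:, None] * (wc * amp * np.abs(g_cer))[None, :]

    # superficial systemic component: subject-level oscillation mix
    rng_osc = np.random.default_rng(ss_osc)
    freqs = np.asarray(physio.osc_freqs_hz) * (
        1.0 + physio.osc_freq_jitter * rng_osc.uniform(-1, 1, len(physio.osc_freqs_hz))
    )
    phases = rng_osc.uniform(0, 2 * np.pi, len(freqs))
    s_sup = np.zeros(n)
    for f, ph, a in zip(freqs, phases, physio.osc_rel_amps):
        s_sup += a * np.sin(2 * np.pi * f * t + ph)
    s_sup *= profile.superficial_amplitude
    ws = np.array([physio.w_s(s) for s in sep])
    superficial = s_sup[:, None] * (ws * np.abs(g_sup))[None, :]

    # slow drift, channel specific
    rng_drift = np.random.default_rng(ss_drift)
    lin = rng_drift.standard_normal(C)
    ph_d = rng_drift.uniform(0, 2 * np.pi, C)
    tnorm = (2.0 * t / t[-1] - 1.0) if n > 1 else t
    drift = physio.drift_amp_um * (
        tnorm[:, None] * lin[None, :]
        + np.sin(2 * np.pi * physio.drift_freq_hz * t[:, None] + ph_d[None, :])
    )
    if physio.drift_amp_um == 0:
        drift = np.zeros((n, C))

    rng_noise = np.random.default_rng(ss_noise)
    noise_hbo = physio.noise_sd_um * rng_noise.standard_normal((n, C))
    noise_hbr = physio.hbr_noise_sd_um * rng_noise.standard_normal((n, C))

    hbo = cerebral + superficial + drift + noise_hbo
    hbr = -physio.hbr_ratio * cerebral + noise_hbr
    od = forward_mbll(hbo, hbr, sep)

    motion_od, motion = _simulate_motion(profile, physio, schedule, C,
                                         np.random.default_rng(ss_motion))
    od = od + motion_od

    gt = GroundTruth(
        cerebral_hbo=cerebral,
        superficial_hbo=superficial,
        drift_hbo=drift,
        noise_hbo=noise_hbo,
        noise_hbr=noise_hbr,
        motion_od=motion_od,
        hbr_ratio=physio.hbr_ratio,
        profile=profile,
    )
    rec = RawRecording(profile.subject_id, layout, od, motion, schedule, gt)
    rec.validate()
    return rec


def _simulate_motion(
    profile: SubjectProfile,
    physio: PhysioConfig,
    schedule: ProtocolSchedule,
    n_channels: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson motion events: OD spikes/steps plus concurrent sensor bumps."""
    fs = schedule.fs
    n = schedule.n_samples
    t = schedule.time()
    motion_od = np.zeros((n, n_channels, len(WAVELENGTHS)))
    traces = physio.accel_noise_sd * rng.standard_normal((n, 6))
    if physio.accel_noise_sd == 0:
        traces = np.zeros((n, 6))

    duration_min = schedule.total_s / 60.0
    n_events = rng.poisson(profile.motion_rate_per_min * duration_min)
    for _ in range(n_events):
        t0 = rng.uniform(0.0, schedule.total_s)
        i0 = int(t0 * fs)
        amp = rng.lognormal(physio.motion_amp_od_logmu, physio.motion_amp_od_logsd)
        coupling = rng.uniform(0.5, 1.5, n_channels)
        i1 = min(n, i0 + int(10 * fs))
        spike = amp * np.exp(-(t[i0:i1] - t[i0]) / physio.motion_spike_tau_s)
        motion_od[i0:i1] += spike[:, None, None] * coupling[None, :, None]
        if rng.uniform() < physio.motion_shift_prob:
            shift = physio.motion_shift_frac * amp * rng.choice((-1.0, 1.0))
            motion_od[i0:] += shift * coupling[None, :, None]
        # concurrent accelerometer / gyroscope bumps
        axes = 1.0 + 0.5 * rng.standard_normal(6)
        bump = amp * 20.0 * np.exp(-(t[i0:i1] - t[i0]) / (physio.motion_spike_tau_s / 2))
        traces[i0:i1] += bump[:, None] * axes[None, :]
    return motion_od, traces


# ---------------------------------------------------------------------------
# TLX generation
# ---------------------------------------------------------------------------

def generate_tlx(
    profile: SubjectProfile,
    episode: str,
    seed: int | np.random.SeedSequence = 0,
    link: TLXLink | None = None,
) -> TLXRecord:
    """Six clipped affine-plus-noise subscales on the 1..20 scale."""
    link = link or TLXLink()
    if not np.all(np.isfinite([link.base, link.slope, link.noise_sd])):
        raise SimulationError("non-finite TLX link configuration")
    rng = np.random.default_rng(seed)
    raw = link.base + link.slope * profile.latent_load + link.noise_sd * rng.standard_normal(6)
    subs = tuple(float(v) for v in np.clip(raw, 1.0, 20.0))
    return TLXRecord(profile.subject_id, episode, subs, group=profile.group)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    layout: ChannelLayout
    schedule: ProtocolSchedule
    recordings: list[RawRecording]
    tlx: list[TLXRecord]
    truth: pd.DataFrame  # per-subject scalar ground truth

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.truth["subject_id"], self.truth["group"]))


def draw_profile(group: str, subject_id: str, config: StudyConfig,
                 rng: np.random.Generator) -> SubjectProfile:
    latent = rng.standard_normal()
    sign = 1.0 if group == "student" else -1.0
    base = config.student_amp_um if group == "student" else config.attending_amp_um
    amp0 = base + sign * config.load_gain_um * latent
    amp0 += config.amp_subject_sd_um * rng.standard_normal()
    amp0 = max(amp0, 0.0)
    left_mult = config.student_left_mult if group == "student" else 1.0
    amps = {}
    for region in REGIONS:
        for hemi in ("L", "R"):
            m = config.region_mults.get(region, 1.0)
            amps[(region, hemi)] = amp0 * m * (left_mult if hemi == "L" else 1.0)
    sup = config.superficial_amp_um
    if group == "student":
        sup *= config.superficial_student_ratio
    sup *= max(0.0, 1.0 + config.superficial_subject_sd * rng.standard_normal())
    motion_rate = config.motion_rate_per_min
    if group == "student":
        motion_rate *= config.motion_rate_student_ratio
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        latent_load=latent,
        cerebral_amplitude=amps,
        superficial_amplitude=sup,
        motion_rate_per_min=motion_rate,
    )


def simulate_cohort(config: StudyConfig | None = None, seed: int = 0) -> Cohort:
    """Simulate a full cohort: recordings, TLX records, and a truth table."""
    import warnings

    config = config or StudyConfig()
    if min(config.n_students, config.n_attendings) < 2:
        warnings.warn("group size < 2: downstream statistics are degenerate",
                      stacklevel=2)
    layout = build_layout(config.layout)
    schedule = config.schedule()
    subjects = [("student", f"S{i + 1:02d}") for i in range(config.n_students)]
    subjects += [("attending", f"A{i + 1:02d}") for i in range(config.n_attendings)]

    recordings, tlx_records, rows = [], [], []
    for group, sid in subjects:
        ss = subject_seed_sequence(seed, sid)
        ss_profile, ss_rec, ss_tlx = ss.spawn(3)
        profile = draw_profile(group, sid, config, np.random.default_rng(ss_profile))
        recordings.append(simulate_subject(profile, layout, schedule,
                                           config.physio, ss_rec))
        for k, task in enumerate(schedule.task_names()):
            tlx_records.append(
                generate_tlx(profile, task, ss_tlx.spawn(1)[0], config.tlx)
            )
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "latent_load": profile.latent_load,
                "mean_cerebral_amplitude_um": profile.mean_cerebral_amplitude,
                "superficial_amplitude_um": profile.superficial_amplitude,
                "motion_rate_per_min": profile.motion_rate_per_min,
            }
        )
    return Cohort(layout, schedule, recordings, tlx_records, pd.DataFrame(rows))
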