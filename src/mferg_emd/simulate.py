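"""Seeded synthetic mfERG cohort generator.

Each sector trace is a tri-phasic N1/P1/N2 waveform — a sum of three
unit-peak Gaussians (negative N1 trough, positive P1 peak, negative N2
trough) — scaled by an eccentricity-dependent ring gain, with

* subject-level multiplicative amplitude variability (log-normal, given
  coefficient of variation) and mild per-subject waveform-timing
  variability,
* additive white Gaussian noise, split into a common-mode component
  shared by all 61 sectors (the sector responses all derive from one
  electrode's continuous recording) and an independent per-sector
  component, and
* for the patient group, a configurable perturbation: a deterministic
  latency shift, correlated latency jitter of the N1/P1/N2 components,
  an amplitude scale factor and extra per-sector noise.

The generator emulates the statistical structure the analysis pipeline
assumes (a stereotyped per-sector waveform plus noise and group effects);
it does not model m-sequence stimulation, kernel cross-contamination,
blink or fixation artifacts, or the recording chain's analog bandwidth.
All draws flow from a single integer seed, so a cohort is a pure function
of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .recordings import (
    Cohort,
    MfERGRecording,
    N_SECTORS,
    DEFAULT_N_SAMPLES,
    DEFAULT_SAMPLING_RATE_HZ,
)
from .clusters import ClusterLayout, RING_NAMES, default_layout

# ring gains follow the eccentricity gradient of control N1 amplitudes
# (central sector largest, outer rings near unity)
DEFAULT_RING_GAIN = {"R1": 1.92, "R2": 1.30, "R3": 1.12, "R4": 1.00, "R5": 0.98}


@dataclass
class WaveformParams:
    """Tri-Gaussian N1/P1/N2 morphology parameters (latencies ms, amplitudes nV)."""

    n1_latency_ms: float = 15.0
    p1_latency_ms: float = 30.0
    n2_latency_ms: float = 45.0
    n1_amp_nV: float = 160.0
    p1_amp_nV: float = 240.0
    n2_amp_nV: float = 60.0
    n1_width_ms: float = 3.5
    p1_width_ms: float = 2.5
    n2_width_ms: float = 6.0
    ring_gain: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RING_GAIN)
    )

    def validate(self) -> None:
        if not (self.n1_latency_ms < self.p1_latency_ms < self.n2_latency_ms):
            raise ValueError("latencies must be ordered N1 < P1 < N2")
        for name in ("n1_amp_nV", "p1_amp_nV", "n2_amp_nV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(g <= 0 for g in self.ring_gain.values()):
            raise ValueError("ring gains must be positive")


@dataclass
class PatientEffect:
    """Perturbation applied to patient-group waveforms.

    ``latency_shift_ms`` shifts the whole waveform deterministically.
    ``latency_jitter_sd_ms`` is the total SD of random offsets applied
    independently to the N1, P1 and N2 latencies; each offset is the sum
    of a per-subject component and a per-sector component of equal
    variance (intra-subject correlation 0.5), so pathology both varies
    between patients and broadens a patient's cluster-averaged waveform.
    Defaults are calibrated synthetic effect sizes, not physiologic
    measurements: 3 ms latency jitter, a 1.2x amplitude scale, and extra
    additive noise at twice the control noise level.
    """

    latency_shift_ms: float = 0.0
    latency_jitter_sd_ms: float = 3.0
    amp_scale: float = 1.2
    extra_noise_sd_nV: float = 90.0

    @classmethod
    def none(cls) -> "PatientEffect":
        """The null perturbation (patients generated like controls)."""
        return cls(0.0, 0.0, 1.0, 0.0)


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort; a pure function of ``seed``."""

    n_controls: int = 6
    n_patients: int = 15
    seed: int = 0
    noise_sd_nV: float = 45.0
    # common-mode noise shared by all 61 sectors of a recording: the sector
    # responses are all derived from one electrode's continuous signal, so
    # a large part of the contamination (EEG, ECG, eye movements) is common
    # to every sector and does not average out across a cluster
    common_noise_sd_nV: float = 34.0
    inter_subject_cv: float = 0.20
    # healthy inter-subject waveform-timing variability: SD of per-subject,
    # per-component latency offsets applied to every subject (both groups)
    subject_latency_sd_ms: float = 0.25
    patient_effect: PatientEffect = field(default_factory=PatientEffect)
    waveform: WaveformParams = field(default_factory=WaveformParams)
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    n_samples: int = DEFAULT_N_SAMPLES

    def validate(self) -> None:
        if self.n_controls < 1 or self.n_patients < 0:
            raise ValueError("group sizes must be >= 1 control, >= 0 patients")
        if min(
            self.noise_sd_nV,
            self.common_noise_sd_nV,
            self.inter_subject_cv,
            self.subject_latency_sd_ms,
        ) < 0:
            raise ValueError("dispersions must be >= 0")
        self.waveform.validate()

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "patient_effect" in raw:
            raw["patient_effect"] = PatientEffect(**raw["patient_effect"])
        if "waveform" in raw:
            raw["waveform"] = WaveformParams(**raw["waveform"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _ring_of_sector(layout: ClusterLayout) -> dict[int, str]:
    return {s: r for r in RING_NAMES for s in layout[r]}


def make_waveform(
    params: WaveformParams,
    ring: str,
    *,
    n_samples: int = DEFAULT_N_SAMPLES,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    latency_offset_ms: float = 0.0,
    amp_scale: float = 1.0,
) -> np.ndarray:
    """Noiseless tri-phasic sector waveform for a given eccentricity ring.

    ``trace(t) = gain * scale * [-A_N1 g(t; mu_N1) + A_P1 g(t; mu_P1)
    - A_N2 g(t; mu_N2)]`` with g a unit-peak Gaussian.
    ``latency_offset_ms`` may be a scalar (shifting all three component
    latencies together) or a triple of per-component (N1, P1, N2) offsets.
    """
    params.validate()
    gain = params.ring_gain[ring] * amp_scale
    t_ms = 1000.0 * np.arange(n_samples) / sampling_rate_hz
    offsets = np.broadcast_to(np.asarray(latency_offset_ms, dtype=float), (3,))

    def g(mu: float, sigma: float, off: float) -> np.ndarray:
        return np.exp(-0.5 * ((t_ms - mu - off) / sigma) ** 2)

    return gain * (
        -params.n1_amp_nV * g(params.n1_latency_ms, params.n1_width_ms, offsets[0])
        + params.p1_amp_nV * g(params.p1_latency_ms, params.p1_width_ms, offsets[1])
        - params.n2_amp_nV * g(params.n2_latency_ms, params.n2_width_ms, offsets[2])
    )


def make_subject(
    subject_id: str,
    group: str,
    layout: ClusterLayout,
    config: CohortConfig,
    rng: np.random.Generator,
) -> MfERGRecording:
    """One synthetic recording: 61 sector waveforms + variability + noise.

    Subject-level amplitude variability is a single log-normal factor with
    the configured coefficient of variation, applied to all sectors.
    Noise has a common-mode component shared by all sectors and an
    independent per-sector component.  The patient perturbation adds a
    deterministic latency shift, correlated per-subject/per-sector latency
    jitter, an amplitude scale, and extra per-sector white noise.
    """
    config.validate()
    ring_of = _ring_of_sector(layout)
    is_patient = group == "patient"
    effect = config.patient_effect if is_patient else PatientEffect.none()

    cv = config.inter_subject_cv
    if cv > 0:
        sigma_log = float(np.sqrt(np.log1p(cv * cv)))
        subject_gain = float(
            np.exp(rng.normal(-0.5 * sigma_log**2, sigma_log))
        )  # mean-1 log-normal
    else:
        subject_gain = 1.0

    # patient extra noise loads on the per-sector channel: poorer fixation
    # and fatigue degrade individual sector estimates
    sector_sd = float(np.hypot(config.noise_sd_nV, effect.extra_noise_sd_nV))
    common_sd = config.common_noise_sd_nV
    common_noise = (
        rng.normal(0.0, common_sd, config.n_samples) if common_sd > 0 else 0.0
    )
    # per-subject timing: healthy variability plus half the patient jitter
    # variance; the other half varies sector-to-sector within the subject
    half_jitter_sd = effect.latency_jitter_sd_ms / np.sqrt(2.0)
    shared_sd = float(np.hypot(config.subject_latency_sd_ms, half_jitter_sd))
    shared = rng.normal(0.0, shared_sd, size=3) if shared_sd > 0 else np.zeros(3)
    sectors: dict[int, np.ndarray] = {}
    for s in range(1, N_SECTORS + 1):
        local = (
            rng.normal(0.0, half_jitter_sd, size=3)
            if half_jitter_sd > 0
            else np.zeros(3)
        )
        offsets = tuple(effect.latency_shift_ms + shared + local)
        clean = make_waveform(
            config.waveform,
            ring_of[s],
            n_samples=config.n_samples,
            sampling_rate_hz=config.sampling_rate_hz,
            latency_offset_ms=offsets,
            amp_scale=subject_gain * effect.amp_scale,
        )
        noise = (
            rng.normal(0.0, sector_sd, config.n_samples) if sector_sd > 0 else 0.0
        )
        sectors[s] = clean + common_noise + noise
    return MfERGRecording(
        subject_id=subject_id,
        group=group,
        sectors=sectors,
        sampling_rate_hz=config.sampling_rate_hz,
        n_samples=config.n_samples,
    )


def make_cohort(
    config: CohortConfig, layout: ClusterLayout | None = None
) -> Cohort:
    """A full synthetic cohort; byte-identical across runs for a fixed config."""
    config.validate()
    if layout is None:
        layout = default_layout()
    rng = np.random.default_rng(config.seed)
    recordings = []
    for i in range(config.n_controls):
        recordings.append(
            make_subject(f"ctrl{i + 1:02d}", "control", layout, config, rng)
        )
    for i in range(config.n_patients):
        recordings.append(
            make_subject(f"pat{i + 1:02d}", "patient", layout, config, rng)
        )
    return Cohort(recordings)
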