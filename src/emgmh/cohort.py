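"""Synthetic sEMG cohort generator.

Emulates the structure of a paired elbow-trauma study: each patient
contributes a healthy and an injured limb, each limb performs 10 upper-limb
motions (3 repetitions), and 7 forearm/upper-arm muscles are recorded at
~1926 Hz.  A recorded trial is rest -- burst -- rest: band-limited (20-400 Hz)
Gaussian interference-pattern noise plus a filtered impulse train (discrete
"spikes"), shaped by a trapezoidal activation envelope with raised-cosine
ramps, on top of a baseline noise floor and optional 60 Hz line interference.

Class differences are injected through :class:`EffectSpec`, whose knobs move
specific feature families:

* ``amplitude_shift``   -- burst envelope gain (energy features),
* ``spectral_shift``    -- narrows the spectral resonance (in Hz of
  bandwidth), concentrating power around the spectral peak (PSR),
* ``spike_density_shift`` / ``spike_duration_shift`` -- impulse-train rate,
  and the duration of the dominant deflections (impulse width together
  with the broadband upper edge), driving the spike-shape features, MSD
  in particular,
* ``complexity_shift``  -- scales the injured burst duration (injured
  motions run slower), growing the total curve length of the burst -- the
  quantity MFL measures -- while length-normalised features (MAV, DASDV,
  LOG, rates, entropies) stay put.

With a zero-effect spec the two limbs of a patient are draws from the same
distribution, so any downstream classifier is at chance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .io import Recording

MOTIONS = ("EF", "EE", "P", "S", "WF", "WE", "UD", "RD", "HO", "HC")
CHANNELS = ("BB", "TBlat", "TBlong", "PT", "BRD", "ECU", "FCU")

#: primary movers per motion; remaining channels act as synergists or stay quiet
PRIMARY_MOVERS = {
    "EF": ("BB", "BRD"),
    "EE": ("TBlat", "TBlong"),
    "P": ("PT",),
    "S": ("BB",),
    "WF": ("FCU",),
    "WE": ("ECU",),
    "UD": ("ECU", "FCU"),
    "RD": ("BRD",),
    "HO": ("ECU",),
    "HC": ("FCU", "PT"),
}

SYNERGISTS = {
    "EF": ("PT",),
    "EE": (),
    "P": ("BRD",),
    "S": ("BRD",),
    "WF": ("PT",),
    "WE": (),
    "UD": (),
    "RD": ("ECU",),
    "HO": (),
    "HC": ("FCU",),
}

ROLE_GAIN = {"primary-mover": 1.0, "synergist": 0.45, "quiet": 0.0}


@dataclass(frozen=True)
class CohortSpec:
    """Layout of a simulated cohort (sizes, rates, timing)."""

    n_patients: int = 27
    n_repetitions: int = 3
    sampling_rate: float = 1925.93
    motions: tuple[str, ...] = MOTIONS
    channels: tuple[str, ...] = CHANNELS
    burst_duration: float = 2.0
    rest_duration: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")
        if self.sampling_rate < 1000.0:
            raise ValueError("sampling_rate must be >= 1000 Hz")

    @property
    def n_samples(self) -> int:
        return int(round((self.burst_duration + 2 * self.rest_duration) * self.sampling_rate))


@dataclass(frozen=True)
class EffectSpec:
    """Healthy-vs-injured effect sizes applied to the injured limb only.

    All ``*_shift`` multiplicative factors must be > 0; ``spectral_shift``
    is in Hz (the amount by which the injured limb's spectral power
    concentrates, implemented as a resonance-bandwidth reduction).  The
    default instance is the null effect: injured and healthy limbs
    identically distributed.
    """

    amplitude_shift: float = 1.0
    spectral_shift: float = 0.0
    spike_density_shift: float = 1.0
    spike_duration_shift: float = 1.0
    complexity_shift: float = 1.0
    noise_floor: float = 0.02
    line_interference_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("amplitude_shift", "spike_density_shift",
                     "spike_duration_shift", "complexity_shift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")

    @property
    def is_null(self) -> bool:
        return (
            self.amplitude_shift == 1.0
            and self.spectral_shift == 0.0
            and self.spike_density_shift == 1.0
            and self.spike_duration_shift == 1.0
            and self.complexity_shift == 1.0
        )


#: canned effect profiles for the CLI / analysis drivers
EFFECT_PROFILES: dict[str, EffectSpec] = {
    "none": EffectSpec(),
    "small": EffectSpec(
        amplitude_shift=1.0,
        spectral_shift=6.0,
        spike_density_shift=0.85,
        spike_duration_shift=1.3,
        complexity_shift=1.2,
    ),
    # strong, recoverable effects aimed at the PSR / MFL / MSD / spike-rate
    # generators; the small amplitude rise offsets the derivative-power loss
    # that the slower injured oscillations would otherwise hand to DASDV
    "large": EffectSpec(
        amplitude_shift=1.12,
        spectral_shift=20.0,
        spike_density_shift=0.6,
        spike_duration_shift=2.2,
        complexity_shift=1.7,
    ),
}

# generator baseline constants (healthy-limb values)
_RESONANCE_HZ = 130.0     # resonance center (per-patient jitter, class-neutral)
_RESONANCE_BW = 26.0      # resonance bandwidth in Hz
_RESONANCE_BW_MIN = 6.0   # floor when an effect narrows the bandwidth
_RESONANCE_WEIGHT = 0.6   # resonance sd relative to broadband sd
_HIGHBAND_LOW_HZ = 280.0
_HIGHBAND_WEIGHT = 0.30   # 280-400 Hz component sd relative to broadband sd
_SPIKE_RATE_HZ = 22.0     # impulse-train rate inside the burst
_SPIKE_WIDTH_S = 0.003    # impulse (biphasic wavelet) characteristic width
_SPIKE_GAIN = 3.5         # impulse amplitude in broadband-sd units
_PATIENT_AMP_JITTER = 0.20
_PATIENT_TIMING_JITTER_S = 0.20
_PATIENT_FC_JITTER_HZ = 22.0
_TRIAL_DURATION_JITTER = 0.25  # class-neutral per-trial burst-length spread


@dataclass(frozen=True)
class PatientOffsets:
    """Per-patient nuisance variation; shared by both limbs (paired design).

    Amplitude, timing, firing rate and spectral mixture (resonance center
    and weight, high-band tilt) all vary between patients: between-patient
    spectral-shape variance is what keeps whole-spectrum summaries (AR
    coefficients, entropies) from acting as free class labels.
    """

    amp_gain: float
    timing_shift: float
    fc_jitter: float
    rate_gain: float
    tilt_gain: float = 1.0       # multiplier on the high-band weight
    res_weight: float = 0.6      # resonance weight (patient-specific)
    bb_high: float = 400.0       # broadband upper edge (patient-specific)
    fc2: float = 250.0           # idiosyncratic second spectral peak (Hz)
    w2: float = 0.0              # weight of the second peak


def _draw_patient_offsets(rng: np.random.Generator) -> PatientOffsets:
    return PatientOffsets(
        amp_gain=float(1.0 + rng.uniform(-_PATIENT_AMP_JITTER, _PATIENT_AMP_JITTER)),
        timing_shift=float(rng.uniform(-_PATIENT_TIMING_JITTER_S, _PATIENT_TIMING_JITTER_S)),
        fc_jitter=float(rng.normal(0.0, _PATIENT_FC_JITTER_HZ)),
        rate_gain=float(1.0 + rng.uniform(-0.2, 0.2)),
        tilt_gain=float(rng.uniform(0.5, 1.5)),
        res_weight=float(rng.uniform(0.5, 0.7)),
        bb_high=float(rng.uniform(300.0, 400.0)),
        fc2=float(rng.uniform(180.0, 320.0)),
        w2=float(rng.uniform(0.25, 0.55)),
    )


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    low: float, high: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-limited Gaussian noise, unit sd."""
    high = min(high, 0.499 * fs)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def trapezoid_envelope(n_burst: int, ramp_fraction: float = 0.1) -> np.ndarray:
    """Trapezoidal activation envelope with raised-cosine ramps."""
    n_ramp = max(1, int(round(ramp_fraction * n_burst)))
    env = np.ones(n_burst)
    t = np.arange(n_ramp) / n_ramp
    ramp = 0.5 * (1.0 - np.cos(np.pi * t))
    env[:n_ramp] = ramp
    env[-n_ramp:] = ramp[::-1]
    return env


def _spike_component(rng: np.random.Generator, n_burst: int, fs: float,
                     rate_hz: float, width_s: float) -> np.ndarray:
    """Filtered impulse train: biphasic (Gaussian-derivative) wavelets."""
    n_spikes = rng.poisson(rate_hz * n_burst / fs)
    out = np.zeros(n_burst)
    if n_spikes == 0:
        return out
    centers = np.sort(rng.integers(0, n_burst, size=n_spikes))
    half = max(3, int(round(3 * width_s * fs)))
    t = np.arange(-half, half + 1) / fs
    wavelet = -t / width_s * np.exp(0.5 - 0.5 * (t / width_s) ** 2)  # peak amp 1
    amps = 1.0 + 0.3 * rng.standard_normal(n_spikes)
    for c, a in zip(centers, amps):
        lo, hi = max(0, c - half), min(n_burst, c + half + 1)
        out[lo:hi] += a * wavelet[lo - (c - half): hi - (c - half)]
    return out


def channel_role(motion: str, channel: str) -> str:
    if channel in PRIMARY_MOVERS[motion]:
        return "primary-mover"
    if channel in SYNERGISTS[motion]:
        return "synergist"
    return "quiet"


def simulate_channel(
    motion: str,
    channel: str,
    role: str,
    effect: EffectSpec,
    spec: CohortSpec,
    rng: np.random.Generator,
    injured: bool = False,
    offsets: PatientOffsets | None = None,
) -> tuple[np.ndarray, int, int]:
    """Simulate one channel of one trial.

    Returns ``(signal, onset_index, offset_index)`` where the indices bracket
    the true activation burst (identical across channels of a trial when
    driven by the same offsets).
    """
    if motion not in spec.motions:
        raise ValueError(f"unknown motion code {motion!r}")
    if channel not in spec.channels:
        raise ValueError(f"unknown channel code {channel!r}")
    if role not in ROLE_GAIN:
        raise ValueError(f"unknown role {role!r}")

    fs = spec.sampling_rate
    n = spec.n_samples
    burst_s = spec.burst_duration * float(
        1.0 + rng.uniform(-_TRIAL_DURATION_JITTER, _TRIAL_DURATION_JITTER))
    if injured:
        burst_s *= effect.complexity_shift  # injured motions run slower
    n_burst = int(round(burst_s * fs))
    n_base = int(round(0.6 * fs))  # quiet head room for baseline estimation
    n_burst = min(n_burst, n - n_base - 2)
    if n_burst < 3:
        raise ValueError("burst does not fit within the trial")
    offsets = offsets or PatientOffsets(1.0, 0.0, 0.0, 1.0)

    onset = int(round((spec.rest_duration + offsets.timing_shift) * fs))
    onset = max(n_base, min(onset, n - n_burst - 1))
    offset = onset + n_burst

    x = effect.noise_floor * rng.standard_normal(n)

    gain = ROLE_GAIN[role] * offsets.amp_gain
    if injured:
        gain *= effect.amplitude_shift
    if gain > 0:
        fc = float(np.clip(_RESONANCE_HZ + offsets.fc_jitter, 40.0, 360.0))
        bw = _RESONANCE_BW
        w_res = offsets.res_weight
        if injured:  # power concentrates around the peak
            bw = max(_RESONANCE_BW_MIN, bw - effect.spectral_shift)
            w_res *= 1.0 + effect.spectral_shift / 22.0

        bb_high = offsets.bb_high
        if injured:  # slower deflections: the dominant oscillation widens
            bb_high = max(60.0, bb_high / effect.spike_duration_shift)
        broadband = _bandpass_noise(rng, n_burst, fs, 20.0, bb_high)
        resonance = _bandpass_noise(rng, n_burst, fs, fc - bw / 2, fc + bw / 2, order=4)
        highband = _bandpass_noise(rng, n_burst, fs, _HIGHBAND_LOW_HZ, 400.0)
        second = _bandpass_noise(rng, n_burst, fs, offsets.fc2 - 10.0,
                                 offsets.fc2 + 10.0, order=4)

        w_high = _HIGHBAND_WEIGHT * offsets.tilt_gain
        if injured:
            w_high *= np.sqrt(effect.complexity_shift)
        rate = _SPIKE_RATE_HZ * offsets.rate_gain
        width = _SPIKE_WIDTH_S
        if injured:
            rate *= effect.spike_density_shift
            width *= effect.spike_duration_shift
        spikes = _SPIKE_GAIN * _spike_component(rng, n_burst, fs, rate, width)

        burst = (broadband + w_res * resonance + w_high * highband
                 + offsets.w2 * second + spikes)
        # recording-chain bandwidth: confine the assembled burst to 20-400 Hz
        band_sos = signal.butter(2, [20.0, min(400.0, 0.499 * fs)],
                                 btype="bandpass", fs=fs, output="sos")
        burst = signal.sosfiltfilt(band_sos, burst)
        # normalisation uses the patient's healthy mixture: effect-driven
        # extra components change the burst's composition, not a re-scaling
        burst /= np.sqrt(1.0 + w_res**2 + w_high**2 + offsets.w2**2)
        x[onset:offset] += gain * trapezoid_envelope(n_burst) * burst

    if effect.line_interference_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += effect.line_interference_amp * np.sin(
            2 * np.pi * 60.0 * np.arange(n) / fs + phase
        )
    return x, onset, offset


def simulate_trial(
    motion: str,
    spec: CohortSpec,
    effect: EffectSpec,
    rng: np.random.Generator,
    injured: bool,
    offsets: PatientOffsets,
    meta: dict | None = None,
) -> tuple[Recording, int, int]:
    """Simulate all channels of one trial, cut from a shared ground truth."""
    cols = []
    onset = offset = 0
    for ch in spec.channels:
        sig, onset, offset = simulate_channel(
            motion, ch, channel_role(motion, ch), effect, spec, rng,
            injured=injured, offsets=offsets,
        )
        cols.append(sig)
    rec = Recording(
        samples=np.column_stack(cols),
        sampling_rate=spec.sampling_rate,
        channel_names=list(spec.channels),
        meta=dict(meta or {}),
    )
    return rec, onset, offset


@dataclass
class SimulatedCohort:
    """In-memory cohort: recordings plus a manifest with ground truth."""

    spec: CohortSpec
    effect: EffectSpec
    recordings: list[Recording] = field(default_factory=list)
    manifest: list[dict] = field(default_factory=list)

    def __iter__(self):
        return iter(zip(self.manifest, self.recordings))


def simulate_cohort(spec: CohortSpec, effect: EffectSpec | None = None) -> SimulatedCohort:
    """Simulate the full cohort: ``2 * n_patients`` limbs x motions x reps.

    Deterministic under a fixed ``spec.seed``; each trial gets an independent
    child RNG so per-trial signals do not depend on generation order.
    """
    effect = effect or EffectSpec()
    root = np.random.SeedSequence(spec.seed)
    patient_seeds = root.spawn(spec.n_patients)

    cohort = SimulatedCohort(spec=spec, effect=effect)
    healthy = EffectSpec(noise_floor=effect.noise_floor,
                         line_interference_amp=effect.line_interference_amp)
    for p in range(spec.n_patients):
        pseq = patient_seeds[p]
        offsets = _draw_patient_offsets(np.random.default_rng(pseq.spawn(1)[0]))
        trial_seeds = pseq.spawn(2 * len(spec.motions) * spec.n_repetitions)
        i = 0
        for limb, injured in (("healthy", False), ("injured", True)):
            eff = effect if injured else healthy
            for motion in spec.motions:
                for rep in range(spec.n_repetitions):
                    rng = np.random.default_rng(trial_seeds[i])
                    i += 1
                    meta = {
                        "patient": f"P{p:03d}",
                        "limb": limb,
                        "label": limb,
                        "motion": motion,
                        "repetition": rep,
                        "sampling_rate": spec.sampling_rate,
                    }
                    rec, onset, offset = simulate_trial(
                        motion, spec, eff, rng, injured, offsets, meta
                    )
                    cohort.recordings.append(rec)
                    entry = dict(meta)
                    entry["true_onset"] = onset
                    entry["true_offset"] = offset
                    cohort.manifest.append(entry)
    return cohort


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Write one CSV per trial plus a JSON manifest; returns the manifest path."""
    from .io import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for entry, rec in cohort:
        name = "{patient}_{limb}_{motion}_r{repetition}.csv".format(**entry)
        write_recording(rec, out / name)
        e = dict(entry)
        e["path"] = name
        entries.append(e)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps({
        "label_scheme": "healthy-vs-injured",
        "seed": cohort.spec.seed,
        "sampling_rate": cohort.spec.sampling_rate,
        "trials": entries,
    }, indent=1))
    return manifest_path


def zero_effect(noise_floor: float = 0.02) -> EffectSpec:
    return EffectSpec(noise_floor=noise_floor)


def permute_limb_labels(manifest: list[dict], seed: int) -> list[dict]:
    """Randomly swap the healthy/injured labels of each patient's limbs.

    Used for chance-level controls: the permutation operates at patient
    level so the paired grouping structure is preserved.
    """
    rng = np.random.default_rng(seed)
    patients = sorted({e["patient"] for e in manifest})
    flip = {p: bool(rng.integers(0, 2)) for p in patients}
    out = []
    for e in manifest:
        e = dict(e)
        if flip[e["patient"]]:
            e["label"] = "injured" if e["label"] == "healthy" else "healthy"
        out.append(e)
    return out
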