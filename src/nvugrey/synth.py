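"""Synthetic study generator.

Emulates the study design the analysis assumes: a cohort of subjects
(default 11), two regions (targeted under the stimulation montage and the
contralateral nontargeted region), 600 s of 2 mA trapezoidal stimulation
with 30 s ramps after a 120 s baseline, and 4-channel oxy/deoxy recordings
per region at 10 Hz.

The vessel drive of each subject comes from the nonlinear NVU simulator
under that subject's true pathway and lead-field gain; total hemoglobin is
mapped linearly from the vessel-circumference deviation (small-change
assumption).  Channels add systemic sinusoids (Mayer ~0.1 Hz, respiration
~0.25 Hz, cardiac ~1 Hz), slow drift and white noise.  A configurable
subset of subjects is generated under a common-drive regime (shared
low-frequency component on oxy and deoxy) paired with an initial-dip
vessel drive; these subjects fail the anti-correlation QC by construction,
mirroring a realistic rejection fraction of 3 of 11.

Ground-truth labels (pathway, gain, regimes) are carried only in record
metadata and the cohort manifest; the fitting modules never read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError
from .nvu_model import NVUParameters, STATE_NAMES, find_equilibrium, simulate
from .preprocess import SubjectRecord
from .reduction import RationalTF
from .tdcs_input import StimulusWaveform, VasoactiveFilter, vasoactive_signal
from ._lsim import lsim_foh

#: per-pathway reference lead-field gains giving a small-signal vessel
#: deviation of roughly half a micron at 2 mA (pathway 4's net
#: voltage-gated K current is hyperpolarizing, hence the negative sign)
REFERENCE_GAINS = {1: 0.0075, 2: 1.5, 3: 0.002, 4: -0.09}

_X_IDX = STATE_NAMES.index("x")


@dataclass
class CohortSpec:
    """Conditions of the synthetic study."""

    n_subjects: int = 11
    pathway_targeted: int = 3           # true pathway at the stimulated region
    pathway_nontargeted: int = 4        # true pathway contralaterally
    gain_sigma: float = 0.2             # log-normal spread of the lead-field gain
    noise_sd: float = 0.02              # white channel noise (uM)
    mayer_amp: float = 0.15             # ~0.1 Hz systemic amplitude (uM)
    resp_amp: float = 0.10              # ~0.25 Hz amplitude (uM)
    cardiac_amp: float = 0.08           # ~1 Hz amplitude (uM)
    drift_slope: float = 0.0005         # linear drift magnitude (uM/s)
    anti_amp: float = 0.30              # shared anti-phase oxy/deoxy component (uM)
    common_amp: float = 0.30            # common-drive component (uM, QC-fail subjects)
    systemic_deoxy_weight: float = 0.25 # systemic leakage into deoxy
    deoxy_fraction: float = -0.3        # deoxy share of the tHb change (opposite sign)
    thb_per_um: float = 4.0             # uM tHb per um circumference change
    channel_gain_spread: float = 0.3    # per-channel response sensitivity spread
    mayer_pattern_spread: float = 0.5   # spatial spread of the common Mayer mode
    initial_dip_fraction: float = 3.0 / 11.0
    dip_depth: float = 2.0              # early negative drive multiplier
    dip_tau: float = 20.0               # s
    common_deoxy_fraction: float = 0.35 # deoxy share for common-drive subjects (co-moving)
    n_channels: int = 4                 # channels per analysis region
    n_outer_channels: int = 8           # montage channels outside both regions
    outer_response_scale: float = 0.1   # residual evoked response on outer channels
    nontargeted_scale: float = 0.35     # contralateral response attenuation
    sampling_rate: float = 10.0
    baseline: float = 120.0             # s before stimulation onset
    stim: StimulusWaveform = field(default_factory=lambda: StimulusWaveform(
        amplitude=2.0, ramp_up=30.0, plateau=540.0, ramp_down=30.0))
    tau_filter: float = 0.02            # vasoactive filter time constant (s)
    seed: int | None = None             # mandatory for reproducibility

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("CohortSpec.seed is mandatory")
        for a in ("noise_sd", "mayer_amp", "resp_amp", "cardiac_amp",
                  "anti_amp", "common_amp"):
            if getattr(self, a) < 0:
                raise ValidationError(f"{a} must be non-negative")
        if not 0 <= self.initial_dip_fraction <= 1:
            raise ValidationError("initial_dip_fraction must lie in [0,1]")

    @property
    def duration(self) -> float:
        return self.baseline + self.stim.duration

    def n_dip(self) -> int:
        return int(round(self.initial_dip_fraction * self.n_subjects))


def _common_drive_subjects(spec: CohortSpec):
    rng = np.random.default_rng([int(spec.seed), 987654321])
    return sorted(rng.choice(spec.n_subjects, size=spec.n_dip(), replace=False))


def _vessel_drive(spec: CohortSpec, params, eq, pathway: int, gain: float,
                  dip: bool, rtol: float = 1e-6, atol: float = 1e-8):
    """Filtered perturbation series and the resulting vessel trajectory."""
    stim = StimulusWaveform(spec.stim.amplitude, spec.stim.ramp_up,
                            spec.stim.plateau, spec.stim.ramp_down,
                            onset=spec.baseline,
                            sampling_rate=spec.sampling_rate)
    filt = VasoactiveFilter(K_i=gain, tau=spec.tau_filter)
    t_v, v = vasoactive_signal(stim, filt, t_end=spec.duration)
    if dip:
        # early negative-gain transient on the vessel drive (initial dip)
        rel = np.clip(t_v - spec.baseline, 0.0, None)
        v = v * (1.0 - spec.dip_depth * np.exp(-rel / spec.dip_tau))
    traj = simulate(eq.state, params, stimulus=(t_v, v), pathway=pathway,
                    t_span=(0.0, spec.duration), dt_out=1.0 / spec.sampling_rate,
                    rtol=rtol, atol=atol)
    dx = traj["x"] - eq.state.x
    return traj.t, dx


def _systemic(rng, t, spec: CohortSpec, common_phase, mayer_weight):
    """One channel's systemic interference: random per-channel components
    plus a subject-shared Mayer mode whose spatial weight varies by channel
    (the structure the PCA-removal stage is meant to find)."""
    f_m = 0.1 * (1.0 + 0.05 * rng.standard_normal())
    f_r = 0.25 * (1.0 + 0.05 * rng.standard_normal())
    f_c = 1.0 * (1.0 + 0.02 * rng.standard_normal())
    s = (0.5 * spec.mayer_amp * np.sin(2 * np.pi * f_m * t + rng.uniform(0, 2 * np.pi))
         + mayer_weight * spec.mayer_amp * np.sin(2 * np.pi * 0.1 * t + common_phase)
         + spec.resp_amp * np.sin(2 * np.pi * f_r * t + rng.uniform(0, 2 * np.pi))
         + spec.cardiac_amp * np.sin(2 * np.pi * f_c * t + rng.uniform(0, 2 * np.pi)))
    return s


def _smooth_process(rng, t, amp, f_lo=0.01, f_hi=0.06, n_modes=6):
    """Band-limited random process (sum of random low-frequency sinusoids)."""
    out = np.zeros_like(t)
    freqs = rng.uniform(f_lo, f_hi, n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    amps = rng.uniform(0.5, 1.0, n_modes)
    for f, ph, a in zip(freqs, phases, amps):
        out += a * np.sin(2 * np.pi * f * t + ph)
    sd = out.std()
    return amp * out / sd if sd > 0 else out


def _make_channels(rng, t, spec: CohortSpec, g, n_ch, is_common, common_phase):
    """Oxy/deoxy channel matrices for one region given its ground-truth tHb."""
    lam = spec.common_deoxy_fraction if is_common else spec.deoxy_fraction
    oxy = np.empty((n_ch, len(t)))
    deoxy = np.empty_like(oxy)
    # heterogeneous channel sensitivities: the evoked spatial pattern differs
    # from the Mayer-mode pattern, as with real optode montages
    ch_gain = 1.0 + spec.channel_gain_spread * rng.uniform(-1, 1, n_ch)
    mayer_w = 1.0 + spec.mayer_pattern_spread * rng.uniform(-1, 1, n_ch)
    for ch in range(n_ch):
        g_ch = ch_gain[ch] * g
        sys_ch = _systemic(rng, t, spec, common_phase, mayer_w[ch])
        drift = rng.choice([-1.0, 1.0]) * spec.drift_slope * t
        if is_common:
            shared = _smooth_process(rng, t, spec.common_amp)
            o = (1 - lam) * g_ch + shared
            d = lam * g_ch + shared
        else:
            anti = _smooth_process(rng, t, spec.anti_amp)
            o = (1 - lam) * g_ch + anti
            d = lam * g_ch - anti
        oxy[ch] = o + sys_ch + drift + spec.noise_sd * rng.standard_normal(len(t))
        deoxy[ch] = (d + spec.systemic_deoxy_weight * sys_ch - drift
                     + spec.noise_sd * rng.standard_normal(len(t)))
    return oxy, deoxy


def generate_subject(spec: CohortSpec, subject_id: int, params=None, eq=None,
                     regions=("targeted", "nontargeted")):
    """Generate one subject's records: the analysis regions plus, when
    ``spec.n_outer_channels > 0``, an auxiliary ``"outer"`` record holding
    the montage channels outside both regions (systemic physiology with only
    a residual evoked response; used by the subject-level PCA stage).

    ``params``/``eq`` may be passed to reuse the NVU equilibrium across a
    cohort; they are recomputed otherwise.
    """
    if params is None:
        params = NVUParameters.default()
    if eq is None:
        eq = find_equilibrium(params)
    common = _common_drive_subjects(spec)
    is_common = subject_id in common
    rng = np.random.default_rng([int(spec.seed), int(subject_id)])
    gain_factor = float(np.exp(spec.gain_sigma * rng.standard_normal()))
    common_phase = rng.uniform(0, 2 * np.pi)   # montage-wide Mayer phase
    sid = f"S{subject_id + 1:02d}"

    records = []
    g_targeted = None
    for region in regions:
        pathway = (spec.pathway_targeted if region == "targeted"
                   else spec.pathway_nontargeted)
        scale = 1.0 if region == "targeted" else spec.nontargeted_scale
        gain = REFERENCE_GAINS[pathway] * gain_factor * scale
        t, dx = _vessel_drive(spec, params, eq, pathway, gain, dip=is_common)
        g = spec.thb_per_um * dx          # ground-truth tHb (uM)
        if region == "targeted":
            g_targeted = g
        oxy, deoxy = _make_channels(rng, t, spec, g, spec.n_channels,
                                    is_common, common_phase)
        records.append(SubjectRecord(
            subject_id=sid, region=region,
            oxy=oxy, deoxy=deoxy, sampling_rate=spec.sampling_rate,
            stim_onset=spec.baseline, baseline_window=spec.baseline,
            meta={"true_pathway": pathway, "true_gain": gain,
                  "common_drive": is_common, "initial_dip": is_common,
                  "ground_truth_thb": g, "seed": int(spec.seed)}))
    if spec.n_outer_channels > 0:
        n_t = int(round(spec.duration * spec.sampling_rate)) + 1
        g_out = (spec.outer_response_scale * g_targeted
                 if g_targeted is not None else np.zeros(n_t))
        t_out = np.arange(len(g_out)) / spec.sampling_rate
        oxy, deoxy = _make_channels(rng, t_out, spec, g_out,
                                    spec.n_outer_channels, is_common,
                                    common_phase)
        records.append(SubjectRecord(
            subject_id=sid, region="outer",
            oxy=oxy, deoxy=deoxy, sampling_rate=spec.sampling_rate,
            stim_onset=spec.baseline, baseline_window=spec.baseline,
            meta={"common_drive": is_common, "seed": int(spec.seed)}))
    return records


def generate_cohort(spec: CohortSpec, params=None, eq=None,
                    regions=("targeted", "nontargeted")):
    """Generate the full cohort plus a manifest of seeds and truth labels."""
    if params is None:
        params = NVUParameters.default()
    if eq is None:
        eq = find_equilibrium(params)
    records = []
    for sid in range(spec.n_subjects):
        records.extend(generate_subject(spec, sid, params, eq, regions))
    manifest = {
        "seed": int(spec.seed),
        "n_subjects": spec.n_subjects,
        "common_drive_subjects": [int(s) for s in _common_drive_subjects(spec)],
        "pathway_truth": {"targeted": spec.pathway_targeted,
                          "nontargeted": spec.pathway_nontargeted},
        "spec": {k: v for k, v in asdict(spec).items() if k != "stim"},
    }
    return records, manifest


@dataclass
class TFDataset:
    u: np.ndarray
    y: np.ndarray
    y_clean: np.ndarray
    noise_sd: float
    dt: float


def generate_tf_dataset(tf: RationalTF, stimulus: StimulusWaveform,
                        snr: float, seed: int, t_end: float | None = None) -> TFDataset:
    """Simulated response of a stable TF to the stimulus plus Gaussian noise.

    ``snr`` is the variance ratio var(clean)/var(noise); ``snr=inf`` gives
    the exact response.
    """
    if not tf.is_stable():
        raise ValidationError("generate_tf_dataset requires a stable TF")
    t, u = stimulus.sample(t_end)
    dt = 1.0 / stimulus.sampling_rate
    A, B, C, D = tf.to_statespace()
    y_clean = lsim_foh(A, B, C, D, u, dt)
    if np.isinf(snr):
        sd = 0.0
        y = y_clean.copy()
    else:
        sd = float(y_clean.std() / np.sqrt(snr))
        rng = np.random.default_rng(seed)
        y = y_clean + sd * rng.standard_normal(len(y_clean))
    return TFDataset(u=u, y=y, y_clean=y_clean, noise_sd=sd, dt=dt)
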