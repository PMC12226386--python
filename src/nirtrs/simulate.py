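"""Synthetic two-condition block-design experiment generator.

Generates everything the analysis pipeline consumes - two-channel
hemoglobin time courses, optional TCSPC photon histograms, cardiac
interval series, and seven-item visual-analogue-scale ratings - with the
statistical structure the pipeline assumes, so every downstream stage is
testable without any recorded data.

The default condition-by-period effect profiles are the study-calibrated
per-period mean change rates (and their between-subject SDs) for oxy- and
deoxy-hemoglobin in both channels. Subject heterogeneity enters through a
shared response-gain factor ``g ~ N(1, gain_sd)`` scaling each subject's
deviation-from-baseline profile, plus independent per-cell noise at the
tabled SDs. The gain's z-score is the latent "responder" trait that
couples (negatively) to post-task heart rate and (positively) to the
hedonic VAS items.

Within a subject's record, per-period targets are reached through
first-order kinetics (tau = 30 s); the step levels are solved from a
linear system so that the *period means* of the smoothed series equal the
targets exactly when noise is off. Physiological nuisance oscillations
(Mayer ~0.1 Hz, respiration ~0.25 Hz, cardiac ~1.1 Hz, aliased by the
0.33 Hz sampling) and white sample noise are superposed multiplicatively.

All randomness derives from ``config.seed`` through per-(subject,
condition) child streams, so changing one condition's profile or adding
subjects never perturbs the draws of another stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chromophore import ExtinctionTable, HbState, mua_from_hb
from .design import CONDITIONS, ExperimentDesign
from .optics import (
    TPSF,
    ProbeGeometry,
    TimeGrid,
    convolve_irf,
    gaussian_irf,
    reflectance,
    sample_counts,
)
from .autonomic import IntervalSeries

__all__ = [
    "SimulationConfig",
    "HbChannelSeries",
    "SyntheticExperiment",
    "simulate_subject_hb",
    "simulate_period_matrix",
    "simulate_tpsf_stream",
    "simulate_rr",
    "simulate_vas",
    "simulate_experiment",
    "VAS_ITEMS",
]

# Default per-period mean change rates and between-subject SDs, indexed
# [period] over (pre1..3, t1..7, post1..3), per condition and channel.
# These are the generator's study-calibrated operating point.
OXY_TARGETS = {
    ("creative", "ch1"): [1.000, 1.003, 1.005, 1.003, 1.010, 1.009, 1.007,
                          1.006, 1.009, 1.010, 1.014, 1.022, 1.023],
    ("simple", "ch1"):   [1.003, 1.000, 1.002, 0.994, 0.993, 0.992, 0.992,
                          0.992, 0.991, 0.992, 0.987, 0.995, 0.994],
    ("creative", "ch2"): [1.001, 1.002, 1.003, 1.001, 1.005, 1.003, 1.001,
                          0.999, 1.000, 1.001, 1.005, 1.016, 1.017],
    ("simple", "ch2"):   [1.000, 0.998, 1.001, 0.994, 0.995, 0.994, 0.993,
                          0.993, 0.991, 0.992, 0.988, 0.996, 0.994],
}
OXY_SDS = {
    ("creative", "ch1"): [0.010, 0.016, 0.016, 0.019, 0.022, 0.019, 0.020,
                          0.019, 0.018, 0.020, 0.018, 0.024, 0.026],
    ("simple", "ch1"):   [0.020, 0.027, 0.022, 0.018, 0.023, 0.022, 0.022,
                          0.022, 0.023, 0.025, 0.021, 0.025, 0.028],
    ("creative", "ch2"): [0.011, 0.017, 0.018, 0.017, 0.020, 0.019, 0.021,
                          0.021, 0.022, 0.025, 0.016, 0.020, 0.025],
    ("simple", "ch2"):   [0.013, 0.014, 0.015, 0.016, 0.022, 0.020, 0.022,
                          0.025, 0.023, 0.025, 0.020, 0.021, 0.022],
}
DEOXY_TARGETS = {
    ("creative", "ch1"): [0.995, 0.990, 0.987, 0.982, 0.966, 0.960, 0.959,
                          0.959, 0.955, 0.956, 0.964, 0.962, 0.960],
    ("simple", "ch1"):   [0.992, 0.986, 0.987, 0.991, 0.983, 0.977, 0.976,
                          0.975, 0.974, 0.970, 0.976, 0.973, 0.973],
    ("creative", "ch2"): [0.993, 0.989, 0.987, 0.986, 0.975, 0.966, 0.968,
                          0.967, 0.964, 0.963, 0.970, 0.964, 0.964],
    ("simple", "ch2"):   [0.995, 0.996, 0.990, 0.996, 0.991, 0.983, 0.981,
                          0.983, 0.982, 0.979, 0.983, 0.978, 0.977],
}
DEOXY_SDS = {
    ("creative", "ch1"): [0.014, 0.023, 0.029, 0.024, 0.026, 0.024, 0.025,
                          0.028, 0.034, 0.033, 0.030, 0.031, 0.030],
    ("simple", "ch1"):   [0.037, 0.050, 0.040, 0.026, 0.027, 0.034, 0.034,
                          0.032, 0.033, 0.033, 0.035, 0.037, 0.040],
    ("creative", "ch2"): [0.011, 0.018, 0.027, 0.028, 0.028, 0.024, 0.027,
                          0.028, 0.030, 0.036, 0.036, 0.033, 0.033],
    ("simple", "ch2"):   [0.026, 0.030, 0.028, 0.022, 0.024, 0.026, 0.027,
                          0.028, 0.029, 0.028, 0.029, 0.029, 0.033],
}

VAS_ITEMS = (
    "enjoyment",
    "arousal",
    "like_dislike",
    "concentration",
    "difficulty",
    "motivation",
    "lack_of_fatigue",
)
# item -> (simple mean, simple sd, creative mean, creative sd, hedonic-coupled)
VAS_DEFAULTS = {
    "enjoyment":       (39.61, 19.61, 83.57, 11.95, True),
    "arousal":         (43.17, 27.70, 81.17, 16.04, True),
    "like_dislike":    (52.72, 17.64, 82.48, 13.76, True),
    "concentration":   (66.26, 19.11, 85.04, 12.14, False),
    "difficulty":      (6.283, 8.301, 60.96, 15.91, False),
    "motivation":      (60.28, 23.17, 84.17, 11.75, True),
    "lack_of_fatigue": (47.37, 18.08, 52.35, 14.91, False),
}

CHANNELS = ("ch1", "ch2")
CHANNEL_WAVELENGTHS = {"ch1": (763.0, 802.0, 835.0), "ch2": (762.0, 800.0, 837.0)}


def _as_profile(d: dict) -> dict:
    return {k: np.asarray(v, dtype=float) for k, v in d.items()}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; the seed fully determines
    the output. SDs and amplitudes of zero give a noise-free study whose
    period means equal the configured targets exactly."""

    n_subjects: int = 23
    seed: int = 0
    fidelity: str = "concentration"      # or "photon"
    baseline_oxy_um: float = 25.0
    baseline_deoxy_um: float = 12.0
    oxy_targets: dict = field(default_factory=lambda: _as_profile(OXY_TARGETS))
    oxy_sds: dict = field(default_factory=lambda: _as_profile(OXY_SDS))
    deoxy_targets: dict = field(default_factory=lambda: _as_profile(DEOXY_TARGETS))
    deoxy_sds: dict = field(default_factory=lambda: _as_profile(DEOXY_SDS))
    gain_sd: float = 0.3                 # SD of the shared response gain
    sample_noise_sd: float = 0.005       # white noise on the change rate
    mayer_amp: float = 0.003             # ~0.1 Hz vasomotion
    resp_amp: float = 0.002              # ~0.25 Hz respiration (aliased)
    cardiac_amp: float = 0.001           # ~1.1 Hz cardiac (aliased)
    tau_s: float = 30.0                  # first-order transition constant
    # cardiac interval generator
    hr_base_bpm: float = 65.0
    hr_between_sd_bpm: float = 7.0
    hr_coupling_bpm: float = 4.0         # post-task HR drop per responder z
    lf_mod_amp: float = 0.04             # fractional LF (0.1 Hz) modulation
    hf_mod_amp: float = 0.04             # fractional HF (0.25 Hz) modulation
    rr_jitter_s: float = 0.002
    # VAS generator
    vas_params: dict = field(default_factory=lambda: dict(VAS_DEFAULTS))
    vas_coupling: float = 0.5            # latent-factor loading of hedonic items
    # photon-level fidelity
    photons_per_sample: int = 1_000_000
    musp_ref: float = 1.1                # reduced scattering at 800 nm, 1/mm
    scatter_power: float = 1.0           # musp ~ (lambda/800)^(-scatter_power)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fidelity not in ("concentration", "photon"):
            raise ValueError(f"unknown fidelity {self.fidelity!r}")
        for name in ("gain_sd", "sample_noise_sd", "mayer_amp", "resp_amp",
                     "cardiac_amp", "hr_between_sd_bpm", "rr_jitter_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for table in (self.oxy_targets, self.oxy_sds,
                      self.deoxy_targets, self.deoxy_sds):
            for key, arr in table.items():
                arr = np.asarray(arr, dtype=float)
                table[key] = arr
                if arr.shape != (13,):
                    raise ValueError(f"profile {key} must have 13 periods")
        if self.photons_per_sample < 10_000:
            import warnings

            warnings.warn(
                "photon budget < 1e4 per sample: optical-property recovery "
                "is unreliable", stacklevel=2
            )

    @classmethod
    def noiseless(cls, **overrides) -> "SimulationConfig":
        """A configuration with every hemodynamic noise source disabled
        (zero between-subject SDs, gain spread, sample noise and nuisance
        oscillations): period means then equal the targets exactly."""
        zeros_oxy = {k: np.zeros(13) for k in OXY_SDS}
        zeros_deoxy = {k: np.zeros(13) for k in DEOXY_SDS}
        kw = dict(
            oxy_sds=zeros_oxy,
            deoxy_sds=zeros_deoxy,
            gain_sd=0.0,
            sample_noise_sd=0.0,
            mayer_amp=0.0,
            resp_amp=0.0,
            cardiac_amp=0.0,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A no-condition-effect configuration: the creative condition
        inherits the simple condition's target profiles (noise sources
        stay at their defaults), so any detected condition difference is
        a false positive."""
        oxy = _as_profile(OXY_TARGETS)
        deoxy = _as_profile(DEOXY_TARGETS)
        for chan in CHANNELS:
            oxy[("creative", chan)] = oxy[("simple", chan)].copy()
            deoxy[("creative", chan)] = deoxy[("simple", chan)].copy()
        kw = dict(oxy_targets=oxy, deoxy_targets=deoxy)
        kw.update(overrides)
        return cls(**kw)

    def hash(self) -> str:
        """Stable hash of the full configuration."""
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o

        blob = json.dumps(enc(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class HbChannelSeries:
    """One channel's sampled hemoglobin time course (micromolar)."""

    times: np.ndarray
    oxy_um: np.ndarray
    deoxy_um: np.ndarray

    @property
    def total_um(self) -> np.ndarray:
        return self.oxy_um + self.deoxy_um


# --- period-target kinetics -------------------------------------------------

_KINETICS_CACHE: dict = {}


def _kinetics_operator(design: ExperimentDesign, tau_s: float):
    """Linear map from 13 step levels to (per-sample trace, period means).

    Returns (basis, base, M, b): the smoothed trace is
    ``base + basis @ levels`` and its period means are ``b + M @ levels``.
    The baseline segment sits at level 1 and the filter starts at steady
    state there.
    """
    key = (design.dt, design.baseline_samples, design.n_periods,
           design.period_duration_s, design.n_samples, tau_s)
    if key in _KINETICS_CACHE:
        return _KINETICS_CACHE[key]
    t = design.sample_times()
    pidx = design.period_index(t)          # -1 for baseline samples
    n, k = design.n_samples, design.n_periods
    alpha = 1.0 - np.exp(-design.dt / tau_s)
    # step input for each unit level vector plus the baseline-only input
    u = np.zeros((n, k + 1))
    u[pidx < 0, 0] = 1.0                    # baseline channel at level 1
    for p in range(k):
        u[pidx == p, p + 1] = 1.0
    x = np.zeros_like(u)
    x[0] = u[0]                             # steady state at record start
    for i in range(1, n):
        x[i] = x[i - 1] + alpha * (u[i] - x[i - 1])
    means = np.empty((k, k + 1))
    for p in range(k):
        means[p] = x[pidx == p].mean(axis=0)
    base, basis = x[:, 0], x[:, 1:]
    b, M = means[:, 0], means[:, 1:]
    _KINETICS_CACHE[key] = (basis, base, M, b)
    return basis, base, M, b


def _smooth_trace(targets: np.ndarray, design: ExperimentDesign, tau_s: float) -> np.ndarray:
    """Per-sample change-rate trace whose 13 period means equal ``targets``."""
    basis, base, M, b = _kinetics_operator(design, tau_s)
    levels = np.linalg.solve(M, targets - b)
    return base + basis @ levels


# --- RNG streams -------------------------------------------------------------

def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def subject_gain(config: SimulationConfig, subject: int) -> float:
    """The subject's shared response gain g ~ N(1, gain_sd)."""
    return float(1.0 + config.gain_sd * _stream(config.seed, subject).standard_normal())


def subject_z(config: SimulationConfig, subject: int) -> float:
    """Responder z-score: (g - 1) / gain_sd (standard normal)."""
    if config.gain_sd == 0:
        return 0.0
    return (subject_gain(config, subject) - 1.0) / config.gain_sd


# --- generators --------------------------------------------------------------

def simulate_subject_hb(
    config: SimulationConfig,
    subject: int,
    condition: str,
    design: ExperimentDesign | None = None,
) -> dict[str, HbChannelSeries]:
    """One subject's two-channel hemoglobin record under one condition.

    Returns absolute concentrations (micromolar): the change-rate profile
    times the configured baseline concentration, including the leading
    baseline window at change rate ~1.
    """
    design = design or ExperimentDesign()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    g = subject_gain(config, subject)
    rng = _stream(config.seed, subject, CONDITIONS.index(condition), 0)
    t = design.sample_times()
    out: dict[str, HbChannelSeries] = {}
    for chan in CHANNELS:
        series = {}
        for chrom, targets_tab, sds_tab, base_um in (
            ("oxy", config.oxy_targets, config.oxy_sds, config.baseline_oxy_um),
            ("deoxy", config.deoxy_targets, config.deoxy_sds, config.baseline_deoxy_um),
        ):
            targets = targets_tab[(condition, chan)]
            sds = sds_tab[(condition, chan)]
            m = 1.0 + g * (targets - 1.0) + rng.normal(0.0, 1.0, 13) * sds
            trace = _smooth_trace(m, design, config.tau_s)
            osc = np.zeros_like(t)
            for amp, hz in (
                (config.mayer_amp, 0.10),
                (config.resp_amp, 0.25),
                (config.cardiac_amp, 1.10),
            ):
                if amp > 0:
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    osc += amp * np.sin(2.0 * np.pi * hz * t + phase)
            noise = (
                rng.normal(0.0, config.sample_noise_sd, t.shape[0])
                if config.sample_noise_sd > 0
                else 0.0
            )
            series[chrom] = (trace + osc + noise) * base_um
        out[chan] = HbChannelSeries(
            times=t, oxy_um=series["oxy"], deoxy_um=series["deoxy"]
        )
    return out


def simulate_period_matrix(
    config: SimulationConfig,
    n_subjects: int | None = None,
) -> dict[str, np.ndarray]:
    """Fast path: subject-level period means drawn directly, skipping the
    sample-level series. Arrays are (subject, condition, channel, period)
    with the condition axis ordered as ``CONDITIONS`` (simple, creative).
    Shares the per-subject gain and per-cell noise model of
    :func:`simulate_subject_hb`, whose period means it matches in
    distribution up to sample-level noise.
    """
    n = n_subjects or config.n_subjects
    out = {}
    gains = np.array([subject_gain(config, i) for i in range(n)])
    for chrom, targets_tab, sds_tab in (
        ("oxy", config.oxy_targets, config.oxy_sds),
        ("deoxy", config.deoxy_targets, config.deoxy_sds),
    ):
        arr = np.empty((n, len(CONDITIONS), len(CHANNELS), 13))
        for ci, cond in enumerate(CONDITIONS):
            for i in range(n):
                rng = _stream(config.seed, i, ci, 3, 0 if chrom == "oxy" else 1)
                for hi, chan in enumerate(CHANNELS):
                    targets = targets_tab[(cond, chan)]
                    sds = sds_tab[(cond, chan)]
                    arr[i, ci, hi] = (
                        1.0
                        + gains[i] * (targets - 1.0)
                        + rng.normal(0.0, 1.0, 13) * sds
                    )
        out[chrom] = arr
    return out


def simulate_tpsf_stream(
    series: HbChannelSeries,
    config: SimulationConfig,
    wavelengths: tuple[float, float, float],
    geometry: ProbeGeometry | None = None,
    grid: TimeGrid | None = None,
    rng: np.random.Generator | None = None,
    table: ExtinctionTable | None = None,
    max_samples: int | None = None,
    noiseless: bool = False,
) -> list[tuple[TPSF, TPSF, TPSF]]:
    """Photon-level fidelity: map each concentration sample to absorption
    at the three wavelengths, forward-model the diffuse reflectance,
    convolve the simulated IRF, and Poisson-sample at the configured
    photon budget. Returns one 3-wavelength TPSF tuple per sample.
    """
    geometry = geometry or ProbeGeometry()
    grid = grid or TimeGrid()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    table = table or ExtinctionTable.default()
    irf_shape = gaussian_irf(grid)
    irf_counts = np.round(irf_shape * 1e6).astype(np.int64)
    wl = np.asarray(wavelengths, dtype=float)
    musp = config.musp_ref * (wl / 800.0) ** (-config.scatter_power)
    n = series.times.shape[0] if max_samples is None else min(
        max_samples, series.times.shape[0]
    )
    stream = []
    for i in range(n):
        state = HbState(oxy=float(series.oxy_um[i]), deoxy=float(series.deoxy_um[i]))
        mua = mua_from_hb(state, wl, table)
        tpsfs = []
        for j in range(3):
            props_curve = reflectance(
                geometry,
                _props(mua[j], musp[j], wl[j]),
                grid,
            )
            expected = convolve_irf(props_curve, irf_shape)
            if noiseless:
                counts = expected / expected.sum() * config.photons_per_sample
            else:
                counts = sample_counts(expected, config.photons_per_sample, rng)
            tpsfs.append(
                TPSF(
                    grid=grid,
                    counts=counts,
                    irf_counts=irf_counts,
                    wavelength=float(wl[j]),
                    geometry=geometry,
                )
            )
        stream.append(tuple(tpsfs))
    return stream


def _props(mua: float, musp: float, wl: float):
    from .optics import OpticalProperties

    return OpticalProperties(mua=mua, musp=musp, wavelength=wl)


def simulate_rr(
    config: SimulationConfig,
    subject: int,
    condition: str,
    oxy_response_z: float | None = None,
    design: ExperimentDesign | None = None,
) -> IntervalSeries:
    """Cardiac inter-beat interval series spanning the 13-period record.

    Instantaneous intervals carry fractional LF (0.1 Hz) and HF (0.25 Hz)
    modulations; during the post-task rest periods the underlying heart
    rate is shifted by ``-hr_coupling_bpm * z`` where z is the subject's
    responder z-score, producing the negative HR-vs-response coupling the
    analysis probes for.
    """
    design = design or ExperimentDesign()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    z = subject_z(config, subject) if oxy_response_z is None else oxy_response_z
    rng = _stream(config.seed, subject, CONDITIONS.index(condition), 1)
    hr0 = config.hr_base_bpm + config.hr_between_sd_bpm * rng.standard_normal()
    hr0 = max(hr0, 40.0)
    phi_lf, phi_hf = rng.uniform(0.0, 2.0 * np.pi, 2)
    post_start = 10 * design.period_duration_s
    total = design.task_duration_s + 20.0
    times = [0.0]
    t = 0.0
    while t < total:
        hr = hr0 - (config.hr_coupling_bpm * z if t >= post_start else 0.0)
        base = 60.0 / max(hr, 30.0)
        mod = (
            1.0
            + config.lf_mod_amp * np.sin(2.0 * np.pi * 0.10 * t + phi_lf)
            + config.hf_mod_amp * np.sin(2.0 * np.pi * 0.25 * t + phi_hf)
        )
        iv = base * mod
        if config.rr_jitter_s > 0:
            iv += config.rr_jitter_s * rng.standard_normal()
        iv = float(np.clip(iv, 0.3, 2.0))
        t += iv
        times.append(t)
    return IntervalSeries(event_times=np.array(times))


def simulate_vas(
    config: SimulationConfig,
    subject: int,
    condition: str,
    oxy_response_z: float | None = None,
) -> dict[str, float]:
    """Seven VAS item scores (0-100, clipped) for one subject/condition.

    Hedonic items (enjoyment, arousal, motivation, like/dislike) load on
    the subject's responder z with weight ``vas_coupling``; the rest are
    independent noise around their configured condition means.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    z = subject_z(config, subject) if oxy_response_z is None else oxy_response_z
    rng = _stream(config.seed, subject, CONDITIONS.index(condition), 2)
    lam = config.vas_coupling
    out = {}
    for item in VAS_ITEMS:
        s_mean, s_sd, c_mean, c_sd, coupled = config.vas_params[item]
        mean, sd = (c_mean, c_sd) if condition == "creative" else (s_mean, s_sd)
        eps = rng.standard_normal()
        latent = lam * z + np.sqrt(max(1.0 - lam**2, 0.0)) * eps if coupled else eps
        out[item] = float(np.clip(mean + sd * latent, 0.0, 100.0))
    return out


def realized_oxy_z(
    config: SimulationConfig,
    channels: dict[str, HbChannelSeries],
    design: ExperimentDesign,
    channel: str = "ch1",
    period: int = 10,
) -> float:
    """A subject's realized oxy response as a z-score: the first post-task
    period's mean change rate in the given channel, standardised by the
    configured creative-condition target and between-subject SD."""
    from .stats import normalize_baseline, segment_periods

    rate = normalize_baseline(channels[channel].oxy_um, design)
    m = segment_periods(rate, design)[period]
    target = config.oxy_targets[("creative", channel)][period]
    sd = config.oxy_sds[("creative", channel)][period]
    if sd <= 0:
        return 0.0
    return float((m - target) / sd)


@dataclass
class SyntheticExperiment:
    """A complete simulated study: the analysis pipeline's input bundle."""

    config: SimulationConfig
    design: ExperimentDesign
    hb: dict            # (subject, condition) -> {channel: HbChannelSeries}
    rr: dict            # (subject, condition) -> IntervalSeries
    vas: pd.DataFrame   # columns: subject, condition, item, score
    manifest: dict


def simulate_experiment(
    config: SimulationConfig, design: ExperimentDesign | None = None
) -> SyntheticExperiment:
    """Generate the full study for ``config.n_subjects`` subjects under
    both conditions. Deterministic under ``config.seed``."""
    design = design or ExperimentDesign()
    hb, rr, vas_rows = {}, {}, []
    for i in range(config.n_subjects):
        for cond in CONDITIONS:
            hb[(i, cond)] = simulate_subject_hb(config, i, cond, design)
        # couple autonomic and subjective outputs to the subject's realized
        # creative-condition post-task oxy response
        z = realized_oxy_z(config, hb[(i, "creative")], design)
        for cond in CONDITIONS:
            rr[(i, cond)] = simulate_rr(config, i, cond, z, design)
            for item, score in simulate_vas(config, i, cond, z).items():
                vas_rows.append(
                    {"subject": i, "condition": cond, "item": item, "score": score}
                )
    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_subjects": config.n_subjects,
        "fidelity": config.fidelity,
    }
    return SyntheticExperiment(
        config=config,
        design=design,
        hb=hb,
        rr=rr,
        vas=pd.DataFrame(vas_rows),
        manifest=manifest,
    )
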