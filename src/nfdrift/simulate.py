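"""Multi-subject, trial-structured synthetic EEG with known ground truth.

The generator emulates a passive neurofeedback-like session: 4 conditions
(Control, 1 Hz, 5 Hz, 10 Hz circle-modification rates) × 8 trials of 60 s at
250 Hz on Fz/Cz/Pz, with condition order counterbalanced by a partial Latin
square.  Each channel-trial is a 1/f-shaped Gaussian background plus
narrowband oscillations (Gaussian spectral bumps) in the four canonical bands,
optionally a steady-state (SSVEP-like) sinusoid at the stimulation frequency
in the 5 and 10 Hz conditions.

Ground-truth effects are specified in z-units of the standardized band power
the downstream pipeline analyzes:

* ``alpha_trend`` — linear increase of alpha log-power per *global* trial
  (the spontaneous drift the study is about),
* ``theta_condition_effect`` — theta log-power increment in the three
  experimental conditions relative to Control, localized by default at Pz.

z-unit effects are converted to dB through a deterministic pre-run
calibration: band power is measured through the full analysis chain with
oscillations on and off, giving (i) the per-bin oscillation/background
profiles that map dB offsets onto oscillation-amplitude multipliers and
(ii) the spectral-estimation noise floor.  One z-unit is the pooled dB SD
the downstream z-scoring will divide by, computed exactly from the cohort's
own injected power offsets combined with that noise floor.  Between-subject
heterogeneity enters as per-subject band-power intercepts (dB) and
multiplicative perturbations of the effect sizes; trial-to-trial
physiological power fluctuations are injected as dB noise shared across
channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import FilterSpec, TrimSpec, preprocess_trial
from .recording import CONDITION_LABELS, DEFAULT_CHANNELS, TrialRecording
from .spectral import BANDS, SpectralConfig, band_power_table, welch_psd

logger = logging.getLogger(__name__)

#: Condition-order quadruplets of the partial Latin square (1-based condition
#: indices: 1=Control, 2=1Hz, 3=5Hz, 4=10Hz).
LATIN_SQUARE_QUADRUPLETS = ((2, 1, 4, 3), (1, 4, 3, 2), (3, 2, 1, 4), (4, 3, 2, 1))

_STIM_FREQ = {"1Hz": 1.0, "5Hz": 5.0, "10Hz": 10.0}

# fixed entropy stream: calibration is a deterministic property of a config,
# shared by all cohort seeds
_CAL_MAP_SEED = 202_401


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and signal parameters of the synthetic cohort.

    Defaults are the study conditions: 32 subjects, 4 × 8 × 60-s trials at
    250 Hz on Fz/Cz/Pz; effect magnitudes are the published estimates
    (alpha drift 0.02 z per trial, theta condition increment 0.165 z at Pz).
    Amplitude/noise defaults were chosen once so the synthetic band-power
    distributions match the published scales (band power of a few dB spread
    ≈ 2.6 dB pooled, credible-interval widths of the same order as printed).
    """

    n_subjects: int = 32
    n_conditions: int = 4
    n_trials_per_condition: int = 8
    trial_duration: float = 60.0
    sampling_rate: float = 250.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    aperiodic_exponent: float = 1.0
    aperiodic_knee: float = 2.0        # Hz; background PSD ∝ 1/(knee^χ + f^χ)
    aperiodic_amplitude: float = 12.0  # µV RMS of the aperiodic background
    band_amplitudes: tuple[tuple[str, float], ...] = (
        ("theta", 5.0), ("alpha", 10.0), ("smr", 3.0), ("beta", 4.0))  # µV

    alpha_trend: float = 0.02            # z-units of alpha log-power per global trial
    theta_condition_effect: float = 0.165  # z-units, experimental vs Control
    theta_effect_channels: tuple[str, ...] = ("Pz",)
    ssvep_amplitude: float = 0.0         # µV peak at the stimulation frequency
    ssvep_at_1hz: bool = False

    subject_sd: float = 0.25             # relative SD of per-subject effect sizes
    subject_intercept_db_sd: float = 2.5  # dB, per-subject per-band power offsets
    trial_power_db_sd: float = 0.3       # dB, trial-to-trial power fluctuation

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_conditions, self.n_trials_per_condition) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.n_conditions != 4:
            raise ConfigurationError("the task design has exactly 4 conditions")
        highest_edge = max(high for _, high in BANDS.values())
        if self.sampling_rate <= 2 * highest_edge:
            raise ConfigurationError(
                f"sampling_rate must exceed twice the highest band edge ({highest_edge} Hz)")
        if self.aperiodic_amplitude < 0 or self.ssvep_amplitude < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        if any(a < 0 for _, a in self.band_amplitudes):
            raise ConfigurationError("band amplitudes must be non-negative")
        if self.trial_duration <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("trial_duration and sampling_rate must be positive")

    @property
    def amplitude_map(self) -> dict[str, float]:
        return dict(self.band_amplitudes)

    @property
    def n_trials_total(self) -> int:
        return self.n_conditions * self.n_trials_per_condition

    @property
    def n_samples(self) -> int:
        return round(self.trial_duration * self.sampling_rate)


def latin_square_orders() -> list[tuple[int, ...]]:
    """The four counterbalancing quadruplets (each condition once per order,
    each condition in every temporal position across orders)."""
    return [tuple(q) for q in LATIN_SQUARE_QUADRUPLETS]


def assign_orders(n_subjects: int) -> list[tuple[int, ...]]:
    """Distribute subjects across the four quadruplets as evenly as possible."""
    orders = latin_square_orders()
    return [orders[i % len(orders)] for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# calibration: z-units and dB offsets → oscillation amplitude multipliers


class Calibration:
    """Maps band-power offsets in dB onto oscillation-amplitude multipliers.

    Band power is the *mean of per-bin dB values*, so scaling the oscillation
    by ``a`` shifts the measure by mean_f 10·log10((a²·s_osc(f) + s_bg(f)) /
    (s_osc(f) + s_bg(f))) over the band's bins — peak bins respond by the full
    20·log10(a), background-dominated edge bins barely move.  The calibration
    therefore stores the oscillation and background PSD profiles per band
    (measured through the full preprocessing/Welch chain with oscillations on
    and off) and inverts that exact response curve on a precomputed monotone
    grid.  ``sd_meas`` is the residual trial-to-trial SD of the band measure
    (dB) under fixed settings — the spectral-estimation noise floor.
    """

    _LOG_A_GRID = np.linspace(np.log(1e-3), np.log(1e3), 600)

    def __init__(self, profiles: dict[str, tuple[np.ndarray, np.ndarray]],
                 sd_meas: dict[str, float]):
        self.profiles = {b: (np.asarray(o, float), np.asarray(g, float))
                         for b, (o, g) in profiles.items()}
        self.sd_meas = dict(sd_meas)
        self._response: dict[str, np.ndarray] = {}

    def response_db(self, band: str, log_a: np.ndarray) -> np.ndarray:
        """Band-measure shift (dB) as a function of log amplitude multiplier."""
        s_osc, s_bg = self.profiles[band]
        a2 = np.exp(2.0 * np.asarray(log_a))[..., None]
        num = a2 * s_osc + s_bg
        den = s_osc + s_bg
        return np.mean(10.0 * np.log10(np.maximum(num, 1e-300) / den), axis=-1)

    def amplitude_multiplier(self, band: str, delta_db: np.ndarray) -> np.ndarray:
        """Invert the response curve: the amplitude factor whose band-measure
        shift equals ``delta_db`` (clipped to the achievable range)."""
        if band not in self._response:
            self._response[band] = self.response_db(band, self._LOG_A_GRID)
        grid = self._response[band]
        log_a = np.interp(np.asarray(delta_db, float), grid, self._LOG_A_GRID)
        return np.exp(log_a)


_CAL_CACHE: dict[tuple, Calibration] = {}


def _calibration_key(config: SimulationConfig) -> tuple:
    return (config.n_trials_per_condition, config.trial_duration, config.sampling_rate,
            config.channels, config.aperiodic_exponent, config.aperiodic_amplitude,
            config.band_amplitudes, config.subject_intercept_db_sd, config.trial_power_db_sd)


def _measure_chain(config: SimulationConfig):
    """Band-power table and trial-averaged linear PSD through the analysis chain."""
    recs = _simulate(config, None)
    recs = [preprocess_trial(r, FilterSpec(), TrimSpec()) for r in recs]
    table = band_power_table(recs, SpectralConfig())
    spectra = []
    freqs = None
    for rec in recs:
        for ch, psd in welch_psd(rec, SpectralConfig()).items():
            spectra.append(psd.power)
            freqs = psd.frequencies
    return table, freqs, np.mean(spectra, axis=0)


def get_calibration(config: SimulationConfig) -> Calibration:
    """Pre-run calibration of the dB→amplitude map (cached, deterministic).

    Two small effect-free runs through the full preprocessing/Welch chain:
    with oscillations on (total band power, and its trial-to-trial estimation
    noise ``sd_meas``) and with oscillations off (background band power).
    """
    key = _calibration_key(config)
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]

    base = replace(config, n_subjects=2, n_trials_per_condition=4,
                   alpha_trend=0.0, theta_condition_effect=0.0, ssvep_amplitude=0.0,
                   subject_intercept_db_sd=0.0, trial_power_db_sd=0.0, seed=_CAL_MAP_SEED)
    tbl_on, freqs, psd_on = _measure_chain(base)
    zero_amps = tuple((b, 0.0) for b, _ in config.band_amplitudes)
    _, _, psd_off = _measure_chain(replace(base, band_amplitudes=zero_amps))

    profiles = {}
    for band, (low, high) in BANDS.items():
        mask = (freqs >= low) & (freqs < high)
        s_bg = np.maximum(psd_off[mask], 1e-12)
        s_osc = np.maximum(psd_on[mask] - psd_off[mask], 0.0)
        profiles[band] = (s_osc, s_bg)
    sd_meas = {b: float(tbl_on.loc[tbl_on["band"] == b, "power_db"].std(ddof=0))
               for b in BANDS}

    cal = Calibration(profiles=profiles, sd_meas=sd_meas)
    _CAL_CACHE[key] = cal
    logger.info("calibration for %s: sd_meas=%s", key, sd_meas)
    return cal


# ---------------------------------------------------------------------------
# signal synthesis


def _band_bump(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    center = 0.5 * (low + high)
    width = (high - low) / 6.0
    return np.exp(-0.5 * ((freqs - center) / width) ** 2)


def _aperiodic_shape(freqs: np.ndarray, exponent: float, knee: float) -> np.ndarray:
    # Lorentzian-style aperiodic spectrum: PSD ∝ 1/(knee^χ + f^χ); the knee
    # bounds low-frequency power the way resting EEG spectra flatten below a
    # few Hz, so oscillatory peaks can dominate the PSD maximum
    shape = (knee ** exponent + freqs ** exponent) ** -0.5
    shape[0] = 0.0  # no DC
    return shape


def _colored_noise(rng: np.random.Generator, shape_f: np.ndarray,
                   n_series: int, n_samples: int) -> np.ndarray:
    """Independent Gaussian series with amplitude spectrum ``shape_f`` (unit-free)."""
    n_freq = shape_f.size
    spec = (rng.standard_normal((n_series, n_freq))
            + 1j * rng.standard_normal((n_series, n_freq))) * shape_f
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def _normalize_rms(x: np.ndarray, target_rms: np.ndarray | float) -> np.ndarray:
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    rms = np.where(rms > 0, rms, 1.0)
    return x * (np.asarray(target_rms)[..., None] / rms)


def _subject_conditions(config: SimulationConfig, order: tuple[int, ...]) -> list[str]:
    """Condition label of each global trial for one subject."""
    labels = []
    for cond_idx in order[: config.n_conditions]:
        labels.extend([CONDITION_LABELS[cond_idx - 1]] * config.n_trials_per_condition)
    return labels


def _simulate(config: SimulationConfig, cal: Calibration | None) -> list[TrialRecording]:
    uses_db_machinery = (config.subject_intercept_db_sd > 0 or config.trial_power_db_sd > 0
                         or config.alpha_trend != 0 or config.theta_condition_effect != 0)
    if uses_db_machinery and cal is None:
        raise ConfigurationError("internal: dB effects requested without calibration")

    n = config.n_samples
    fs = config.sampling_rate
    n_ch = len(config.channels)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band_names = list(BANDS)
    amps = config.amplitude_map
    orders = assign_orders(config.n_subjects)

    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(config.n_subjects)
    n_trials_total = config.n_trials_total

    # pass 1: subject-level parameters (so the cohort's realized z scale is
    # known before synthesis: one z-unit = pooled dB SD the analysis will see)
    params = []
    for sseed in subject_seeds:
        par_seed, sig_seed = sseed.spawn(2)
        rng_p = np.random.default_rng(par_seed)
        params.append({
            "intercept_db": rng_p.normal(0.0, config.subject_intercept_db_sd,
                                         size=len(band_names)),
            "slope": config.alpha_trend * (1.0 + config.subject_sd * rng_p.standard_normal()),
            "theta": config.theta_condition_effect * (
                1.0 + config.subject_sd * rng_p.standard_normal()),
            "trial_noise_db": rng_p.normal(0.0, config.trial_power_db_sd,
                                           size=(n_trials_total, len(band_names))),
            "signal_seed": sig_seed,
        })
    if cal is not None:
        offsets = np.stack([p["intercept_db"][None, :] + p["trial_noise_db"]
                            for p in params])            # (S, T, B)
        sd_meas = np.array([cal.sd_meas[b] for b in band_names])
        sd_ref = np.sqrt(offsets.reshape(-1, len(band_names)).var(axis=0) + sd_meas ** 2)
        sd_ref = np.maximum(sd_ref, 1e-6)
    else:
        sd_ref = np.ones(len(band_names))

    theta_ch_mask = np.array([ch in config.theta_effect_channels for ch in config.channels])
    recordings: list[TrialRecording] = []
    for i, (order, par) in enumerate(zip(orders, params)):
        rng = np.random.default_rng(par["signal_seed"])
        subject_id = f"S{i + 1:02d}"
        conds = _subject_conditions(config, order)
        n_trials = len(conds)

        intercept_db = par["intercept_db"]
        slope_i, theta_i = par["slope"], par["theta"]
        trial_noise_db = par["trial_noise_db"]

        # band-power offsets in dB, (trial, band, channel):
        #  - gain_db (power level: subject intercepts + trial fluctuations)
        #    scales the whole band content, background included, so the
        #    realized dB offset is exact;
        #  - effect_db (the z-unit ground-truth effects) scales only the
        #    oscillation amplitude through the calibrated map.
        gain_db = (intercept_db[None, :, None]
                   + trial_noise_db[:, :, None]) * np.ones((n_trials, 1, n_ch))
        effect_db = np.zeros((n_trials, len(band_names), n_ch))
        if cal is not None:
            g = np.arange(n_trials, dtype=float)  # global trial − 1
            ia, ith = band_names.index("alpha"), band_names.index("theta")
            effect_db[:, ia, :] += (slope_i * g * sd_ref[ia])[:, None]
            exp_mask = np.array([c != "Control" for c in conds], dtype=float)
            effect_db[:, ith, :] += ((theta_i * exp_mask * sd_ref[ith])[:, None]
                                     * theta_ch_mask[None, :])

        # aperiodic background with per-band level gains applied spectrally
        shape_ap = _aperiodic_shape(freqs, config.aperiodic_exponent, config.aperiodic_knee)
        n_freq = freqs.size
        spec = (rng.standard_normal((n_trials * n_ch, n_freq))
                + 1j * rng.standard_normal((n_trials * n_ch, n_freq))) * shape_ap
        x0 = np.fft.irfft(spec, n=n, axis=-1)
        rms0 = np.sqrt(np.mean(x0 ** 2, axis=-1))
        spec *= (config.aperiodic_amplitude / np.where(rms0 > 0, rms0, 1.0))[:, None]
        if np.any(gain_db != 0):
            gain_f = np.ones((n_trials, n_ch, n_freq))
            for b, name in enumerate(band_names):
                low, high = BANDS[name]
                mask = (freqs >= low) & (freqs < high)
                gain_f[:, :, mask] = 10.0 ** (gain_db[:, b, :, None] / 20.0)
            spec = spec.reshape(n_trials, n_ch, n_freq) * gain_f
        x = np.fft.irfft(spec.reshape(n_trials * n_ch, n_freq), n=n, axis=-1)
        x = x.reshape(n_trials, n_ch, n)

        # narrowband oscillations with per-trial amplitude multipliers
        for b, name in enumerate(band_names):
            amp = amps.get(name, 0.0)
            if amp == 0.0:
                continue
            mult = 10.0 ** (gain_db[:, b, :] / 20.0)
            if cal is not None:
                mult = mult * cal.amplitude_multiplier(name, effect_db[:, b, :])
            osc = _colored_noise(rng, _band_bump(freqs, *BANDS[name]), n_trials * n_ch, n)
            osc = osc.reshape(n_trials, n_ch, n)
            x += _normalize_rms(osc, amp / np.sqrt(2.0) * mult)

        # steady-state response at the stimulation frequency
        if config.ssvep_amplitude > 0:
            t = np.arange(n) / fs
            for trial, cond in enumerate(conds):
                f_stim = _STIM_FREQ.get(cond)
                if f_stim is None or (cond == "1Hz" and not config.ssvep_at_1hz):
                    continue
                phase = rng.uniform(0, 2 * np.pi)
                x[trial] += config.ssvep_amplitude * np.sin(2 * np.pi * f_stim * t + phase)

        for trial, cond in enumerate(conds):
            recordings.append(TrialRecording(
                subject_id=subject_id, condition=cond,
                trial_index=trial % config.n_trials_per_condition + 1,
                global_trial_index=trial + 1,
                channel_labels=config.channels, sampling_rate=fs,
                samples=x[trial],
            ))
    return recordings


def simulate_cohort(config: SimulationConfig | None = None) -> list[TrialRecording]:
    """Deterministic synthetic cohort; identical seeds give identical samples."""
    config = config or SimulationConfig()
    uses_db_machinery = (config.subject_intercept_db_sd > 0 or config.trial_power_db_sd > 0
                         or config.alpha_trend != 0 or config.theta_condition_effect != 0)
    cal = get_calibration(config) if uses_db_machinery else None
    return _simulate(config, cal)


# ---------------------------------------------------------------------------
# optional blink artifacts (exercise the pluggable removal stage)

_BLINK_WEIGHTS = {"Fp1": 1.0, "Fpz": 1.0, "Fp2": 1.0, "Fz": 0.8, "Cz": 0.35, "Pz": 0.12}


def blink_waveform(fs: float, width_s: float = 0.12) -> np.ndarray:
    """A smooth positive transient (Gaussian bump) spanning ±3 widths."""
    t = np.arange(-3 * width_s, 3 * width_s, 1.0 / fs)
    return np.exp(-0.5 * (t / width_s) ** 2)


def inject_artifacts(recordings: list[TrialRecording], blink_rate: float,
                     seed: int = 0, amplitude: float = 120.0,
                     return_reference: bool = False):
    """Add frontal-weighted blink transients at ``blink_rate`` events/s.

    With ``return_reference=True`` also returns, per trial, the pure artifact
    time course (the known mixing used by round-trip tests and by
    regression-based removers).
    """
    if blink_rate < 0:
        raise ConfigurationError("blink_rate must be >= 0")
    if blink_rate == 0:
        return (recordings, [None] * len(recordings)) if return_reference else recordings
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB11)))
    out, refs = [], []
    for rec in recordings:
        fs = rec.sampling_rate
        wave = blink_waveform(fs)
        ref = np.zeros(rec.n_samples)
        n_blinks = rng.poisson(blink_rate * rec.duration)
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, rec.n_samples - wave.size))
            ref[start:start + wave.size] += wave * amplitude * rng.uniform(0.7, 1.3)
        weights = np.array([_BLINK_WEIGHTS.get(ch, 0.3) for ch in rec.channel_labels])
        out.append(rec.with_samples(rec.samples + weights[:, None] * ref[None, :]))
        refs.append(ref)
    return (out, refs) if return_reference else out
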