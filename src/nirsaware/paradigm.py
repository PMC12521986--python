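"""Synthetic fNIRS command-following experiments with known ground truth.

A run follows the block-design imagery paradigm: a 40-s baseline, then six
blocks of five trials alternating between IMAGERY and NO-IMAGERY blocks; each
trial is a 1-s auditory cue, a 2-s task period and 15-s rest, giving a run of
580 s sampled at 6.94 Hz.  In the RESPONSIVE state the subject performs the
imagery task on IMAGERY trials, adding a hemodynamic response (canonical
double-gamma convolved with the 2-s task boxcar) to HbO/HbR on the cortical
channels.  In the UNRESPONSIVE state no trial carries any evoked response.

Concentration traces are contaminated with shared systemic physiology (a
slowly amplitude-modulated ~0.1-Hz Mayer wave, a ~1-Hz cardiac oscillation
and a linear drift, each entering every channel with a channel-specific gain)
plus white measurement noise.  The 1-cm short channel carries the systemic
components and noise but never the evoked response.  Concentrations are
mapped to raw two-wavelength intensities by the inverse of the modified
Beer-Lambert law so the full preprocessing chain can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.stats import gamma as gamma_dist

from .extinction import extinction_matrix
from .io import RawRecording
from .montage import Montage, default_montage

__all__ = [
    "State",
    "Condition",
    "ParadigmSpec",
    "GroundTruth",
    "SimulatedConcentrations",
    "generate_events",
    "double_gamma_hrf",
    "simulate_concentrations",
    "forward_to_intensity",
    "simulate_run",
    "simulate_dataset",
]


class State(str, Enum):
    RESPONSIVE = "RESPONSIVE"
    UNRESPONSIVE = "UNRESPONSIVE"


class Condition(str, Enum):
    IMAGERY = "IMAGERY"
    NO_IMAGERY = "NO_IMAGERY"


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and structure of one experimental run."""

    sampling_rate: float = 6.94
    baseline_s: float = 40.0
    n_blocks: int = 6
    trials_per_block: int = 5
    cue_s: float = 1.0
    task_s: float = 2.0
    rest_s: float = 15.0
    state: State = State.RESPONSIVE
    first_block_condition: Condition = Condition.IMAGERY

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ValueError("block and trial counts must be positive")
        for name in ("baseline_s", "cue_s", "task_s", "rest_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.trial_s <= 0:
            raise ValueError("trial period must be positive")

    @property
    def trial_s(self) -> float:
        """One trial's footprint: cue + task + rest."""
        return self.cue_s + self.task_s + self.rest_s

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def duration_s(self) -> float:
        return self.baseline_s + self.n_trials * self.trial_s

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.duration_s * self.sampling_rate))


@dataclass(frozen=True)
class GroundTruth:
    """Physics and physiology parameters of a simulated run.

    ``evoked_amplitude_hbo`` is the peak single-trial HbO excursion (uM) at
    the most responsive channel; the spatial profile over long channels is a
    smooth unimodal loading so a spatial filter has a pattern to find.  The
    HbR response mirrors HbO scaled by ``-hbr_ratio`` and lagged by
    ``hbr_lag_s``.  All noise amplitudes are concentration-domain (uM) except
    ``intensity_noise_sd``, which is multiplicative white noise applied in
    the optical (log-intensity) domain.
    """

    evoked_amplitude_hbo: float = 0.3
    hbr_ratio: float = 1.0 / 3.0
    hbr_lag_s: float = 1.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    mayer_amp: float = 0.4
    mayer_freq: float = 0.1
    cardiac_amp: float = 0.15
    cardiac_freq: float = 1.1
    drift_slope: float = 0.002
    white_noise_sd: float = 0.25
    short_channel_noise_factor: float = 0.3
    intensity_noise_sd: float = 5e-4
    evoked_center: float = 0.45
    evoked_width: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mayer_amp", "cardiac_amp", "white_noise_sd",
                     "intensity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.evoked_amplitude_hbo < 0:
            raise ValueError("evoked_amplitude_hbo must be non-negative")

    def channel_amplitudes(self, montage: Montage) -> np.ndarray:
        """Per-channel peak HbO amplitude (uM), zero on the short channel.

        A Gaussian loading over the ordered long channels, centred at
        fraction ``evoked_center`` of the channel list with width
        ``evoked_width`` (fractions of the list length), peaking at
        ``evoked_amplitude_hbo``.
        """
        amps = np.zeros(montage.n_channels)
        idx = montage.long_indices
        x = np.linspace(0.0, 1.0, len(idx))
        profile = np.exp(-0.5 * ((x - self.evoked_center) / self.evoked_width) ** 2)
        amps[idx] = self.evoked_amplitude_hbo * profile
        return amps


@dataclass
class SimulatedConcentrations:
    """Per-channel concentration traces plus the injected ground truth."""

    hbo: np.ndarray            # (n_channels, n_samples), uM
    hbr: np.ndarray            # (n_channels, n_samples), uM
    evoked_hbo: np.ndarray     # (n_channels, n_samples), uM: evoked component only
    mayer: np.ndarray          # (n_samples,): the shared Mayer source, uM
    sampling_rate: float
    events: pd.DataFrame
    spec: ParadigmSpec
    truth: GroundTruth


def generate_events(spec: ParadigmSpec, seed: int | None = None) -> pd.DataFrame:
    """Event table for one run: one row per trial at cue onset.

    Conditions alternate block-wise starting from
    ``spec.first_block_condition``; onsets are spaced by the trial period.
    The ``seed`` argument is accepted for interface symmetry -- the block
    design is deterministic, randomness enters only through the condition
    order chosen via ``first_block_condition``.
    """
    rows = []
    for b in range(spec.n_blocks):
        if b % 2 == 0:
            cond = spec.first_block_condition
        else:
            cond = (Condition.NO_IMAGERY
                    if spec.first_block_condition == Condition.IMAGERY
                    else Condition.IMAGERY)
        for t in range(spec.trials_per_block):
            onset = spec.baseline_s + (b * spec.trials_per_block + t) * spec.trial_s
            rows.append((onset, spec.cue_s + spec.task_s, cond.value))
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response.

    Two gamma densities with modes at ``peak_s`` and ``undershoot_s`` (shape
    parameters 6 and 12), the undershoot subtracted with weight
    ``undershoot_ratio``; the result is normalized to unit peak.
    """
    t = np.asarray(t, dtype=float)
    a1, a2 = 6.0, 12.0
    h = (gamma_dist.pdf(t, a1, scale=peak_s / (a1 - 1.0))
         - undershoot_ratio * gamma_dist.pdf(t, a2, scale=undershoot_s / (a2 - 1.0)))
    peak = h.max()
    return h / peak if peak > 0 else h


def _trial_template(spec: ParadigmSpec, truth: GroundTruth) -> np.ndarray:
    """Unit-peak single-trial HbO response, time-locked to task onset."""
    fs = spec.sampling_rate
    n = int(np.ceil((truth.hrf_undershoot_s + 16.0 + spec.task_s) * fs))
    t = np.arange(n) / fs
    hrf = double_gamma_hrf(t, truth.hrf_peak_s, truth.hrf_undershoot_s,
                           truth.hrf_undershoot_ratio)
    boxcar = (t < spec.task_s).astype(float)
    resp = np.convolve(boxcar, hrf)[:n]
    peak = resp.max()
    return resp / peak if peak > 0 else resp


def _narrowband(rng: np.random.Generator, n: int, fs: float, center_hz: float,
                halfwidth_hz: float, rms: float) -> np.ndarray:
    """Gaussian noise band-passed around ``center_hz``, scaled to ``rms``.

    Emulates a quasi-periodic physiological oscillation whose phase and
    envelope wander on the timescale of ``1 / halfwidth_hz``.
    """
    if rms == 0 or n < 12:
        return np.zeros(n)
    nyq = fs / 2.0
    lo = max(center_hz - halfwidth_hz, 1e-3) / nyq
    hi = min(center_hz + halfwidth_hz, 0.99 * nyq) / nyq
    b, a = butter(2, [lo, hi], btype="band")
    x = filtfilt(b, a, rng.standard_normal(n))
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def simulate_concentrations(spec: ParadigmSpec, montage: Montage,
                            truth: GroundTruth) -> SimulatedConcentrations:
    """Generate HbO/HbR concentration traces (uM) for one run."""
    fs = spec.sampling_rate
    n = spec.n_samples
    t = np.arange(n) / fs
    rng = np.random.default_rng(truth.seed)
    events = generate_events(spec)

    # --- evoked component ---------------------------------------------------
    amps = truth.channel_amplitudes(montage)
    if spec.state == State.UNRESPONSIVE:
        amps = np.zeros_like(amps)
    template = _trial_template(spec, truth)
    stick = np.zeros(n)
    for _, ev in events.iterrows():
        if ev["trial_type"] == Condition.IMAGERY.value:
            i = int(round((ev["onset"] + spec.cue_s) * fs))
            if i < n:
                stick[i] = 1.0
    evoked_shape = np.convolve(stick, template)[:n]
    lag = int(round(truth.hbr_lag_s * fs))
    evoked_shape_hbr = np.roll(evoked_shape, lag)
    evoked_shape_hbr[:lag] = 0.0
    evoked_hbo = amps[:, None] * evoked_shape[None, :]
    evoked_hbr = -truth.hbr_ratio * amps[:, None] * evoked_shape_hbr[None, :]

    # --- systemic physiology (shared sources, channel-specific gains) -------
    # narrowband noise, not pure sinusoids: physiological oscillations drift
    # in phase and amplitude, so they must not be phase-locked to the trial
    # grid (a locked oscillation would masquerade as task structure)
    mayer = _narrowband(rng, n, fs, truth.mayer_freq, 0.2 * truth.mayer_freq,
                        truth.mayer_amp / np.sqrt(2.0))
    cardiac = _narrowband(rng, n, fs, truth.cardiac_freq,
                          0.1 * truth.cardiac_freq,
                          truth.cardiac_amp / np.sqrt(2.0))
    drift = truth.drift_slope * (t - t.mean())
    n_ch = montage.n_channels
    gain_sys = rng.lognormal(mean=0.0, sigma=0.25, size=n_ch)
    gain_drift = rng.normal(loc=1.0, scale=0.3, size=n_ch)
    systemic = (gain_sys[:, None] * (mayer + cardiac)[None, :]
                + gain_drift[:, None] * drift[None, :])

    hbr_sys_gain = 0.25   # systemic fluctuations are predominantly arterial (HbO)
    noise_hbo = rng.normal(0.0, truth.white_noise_sd, size=(n_ch, n))
    noise_hbr = rng.normal(0.0, 0.5 * truth.white_noise_sd, size=(n_ch, n))
    # the 1-cm channel collects roughly an order of magnitude more light
    # than the 3-cm channels, so its measurement noise is much lower; a
    # noisy short channel would attenuate the regression coefficient and
    # defeat the systemic-noise removal
    sci = montage.short_channel_index
    noise_hbo[sci] *= truth.short_channel_noise_factor
    noise_hbr[sci] *= truth.short_channel_noise_factor

    hbo = evoked_hbo + systemic + noise_hbo
    hbr = evoked_hbr + hbr_sys_gain * systemic + noise_hbr
    return SimulatedConcentrations(
        hbo=hbo, hbr=hbr, evoked_hbo=evoked_hbo, mayer=mayer,
        sampling_rate=fs, events=events, spec=spec, truth=truth,
    )


def forward_to_intensity(conc: SimulatedConcentrations, montage: Montage,
                         truth: GroundTruth, ppf: float = 6.0,
                         i0: float = 1.0) -> RawRecording:
    """Map concentrations to raw intensities via the Beer-Lambert forward model.

    ``dOD(lambda, t) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * ppf``
    with concentrations in mol/L and separations in cm, then
    ``I = i0 * exp(-dOD)`` with multiplicative log-normal measurement noise of
    standard deviation ``truth.intensity_noise_sd`` in the log domain.
    """
    E = extinction_matrix(montage.wavelengths_nm)  # (2 wavelengths, 2 chromo)
    c = np.stack([conc.hbo, conc.hbr], axis=1) * 1e-6  # (n_ch, 2, n) in M
    od = np.einsum("wk,ckn->cwn", E, c) * (
        montage.distances_cm[:, None, None] * ppf
    )
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x0D]))
    if truth.intensity_noise_sd > 0:
        od = od + rng.normal(0.0, truth.intensity_noise_sd, size=od.shape)
    intensities = i0 * np.exp(-od)
    return RawRecording(
        intensities=intensities,
        sampling_rate=conc.sampling_rate,
        montage=montage,
        events=conc.events,
        annotations={
            "state": conc.spec.state.value,
            "ppf": ppf,
            "ground_truth": {
                k: (v.value if isinstance(v, Enum) else v)
                for k, v in vars(truth).items()
            },
        },
    )


def simulate_run(spec: ParadigmSpec, montage: Montage | None = None,
                 truth: GroundTruth | None = None, ppf: float = 6.0,
                 ) -> tuple[RawRecording, SimulatedConcentrations]:
    """Simulate one run end to end: concentrations and raw intensities."""
    montage = montage if montage is not None else default_montage()
    truth = truth if truth is not None else GroundTruth()
    conc = simulate_concentrations(spec, montage, truth)
    return forward_to_intensity(conc, montage, truth, ppf=ppf), conc


def simulate_dataset(state: State | str, n_runs: int = 2, seed: int = 0,
                     montage: Montage | None = None,
                     truth: GroundTruth | None = None,
                     ) -> list[RawRecording]:
    """Simulate one participant-state dataset (default: two runs).

    Runs alternate the condition of the first block, mirroring the
    counterbalancing of the block order across runs; per-run noise seeds are
    derived from ``seed``.
    """
    state = State(state)
    montage = montage if montage is not None else default_montage()
    base = truth if truth is not None else GroundTruth()
    runs = []
    for r in range(n_runs):
        first = Condition.IMAGERY if r % 2 == 0 else Condition.NO_IMAGERY
        spec = ParadigmSpec(state=state, first_block_condition=first)
        run_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0]
                       % (2 ** 31))
        rt = replace(base, seed=run_seed)
        rec, _ = simulate_run(spec, montage, rt)
        runs.append(rec)
    return runs
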