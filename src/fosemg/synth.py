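"""Synthetic HD-SEMG and force generator.

Surface EMG is modelled phenomenologically as amplitude modulation: each
latent component k has a time-invariant spatial pattern over the electrode
grid (a 2-D Gaussian footprint) and a nonnegative activation curve; channel
c records

    s_c(t) = sum_k W[c, k] * h_k(t) * n_k(t) + eps_c(t)

where n_k are independent zero-mean, unit-variance carriers band-limited to
the surface-EMG band (20-500 Hz) and eps is white measurement noise. The
carriers are independent across components so the independence assumption
of ICA is satisfiable by construction, and rectification + low-pass
filtering demodulates each channel back to its pattern-weighted sum of
curves.

Activation curves follow the isometric ramp-and-hold protocol: a linear
ramp from zero to the target fraction of maximum voluntary contraction,
then a constant hold. Force is synthesized from the true activation
signals through functions of the FOS candidate pool, which guarantees the
force model is realizable and gives every downstream test a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import GridSpec, InvalidArgumentError, ProtocolSpec, SignalMatrix
from .fos import DUAL_POOL_NAMES, SINGLE_POOL_NAMES, basis_function
from .preprocess import lowpass_envelope, normalize_to_max

__all__ = [
    "GridSpec",
    "ProtocolSpec",
    "GroundTruth",
    "MuscleScenario",
    "TrialRecording",
    "StudySession",
    "make_activation_curves",
    "make_activation_patterns",
    "synthesize_hdsemg",
    "synthesize_force",
    "lever_force",
    "simulate_study",
    "default_agonist_scenario",
    "default_antagonist_scenario",
    "DEFAULT_FORCE_COEFFS",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible 31-bit child seeds from one integer seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


@dataclass
class GroundTruth:
    """Generative parameters behind one synthetic session."""

    patterns_true: np.ndarray  # channels x components
    curves_true: np.ndarray  # components x samples
    force_coeffs: dict[str, float]
    lever_arms: tuple[float, float] = (1.0, 1.0)  # (L_elbow, L_wrist)

    def __post_init__(self) -> None:
        self.patterns_true = np.asarray(self.patterns_true, dtype=float)
        self.curves_true = np.asarray(self.curves_true, dtype=float)
        if np.any(self.curves_true < 0):
            raise InvalidArgumentError("true curves must be nonnegative")
        if np.any(np.linalg.norm(self.patterns_true, axis=0) <= 0):
            raise InvalidArgumentError("pattern columns must have positive norm")
        valid = set(DUAL_POOL_NAMES) | set(SINGLE_POOL_NAMES)
        unknown = set(self.force_coeffs) - valid
        if unknown:
            raise InvalidArgumentError(f"force coefficients reference unknown functions: {sorted(unknown)}")


def make_activation_curves(
    protocol: ProtocolSpec,
    n_components: int,
    shape_jitter: float = 0.0,
    seed: int = 0,
    onset_delays: list[float] | None = None,
    plateau_drifts: list[float] | None = None,
) -> np.ndarray:
    """Trapezoidal activation curves, one row per component.

    Each curve ramps linearly from 0 to ``protocol.target_level`` over the
    ramp duration and holds the target for the rest of the trial.
    ``shape_jitter`` perturbs each curve multiplicatively by
    ``1 + shape_jitter * z(t)`` where z is smooth low-frequency noise
    clipped to [-1, 1], so the deviation from the ideal trapezoid never
    exceeds ``shape_jitter * target_level`` and curves stay nonnegative.

    Two optional per-component deviations from the ideal trapezoid model
    load sharing between muscle regions during a sustained contraction:
    ``onset_delays`` shifts the ramp start of individual components
    (seconds, components recruited later), and ``plateau_drifts`` lets a
    component's plateau drift linearly to ``target * (1 + drift)`` by the
    trial end (negative drift: the region de-recruits while others take
    over). Both default to zero, giving the exact trapezoid.
    """
    if n_components < 1:
        raise InvalidArgumentError("n_components must be at least 1")
    if not (0.0 <= shape_jitter < 1.0):
        raise InvalidArgumentError("shape_jitter must be in [0, 1)")
    if onset_delays is None:
        onset_delays = [0.0] * n_components
    if plateau_drifts is None:
        plateau_drifts = [0.0] * n_components
    if len(onset_delays) != n_components or len(plateau_drifts) != n_components:
        raise InvalidArgumentError("one onset delay and drift per component required")

    t = protocol.times
    curves = np.empty((n_components, protocol.n_samples))
    for k, (delay, drift) in enumerate(zip(onset_delays, plateau_drifts)):
        if delay < 0 or delay + protocol.ramp_duration > protocol.trial_duration:
            raise InvalidArgumentError("onset delay pushes the ramp past the trial end")
        if drift < -1.0:
            raise InvalidArgumentError("plateau drift below -1 makes the curve negative")
        ramp = (t - delay) / protocol.ramp_duration
        curve = protocol.target_level * np.clip(ramp, 0.0, 1.0)
        ramp_end = delay + protocol.ramp_duration
        hold = protocol.trial_duration - ramp_end
        if drift != 0.0 and hold > 0:
            frac = np.clip((t - ramp_end) / hold, 0.0, 1.0)
            curve = curve * (1.0 + drift * frac)
        curves[k] = curve

    if shape_jitter > 0:
        for k, s in enumerate(_child_seeds(seed, n_components)):
            rng = np.random.default_rng(s)
            rough = rng.standard_normal(protocol.n_samples)
            smooth = lowpass_envelope(rough, protocol.sampling_rate, cutoff=1.0)
            peak = np.max(np.abs(smooth))
            if peak > 0:
                smooth = np.clip(smooth / peak, -1.0, 1.0)
            curves[k] *= 1.0 + shape_jitter * smooth
    return curves


def make_activation_patterns(
    grid: GridSpec,
    n_components: int,
    centers: list[tuple[float, float]],
    width,
    seed: int = 0,
    floor: float = 0.02,
    channel_gain_jitter: float = 0.0,
) -> np.ndarray:
    """Spatial activation patterns: one Gaussian footprint per component.

    Column k is a 2-D Gaussian bump over the grid (row-major channel
    order), peak 1 at ``centers[k]``, resting on a small positive floor so
    every electrode sees some activity. ``width`` (standard deviation in
    electrode pitches) may be a scalar or one value per component;
    footprints of different widths are how spatial activation
    heterogeneity is emulated. ``channel_gain_jitter`` applies one shared
    multiplicative gain ``1 + jitter*u``, u ~ U(-1, 1), per electrode,
    emulating electrode-to-electrode gain differences.
    """
    if len(centers) != n_components:
        raise InvalidArgumentError("one center per component required")
    widths = np.broadcast_to(np.asarray(width, dtype=float), (n_components,))
    if not (0.0 <= floor < 1.0):
        raise InvalidArgumentError("floor must be in [0, 1)")

    rows, cols = np.divmod(np.arange(grid.n_channels), grid.n_cols)
    patterns = np.empty((grid.n_channels, n_components))
    for k, (cr, cc) in enumerate(centers):
        if not (0 <= cr <= grid.n_rows - 1 and 0 <= cc <= grid.n_cols - 1):
            raise InvalidArgumentError(f"center {(cr, cc)} outside grid")
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        if widths[k] < 1e-9:
            bump = (d2 == 0).astype(float)
        else:
            bump = np.exp(-d2 / (2.0 * widths[k] ** 2))
        patterns[:, k] = (1.0 - floor) * bump + floor
    if channel_gain_jitter > 0:
        rng = np.random.default_rng(seed)
        gains = 1.0 + channel_gain_jitter * rng.uniform(-1.0, 1.0, grid.n_channels)
        patterns *= gains[:, None]
    return patterns


def _bandlimited_carrier(
    rng: np.random.Generator, n_samples: int, sampling_rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Zero-mean unit-variance Gaussian noise band-passed with a zero-phase FIR."""
    lo, hi = band
    nyq = sampling_rate / 2.0
    if not (0 < lo < nyq) or hi <= lo:
        raise InvalidArgumentError("carrier band must satisfy 0 < low < high <= Nyquist")
    numtaps = 251
    if hi >= 0.999 * nyq:
        taps = sps.firwin(numtaps, lo, pass_zero=False, fs=sampling_rate)
    else:
        taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=sampling_rate)
    x = rng.standard_normal(n_samples)
    x = sps.filtfilt(taps, [1.0], x, padlen=min(3 * numtaps, n_samples - 1))
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_hdsemg(
    patterns_true: np.ndarray,
    curves_true: np.ndarray,
    carrier_band: tuple[float, float] = (20.0, 500.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 1000.0,
    grid: GridSpec | None = None,
    muscle_label: str = "agonist",
) -> SignalMatrix:
    """Amplitude-modulated multichannel SEMG from patterns and curves.

    Each component modulates its own independent band-limited carrier; white
    noise of standard deviation ``noise_sd`` is added per channel.
    """
    W = np.asarray(patterns_true, dtype=float)
    H = np.asarray(curves_true, dtype=float)
    if W.ndim != 2 or H.ndim != 2 or W.shape[1] != H.shape[0]:
        raise InvalidArgumentError("patterns columns must match curves rows")
    n_comp, n_samples = H.shape
    carrier_seed, noise_seed = _child_seeds(seed, 2)
    carrier_rng = np.random.default_rng(carrier_seed)
    carriers = np.vstack(
        [_bandlimited_carrier(carrier_rng, n_samples, sampling_rate, carrier_band) for _ in range(n_comp)]
    )
    data = W @ (H * carriers)
    if noise_sd > 0:
        data = data + noise_sd * np.random.default_rng(noise_seed).standard_normal(data.shape)
    elif noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be nonnegative")
    if grid is None:
        if W.shape[0] == 32:
            grid = GridSpec()
        else:
            raise InvalidArgumentError("grid must be given for non-4x8 channel counts")
    return SignalMatrix(data, sampling_rate, grid, muscle_label)


def synthesize_force(
    h_bi,
    h_tr,
    force_coeffs: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Force trace as a named combination of candidate-pool functions.

    ``force_coeffs`` maps basis-function names (e.g. ``"H_BI"``,
    ``"H_TR^2"``, ``"bias"``) to coefficients; building force this way
    guarantees the FOS model can represent it exactly in the noiseless
    case.
    """
    from .core import signal_values

    signals = {"H_BI": signal_values(h_bi), "H_TR": signal_values(h_tr)}
    if signals["H_BI"].size != signals["H_TR"].size:
        raise InvalidArgumentError("activation signals must have equal length")
    signals["H"] = signals["H_BI"]
    y = np.zeros(signals["H_BI"].size)
    for name, coeff in force_coeffs.items():
        y += float(coeff) * basis_function(name)(signals)
    if noise_sd > 0:
        y = y + noise_sd * np.random.default_rng(seed).standard_normal(y.size)
    elif noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be nonnegative")
    return y


def lever_force(f_elbow: float, l_elbow: float, l_wrist: float) -> float:
    """Static lever balance: the wrist force equivalent of an elbow force.

    The isometric task is static, so moments about the elbow joint sum to
    zero: F_wrist * L_wrist + F_elbow * L_elbow = 0.
    """
    if l_wrist == 0:
        raise InvalidArgumentError("wrist lever arm must be nonzero")
    return -f_elbow * l_elbow / l_wrist


# ---------------------------------------------------------------------------
# Study-level simulation (repetitions of agonist + antagonist grids + force)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MuscleScenario:
    """Spatial and load-sharing layout of one muscle's latent components.

    The muscle's net drive follows the tracked ramp-and-hold profile; how
    that drive is shared among the components varies randomly from
    repetition to repetition within ``share_range`` (and drifts smoothly
    within a trial by up to ``share_drift``), emulating variable load
    sharing among regions of a muscle whose summed output is under
    feedback control.
    """

    centers: tuple[tuple[float, float], ...]
    widths: tuple[float, ...]
    share_range: tuple[float, float] = (0.25, 0.75)
    share_drift: float = 0.25
    onset_delay: float = 0.0
    curve_scale: float = 1.0
    grid: GridSpec = field(default_factory=GridSpec)

    @property
    def n_components(self) -> int:
        return len(self.centers)


def default_agonist_scenario() -> MuscleScenario:
    """Two-headed agonist with strong spatial heterogeneity.

    One concentrated and one diffuse footprint share the drive; because
    averaging all channels weights each region by its footprint size, the
    repetition-to-repetition variation of the load share contaminates the
    averaged envelope but cancels in the (equal-weight) sum of separated
    activation curves.
    """
    return MuscleScenario(
        centers=((1.0, 1.0), (2.0, 6.0)),
        widths=(0.7, 1.5),
    )


def default_antagonist_scenario() -> MuscleScenario:
    """Three-headed antagonist co-contracting at half the agonist drive."""
    return MuscleScenario(
        centers=((0.0, 1.0), (3.0, 4.0), (1.0, 7.0)),
        widths=(0.7, 1.1, 0.9),
        onset_delay=0.3,
        curve_scale=0.5,
    )


def split_load(
    drive: np.ndarray,
    n_components: int,
    rng: np.random.Generator,
    share_range: tuple[float, float],
    share_drift: float,
) -> np.ndarray:
    """Split one net drive into component curves with random load shares.

    Component shares start from a random point of the simplex (uniform on
    ``share_range`` per component, then normalized) and drift linearly to
    another random point over the trial, so the shares sum to 1 at every
    sample and the component curves always add back to ``drive``.
    """
    lo, hi = share_range
    if not (0.0 <= lo < hi):
        raise InvalidArgumentError("share_range must satisfy 0 <= lo < hi")
    if n_components == 1:
        return drive[None, :].copy()
    start = rng.uniform(lo, hi, n_components)
    end = np.clip(start + rng.uniform(-share_drift, share_drift, n_components), lo, hi)
    start /= start.sum()
    end /= end.sum()
    frac = np.linspace(0.0, 1.0, drive.size)
    shares = start[:, None] + (end - start)[:, None] * frac[None, :]
    return shares * drive[None, :]


#: Default ground-truth force composition: mostly linear in the agonist
#: drive with a quadratic term and a small antagonist contribution.
DEFAULT_FORCE_COEFFS: dict[str, float] = {"H_BI": 0.6, "H_BI^2": 0.3, "H_TR": 0.1}


@dataclass
class TrialRecording:
    """One repetition: both grids, the force trace, and its ground truth."""

    agonist: SignalMatrix
    antagonist: SignalMatrix
    force: np.ndarray
    h_bi_true: np.ndarray
    h_tr_true: np.ndarray


@dataclass
class StudySession:
    """All repetitions of one synthetic session at one force level."""

    protocol: ProtocolSpec
    repetitions: list[TrialRecording]
    truth_agonist: GroundTruth
    truth_antagonist: GroundTruth
    force_coeffs: dict[str, float]


def simulate_study(
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    agonist: MuscleScenario | None = None,
    antagonist: MuscleScenario | None = None,
    force_coeffs: dict[str, float] | None = None,
    carrier_band: tuple[float, float] = (20.0, 500.0),
    emg_noise_sd: float = 0.02,
    force_noise_sd: float = 0.01,
    shape_jitter: float = 0.05,
    channel_gain_jitter: float = 0.3,
) -> StudySession:
    """Simulate one session: ``protocol.n_repetitions`` ramp-and-hold trials.

    The net drive of each muscle tracks the ramp-and-hold target (with
    smooth trial-to-trial jitter); within each repetition that drive is
    split among the muscle's components with randomly drawn load shares,
    so the spatial distribution of activity varies between repetitions
    while the summed drive, and hence the force, stays reproducible.
    Spatial patterns are fixed across repetitions, as they are anatomical;
    carriers and measurement noise are redrawn per repetition. Force is
    synthesized from the max-normalized true drives through
    ``force_coeffs`` plus white sensor noise.
    """
    protocol = protocol or ProtocolSpec()
    agonist = agonist or default_agonist_scenario()
    antagonist = antagonist or default_antagonist_scenario()
    force_coeffs = dict(force_coeffs or DEFAULT_FORCE_COEFFS)

    pat_seed_ag, pat_seed_ant, *rep_seeds = _child_seeds(seed, 2 + protocol.n_repetitions)
    w_ag = make_activation_patterns(
        agonist.grid, agonist.n_components, list(agonist.centers), agonist.widths,
        seed=pat_seed_ag, channel_gain_jitter=channel_gain_jitter,
    )
    w_ant = make_activation_patterns(
        antagonist.grid, antagonist.n_components, list(antagonist.centers), antagonist.widths,
        seed=pat_seed_ant, channel_gain_jitter=channel_gain_jitter,
    )

    repetitions = []
    first_curves = {}
    for rep, rep_seed in enumerate(rep_seeds):
        seeds = _child_seeds(rep_seed, 7)
        drive_ag = make_activation_curves(
            protocol, 1, shape_jitter, seeds[0], onset_delays=[agonist.onset_delay]
        )[0] * agonist.curve_scale
        drive_ant = make_activation_curves(
            protocol, 1, shape_jitter, seeds[1], onset_delays=[antagonist.onset_delay]
        )[0] * antagonist.curve_scale
        h_ag = split_load(
            drive_ag, agonist.n_components, np.random.default_rng(seeds[2]),
            agonist.share_range, agonist.share_drift,
        )
        h_ant = split_load(
            drive_ant, antagonist.n_components, np.random.default_rng(seeds[3]),
            antagonist.share_range, antagonist.share_drift,
        )
        s_ag = synthesize_hdsemg(
            w_ag, h_ag, carrier_band, emg_noise_sd, seeds[4],
            protocol.sampling_rate, agonist.grid, "agonist",
        )
        s_ant = synthesize_hdsemg(
            w_ant, h_ant, carrier_band, emg_noise_sd, seeds[5],
            protocol.sampling_rate, antagonist.grid, "antagonist",
        )
        h_bi_true = normalize_to_max(h_ag.sum(axis=0))
        h_tr_true = normalize_to_max(h_ant.sum(axis=0))
        force = synthesize_force(h_bi_true, h_tr_true, force_coeffs, force_noise_sd, seeds[6])
        repetitions.append(TrialRecording(s_ag, s_ant, force, h_bi_true, h_tr_true))
        if rep == 0:
            first_curves = {"agonist": h_ag, "antagonist": h_ant}

    return StudySession(
        protocol=protocol,
        repetitions=repetitions,
        truth_agonist=GroundTruth(w_ag, first_curves["agonist"], force_coeffs),
        truth_antagonist=GroundTruth(w_ant, first_curves["antagonist"], force_coeffs),
        force_coeffs=force_coeffs,
    )
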