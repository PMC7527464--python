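"""Synthetic-night generator.

Produces complete synthetic recordings -- multi-channel raw signals, a
channel map, a 30 s-epoch hypnogram, an artifact mask and the ground-truth
SOZ side -- with the statistical structure the analysis assumes:

* channels consistent with the surrogate null hypothesis: a stationary
  linear stochastic correlated Gaussian process (an AR(2) resonance)
  observed through an invertible static nonlinearity ``y = x + c*x^3``;
* SOZ-hemisphere channels additionally carry a nonlinear deterministic
  component (first coordinate of the Roessler flow, time-scaled so its
  dominant period is about 1 s), whose amplitude is modulated by sleep
  stage (non-REM > wake > REM);
* the acquisition geometry of the real pipeline: 8 macro contacts per
  depth electrode sharing a correlated background (so bipolar referencing
  is meaningful), 8 recording wires per micro bundle, native 2048 Hz.

Everything is a pure function of the configuration, including its master
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import lfilter

from psilat.hypnogram import Hypnogram
from psilat.preprocess import ArtifactMask, ChannelMap, Electrode, STAGES

__all__ = [
    "NightConfig",
    "NightData",
    "ar2_coefficients",
    "generate_null_channel",
    "generate_null_windows",
    "generate_soz_channel",
    "roessler_first_coordinate",
    "henon_first_coordinate",
    "generate_night",
    "reduced_night_config",
]

#: default sleep-stage modulation of the deterministic component:
#: strongest during non-REM sleep, weakest during REM
DEFAULT_STAGE_MODULATION = {"W": 0.5, "REM": 0.25, "N1": 0.75, "N2": 1.0, "N3": 1.0}

#: default hypnogram cycle as (stage, number of 30 s epochs); repeated
#: until the night is covered (120 epochs = 1 h per cycle)
DEFAULT_STAGE_CYCLE = (("W", 40), ("N1", 10), ("N2", 30), ("N3", 20), ("REM", 20))

#: compressed cycle for scaled-down validation runs: every stage appears
#: in 2-minute runs, so a 10-minute night covers the full cycle
REDUCED_STAGE_CYCLE = (("W", 4), ("N1", 4), ("N2", 4), ("N3", 4), ("REM", 4))


@dataclass(frozen=True)
class NightConfig:
    """Study conditions of one synthetic night.

    The null process is parameterized by a resonance frequency and
    bandwidth (Hz) from which stable AR(2) coefficients are derived at
    whatever sampling rate a channel is generated at.  ``effect_size`` is
    the amplitude of the deterministic component relative to the noise
    standard deviation *in the referenced channel* (bipolar difference or
    bundle-mean-referenced wire).
    """

    n_electrodes_per_hemisphere: int = 6
    contacts_per_electrode: int = 8
    wires_per_bundle: int = 8
    duration_hours: float = 13.6
    raw_rate: float = 2048.0
    soz_side: str = "L"
    effect_size: float = 2.0
    stage_modulation: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_MODULATION))
    stage_cycle: tuple = DEFAULT_STAGE_CYCLE
    resonance_hz: float = 0.0
    bandwidth_hz: float = 60.0
    measurement_cubic: float = 0.1
    artifact_rate: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.soz_side not in ("L", "R"):
            raise ValueError("soz_side must be 'L' or 'R'")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.contacts_per_electrode != 8 or self.wires_per_bundle != 8:
            raise ValueError("hybrid-electrode geometry requires 8 contacts and 8 wires")
        a1, a2 = ar2_coefficients(self.resonance_hz, self.bandwidth_hz, self.raw_rate)
        # stability of the AR(2): roots of z^2 - a1 z - a2 inside unit circle
        roots = np.roots([1.0, -a1, -a2])
        if np.any(np.abs(roots) >= 1.0):
            raise ValueError("unstable AR specification (resonance/bandwidth vs. rate)")


def ar2_coefficients(resonance_hz: float, bandwidth_hz: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients of a damped resonance at ``fs``.

    Complex pole pair at radius ``r = exp(-pi * bandwidth / fs)`` and
    angle ``2*pi*resonance/fs``:  x_t = a1 x_{t-1} + a2 x_{t-2} + e_t.
    """
    r = np.exp(-np.pi * bandwidth_hz / fs)
    theta = 2.0 * np.pi * resonance_hz / fs
    return 2.0 * r * np.cos(theta), -(r * r)


def _ar2_gaussian(n: int, fs: float, rng: np.random.Generator, resonance_hz: float,
                  bandwidth_hz: float) -> np.ndarray:
    """Unit-variance stationary AR(2) Gaussian sample path."""
    a1, a2 = ar2_coefficients(resonance_hz, bandwidth_hz, fs)
    burn = max(1000, int(10 * fs / max(bandwidth_hz, 1e-6)))
    e = rng.standard_normal(n + burn)
    x = lfilter([1.0], [1.0, -a1, -a2], e)[burn:]
    return x / x.std()


def _measure(x: np.ndarray, cubic: float) -> np.ndarray:
    """Invertible static measurement function ``y = x + cubic * x**3``.

    The input is standardized first so the cubic term has comparable
    strength on every channel regardless of its raw amplitude.
    """
    x = x / x.std()
    return x + cubic * x**3


def generate_null_channel(config: NightConfig, seed, n_samples: int | None = None,
                          fs: float | None = None) -> np.ndarray:
    """One channel consistent with the surrogate null hypothesis.

    A stationary AR(2) Gaussian process observed through the monotone
    measurement function, at the raw rate unless ``fs`` is given.
    """
    fs = config.raw_rate if fs is None else fs
    if n_samples is None:
        n_samples = int(round(config.duration_hours * 3600 * fs))
    rng = np.random.default_rng(seed)
    x = _ar2_gaussian(n_samples, fs, rng, config.resonance_hz, config.bandwidth_hz)
    return _measure(x, config.measurement_cubic)


def generate_null_windows(n_windows: int, seed, n_samples: int = 4096, fs: float = 256.0,
                          config: NightConfig | None = None) -> np.ndarray:
    """Non-overlapping analysis-rate windows of the null process.

    Convenience for calibration studies: returns an
    ``(n_windows, n_samples)`` array cut from one continuous realization
    generated directly at the analysis rate (so the windows are exactly
    within the null class the surrogates embody).
    """
    config = config or NightConfig()
    x = generate_null_channel(config, seed, n_samples=n_windows * n_samples, fs=fs)
    return x.reshape(n_windows, n_samples)


@njit(cache=True)
def _roessler_rk4(n, dt, x0, y0, z0, a, b, c, transient):  # pragma: no cover
    out = np.empty(n)
    x, y, z = x0, y0, z0
    for i in range(n + transient):
        # classic 4th-order Runge-Kutta on the Roessler flow
        k1x = -y - z; k1y = x + a * y; k1z = b + z * (x - c)
        x2 = x + 0.5 * dt * k1x; y2 = y + 0.5 * dt * k1y; z2 = z + 0.5 * dt * k1z
        k2x = -y2 - z2; k2y = x2 + a * y2; k2z = b + z2 * (x2 - c)
        x3 = x + 0.5 * dt * k2x; y3 = y + 0.5 * dt * k2y; z3 = z + 0.5 * dt * k2z
        k3x = -y3 - z3; k3y = x3 + a * y3; k3z = b + z3 * (x3 - c)
        x4 = x + dt * k3x; y4 = y + dt * k3y; z4 = z + dt * k3z
        k4x = -y4 - z4; k4y = x4 + a * y4; k4z = b + z4 * (x4 - c)
        x += dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        y += dt * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
        z += dt * (k1z + 2 * k2z + 2 * k3z + k4z) / 6.0
        if i >= transient:
            out[i - transient] = x
    return out


def roessler_first_coordinate(n: int, fs: float, seed, time_units_per_second: float = 6.0,
                              a: float = 0.2, b: float = 0.2, c: float = 5.7) -> np.ndarray:
    """Unit-variance first coordinate of the Roessler flow.

    The flow's dominant period is about 6 time units, so the default
    scaling of 6 time units per second puts the dominant spectral peak
    near 1 Hz (well inside the analysis band).  Initial conditions are
    drawn from ``seed``; a transient is discarded.
    """
    rng = np.random.default_rng(seed)
    dt = time_units_per_second / fs
    transient = int(round(200.0 / dt))  # 200 time units onto the attractor
    x0, y0, z0 = rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(0, 1)
    x = _roessler_rk4(n, dt, x0, y0, z0, a, b, c, transient)
    x = x - x.mean()
    return x / x.std()


@njit(cache=True)
def _henon_iter(n, a, b, x0, y0, transient):  # pragma: no cover
    out = np.empty(n)
    x, y = x0, y0
    for i in range(n + transient):
        x, y = 1.0 - a * x * x + y, b * x
        if i >= transient:
            out[i - transient] = x
    return out


def henon_first_coordinate(n: int, seed, a: float = 1.4, b: float = 0.3) -> np.ndarray:
    """First coordinate of the Henon map (standard parameters), unit
    variance, random in-basin initial condition, transient discarded."""
    rng = np.random.default_rng(seed)
    x = _henon_iter(n, a, b, rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), 1000)
    x = x - x.mean()
    return x / x.std()


def _stage_multiplier_per_sample(hypnogram: Hypnogram, n: int, fs: float,
                                 modulation: dict) -> np.ndarray:
    mult = np.array([modulation.get(l, 0.0) for l in hypnogram.labels])
    per_epoch = int(round(hypnogram.epoch_seconds * fs))
    full = np.repeat(mult, per_epoch)
    if full.size >= n:
        return full[:n]
    return np.concatenate([full, np.zeros(n - full.size)])


def generate_soz_channel(config: NightConfig, hypnogram: Hypnogram, seed,
                         n_samples: int | None = None, fs: float | None = None) -> np.ndarray:
    """Null channel plus a stage-modulated deterministic component.

    The deterministic component (Roessler first coordinate) is added to
    the pre-measurement Gaussian process with amplitude
    ``effect_size * stage_multiplier``, then observed through the
    measurement function.  ``effect_size = 0`` reduces exactly to a null
    channel statistically.
    """
    fs = config.raw_rate if fs is None else fs
    if n_samples is None:
        n_samples = int(round(config.duration_hours * 3600 * fs))
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_noise, s_det = ss.spawn(2)
    rng = np.random.default_rng(s_noise)
    x = _ar2_gaussian(n_samples, fs, rng, config.resonance_hz, config.bandwidth_hz)
    det = roessler_first_coordinate(n_samples, fs, s_det)
    mult = _stage_multiplier_per_sample(hypnogram, n_samples, fs, config.stage_modulation)
    return _measure(x + config.effect_size * mult * det, config.measurement_cubic)


def _build_hypnogram(config: NightConfig) -> Hypnogram:
    n_epochs = int(config.duration_hours * 3600 // 30)
    labels: list[str] = []
    while len(labels) < n_epochs:
        for stage, reps in config.stage_cycle:
            labels.extend([stage] * reps)
    return Hypnogram(labels=labels[:n_epochs])


def reduced_night_config(master_seed: int, soz_side: str = "L",
                         effect_size: float | None = None, **overrides) -> NightConfig:
    """Scaled-down study conditions for fast end-to-end validation.

    Ten-minute nights with one electrode per hemisphere and two-minute
    stage runs; all other conditions (rates, geometry, null process,
    effect size) keep their defaults.
    """
    kw = dict(n_electrodes_per_hemisphere=1, duration_hours=10.0 / 60.0,
              stage_cycle=REDUCED_STAGE_CYCLE, soz_side=soz_side,
              master_seed=master_seed)
    if effect_size is not None:
        kw["effect_size"] = effect_size
    kw.update(overrides)
    return NightConfig(**kw)


_ELECTRODE_LABELS = ["AH", "A", "EC", "MH", "PHC", "PH", "TP", "TB", "TL", "FL"]


def _build_channel_map(config: NightConfig) -> ChannelMap:
    electrodes = []
    for side in ("L", "R"):
        for e in range(config.n_electrodes_per_hemisphere):
            label = _ELECTRODE_LABELS[e % len(_ELECTRODE_LABELS)]
            suffix = "" if e < len(_ELECTRODE_LABELS) else str(e // len(_ELECTRODE_LABELS) + 1)
            name = f"{label}{suffix}{side}"
            electrodes.append(Electrode(
                name=name, hemisphere=side,
                macro_contacts=[f"{name}m{c}" for c in range(1, 9)],
                micro_wires=[f"{name}u{w}" for w in range(1, 9)],
            ))
    return ChannelMap(electrodes=electrodes, soz_hemisphere=config.soz_side)


@dataclass
class NightData:
    """A self-consistent synthetic recording bundle."""

    signals: dict
    channel_map: ChannelMap
    hypnogram: Hypnogram
    mask: ArtifactMask
    sample_rate: float
    config: NightConfig

    @property
    def soz_hemisphere(self) -> str:
        return self.channel_map.soz_hemisphere


# polarity-alternating projection of the deterministic source onto the
# contacts/wires (a nearby dipolar source flips sign between neighbors).
# Equal magnitudes keep every raw channel's variance identical, so the
# shared background still cancels exactly under both reference schemes:
# bipolar differences see gain +/-2, bundle-referenced wires +/-1.
_MACRO_GAINS = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
_MICRO_GAINS = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])


def generate_night(config: NightConfig) -> NightData:
    """Generate one complete synthetic night.

    Macro contacts of an electrode share a correlated AR background (so
    bipolar differences retain contact-specific structure instead of
    cancelling); micro wires share a bundle background removed again by
    the bundle reference.  On SOZ-side electrodes the deterministic
    component enters with per-contact/per-wire gains chosen so that after
    referencing its amplitude relative to the residual noise standard
    deviation equals ``effect_size * stage_multiplier``.
    """
    fs = config.raw_rate
    n = int(round(config.duration_hours * 3600 * fs))
    hyp = _build_hypnogram(config)
    cmap = _build_channel_map(config)
    root = np.random.SeedSequence(config.master_seed)
    mult = None

    signals: dict[str, np.ndarray] = {}
    for electrode in cmap.electrodes:
        ss = np.random.SeedSequence([config.master_seed, _stable_key(electrode.name)])
        (s_common_m, s_common_u, s_det), s_rest = ss.spawn(3), ss.spawn(17)
        on_soz = electrode.hemisphere == config.soz_side and config.effect_size > 0
        if on_soz:
            det = roessler_first_coordinate(n, fs, s_det)
            if mult is None:
                mult = _stage_multiplier_per_sample(hyp, n, fs, config.stage_modulation)
            det = det * mult
        common_m = _ar2_gaussian(n, fs, np.random.default_rng(s_common_m),
                                 config.resonance_hz, config.bandwidth_hz)
        common_u = _ar2_gaussian(n, fs, np.random.default_rng(s_common_u),
                                 config.resonance_hz, config.bandwidth_hz)
        for c, raw_id in enumerate(electrode.macro_contacts):
            ind = _ar2_gaussian(n, fs, np.random.default_rng(s_rest[c]),
                                config.resonance_hz, config.bandwidth_hz)
            sig = common_m + ind
            if on_soz:
                # bipolar gain is +/-2 and bipolar noise sd sqrt(2), so
                # amplitude effect_size / sqrt(2) gives the configured ratio
                sig = sig + config.effect_size / np.sqrt(2.0) * _MACRO_GAINS[c] * det
            signals[raw_id] = _measure(sig, config.measurement_cubic).astype(np.float32)
        for w, raw_id in enumerate(electrode.micro_wires):
            ind = _ar2_gaussian(n, fs, np.random.default_rng(s_rest[8 + w]),
                                config.resonance_hz, config.bandwidth_hz)
            sig = common_u + ind
            if on_soz:
                # bundle reference leaves gain +/-1 over noise sd sqrt(7/8)
                sig = sig + np.sqrt(7.0 / 8.0) * config.effect_size * _MICRO_GAINS[w] * det
            signals[raw_id] = _measure(sig, config.measurement_cubic).astype(np.float32)

    mask = _inject_artifacts(signals, cmap, config, root)
    return NightData(signals=signals, channel_map=cmap, hypnogram=hyp, mask=mask,
                     sample_rate=fs, config=config)


def _stable_key(name: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")


def _inject_artifacts(signals: dict, cmap: ChannelMap, config: NightConfig,
                      root: np.random.SeedSequence) -> ArtifactMask:
    """Optionally inject large-amplitude transients and list them in the
    mask.  A masked (derived channel, window) entry corresponds to a
    half-second 10-sigma pulse in the underlying raw channel(s)."""
    mask = ArtifactMask()
    if config.artifact_rate <= 0:
        return mask
    fs = config.raw_rate
    wlen = int(16 * fs)
    n = next(iter(signals.values())).size
    n_win = n // wlen
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 0xA27]))
    for electrode in cmap.electrodes:
        for c, raw_id in enumerate(electrode.macro_contacts[:-1]):
            for w in range(n_win):
                if rng.random() < config.artifact_rate:
                    start = w * wlen + rng.integers(0, wlen - int(fs // 2))
                    amp = 10.0 * signals[raw_id].std()
                    signals[raw_id][start : start + int(fs // 2)] += amp
                    mask.window_entries.add((f"{electrode.name}-b{c + 1}", w))
        for w_idx, raw_id in enumerate(electrode.micro_wires):
            for w in range(n_win):
                if rng.random() < config.artifact_rate:
                    start = w * wlen + rng.integers(0, wlen - int(fs // 2))
                    amp = 10.0 * signals[raw_id].std()
                    signals[raw_id][start : start + int(fs // 2)] += amp
                    mask.window_entries.add((f"{electrode.name}-w{w_idx + 1}", w))
    return mask
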