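"""Iterative amplitude-adjusted (IAAFT) surrogates and the surrogate-
corrected predictability score psi.

An IAAFT surrogate is a constrained randomization of a signal embodying
the null hypothesis of a stationary linear stochastic correlated Gaussian
process observed through an invertible, possibly nonlinear, static
measurement function.  The surrogate has exactly the same amplitude
distribution as the original (multiset identity) and a periodogram that is
practically indistinguishable from the original's.

psi = S_O - S_S corrects the predictability score of the original window
(S_O) by the score of its surrogate (S_S): psi ~ 0 under the null,
psi > 0 for nonlinear deterministic structure, and psi may be negative,
e.g. under nonstationarity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from psilat.score import EmbeddingParams, predictability_score

__all__ = [
    "SurrogateConfig",
    "ScoreResult",
    "window_seed_sequence",
    "iaaft_surrogate",
    "periodogram_rms_deviation",
    "psi_score",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """IAAFT settings.

    Iteration stops early once the surrogate's amplitude rank vector is
    unchanged between consecutive iterations (an exact fixed point); the
    final step is always the amplitude adjustment, so the amplitude
    distribution is exact and the periodogram approximate.  One surrogate
    is drawn per window.
    """

    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def window_seed_sequence(master_seed: int, channel_id: str, window_index: int) -> np.random.SeedSequence:
    """Counter-based per-window seeding.

    Derives an independent random stream for every (channel, window) pair
    from a single master seed, so any window is reproducible in isolation.
    The channel id enters through a stable (process-independent) hash.
    """
    digest = hashlib.sha256(channel_id.encode("utf-8")).digest()
    channel_key = int.from_bytes(digest[:4], "little")
    return np.random.SeedSequence([int(master_seed), channel_key, int(window_index)])


def iaaft_surrogate(samples, config: SurrogateConfig | None = None, seed=0) -> np.ndarray:
    """Draw one IAAFT surrogate of ``samples``.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`.
    Deterministic given (samples, seed).  Raises ``ValueError`` on
    constant input, for which the randomization is degenerate.
    """
    if config is None:
        config = SurrogateConfig()
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expected a 1-d signal with at least 2 samples")
    if np.ptp(x) == 0.0:
        raise ValueError("constant input: surrogate generation is degenerate")

    rng = np.random.default_rng(seed)
    sorted_amp = np.sort(x)                 # exact target amplitude multiset
    target_mag = np.abs(np.fft.rfft(x))     # target periodogram (magnitudes)

    s = rng.permutation(x)                  # random shuffle start
    arange = np.arange(x.size)
    ranks = np.empty(x.size, dtype=np.intp)
    prev_ranks = None
    for _ in range(config.max_iterations):
        # spectral step: impose original magnitudes, keep current phases
        spec = np.fft.rfft(s)
        phases = np.angle(spec)
        s = np.fft.irfft(target_mag * np.exp(1j * phases), n=x.size)
        # amplitude step: rank-order remap onto the original amplitudes
        order = np.argsort(s, kind="stable")
        ranks[order] = arange
        s = sorted_amp[ranks]
        if prev_ranks is not None and np.array_equal(ranks, prev_ranks):
            break
        prev_ranks = ranks.copy()
    return s


def periodogram_rms_deviation(original, surrogate) -> float:
    """Relative root-mean-square deviation between the periodograms of an
    original signal and its surrogate (DC bin excluded)."""
    p0 = np.abs(np.fft.rfft(np.asarray(original, dtype=float))) ** 2
    p1 = np.abs(np.fft.rfft(np.asarray(surrogate, dtype=float))) ** 2
    p0, p1 = p0[1:], p1[1:]
    return float(np.sqrt(np.mean((p1 - p0) ** 2)) / np.sqrt(np.mean(p0**2)))


@dataclass(frozen=True)
class ScoreResult:
    """Original score, surrogate score and their difference psi."""

    s_original: float
    s_surrogate: float

    @property
    def psi(self) -> float:
        return self.s_original - self.s_surrogate


def psi_score(window, params: EmbeddingParams | None = None,
              config: SurrogateConfig | None = None, seed=0) -> ScoreResult:
    """Surrogate-corrected predictability score of one window.

    Computes S on the window and on one IAAFT surrogate drawn with
    ``seed``; unscorable-window errors from either score propagate.
    """
    x = np.asarray(getattr(window, "samples", window), dtype=np.float64)
    s_o = predictability_score(x, params)
    surr = iaaft_surrogate(x, config, seed)
    s_s = predictability_score(surr, params)
    return ScoreResult(s_original=s_o, s_surrogate=s_s)
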