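"""Rank-based nonlinear predictability score.

The score ``S`` quantifies how well the future of a scalar signal can be
predicted from the futures of its nearest neighbors in a delay-embedded
state space.  For each reference state the ``k`` nearest embedded states
are located (excluding temporally close states via a Theiler window), and
the amplitudes observed ``h`` samples after those neighbors are compared
with the amplitude observed ``h`` samples after the reference.  The
comparison is made on ranks of absolute amplitude differences, which makes
``S`` invariant under affine rescaling of the signal:

* ``S = 1``  -- fully predictable (periodic) dynamics,
* ``S = 0``  -- expected value for uncorrelated stochastic signals.

Index conventions follow the defining equations: with embedding dimension
``m`` and delay ``tau`` the embedding window is ``eta = (m - 1) * tau``;
embedded states exist for (1-based) sample indices ``eta+1 .. N`` and
reference states run over ``eta+1 .. N-h``.  Internally everything is
0-based: embedded states occupy array indices ``eta .. N-1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "EmbeddingParams",
    "UnscorableWindowError",
    "DegenerateWindowError",
    "delay_embed",
    "theiler_neighbors",
    "rank_list",
    "predictability_score",
]


class UnscorableWindowError(ValueError):
    """Window cannot be scored under the given embedding parameters."""


class DegenerateWindowError(UnscorableWindowError):
    """Constant window: every distance ties, the score is undefined."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Parameters of the predictability score.

    Defaults correspond to 256 Hz signals: embedding dimension ``m = 8``,
    delay ``tau = 8`` samples, ``k = 5`` neighbors, prediction horizon
    ``h = 8`` samples and Theiler window ``theiler = 38`` samples.
    """

    m: int = 8
    tau: int = 8
    k: int = 5
    h: int = 8
    theiler: int = 38

    def __post_init__(self) -> None:
        for name in ("m", "tau", "k", "h"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if int(self.theiler) < 0:
            raise ValueError("theiler must be a non-negative integer")

    @property
    def eta(self) -> int:
        """Embedding window ``(m - 1) * tau`` in samples."""
        return (self.m - 1) * self.tau


def _as_samples(x) -> np.ndarray:
    x = np.ascontiguousarray(np.asarray(x, dtype=np.float64))
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional sample sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    return x


def delay_embed(samples, params: EmbeddingParams) -> np.ndarray:
    """Embed ``samples`` into delay vectors.

    Returns an ``(N - eta, m)`` matrix whose row for array index
    ``i`` (``i = eta .. N-1``) is ``(x[i], x[i-tau], ..., x[i-(m-1)tau])``.
    """
    x = _as_samples(samples)
    n = x.size
    eta = params.eta
    if n <= eta:
        raise UnscorableWindowError(
            f"window of {n} samples too short for m={params.m}, tau={params.tau} "
            f"(embedding window eta={eta})"
        )
    cols = [x[eta - d * params.tau : n - d * params.tau] for d in range(params.m)]
    return np.stack(cols, axis=1)


def _candidate_mask(n: int, eta: int, upper: int, i0: int, theiler: int) -> np.ndarray:
    """Boolean mask over array indices 0..n-1 of the Theiler-corrected
    candidate set ``{j : eta <= j <= upper, |i0 - j| > theiler}``."""
    j = np.arange(n)
    return (j >= eta) & (j <= upper) & (np.abs(j - i0) > theiler)


def theiler_neighbors(embedding: np.ndarray, i0: int, params: EmbeddingParams, n: int) -> np.ndarray:
    """Indices (into the sample array) of the ``k`` nearest embedded states.

    Candidates are embedded states ``j`` with ``eta <= j <= n-1-h`` and
    ``|i0 - j| > theiler``.  Ties in distance are broken toward smaller
    ``j`` (stable order), so the result is deterministic.
    """
    eta = params.eta
    mask = _candidate_mask(n, eta, n - 1 - params.h, i0, params.theiler)
    cand = np.nonzero(mask)[0]
    if cand.size < params.k:
        raise UnscorableWindowError(
            f"only {cand.size} Theiler-corrected neighbor candidates for "
            f"reference {i0}, need k={params.k}"
        )
    diff = embedding[cand - eta] - embedding[i0 - eta]
    d2 = np.einsum("ij,ij->i", diff, diff)
    # stable selection: candidates are in ascending j order already
    order = np.argsort(d2, kind="stable")[: params.k]
    return cand[order]


def rank_list(samples, i0: int, params: EmbeddingParams) -> tuple[np.ndarray, np.ndarray, int]:
    """Mid-ranks of amplitude distances from sample ``i0``.

    Distances ``u = |x[i0] - x[j]|`` are formed over the candidate set
    ``{j : eta <= j <= N-1, |i0 - j| > theiler}`` and ranked ascending,
    tied values receiving the average of their positions (mid-rank).
    Returns ``(candidate_indices, ranks, M)`` where ``M`` is the actual
    candidate-set cardinality (obtained by counting, which also covers
    references near the window edges).
    """
    from scipy.stats import rankdata

    x = _as_samples(samples)
    n = x.size
    mask = _candidate_mask(n, params.eta, n - 1, i0, params.theiler)
    cand = np.nonzero(mask)[0]
    u = np.abs(x[i0] - x[cand])
    return cand, rankdata(u, method="average"), cand.size


@njit(cache=True)
def _score_kernel(x, m, tau, k, h, theiler):  # pragma: no cover - exercised via wrapper
    """Fused scoring loop.

    Streams one reference state at a time (never materializes the full
    pairwise tables).  Returns (status, S): status 0 ok, 1 too short,
    2 fewer than k neighbor candidates somewhere.
    """
    n = x.size
    eta = (m - 1) * tau
    n_ref = n - eta - h
    if n_ref < 1 or n <= eta:
        return 1, 0.0

    # contiguous embedding matrix E[i - eta, d] = x[i - d*tau], i = eta..n-1
    n_emb = n - eta
    emb = np.empty((n_emb, m))
    for i in range(n_emb):
        for d in range(m):
            emb[i, d] = x[eta + i - d * tau]

    nb_d2 = np.empty(k)
    nb_j = np.empty(k, dtype=np.int64)
    d2row = np.empty(n_emb)
    urow = np.empty(n_emb)
    rl = (k + 1) / 2.0
    acc = 0.0

    for a in range(eta, n - h):  # reference states
        # --- k nearest embedded neighbors, candidates j in [eta, n-1-h],
        #     |a - j| > theiler; ties prefer smaller j (scan ascending,
        #     replace only on strictly smaller distance).  The Theiler band
        #     splits the candidate range into two contiguous segments.
        seg1_end = min(a - theiler, n - h)     # exclusive
        seg2_beg = max(a + theiler + 1, eta)
        for j in range(eta, max(seg1_end, eta)):
            d2 = 0.0
            for d in range(m):
                t = emb[a - eta, d] - emb[j - eta, d]
                d2 += t * t
            d2row[j - eta] = d2
        for j in range(seg2_beg, n - h):
            d2 = 0.0
            for d in range(m):
                t = emb[a - eta, d] - emb[j - eta, d]
                d2 += t * t
            d2row[j - eta] = d2

        found = 0
        for j in range(eta, max(seg1_end, eta)):
            d2 = d2row[j - eta]
            if found < k:
                p = found
                while p > 0 and nb_d2[p - 1] > d2:
                    nb_d2[p] = nb_d2[p - 1]
                    nb_j[p] = nb_j[p - 1]
                    p -= 1
                nb_d2[p] = d2
                nb_j[p] = j
                found += 1
            elif d2 < nb_d2[k - 1]:
                p = k - 1
                while p > 0 and nb_d2[p - 1] > d2:
                    nb_d2[p] = nb_d2[p - 1]
                    nb_j[p] = nb_j[p - 1]
                    p -= 1
                nb_d2[p] = d2
                nb_j[p] = j
        for j in range(seg2_beg, n - h):
            d2 = d2row[j - eta]
            if found < k:
                p = found
                while p > 0 and nb_d2[p - 1] > d2:
                    nb_d2[p] = nb_d2[p - 1]
                    nb_j[p] = nb_j[p - 1]
                    p -= 1
                nb_d2[p] = d2
                nb_j[p] = j
                found += 1
            elif d2 < nb_d2[k - 1]:
                p = k - 1
                while p > 0 and nb_d2[p - 1] > d2:
                    nb_d2[p] = nb_d2[p - 1]
                    nb_j[p] = nb_j[p - 1]
                    p -= 1
                nb_d2[p] = d2
                nb_j[p] = j
        if found < k:
            return 2, 0.0

        # --- rank list at the shifted reference b = a + h over
        #     j in [eta, n-1] with |b - j| > theiler; cardinality M by
        #     actual counting (edge-aware).  Amplitude distances are
        #     buffered once, then each neighbor's mid-rank is obtained by
        #     counting strictly-smaller and tied entries.
        b = a + h
        xb = x[b]
        u_seg1_end = min(b - theiler, n)       # exclusive
        u_seg2_beg = max(b + theiler + 1, eta)
        m_count = 0
        for j in range(eta, max(u_seg1_end, eta)):
            urow[m_count] = abs(xb - x[j])
            m_count += 1
        for j in range(u_seg2_beg, n):
            urow[m_count] = abs(xb - x[j])
            m_count += 1

        r_sum = 0.0
        for r in range(k):
            jt = nb_j[r] + h  # neighbor future; |b - jt| = |a - nb_j[r]| > theiler
            t = abs(xb - x[jt])
            c_less = 0
            c_eq = 0
            for p in range(m_count):
                u = urow[p]
                if u < t:
                    c_less += 1
                elif u == t:
                    c_eq += 1
            # mid-rank of the tied group containing u = t
            r_sum += c_less + (c_eq + 1) / 2.0
        r_mean = r_sum / k
        ru = (m_count + 1) / 2.0
        acc += (ru - r_mean) / (ru - rl)

    return 0, acc / n_ref


def predictability_score(window, params: EmbeddingParams | None = None) -> float:
    """Rank-based nonlinear predictability score ``S`` of one window.

    ``window`` may be a raw sample sequence or any object with a
    ``samples`` attribute.  Raises :class:`DegenerateWindowError` for a
    constant window and :class:`UnscorableWindowError` when the window is
    too short or a reference state has fewer than ``k`` Theiler-corrected
    neighbor candidates.
    """
    if params is None:
        params = EmbeddingParams()
    x = _as_samples(getattr(window, "samples", window))
    if x.size and np.ptp(x) == 0.0:
        raise DegenerateWindowError(
            "constant window: all amplitude distances tie, score undefined"
        )
    status, s = _score_kernel(
        x, int(params.m), int(params.tau), int(params.k), int(params.h), int(params.theiler)
    )
    if status == 1:
        raise UnscorableWindowError(
            f"window of {x.size} samples too short for m={params.m}, tau={params.tau}, "
            f"h={params.h} (eta={params.eta})"
        )
    if status == 2:
        raise UnscorableWindowError(
            f"fewer than k={params.k} Theiler-corrected neighbor candidates "
            f"(N={x.size}, theiler={params.theiler})"
        )
    return float(s)
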