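"""Nonlinear dysphonia measures: DFA, RPDE, correlation dimension, PPE.

These quantify properties that cycle-based perturbation measures miss:
long-range correlation structure of the waveform (DFA), the regularity of
orbit recurrences in a time-delay embedding (RPDE), the geometric
complexity of the reconstructed attractor (D2), and the unpredictability
of semitone-scale pitch variation (PPE). All four normalize amplitude
internally and are deterministic for fixed input and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from voicepd.pitch import PitchTrack

_D2_SUBSAMPLE_SEED = 0x5EED  # fixed: distance subsampling must be reproducible


@dataclass
class EmbeddingParams:
    """Time-delay embedding parameters for RPDE/D2."""

    m: int = 4
    tau: int = 14  # ~1.4 ms at 10 kHz
    eps_frac: float = 0.12
    theiler: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.tau < 1 or self.eps_frac <= 0 or self.theiler < 0:
            raise ValueError("invalid embedding parameters")


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n <= 0:
        raise ValueError("signal too short for the requested embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def default_dfa_scales(n: int) -> np.ndarray:
    hi = min(1000, n // 4)
    scales = np.unique(np.geomspace(40, hi, 10).round().astype(int))
    return scales


def dfa(x, scales=None) -> float:
    """Detrended fluctuation analysis scaling exponent alpha.

    The profile (cumulative sum of the mean-removed signal) is split into
    non-overlapping windows of each scale, linearly detrended, and the RMS
    residual F(L) pooled over windows; alpha is the log-log slope of F(L)
    against L. White noise gives alpha ~ 0.5, a random walk ~ 1.5.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.ptp(x) == 0:
        raise ValueError("DFA undefined for a constant signal")
    scales = default_dfa_scales(len(x)) if scales is None else np.asarray(scales, int)
    if len(scales) < 4:
        raise ValueError("need at least 4 scales")
    if len(x) < 4 * scales.max():
        raise ValueError("signal too short for the largest scale")

    y = np.cumsum(x - x.mean())
    fs = []
    for L in scales:
        n_win = len(y) // L
        seg = y[: n_win * L].reshape(n_win, L)
        t = np.arange(L, dtype=np.float64)
        t_c = t - t.mean()
        # per-window least-squares line via closed form
        slope = seg @ t_c / (t_c @ t_c)
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t_c[None, :]
        fs.append(np.sqrt(np.mean(resid**2)))
    fs = np.asarray(fs)
    if np.any(fs <= 0):
        raise ValueError("degenerate fluctuation (constant within windows)")
    alpha, _ = np.polyfit(np.log(scales), np.log(fs), 1)
    return float(alpha)


def rpde(x, params: EmbeddingParams | None = None, t_max: int = 1500,
         max_anchors: int = 6000) -> float:
    """Recurrence period density entropy, normalized to [0, 1].

    The signal is standardized and embedded; for each anchor point the
    orbit is followed until it leaves the eps-ball around the anchor and
    later re-enters it, and the re-entry lag is accumulated into a
    recurrence-period histogram. The normalized Shannon entropy of that
    histogram is ~0 for a periodic signal and large for noise.
    """
    params = params or EmbeddingParams()
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 1000:
        raise ValueError("RPDE needs at least 1000 samples")
    if np.ptp(x) == 0:
        raise ValueError("RPDE undefined for a constant signal")
    x = (x - x.mean()) / x.std()
    emb = _embed(x, params.m, params.tau)
    n = len(emb)
    eps = params.eps_frac * float(emb.std())

    stride = max(1, n // max_anchors)
    anchors = np.arange(0, n - 2, stride)

    counts = np.zeros(t_max + 1, dtype=np.int64)
    for i in anchors:
        horizon = min(n, i + 1 + t_max)
        d = np.linalg.norm(emb[i + 1 : horizon] - emb[i], axis=1)
        outside = d > eps
        if not outside.any():
            continue
        j0 = int(np.argmax(outside))  # first departure
        back = np.nonzero(d[j0:] <= eps)[0]
        if back.size == 0:
            continue
        T = j0 + int(back[0]) + 1  # lag from the anchor
        counts[T] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no recurrences found; try a larger eps_frac")
    observed = np.nonzero(counts)[0]
    t_obs = int(observed[-1])
    if t_obs <= 1:
        return 0.0
    p = counts[1 : t_obs + 1] / total
    p = p[p > 0]
    h = -np.sum(p * np.log(p))
    return float(h / np.log(t_obs))


def _first_minimum_mutual_information(x: np.ndarray, max_lag: int = 50,
                                      bins: int = 16) -> int:
    """Delay selection: first local minimum of the binned auto mutual information."""
    edges = np.histogram_bin_edges(x, bins=bins)
    digit = np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
    mis = []
    for lag in range(1, max_lag + 1):
        a, b = digit[:-lag], digit[lag:]
        joint = np.zeros((bins, bins))
        np.add.at(joint, (a, b), 1)
        joint /= joint.sum()
        pa = joint.sum(axis=1, keepdims=True)
        pb = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        mi = np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz]))
        mis.append(mi)
        if len(mis) >= 2 and mis[-1] > mis[-2]:
            return lag - 1
    return max_lag


def correlation_dimension(x, params: EmbeddingParams | None = None,
                          m: int = 5, max_pairs: int = 1_000_000) -> float:
    """Correlation dimension D2 by correlation-sum slope fitting.

    Embeds at dimension ``m`` with delay chosen as the first minimum of
    the auto mutual information (capped at 50 samples); the correlation sum
    C(r) is evaluated on a seeded subsample of at most ``max_pairs``
    time-separated pairs, and D2 is the log-log slope over the contiguous
    third of radii with the most stable local slope. A limit cycle gives
    D2 ~ 1, a 2-torus ~ 2.
    """
    del params  # tau/theiler derived below; kept for interface symmetry
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2000:
        raise ValueError("D2 needs at least 2000 samples")
    if np.ptp(x) == 0:
        raise ValueError("D2 undefined for a constant signal")
    x = (x - x.mean()) / x.std()
    tau = _first_minimum_mutual_information(x)
    tau = max(1, tau)
    emb = _embed(x, m, tau)
    n = len(emb)
    theiler = tau

    rng = np.random.default_rng(_D2_SUBSAMPLE_SEED)
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n, size=max_pairs)
    keep = np.abs(i - j) > theiler
    i, j = i[keep], j[keep]
    d = np.linalg.norm(emb[i] - emb[j], axis=1)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("degenerate distance distribution")

    r_lo, r_hi = np.percentile(d, [1, 50])
    if r_lo <= 0 or r_hi <= r_lo:
        raise ValueError("degenerate distance distribution")
    radii = np.geomspace(r_lo, r_hi, 20)
    c = np.searchsorted(np.sort(d), radii) / d.size
    ok = c > 0
    radii, c = radii[ok], c[ok]
    log_r, log_c = np.log(radii), np.log(c)

    local = np.diff(log_c) / np.diff(log_r)
    w = max(4, len(radii) // 3)  # contiguous third of the radius range
    best_var, best_slice = np.inf, None
    for s in range(0, len(local) - w + 1):
        v = np.var(local[s : s + w])
        if v < best_var:
            best_var, best_slice = v, slice(s, s + w + 1)
    slope, _ = np.polyfit(log_r[best_slice], log_c[best_slice], 1)
    return float(max(slope, 0.0))


def ppe(track: PitchTrack, n_bins: int = 30, lp_order: int = 2) -> float:
    """Pitch period entropy, normalized to [0, 1].

    F0 is mapped to semitones relative to the recording's own median, the
    smooth self-correlated component is removed by a least-squares linear
    prediction filter, and the normalized entropy of the residual histogram
    is returned. Constant pitch gives 0; erratic pitch control approaches 1.
    """
    f0 = track.voiced_f0
    if f0.size < 30:
        raise ValueError("PPE needs at least 30 voiced frames")
    ref = float(np.median(f0))
    r = 12.0 * np.log2(f0 / ref)
    # one-step linear prediction residual
    p = lp_order
    X = np.column_stack([r[p - k - 1 : len(r) - k - 1] for k in range(p)])
    y = r[p:]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ coef
    if np.ptp(e) == 0:
        return 0.0
    counts, _ = np.histogram(e, bins=n_bins)
    prob = counts / counts.sum()
    prob = prob[prob > 0]
    h = -np.sum(prob * np.log(prob))
    return float(h / np.log(n_bins))
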