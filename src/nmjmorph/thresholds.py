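"""Histogram-based automatic threshold selection.

All four selectors operate on a 256-bin intensity histogram and return a
*bin index* ``t``; foreground is the set of bins strictly greater than
``t``.  Images of any bit depth are first mapped linearly onto 256 bins
over their own [min, max] range (:func:`histogram_256`) and the chosen
bin is mapped back to original intensity units
(:func:`threshold_intensity`).

Conventions (stated because the classical papers leave them open):

* ties between equally good candidate bins are broken toward the
  smallest bin index;
* only thresholds with non-zero probability mass on both sides are
  candidates;
* a histogram whose mass sits in a single bin is degenerate and raises
  :class:`DegenerateHistogramError`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateHistogramError",
    "histogram_256",
    "threshold_intensity",
    "renyi_entropy_threshold",
    "li_threshold",
    "huang_threshold",
    "moments_threshold",
    "SELECTORS",
]


class DegenerateHistogramError(ValueError):
    """Raised when a histogram cannot support a two-class split."""


def _as_probabilities(hist) -> np.ndarray:
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total <= 0:
        raise DegenerateHistogramError("empty histogram")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("degenerate histogram: fewer than 2 non-empty bins")
    return hist / total


def _candidates(p: np.ndarray) -> np.ndarray:
    """Bin indices t with mass on both sides of the split (<=t, >t)."""
    nz = np.nonzero(p)[0]
    return np.arange(nz[0], nz[-1])


def _argbest(cand: np.ndarray, vals: np.ndarray, maximize: bool = False) -> int:
    """Smallest candidate bin within float tolerance of the optimum.

    Criterion curves are flat across empty bins; the documented
    tie-break (smallest qualifying bin) must not be disturbed by
    last-digit rounding differences on such plateaus.
    """
    best = vals.max() if maximize else vals.min()
    tol = 1e-12 + 1e-9 * abs(best)
    ok = vals >= best - tol if maximize else vals <= best + tol
    return int(cand[np.nonzero(ok)[0][0]])


def histogram_256(image, mask=None):
    """Build a 256-bin histogram of ``image`` (optionally within ``mask``).

    Returns ``(counts, lo, width)`` where bin ``i`` covers intensities
    ``[lo + i*width, lo + (i+1)*width)`` (last bin closed above).
    """
    values = np.asarray(image, dtype=np.float64)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values.ravel()
    if values.size == 0:
        raise ValueError("no pixels to histogram")
    lo = float(values.min())
    hi = float(values.max())
    if hi <= lo:
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = values.size
        return counts, lo, 0.0
    width = (hi - lo) / 256.0
    idx = np.minimum(((values - lo) / width).astype(np.int64), 255)
    counts = np.bincount(idx, minlength=256).astype(np.int64)
    return counts, lo, width


def bin_indices(image, lo: float, width: float) -> np.ndarray:
    """Map intensities to the bin indices of a histogram built with the same (lo, width)."""
    img = np.asarray(image, dtype=np.float64)
    if width <= 0:
        return np.zeros(img.shape, dtype=np.int64)
    return np.minimum(np.floor((img - lo) / width).astype(np.int64).clip(min=0), 255)


def threshold_intensity(image, method: str, mask=None) -> float:
    """Select a threshold on ``image`` and return it in intensity units.

    Foreground is ``image > returned value`` (up to binning resolution;
    use :func:`foreground_mask` for the exact bin-level rule).
    """
    counts, lo, width = histogram_256(image, mask)
    t = SELECTORS[method](counts)
    return lo + (t + 1) * width


def foreground_mask(image, method: str, mask=None) -> np.ndarray:
    """Binary foreground by bin-level thresholding (bin index strictly > t)."""
    counts, lo, width = histogram_256(image, mask)
    t = SELECTORS[method](counts)
    fg = bin_indices(image, lo, width) > t
    if mask is not None:
        fg &= np.asarray(mask, dtype=bool)
    return fg


# ---------------------------------------------------------------------------
# Renyi entropy (maximum-entropy family; Kapur at order 1, plus orders
# 1/2 and 2 combined by the published weighting rule of Sahoo et al.)
# ---------------------------------------------------------------------------

def _order_entropy_curve(p: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Renyi entropy criterion over all candidate thresholds, one order.

    rho == 1.0 means the Shannon limit (Kapur's criterion).
    Returns (candidate bins, criterion values).
    """
    cand = _candidates(p)
    cum = np.cumsum(p)
    vals = np.empty(cand.size)
    for k, t in enumerate(cand):
        p1 = cum[t]
        p2 = 1.0 - p1
        lowp = p[: t + 1]
        highp = p[t + 1 :]
        lowp = lowp[lowp > 0] / p1
        highp = highp[highp > 0] / p2
        if rho == 1.0:
            vals[k] = -(lowp * np.log(lowp)).sum() - (highp * np.log(highp)).sum()
        else:
            vals[k] = (np.log((lowp**rho).sum()) + np.log((highp**rho).sum())) / (1.0 - rho)
    return cand, vals


def _argmax_entropy(p: np.ndarray, rho: float) -> int:
    cand, vals = _order_entropy_curve(p, rho)
    return _argbest(cand, vals, maximize=True)


def renyi_entropy_threshold(hist) -> int:
    """Renyi-entropy threshold (Sahoo/Wong/Soundararajan three-order rule).

    Maximum-entropy thresholds are computed at orders rho -> 1 (Shannon
    limit), rho = 1/2 and rho = 2; the three are then blended by the
    published weighting scheme, which weights them by how much they
    disagree (within 5 bins counts as agreement) and by the probability
    mass between the extreme candidates.
    """
    p = _as_probabilities(hist)
    t1 = _argmax_entropy(p, 1.0)
    t2 = _argmax_entropy(p, 0.5)
    t3 = _argmax_entropy(p, 2.0)
    t_lo, t_mid, t_hi = sorted((t1, t2, t3))

    if abs(t_lo - t_mid) <= 5:
        if abs(t_mid - t_hi) <= 5:
            beta = (1, 2, 1)
        else:
            beta = (0, 1, 3)
    else:
        if abs(t_mid - t_hi) <= 5:
            beta = (3, 1, 0)
        else:
            beta = (1, 2, 1)

    cum = np.cumsum(p)
    omega = cum[t_hi] - cum[t_lo]
    t_star = (
        t_lo * (cum[t_lo] + 0.25 * omega * beta[0])
        + 0.25 * t_mid * omega * beta[1]
        + t_hi * (1.0 - cum[t_hi] + 0.25 * omega * beta[2])
    )
    return int(round(t_star))


# ---------------------------------------------------------------------------
# Li minimum cross entropy
# ---------------------------------------------------------------------------

def li_criterion(p: np.ndarray, t: int) -> float:
    """Li & Lee cross-entropy objective at threshold t (lower is better).

    Up to an additive constant the cross entropy equals
    ``-(A0*log(mu0) + A1*log(mu1))`` with ``A_k`` the intensity-weighted
    mass and ``mu_k`` the mean of each class (bin index as intensity).
    """
    i = np.arange(256, dtype=np.float64)
    w = i * p
    a0 = w[: t + 1].sum()
    a1 = w[t + 1 :].sum()
    m0 = p[: t + 1].sum()
    m1 = p[t + 1 :].sum()
    out = 0.0
    if a0 > 0 and m0 > 0:
        out -= a0 * np.log(a0 / m0)
    if a1 > 0 and m1 > 0:
        out -= a1 * np.log(a1 / m1)
    return out


def li_threshold(hist) -> int:
    """Minimum-cross-entropy threshold, found by exhaustive scan."""
    p = _as_probabilities(hist)
    cand = _candidates(p)
    vals = np.array([li_criterion(p, int(t)) for t in cand])
    return _argbest(cand, vals)


# ---------------------------------------------------------------------------
# Huang fuzzy thresholding
# ---------------------------------------------------------------------------

def huang_criterion(p: np.ndarray, t: int) -> float:
    """Huang & Wang measure of fuzziness at threshold t (lower is better)."""
    i = np.arange(256, dtype=np.float64)
    nz = np.nonzero(p)[0]
    c = float(nz[-1] - nz[0])
    if c <= 0:
        raise DegenerateHistogramError("degenerate histogram")
    w = i * p
    m0 = p[: t + 1].sum()
    m1 = p[t + 1 :].sum()
    mu0 = w[: t + 1].sum() / m0 if m0 > 0 else 0.0
    mu1 = w[t + 1 :].sum() / m1 if m1 > 0 else 0.0
    mu = np.where(i <= t, mu0, mu1)
    u = 1.0 / (1.0 + np.abs(i - mu) / c)
    # Shannon entropy of the membership value, weighted by the histogram
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
    h = np.where((u <= 0) | (u >= 1), 0.0, h)
    return float((p * h).sum())


def huang_threshold(hist) -> int:
    p = _as_probabilities(hist)
    cand = _candidates(p)
    vals = np.array([huang_criterion(p, int(t)) for t in cand])
    return _argbest(cand, vals)


# ---------------------------------------------------------------------------
# Tsai moment-preserving threshold
# ---------------------------------------------------------------------------

def moments_fraction(p: np.ndarray) -> float:
    """Below-threshold mass fraction p0 preserving the first three moments."""
    i = np.arange(256, dtype=np.float64)
    m1 = float((i * p).sum())
    m2 = float((i**2 * p).sum())
    m3 = float((i**3 * p).sum())
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("degenerate histogram: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        disc = 0.0
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise DegenerateHistogramError("degenerate histogram: coincident moment levels")
    return float((z1 - m1) / (z1 - z0))


def moments_threshold(hist) -> int:
    """Tsai's rule: split so the below-threshold mass best matches p0."""
    p = _as_probabilities(hist)
    p0 = moments_fraction(p)
    cand = _candidates(p)
    cum = np.cumsum(p)
    vals = np.abs(cum[cand] - p0)
    return _argbest(cand, vals)


SELECTORS = {
    "renyi": renyi_entropy_threshold,
    "li": li_threshold,
    "huang": huang_threshold,
    "moments": moments_threshold,
}
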