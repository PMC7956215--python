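"""Non-linear dynamics features: recurrence analysis, entropy and scaling.

The recurrence-based block embeds a window in phase space (delay from the
first local minimum of auto mutual information, dimension from false
nearest neighbors), thresholds pairwise distances at 10% of the average
phase-space diameter (read as the mean pairwise distance) to build a
recurrence plot, and quantifies its line structure: recurrence rate,
determinism, laminarity, longest diagonal, diagonal line entropy and
trapping time.  Correlation dimension uses the Grassberger-Procaccia
slope; multiscale entropy is sample entropy of coarse-grained series at
scales 1-5; detrended fluctuation analysis yields the scaling exponent
alpha (0.5 for white noise, 1.5 for a random walk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .io import ValidationError


class DegenerateSeriesError(ValueError):
    """Input has no usable variation (constant or collapsed geometry)."""


# ---------------------------------------------------------------------------
# Phase-space embedding


@dataclass
class Embedding:
    delay: int  # samples
    dimension: int
    points: np.ndarray  # shape (n_points, dimension)


def embed(x: np.ndarray, delay: int, dimension: int) -> Embedding:
    """Takens delay embedding; point count is ``N - (M-1)*T``."""
    x = np.asarray(x, dtype=float)
    if delay < 1 or dimension < 1:
        raise ValidationError("delay and dimension must be >= 1")
    n_points = len(x) - (dimension - 1) * delay
    if n_points <= 0:
        raise ValidationError(
            f"series of {len(x)} samples too short for M={dimension}, T={delay}"
        )
    cols = [x[i * delay : i * delay + n_points] for i in range(dimension)]
    return Embedding(delay, dimension, np.column_stack(cols))


def _mutual_information(x: np.ndarray, lag: int, bins: int = 16) -> float:
    """Auto mutual information (nats) between x(t) and x(t+lag), equal-width bins."""
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def estimate_delay(x: np.ndarray, max_lag: int, bins: int = 16) -> int:
    """First local minimum of the auto-mutual-information curve.

    Lag 1 counts as a local minimum when MI rises from lag 1 to lag 2
    (the curve is already at its floor).  If no local minimum exists up to
    ``max_lag``, returns ``max_lag`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        raise DegenerateSeriesError("constant series has no informative delay")
    if len(x) < 4 * max_lag:
        raise ValidationError(f"need at least {4 * max_lag} samples for max_lag={max_lag}")
    mi = np.array([_mutual_information(x, lag, bins) for lag in range(1, max_lag + 1)])
    if len(mi) >= 2 and mi[0] < mi[1]:
        return 1
    for i in range(1, len(mi) - 1):
        if mi[i] < mi[i - 1] and mi[i] <= mi[i + 1]:
            return i + 1
    warnings.warn("no local minimum of mutual information; using max_lag", stacklevel=2)
    return max_lag


def estimate_dimension(
    x: np.ndarray,
    delay: int,
    max_dim: int = 8,
    rtol: float = 15.0,
    atol: float = 2.0,
    fnn_threshold: float = 0.01,
) -> int:
    """Smallest embedding dimension with a false-nearest-neighbor fraction < 1%.

    Kennel criteria: a neighbor is false when the extra-coordinate distance
    exceeds ``rtol`` times the M-dimensional distance, or the augmented
    distance exceeds ``atol`` standard deviations of the series.
    """
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    if sd == 0:
        raise DegenerateSeriesError("constant series")
    for m in range(1, max_dim + 1):
        n_points = len(x) - m * delay  # need the (m+1)-th coordinate too
        if n_points < 10:
            raise ValidationError(
                f"series of {len(x)} samples too short for FNN at M={m}, T={delay}"
            )
        pts = embed(x, delay, m).points[:n_points]
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=2)
        d, nn = dist[:, 1], idx[:, 1]
        extra = np.abs(x[np.arange(n_points) + m * delay] - x[nn + m * delay])
        # floor the denominator so exact/near-duplicate points (periodic
        # noise-free series) are judged by the absolute criterion only
        denom = np.maximum(d, 1e-10 * sd)
        false = (extra / denom > rtol) | (np.sqrt(d**2 + extra**2) / sd > atol)
        if np.mean(false) < fnn_threshold:
            return m
    warnings.warn("false-neighbor fraction never fell below threshold; using max_dim", stacklevel=2)
    return max_dim


# ---------------------------------------------------------------------------
# Recurrence plots and their quantification


@dataclass
class RecurrenceMatrix:
    matrix: np.ndarray  # boolean, symmetric, True diagonal
    threshold: float


def recurrence_matrix(emb: Embedding, e_frac: float = 0.10) -> RecurrenceMatrix:
    """Threshold pairwise distances at ``e_frac`` of the mean pairwise distance."""
    pts = emb.points
    if len(pts) < 10:
        raise ValidationError("recurrence matrix needs at least 10 embedded points")
    d = pdist(pts)
    mean_d = d.mean()
    if mean_d <= 0:
        raise DegenerateSeriesError("all embedded points identical")
    eps = e_frac * mean_d
    mat = squareform(d) <= eps
    np.fill_diagonal(mat, True)
    return RecurrenceMatrix(matrix=mat, threshold=float(eps))


@dataclass
class RqaMeasures:
    recurrence_rate: float
    determinism: float
    laminarity: float
    longest_diagonal: float
    diagonal_entropy: float
    trapping_time: float


def _run_lengths(b: np.ndarray) -> np.ndarray:
    """Lengths of runs of True in a 1-D boolean array."""
    if b.size == 0 or not b.any():
        return np.empty(0, dtype=int)
    padded = np.concatenate(([0], b.view(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def _diagonal_line_lengths(mat: np.ndarray, theiler: int) -> np.ndarray:
    """Line lengths on all diagonals with |offset| >= theiler (symmetric: x2)."""
    n = mat.shape[0]
    lengths = []
    for k in range(max(theiler, 1), n):
        lengths.append(_run_lengths(np.diagonal(mat, k)))
    if not lengths:
        return np.empty(0, dtype=int)
    upper = np.concatenate(lengths) if lengths else np.empty(0, dtype=int)
    return np.concatenate([upper, upper])  # symmetry: lower triangle mirrors upper


def _vertical_line_lengths(mat: np.ndarray) -> np.ndarray:
    """Line lengths down all columns of an (already masked) matrix."""
    n = mat.shape[0]
    # insert a False row between columns so runs cannot span column boundaries
    padded = np.vstack([mat, np.zeros((1, n), dtype=bool)])
    return _run_lengths(padded.T.ravel())


def rqa_measures(
    rp: RecurrenceMatrix, l_min: int = 2, v_min: int = 2, theiler: int = 1
) -> RqaMeasures:
    """Line-structure statistics of a recurrence plot.

    The Theiler band ``|i - j| < theiler`` (the line of identity for
    ``theiler=1``) is excluded from the recurrence rate, from all line
    counts and from the rate denominators.  Empty structures give zeros.
    """
    mat = rp.matrix
    n = mat.shape[0]
    i, j = np.indices(mat.shape, sparse=True)
    keep = np.abs(i - j) >= max(theiler, 1)
    masked = mat & keep
    n_keep = int(keep.sum())
    n_rec = int(masked.sum())
    rr = n_rec / n_keep if n_keep else 0.0

    diag = _diagonal_line_lengths(mat, max(theiler, 1))
    diag_long = diag[diag >= l_min]
    det = float(diag_long.sum() / n_rec) if n_rec else 0.0
    lmax = float(diag.max()) if diag.size else 0.0
    if diag_long.size:
        _, counts = np.unique(diag_long, return_counts=True)
        p = counts / counts.sum()
        entr = float(-np.sum(p * np.log(p)))
    else:
        entr = 0.0

    vert = _vertical_line_lengths(masked)
    vert_long = vert[vert >= v_min]
    lam = float(vert_long.sum() / n_rec) if n_rec else 0.0
    tt = float(vert_long.mean()) if vert_long.size else 0.0

    return RqaMeasures(
        recurrence_rate=float(rr),
        determinism=det,
        laminarity=lam,
        longest_diagonal=lmax,
        diagonal_entropy=entr,
        trapping_time=tt,
    )


# ---------------------------------------------------------------------------
# Correlation dimension, multiscale entropy, DFA


def correlation_dimension(
    emb: Embedding, pct_lo: float = 5.0, pct_hi: float = 50.0, n_radii: int = 12
) -> float:
    """Grassberger-Procaccia correlation dimension D2.

    Slope of log C(r) against log r over radii log-spaced between the 5th
    and 50th percentile of pairwise distances.  Degenerate geometry
    (collapsed cloud) returns a flagged 0.
    """
    pts = emb.points
    if len(pts) < 100:
        raise ValidationError("correlation dimension needs at least 100 points")
    d = pdist(pts)
    lo, hi = np.percentile(d, [pct_lo, pct_hi])
    if not (0 < lo < hi):
        return 0.0
    radii = np.logspace(np.log10(lo), np.log10(hi), n_radii)
    c = np.array([np.mean(d < r) for r in radii])
    if np.any(c <= 0):
        return 0.0
    slope = np.polyfit(np.log(radii), np.log(c), 1)[0]
    return float(slope)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev template matching.

    ``B`` counts pairs of length-``m`` templates within ``r``; ``A`` the
    same for length ``m+1``; both use the ``N - m`` templates that admit an
    ``m+1``-long extension (Richman-Moorman).  Returns 0 (flagged) when no
    matches exist at either length.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    n = len(x)
    if n < m + 2:
        raise ValidationError(f"series of {n} samples too short for m={m}")
    if r <= 0:
        return 0.0
    templates = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n-m, m+1)
    tm = templates[:, :m]
    # Chebyshev distances between all template pairs
    dm = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=-1)
    dm1 = np.maximum(dm, np.abs(templates[:, m][:, None] - templates[None, :, m]))
    iu = np.triu_indices(len(templates), k=1)
    b = int(np.sum(dm[iu] <= r))
    a = int(np.sum(dm1[iu] <= r))
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def multiscale_entropy(
    x: np.ndarray, n_scales: int = 5, m: int = 2, r_frac: float = 0.2
) -> np.ndarray:
    """Sample entropy of coarse-grained series at scales 1..n_scales.

    Scale ``s`` replaces the series by non-overlapping means of ``s``
    consecutive samples; the tolerance ``r`` is ``r_frac`` times the SD of
    the *original* series at every scale.  Constant input gives flagged
    zeros.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * n_scales * (m + 1):
        raise ValidationError(
            f"series of {len(x)} samples too short for {n_scales} scales at m={m}"
        )
    sd = np.std(x)
    if sd == 0:
        return np.zeros(n_scales)
    r = r_frac * sd
    out = np.empty(n_scales)
    for s in range(1, n_scales + 1):
        k = len(x) // s
        coarse = x[: k * s].reshape(k, s).mean(axis=1)
        out[s - 1] = sample_entropy(coarse, m=m, r=r)
    return out


def dfa_alpha(
    x: np.ndarray, min_box: int = 4, max_box_frac: float = 0.25, n_boxes: int = 12
) -> float:
    """Detrended fluctuation analysis scaling exponent.

    Integrates the mean-removed series, splits it into non-overlapping
    boxes of log-spaced sizes from ``min_box`` to ``max_box_frac * N``,
    removes a linear trend per box, and fits the slope of
    log F(n) vs log n.  Constant input gives a flagged 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 64:
        raise ValidationError(f"DFA needs at least 64 samples, got {n}")
    if np.std(x) == 0:
        return 0.0
    profile = np.cumsum(x - x.mean())
    max_box = int(max_box_frac * n)
    sizes = np.unique(
        np.round(np.logspace(np.log10(min_box), np.log10(max_box), n_boxes)).astype(int)
    )
    sizes = sizes[(sizes >= min_box) & (sizes <= max_box)]
    fluct = np.empty(len(sizes))
    for k, size in enumerate(sizes):
        n_seg = n // size
        segs = profile[: n_seg * size].reshape(n_seg, size)
        t = np.arange(size, dtype=float)
        t -= t.mean()
        denom = np.sum(t**2)
        slope = segs @ t / denom
        mean = segs.mean(axis=1)
        resid = segs - mean[:, None] - slope[:, None] * t[None, :]
        fluct[k] = np.sqrt(np.mean(resid**2))
    good = fluct > 0
    if good.sum() < 2:
        return 0.0
    alpha = np.polyfit(np.log(sizes[good]), np.log(fluct[good]), 1)[0]
    return float(alpha)
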