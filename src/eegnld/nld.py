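"""Nonlinear invariant measures: sample entropy, DFA, and RQA.

Nine scalars summarize each band series, in the fixed order
(RR, DET, LAM, L_max, L_entr, L_mean, TT, SampE, DFA):

* the seven recurrence-quantification statistics — recurrence rate,
  determinism, laminarity, longest and mean diagonal line, Shannon
  entropy of diagonal line lengths, trapping time — computed from a
  thresholded max-norm recurrence plot of a delay embedding, with the
  line of identity excluded;
* sample entropy, -ln(A/B) over template matches with a tolerance in
  units of the series SD;
* the DFA scaling exponent (a Hurst-parameter estimate valid for
  nonstationary series).

Degenerate situations (zero variance, no template matches, no lines of
the minimum length) yield NaN sentinels or zeros as documented per
function, never exceptions, so a single pathological band cannot abort
a full-cohort feature extraction.

Two RQA code paths exist on purpose: :func:`rqa_measures` works from an
explicit recurrence matrix (used for small inputs and for validation
against brute-force line enumeration), while the numba kernel behind
:func:`rqa_from_series` streams over diagonals and columns without
materializing the matrix; the two are tested to agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

#: Canonical measure order used for feature indexing everywhere.
MEASURE_NAMES: tuple[str, ...] = (
    "RR", "DET", "LAM", "L_max", "L_entr", "L_mean", "TT", "SampE", "DFA",
)


# ---------------------------------------------------------------------------
# embedding and recurrence plot

@dataclass
class EmbeddedSeries:
    """Delay-coordinate embedding of a scalar series."""

    points: np.ndarray  # (n_points, dim)
    dim: int
    tau: int


@dataclass
class RecurrencePlot:
    """Binary recurrence indicator with its construction settings."""

    matrix: np.ndarray  # (n, n) bool
    epsilon: float
    norm: str = "chebyshev"
    loi_excluded: bool = True


def embed(x: np.ndarray, dim: int, tau: int) -> EmbeddedSeries:
    """Delay embedding: point ``i`` is ``(x[i], x[i+tau], ..., x[i+(dim-1)tau])``."""
    x = np.asarray(x, dtype=np.float64)
    if dim < 1 or tau < 1:
        raise ValueError("embedding dimension and delay must be >= 1")
    n_pts = x.size - (dim - 1) * tau
    if n_pts < 1:
        raise ValueError(
            f"series of length {x.size} too short for dim={dim}, tau={tau}"
        )
    idx = np.arange(n_pts)[:, None] + tau * np.arange(dim)[None, :]
    return EmbeddedSeries(points=x[idx], dim=dim, tau=tau)


def recurrence_matrix(
    e: EmbeddedSeries, epsilon: float, loi_excluded: bool = True
) -> RecurrencePlot:
    """Thresholded pairwise max-norm distances of the embedded points."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    pts = e.points
    if pts.shape[0] < 1:
        raise ValueError("empty embedding")
    diff = np.abs(pts[:, None, :] - pts[None, :, :]).max(axis=2)
    return RecurrencePlot(
        matrix=diff <= epsilon, epsilon=float(epsilon), loi_excluded=loi_excluded
    )


# ---------------------------------------------------------------------------
# RQA statistics

@dataclass
class RQAResult:
    """The seven recurrence statistics plus the settings that produced them."""

    rr: float
    det: float
    lam: float
    l_max: float
    l_entr: float
    l_mean: float
    tt: float
    settings: dict = field(default_factory=dict)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.rr, self.det, self.lam, self.l_max,
                self.l_entr, self.l_mean, self.tt)


def _line_stats(hist: np.ndarray, l_min: int) -> tuple[float, float, float, float]:
    """(weighted_frac, longest, mean_len, entropy) from a run-length histogram.

    ``weighted_frac`` is sum(l*P(l), l>=l_min) / sum(l*P(l), all l) — the
    DET/LAM form; mean length and Shannon entropy (nats) are over the
    l >= l_min line distribution; all are 0 when no qualifying line exists.
    """
    lengths = np.arange(hist.size)
    total = float((lengths * hist).sum())
    if total == 0:
        return 0.0, 0.0, 0.0, 0.0
    sel = hist.copy()
    sel[:l_min] = 0
    n_lines = float(sel.sum())
    longest = float(np.nonzero(hist)[0].max())
    if n_lines == 0:
        return 0.0, longest, 0.0, 0.0
    frac = float((lengths * sel).sum()) / total
    mean_len = float((lengths * sel).sum()) / n_lines
    p = sel[sel > 0] / n_lines
    entropy = float(-(p * np.log(p)).sum())
    return frac, longest, mean_len, entropy


def _runs_histogram(lines: list[np.ndarray], size: int) -> np.ndarray:
    """Histogram of maximal 1-runs over a list of binary 1-D arrays."""
    hist = np.zeros(size + 1, dtype=np.int64)
    for line in lines:
        padded = np.concatenate([[0], line.astype(np.int8), [0]])
        d = np.diff(padded)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for ln in ends - starts:
            hist[ln] += 1
    return hist


def rqa_measures(
    rp: RecurrencePlot, l_min: int = 2, v_min: int = 2
) -> RQAResult:
    """Compute the seven recurrence statistics from an explicit plot.

    The line of identity is masked (unless ``rp.loi_excluded`` is False)
    before counting: RR is the recurrent fraction of off-diagonal cells,
    diagonal lines are maximal runs along every off-main diagonal, and
    vertical lines are maximal runs within columns of the masked matrix.
    """
    if l_min < 2 or v_min < 2:
        raise ValueError("l_min and v_min must be >= 2")
    m = np.asarray(rp.matrix, dtype=bool)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("recurrence matrix must be square")
    n = m.shape[0]
    if l_min > n:
        raise ValueError("l_min exceeds matrix size")
    work = m.copy()
    if rp.loi_excluded:
        np.fill_diagonal(work, False)
        denom = n * n - n
    else:
        denom = n * n
    rr = float(work.sum()) / denom if denom else 0.0

    diags = [np.diagonal(work, k) for k in range(-(n - 1), n) if k != 0]
    if not rp.loi_excluded:
        diags.append(np.diagonal(work, 0))
    hist_d = _runs_histogram(diags, n)
    det, l_max, l_mean, l_entr = _line_stats(hist_d, l_min)

    hist_v = _runs_histogram([work[:, j] for j in range(n)], n)
    lam, _, tt, _ = _line_stats(hist_v, v_min)

    return RQAResult(
        rr=rr, det=det, lam=lam, l_max=l_max, l_entr=l_entr,
        l_mean=l_mean, tt=tt,
        settings={"epsilon": rp.epsilon, "l_min": l_min, "v_min": v_min,
                  "norm": rp.norm, "loi_excluded": rp.loi_excluded},
    )


@njit(cache=True)
def _rqa_kernel(pts, eps, l_min, v_min):  # pragma: no cover - exercised via wrapper
    """Streaming RQA over a delay embedding; LOI always excluded.

    Returns (rr, hist_d, hist_v) where the histograms count maximal
    diagonal / vertical runs (diagonal runs counted once per symmetric
    pair, i.e. doubled).
    """
    n = pts.shape[0]
    dim = pts.shape[1]
    hist_d = np.zeros(n + 1, dtype=np.int64)
    hist_v = np.zeros(n + 1, dtype=np.int64)
    rec_pairs = 0
    for d in range(1, n):
        run = 0
        for i in range(n - d):
            dist = 0.0
            for k in range(dim):
                a = abs(pts[i, k] - pts[i + d, k])
                if a > dist:
                    dist = a
            if dist <= eps:
                run += 1
                rec_pairs += 1
            else:
                if run > 0:
                    hist_d[run] += 2
                run = 0
        if run > 0:
            hist_d[run] += 2
    for j in range(n):
        run = 0
        for i in range(n):
            hit = False
            if i != j:
                dist = 0.0
                for k in range(dim):
                    a = abs(pts[i, k] - pts[j, k])
                    if a > dist:
                        dist = a
                hit = dist <= eps
            if hit:
                run += 1
            else:
                if run > 0:
                    hist_v[run] += 1
                run = 0
        if run > 0:
            hist_v[run] += 1
    denom = n * n - n
    rr = 2.0 * rec_pairs / denom if denom > 0 else 0.0
    return rr, hist_d, hist_v


def rqa_from_series(
    x: np.ndarray,
    dim: int = 3,
    tau: int = 1,
    epsilon_sd: float = 0.2,
    l_min: int = 2,
    v_min: int = 2,
    max_points: int | None = None,
) -> RQAResult:
    """RQA of a scalar series without materializing the recurrence matrix.

    The threshold is ``epsilon_sd`` times the series SD (max-norm).  If
    ``max_points`` is set, only the first ``max_points + (dim-1)*tau``
    samples are embedded — the O(N^2) recurrence computation is the cost
    driver of full-cohort extraction, and a fixed analysis window keeps
    it bounded while leaving every other measure on the full series.
    """
    x = np.asarray(x, dtype=np.float64)
    eps = float(epsilon_sd * x.std())
    e = embed(x, dim, tau)
    pts = e.points
    if max_points is not None and pts.shape[0] > max_points:
        pts = pts[:max_points]
    rr, hist_d, hist_v = _rqa_kernel(
        np.ascontiguousarray(pts), eps, l_min, v_min
    )
    det, l_max, l_mean, l_entr = _line_stats(hist_d, l_min)
    lam, _, tt, _ = _line_stats(hist_v, v_min)
    return RQAResult(
        rr=float(rr), det=det, lam=lam, l_max=l_max, l_entr=l_entr,
        l_mean=l_mean, tt=tt,
        settings={"dim": dim, "tau": tau, "epsilon": eps,
                  "epsilon_sd": epsilon_sd, "l_min": l_min, "v_min": v_min,
                  "n_points": int(pts.shape[0]), "norm": "chebyshev",
                  "loi_excluded": True},
    )


# ---------------------------------------------------------------------------
# sample entropy

@njit(cache=True)
def _sampen_counts(x, m, r_abs):  # pragma: no cover - exercised via wrapper
    n = x.size
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r_abs:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    a += 1
    return a, b


def sample_entropy(
    x: np.ndarray, m: int = 2, r: float = 0.2, r_absolute: float | None = None
) -> float:
    """Sample entropy -ln(A/B) in nats.

    B counts pairs of length-``m`` templates within Chebyshev distance
    ``r`` * SD(x) (self-matches excluded); A counts the corresponding
    length-``m+1`` matches.  Pass ``r_absolute`` to use an absolute
    tolerance instead.  Returns NaN when the tolerance degenerates to
    zero (constant series under SD units) or no matches exist.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m+1} samples")
    if r_absolute is not None:
        r_abs = float(r_absolute)
    else:
        if r <= 0:
            raise ValueError("tolerance r must be positive")
        r_abs = float(r * x.std())
    if r_abs <= 0 and r_absolute is None:
        return float("nan")  # zero-variance series: tolerance collapses
    if r_abs < 0:
        raise ValueError("absolute tolerance must be non-negative")
    a, b = _sampen_counts(np.ascontiguousarray(x), m, r_abs)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# detrended fluctuation analysis

def default_dfa_boxes(n: int, n_sizes: int = 8, min_size: int = 16) -> np.ndarray:
    """Log-spaced box sizes from ``min_size`` to ``n // 4``."""
    if n < 4 * min_size:
        raise ValueError("series too short for DFA")
    sizes = np.geomspace(min_size, n // 4, n_sizes)
    return np.unique(np.round(sizes).astype(int))


def dfa(x: np.ndarray, box_sizes: np.ndarray | None = None) -> float:
    """DFA scaling exponent (first-order detrending).

    The mean-centered series is integrated; within each non-overlapping
    box of each size a least-squares line is removed; the exponent is
    the slope of log RMS residual vs log box size.  For fractional
    Gaussian noise the exponent estimates the Hurst parameter H.
    """
    x = np.asarray(x, dtype=np.float64)
    if box_sizes is None:
        box_sizes = default_dfa_boxes(x.size)
    box_sizes = np.asarray(box_sizes, dtype=int)
    usable = box_sizes[(box_sizes >= 4) & (box_sizes <= x.size // 2)]
    if usable.size < 2:
        raise ValueError("need at least 2 usable box sizes")
    y = np.cumsum(x - x.mean())
    fluct = np.empty(usable.size)
    for s_i, s in enumerate(usable):
        nb = y.size // s
        seg = y[: nb * s].reshape(nb, s)
        t = np.arange(s, dtype=np.float64)
        t_c = t - t.mean()
        denom = (t_c ** 2).sum()
        slope = seg @ t_c / denom
        inter = seg.mean(axis=1)
        resid = seg - inter[:, None] - slope[:, None] * t[None, :] + slope[:, None] * t.mean()
        fluct[s_i] = np.sqrt((resid ** 2).mean())
    if np.any(fluct <= 0):
        return float("nan")  # perfectly linear / constant boxes
    coef = np.polyfit(np.log(usable), np.log(fluct), 1)
    return float(coef[0])


# ---------------------------------------------------------------------------
# per-band bundle

@dataclass
class NLDSettings:
    """Fixed settings for the nine measures on one band series.

    Embedding and tolerance defaults (dim 3, tau 1, epsilon 0.2 SD,
    l_min = v_min = 2; sample entropy m=2, r=0.2 SD) follow common RQA
    and sample-entropy practice.  ``rqa_max_points`` bounds the O(N^2)
    recurrence computation to the opening window of the band series;
    sample entropy and DFA always use the full series.
    """

    dim: int = 3
    tau: int = 1
    epsilon_sd: float = 0.2
    l_min: int = 2
    v_min: int = 2
    sampen_m: int = 2
    sampen_r: float = 0.2
    rqa_max_points: int | None = 2000
    dfa_boxes: np.ndarray | None = None


@dataclass
class NLDMeasureSet:
    """The nine measures for one channel/band, in canonical order."""

    values: np.ndarray  # (9,)
    names: tuple[str, ...]
    rqa: RQAResult

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def channel_band_measures(
    band: np.ndarray, settings: NLDSettings | None = None
) -> NLDMeasureSet:
    """Compute the nine nonlinear measures for one band series."""
    settings = settings or NLDSettings()
    band = np.asarray(band, dtype=np.float64)
    sd = band.std()
    # a constant input channel yields detail series at round-off scale;
    # treat those as degenerate rather than analyzing numerical noise
    if sd < 1e-10:
        rqa = RQAResult(rr=np.nan, det=np.nan, lam=np.nan, l_max=np.nan,
                        l_entr=np.nan, l_mean=np.nan, tt=np.nan,
                        settings={"degenerate": "zero variance"})
        sampen = float("nan")
        dfa_exp = float("nan")
    else:
        rqa = rqa_from_series(
            band, dim=settings.dim, tau=settings.tau,
            epsilon_sd=settings.epsilon_sd, l_min=settings.l_min,
            v_min=settings.v_min, max_points=settings.rqa_max_points,
        )
        sampen = sample_entropy(band, m=settings.sampen_m, r=settings.sampen_r)
        try:
            dfa_exp = dfa(band, settings.dfa_boxes)
        except ValueError:
            dfa_exp = float("nan")
    values = np.array(list(rqa.as_tuple()) + [sampen, dfa_exp])
    return NLDMeasureSet(values=values, names=MEASURE_NAMES, rqa=rqa)
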