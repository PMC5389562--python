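"""Photobleaching step detection in single-spot intensity traces.

A bleaching trace is modeled as a piecewise-constant signal plus
independent Gaussian noise: each discrete drop corresponds to the
irreversible bleaching of one fluorophore, so the number of downward
steps counts the labeled molecules in the spot. Change points are
placed by exact dynamic-programming segmentation (globally optimal
residual sum of squares for every candidate step count), and the
number of steps retained maximizes a Schwarz-type penalized marginal
likelihood. Traces whose best fit violates the physics of bleaching —
upward steps, a terminal level off background, wildly uneven step
amplitudes, too-short dwells, or an ambiguous model score — are
classified not-determinable ("n.d.") and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StepFitParams", "StepFit", "StepClass", "fit_steps", "classify_trace",
           "estimate_noise_sd"]

ND = "n.d."


@dataclass(frozen=True)
class StepFitParams:
    """Settings for step fitting and trace classification.

    ``penalty`` scales the Schwarz penalty term; 1.0 is the plain BIC.
    The classification thresholds implement the rejection rules that
    feed the "n.d." class: ``max_terminal_sd`` bounds the final level's
    distance from background (in noise SDs), ``amp_band`` bounds each
    step amplitude relative to the median step, and ``score_margin``
    declares the fit ambiguous when a competing step count scores
    within that margin of the winner.
    """

    max_steps: int = 6
    min_dwell: int = 3
    penalty: float = 2.0
    max_terminal_sd: float = 3.0
    amp_band: tuple[float, float] = (0.4, 2.5)
    score_margin: float = 0.0
    background: float = 0.0


@dataclass(frozen=True)
class StepFit:
    """Change-point decomposition of one trace."""

    change_points: tuple[int, ...]  # frame index where each new segment starts
    levels: tuple[float, ...]  # mean level per segment
    noise_sd: float
    scores: dict[int, float]  # Schwarz-type score per candidate step count
    n_steps: int  # chosen number of change points

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.change_points) + 1:
            raise ValueError("levels must have one more entry than change points")
        if self.n_steps != len(self.change_points):
            raise ValueError("chosen count must equal retained change points")


@dataclass(frozen=True)
class StepClass:
    """Verdict for one trace: a step count, or the marker "n.d."."""

    verdict: int | str
    reason: str = ""

    @property
    def determined(self) -> bool:
        return self.verdict != ND


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD from first differences: MAD(diff) / (1.4826 * sqrt(2)).

    First differencing removes the piecewise-constant signal except at
    the (few) change points, which the median absolute deviation then
    ignores.
    """
    d = np.diff(np.asarray(trace, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / np.sqrt(2.0))


def _segment_cost_matrix(y: np.ndarray, min_dwell: int) -> np.ndarray:
    """cost[i, j] = RSS of segment y[i:j+1]; inf where shorter than min_dwell."""
    n = y.size
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    s1 = c1[j + 1] - c1[i]
    s2 = c2[j + 1] - c2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = s2 - s1 * s1 / length
    cost = np.where(length >= min_dwell, cost, np.inf)
    return np.maximum(cost, 0.0)  # clamp tiny negative rounding residue


def _optimal_partitions(cost: np.ndarray, max_cp: int) -> tuple[np.ndarray, np.ndarray]:
    """DP over change-point counts.

    Returns (rss, back) where rss[m, j] is the minimal total RSS of
    y[0:j+1] split into m+1 segments and back[m, j] the start frame of
    the last segment in that optimum.
    """
    n = cost.shape[0]
    rss = np.full((max_cp + 1, n), np.inf)
    back = np.zeros((max_cp + 1, n), dtype=int)
    rss[0] = cost[0]
    for m in range(1, max_cp + 1):
        # last segment starts at t (1..n-1); the part before it ends at t-1
        t = np.arange(1, n)
        totals = rss[m - 1][t - 1][:, None] + cost[t, :]  # (n-1, n)
        best_idx = np.argmin(totals, axis=0)
        rss[m] = totals[best_idx, np.arange(n)]
        back[m] = t[best_idx]
    return rss, back


def _score(rss_total: float, n: int, m: int, penalty: float) -> float:
    """Schwarz-type model score (lower is better) for m change points.

    Gaussian profile log-likelihood gives (n/2) log(RSS/n); each change
    point adds a location and a level, plus one overall level and one
    noise SD, hence (2m + 2) free parameters penalized by log(n).
    """
    rss_total = max(rss_total, 1e-12 * n)
    return n * np.log(rss_total / n) + penalty * (2 * m + 2) * np.log(n)


def fit_steps(trace: np.ndarray, params: StepFitParams | None = None) -> StepFit:
    """Fit a piecewise-constant bleaching profile to one trace.

    For every candidate step count m up to ``params.max_steps`` the
    globally optimal change-point placement (minimal residual sum of
    squares, dwell >= ``min_dwell``) is found by dynamic programming;
    the retained m minimizes the Schwarz-type score. All candidate
    scores are returned so the model selection is auditable.
    """
    params = params or StepFitParams()
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1:
        raise ValueError("trace must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    n = y.size
    if n < 2 * params.min_dwell:
        raise ValueError(
            f"trace length {n} shorter than 2 x min_dwell ({2 * params.min_dwell})"
        )
    max_cp = min(params.max_steps, n // params.min_dwell - 1)
    cost = _segment_cost_matrix(y, params.min_dwell)
    rss, back = _optimal_partitions(cost, max_cp)

    scores = {}
    for m in range(max_cp + 1):
        total = rss[m, n - 1]
        if np.isfinite(total):
            scores[m] = float(_score(total, n, m, params.penalty))
    m_best = min(scores, key=lambda m: (scores[m], m))

    # backtrack change points for the chosen m
    cps = []
    j = n - 1
    for m in range(m_best, 0, -1):
        t = int(back[m, j])
        cps.append(t)
        j = t - 1
    cps = tuple(sorted(cps))
    starts = (0,) + cps
    ends = cps + (n,)
    levels = tuple(float(np.mean(y[a:b])) for a, b in zip(starts, ends))
    return StepFit(
        change_points=cps,
        levels=levels,
        noise_sd=estimate_noise_sd(y),
        scores=scores,
        n_steps=m_best,
    )


def classify_trace(fit: StepFit, params: StepFitParams | None = None) -> StepClass:
    """Turn a step fit into a verdict, applying the bleaching rejection rules.

    The verdict equals the chosen step count when every retained step
    is a decrease, the terminal level is consistent with background,
    step amplitudes are mutually consistent, and no competing step
    count scores within ``score_margin`` of the winner; otherwise the
    trace is "n.d.".
    """
    params = params or StepFitParams()
    m = fit.n_steps
    sd = fit.noise_sd

    if params.score_margin > 0 and len(fit.scores) > 1:
        best = fit.scores[m]
        runner = min(v for k, v in fit.scores.items() if k != m)
        if runner - best < params.score_margin:
            return StepClass(ND, reason="ambiguous model score")

    drops = [fit.levels[i] - fit.levels[i + 1] for i in range(m)]
    if any(d <= 0 for d in drops):
        return StepClass(ND, reason="upward step")

    terminal = fit.levels[-1] - params.background
    if sd > 0 and abs(terminal) > params.max_terminal_sd * sd:
        return StepClass(ND, reason="terminal level off background")

    if m >= 2:
        med = float(np.median(drops))
        lo, hi = params.amp_band
        if any(not (lo * med <= d <= hi * med) for d in drops):
            return StepClass(ND, reason="inconsistent step amplitudes")

    return StepClass(m)
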