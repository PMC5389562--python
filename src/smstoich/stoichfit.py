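"""Occupancy inference from photobleaching step counts.

A surface-tethered pre-mRNA molecule offers 0, 1 or 2 binding sites to
a splicing factor. Each bound factor molecule is visible only if it
carries a mature fluorophore (probability ``f_labeled``), and a free
labeled molecule may itself be a dimer, bleaching in two steps instead
of one. The single-site step distribution is therefore taken directly
from free-protein calibration counts (spots bleaching in 1 vs 2 steps
in the absence of RNA), and the k-site expectation is its k-fold
convolution with the unlabeled mass mixed in per site, conditioned on
at least one visible step (an invisible complex is never scored).

Observed step histograms are compared with these expectations by
Pearson chi-square on classes pooled to an expected count >= 5, and the
proportions of RNA occupied at 0/1/2 sites are estimated by direct
chi-square minimization over the occupancy simplex and the number of
spots accessible in principle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LabelingParams",
    "StepDist",
    "StepHistogram",
    "GofResult",
    "OccupancyFit",
    "single_site_distribution",
    "k_site_distribution",
    "pool_classes",
    "chisq_gof",
    "fit_occupancy_mixture",
    "binomial_error",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class LabelingParams:
    """Calibration constants for one fluorescent fusion protein.

    Parameters
    ----------
    f_labeled:
        Fraction of the RNA-bound pool of this protein that carries a
        detectable fluorophore (labeled : unlabeled from affinity
        purification on biotinylated RNA).
    dimer_1step, dimer_2step:
        Counts of free labeled-protein spots (no RNA present) whose
        fluorescence bleached in one step vs two steps; their ratio
        measures RNA-independent dimerization.
    """

    f_labeled: float
    dimer_1step: int
    dimer_2step: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_labeled <= 1.0:
            raise ValueError(f"f_labeled must be in [0, 1], got {self.f_labeled}")
        if self.dimer_1step < 0 or self.dimer_2step < 0:
            raise ValueError("step counts must be non-negative")

    @property
    def dimer_fraction(self) -> float:
        """Fraction of free labeled spots that bleach in two steps."""
        total = self.dimer_1step + self.dimer_2step
        if total == 0:
            return 0.0
        return self.dimer_2step / total


@dataclass(frozen=True)
class StepDist:
    """Probability distribution over visible photobleaching step counts."""

    probs: dict[int, float]
    conditioned: bool  # True if renormalized onto {>= 1 visible step}

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        if any(p < -_SUM_TOL for p in self.probs.values()):
            raise ValueError("probabilities must be non-negative")
        if self.conditioned and self.probs.get(0, 0.0) > _SUM_TOL:
            raise ValueError("conditioned distribution must have no mass at 0")

    def as_array(self, max_steps: int) -> np.ndarray:
        """Probabilities on support 0..max_steps; tail mass folded into the top class."""
        arr = np.zeros(max_steps + 1)
        for k, p in self.probs.items():
            arr[min(k, max_steps)] += p
        return arr

    @property
    def support(self) -> list[int]:
        return sorted(k for k, p in self.probs.items() if p > 0)


@dataclass
class StepHistogram:
    """Observed step-count table for one protein/condition.

    ``counts`` maps visible step count (>= 1) to the number of
    colocalized complexes with that verdict; ``nd_count`` holds the
    not-determinable traces, which are reported but excluded from all
    statistics; ``total_rna`` is the number of RNA spots examined.
    """

    counts: dict[int, int] = field(default_factory=dict)
    nd_count: int = 0
    total_rna: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()) or self.nd_count < 0:
            raise ValueError("counts must be non-negative")
        if self.total_rna and self.total_colocalized > self.total_rna:
            raise ValueError("colocalized count exceeds RNA count")

    @property
    def total_scored(self) -> int:
        return sum(self.counts.values())

    @property
    def total_colocalized(self) -> int:
        return self.total_scored + self.nd_count

    @property
    def colocalized_fraction(self) -> float:
        if self.total_rna == 0:
            raise ValueError("total_rna not set")
        return self.total_colocalized / self.total_rna


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square goodness of fit on pooled step classes."""

    statistic: float
    df: int
    pvalue: float
    classes: list[tuple[int, int]]  # inclusive (lo, hi) step range per pooled class


@dataclass(frozen=True)
class OccupancyFit:
    """Estimated occupancy mixture over 0/1/2 occupied sites."""

    pi: tuple[float, float, float]
    n_accessible: int
    chisq: float


def single_site_distribution(free_1step: int, free_2step: int) -> StepDist:
    """Step distribution expected for a single occupied site.

    Taken directly from the observed free-protein calibration: the
    counts of labeled spots bleaching in one vs two steps in splicing
    conditions without RNA. Already conditioned on being visible.
    """
    if free_1step < 0 or free_2step < 0:
        raise ValueError("counts must be non-negative")
    total = free_1step + free_2step
    if total == 0:
        raise ValueError("at least one calibration count must be positive")
    probs = {}
    if free_1step:
        probs[1] = free_1step / total
    if free_2step:
        probs[2] = free_2step / total
    return StepDist(probs, conditioned=True)


def _per_site_pmf(single: StepDist, f_labeled: float, max_steps: int) -> np.ndarray:
    """Visible-step pmf for one occupied site: unlabeled with prob 1-f."""
    pmf = np.zeros(max_steps + 1)
    pmf[0] = 1.0 - f_labeled
    for s, p in single.probs.items():
        pmf[s] += f_labeled * p
    return pmf


def k_site_distribution(
    k: int,
    single: StepDist,
    f_labeled: float,
    *,
    conditioned: bool = True,
) -> StepDist:
    """Expected step distribution when ``k`` sites are all occupied.

    Each occupied site contributes 0 visible steps with probability
    ``1 - f_labeled`` (unlabeled endogenous protein, or immature
    fluorophore) and otherwise a draw from ``single``. The k-fold
    convolution is conditioned on a total of >= 1 visible step, because
    only spots showing some protein signal are ever scored; with
    ``conditioned=False`` the raw convolution (including the invisible
    class) is returned, as needed by the occupancy mixture.
    """
    if k < 1:
        raise ValueError("k must be >= 1 (no conditioning possible for k=0)")
    if not single.conditioned:
        raise ValueError("single-site distribution must be conditioned on >= 1 step")
    if not 0.0 <= f_labeled <= 1.0:
        raise ValueError("f_labeled must be in [0, 1]")
    s_max = max(single.support)
    site = _per_site_pmf(single, f_labeled, s_max)
    pmf = site
    for _ in range(k - 1):
        pmf = np.convolve(pmf, site)
    if conditioned:
        invisible = pmf[0]
        if invisible >= 1.0 - _SUM_TOL:
            raise ValueError("no visible mass to condition on (f_labeled = 0?)")
        pmf = pmf / (1.0 - invisible)
        probs = {s: float(p) for s, p in enumerate(pmf) if s >= 1 and p > 0}
        return StepDist(probs, conditioned=True)
    probs = {s: float(p) for s, p in enumerate(pmf) if p > 0 or s == 0}
    return StepDist(probs, conditioned=False)


def enumerate_k_site_distribution(
    k: int, single: StepDist, f_labeled: float, *, conditioned: bool = True
) -> StepDist:
    """Brute-force oracle for :func:`k_site_distribution`.

    Enumerates every joint outcome over the k sites explicitly
    (labeled/unlabeled x step count per site) instead of convolving.
    Exponential in k; intended for cross-checks at k <= 4.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    site_outcomes = [(0, 1.0 - f_labeled)] + [
        (s, f_labeled * p) for s, p in single.probs.items()
    ]
    totals: dict[int, float] = {}
    for combo in itertools.product(site_outcomes, repeat=k):
        steps = sum(s for s, _ in combo)
        prob = float(np.prod([p for _, p in combo]))
        totals[steps] = totals.get(steps, 0.0) + prob
    if conditioned:
        invisible = totals.pop(0, 0.0)
        norm = 1.0 - invisible
        totals = {s: p / norm for s, p in totals.items()}
    return StepDist({s: p for s, p in totals.items() if p > 0 or s == 0},
                    conditioned=conditioned)


def pool_classes(
    observed: StepHistogram | dict[int, int],
    expected: StepDist,
    n_expected_total: float,
    min_expected: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Pool step classes so every expected count is >= ``min_expected``.

    Classes are merged from the highest step count downward until each
    pooled class has an expected count of at least ``min_expected``
    (the standard validity rule for the Pearson test). Not-determinable
    traces are excluded. Returns pooled observed counts, pooled
    expected counts and the inclusive (lo, hi) step range of each
    pooled class; the top class is open-ended (hi = max observed or
    expected support).

    Raises if fewer than two pooled classes remain, in which case the
    test is undefined.
    """
    if n_expected_total <= 0:
        raise ValueError("n_expected_total must be positive")
    obs_counts = observed.counts if isinstance(observed, StepHistogram) else observed
    if any(s < 1 for s in obs_counts):
        raise ValueError("observed step classes must be >= 1 (n.d. excluded upstream)")
    if not expected.conditioned:
        raise ValueError("expected distribution must be conditioned on >= 1 step")
    s_max = max(
        max(expected.support, default=1), max((s for s in obs_counts), default=1)
    )
    exp = np.array([expected.probs.get(s, 0.0) * n_expected_total
                    for s in range(1, s_max + 1)])
    obs = np.array([obs_counts.get(s, 0) for s in range(1, s_max + 1)], dtype=float)

    # merge from the top down until every class reaches min_expected
    bounds = [(s, s) for s in range(1, s_max + 1)]
    exp_list = list(exp)
    obs_list = list(obs)
    i = len(exp_list) - 1
    while i > 0:
        if exp_list[i] < min_expected:
            exp_list[i - 1] += exp_list.pop(i)
            obs_list[i - 1] += obs_list.pop(i)
            lo, _ = bounds[i - 1]
            _, hi = bounds.pop(i)
            bounds[i - 1] = (lo, hi)
        i -= 1
    # the bottom class may still be short; merge upward into its neighbor
    while len(exp_list) > 1 and exp_list[0] < min_expected:
        exp_list[1] += exp_list[0]
        obs_list[1] += obs_list[0]
        bounds[1] = (bounds[0][0], bounds[1][1])
        exp_list.pop(0)
        obs_list.pop(0)
        bounds.pop(0)
    if len(exp_list) < 2:
        raise ValueError("fewer than 2 pooled classes remain; test undefined")
    return np.asarray(obs_list), np.asarray(exp_list), bounds


def chisq_gof(observed: np.ndarray, expected: np.ndarray,
              classes: list[tuple[int, int]] | None = None) -> GofResult:
    """Pearson chi-square test of observed against expected class counts.

    Degrees of freedom are (number of classes - 1): the expected
    distribution comes from an independent free-protein calibration, so
    no parameter is fitted to the observed counts.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have matching classes")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = observed.size - 1
    if df < 1:
        raise ValueError("need at least 2 classes")
    p = float(stats.chi2.sf(stat, df))
    if classes is None:
        classes = [(i + 1, i + 1) for i in range(observed.size)]
    return GofResult(statistic=stat, df=df, pvalue=p, classes=list(classes))


def single_site_gof(
    observed: StepHistogram | dict[int, int],
    labeling: LabelingParams,
    *,
    sites: int = 1,
    min_expected: float = 5.0,
) -> GofResult:
    """Convenience: test an observed histogram against full k-site occupancy."""
    single = single_site_distribution(labeling.dimer_1step, labeling.dimer_2step)
    if sites == 1:
        dist = single
    else:
        dist = k_site_distribution(sites, single, labeling.f_labeled)
    obs_counts = observed.counts if isinstance(observed, StepHistogram) else observed
    n = sum(obs_counts.values())
    obs, exp, bounds = pool_classes(obs_counts, dist, n, min_expected)
    return chisq_gof(obs, exp, bounds)


def fit_occupancy_mixture(
    observed: StepHistogram | dict[int, int],
    single: StepDist,
    f_labeled: float,
    n_total_candidates: range | list[int],
    *,
    grid_step: float = 0.01,
    min_expected: float = 5.0,
) -> OccupancyFit:
    """Estimate the proportions of RNA occupied at 0, 1 and 2 sites.

    Grid search over the occupancy simplex (pi0, pi1, pi2) at
    ``grid_step`` resolution and over the total number of spots N
    considered accessible in principle, minimizing the Pearson
    chi-square between observed and predicted class counts. Predicted
    visible-class counts use the *unconditioned* per-k distributions
    (a pi0 molecule, or an occupied one whose fluorophores are all
    dark, contributes to the invisible class); the invisible class
    itself enters the statistic whenever N exceeds the observed
    visible total. Ties break toward smaller pi2, then smaller N.
    """
    candidates = list(n_total_candidates)
    if not candidates:
        raise ValueError("empty candidate range for N")
    obs_counts = observed.counts if isinstance(observed, StepHistogram) else observed
    m_visible = sum(obs_counts.values())
    if any(n < m_visible for n in candidates):
        raise ValueError("candidate N below observed visible total")

    u1 = k_site_distribution(1, single, f_labeled, conditioned=False)
    u2 = k_site_distribution(2, single, f_labeled, conditioned=False)
    s_max = max(max(u2.support, default=1), max(obs_counts, default=1))
    a1 = u1.as_array(s_max)
    a2 = u2.as_array(s_max)
    obs_vec = np.array([obs_counts.get(s, 0) for s in range(1, s_max + 1)],
                       dtype=float)

    n_ticks = round(1.0 / grid_step)
    ij = [(i, j) for i in range(n_ticks + 1) for j in range(n_ticks + 1 - i)]
    pi0 = np.array([i for i, _ in ij]) * grid_step
    pi1 = np.array([j for _, j in ij]) * grid_step
    pi2 = np.maximum(1.0 - pi0 - pi1, 0.0)
    # visible-class probabilities per grid point: (grid, classes 1..s_max)
    p_vis = pi1[:, None] * a1[None, 1:] + pi2[:, None] * a2[None, 1:]
    p_inv = pi0 + pi1 * a1[0] + pi2 * a2[0]

    best = None
    for n_total in candidates:
        exp_vis = n_total * p_vis
        # chi-square over visible classes with expected>0; infeasible rows
        # (zero expected where counts were observed) are excluded
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (obs_vec[None, :] - exp_vis) ** 2 / exp_vis
        terms = np.where(exp_vis > 0, terms,
                         np.where(obs_vec[None, :] > 0, np.inf, 0.0))
        chi = terms.sum(axis=1)
        if n_total > m_visible:
            exp_inv = n_total * p_inv
            obs_inv = n_total - m_visible
            with np.errstate(divide="ignore", invalid="ignore"):
                inv_term = (obs_inv - exp_inv) ** 2 / exp_inv
            chi = chi + np.where(exp_inv > 0, inv_term,
                                 np.inf if obs_inv > 0 else 0.0)
        order = np.lexsort((pi0, -pi1, pi2, chi))  # chi, then small pi2, ...
        idx = order[0]
        key = (float(chi[idx]), float(pi2[idx]), n_total)
        if best is None or key < best[0]:
            best = (key, (float(pi0[idx]), float(pi1[idx]), float(pi2[idx])),
                    n_total, float(chi[idx]))
    _, pi, n_best, chi_best = best
    return OccupancyFit(pi=pi, n_accessible=n_best, chisq=chi_best)


def binomial_error(count: int, n: int) -> float:
    """Standard error of a binomial proportion, sqrt(p(1-p)/n).

    Used for the error bars on step-frequency histograms: the square
    root of the variance of the binomial probability that an RNA spot
    shows the given number of protein bleaching steps.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError("count must be in [0, n]")
    p = count / n
    return float(np.sqrt(p * (1.0 - p) / n))
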