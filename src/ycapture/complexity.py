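"""Library-complexity estimation and yield / enrichment extrapolation.

The duplicate-count histogram (n_j distinct templates seen exactly j times)
is the sufficient statistic for how unique-read yield saturates with
sequencing effort. Per-template read counts are modeled as negative
binomial (a Gamma-Poisson mixture over template "capturability"); the
unobserved zero class is recovered by an EM fit of the zero-truncated
negative binomial, giving a library-size estimate

    L = D / (1 - p0),        p0 = (1 + mu/r)^(-r)

for D observed distinct templates, and an expected-yield function

    yield(t) = L * (1 - (1 + t*mu/r)^(-r))

at effort multiplier t (relative to the observed read count). This is
increasing and concave in t, interpolates the observed distinct count at
t = 1, and reduces to the Poisson occupancy curve as r -> infinity.
Libraries without duplicates carry no curvature information; a linear
model with slope unique/total is used instead. Uncertainty comes from
bootstrapping the histogram (100 replicates by default): resample the
observed template classes with replacement, refit, re-extrapolate, and
report the per-grid-point median and variance.

Effort grids are expressed in total sequenced reads and converted to
on-target effort through the library's on-target read fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import optimize, special

from .accounting import DuplicateHistogram

#: Default effort grid: 50 log-spaced points over 1e2..1e7 total reads.
DEFAULT_EFFORT_GRID = np.logspace(2, 7, 50)

DEFAULT_N_BOOTSTRAP = 100

_R_LOG_BOUNDS = (-4.0, 8.0)  # log10 bounds for the NB dispersion parameter


class NoDuplicatesError(ValueError):
    """Raised when a histogram has no multiplicity >= 2 class.

    Without duplicates the saturation of the library is unidentifiable;
    callers should fall back to :func:`linear_fallback`.
    """


class YieldModel(Protocol):
    """Expected distinct reads as a function of (on-target) sequencing effort."""

    def expected_distinct(self, n_reads: np.ndarray | float) -> np.ndarray | float: ...


@dataclass(frozen=True)
class ZTNBYieldModel:
    """Zero-truncated negative-binomial library model.

    Attributes (fitted): ``library_size_`` L, dispersion ``r_``, per-template
    mean ``mu_`` at the observed effort, and the observed totals.
    """

    library_size_: float
    r_: float
    mu_: float
    observed_reads_: int
    observed_distinct_: int
    tag: str = "ztnb"

    def expected_distinct(self, n_reads):
        t = np.asarray(n_reads, dtype=float) / self.observed_reads_
        p0 = np.exp(-self.r_ * np.log1p(t * self.mu_ / self.r_))
        out = self.library_size_ * (1.0 - p0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class LinearYieldModel:
    """Duplicate-free fallback: yield proportional to effort.

    Slope is the proportion of unique on-target reads in the library;
    effort units are whatever ``total_reads`` was expressed in.
    """

    slope_: float
    observed_reads_: int
    observed_distinct_: int
    tag: str = "linear"

    def expected_distinct(self, n_reads):
        out = self.slope_ * np.asarray(n_reads, dtype=float)
        return out if out.ndim else float(out)


def _nb_zero_prob(mu: float, r: float) -> float:
    return float(np.exp(-r * np.log1p(mu / r)))


def _nb_loglik_r(log10_r: float, js: np.ndarray, ws: np.ndarray, mu: float) -> float:
    """Weighted NB log-likelihood profiled over the dispersion (mean fixed)."""
    r = 10.0**log10_r
    # logpmf(j; r, p) with p = r/(r+mu), written via gammaln for stability
    logp = r * np.log(r / (r + mu)) + js * np.log(mu / (r + mu))
    logp += special.gammaln(js + r) - special.gammaln(r) - special.gammaln(js + 1)
    return float(np.dot(ws, logp))


def fit_yield_model(
    hist: DuplicateHistogram, max_iter: int = 100, tol: float = 1e-6
) -> ZTNBYieldModel:
    """Fit the zero-truncated negative binomial by EM.

    E-step imputes the expected count of unseen templates from the current
    zero probability; M-step updates the mean in closed form and the
    dispersion by 1-d profile likelihood. Raises :class:`NoDuplicatesError`
    when every observed class has multiplicity 1.
    """
    if not hist.counts or hist.distinct == 0:
        raise ValueError("empty histogram")
    if not hist.has_duplicates:
        raise NoDuplicatesError("histogram has no duplicate class; use linear_fallback")
    js_obs = np.fromiter(hist.counts.keys(), dtype=float)
    ws_obs = np.fromiter(hist.counts.values(), dtype=float)
    D = float(hist.distinct)
    N = float(hist.total_reads)

    mu = N / D
    r = 1.0
    n0 = 0.0
    for _ in range(max_iter):
        p0 = _nb_zero_prob(mu, r)
        n0_new = D * p0 / (1.0 - p0)
        total = D + n0_new
        mu_new = N / total
        js = np.concatenate(([0.0], js_obs))
        ws = np.concatenate(([n0_new], ws_obs))
        res = optimize.minimize_scalar(
            lambda x: -_nb_loglik_r(x, js, ws, mu_new),
            bounds=_R_LOG_BOUNDS,
            method="bounded",
        )
        r_new = 10.0**res.x
        if (
            abs(mu_new - mu) < tol * max(1.0, mu)
            and abs(r_new - r) < tol * max(1.0, r)
            and abs(n0_new - n0) < tol * max(1.0, n0)
        ):
            mu, r, n0 = mu_new, r_new, n0_new
            break
        mu, r, n0 = mu_new, r_new, n0_new
    p0 = _nb_zero_prob(mu, r)
    L = D / (1.0 - p0)
    return ZTNBYieldModel(L, r, mu, int(N), int(D))


def linear_fallback(unique_on_target: int, total_reads: int) -> LinearYieldModel:
    """Linear yield model for duplicate-free libraries: yield(n) = n * unique/total."""
    if total_reads < 1 or unique_on_target < 0 or unique_on_target > total_reads:
        raise ValueError("need 0 <= unique_on_target <= total_reads, total_reads >= 1")
    return LinearYieldModel(unique_on_target / total_reads, total_reads, unique_on_target)


@dataclass(frozen=True)
class YieldCurve:
    """Expected unique on-target reads vs total sequencing effort."""

    efforts: np.ndarray  # total sequenced reads
    median: np.ndarray  # expected / bootstrap-median unique on-target reads
    variance: np.ndarray | None
    on_target_fraction: float
    model_tag: str

    def check_shape(self, rtol: float = 1e-9) -> None:
        """Assert the curve is non-decreasing and concave on its grid."""
        d1 = np.diff(self.median)
        if np.any(d1 < -rtol * np.maximum(1.0, self.median[:-1])):
            raise AssertionError("yield curve is not non-decreasing")
        slopes = d1 / np.diff(self.efforts)
        if np.any(np.diff(slopes) > rtol * np.maximum(1e-12, np.abs(slopes[:-1]))):
            raise AssertionError("yield curve is not concave")


@dataclass(frozen=True)
class EnrichmentCurve:
    """Pointwise ratio of two yield-curve medians over a shared effort grid."""

    efforts: np.ndarray
    fold: np.ndarray  # NaN where the denominator median is zero
    numerator_label: str
    denominator_label: str


def _prepare_grid(effort_grid: Sequence[float]) -> np.ndarray:
    grid = np.asarray(effort_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("effort grid values must be >= 0")
    if np.any(np.diff(grid) < 0):
        warnings.warn("effort grid not sorted; sorting", stacklevel=3)
        grid = np.sort(grid)
    return grid


def extrapolate_yield(
    model: YieldModel,
    effort_grid: Sequence[float],
    on_target_fraction: float,
    model_tag: str | None = None,
) -> YieldCurve:
    """Evaluate a yield model over a total-effort grid.

    Total sequencing effort is converted to on-target effort by the
    library's on-target read fraction before the model is evaluated, so
    the curve answers "how many unique on-target reads for n total reads".
    """
    if not 0.0 < on_target_fraction <= 1.0:
        raise ValueError("on_target_fraction must be in (0, 1]")
    grid = _prepare_grid(effort_grid)
    median = np.asarray(model.expected_distinct(grid * on_target_fraction), dtype=float)
    return YieldCurve(
        grid, median, None, on_target_fraction, model_tag or getattr(model, "tag", "?")
    )


def _fit_or_fallback(hist: DuplicateHistogram) -> YieldModel:
    try:
        return fit_yield_model(hist)
    except NoDuplicatesError:
        return linear_fallback(hist.distinct, hist.total_reads)


def bootstrap_yield(
    hist: DuplicateHistogram,
    effort_grid: Sequence[float],
    on_target_fraction: float,
    n_boot: int = DEFAULT_N_BOOTSTRAP,
    seed: int = 0,
) -> YieldCurve:
    """Bootstrap the yield curve by resampling the duplicate histogram.

    Each replicate draws the observed number of distinct template classes
    with replacement from the observed classes (i.e. bootstraps the
    histogram, the sufficient statistic), refits — falling back to the
    linear model for duplicate-free replicates — and re-extrapolates, each
    replicate normalized to its own resampled read total. Reports
    per-grid-point median and variance across replicates. Resampling
    classes rather than individual reads keeps every replicate curve
    interpolating its own observed distinct count; read-level resampling
    would systematically shed a fraction of singleton classes and bias the
    curve low at the observed effort.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    grid = _prepare_grid(effort_grid)
    rng = np.random.default_rng(seed)
    mult = hist.multiplicities()
    D = len(mult)
    curves = np.empty((n_boot, len(grid)))
    tags = []
    for b in range(n_boot):
        resampled = mult[rng.integers(0, D, size=D)]
        hist_b = DuplicateHistogram.from_multiplicities(resampled)
        model = _fit_or_fallback(hist_b)
        tags.append(model.tag)
        curves[b] = np.asarray(model.expected_distinct(grid * on_target_fraction), dtype=float)
    median = np.median(curves, axis=0)
    variance = np.var(curves, axis=0)
    tag = "ztnb" if "ztnb" in tags else "linear"
    return YieldCurve(grid, median, variance, on_target_fraction, f"{tag}+bootstrap")


def enrichment_curve(numerator: YieldCurve, denominator: YieldCurve) -> EnrichmentCurve:
    """Pointwise fold-enrichment between two yield curves on a shared grid.

    Grid points where the denominator median is zero are reported missing
    (NaN); no zero-substitution rule applies to curves.
    """
    if not np.array_equal(numerator.efforts, denominator.efforts):
        raise ValueError("curves must share the effort grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            denominator.median > 0, numerator.median / denominator.median, np.nan
        )
    return EnrichmentCurve(
        numerator.efforts, fold, numerator.model_tag, denominator.model_tag
    )


def occupancy_expected_distinct(
    retention_probs: Sequence[float], n_reads: int
) -> float:
    """Closed-form expected distinct templates: sum_i 1 - (1 - p_i)^n.

    Exact for sampling n reads independently where read -> template i with
    probability p_i; the uniform case reduces to P * (1 - (1 - 1/P)^n).
    Serves as the independent oracle for the simulator and the extrapolator.
    """
    p = np.asarray(retention_probs, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("retention_probs must be a probability vector")
    return float(np.sum(-np.expm1(n_reads * np.log1p(-p))))
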