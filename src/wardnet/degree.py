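"""Degree-distribution histograms and Weibull-vs-normal model comparison.

Modular ward-unit graphs have hubbed, fat-tailed degree distributions: a few
high-degree units tie many wards together while most nodes have few links.
To quantify the shape, the pooled node-degree histogram (wards and units
together, fixed bin width, normalized to a density) is fitted by nonlinear
least squares with two candidate families — a two-parameter Weibull (an
exponential-family, fat-tail-capable shape) and a normal — and the families
are compared by the mean squared error between fitted and observed densities
at the bin centres.  A lower Weibull MSE indicates the skewed, non-Gaussian
shape expected of a modular service structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .build import SnapshotGraph
from .errors import FitError, GraphError

#: Default histogram bin width for node degrees.
DEFAULT_BIN_WIDTH = 0.99


@dataclass
class DegreeHistogram:
    """Normalized degree histogram: sum(density * bin_width) == 1."""

    bin_edges: np.ndarray
    densities: np.ndarray
    n_nodes: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centres(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class FitResult:
    """One family's least-squares fit to a density histogram.

    ``params`` holds ``(shape k, scale lam)`` for the Weibull family and
    ``(mean mu, sd sigma)`` for the normal.  ``mse`` is the achieved mean
    squared error between fitted and observed densities at bin centres.
    """

    family: str
    params: tuple[float, float]
    mse: float


def _histogram(values: np.ndarray, bin_width: float) -> DegreeHistogram:
    lo = float(np.min(values))
    hi = float(np.max(values))
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width + 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= hi:  # right edge must cover the max (numpy closes last bin)
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(values, bins=edges)
    dens = counts / (len(values) * bin_width)
    return DegreeHistogram(bin_edges=edges, densities=dens, n_nodes=len(values))


def degree_histogram(graph: SnapshotGraph, bin_width: float = DEFAULT_BIN_WIDTH) -> DegreeHistogram:
    """Histogram of pooled ward+unit node degrees, bins starting at the
    minimum degree."""
    if graph.n_nodes == 0:
        raise GraphError("degree histogram of an empty graph")
    degrees = np.array(sorted(graph.degree().values()), dtype=float)
    return _histogram(degrees, bin_width)


def sample_histogram(
    values: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH
) -> DegreeHistogram:
    """Histogram of arbitrary samples with the same normalization, for
    calibration studies on known distributions."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise GraphError("cannot histogram an empty sample")
    return _histogram(values, bin_width)


def _weibull_pdf(x: np.ndarray, k: float, lam: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    z = x[pos] / lam
    out[pos] = (k / lam) * z ** (k - 1.0) * np.exp(-(z**k))
    return out


def _normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return stats.norm.pdf(x, loc=mu, scale=sigma)


def _moments(hist: DegreeHistogram) -> tuple[float, float]:
    """Mean and sd of the binned distribution (density-weighted centres)."""
    c = hist.bin_centres
    w = hist.densities * hist.bin_width
    mean = float(np.sum(w * c))
    var = float(np.sum(w * (c - mean) ** 2))
    return mean, max(np.sqrt(var), 1e-6)


def _weibull_moment_start(mean: float, sd: float) -> tuple[float, float]:
    # standard approximation k ~ (mean/sd)^1.086, then scale from the mean
    k0 = float(np.clip((mean / sd) ** 1.086, 0.1, 50.0))
    lam0 = mean / float(special.gamma(1.0 + 1.0 / k0))
    return k0, lam0


def fit_family(hist: DegreeHistogram, family: str) -> FitResult:
    """Least-squares fit of one density family to the histogram.

    Minimizes the summed squared difference between the family's pdf at the
    bin centres and the observed densities, starting from method-of-moments
    estimates (deterministic).  The Weibull location is fixed at zero.

    Raises
    ------
    FitError
        Degenerate histogram (< 3 non-empty bins) or optimizer failure.
    """
    if family not in ("weibull", "normal"):
        raise ValueError(f"unknown family {family!r}")
    if int(np.sum(hist.densities > 0)) < 3:
        raise FitError(
            f"{family} fit needs >= 3 non-empty bins, got {int(np.sum(hist.densities > 0))}"
        )
    x = hist.bin_centres
    y = hist.densities
    mean, sd = _moments(hist)
    if family == "weibull":
        if np.any(x <= 0):
            # shift is not modelled; degrees are >= 1 in practice
            raise FitError("weibull fit requires positive bin centres")
        pdf = _weibull_pdf
        p0 = _weibull_moment_start(mean, sd)
        bounds = ([1e-3, 1e-6], [200.0, np.inf])
    else:
        pdf = _normal_pdf
        p0 = (mean, sd)
        bounds = ([-np.inf, 1e-9], [np.inf, np.inf])

    def residuals(p):
        return pdf(x, *p) - y

    res = optimize.least_squares(residuals, p0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise FitError(f"{family} fit did not converge: {res.message}", trace=res)
    mse = float(np.mean(res.fun**2))
    return FitResult(family=family, params=(float(res.x[0]), float(res.x[1])), mse=mse)


def compare_fits(hist: DegreeHistogram) -> tuple[FitResult, FitResult, str]:
    """Fit both families and name the one with the smaller MSE.

    Returns ``(weibull_fit, normal_fit, preferred)`` where ``preferred`` is
    ``"weibull"``, ``"normal"``, or ``"indeterminate"`` when the MSEs agree
    to within 1e-12.
    """
    wb = fit_family(hist, "weibull")
    nm = fit_family(hist, "normal")
    if abs(wb.mse - nm.mse) <= 1e-12:
        preferred = "indeterminate"
    else:
        preferred = "weibull" if wb.mse < nm.mse else "normal"
    return wb, nm, preferred


def loglog_points(hist: DegreeHistogram) -> tuple[np.ndarray, np.ndarray]:
    """(log degree, log density) for non-empty bins — a plotting aid for
    eyeballing non-Gaussian tails; no inference is attached to it."""
    mask = (hist.densities > 0) & (hist.bin_centres > 0)
    return np.log10(hist.bin_centres[mask]), np.log10(hist.densities[mask])


def plot_degree_fit(hist: DegreeHistogram, ax=None):
    """Plot the degree histogram with both fitted families overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    wb, nm, preferred = compare_fits(hist)
    ax.bar(hist.bin_centres, hist.densities, width=hist.bin_width * 0.9,
           color="lightsteelblue", label="observed")
    xs = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 200)
    ax.plot(xs, _weibull_pdf(xs, *wb.params), label=f"weibull (mse={wb.mse:.2g})")
    ax.plot(xs, _normal_pdf(xs, *nm.params), label=f"normal (mse={nm.mse:.2g})")
    ax.set_xlabel("node degree")
    ax.set_ylabel("density")
    ax.legend(title=f"preferred: {preferred}")
    return ax
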