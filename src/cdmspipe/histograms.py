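"""Histograms of ion measurements and Gaussian conformer decomposition.

Charge histograms of electrosprayed capsids resolve coexisting solution
conformers as overlapping sub-distributions.  Following standard CDMS
practice the decomposition is a non-linear least-squares fit of a sum of
Gaussians to the *binned* counts (not per-ion maximum likelihood), exposed
statsmodels-style: ``GaussianMixtureModel(hist, k).fit()`` returns a
:class:`GaussianMixtureResults` carrying components, standard errors,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .rayleigh import RayleighConstants, DEFAULT_CONSTANTS, rayleigh_charge_for_mass

__all__ = [
    "Histogram",
    "Histogram2D",
    "GaussianComponent",
    "GaussianMixtureModel",
    "GaussianMixtureResults",
    "histogram1d",
    "histogram2d",
    "charge_histogram",
    "mass_histogram",
    "fit_gaussian_mixture",
    "centroid",
]

#: default bin widths: charge 1 e (integer-centered), mass 20 kDa
CHARGE_BIN_E = 1.0
MASS_BIN_DA = 2.0e4


@dataclass(frozen=True)
class Histogram:
    """Uniform-bin 1D histogram; bins are half-open [lo, hi)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"center": self.centers, "count": self.counts})


@dataclass(frozen=True)
class Histogram2D:
    """Joint mass/charge histogram with an optional Rayleigh-line overlay."""

    mass_edges: np.ndarray
    charge_edges: np.ndarray
    counts: np.ndarray
    rayleigh_overlay_e: np.ndarray | None = None

    @property
    def mass_centers(self) -> np.ndarray:
        return 0.5 * (self.mass_edges[:-1] + self.mass_edges[1:])

    @property
    def charge_centers(self) -> np.ndarray:
        return 0.5 * (self.charge_edges[:-1] + self.charge_edges[1:])


@dataclass(frozen=True)
class GaussianComponent:
    """One conformer sub-distribution: centroid, width, area (ion count)."""

    centroid: float
    sigma: float
    area: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.area <= 0:
            raise ValueError("sigma and area must be strictly positive")


def histogram1d(values, bin_width: float, range_=None, label: str = "", units: str = "") -> Histogram:
    """Uniform histogram with bins centered on multiples of ``bin_width``.

    With the default 1 e charge bins the centers sit on integers, so 164.5
    falls in the (right-open) 165 bin.  Empty input yields an empty (all-zero,
    single-bin) histogram rather than an error.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be strictly positive")
    v = np.asarray(values, dtype=float)
    if range_ is not None:
        lo, hi = range_
    elif v.size == 0:
        lo, hi = 0.0, bin_width
    else:
        lo, hi = float(v.min()), float(v.max())
    c0 = bin_width * np.floor(lo / bin_width + 0.5)
    c1 = bin_width * np.floor(hi / bin_width + 0.5)
    edges = np.arange(c0 - bin_width / 2.0, c1 + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([c0 - bin_width / 2.0, c0 + bin_width / 2.0])
    counts, edges = np.histogram(v, bins=edges)
    # np.histogram closes the last bin; re-assign exact upper-edge hits to
    # preserve the half-open convention by appending one bin when needed
    if v.size and np.any(v == edges[-1]):
        counts = np.append(counts, 0)
        n_top = int(np.sum(v == edges[-1]))
        counts[-2] -= n_top
        counts[-1] += n_top
        edges = np.append(edges, edges[-1] + bin_width)
    return Histogram(bin_edges=edges, counts=counts, label=label, units=units)


def charge_histogram(values, bin_width: float = CHARGE_BIN_E) -> Histogram:
    return histogram1d(values, bin_width, label="charge", units="e")


def mass_histogram(values, bin_width: float = MASS_BIN_DA) -> Histogram:
    return histogram1d(values, bin_width, label="mass", units="Da")


def histogram2d(
    mass_values,
    charge_values,
    mass_bin: float = MASS_BIN_DA,
    charge_bin: float = CHARGE_BIN_E,
    consts: RayleighConstants | None = DEFAULT_CONSTANTS,
) -> Histogram2D:
    """Joint mass/charge histogram; the overlay gives the Rayleigh-limit
    charge at each mass-bin center (the dashed "Rayleigh line")."""
    m = np.asarray(mass_values, dtype=float)
    z = np.asarray(charge_values, dtype=float)
    if m.shape != z.shape:
        raise ValueError("mass and charge arrays must have equal length")
    hm = histogram1d(m, mass_bin)
    hz = histogram1d(z, charge_bin)
    counts, me, ze = np.histogram2d(m, z, bins=[hm.bin_edges, hz.bin_edges])
    overlay = None
    if consts is not None:
        overlay = rayleigh_charge_for_mass(0.5 * (me[:-1] + me[1:]), consts)
        overlay = np.atleast_1d(overlay)
    return Histogram2D(mass_edges=me, charge_edges=ze, counts=counts, rayleigh_overlay_e=overlay)


# --------------------------------------------------------------------------
# Gaussian mixture decomposition


def _mixture_model(x: np.ndarray, params: np.ndarray, bin_width: float) -> np.ndarray:
    k = len(params) // 3
    out = np.zeros_like(x)
    for j in range(k):
        area, c, s = params[3 * j : 3 * j + 3]
        out += area * bin_width / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / s) ** 2)
    return out


def _initial_centroids(hist: Histogram, k: int) -> np.ndarray:
    """Local maxima of the 3-bin-smoothed counts; quantile fill-in if fewer
    than k maxima exist."""
    smooth = np.convolve(hist.counts.astype(float), np.ones(3) / 3.0, mode="same")
    peaks, props = signal.find_peaks(smooth, height=max(smooth.max() * 0.05, 1e-12))
    centers = hist.centers
    if peaks.size:
        order = np.argsort(props["peak_heights"])[::-1]
        cands = list(centers[peaks[order]])
    else:
        cands = []
    if len(cands) < k:
        w = hist.counts / max(hist.n, 1)
        qs = np.linspace(0.1, 0.9, k - len(cands))
        cdf = np.cumsum(w)
        extra = [centers[np.searchsorted(cdf, q)] for q in qs]
        cands.extend(extra)
    return np.array(sorted(cands[:k]))


class GaussianMixtureModel:
    """Sum-of-Gaussians model for a binned histogram.

    Parameters
    ----------
    hist : Histogram
        Nonempty histogram to decompose.
    k : int or "auto"
        Number of components; "auto" selects k in 1..8 by BIC computed from
        the least-squares residual under a Gaussian-error assumption.
    init : sequence of float, optional
        Initial centroids; defaults to local maxima of the 3-bin-smoothed
        counts.
    poisson_weights : bool
        Weight residuals by 1/sqrt(counts+1) (approximate Poisson weighting);
        off by default.
    sigma_bounds : (float, float), optional
        Bounds on component widths; default (bin_width/2, span/2), which with
        the standard 1 e charge bins gives a 0.5 e anti-collapse floor.
    """

    MAX_AUTO_K = 8

    def __init__(self, hist: Histogram, k=1, init=None, poisson_weights: bool = False,
                 sigma_bounds: tuple[float, float] | None = None):
        if hist.n == 0:
            raise ValueError("histogram is empty")
        self.hist = hist
        self.k = k
        self.init = None if init is None else np.asarray(init, dtype=float)
        self.poisson_weights = poisson_weights
        span = float(hist.bin_edges[-1] - hist.bin_edges[0])
        self.sigma_bounds = sigma_bounds or (hist.bin_width / 2.0, max(span / 2.0, hist.bin_width))

    def _fit_k(self, k: int) -> "GaussianMixtureResults":
        hist = self.hist
        x, y = hist.centers, hist.counts.astype(float)
        if np.count_nonzero(y) < 2 and k >= 1:
            raise ValueError("histogram is degenerate (fewer than two occupied bins)")
        if self.init is not None and len(self.init) == k:
            c0 = np.sort(np.asarray(self.init, dtype=float))
        else:
            c0 = _initial_centroids(hist, k)
        slo, shi = self.sigma_bounds
        spacing = np.min(np.diff(c0)) / 2.0 if k > 1 else (x.max() - x.min()) / 4.0
        s0 = np.clip(max(spacing, 2.0 * hist.bin_width), slo, shi)
        a0 = max(hist.n / k, 1.0)
        p0, lo, hi = [], [], []
        for c in c0:
            p0 += [a0, c, s0]
            lo += [0.0, x.min() - hist.bin_width, slo]
            hi += [np.inf, x.max() + hist.bin_width, shi]
        w = 1.0 / np.sqrt(y + 1.0) if self.poisson_weights else np.ones_like(y)
        bw = hist.bin_width

        def resid(p):
            return w * (_mixture_model(x, p, bw) - y)

        def jac(p):
            J = np.empty((x.size, p.size))
            for j in range(k):
                area, c, s = p[3 * j : 3 * j + 3]
                u = (x - c) / s
                phi = bw / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * u**2)
                J[:, 3 * j] = w * phi
                J[:, 3 * j + 1] = w * area * phi * u / s
                J[:, 3 * j + 2] = w * area * phi * (u**2 - 1.0) / s
            return J

        sol = optimize.least_squares(resid, p0, jac=jac, bounds=(lo, hi), max_nfev=120 * k)
        comps = []
        for j in range(k):
            area, c, s = sol.x[3 * j : 3 * j + 3]
            comps.append(GaussianComponent(centroid=c, sigma=s, area=max(area, 1e-12)))
        comps.sort(key=lambda g: -g.centroid)
        rss = float(np.sum((resid(sol.x) / w) ** 2))
        n_bins = len(y)
        p = 3 * k
        if self.poisson_weights:
            # weighted RSS is the chi-square statistic of a Gaussian error
            # model with known per-bin variances -> BIC = chi2 + p ln(nbins)
            chi2 = float(np.sum(resid(sol.x) ** 2))
            bic = chi2 + p * np.log(n_bins)
        else:
            bic = n_bins * np.log(max(rss / n_bins, 1e-300)) + p * np.log(n_bins)
        # standard errors from the Gauss-Newton approximation J'J
        stderr = np.full(p, np.nan)
        try:
            jtj = sol.jac.T @ sol.jac
            s2 = rss / max(n_bins - p, 1)
            cov = s2 * np.linalg.pinv(jtj)
            stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except Exception:  # pragma: no cover - singular fit
            pass
        return GaussianMixtureResults(
            model=self,
            components=comps,
            converged=bool(sol.success),
            rss=rss,
            bic=float(bic),
            k=k,
            param_stderr=stderr,
            n_bins=n_bins,
        )

    def fit(self) -> "GaussianMixtureResults":
        if self.k == "auto":
            # Selection runs on Poisson-weighted fits (per-bin variances are
            # count-dependent, so the chi-square BIC is the meaningful one);
            # the chosen k is then refitted with the user's weighting.
            # Smallest k within delta-BIC <= 2 of the minimum wins; stop once
            # BIC has failed to improve twice in a row.
            selector = (
                self
                if self.poisson_weights
                else GaussianMixtureModel(
                    self.hist, k=1, init=self.init, poisson_weights=True,
                    sigma_bounds=self.sigma_bounds,
                )
            )
            fits, stall = [], 0
            for k in range(1, self.MAX_AUTO_K + 1):
                try:
                    res = selector._fit_k(k)
                except ValueError:
                    continue
                fits.append(res)
                if len(fits) > 1 and res.bic > min(f.bic for f in fits[:-1]) - 2.0:
                    stall += 1
                    if stall >= 2:
                        break
                else:
                    stall = 0
            if not fits:
                raise ValueError("no mixture size could be fitted")
            best_bic = min(f.bic for f in fits)
            k_best = next(f.k for f in fits if f.bic <= best_bic + 2.0)
            return self._fit_k(k_best)
        return self._fit_k(int(self.k))


@dataclass
class GaussianMixtureResults:
    """Fitted mixture: components sorted by descending centroid."""

    model: GaussianMixtureModel
    components: list
    converged: bool
    rss: float
    bic: float
    k: int
    param_stderr: np.ndarray
    n_bins: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.components])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.components])

    def predict(self, x) -> np.ndarray:
        params = []
        for c in self.components:
            params += [c.area, c.centroid, c.sigma]
        return _mixture_model(np.asarray(x, dtype=float), np.array(params), self.model.hist.bin_width)

    def r_squared(self) -> float:
        y = self.model.hist.counts.astype(float)
        tss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - self.rss / tss if tss > 0 else 0.0

    def summary(self) -> str:
        lines = [
            "Gaussian mixture decomposition",
            f"  components: {self.k}   bins: {self.n_bins}   converged: {self.converged}",
            f"  RSS: {self.rss:.4g}   BIC: {self.bic:.4g}   R^2: {self.r_squared():.4f}",
            f"  {'centroid':>12} {'sigma':>10} {'area':>12}",
        ]
        for c in self.components:
            lines.append(f"  {c.centroid:>12.2f} {c.sigma:>10.2f} {c.area:>12.1f}")
        return "\n".join(lines)


def fit_gaussian_mixture(hist: Histogram, k=1, init=None, **kwargs) -> GaussianMixtureResults:
    """Decompose a histogram into Gaussian components (non-linear least
    squares on the binned counts).  See :class:`GaussianMixtureModel`."""
    return GaussianMixtureModel(hist, k=k, init=init, **kwargs).fit()


def centroid(hist: Histogram, full_output: bool = False):
    """Centroid of a histogram from a single-Gaussian least-squares fit.

    Falls back to the count-weighted mean (flagged) when the fit fails or
    describes the data poorly (R^2 < 0.8, e.g. strongly bimodal input).
    """
    if hist.n == 0:
        raise ValueError("histogram is empty")
    fallback = float(np.average(hist.centers, weights=hist.counts))
    flagged = False
    try:
        res = fit_gaussian_mixture(hist, k=1)
        value = float(res.centroids[0])
        if not res.converged or res.r_squared() < 0.8:
            value, flagged = fallback, True
    except (ValueError, RuntimeError):
        value, flagged = fallback, True
    return (value, flagged) if full_output else value
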