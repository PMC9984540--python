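"""Histogramming, time-resolution fitting, background subtraction and the
integral fall-off shift statistic.

The shift statistic compares an experimental profile against a
high-statistics reference: both are integrated into normalized cumulative
functions, the reference x value is the distal maximum of the reference
profile, and the measured displacement is

    d = F_profile^-1(y_ref) - x_ref,   y_ref = F_ref(x_ref),

evaluated by linear interpolation.  Working on cumulative functions filters
bin-level noise and makes the statistic independent of the profiles' total
counts and shapes away from the fall-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_rms(fwhm):
    """Gaussian FWHM -> standard deviation (fwhm / 2 sqrt(2 ln 2))."""
    if fwhm < 0:
        raise ValueError("FWHM must be non-negative")
    return fwhm / _FWHM


def rms_to_fwhm(rms):
    """Gaussian standard deviation -> FWHM."""
    if rms < 0:
        raise ValueError("rms must be non-negative")
    return rms * _FWHM


@dataclass
class Histogram1D:
    """Binned 1-D profile with half-open bins [left, right).

    Counts may only go negative after a background subtraction.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need exactly len(counts)+1 bin edges")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")

    @classmethod
    def from_samples(cls, samples, bin_width, window=None):
        """Histogram raw samples on a regular grid of the given bin width."""
        samples = np.asarray(samples, dtype=float)
        if window is None:
            lo = math.floor(samples.min() / bin_width) * bin_width
            hi = math.ceil(samples.max() / bin_width) * bin_width
        else:
            lo, hi = window
        n = max(1, round((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(n + 1)
        counts, _ = np.histogram(samples, bins=edges)
        return cls(edges, counts.astype(float))

    @property
    def centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self):
        return np.diff(self.bin_edges)

    @property
    def total(self):
        return float(self.counts.sum())

    def cumulative(self):
        """Normalized cumulative function at the bin edges (starts 0, ends 1)."""
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty histogram")
        return np.concatenate([[0.0], np.cumsum(self.counts)]) / total

    def to_table(self):
        """(edge_left, edge_right, counts) array for delimited-text export."""
        return np.column_stack([self.bin_edges[:-1], self.bin_edges[1:],
                                self.counts])

    def write(self, path, label="counts"):
        np.savetxt(path, self.to_table(), delimiter="\t",
                   header=f"edge_left\tedge_right\t{label}", comments="")

    @classmethod
    def read(cls, path):
        table = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        edges = np.concatenate([table[:, 0], [table[-1, 1]]])
        return cls(edges, table[:, 2])


@dataclass
class CTRFitResult:
    """Result of the Gaussian (x) uniform coincidence-time-resolution fit."""

    sigma: float
    centroid: float
    amplitude: float
    baseline: float
    uniform_width: float
    uncertainties: dict = field(default_factory=dict)

    @property
    def fwhm(self):
        return rms_to_fwhm(self.sigma)

    @property
    def fwhm_uncertainty(self):
        return rms_to_fwhm(self.uncertainties.get("sigma", 0.0))

    def report(self):
        return (f"CTR fit: FWHM = {self.fwhm:.1f} +/- "
                f"{self.fwhm_uncertainty:.1f} ps "
                f"(sigma = {self.sigma:.1f} ps, centroid = {self.centroid:.1f} ps, "
                f"fixed uniform width = {self.uniform_width:.1f} ps)")


def _gauss_conv_uniform(t, amplitude, centroid, sigma, baseline, width):
    """Gaussian pdf convolved with a centred uniform of the given width."""
    if width == 0:
        return amplitude * stats.norm.pdf(t, centroid, sigma) + baseline
    a = (t - centroid + width / 2) / sigma
    b = (t - centroid - width / 2) / sigma
    return amplitude * (stats.norm.cdf(a) - stats.norm.cdf(b)) / width + baseline


def fit_gauss_conv_uniform(hist, uniform_width):
    """Fit a Gaussian-convolved-uniform peak shape to a TOF histogram.

    The uniform width (the proton transit-time smear in a thin target) is
    held fixed; the returned Gaussian FWHM is the system coincidence time
    resolution.  Raises a fit error on non-convergence.
    """
    populated = hist.counts > 0
    if populated.sum() < 10:
        raise ValueError("need at least 10 populated bins spanning the peak")
    t = hist.centers
    y = hist.counts
    bw = float(np.mean(hist.widths))
    # moment-based initial guesses
    w = np.clip(y, 0, None)
    mu0 = float(np.sum(t * w) / np.sum(w))
    var0 = float(np.sum((t - mu0) ** 2 * w) / np.sum(w))
    sigma0 = math.sqrt(max(var0 - uniform_width ** 2 / 12.0, bw ** 2))
    amp0 = float(y.max() * sigma0 * math.sqrt(2 * math.pi))

    def model(tt, amplitude, centroid, sigma, baseline):
        return bw * _gauss_conv_uniform(tt, amplitude, centroid, abs(sigma),
                                        0.0, uniform_width) + baseline

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[amp0 / bw, mu0, sigma0, 0.0], maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"CTR fit failed to converge (initial guesses: mu={mu0:.1f}, "
            f"sigma={sigma0:.1f}): {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return CTRFitResult(
        sigma=abs(popt[2]), centroid=popt[1], amplitude=popt[0],
        baseline=popt[3], uniform_width=uniform_width,
        uncertainties={"amplitude": perr[0], "centroid": perr[1],
                       "sigma": perr[2], "baseline": perr[3]},
    )


def subtract_flat_background(hist, off_signal_window, signal_window=None):
    """Subtract the mean off-window level from every bin.

    ``off_signal_window`` is an (lo, hi) interval in the histogram axis units
    that must not overlap the signal region (if given).  Bins are not
    clamped, so residuals may go slightly negative.  Returns
    (subtracted histogram, level per bin).
    """
    lo, hi = off_signal_window
    if signal_window is not None:
        s_lo, s_hi = signal_window
        if lo < s_hi and hi > s_lo:
            raise ValueError("off-signal window overlaps the signal region")
    centers = hist.centers
    sel = (centers >= lo) & (centers < hi)
    if not np.any(sel):
        raise ValueError("off-signal window contains no bins")
    level = float(hist.counts[sel].mean())
    return Histogram1D(hist.bin_edges, hist.counts - level), level


def subtract_pgti_background(hist, template, off_signal_window):
    """Fit a normalized spatial background template off-signal and subtract it.

    The template (same binning as ``hist``, integral 1 over the histogram
    support) is scaled by least squares on the off-signal bins, then
    subtracted bin-wise.  Returns (subtracted histogram, fitted amplitude).
    """
    template = np.asarray(template, dtype=float)
    if template.shape != hist.counts.shape:
        raise ValueError("template binning does not match the histogram")
    lo, hi = off_signal_window
    centers = hist.centers
    sel = (centers >= lo) & (centers < hi)
    if not np.any(sel):
        raise ValueError("off-signal region contains no bins")
    t = template[sel]
    denom = float(np.sum(t * t))
    if denom == 0:
        amplitude = 0.0
    else:
        amplitude = float(np.sum(hist.counts[sel] * t) / denom)
    return Histogram1D(hist.bin_edges, hist.counts - amplitude * template), \
        amplitude


@dataclass
class ShiftResult:
    """Fall-off displacement with bootstrap-extrapolated errors.

    ``d`` is in ps (PGT) or cm (PGTI); sigma2 is always twice sigma1; ``k``
    is the coefficient of the k/sqrt(N) error law (same units x sqrt(count)).
    """

    d: float
    sigma1: float = float("nan")
    sigma2: float = float("nan")
    n_events: int = 0
    k_coefficient: float = float("nan")
    units: str = "ps"


def distal_maximum(reference):
    """Location of the reference profile maximum within its distal half."""
    centers = reference.centers
    mid = 0.5 * (centers[0] + centers[-1])
    distal = centers >= mid
    idx = np.argmax(reference.counts[distal])
    return float(centers[distal][idx])


def falloff_shift(profile, reference, x_ref=None):
    """Integral fall-off displacement of ``profile`` relative to ``reference``.

    Both histograms are turned into normalized cumulative functions; the
    displacement is the horizontal distance between them at the cumulative
    level of the reference's distal maximum.  Returns a ShiftResult carrying
    only ``d`` (errors are attached by the bootstrap machinery).
    """
    if x_ref is None:
        x_ref = distal_maximum(reference)
    f_ref = reference.cumulative()
    if not reference.bin_edges[0] <= x_ref <= reference.bin_edges[-1]:
        raise ValueError("x_ref outside the reference histogram support")
    y_ref = float(np.interp(x_ref, reference.bin_edges, f_ref))
    f_prof = profile.cumulative()
    if not f_prof[0] <= y_ref <= f_prof[-1]:
        raise ValueError("cumulative level y_ref outside the profile's range")
    # invert the cumulative by linear interpolation on the edges
    x_at_level = float(np.interp(y_ref, f_prof, profile.bin_edges))
    return ShiftResult(d=x_at_level - x_ref)
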