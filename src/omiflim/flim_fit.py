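"""Fluorescence-decay modeling and fitting for TCSPC FLIM data.

Each pixel of a FLIM image holds a histogram of photon arrival times.  For
the metabolic co-enzymes NAD(P)H and FAD the decay is bi-exponential,

    I(t) = a1 * exp(-t / tau1) + a2 * exp(-t / tau2) + C,

with the short component ``tau1`` attributed to the free co-enzyme
conformation and the long component ``tau2`` to the protein-bound one
(for NAD(P)H; the assignment is reversed for FAD but the model is the
same).  ``a1 + a2 = 1`` are the fractional amplitude contributions and
``C`` is a constant background-light term.  The measured histogram is the
ideal decay convolved with the instrument response function (IRF), so the
fit is done by *iterative reconvolution*: the model is convolved with the
measured IRF at every optimizer step and compared to the raw counts.

The mean lifetime reported per pixel is the amplitude-weighted average

    tau_m = a1 * tau1 + a2 * tau2 .
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DecayHistogram",
    "InstrumentResponse",
    "BiExpParams",
    "FitResult",
    "LifetimeImageSet",
    "InsufficientPhotonsError",
    "model_decay",
    "fit_biexponential",
    "fit_monoexponential",
    "mean_lifetime",
    "irf_fwhm",
    "bin_pixels",
    "intensity_image",
    "fit_image",
]

# Default TCSPC grid: 1024 ADC bins of 12.2 ps spanning the 12.49 ns
# period of an 80 MHz excitation laser.
DEFAULT_N_BINS = 1024
DEFAULT_BIN_WIDTH_NS = 0.0122


class InsufficientPhotonsError(ValueError):
    """Raised when a decay has too few photons for a stable fit."""


def _bin_centers(n_bins: int, bin_width_ns: float) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) * bin_width_ns


@dataclass
class DecayHistogram:
    """Photon counts per TCSPC time bin for one pixel or region."""

    counts: np.ndarray
    bin_width_ns: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("decay histogram must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if self.bin_width_ns <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())

    @property
    def times_ns(self) -> np.ndarray:
        return _bin_centers(self.n_bins, self.bin_width_ns)


@dataclass
class InstrumentResponse:
    """Instrument response function on the same time grid as the data.

    The kernel is normalized to unit sum on construction so that
    reconvolution preserves total photon amplitude.
    """

    kernel: np.ndarray
    bin_width_ns: float

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1:
            raise ValueError("IRF kernel must be one-dimensional")
        if np.any(k < 0):
            raise ValueError("IRF kernel must be non-negative")
        s = k.sum()
        if s <= 0:
            raise ValueError("IRF kernel must have positive mass")
        self.kernel = k / s
        if self.bin_width_ns <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_bins(self) -> int:
        return self.kernel.size

    @property
    def fwhm_ps(self) -> float:
        return irf_fwhm(self)

    @classmethod
    def delta(cls, n_bins: int, bin_width_ns: float) -> "InstrumentResponse":
        """Identity kernel: a single unit impulse in the first bin."""
        k = np.zeros(n_bins)
        k[0] = 1.0
        return cls(k, bin_width_ns)


@dataclass
class BiExpParams:
    """Parameters of the bi-exponential decay model.

    ``alpha1 + alpha2 == 1`` and ``tau1 < tau2`` (short component first).
    A mono-exponential decay is expressed as ``alpha2 == 0``.
    """

    alpha1: float
    alpha2: float
    tau1: float
    tau2: float
    offset_c: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-9:
            raise ValueError("alpha1 + alpha2 must equal 1")
        if not (0.0 < self.tau1 < self.tau2):
            raise ValueError("lifetimes must satisfy 0 < tau1 < tau2")
        if self.offset_c < 0:
            raise ValueError("background offset C must be non-negative")

    @property
    def tau_m(self) -> float:
        return mean_lifetime(self)


@dataclass
class FitResult:
    params: BiExpParams
    chi2_reduced: float
    photons: int
    converged: bool
    scale: float = 1.0


@dataclass
class LifetimeImageSet:
    """Per-pixel lifetime maps from fitting one FLIM channel.

    ``tau_m`` is defined only where ``valid_mask`` is True; invalid pixels
    hold NaN.  ``intensity`` is the raw (unbinned) photon sum per pixel.
    """

    tau1: np.ndarray
    tau2: np.ndarray
    alpha1: np.ndarray
    tau_m: np.ndarray
    intensity: np.ndarray
    valid_mask: np.ndarray
    chi2_reduced: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.tau1, self.tau2, self.alpha1,
                                    self.tau_m, self.intensity, self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")


def mean_lifetime(params) -> float:
    """Amplitude-weighted mean lifetime tau_m = a1*tau1 + a2*tau2 (ns)."""
    return params.alpha1 * params.tau1 + params.alpha2 * params.tau2


def _prepulse_offset(counts: np.ndarray, kernel: np.ndarray) -> float:
    """Estimate constant background from bins before the IRF rise."""
    rise = int(np.argmax(np.cumsum(kernel) > 1e-4))
    if rise < 4:
        return 0.0
    return float(np.mean(counts[: rise - 2]))


def _trim_kernel(kernel: np.ndarray, rel_tol: float = 1e-14):
    """Significant support of the kernel, as (offset, trimmed) pair."""
    nz = np.nonzero(kernel > rel_tol * kernel.max())[0]
    return int(nz[0]), kernel[nz[0]: nz[-1] + 1]


def _reconvolve(decay: np.ndarray, kernel: np.ndarray, n_bins: int) -> np.ndarray:
    off, k = _trim_kernel(kernel)
    full = np.convolve(decay, k)[: n_bins - off]
    out = np.zeros(n_bins)
    out[off:] = full
    return out


def model_decay(params: BiExpParams, irf: InstrumentResponse,
                n_bins: int, bin_width_ns: float,
                scale: float = 1.0) -> np.ndarray:
    """Expected counts per bin: bi-exponential reconvolved with the IRF.

    The background term C is added *after* convolution (uncorrelated
    ambient light is not shaped by the instrument response).
    """
    if irf.n_bins != n_bins or abs(irf.bin_width_ns - bin_width_ns) > 1e-12:
        raise ValueError("IRF grid does not match the requested time grid")
    t = _bin_centers(n_bins, bin_width_ns)
    decay = (params.alpha1 * np.exp(-t / params.tau1)
             + params.alpha2 * np.exp(-t / params.tau2))
    return scale * _reconvolve(decay, irf.kernel, n_bins) + params.offset_c


@dataclass
class FitBounds:
    """Box constraints for the bi-exponential fit (lifetimes in ns)."""

    tau1: tuple = (0.05, 1.5)
    tau2: tuple = (0.8, 8.0)
    alpha1: tuple = (0.0, 1.0)


#: published initial guesses for the free/bound lifetime components
NADH_INIT = BiExpParams(0.7, 0.3, 0.4, 2.5)
FAD_INIT = BiExpParams(0.7, 0.3, 0.3, 2.0)


def _residual_and_jac(x, t, kernel, counts, weighting, n_bins):
    amp, a1, tau1, tau2, c = x
    e1 = np.exp(-t / tau1)
    e2 = np.exp(-t / tau2)
    decay = a1 * e1 + (1.0 - a1) * e2
    conv = _reconvolve(decay, kernel, n_bins)
    model = amp * conv + c
    # analytic partials of the model, each reconvolved with the kernel
    d_a1 = amp * _reconvolve(e1 - e2, kernel, n_bins)
    d_t1 = amp * a1 * _reconvolve(e1 * t / tau1 ** 2, kernel, n_bins)
    d_t2 = amp * (1.0 - a1) * _reconvolve(e2 * t / tau2 ** 2, kernel, n_bins)
    dm = np.column_stack((conv, d_a1, d_t1, d_t2, np.ones_like(t)))
    res, drdm = _apply_weighting(model, counts, weighting)
    return res, dm * drdm[:, None]


def _apply_weighting(model, counts, weighting):
    """Residual vector and its derivative w.r.t. the model per bin."""
    if weighting == "neyman":
        w = 1.0 / np.sqrt(np.clip(counts, 1.0, None))
        return (model - counts) * w, w
    # Poisson maximum likelihood via signed deviance residuals:
    # r = sign(m - c) * sqrt(2 * (m - c + c * ln(c / m)))
    m = np.clip(model, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / m), 0.0)
    dev2 = np.clip(2.0 * (m - counts + term), 0.0, None)
    res = np.sign(m - counts) * np.sqrt(dev2)
    # d r / d m = (1 - c/m) / r, with the c -> m limit 1 / sqrt(m)
    small = np.abs(res) < 1e-8
    drdm = np.where(small, 1.0 / np.sqrt(m),
                    (1.0 - counts / m) / np.where(small, 1.0, res))
    return res, drdm


def fit_biexponential(decay: DecayHistogram, irf: InstrumentResponse,
                      init: BiExpParams | None = None,
                      bounds: FitBounds | None = None,
                      photon_threshold: int = 500,
                      weighting: str = "poisson") -> FitResult:
    """Reconvolution fit of the bi-exponential model to a photon histogram.

    The default objective is the Poisson maximum likelihood, minimized
    through signed deviance residuals — the correct statistics for TCSPC
    counts, which at typical per-pixel totals leave many near-empty tail
    bins where Gaussian chi-square weighting is biased.  Neyman
    chi-square (1/sqrt(counts), counts clipped at >= 1) is available via
    ``weighting="neyman"``.  If the optimizer lands with tau1 >= tau2 the
    component pairs are swapped so the short lifetime is always first.
    """
    if weighting not in ("poisson", "neyman"):
        raise ValueError("weighting must be 'poisson' or 'neyman'")
    if decay.total_photons < photon_threshold:
        raise InsufficientPhotonsError(
            f"insufficient photons: {decay.total_photons} < {photon_threshold}")
    init = init or NADH_INIT
    bounds = bounds or FitBounds()
    n = decay.n_bins
    counts = decay.counts.astype(float)
    t = decay.times_ns

    # background init from the pre-pulse bins (before the IRF rise the
    # model is ~0, so any counts there are offset); amplitude scale so
    # the initial model carries the observed photons
    c0 = _prepulse_offset(counts, irf.kernel)
    decay0 = (init.alpha1 * np.exp(-t / init.tau1)
              + init.alpha2 * np.exp(-t / init.tau2))
    amp0 = max(counts.sum() - c0 * n, 1.0) / max(decay0.sum(), 1e-30)
    x0 = np.array([amp0, init.alpha1, init.tau1, init.tau2, c0])
    lo = np.array([0.0, bounds.alpha1[0], bounds.tau1[0], bounds.tau2[0], 0.0])
    hi = np.array([np.inf, bounds.alpha1[1], bounds.tau1[1], bounds.tau2[1],
                   max(counts.max(), 1.0)])
    x0 = np.clip(x0, lo, hi)

    cache: dict = {}

    def f(x):
        key = tuple(x)
        if key not in cache:
            cache.clear()
            cache[key] = _residual_and_jac(x, t, irf.kernel, counts,
                                           weighting, n)
        return cache[key][0]

    def jac(x):
        key = tuple(x)
        if key not in cache:
            cache.clear()
            cache[key] = _residual_and_jac(x, t, irf.kernel, counts,
                                           weighting, n)
        return cache[key][1]

    sol = least_squares(f, x0, jac=jac, bounds=(lo, hi), x_scale="jac",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200)
    amp, a1, tau1, tau2, c = sol.x
    if tau1 >= tau2:  # tie-break: keep the short component first
        tau1, tau2 = tau2, tau1
        a1 = 1.0 - a1
    tau1 = min(tau1, tau2 - 1e-9)
    params = BiExpParams(a1, 1.0 - a1, tau1, tau2, c)
    chi2 = float(np.sum(sol.fun ** 2)) / max(n - 5, 1)
    return FitResult(params=params, chi2_reduced=chi2,
                     photons=decay.total_photons,
                     converged=bool(sol.status > 0), scale=float(amp))


def fit_monoexponential(decay: DecayHistogram, irf: InstrumentResponse,
                        photon_threshold: int = 500,
                        init_tau: float = 2.0,
                        weighting: str = "poisson") -> float:
    """Single-exponential reconvolution fit; returns the lifetime in ns.

    Used for lifetime standards (e.g. the daily fluorescent-microsphere
    measurement) where the fluorophore decay is mono-exponential.
    """
    if decay.total_photons < photon_threshold:
        raise InsufficientPhotonsError(
            f"insufficient photons: {decay.total_photons} < {photon_threshold}")
    n = decay.n_bins
    counts = decay.counts.astype(float)
    t = decay.times_ns
    c0 = _prepulse_offset(counts, irf.kernel)
    amp0 = (max(counts.sum() - c0 * n, 1.0)
            / max(np.exp(-t / init_tau).sum(), 1e-30))
    x0 = np.array([amp0, init_tau, c0])
    lo = np.array([0.0, 0.05, 0.0])
    hi = np.array([np.inf, 10.0, max(counts.max(), 1.0)])

    def _parts(x):
        amp, tau, c = x
        e = np.exp(-t / tau)
        conv = _reconvolve(e, irf.kernel, n)
        model = amp * conv + c
        dm = np.column_stack((conv,
                              amp * _reconvolve(e * t / tau ** 2,
                                                irf.kernel, n),
                              np.ones_like(t)))
        res, drdm = _apply_weighting(model, counts, weighting)
        return res, dm * drdm[:, None]

    sol = least_squares(lambda x: _parts(x)[0], np.clip(x0, lo, hi),
                        jac=lambda x: _parts(x)[1], bounds=(lo, hi),
                        x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=200)
    return float(sol.x[1])


def irf_fwhm(irf: InstrumentResponse) -> float:
    """Full width at half maximum of the IRF, in picoseconds.

    Crossing times are located by linear interpolation between the bins
    that bracket the half-maximum on each side of the peak.
    """
    k = irf.kernel
    t = _bin_centers(irf.n_bins, irf.bin_width_ns)
    ipk = int(np.argmax(k))
    half = k[ipk] / 2.0

    def _cross(i_lo, i_hi, side):
        idx = np.arange(i_lo, i_hi)
        below = np.nonzero(k[idx] < half)[0]
        if below.size == 0:
            return t[i_lo] if side == "left" else t[i_hi - 1]
        if side == "left":
            j = idx[below[-1]]
            frac = (half - k[j]) / (k[j + 1] - k[j])
            return t[j] + frac * irf.bin_width_ns
        j = idx[below[0]]
        frac = (half - k[j - 1]) / (k[j] - k[j - 1])
        return t[j - 1] + frac * irf.bin_width_ns

    t_left = _cross(0, ipk + 1, "left")
    t_right = _cross(ipk, irf.n_bins, "right")
    return (t_right - t_left) * 1000.0


def bin_pixels(stack, radius: int):
    """Spatially bin a FLIM stack: each pixel's decay becomes the sum over
    its (2*radius+1)^2 neighborhood, clipped at the image edge.

    Standard TCSPC practice to reach fit-worthy photon counts per pixel.
    Returns a new stack of the same type; radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return stack
    from .io_formats import FlimStack  # local import to avoid a cycle
    counts = stack.counts
    t, h, w = counts.shape
    # summed-area table per time bin for exact integer window sums
    sat = np.zeros((t, h + 1, w + 1), dtype=np.int64)
    np.cumsum(counts, axis=1, out=sat[:, 1:, 1:])
    np.cumsum(sat[:, 1:, 1:], axis=2, out=sat[:, 1:, 1:])
    r = radius
    y0 = np.clip(np.arange(h) - r, 0, h)
    y1 = np.clip(np.arange(h) + r + 1, 0, h)
    x0 = np.clip(np.arange(w) - r, 0, w)
    x1 = np.clip(np.arange(w) + r + 1, 0, w)
    out = (sat[:, y1[:, None], x1[None, :]] - sat[:, y0[:, None], x1[None, :]]
           - sat[:, y1[:, None], x0[None, :]] + sat[:, y0[:, None], x0[None, :]])
    return FlimStack(counts=out, bin_width_ns=stack.bin_width_ns,
                     channel=stack.channel, pixel_size_um=stack.pixel_size_um)


def intensity_image(stack) -> np.ndarray:
    """Total photon count per pixel (sum over all time bins)."""
    return np.asarray(stack.counts).sum(axis=0)


def fit_image(stack, irf: InstrumentResponse, config=None) -> LifetimeImageSet:
    """Fit every pixel of a FLIM stack after spatial binning.

    Pixels whose binned decay falls below the photon threshold are marked
    invalid (NaN in every map).  The intensity map is the *unbinned*
    photon sum.
    """
    from .io_formats import RunConfig
    config = config or RunConfig()
    init = NADH_INIT if getattr(stack, "channel", "NADH") == "NADH" else FAD_INIT
    binned = bin_pixels(stack, config.binning_radius)
    inten = intensity_image(stack)
    h, w = inten.shape
    maps = {k: np.full((h, w), np.nan) for k in
            ("tau1", "tau2", "alpha1", "tau_m", "chi2_reduced")}
    valid = np.zeros((h, w), dtype=bool)
    bcounts = binned.counts
    totals = bcounts.sum(axis=0)
    ys, xs = np.nonzero(totals >= config.photon_threshold)
    for y, x in zip(ys, xs):
        d = DecayHistogram(bcounts[:, y, x], stack.bin_width_ns)
        try:
            res = fit_biexponential(d, irf, init=init,
                                    photon_threshold=config.photon_threshold)
        except InsufficientPhotonsError:  # pragma: no cover - guarded above
            continue
        if not res.converged:
            warnings.warn(f"fit did not converge at pixel ({y}, {x})")
        p = res.params
        maps["tau1"][y, x] = p.tau1
        maps["tau2"][y, x] = p.tau2
        maps["alpha1"][y, x] = p.alpha1
        maps["tau_m"][y, x] = mean_lifetime(p)
        maps["chi2_reduced"][y, x] = res.chi2_reduced
        valid[y, x] = True
    return LifetimeImageSet(tau1=maps["tau1"], tau2=maps["tau2"],
                            alpha1=maps["alpha1"], tau_m=maps["tau_m"],
                            intensity=inten, valid_mask=valid,
                            chi2_reduced=maps["chi2_reduced"])
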