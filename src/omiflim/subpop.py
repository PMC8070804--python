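"""Single-cell subpopulation analysis of the OMI index.

The distribution of per-cell OMI indices within one patient and
treatment condition is modeled as a Gaussian mixture fitted by
expectation-maximization, restarted 100 times from random initial
conditions and keeping the best log-likelihood solution.  The number of
components (1 to 3) is chosen by the Akaike information criterion,
AIC = 2k - 2 ln L with k = 3K - 1 free parameters for K univariate
components.  Groups enter the analysis only when they contain strictly
more than 100 cells, the minimum for robust subpopulation estimation.

Heterogeneity is summarized by the weighted heterogeneity index

    wH-index = sum_i (1 - p_i * ln(p_i + 1)) * (sigma_i + d_i)

over mixture components i, where p_i is the component proportion,
sigma_i its standard deviation, and d_i the distance between the
component median (= its mean, by symmetry) and the median of the whole
distribution.  A single tight population scores low; multiple and/or
broad populations score high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "WHIndexResult",
    "fit_gmm",
    "select_model",
    "wh_index",
    "gate_min_cells",
    "normalized_density",
]


@dataclass
class GaussianComponent:
    p: float      # proportion of cells in this subpopulation
    mu: float     # mean OMI index
    sigma: float  # standard deviation

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("proportion must lie in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class MixtureModel:
    components: list[GaussianComponent]
    loglik: float
    n_cells: int
    seed: int | None = None
    #: no EM restart produced distinct, well-populated components; the
    #: best collapsed/overlapping solution is reported instead
    degenerate: bool = False
    aic: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(c.p for c in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("component proportions must sum to 1")
        self.components = sorted(self.components, key=lambda c: c.mu)
        self.aic = 2.0 * self.n_parameters - 2.0 * self.loglik

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_parameters(self) -> int:
        # K means + K sigmas + (K - 1) free weights
        return 3 * self.n_components - 1


@dataclass
class WHIndexResult:
    wh_index: float
    overall_median: float
    terms: list[float]
    distances: list[float]


def _degenerate_model(values: np.ndarray, seed) -> MixtureModel:
    sd = max(float(np.std(values)), 1e-12)
    comp = GaussianComponent(1.0, float(np.mean(values)), max(sd, 1e-12))
    ll = float(np.sum(norm.logpdf(values, comp.mu, comp.sigma)))
    return MixtureModel([comp], loglik=ll, n_cells=values.size, seed=seed)


#: a candidate subpopulation must hold at least this fraction of cells;
#: with the >100-cell gate this means >= ~10-30 cells, the minimum for
#: estimating a component's weight, mean, and SD
MIN_COMPONENT_WEIGHT = 0.10
#: ... and be no tighter than this fraction of the overall data SD
MIN_COMPONENT_SIGMA_FRAC = 0.05
#: ... and every component pair must be separated by at least this
#: Ashman's D (sqrt(2)|mu1 - mu2| / sqrt(s1^2 + s2^2)); D >= 2 is the
#: classical threshold for a cleanly bimodal pair
MIN_ASHMAN_D = 2.0


def _is_degenerate(gm: GaussianMixture, n: int, data_sd: float) -> bool:
    """A restart is degenerate when its components do not describe
    distinct subpopulations.

    Three failure modes are rejected: a component collapsed onto a
    handful of points (vanishing weight, or an SD far below the data
    scale) — such spikes carry near-unbounded likelihood and would
    always win the best-of-restarts selection, defeating the AIC
    comparison; and a pair of heavily overlapping components (Ashman's
    D < 2) that merely split one mode in two rather than describing
    separate cell populations.
    """
    min_weight = max(MIN_COMPONENT_WEIGHT, 2.0 / n)
    if np.any(gm.weights_ < min_weight):
        return True
    sigmas = np.sqrt(gm.covariances_[:, 0, 0])
    if np.any(sigmas < MIN_COMPONENT_SIGMA_FRAC * data_sd):
        return True
    mus = gm.means_[:, 0]
    for i in range(mus.size):
        for j in range(i + 1, mus.size):
            d = (np.sqrt(2.0) * abs(mus[i] - mus[j])
                 / np.sqrt(sigmas[i] ** 2 + sigmas[j] ** 2))
            if d < MIN_ASHMAN_D:
                return True
    return False


def fit_gmm(values, k: int, n_restarts: int = 100,
            seed: int | None = None) -> MixtureModel:
    """EM fit of a K-component univariate Gaussian mixture.

    ``n_restarts`` random initializations (means drawn from the data
    points, uniform weights) are run and the best log-likelihood
    non-degenerate solution kept.  Degenerate data (all values equal)
    with K > 1 collapses to a single component with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 5 * k:
        raise ValueError(f"need at least {5 * k} values to fit {k} components")
    if np.ptp(x) == 0:
        if k > 1:
            warnings.warn("degenerate data: all values identical; "
                          "collapsing to a single component")
        comp = GaussianComponent(1.0, float(x[0]), 1e-12 + 1e-4)
        ll = float(np.sum(norm.logpdf(x, comp.mu, comp.sigma)))
        return MixtureModel([comp], loglik=ll, n_cells=x.size, seed=seed)
    data_sd = float(np.std(x))
    X = x.reshape(-1, 1)
    rng = np.random.default_rng(seed)
    if k == 1:  # EM for one component is deterministic
        n_restarts = 1
    best_valid = best_any = None
    ll_valid = ll_any = -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # EM convergence chatter
        for _ in range(n_restarts):
            gm = GaussianMixture(
                n_components=k, covariance_type="full", tol=1e-6,
                max_iter=500, n_init=1, init_params="random_from_data",
                reg_covar=(1e-4 * data_sd) ** 2,
                random_state=int(rng.integers(2**31 - 1)))
            gm.fit(X)
            ll = float(gm.score(X) * x.size)
            if ll > ll_any:
                best_any, ll_any = gm, ll
            if ll > ll_valid and not _is_degenerate(gm, x.size, data_sd):
                best_valid, ll_valid = gm, ll
    gm, loglik = ((best_valid, ll_valid) if best_valid is not None
                  else (best_any, ll_any))
    if best_valid is None and k > 1:
        warnings.warn(f"all {n_restarts} K={k} restarts degenerate; "
                      "returning the best collapsed solution")
    comps = [GaussianComponent(float(w), float(m[0]),
                               float(np.sqrt(c[0, 0])))
             for w, m, c in zip(gm.weights_, gm.means_, gm.covariances_)]
    # renormalize against floating-point drift in the weights
    total = sum(c.p for c in comps)
    for c in comps:
        c.p /= total
    return MixtureModel(comps, loglik=loglik, n_cells=x.size, seed=seed,
                        degenerate=best_valid is None and k > 1)


def select_model(values, k_max: int = 3, n_restarts: int = 100,
                 seed: int | None = None) -> MixtureModel:
    """Fit K = 1..k_max mixtures and return the minimum-AIC model.

    Within each K the best of ``n_restarts`` EM runs is taken first, so
    AIC compares converged per-K optima.
    """
    x = np.asarray(values, dtype=float).ravel()
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collapsed-K restarts are expected
        for k in range(1, k_max + 1):
            if x.size < 5 * k:
                break
            sub_seed = None if seed is None else seed + k
            model = fit_gmm(x, k, n_restarts=n_restarts, seed=sub_seed)
            if model.degenerate:
                continue  # K distinct subpopulations do not exist
            if best is None or model.aic < best.aic:
                best = model
    if best is None:
        raise ValueError("too few values for any mixture fit")
    return best


def wh_index(model: MixtureModel, values) -> WHIndexResult:
    """Weighted heterogeneity index of a fitted mixture.

    The overall median is taken from the raw per-cell values; each
    component's median equals its mean by Gaussian symmetry.
    """
    x = np.asarray(values, dtype=float).ravel()
    med = float(np.median(x))
    terms, dists = [], []
    for c in model.components:
        d = abs(c.mu - med)
        term = (1.0 - c.p * np.log(c.p + 1.0)) * (c.sigma + d)
        terms.append(float(term))
        dists.append(float(d))
    return WHIndexResult(wh_index=float(sum(terms)), overall_median=med,
                         terms=terms, distances=dists)


def gate_min_cells(table, min_n: int = 100):
    """(patient, condition) groups with strictly more than ``min_n`` cells.

    Returns a DataFrame with columns patient_id, condition, n_cells for
    the eligible groups only.
    """
    counts = (table.groupby(["patient_id", "condition"], sort=True)
              .size().rename("n_cells").reset_index())
    return counts[counts["n_cells"] > min_n].reset_index(drop=True)


def normalized_density(model: MixtureModel, grid) -> np.ndarray:
    """Mixture density on a grid, rescaled to unit trapezoid area.

    Lets distributions with different cell counts be overlaid with equal
    areas under the curve.
    """
    grid = np.asarray(grid, dtype=float)
    pdf = np.zeros_like(grid)
    for c in model.components:
        pdf += c.p * norm.pdf(grid, c.mu, c.sigma)
    area = np.trapezoid(pdf, grid)
    if area <= 0:
        raise ValueError("grid does not cover the mixture support")
    return pdf / area
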