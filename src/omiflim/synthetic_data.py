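"""Synthetic FLIM data with known ground truth.

No raw microscope data ship with this project, so every input the
pipeline consumes is generated here with full ground truth attached:

* photon-count decay histograms (Poisson statistics over a reconvolved
  bi-exponential expectation, Gaussian IRF of 220 ps FWHM);
* the daily mono-exponential lifetime standard (fluorescent microspheres
  at a nominal 2.1 ns);
* two-channel (NAD(P)H + FAD) organoid-cross-section scenes with the
  intensity ordering the segmentation assumes
  (background < nucleus < cytoplasm), in solid or hollow morphology;
* a 7-patient x 4-condition treatment cohort whose ground-truth effect
  directions reproduce the study design this package analyzes:
  patients 1, 3 and 7 respond to both single agents and the
  combination, patients 2 and 5 to the combination only, patient 4 to
  the single agents but not the combination, and patient 6 to nothing —
  4 everolimus responders, 4 ABT263 responders, 5 combination
  responders.  Patient 6 carries a 50/50 bimodal cell mixture in every
  condition, patient 1 doubles its spread under everolimus, patient 7
  is uniformly narrow, and only patients 1, 6 and 7 clear the
  >100-cells-per-group gate for subpopulation modeling;
* organoid diameter-change tables: slow-growing neuroendocrine lines
  centered at zero growth versus a fast-growing colorectal comparator.

Responder groups shift the ground-truth OMI index down by 1.2 control
SDs (realized through lower NAD(P)H intensity and lifetimes and a higher
FAD lifetime, so the shift survives decay fitting); non-responders shift
up by 0.2 SD, which the response caller reports as "n.a.".  Every
generator is a pure function of (preset, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flim_fit import (DEFAULT_BIN_WIDTH_NS, DEFAULT_N_BINS, BiExpParams,
                       DecayHistogram, InstrumentResponse, model_decay)
from .io_formats import FlimStack
from .segmentation import LabelMasks

__all__ = [
    "IRF_FWHM_PS",
    "MICROSPHERE_LIFETIME_NS",
    "CONDITIONS",
    "PatientPreset",
    "ScenePreset",
    "default_irf",
    "simulate_decay",
    "microsphere_standard",
    "render_scene",
    "default_cohort_presets",
    "cohort",
    "growth_generator",
    "stc1_preset",
]

#: measured instrument response width emulated by the default IRF
IRF_FWHM_PS = 220.0
#: nominal lifetime of the daily fluorescent-microsphere standard
MICROSPHERE_LIFETIME_NS = 2.1

CONDITIONS = ("control", "everolimus", "abt263", "combination")

# ground-truth OMI-index effects, in units of the control-group SD
RESPONDER_SHIFT_SD = -1.2
NONRESPONDER_SHIFT_SD = +0.2

# multiplicative mean shifts on (redox ratio, NAD(P)H tau_m, FAD tau_m)
# realizing the effects above given the baseline CVs in _draw_cells
_EFFECTS = {
    "respond": (0.933, 0.947, 1.042),   # OMI index down ~1.2 control SD
    "increase": (1.012, 1.010, 0.994),  # OMI index up ~0.2 control SD
    "none": (1.0, 1.0, 1.0),
}

# 50/50 subtype shifts placing patient-6 components 4 component-SDs apart
_BIMODAL_SHIFTS = [(0.885, 0.915, 1.0696), (1.115, 1.085, 0.9304)]


def default_irf(bin_width_ns: float = DEFAULT_BIN_WIDTH_NS,
                n_bins: int = DEFAULT_N_BINS) -> InstrumentResponse:
    """Gaussian IRF with 220 ps FWHM (sigma = FWHM / 2.3548 = 93.4 ps),
    centered at 10% of the time range."""
    sigma_ns = IRF_FWHM_PS / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = (np.arange(n_bins) + 0.5) * bin_width_ns
    t0 = 0.1 * n_bins * bin_width_ns
    kernel = np.exp(-0.5 * ((t - t0) / sigma_ns) ** 2)
    return InstrumentResponse(kernel=kernel, bin_width_ns=bin_width_ns)


def simulate_decay(params: BiExpParams, irf: InstrumentResponse,
                   total_photons: float, seed: int,
                   n_bins: int | None = None,
                   bin_width_ns: float | None = None) -> DecayHistogram:
    """Poisson-sample a decay histogram with the given expected total.

    The expectation is the reconvolved model curve scaled so its sum is
    ``total_photons``; each bin is then drawn independently Poisson.
    """
    n_bins = n_bins or irf.n_bins
    bin_width_ns = bin_width_ns or irf.bin_width_ns
    rng = np.random.default_rng(seed)
    expected = model_decay(params, irf, n_bins, bin_width_ns)
    s = expected.sum()
    if total_photons > 0 and s > 0:
        expected = expected * (total_photons / s)
    else:
        expected = np.zeros(n_bins)
    counts = rng.poisson(expected)
    return DecayHistogram(counts=counts, bin_width_ns=bin_width_ns)


def microsphere_standard(seed: int, n_replicates: int = 7,
                         total_photons: int = 200_000,
                         irf: InstrumentResponse | None = None):
    """Daily lifetime-standard replicates: mono-exponential decays at the
    nominal 2.1 ns microsphere lifetime, >= 1e5 photons each."""
    if total_photons < 100_000:
        raise ValueError("standard replicates need at least 1e5 photons")
    irf = irf or default_irf()
    params = BiExpParams(alpha1=1.0, alpha2=0.0,
                         tau1=MICROSPHERE_LIFETIME_NS,
                         tau2=4 * MICROSPHERE_LIFETIME_NS)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    return [simulate_decay(params, irf, total_photons, int(s)) for s in seeds]


# --------------------------------------------------------------------------
# cell-level ground truth

# baseline per-cell distributions (mean, SD) of the decay parameters;
# lifetimes in ns, intensities in photons per cytoplasm pixel.  The
# variability budget is placed on terms that enter the OMI index
# linearly (NAD(P)H intensity, tau2): ratio denominators and the
# alpha1 * (tau1 - tau2) cross-term get small CVs so the per-cell OMI
# index is close to Gaussian, matching the single-Gaussian shape of
# unimodal patient groups.
_BASE = {
    "nadh_alpha1": (0.75, 0.010), "nadh_tau1": (0.40, 0.020),
    "nadh_tau2": (2.50, 0.160), "nadh_intensity": (800.0, 88.8),
    "fad_alpha1": (0.75, 0.010), "fad_tau1": (0.30, 0.015),
    "fad_tau2": (2.00, 0.130), "fad_intensity": (530.0, 10.6),
}


def _draw_cells(rng: np.random.Generator, n: int,
                effect=(1.0, 1.0, 1.0), sd_scale: float = 1.0,
                subtype_shifts=None) -> pd.DataFrame:
    """Draw ground-truth per-cell decay parameters for one group.

    ``effect`` multiplies the means of (NAD(P)H intensity, NAD(P)H
    lifetimes, FAD lifetimes), steering redox ratio and both tau_m.
    ``subtype_shifts`` optionally defines an equal-weight cell-subtype
    mixture of additional multiplicative shifts.
    """
    rr_f, ntm_f, ftm_f = effect
    if subtype_shifts is None:
        sub = np.ones((n, 3))
    else:
        pick = rng.integers(0, len(subtype_shifts), size=n)
        sub = np.asarray(subtype_shifts)[pick]
    df = pd.DataFrame(index=range(n))

    def draw(key, factor):
        mu, sd = _BASE[key]
        return rng.normal(mu * factor, sd * sd_scale, size=n)

    df["nadh_alpha1"] = np.clip(draw("nadh_alpha1", 1.0), 0.5, 0.95)
    df["nadh_tau1"] = np.clip(draw("nadh_tau1", ntm_f * sub[:, 1]), 0.10, 1.40)
    df["nadh_tau2"] = np.clip(draw("nadh_tau2", ntm_f * sub[:, 1]), 1.00, 7.50)
    df["fad_alpha1"] = np.clip(draw("fad_alpha1", 1.0), 0.5, 0.95)
    df["fad_tau1"] = np.clip(draw("fad_tau1", ftm_f * sub[:, 2]), 0.08, 1.40)
    df["fad_tau2"] = np.clip(draw("fad_tau2", ftm_f * sub[:, 2]), 1.00, 7.50)
    df["nadh_intensity"] = np.clip(draw("nadh_intensity", rr_f * sub[:, 0]),
                                   10.0, None)
    df["fad_intensity"] = np.clip(draw("fad_intensity", 1.0), 10.0, None)
    df["nadh_tau_m"] = (df["nadh_alpha1"] * df["nadh_tau1"]
                        + (1 - df["nadh_alpha1"]) * df["nadh_tau2"])
    df["fad_tau_m"] = (df["fad_alpha1"] * df["fad_tau1"]
                       + (1 - df["fad_alpha1"]) * df["fad_tau2"])
    df["redox_ratio"] = df["nadh_intensity"] / df["fad_intensity"]
    return df


@dataclass
class PatientPreset:
    """Ground-truth design of one synthetic patient line."""

    patient_id: str
    responses: dict        # condition -> "respond" | "increase"
    n_cells: int = 100
    sd_scale: dict = field(default_factory=dict)  # condition -> spread factor
    bimodal: bool = False


def default_cohort_presets() -> list[PatientPreset]:
    """The 7-patient cohort design (see module docstring)."""
    both = {"everolimus": "respond", "abt263": "respond",
            "combination": "respond"}
    combo_only = {"everolimus": "increase", "abt263": "increase",
                  "combination": "respond"}
    singles_only = {"everolimus": "respond", "abt263": "respond",
                    "combination": "increase"}
    nothing = {"everolimus": "increase", "abt263": "increase",
               "combination": "increase"}
    return [
        PatientPreset("P1", dict(both), n_cells=300,
                      sd_scale={"everolimus": 2.0}),
        PatientPreset("P2", dict(combo_only), n_cells=100),
        PatientPreset("P3", dict(both), n_cells=100),
        PatientPreset("P4", dict(singles_only), n_cells=100),
        PatientPreset("P5", dict(combo_only), n_cells=100),
        PatientPreset("P6", dict(nothing), n_cells=300, bimodal=True),
        PatientPreset("P7", dict(both), n_cells=300,
                      sd_scale={c: 0.6 for c in CONDITIONS}),
    ]


def _preset_table(preset: PatientPreset, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for condition in CONDITIONS:
        effect = _EFFECTS["none" if condition == "control"
                          else preset.responses[condition]]
        sd_scale = preset.sd_scale.get(condition, 1.0)
        sub = _BIMODAL_SHIFTS if preset.bimodal else None
        df = _draw_cells(rng, preset.n_cells, effect=effect,
                         sd_scale=sd_scale, subtype_shifts=sub)
        df.insert(0, "cell_id", np.arange(1, len(df) + 1))
        df.insert(0, "condition", condition)
        df.insert(0, "patient_id", preset.patient_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort(seed: int, presets: list[PatientPreset] | None = None) -> pd.DataFrame:
    """Table-level synthetic cohort: one row per cell with ground-truth
    OMI variables for 7 patients x 4 conditions."""
    presets = presets or default_cohort_presets()
    rng = np.random.default_rng(seed)
    return pd.concat([_preset_table(p, rng) for p in presets],
                     ignore_index=True)


def stc1_preset(seed: int, n_cells: int = 400) -> pd.DataFrame:
    """Single neuroendocrine cell-line 'patient': OMI index decreases
    under ABT263 and the combination, increases under everolimus."""
    preset = PatientPreset("STC1", {"everolimus": "increase",
                                    "abt263": "respond",
                                    "combination": "respond"},
                           n_cells=n_cells)
    return _preset_table(preset, np.random.default_rng(seed))


# --------------------------------------------------------------------------
# scene rendering

@dataclass
class ScenePreset:
    """Layout of one synthetic organoid cross-section."""

    shape: tuple = (96, 96)
    n_cells: int = 8
    morphology: str = "solid"   # or "hollow" (cells ring an empty lumen)
    cell_radius: int = 7
    nucleus_radius: int = 3
    cytoplasm_photons: float = 5000.0
    nucleus_photons: float = 2000.0
    background_photons: float = 50.0
    fad_intensity_scale: float = 0.66  # FAD photons per NAD(P)H photon

    def __post_init__(self) -> None:
        if self.morphology not in ("solid", "hollow"):
            raise ValueError("morphology must be 'solid' or 'hollow'")
        if not (0 < self.nucleus_radius < self.cell_radius):
            raise ValueError("need 0 < nucleus_radius < cell_radius")
        if not (self.background_photons < self.nucleus_photons
                < self.cytoplasm_photons):
            raise ValueError("intensity ordering background < nucleus "
                             "< cytoplasm is required")


def _place_centers(preset: ScenePreset, rng: np.random.Generator) -> np.ndarray:
    h, w = preset.shape
    r = preset.cell_radius
    if preset.morphology == "hollow":
        ring_r = min(h, w) / 2.0 - r - 2
        angles = (np.arange(preset.n_cells) / preset.n_cells * 2 * np.pi
                  + rng.uniform(0, 2 * np.pi))
        centers = np.column_stack([h / 2 + ring_r * np.sin(angles),
                                   w / 2 + ring_r * np.cos(angles)])
        if preset.n_cells > 1:
            spacing = 2 * ring_r * np.sin(np.pi / preset.n_cells)
            if spacing < 2 * r + 1:
                raise ValueError("too many cells for a hollow ring this size")
        return centers
    min_sep = 2 * r + 2
    centers: list = []
    for _ in range(20_000):
        if len(centers) == preset.n_cells:
            break
        c = rng.uniform([r + 1, r + 1], [h - r - 1, w - r - 1])
        if all(np.hypot(*(c - o)) >= min_sep for o in centers):
            centers.append(c)
    if len(centers) < preset.n_cells:
        raise ValueError("could not place all cells without overlap; "
                         "reduce n_cells or cell_radius")
    return np.asarray(centers)


def render_scene(preset: ScenePreset, seed: int,
                 cell_params: pd.DataFrame | None = None,
                 irf: InstrumentResponse | None = None,
                 n_bins: int | None = None,
                 bin_width_ns: float | None = None):
    """Render a two-channel FLIM scene with ground truth.

    Returns ``(nadh_stack, fad_stack, truth_masks, truth_table)`` where
    ``truth_table`` holds each cell's generating decay parameters and
    per-pixel intensities.  Per-cell parameters are drawn from the
    baseline distributions unless ``cell_params`` provides them.
    """
    irf = irf or default_irf()
    n_bins = n_bins or irf.n_bins
    bin_width_ns = bin_width_ns or irf.bin_width_ns
    rng = np.random.default_rng(seed)
    centers = _place_centers(preset, rng)
    if cell_params is None:
        cell_params = _draw_cells(rng, preset.n_cells)
    elif len(cell_params) < preset.n_cells:
        raise ValueError("cell_params has fewer rows than cells")

    h, w = preset.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cells = np.zeros((h, w), dtype=np.int32)
    nuclei = np.zeros((h, w), dtype=np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cells[d2 <= preset.cell_radius ** 2] = i
        nuclei[d2 <= preset.nucleus_radius ** 2] = i
    cyto = np.where(nuclei > 0, 0, cells).astype(np.int32)
    masks = LabelMasks(nuclei=nuclei, cells=cells, cytoplasm=cyto)

    stacks = {}
    for channel, prefix in (("NADH", "nadh"), ("FAD", "fad")):
        chan_scale = 1.0 if channel == "NADH" else preset.fad_intensity_scale
        expected = np.full((n_bins, h, w),
                           preset.background_photons * chan_scale / n_bins,
                           dtype=np.float64)
        for i in range(1, preset.n_cells + 1):
            row = cell_params.iloc[i - 1]
            a1 = float(row[f"{prefix}_alpha1"])
            params = BiExpParams(a1, 1.0 - a1,
                                 float(row[f"{prefix}_tau1"]),
                                 float(row[f"{prefix}_tau2"]))
            curve = model_decay(params, irf, n_bins, bin_width_ns)
            curve /= curve.sum()
            # per-cell intensity scaled by the cell's ground-truth photon
            # budget relative to the baseline mean
            rel = float(row[f"{prefix}_intensity"]) / _BASE[f"{prefix}_intensity"][0]
            for compartment, level in ((cyto == i, preset.cytoplasm_photons),
                                       (nuclei == i, preset.nucleus_photons)):
                expected[:, compartment] = (curve[:, None]
                                            * level * rel * chan_scale)
        counts = rng.poisson(expected)
        stacks[channel] = FlimStack(counts=counts, bin_width_ns=bin_width_ns,
                                    channel=channel)

    truth = cell_params.iloc[: preset.n_cells].copy()
    truth.insert(0, "cell_id", np.arange(1, preset.n_cells + 1))
    truth["cytoplasm_photons"] = (preset.cytoplasm_photons
                                  * truth["nadh_intensity"]
                                  / _BASE["nadh_intensity"][0])
    return stacks["NADH"], stacks["FAD"], masks, truth


# --------------------------------------------------------------------------
# organoid growth

def growth_generator(kind: str, n: int, seed: int) -> pd.DataFrame:
    """Diameter pairs for organoid growth assays.

    ``gepnet``: slow-growing neuroendocrine organoids, percent diameter
    change ~ Normal(0, 5).  ``crc``: fast-growing colorectal comparator,
    ~ Normal(40, 15) truncated above -100% (an organoid cannot lose more
    than its whole diameter).
    """
    rng = np.random.default_rng(seed)
    if kind == "gepnet":
        pct = rng.normal(0.0, 5.0, size=n)
    elif kind == "crc":
        pct = rng.normal(40.0, 15.0, size=n)
        while np.any(pct <= -100.0):  # truncate by redraw
            bad = pct <= -100.0
            pct[bad] = rng.normal(40.0, 15.0, size=bad.sum())
    else:
        raise ValueError("kind must be 'gepnet' or 'crc'")
    day1 = np.clip(rng.normal(120.0, 25.0, size=n), 40.0, None)
    day7 = day1 * (1.0 + pct / 100.0)
    return pd.DataFrame({"day1_diameter_um": day1, "day7_diameter_um": day7,
                         "true_growth_percent": pct})
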