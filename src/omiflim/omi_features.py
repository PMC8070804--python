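"""Per-cell optical metabolic imaging (OMI) features.

From the per-pixel lifetime maps of the NAD(P)H and FAD channels this
module derives, for each segmented cell cytoplasm: the bi-exponential
lifetime variables (tau1, tau2, alpha1, tau_m), channel intensities, the
optical redox ratio (NAD(P)H intensity / FAD intensity), and the
composite OMI index

    OMI index = normalized redox ratio
              + normalized NAD(P)H tau_m
              - normalized FAD tau_m ,

where "normalized" means divided by the mean of that variable over the
same patient's untreated control cells.  On that common, unitless scale
the control group's OMI index is 1 in expectation, and a *decrease*
under treatment indicates metabolic drug response.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "redox_ratio_map",
    "aggregate_cell",
    "normalize_to_control",
    "omi_index",
    "add_omi_index",
    "zscore_table",
    "OMI_VARIABLES",
]

#: the per-cell variables reported for every cell cytoplasm
OMI_VARIABLES = [
    "nadh_tau1", "nadh_tau2", "nadh_alpha1", "nadh_tau_m", "nadh_intensity",
    "fad_tau1", "fad_tau2", "fad_alpha1", "fad_tau_m", "fad_intensity",
    "redox_ratio",
]


def redox_ratio_map(nadh_intensity: np.ndarray,
                    fad_intensity: np.ndarray) -> np.ndarray:
    """Per-pixel optical redox ratio NAD(P)H / FAD; NaN where FAD is 0."""
    nadh = np.asarray(nadh_intensity, dtype=float)
    fad = np.asarray(fad_intensity, dtype=float)
    if nadh.shape != fad.shape:
        raise ValueError("intensity images must share one shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = nadh / fad
    ratio[fad == 0] = np.nan
    return ratio


def _masked_stat(values: np.ndarray, mask: np.ndarray, statistic: str) -> float:
    v = values[mask]
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan
    return float(np.median(v) if statistic == "median" else np.mean(v))


def aggregate_cell(nadh_maps, fad_maps, ratio_map: np.ndarray,
                   cytoplasm: np.ndarray, patient_id: str, condition: str,
                   min_valid_pixels: int = 10,
                   statistic: str = "mean") -> pd.DataFrame:
    """Aggregate pixel maps to one row per cell cytoplasm.

    A pixel contributes only where both channel fits are valid; cells
    with fewer than ``min_valid_pixels`` such pixels are dropped (logged).
    """
    valid = nadh_maps.valid_mask & fad_maps.valid_mask
    rows = []
    for cid in np.unique(cytoplasm):
        if cid == 0:
            continue
        mask = (cytoplasm == cid) & valid
        n_valid = int(np.count_nonzero(mask))
        if n_valid < min_valid_pixels:
            logger.info("cell %s dropped: %d valid cytoplasm pixels < %d",
                        cid, n_valid, min_valid_pixels)
            continue
        rows.append({
            "patient_id": patient_id, "condition": condition, "cell_id": int(cid),
            "nadh_tau1": _masked_stat(nadh_maps.tau1, mask, statistic),
            "nadh_tau2": _masked_stat(nadh_maps.tau2, mask, statistic),
            "nadh_alpha1": _masked_stat(nadh_maps.alpha1, mask, statistic),
            "nadh_tau_m": _masked_stat(nadh_maps.tau_m, mask, statistic),
            "nadh_intensity": _masked_stat(nadh_maps.intensity, mask, statistic),
            "fad_tau1": _masked_stat(fad_maps.tau1, mask, statistic),
            "fad_tau2": _masked_stat(fad_maps.tau2, mask, statistic),
            "fad_alpha1": _masked_stat(fad_maps.alpha1, mask, statistic),
            "fad_tau_m": _masked_stat(fad_maps.tau_m, mask, statistic),
            "fad_intensity": _masked_stat(fad_maps.intensity, mask, statistic),
            "redox_ratio": _masked_stat(ratio_map, mask, statistic),
            "n_valid_pixels": n_valid,
        })
    return pd.DataFrame(rows)


NORMALIZED_VARIABLES = ["redox_ratio", "nadh_tau_m", "fad_tau_m"]


def normalize_to_control(table: pd.DataFrame,
                         control_condition: str = "control") -> pd.DataFrame:
    """Divide redox ratio and both mean lifetimes by the patient-matched
    control-group mean, adding ``norm_*`` columns.

    After normalization each control group's normalized means are exactly
    1, making the three variables commensurate for the OMI index.
    """
    out = table.copy()
    for var in NORMALIZED_VARIABLES:
        out[f"norm_{var}"] = np.nan
    for patient, grp in table.groupby("patient_id"):
        ctrl = grp[grp["condition"] == control_condition]
        if ctrl.empty:
            raise ValueError(f"patient {patient!r} has no "
                             f"{control_condition!r} group to normalize to")
        idx = grp.index
        for var in NORMALIZED_VARIABLES:
            mean = ctrl[var].mean()
            if not np.isfinite(mean) or mean == 0:
                raise ValueError(f"degenerate control mean for {var!r} "
                                 f"in patient {patient!r}")
            out.loc[idx, f"norm_{var}"] = table.loc[idx, var] / mean
    return out


def omi_index(norm_redox_ratio, norm_nadh_tau_m, norm_fad_tau_m):
    """OMI index: linear combination with coefficients (1, 1, -1)."""
    return (np.asarray(norm_redox_ratio, dtype=float)
            + np.asarray(norm_nadh_tau_m, dtype=float)
            - np.asarray(norm_fad_tau_m, dtype=float))


def add_omi_index(table: pd.DataFrame,
                  control_condition: str = "control") -> pd.DataFrame:
    """Normalize to control and append the per-cell ``omi_index`` column."""
    out = normalize_to_control(table, control_condition)
    out["omi_index"] = omi_index(out["norm_redox_ratio"],
                                 out["norm_nadh_tau_m"],
                                 out["norm_fad_tau_m"])
    return out


def zscore_table(table: pd.DataFrame, variables=None,
                 control_condition: str = "control") -> pd.DataFrame:
    """Control-referenced Z-scores per (patient, condition, variable).

    Z = (treated group mean - control mean) / control SD, the heatmap
    statistic for cross-patient comparison of all OMI variables.
    """
    variables = variables or [v for v in OMI_VARIABLES if v in table.columns]
    rows = []
    for patient, grp in table.groupby("patient_id"):
        ctrl = grp[grp["condition"] == control_condition]
        if ctrl.empty:
            raise ValueError(f"patient {patient!r} has no control group")
        for condition, sub in grp.groupby("condition"):
            if condition == control_condition:
                continue
            for var in variables:
                sd = ctrl[var].std(ddof=1)
                z = (sub[var].mean() - ctrl[var].mean()) / sd if sd > 0 else np.nan
                rows.append({"patient_id": patient, "condition": condition,
                             "variable": var, "z_score": z})
    return pd.DataFrame(rows)
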