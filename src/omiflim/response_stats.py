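"""Drug-response calling from single-cell OMI indices.

For every patient and treatment condition the per-cell OMI index of the
treated group is compared to the patient's untreated control group:

* a one-way ANOVA (two groups, so F = t^2 of the unpaired t-test) tests
  whether the groups differ, significance at p < 0.05;
* Glass's delta, (mean_control - mean_treated) / SD_control, measures
  effect size with the control group's sample SD (n-1 denominator) as
  the yardstick — appropriate when treatment may change the variance.
  With the thousands of cells OMI measures, p-values alone are nearly
  always significant, so the effect-size gate (delta > 0.75) carries the
  decision.

Because only a *decrease* in OMI index indicates metabolic response, an
increase under treatment yields no delta at all ("n.a.") and the group is
called non-responsive regardless of the p-value.

Also here: organoid growth percent from brightfield diameter pairs,
Growth % = (day7 - day1) / day1 * 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponderStatus",
    "ResponseCall",
    "anova_control_vs_treatment",
    "glass_delta",
    "call_response",
    "calls_to_frame",
    "count_responders",
    "growth_percent",
]


class ResponderStatus(str, Enum):
    RESPONDER = "responder"
    NON_RESPONDER = "non_responder"
    NA_INCREASE = "na_increase"


@dataclass
class ResponseCall:
    patient_id: str
    condition: str
    mean_control: float
    mean_treated: float
    p_value: float
    glass_delta: float  # NaN encodes "n.a." (OMI index increased)
    responder: ResponderStatus


def anova_control_vs_treatment(control, treated) -> tuple[float, float]:
    """One-way ANOVA of control vs. one treated group: returns (F, p).

    For two groups this is exactly the unpaired equal-variance t-test
    (F = t^2, identical p).
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size < 2 or treated.size < 2:
        raise ValueError("both groups need at least 2 values")
    f, p = stats.f_oneway(control, treated)
    return float(f), float(p)


def glass_delta(control, treated) -> float:
    """Glass's delta with the control-group sample SD as denominator.

    Signed so that a *decrease* under treatment is positive.  Returns NaN
    ("n.a.") when the treated mean is at or above the control mean, since
    an OMI-index increase never indicates response.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size < 2:
        raise ValueError("control group needs at least 2 values")
    mc, mt = control.mean(), treated.mean()
    if mt >= mc:
        return np.nan
    sd = control.std(ddof=1)
    if sd == 0:
        raise ValueError("control group has zero variance")
    return float((mc - mt) / sd)


def call_response(table: pd.DataFrame, alpha: float = 0.05,
                  delta_cutoff: float = 0.75, value_col: str = "omi_index",
                  control_condition: str = "control",
                  require_p: bool = True,
                  require_delta: bool = True) -> list[ResponseCall]:
    """Call response per (patient, condition) from a per-cell table.

    A group is a responder when the OMI index decreased, the ANOVA p is
    below ``alpha`` and Glass's delta exceeds ``delta_cutoff`` (each gate
    individually switchable).
    """
    calls = []
    for patient, grp in table.groupby("patient_id", sort=True):
        ctrl = grp.loc[grp["condition"] == control_condition, value_col].to_numpy()
        if ctrl.size < 2:
            raise ValueError(f"patient {patient!r} lacks a usable control group")
        for condition in sorted(grp["condition"].unique()):
            if condition == control_condition:
                continue
            treated = grp.loc[grp["condition"] == condition, value_col].to_numpy()
            _, p = anova_control_vs_treatment(ctrl, treated)
            delta = glass_delta(ctrl, treated)
            if np.isnan(delta):
                status = ResponderStatus.NA_INCREASE
            else:
                ok = True
                if require_p:
                    ok &= p < alpha
                if require_delta:
                    ok &= delta > delta_cutoff
                status = (ResponderStatus.RESPONDER if ok
                          else ResponderStatus.NON_RESPONDER)
            calls.append(ResponseCall(
                patient_id=str(patient), condition=str(condition),
                mean_control=float(ctrl.mean()), mean_treated=float(treated.mean()),
                p_value=float(p), glass_delta=delta, responder=status))
    return calls


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": c.patient_id, "condition": c.condition,
        "mean_control": c.mean_control, "mean_treated": c.mean_treated,
        "p_value": c.p_value, "glass_delta": c.glass_delta,
        "responder": c.responder.value} for c in calls])


def count_responders(calls, condition: str) -> int:
    """Number of patients called responders for one treatment condition."""
    return sum(1 for c in calls
               if c.condition == condition
               and c.responder is ResponderStatus.RESPONDER)


def growth_percent(day1_diameter, day7_diameter):
    """Organoid growth percent between two brightfield measurements."""
    d1 = np.asarray(day1_diameter, dtype=float)
    d7 = np.asarray(day7_diameter, dtype=float)
    if np.any(d1 <= 0):
        raise ValueError("day-1 diameters must be positive")
    return (d7 - d1) / d1 * 100.0
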