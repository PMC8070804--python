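"""On-disk formats for the OMI pipeline.

Every artifact is a plain, inspectable file: FLIM photon-count stacks are
multi-page TIFFs (pages = time bins) with a JSON metadata sidecar, label
masks are 16-bit integer TIFFs with background 0, and all tabular data
(per-cell features, response calls, organoid diameters) travel as CSV
with snake_case headers.  Tables written by this module carry a leading
``#`` comment line embedding the RNG seed and a hash of the run
configuration, so any output can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FlimStack",
    "RunConfig",
    "CELL_TABLE_COLUMNS",
    "read_flim_stack",
    "write_flim_stack",
    "read_label_mask",
    "write_label_mask",
    "read_cell_table",
    "write_cell_table",
]

CHANNELS = ("NADH", "FAD")

#: stable column order for per-cell feature tables; one row per cell,
#: every OMI variable for both channels plus the redox ratio.
CELL_TABLE_COLUMNS = [
    "patient_id", "condition", "cell_id",
    "nadh_tau1", "nadh_tau2", "nadh_alpha1", "nadh_tau_m", "nadh_intensity",
    "fad_tau1", "fad_tau2", "fad_alpha1", "fad_tau_m", "fad_intensity",
    "redox_ratio",
]


@dataclass
class FlimStack:
    """A time-resolved photon-count image: axes (time_bin, row, col)."""

    counts: np.ndarray
    bin_width_ns: float
    channel: str
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("FLIM stack must be (time_bin, row, col)")
        if self.counts.shape[0] < 16:
            raise ValueError("FLIM stack needs at least 16 time bins")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if self.bin_width_ns <= 0:
            raise ValueError("bin width must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class RunConfig:
    """All tunable knobs of the pipeline, with documented defaults."""

    # decay fitting
    binning_radius: int = 1
    photon_threshold: int = 500
    # segmentation
    min_nucleus_area: int = 15
    max_nucleus_area: int = 2000
    max_eccentricity: float = 0.9
    min_solidity: float = 0.8
    min_overlap_frac: float = 0.25
    # feature aggregation
    min_valid_pixels: int = 10
    aggregate_statistic: str = "mean"  # or "median"
    # response calling
    anova_alpha: float = 0.05
    glass_delta_cutoff: float = 0.75
    # subpopulation modeling
    gmm_k_max: int = 3
    gmm_restarts: int = 100
    min_cells_per_group: int = 100
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.binning_radius < 0 or self.photon_threshold < 0:
            raise ValueError("binning radius and photon threshold must be >= 0")
        if not 0 < self.anova_alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.glass_delta_cutoff < 0:
            raise ValueError("Glass delta cutoff must be >= 0")
        if self.gmm_k_max < 1 or self.gmm_restarts < 1:
            raise ValueError("GMM settings must be positive")
        if self.aggregate_statistic not in ("mean", "median"):
            raise ValueError("aggregate_statistic must be 'mean' or 'median'")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_flim_stack(stack: FlimStack, path, seed: int | None = None,
                     config: RunConfig | None = None) -> Path:
    """Write a stack as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.counts.astype(np.uint32),
                     photometric="minisblack")
    meta = {"bin_width_ns": stack.bin_width_ns, "channel": stack.channel,
            "pixel_size_um": stack.pixel_size_um}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_hash"] = config.config_hash()
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_flim_stack(path) -> FlimStack:
    """Read a stack written by :func:`write_flim_stack`; bit-exact round trip."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata required: sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    for key in ("bin_width_ns", "channel"):
        if key not in meta:
            raise ValueError(f"metadata required: missing '{key}' in sidecar")
    counts = tifffile.imread(path)
    if np.any(counts < 0):
        raise ValueError("photon counts must be non-negative")
    return FlimStack(counts=counts, bin_width_ns=meta["bin_width_ns"],
                     channel=meta["channel"],
                     pixel_size_um=meta.get("pixel_size_um"))


def write_label_mask(mask: np.ndarray, path) -> Path:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label mask must fit in uint16 with background 0")
    path = Path(path)
    tifffile.imwrite(path, mask.astype(np.uint16),
                     photometric="minisblack")
    return path


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_cell_table(records, path, seed: int | None = None,
                     config: RunConfig | None = None) -> Path:
    """Write per-cell OMI features as CSV with a stable column order.

    ``records`` is a DataFrame or an iterable of mappings.  The
    (patient_id, condition, cell_id) triple must be unique.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("cannot write an empty cell table")
    missing = [c for c in ("patient_id", "condition", "cell_id")
               if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing key columns: {missing}")
    key = df[["patient_id", "condition", "cell_id"]]
    if key.duplicated().any():
        raise ValueError("duplicate (patient_id, condition, cell_id) rows")
    ordered = [c for c in CELL_TABLE_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    path = Path(path)
    header = ""
    if seed is not None or config is not None:
        bits = []
        if seed is not None:
            bits.append(f"seed={seed}")
        if config is not None:
            bits.append(f"config_hash={config.config_hash()}")
        header = "# " + " ".join(bits) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df[ordered].to_csv(fh, index=False)
    return path


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
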