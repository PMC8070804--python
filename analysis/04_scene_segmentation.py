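#!/usr/bin/env python
"""Render a synthetic organoid FLIM scene, fit it pixel by pixel, segment
cells from the NAD(P)H intensity image, and extract the per-cell table.

Reports segmentation accuracy against the generator's ground-truth masks
(object-level F1 at IoU 0.5) and the recovery of per-cell mean lifetime.
Writes results/scene_cells.csv and the masks as TIFFs under results/.
"""

import numpy as np

from omiflim import flim_fit as ff
from omiflim import io_formats as iof
from omiflim import omi_features as of
from omiflim import segmentation as seg
from omiflim import synthetic_data as sd

SEED = 7
OUT = "results/scene_cells.csv"


def main() -> None:
    preset = sd.ScenePreset(shape=(64, 64), n_cells=5, cell_radius=7,
                            nucleus_radius=3)
    nadh, fad, truth_masks, truth = sd.render_scene(preset, seed=SEED)
    irf = sd.default_irf()
    config = iof.RunConfig(seed=SEED)

    nadh_maps = ff.fit_image(nadh, irf, config)
    fad_maps = ff.fit_image(fad, irf, config)
    masks = seg.segment_scene(nadh_maps.intensity)
    f1_nuc = seg.object_f1(masks.nuclei, truth_masks.nuclei)
    f1_cell = seg.object_f1(masks.cells, truth_masks.cells)
    print(f"segmentation F1: nuclei {f1_nuc:.2f}, cells {f1_cell:.2f} "
          f"({masks.cells.max()} cells found, {preset.n_cells} true)")

    ratio = of.redox_ratio_map(nadh_maps.intensity, fad_maps.intensity)
    table = of.aggregate_cell(nadh_maps, fad_maps, ratio, masks.cytoplasm,
                              "scene", "control",
                              min_valid_pixels=config.min_valid_pixels)
    err = []
    for _, row in table.iterrows():
        pred = masks.cytoplasm == row.cell_id
        tid = np.bincount(truth_masks.cells[pred].ravel()).argmax()
        t = truth[truth.cell_id == tid].iloc[0]
        err.append(abs(row.nadh_tau_m / t.nadh_tau_m - 1.0))
    print(f"per-cell NAD(P)H tau_m: median |error| {np.median(err)*100:.1f}% "
          f"over {len(table)} cells")

    iof.write_cell_table(table, OUT, seed=SEED, config=config)
    iof.write_label_mask(masks.cells, "results/scene_cell_mask.tif")
    iof.write_label_mask(masks.nuclei, "results/scene_nucleus_mask.tif")
    print(f"wrote {OUT} and results/scene_*_mask.tif")


if __name__ == "__main__":
    main()
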