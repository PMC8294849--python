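"""Morphometry and mitochondrial distribution of reconstructed neurons.

Generates WT-like and KO-like reconstructions (the KO-like condition has
more axonal branch points and soma-biased mitochondria), then computes
lengths, branch counts, Sholl and MitoSholl profiles, and the
branch-point-to-mitochondrion proximity statistics, normalizing distances
to the WT-like group.  Writes results/morphometry_summary.csv and the
profile tables.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mitonet import image_quant, morphometry, synthetic
from mitonet.containers import VoxelStack

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

CONDITIONS = {
    "WT": dict(n_branch_axon=6, placement="uniform_on_tree"),
    "KO": dict(n_branch_axon=9, placement="biased_to_soma"),
}

prox_by_group = {}
rows = []
for gi, (name, cond) in enumerate(CONDITIONS.items()):
    morph = synthetic.gen_morphology(
        n_branch_axon=cond["n_branch_axon"], n_branch_dend=4, seed=300 + gi
    )
    morphometry.write_swc(morph, OUT / f"morph_{name.lower()}.swc")
    stack, truth = synthetic.gen_mito_stack(
        morph, n_mito=200, placement=cond["placement"],
        voxel_size=1.0, psf_sigma=0.5, seed=300 + gi,
    )
    mask = morphometry.fill_volume_mask(
        morph, 1.0, origin=stack.origin, shape=stack.shape
    )
    sholl = morphometry.sholl_intersections(morph, "axon", step=1.0)
    pd.DataFrame({"radius_um": sholl.radii, "count": sholl.counts}).to_csv(
        OUT / f"sholl_axon_{name.lower()}.csv", index=False
    )
    msholl = morphometry.mito_sholl(stack, mask, morph.soma_center, step=1.0,
                                    rolling_ball_radius=15)
    pd.DataFrame({"radius_um": msholl.radii, "count": msholl.counts}).to_csv(
        OUT / f"mitosholl_{name.lower()}.csv", index=False
    )
    binary = VoxelStack(
        stack.data > image_quant.threshold_value(stack.data, "otsu"),
        stack.voxel_size, stack.origin,
    )
    bps = morphometry.branch_points(morph, "all")
    prox_by_group[name] = morphometry.min_branch_mito_distance(bps, binary)
    rows.append({
        "condition": name,
        "total_length_um": morphometry.total_length(morph, "all"),
        "axon_branch_points": int(morphometry.branch_points(morph, "axon").shape[0]),
        "n_processes": morphometry.count_processes(morph),
        "p_within_1um": morphometry.prob_within_radius(prox_by_group[name], 1.0),
        # center of mass of the mito shell profile: soma bias pulls it inward
        "mitosholl_mean_radius_um": float(
            np.average(msholl.radii, weights=np.maximum(msholl.counts, 0))
            if msholl.counts.sum() else np.nan
        ),
    })

normalized = morphometry.normalize_distances(prox_by_group, "WT")
for row in rows:
    row["normalized_min_dist_mean"] = float(
        np.mean(normalized[row["condition"]].normalized)
    )

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "morphometry_summary.csv", index=False)
print(summary.to_string(index=False))
print("\nThe WT-normalized mean distance is exactly 1 for the reference "
      "group by construction, and soma-biased placement pulls the MitoSholl "
      "mass sharply toward the soma (compare the mean shell radii).")
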