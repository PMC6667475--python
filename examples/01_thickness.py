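"""Grid-based bilayer thickness on a synthetic flat membrane.

Builds a two-leaflet bilayer with phosphate planes 36.33 Å apart (plus
0.5 Å bead jitter), assigns leaflets, and measures the 40×40 grid thickness.
The printed mean should sit within its block-averaged error of 36.33 Å —
the generator's ground truth.
"""

import memfission as mf

series = mf.gen_flat_bilayer(n_per_leaflet=800, box_xy=400.0,
                             thickness=36.33, z_jitter=0.5, seed=1,
                             n_frames=20)
labels = mf.assign_leaflets_series(series)
result = mf.grid_thickness(series, labels, nx=40, ny=40)

print(f"constructed separation : 36.33 Å")
print(f"measured thickness     : {result.mean:.3f} ± {result.stderr:.3f} Å")
print("The grid estimator averages the phosphate-COM separation per cell;")
print("cells missing beads in either leaflet are excluded, not interpolated.")
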