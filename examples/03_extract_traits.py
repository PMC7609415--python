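"""Extract plot-level canopy temperature from a simulated flight.

Each orthorectified image contributes one observation per plot fully
contained in it (the subsamples); the mosaic contributes exactly one.
The plot value is the mode of non-zero thermal pixels inside the plot
polygon, converted to degC.
"""

from orthopheno import (
    SimParams,
    extract_trait_table,
    render_mosaic,
    render_orthorectified,
    simulate_field,
    synthetic_layout,
)

layout = synthetic_layout(n_entries=24, n_blocks=2, seed=7)
params = SimParams()
values, truth = simulate_field(layout, params, seed=7)
images, truth = render_orthorectified(layout, values, params=params, seed=7, kind="thermal", truth=truth)
mosaic = render_mosaic(images, blend="mean")

table = extract_trait_table(images, layout, "CT", mosaic=mosaic, date="2026-06-01")
table.to_csv("traits_ct.csv", index=False)

ortho = table[table.source_id != "MOSAIC"]
counts = ortho.groupby("plot_id").size()
print(f"{len(table)} observations written to traits_ct.csv")
print(f"  {len(table) - len(ortho)} mosaic records (one per plot)")
print(f"  {len(ortho)} orthorectified records; per-plot subsamples "
      f"{counts.min()}..{counts.max()} (median {counts.median():.0f})")
print(table.head(3).to_string(index=False))
print("azimuth_deg is the camera direction seen from the plot centre")
print("(east = 0 deg, counter-clockwise); it is empty for mosaic records.")
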