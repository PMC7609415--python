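"""Build a georeferenced field map from four surveyed corners.

A breeding trial is surveyed only at its four field corners; every plot
polygon is interpolated from them given the grid size and the sown plot
dimensions, then labelled with the experimental design (entry, block,
row, column) from a plot-map table.
"""

import pandas as pd

from orthopheno import attach_plot_map, build_plot_grid, write_layout

# four corners in a local metric frame (metres), ordered NW, NE, SE, SW:
# a 24 m x 12 m field holding 4 rows x 6 columns of plots on a
# 4 m x 2 m pitch, each sown plot 2.4 m x 1.5 m
corners = [(0.0, 16.0), (12.0, 16.0), (12.0, 0.0), (0.0, 0.0)]
grid = build_plot_grid(corners, n_rows=4, n_cols=6, plot_length_m=2.4, plot_width_m=1.5)

# label 20 of the 24 cells (the last column of each half is filler)
records = []
for r in range(1, 5):
    for c in range(1, 6):
        block = 1 if c <= 3 else 2
        records.append(
            {
                "plot_id": f"P{r}{c}",
                "entry": f"E{(r - 1) * 5 + c:02d}",
                "block": block,
                "row": r,
                "col": c,
            }
        )
layout = attach_plot_map(grid, pd.DataFrame(records))

path = write_layout(layout, "field_map.geojson")
first = layout.plots[0]
print(f"{len(layout.plots)} labelled plots written to {path}")
print(f"first plot {first.plot_id}: entry={first.entry} block={first.block}")
print(f"  polygon bounds (m): {tuple(round(v, 2) for v in first.polygon.bounds)}")
print("Each polygon is the grid cell shrunk to the sown plot size;")
print("these bounds feed the raster cropping of every later step.")
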