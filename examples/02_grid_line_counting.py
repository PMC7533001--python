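"""Grid Line Selection on a hand-built mask, step by step.

Two full-height vertical bars are placed between grid columns: each bar
crosses all 9 grid rows once and no grid column, so the total crossing
count is 18 and h = 2 * 18 / 9 = 4 ... except each bar is one hair, so
the estimate reads 2.0 hairs per full-height bar (a full-side hair
counts as two mean-length hairs).
"""

import numpy as np

from trichokit import BinaryFeatureImage, estimate_hair_count, grid_positions
from trichokit.gls import count_crossings

side = 512
mask = np.zeros((side, side), dtype=bool)
mask[:, 100:103] = True
mask[:, 300:303] = True
bfi = BinaryFeatureImage(mask=mask, branch="gls", erosion_applied=False)

grid = grid_positions(side, n_grid=8)
print("grid rows:", grid.rows.tolist())
cc = count_crossings(bfi, grid)
print("per-row crossings:", cc.per_row.tolist())
print("per-col crossings:", cc.per_col.tolist())
print("total:", cc.total)

est = estimate_hair_count(bfi, n_grid=8)
print(f"h = {est.ratio_constant} * {est.total_crossings} / {est.n_grid + 1} = {est.h}")
# Two bars spanning the full image height count as 4.0 mean-length hairs:
# the length-ratio constant 2 assumes an average hair spans half the frame.
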