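"""Remove uninformative and noisy cells before scoring.

Builds a mixture of diploid cells (no copy-number signal), clean
aneuploid tumor cells, and one noisy cell with a high-MAD profile, then
applies the default filters: drop cells with ploidy in [1.6, 2.9], then
cells above the 95th MAD percentile of the survivors.
"""

import json

import numpy as np
import pandas as pd

from spathet import CNVMatrix, annotate_cells, filter_cells

rng = np.random.default_rng(1)
n_bins = 60
bins = pd.DataFrame({"chromosome": "chr1",
                     "start": np.arange(n_bins) * 500_000,
                     "end": (np.arange(n_bins) + 1) * 500_000})

diploid = np.full((8, n_bins), 2)
tumor = np.full((25, n_bins), 4)
tumor[:, :20] = 6                      # ploidy ~4.7, clearly aneuploid
noisy = np.tile([1, 7], n_bins // 2)[None, :]  # erratic profile, MAD 3

X = np.vstack([diploid, tumor, noisy])
m = CNVMatrix(X, bins, [f"cell{i}" for i in range(len(X))])

print(annotate_cells(m).round(2).groupby("ploidy").size().to_string())
kept, report = filter_cells(m)
print(json.dumps(report.as_dict(), indent=2))
print(f"\nkept {kept.n_cells} tumor cells; the {report.n_removed_ploidy} "
      "diploid cells fell to the ploidy filter and the "
      f"{report.n_removed_mad} erratic cell to the MAD filter.")
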