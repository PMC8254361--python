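"""Find the most natural grouping of three tumor samples.

Builds three samples where two are independent draws from the same clone
and the third from a diverged clone, then scores every way of merging the
samples into >= 2 groups.  The top-ranked partition merges the two
same-clone samples, mirroring how the scan is used to spot clonally
related regions.
"""

import numpy as np
import pandas as pd

from spathet import CNVMatrix, aggregate, partition_scan

rng = np.random.default_rng(0)
bins = pd.DataFrame({"chromosome": "chr1",
                     "start": np.arange(40) * 1_000_000,
                     "end": (np.arange(40) + 1) * 1_000_000})


def sample(prefix, base):
    X = base + rng.integers(0, 2, size=(15, 40))
    return CNVMatrix(X, bins, [f"{prefix}{i}" for i in range(15)], prefix)


clone1 = np.full(40, 2)
clone2 = np.concatenate([np.full(20, 2), np.full(20, 5)])
m = aggregate([sample("s1_", clone1), sample("s2_", clone1),
               sample("s3_", clone2)], ["s1", "s2", "s3"])

scan = partition_scan(m)
print(scan.table.to_string(index=False))
print(f"\nbest partition: {scan.best.name} "
      f"(SHscore {scan.best_result.score:.4f})")
print("s1 and s2 are draws from one clone, so merging them against s3 "
      "yields the highest score.")
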