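"""Locate sex differences in the consensus-edge network summaries.

Reads the F - M inter-network difference maps and the intra-DMN heatmaps
from the script-03 results tree and reports where the positive-predictor
differences concentrate (expected: DMN-DMN for female models, visual pairs
for male models, matching the planted ground truth).
"""

from pathlib import Path

import numpy as np
import pandas as pd

RESULTS = Path("results/analysis/pipeline")

def main():
    for scan in ("FACENAME",):
        for score in ("ravlt_ir",):
            d = pd.read_csv(RESULTS / "difference_maps" /
                            f"{scan}_{score}_positive_FminusM.csv", index_col=0)
            arr = d.to_numpy()
            iu = np.triu_indices(arr.shape[0])
            vals = arr[iu]
            nets = list(d.index)
            hi = np.argmax(vals)
            lo = np.argmin(vals)
            print(f"{scan}/{score} positive F-M difference map:")
            print(f"  most female-weighted pair: "
                  f"{nets[iu[0][hi]]}-{nets[iu[1][hi]]} ({vals[hi]:+.3f})")
            print(f"  most male-weighted pair:   "
                  f"{nets[iu[0][lo]]}-{nets[iu[1][lo]]} ({vals[lo]:+.3f})")
            for group in ("F", "M"):
                sv = pd.read_csv(RESULTS / "intranetwork" /
                                 f"{group}_{scan}_{score}_DMN_sv.csv")
                top = sv.loc[sv["sv"].idxmax()]
                print(f"  {group}: top intra-DMN node by summed vector: "
                      f"node {int(top['node'])} (SV {top['sv']:.0f})")

if __name__ == "__main__":
    main()
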