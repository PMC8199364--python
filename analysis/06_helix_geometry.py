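"""Helix-dimension analysis: rise d, length L = d*n, radius r, twist theta
and end-to-end distance Ree per helix and noise tier, block-averaged.

Writes results/{wtrop,rm6}/helix_metrics.csv and helix_metrics_by_tier.csv.
"""

import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from helixmd.pipeline import run_analysis


def main():
    for name, cfg in (("wtrop", common.wtrop_config(n_waters=0)),
                      ("rm6", common.rm6_config())):
        out = common.RESULTS / name
        run_analysis(cfg, out, stages=["helix"])
        print(f"== {name}")
        print(pd.read_csv(out / "helix_metrics_by_tier.csv")
              .to_string(index=False))
    print("\nHelix dimensions are robust summary statistics: d, r and theta "
          "shift only slightly across tiers, while Ree and the block errors "
          "grow with the noise amplitude.")


if __name__ == "__main__":
    main()
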