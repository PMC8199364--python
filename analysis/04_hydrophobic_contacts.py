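"""Hydrophobic-core analysis: CB-CB radial distribution functions between
chains (dimer) or chain pairs (tetramer) and the distance between hydrophobic
centres of mass, per noise tier.

Writes results/{wtrop,rm6}/rdf.csv and cm_dist.csv.
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
        run_analysis(cfg, out, stages=["rdf"])
        g = pd.read_csv(out / "rdf.csv")
        cm = pd.read_csv(out / "cm_dist.csv")
        print(f"== {name}")
        tiers = [c for c in g.columns if c != "r_nm"]
        for t in tiers:
            print(f"  first-peak height {t}: {g[t].max():.2f} at "
                  f"r = {g.loc[g[t].idxmax(), 'r_nm']:.2f} nm")
        print(cm.to_string(index=False))
    print("\nThe first rdf peak decays with the noise tier (loss of "
          "hydrophobic contacts) while the centre-of-mass distance of the "
          "hydrophobic sets stays near the lattice separation.")


if __name__ == "__main__":
    main()
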