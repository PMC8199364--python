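"""Build the two synthetic bundle topologies and report their native helix
geometry, as a baseline for every later stage.

Writes results/native_helix_metrics.csv.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from helixmd.builder import build_bundle
from helixmd.helixgeom import helix_metrics


def main():
    rows = []
    for kind in ("wtrop_like", "rm6_like"):
        system, ann = build_bundle(kind)
        for (cid, label, a, b) in ann.helix_ranges():
            ca = [system.atoms[system.index_of(cid, r, "CA")].position
                  for r in range(a, b + 1)]
            import numpy as np

            m = helix_metrics(np.array(ca))
            rows.append(dict(kind=kind, chain=cid, helix=label,
                             res_start=a, res_end=b, n=m.n,
                             d_nm=m.d, L_nm=m.L, r_nm=m.r, theta_deg=m.theta))
    df = pd.DataFrame(rows)
    common.RESULTS.mkdir(exist_ok=True)
    df.to_csv(common.RESULTS / "native_helix_metrics.csv", index=False,
              float_format="%.6g")
    print(df.to_string(index=False))
    print("\nThe hairpin dimer carries 4 helices (2 per chain), the tetramer "
          "one long helix per chain; all are canonical alpha-helices "
          "(rise ~0.14-0.15 nm, radius ~0.23 nm, twist ~96-100 deg/residue).")


if __name__ == "__main__":
    main()
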