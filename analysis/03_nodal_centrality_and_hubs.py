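"""Summarize the nodal betweenness comparison and hub overlap.

Thin report over the tables written by
``02_global_network_comparison.py``: FDR-significant regions, their
direction, and the hub sets of the two groups with their overlap.

Run from the repository root::

    python analysis/03_nodal_centrality_and_hubs.py
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results-dir", default="results/study")
    args = ap.parse_args()
    rd = Path(args.results_dir)

    nodal = pd.read_csv(rd / "nodal_comparison.csv")
    sig = nodal.query("significant").sort_values("q")
    print(f"regions with FDR-significant NBC differences: {len(sig)}")
    if len(sig):
        cols = ["region", "estimate", "ci_low", "ci_high", "p", "q"]
        print(sig[cols].to_string(index=False, float_format="%.4g"))
        lower = (sig["estimate"] < 0).sum()
        print(f"  carrier NBC lower in {lower}/{len(sig)} significant regions")

    hubs = {}
    for f in sorted(rd.glob("hubs_*.csv")):
        label = f.stem.replace("hubs_", "")
        hubs[label] = set(pd.read_csv(f)["region"])
        print(f"{label}: {len(hubs[label])} hubs (mean NBC > 1.5)")
    if len(hubs) == 2:
        a, b = hubs.values()
        print(f"hubs common to both groups: {len(a & b)}")


if __name__ == "__main__":
    main()
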