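#!/usr/bin/env python
"""Weighted algebraic connectivity of the dispersal-probability networks.

Weights every corridor by the per-day crossing probability of the fitted
negative-exponential kernel (a=0.1, b=-0.0430) and computes λ₂ — the second-
smallest eigenvalue of the weighted Laplacian — plus link-count and mm
diameters for each topology.  Also ranks the networks by λ₂ across a grid of
kernel exponents in both dispersal modes to show that rankings are invariant
for distance-independent kernels but reorder when dispersal decays with
distance.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from netspread import DispersalKernel, connectivity_report, rank_networks
from netspread.io import read_network_graphml

RESULTS = Path(__file__).resolve().parent.parent / "results"
FITTED = DispersalKernel(a=0.1, b=-0.0430)


def main() -> None:
    nets = [read_network_graphml(p) for p in sorted((RESULTS / "networks").glob("*.graphml"))]
    if not nets:
        raise SystemExit("run 01_generate_networks.py first")

    reports = [connectivity_report(net, FITTED) for net in nets]
    conn = pd.DataFrame(
        {
            "topology_id": [r.topology_id for r in reports],
            "rewire_fraction": [r.rewire_fraction for r in reports],
            "lambda2": [r.algebraic_connectivity for r in reports],
            "diameter_links": [r.diameter_links for r in reports],
            "diameter_mm": [r.diameter_mm for r in reports],
        }
    )
    conn.to_csv(RESULTS / "connectivity.csv", index=False)
    print("λ₂ at the fitted kernel (a=0.1, b=-0.0430):")
    print(conn.round(5).to_string(index=False))

    b_grid = np.linspace(-0.1, -0.001, 12)
    for mode in ("distance_independent", "distance_dependent"):
        grid = [DispersalKernel(a=0.1, b=float(b), mode=mode) for b in b_grid]
        ranks, flips = rank_networks(nets, grid)
        ranks.to_csv(RESULTS / f"lambda2_ranks_{mode}.csv", index=False)
        print(
            f"\n{mode}: {len(flips)} network pairs change λ₂ rank "
            f"across b ∈ [-0.1, -0.001]"
        )
    print(
        "\nDistance-independent weights rescale the whole Laplacian uniformly, so "
        "rankings cannot change; distance-dependent weights reweight short vs "
        "long corridors and reorder the networks."
    )


if __name__ == "__main__":
    main()
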