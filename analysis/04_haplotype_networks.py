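#!/usr/bin/env python
"""Haplotype network and sweep-statistic profile for a swept locus.

Simulates haplotypes under a hard sweep, clusters the focal window into
a minimum-spanning-tree network (edges broken above one substitution),
profiles Garud's H12 and haplotype diversity along the region for
carriers and background separately, and computes EHH decay from the
focal variant.  Writes results/hapnet_nodes.tsv, hapnet_edges.tsv,
sweep_profile.tsv and ehh.tsv.
"""

from pathlib import Path

import pandas as pd

from dupsweep import haplotypes as H
from dupsweep import pipeline, simulate

ROOT = Path(__file__).resolve().parent.parent
SEED = 11


def main() -> None:
    haps = simulate.simulate_sweep(
        simulate.SweepSimConfig(
            n_haplotypes=200, n_variants=1000, focal_index=500, seed=SEED
        )
    )
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    # network over the focal window (tagging variant +/- 30 variants)
    window = H._hm_window(haps, 470, 531)
    net = H.build_haplotype_network(
        window, tag_alleles=haps.haplotypes[500]
    )
    pd.DataFrame(
        [
            {"node": n.node_id, "size": n.size, "tag_allele": n.tag_allele}
            for n in net.nodes
        ]
    ).to_csv(out / "hapnet_nodes.tsv", sep="\t", index=False)
    pd.DataFrame(net.edges, columns=["node_a", "node_b", "distance"]).to_csv(
        out / "hapnet_edges.tsv", sep="\t", index=False
    )

    # windowed H12 / diversity per carrier group
    carrier = haps.haplotypes[500].astype(bool)
    rows = []
    for label, mask in (("carrier", carrier), ("background", ~carrier)):
        sub = pipeline.haps_subset(haps, mask)
        h12 = H.moving_statistic(
            sub, lambda h: H.garud_h(h)[1], window_size=50, overlap_fraction=0.2
        )
        div = H.moving_statistic(
            sub, H.haplotype_diversity, window_size=50, overlap_fraction=0.2
        )
        for (_, a), (_, b) in zip(h12.iterrows(), div.iterrows()):
            rows.append(
                {
                    "group": label, "window_index": int(a["window_index"]),
                    "first_variant": int(a["first_variant"]),
                    "h12": a["value"], "diversity": b["value"],
                }
            )
    prof = pd.DataFrame(rows)
    prof.to_csv(out / "sweep_profile.tsv", sep="\t", index=False)

    # EHH decay from the focal variant, both directions
    ehh_rows = []
    for label, mask in (("carrier", carrier), ("background", ~carrier)):
        sub = haps.haplotypes[:, mask]
        for direction in ("left", "right"):
            for step, value in enumerate(H.ehh_decay(sub, 500, direction)):
                ehh_rows.append(
                    {"group": label, "direction": direction,
                     "step": step, "ehh": round(float(value), 4)}
                )
    pd.DataFrame(ehh_rows).to_csv(out / "ehh.tsv", sep="\t", index=False)

    big = max(net.nodes, key=lambda n: n.size)

    def focal_h12(group):
        g = prof[prof["group"] == group]
        return g.loc[(g["first_variant"] - 475).abs().idxmin(), "h12"]

    car, bg = focal_h12("carrier"), focal_h12("background")
    peak = prof.loc[prof[prof["group"] == "carrier"]["h12"].idxmax()]
    print(
        f"network: {len(net.nodes)} clusters, largest n={big.size} "
        f"(tag allele {big.tag_allele}); focal-window H12 carrier={car:.3f} "
        f"vs background={bg:.3f}; carrier H12 peaks in window starting at "
        f"variant {int(peak['first_variant'])} (focal variant = 500)"
    )


if __name__ == "__main__":
    main()
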