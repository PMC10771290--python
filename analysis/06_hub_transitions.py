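#!/usr/bin/env python
"""Betweenness hubs per group network and their Venn partition per band.

Computes weighted betweenness centrality on the group-average delta and
theta networks, applies the mean + 1.5 SD hub rule, partitions hubs into
shared / lost-in-SCD / gained-in-SCD sets, annotates them with lobes and
renders the Venn figures.
"""

import json
from pathlib import Path

from scdnet.atlas import load_default_atlas
from scdnet.connectivity import read_connectivity_matrix
from scdnet.graph_hubs import (
    detect_hubs,
    hub_table,
    plot_venn,
    venn_partition,
    weighted_betweenness,
)

NET = Path("results/analysis/networks")
OUT = Path("results/analysis")


def main() -> None:
    atlas = load_default_atlas()
    venn_report = {}
    for band in ("delta", "theta"):
        hub_sets = {}
        for group in ("non-SCD", "SCD"):
            mat = read_connectivity_matrix(NET / f"group_{group}_{band}.txt")
            bc = weighted_betweenness(mat)
            hub_sets[group] = detect_hubs(bc, group=group, band=band)
            print(f"{band}/{group}: {len(hub_sets[group].hubs)} hubs "
                  f"(threshold {hub_sets[group].threshold:.1f})")
        part = venn_partition(hub_sets["non-SCD"], hub_sets["SCD"])
        shared, lost, gained = part.counts
        print(f"{band}: {shared} shared, {lost} lost in SCD, {gained} gained in SCD")
        table = hub_table(list(hub_sets.values()), atlas)
        table.to_csv(OUT / f"hubs_{band}.csv", index=False)
        plot_venn(part, ("non-SCD", "SCD"), OUT / f"venn_{band}.png")
        venn_report[band] = {
            "shared": sorted(part.shared),
            "lost_in_scd": sorted(part.exclusive_a),
            "gained_in_scd": sorted(part.exclusive_b),
        }
    (OUT / "venn_partitions.json").write_text(
        json.dumps(venn_report, indent=2, sort_keys=True) + "\n"
    )
    print(f"wrote hub tables, venn figures and {OUT / 'venn_partitions.json'}")


if __name__ == "__main__":
    main()
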