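#!/usr/bin/env python
"""Detect cluster marker genes (one-vs-rest Wilcoxon with fraction filters).

Positive markers only: log-FC >= 0.25, expressed in >= 25% of in-cluster
cells, expressing-fraction difference >= 0.25. Exports the per-cluster top-10
signatures as GMT for downstream bulk scoring.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import ensure_results, get_pipeline_result

from tmepat.core_io import save_gene_sets_gmt
from tmepat.markers import find_markers, top_markers


def main() -> None:
    results = ensure_results()
    res, truth = get_pipeline_result()

    markers = find_markers(res.nm, res.assignment)
    markers.to_csv(results / "markers.tsv", sep="\t", index=False)
    sigs = top_markers(markers, n=10,
                       label_by=res.assignment.cluster_table["cell_type"])
    save_gene_sets_gmt(list(sigs.values()), results / "cluster_markers_top10.gmt")

    print(f"{len(markers)} marker rows across "
          f"{markers['cluster'].nunique()} clusters")
    planted = {g for p in truth.programs for g in p.marker_genes}
    hit = markers["gene"].isin(planted).mean()
    print(f"{hit:.0%} of reported markers are planted program genes")
    print(markers.groupby("cluster").size().rename("n_markers").to_string())
    print(f"tables written to {results / 'markers.tsv'} and "
          f"{results / 'cluster_markers_top10.gmt'}")


if __name__ == "__main__":
    main()
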