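#!/usr/bin/env python
"""Embed, cluster and annotate the cohort; call tumor cell clusters.

Runs PCA on highly variable genes, shared-nearest-neighbor graph
construction, Louvain community detection, marker-based annotation and
tumor-cell calling, then reports how well clusters recover the planted cell
types.
"""

import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import ensure_results, get_pipeline_result


def main() -> None:
    results = ensure_results()
    res, truth = get_pipeline_result()

    res.assignment.to_frame().to_csv(results / "cluster_annotation.tsv", sep="\t")

    true_types = truth.cells.loc[res.nm.cells, "cell_type"]
    ari = adjusted_rand_score(true_types, res.assignment.labels)
    table = res.assignment.cluster_table
    print(f"{len(table)} clusters over {len(res.nm.cells)} cells "
          f"(adjusted Rand index vs planted types: {ari:.3f})")
    print(table.to_string())
    n_tumor = int((res.assignment.cell_series("tumor_call") == "tumor").sum())
    print(f"{n_tumor} cells in tumor-called epithelial clusters")
    print(f"annotation written to {results / 'cluster_annotation.tsv'}")


if __name__ == "__main__":
    main()
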