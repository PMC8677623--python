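#!/usr/bin/env python
"""Derive the tumor-cell differentiation axis and its paired 30-gene signatures.

PC1 of tumor-cell expression is oriented against normal alveolar/club
reference scores; the 30 genes most positively / negatively correlated with
the oriented axis become the alveolar/club-like and undifferentiated
signatures. Compares both against the generator's planted programs.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import ensure_results, get_pipeline_result

from tmepat.core_io import GeneSignature, save_gene_sets_gmt
from tmepat.scoring import ModuleScoreParams, module_score
from tmepat.tumor_axis import derive_axis, score_axis_signatures


def main() -> None:
    results = ensure_results()
    res, truth = get_pipeline_result()

    tumor_mask = (res.assignment.cell_series("tumor_call") == "tumor").to_numpy()
    nmt = res.nm.subset_cells(tumor_mask)
    refs = pd.DataFrame({
        name: module_score(nmt, GeneSignature(name, truth.signatures[name]),
                           ModuleScoreParams(seed=1))
        for name in ("AT1", "AT2", "Club")
    }, index=nmt.cells)
    axis = derive_axis(nmt, refs)

    axis.pc1_scores.to_frame().to_csv(results / "tumor_axis_pc1.tsv", sep="\t")
    save_gene_sets_gmt([axis.sig_alveolar, axis.sig_undiff],
                       results / "tumor_axis_signatures.gmt")
    patients = res.meta.loc[nmt.cells, "patient"]
    per_patient = score_axis_signatures(nmt, axis, ModuleScoreParams(seed=1),
                                        patients=patients)
    per_patient.to_csv(results / "tumor_axis_patient_scores.tsv", sep="\t")

    u = truth.cells.loc[nmt.cells, "u"].to_numpy()
    r = np.corrcoef(axis.pc1_scores.to_numpy(), u)[0, 1]
    alv = set(truth.signatures["alveolar_club_like"])
    und = set(truth.signatures["undifferentiated"])
    print(f"{len(nmt.cells)} tumor cells; corr(PC1, planted latent) = {r:.3f}")
    print(f"alveolar/club-like signature: {len(axis.sig_alveolar.genes)} genes, "
          f"{len(alv & set(axis.sig_alveolar.genes))}/{len(alv)} planted recovered")
    print(f"undifferentiated signature: {len(axis.sig_undiff.genes)} genes, "
          f"{len(und & set(axis.sig_undiff.genes))}/{len(und)} planted recovered")
    print("per-patient mean signature scores:")
    print(per_patient.round(3).to_string())


if __name__ == "__main__":
    main()
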