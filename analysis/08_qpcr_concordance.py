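#!/usr/bin/env python
"""Validate DGE ratios against simulated qRT-PCR.

Computes 2^-ddCt relative expression (PT vs MP, three internal-control
reference genes) for the simulated Ct tables and reports per-gene sign
concordance with the DGE log2 ratios.  Writes qpcr_ratios.tsv and
qpcr_concordance.tsv under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tagdge import qpcr

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "de_step", Path(__file__).with_name("05_differential_expression.py"))
_de_step = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_de_step)

BASE = Path(__file__).resolve().parents[1] / "results"
REFERENCES = ["actin", "rDNA18S", "GAPDH"]


def main() -> None:
    ct = qpcr.CtTable.from_tsv(BASE / "sim" / "ct.tsv", REFERENCES)
    targets = [g for g in ct.data.gene_id.unique() if g not in REFERENCES]
    ratios = qpcr.ddct_table(ct, targets, calibrator="MP", test="PT")
    ratios.to_csv(BASE / "qpcr_ratios.tsv", sep="\t")

    table = _de_step.load_expression()
    dge = np.log2((table.tpm.loc[targets, "PT"] + 0.001)
                  / (table.tpm.loc[targets, "MP"] + 0.001))
    per_gene, frac = qpcr.concordance(ratios["log2_ratio"], dge)
    per_gene.to_csv(BASE / "qpcr_concordance.tsv", sep="\t")
    n_up = int((per_gene.qpcr_log2 > 0).sum())
    print(f"{len(targets)} genes assayed: {n_up} up / {len(targets) - n_up} down "
          f"by qPCR (PT vs MP)")
    print(f"sign concordance with DGE log2 ratios: {frac:.2f}")


if __name__ == "__main__":
    main()
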