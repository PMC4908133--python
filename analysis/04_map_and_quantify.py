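#!/usr/bin/env python
"""Map clean tags to genes, quantify TPM, and survey the libraries.

Assigns each clean tag at <= 1 mismatch (multi-gene tags excluded), builds
the gene x stage expression table in tags and TPM, classifies detection and
stage-specificity, and runs the saturation, antisense and fold-change
surveys.  Writes expression.tsv, stage_summary.tsv, mapping_summaries.json,
saturation TSVs and foldchange.tsv under results/.
"""

import json
from pathlib import Path

import pandas as pd

from tagdge import mapping, qc, reference

BASE = Path(__file__).resolve().parents[1] / "results"
STAGES = ("MP", "HP", "PT")


def main() -> None:
    db = reference.load_refdb(BASE / "refdb.tsv")
    n_ref_genes = len(reference.read_fasta(BASE / "sim" / "reference.fa"))

    clean, assignments, summaries = {}, {}, {}
    for stage in STAGES:
        clean[stage] = qc.read_tag_tsv(BASE / f"{stage}_clean.tsv", stage)
        asg, summary = mapping.map_tags(clean[stage], db)
        asg.to_csv(BASE / f"{stage}_assignments.tsv", sep="\t", index=False)
        assignments[stage] = asg
        summaries[stage] = summary
        u = summary.classes["unambiguous_mapping"]
        print(f"{stage}: {u['distinct']:,} distinct tags mapped unambiguously "
              f"({u['total']:,} reads); sense:antisense transcript ratio "
              f"{summary.sense_antisense_gene_ratio:.1f}:1")

    table = mapping.quantify(assignments, clean, sorted({t.gene_id for t in db.tags}
                                                        | set(_gene_ids())),
                             n_reference_genes=n_ref_genes)
    combined = pd.concat({"count": table.counts, "tpm": table.tpm.round(4)}, axis=1)
    combined.columns = [f"{a}_{b}" for a, b in combined.columns]
    combined.to_csv(BASE / "expression.tsv", sep="\t")

    stage_summary = mapping.classify_stages(table)
    stage_summary.to_csv(BASE / "stage_summary.tsv", sep="\t", index=False)
    print(stage_summary.to_string(index=False))

    (BASE / "mapping_summaries.json").write_text(json.dumps(
        {s: m.classes for s, m in summaries.items()}, indent=2) + "\n")

    for stage in STAGES:
        total = clean[stage].total
        depths = [total // 50, total // 20, total // 10, total // 4,
                  total // 2, total]
        curve = mapping.saturation_curve(clean[stage], assignments[stage],
                                         depths, n_reps=5, seed=42)
        curve.to_csv(BASE / f"{stage}_saturation.tsv", sep="\t", index=False)

    fc = {f"{a}vs{b}": mapping.foldchange_distribution(table, a, b)
          for a, b in (("MP", "HP"), ("HP", "PT"))}
    fc_df = pd.DataFrame(fc)
    fc_df.to_csv(BASE / "foldchange.tsv", sep="\t")
    print("fold-change bins (fraction of detected genes):")
    print(fc_df.round(3).to_string())


def _gene_ids():
    return [r.gene_id for r in reference.read_fasta(BASE / "sim" / "reference.fa")]


if __name__ == "__main__":
    main()
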