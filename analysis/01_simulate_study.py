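#!/usr/bin/env python
"""Generate the synthetic three-stage pollen DGE study.

Writes the study inputs every later step consumes — transcriptome FASTA,
per-stage raw tag libraries (MP/HP/PT), term annotations with planted
enrichment, qRT-PCR Ct tables — plus the ground-truth TPM matrix and DE
labels used only for scoring, under results/sim/.
"""

import dataclasses
import json
import sys
from pathlib import Path

import pandas as pd

from tagdge import qc, simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main(seed: int = 42) -> None:
    cfg = simulate.SimulationConfig(seed=seed)
    study = simulate.simulate_study(cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    simulate.write_fasta(study["transcripts"], OUT / "reference.fa")
    for stage, lib in study["libraries"].items():
        qc.write_tag_tsv(lib, OUT / f"{stage}_raw.tsv")
    truth = study["truth"]
    truth.tpm.round(6).to_csv(OUT / "truth_tpm.tsv", sep="\t")
    for cmp, de in truth.de.items():
        de.to_csv(OUT / f"truth_de_{cmp}.tsv", sep="\t")
    rows = [(g, t, name) for t, (name, genes) in study["annotations"].terms.items()
            for g in sorted(genes)]
    pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).to_csv(
        OUT / "annotations.tsv", sep="\t", index=False)
    study["ct"].data.to_csv(OUT / "ct.tsv", sep="\t", index=False)
    (OUT / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2) + "\n")
    (OUT / "planted_terms.json").write_text(
        json.dumps(truth.planted_terms, indent=2) + "\n")

    n_de = {c: int(d.planted.sum()) for c, d in truth.de.items()}
    print(f"study written to {OUT}")
    print(f"  {cfg.n_genes} genes, {cfg.depth:,} raw tags per stage, seed {seed}")
    print(f"  planted DEGs: {n_de}; stage-specific: "
          f"{ {s: len(g) for s, g in truth.specific.items()} }")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
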