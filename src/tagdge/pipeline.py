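"""End-to-end orchestration of the DGE tag-profiling analysis.

Stages run in dependency order — reference construction, per-library QC,
tag mapping, quantification, stage classification, differential expression
per transition, term enrichment, clustering of the DEG intersection, qPCR
concordance — and the run emits a ledger/stage-summary/DE-summary report
assembled from its own outputs, plus a provenance record (config hash,
seed).  All outputs are plain TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, diffexpr, enrichment, mapping, qc, qpcr, reference, simulate

COMPARISONS = {"MPvsHP": ("MP", "HP"), "HPvsPT": ("HP", "PT")}


@dataclass
class RunConfig:
    """Thresholds and seeds of one analysis run (defaults as conventionally
    used for pooled single-library DGE: FDR <= 0.001, p < 0.0005,
    |log2 ratio| >= 1, enrichment q < 0.05, detection at >= 1 tag, one
    mismatch allowed in mapping)."""

    q_max: float = 0.001
    p_max: float = 0.0005
    min_abs_log2_ratio: float = 1.0
    enrich_q: float = 0.05
    min_tags: int = 1
    mismatch: int = 1
    fdr_method: str = "BH"
    seed: int = 42
    sim: simulate.SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("q_max", "p_max", "enrich_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mismatch not in (0, 1):
            raise ValueError("mismatch must be 0 or 1")

    def provenance(self) -> dict:
        cfg = {k: v for k, v in dataclasses.asdict(self).items()}
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return {"config": cfg, "config_hash": digest, "seed": self.seed}


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate a study under ``config`` and run every analysis stage on it.

    Returns the full result bundle; when ``outdir`` is given, also writes
    the stable TSV/JSON file contract for every stage.
    """
    sim_cfg = config.sim or simulate.SimulationConfig(seed=config.seed)
    study = simulate.simulate_study(sim_cfg)

    db = reference.scan_catg_tags(study["transcripts"])
    ref_summary = reference.reference_summary(db)

    clean_libs, ledgers, spectra = {}, {}, {}
    for stage, raw in study["libraries"].items():
        clean, ledger = qc.filter_raw_tags(raw)
        clean_libs[stage] = clean
        ledgers[stage] = ledger
        spectra[stage] = qc.copy_spectrum(clean)

    assignments, map_summaries = {}, {}
    for stage, clean in clean_libs.items():
        assignments[stage], map_summaries[stage] = mapping.map_tags(clean, db)

    table = mapping.quantify(assignments, clean_libs,
                             [t.gene_id for t in study["transcripts"]])
    stage_summary = mapping.classify_stages(table, min_tags=config.min_tags)

    thresholds = {"q_max": config.q_max, "p_max": config.p_max,
                  "min_abs_log2_ratio": config.min_abs_log2_ratio}
    de_results, de_summaries = {}, {}
    for label, (a, b) in COMPARISONS.items():
        de, summ = diffexpr.call_degs(table, a, b, thresholds, config.fdr_method)
        de_results[label] = de
        de_summaries[label] = summ

    enr_results = {}
    for label, de in de_results.items():
        degs = de.index[de.call != "unchanged"]
        if len(degs) == 0:
            enr_results[label] = pd.DataFrame()
            continue
        enr_results[label] = enrichment.enrich(degs, study["annotations"],
                                               q_threshold=config.enrich_q)

    cluster_sel = clustering.select_cluster_genes(
        de_results, table, q_max=config.q_max,
        min_abs_log2_ratio=config.min_abs_log2_ratio, min_tags=config.min_tags)
    cluster_out = None
    if len(cluster_sel.genes) >= 2:
        cluster_out = clustering.hierarchical_cluster(cluster_sel)

    ct = study["ct"]
    targets = [g for g in ct.data.gene_id.unique() if g not in ct.reference_genes]
    qpcr_ratios = qpcr.ddct_table(ct, targets, calibrator="MP", test="PT")
    dge_log2 = np.log2(pd.Series({
        g: (table.tpm.loc[g, "PT"] + diffexpr.PSEUDO_TPM)
           / (table.tpm.loc[g, "MP"] + diffexpr.PSEUDO_TPM)
        for g in targets}))
    concord_table, concord_frac = qpcr.concordance(qpcr_ratios["log2_ratio"], dge_log2)

    report = {
        "provenance": config.provenance(),
        "reference_summary": ref_summary,
        "qc_ledgers": {s: l.as_dict() for s, l in ledgers.items()},
        "mapping_summaries": {s: m.classes for s, m in map_summaries.items()},
        "stage_summary": stage_summary.to_dict(orient="records"),
        "de_summaries": {k: dataclasses.asdict(v) for k, v in de_summaries.items()},
        "qpcr_concordance": concord_frac,
        "n_cluster_genes": len(cluster_sel.genes),
    }

    results = {
        "study": study, "db": db, "clean_libs": clean_libs, "ledgers": ledgers,
        "spectra": spectra, "assignments": assignments,
        "map_summaries": map_summaries, "expression": table,
        "stage_summary": stage_summary, "de_results": de_results,
        "de_summaries": de_summaries, "enrichment": enr_results,
        "cluster_selection": cluster_sel, "cluster": cluster_out,
        "qpcr": qpcr_ratios, "qpcr_concordance": (concord_table, concord_frac),
        "report": report,
    }
    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    reference.write_refdb(results["db"], outdir / "refdb.tsv")
    for stage, clean in results["clean_libs"].items():
        qc.write_tag_tsv(clean, outdir / f"{stage}_clean.tsv")
        results["spectra"][stage].to_csv(outdir / f"{stage}_spectrum.tsv",
                                         sep="\t", index=False)
        results["assignments"][stage].to_csv(outdir / f"{stage}_assignments.tsv",
                                             sep="\t", index=False)
    expr = results["expression"]
    combined = pd.concat(
        {"count": expr.counts, "tpm": expr.tpm.round(4)}, axis=1
    )
    combined.columns = [f"{a}_{b}" for a, b in combined.columns]
    combined.to_csv(outdir / "expression.tsv", sep="\t")
    results["stage_summary"].to_csv(outdir / "stage_summary.tsv", sep="\t", index=False)
    for label, de in results["de_results"].items():
        de.to_csv(outdir / f"de_{label}.tsv", sep="\t")
    for label, enr in results["enrichment"].items():
        if len(enr):
            enr.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t", index=False)
    sel, clust = results["cluster_selection"], results["cluster"]
    if clust is not None:
        clustering.write_eisen_files(sel, clust[0], outdir / "cluster")
    results["qpcr"].to_csv(outdir / "qpcr_ratios.tsv", sep="\t")
    (outdir / "report.json").write_text(
        json.dumps(results["report"], indent=2, default=str) + "\n")
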