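#!/usr/bin/env python
"""Cluster the genes differential in both transitions.

Selects genes expressed in all three stages with FDR <= 0.001 and
|log2 ratio| >= 1 in both the germination and tube-growth comparisons,
clusters their two log2 ratios with 1 - Pearson distance and average
linkage, and exports TreeView-compatible CDT/GTR files plus an ordered TSV
under results/.
"""

from pathlib import Path

import pandas as pd

from tagdge import clustering

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "de_step", Path(__file__).with_name("05_differential_expression.py"))
_de_step = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_de_step)

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = _de_step.load_expression()
    de = {label: pd.read_csv(BASE / f"de_{label}.tsv", sep="\t", index_col=0)
          for label in ("MPvsHP", "HPvsPT")}
    sel = clustering.select_cluster_genes(de, table)
    print(f"{len(sel.genes)} genes qualify for clustering "
          f"(three-stage detection + both-comparison DEG)")
    if len(sel.genes) < 2:
        print("nothing to cluster")
        return
    linkage, ordered_genes, _ = clustering.hierarchical_cluster(sel)
    clustering.write_eisen_files(sel, linkage, BASE / "cluster")
    up_up = sum((sel.matrix.loc[g] >= 1).all() for g in sel.genes)
    flip = sum(v["MPvsHP"] * v["HPvsPT"] < 0 for _, v in sel.matrix.iterrows())
    print(f"  profiles: {up_up} up in both transitions, {flip} reversing "
          f"direction between germination and tube growth")
    print(f"  dendrogram and ordered matrix -> {BASE / 'cluster'}.{{cdt,gtr,ordered.tsv}}")


if __name__ == "__main__":
    main()
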