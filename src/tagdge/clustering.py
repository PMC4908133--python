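"""Selection and hierarchical clustering of the three-stage DEG intersection.

Genes expressed in all three stages that pass FDR <= 0.001 and
|log2 ratio| >= 1 in both stage transitions are clustered on their two log2
ratios (or optionally log2 TPM per stage) with 1 - Pearson correlation
distance and average linkage — the historical defaults of the Eisen Cluster
program — and exported as TreeView-compatible CDT/GTR files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .mapping import ExpressionTable


@dataclass
class ClusterInput:
    genes: list[str]
    matrix: pd.DataFrame  # index gene_id, columns = comparisons or stages


def select_cluster_genes(
    de_results: Mapping[str, pd.DataFrame],
    table: ExpressionTable,
    q_max: float = 0.001,
    min_abs_log2_ratio: float = 1.0,
    quantity: str = "ratios",
    min_tags: int = 1,
) -> ClusterInput:
    """Intersect DEG calls across comparisons with three-stage detection.

    A gene qualifies when it is detected in every stage and satisfies
    q <= q_max and |log2 ratio| >= min_abs_log2_ratio in *every* supplied
    comparison.  ``quantity`` selects the clustered matrix: the per-
    comparison log2 ratios (default) or log2(TPM + 1) per stage.
    """
    detected_all = np.logical_and.reduce(
        [table.detected(s, min_tags).to_numpy() for s in table.stages]
    )
    qualifying = set(table.counts.index[detected_all])
    for de in de_results.values():
        ok = de[(de.q <= q_max) & (de.log2_ratio.abs() >= min_abs_log2_ratio)]
        qualifying &= set(ok.index)
    genes = sorted(qualifying)
    if not genes:
        import warnings

        warnings.warn("empty cluster-gene selection", stacklevel=2)
        return ClusterInput([], pd.DataFrame())
    if quantity == "ratios":
        matrix = pd.DataFrame(
            {label: de.loc[genes, "log2_ratio"] for label, de in de_results.items()},
            index=pd.Index(genes, name="gene_id"),
        )
    elif quantity == "log2_tpm":
        matrix = np.log2(table.tpm.loc[genes] + 1.0)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return ClusterInput(genes, matrix)


def pearson_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """1 - centered Pearson correlation between rows.

    Rows with zero variance have undefined correlation; they are assigned
    distance 1 to every other row (and 0 to themselves).
    """
    x = np.asarray(matrix, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[zero, :] = 1.0
    dist[:, zero] = 1.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def hierarchical_cluster(cluster_input: ClusterInput) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Average-linkage clustering on 1 - Pearson distance.

    Returns the scipy linkage matrix, the leaf-ordered gene list and the
    matrix reordered to match.  Input gene order is fixed (sorted by id), so
    the dendrogram is deterministic.
    """
    n = len(cluster_input.genes)
    if n < 2:
        raise ValueError("clustering needs >= 2 genes")
    dist = pearson_distance_matrix(cluster_input.matrix.to_numpy())
    condensed = dist[np.triu_indices(n, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(linkage)
    genes = [cluster_input.genes[i] for i in order]
    return linkage, genes, cluster_input.matrix.iloc[order]


def write_eisen_files(
    cluster_input: ClusterInput,
    linkage: np.ndarray,
    out_prefix: str | Path,
) -> None:
    """Export TreeView-compatible CDT + GTR files plus a plain ordered TSV.

    GTR node scores are 1 - merge height, i.e. the average Pearson
    correlation at each join, as the Cluster program writes them.
    """
    out_prefix = Path(out_prefix)
    n = len(cluster_input.genes)
    order = hierarchy.leaves_list(linkage)

    gid = [f"GENE{i}X" for i in range(n)]
    node_name: dict[int, str] = {i: gid[i] for i in range(n)}
    gtr_lines = []
    for j, (a, b, height, _) in enumerate(linkage):
        node = f"NODE{j + 1}X"
        gtr_lines.append(
            f"{node}\t{node_name[int(a)]}\t{node_name[int(b)]}\t{1.0 - height:.6f}"
        )
        node_name[n + j] = node
    Path(str(out_prefix) + ".gtr").write_text("\n".join(gtr_lines) + "\n")

    cols = list(cluster_input.matrix.columns)
    header = "GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(map(str, cols))
    eweight = "EWEIGHT\t\t\t\t" + "\t".join("1" for _ in cols)
    lines = [header, eweight]
    for i in order:
        gene = cluster_input.genes[i]
        vals = "\t".join(f"{v:.6g}" for v in cluster_input.matrix.iloc[i])
        lines.append(f"{gid[i]}\t{gene}\t{gene}\t1\t{vals}")
    Path(str(out_prefix) + ".cdt").write_text("\n".join(lines) + "\n")

    ordered = cluster_input.matrix.iloc[order]
    ordered.to_csv(str(out_prefix) + ".ordered.tsv", sep="\t")
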