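"""Tag-to-gene mapping with <=1 mismatch, TPM quantification and library surveys.

Clean tags are looked up in the virtual-tag database, exact matches first;
only tags with no exact hit are considered at Hamming distance 1 (every tag
has 63 single-base neighbours, so the search is a dictionary lookup, not an
alignment).  Within the winning match class a tag hitting two or more
distinct genes is excluded from quantification; a tag hitting exactly one
gene contributes its full copy number to that gene.  Gene expression is
normalised to transcripts per million clean tags (TPM = count / clean total
x 1e6) per library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import TagLibrary
from .reference import ReferenceTagDB, TAG_LEN

_BASES = "ACGT"


def hamming1_neighbors(tag: str) -> Iterable[str]:
    """All 63 sequences at Hamming distance exactly 1 from a 21-mer."""
    for i, orig in enumerate(tag):
        for b in _BASES:
            if b != orig:
                yield tag[:i] + b + tag[i + 1 :]


def _strand_of(hits: Sequence[tuple[str, str]], gene: str) -> str:
    """Strand of the matched virtual tag; sense wins a sense/antisense tie."""
    strands = {s for g, s in hits if g == gene}
    return "sense" if "sense" in strands else "antisense"


@dataclass
class MappingSummary:
    """Partition of one clean library into mapping classes.

    ``all_mapping`` covers every tag with a reference hit at <=1 mismatch
    (including multi-gene tags later excluded); ``unambiguous_mapping`` the
    uniquely assigned subset; ``unknown`` the remainder (the study's separate
    "mapping to genome" class is folded into unknown — no genome aligner
    here).  Antisense statistics are reported both per distinct tag and per
    gene-level transcript call.
    """

    stage: str
    classes: dict = field(default_factory=dict)
    sense_distinct: int = 0
    antisense_distinct: int = 0
    sense_genes: int = 0
    antisense_genes: int = 0

    @property
    def sense_antisense_gene_ratio(self) -> float:
        return self.sense_genes / self.antisense_genes if self.antisense_genes else float("inf")


def map_tags(clean: TagLibrary, db: ReferenceTagDB) -> tuple[pd.DataFrame, MappingSummary]:
    """Assign every clean tag to exact / one_mismatch / unknown classes.

    Returns an assignment table (one row per distinct clean tag) and the
    class partition summary.  Exact matches take absolute priority; ambiguity
    (>=2 distinct genes) is evaluated only within the winning class.
    """
    if not db.tag_genes:
        raise ValueError("empty reference tag database")
    rows = []
    for tag, n in clean.counts.items():
        genes = db.tag_genes.get(tag)
        if genes is not None:
            match_class = "exact"
            hits = db.tag_hits[tag]
        else:
            gene_set: set[str] = set()
            hits = []
            for nb in hamming1_neighbors(tag):
                g = db.tag_genes.get(nb)
                if g is not None:
                    gene_set.update(g)
                    hits.extend(db.tag_hits[nb])
            if gene_set:
                match_class = "one_mismatch"
                genes = tuple(sorted(gene_set))
            else:
                match_class = "unknown"
                genes = ()
        excluded = len(genes) >= 2
        if len(genes) == 1:
            gene = genes[0]
            strand = _strand_of(hits, gene)
        else:
            gene, strand = "", "none"
        rows.append((tag, n, match_class, gene, strand, excluded, len(genes)))

    assignments = pd.DataFrame(
        rows,
        columns=["tag_seq", "count", "match_class", "gene_id", "strand",
                 "excluded_multi_gene", "n_genes"],
    )

    summary = MappingSummary(stage=clean.stage)
    mapped = assignments[assignments.match_class != "unknown"]
    uniq = assignments[assignments.n_genes == 1]
    multi = assignments[assignments.excluded_multi_gene]
    unknown = assignments[assignments.match_class == "unknown"]
    for name, sub in (
        ("all_mapping", mapped),
        ("exact", assignments[assignments.match_class == "exact"]),
        ("one_mismatch", assignments[assignments.match_class == "one_mismatch"]),
        ("unambiguous_mapping", uniq),
        ("excluded_multi_gene", multi),
        ("unknown", unknown),
        ("clean", assignments),
    ):
        summary.classes[name] = {"distinct": len(sub), "total": int(sub["count"].sum())}
    summary.sense_distinct = int((uniq.strand == "sense").sum())
    summary.antisense_distinct = int((uniq.strand == "antisense").sum())
    summary.sense_genes = uniq.loc[uniq.strand == "sense", "gene_id"].nunique()
    summary.antisense_genes = uniq.loc[uniq.strand == "antisense", "gene_id"].nunique()
    return assignments, summary


@dataclass
class ExpressionTable:
    """Gene x stage unambiguous-tag counts and TPM."""

    counts: pd.DataFrame  # index gene_id, one column per stage
    tpm: pd.DataFrame
    clean_totals: dict[str, int]
    n_reference_genes: int

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)

    def detected(self, stage: str, min_tags: int = 1) -> pd.Series:
        return self.counts[stage] >= min_tags


def quantify(
    assignments_per_stage: Mapping[str, pd.DataFrame],
    clean_libs: Mapping[str, TagLibrary],
    gene_ids: Sequence[str],
    n_reference_genes: int | None = None,
) -> ExpressionTable:
    """Sum uniquely assigned tag copies per gene and normalise to TPM.

    Sense and antisense assignments are pooled into the gene's count (per-
    strand tallies live in the assignment table); TPM uses each stage's clean
    total as denominator.
    """
    gene_index = pd.Index(sorted(gene_ids), name="gene_id")
    counts = pd.DataFrame(0, index=gene_index, columns=list(assignments_per_stage))
    totals: dict[str, int] = {}
    for stage, asg in assignments_per_stage.items():
        total = clean_libs[stage].total
        if total == 0:
            raise ValueError(f"stage {stage!r} has zero clean tags")
        totals[stage] = total
        uniq = asg[asg.n_genes == 1]
        per_gene = uniq.groupby("gene_id")["count"].sum()
        counts.loc[per_gene.index, stage] = per_gene.astype(int)
    tpm = counts.div(pd.Series(totals)) * 1e6
    return ExpressionTable(counts, tpm,
                           totals,
                           n_reference_genes if n_reference_genes is not None else len(gene_index))


def pct(count: float, denom: float, ndigits: int = 2) -> float:
    """Percentage rounded to ``ndigits`` decimals (half-away-from-zero)."""
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(
        (decimal.Decimal(count) / decimal.Decimal(denom) * 100).quantize(
            q, rounding=decimal.ROUND_HALF_UP
        )
    )


def stage_summary_from_counts(
    detected: Mapping[str, int],
    specific: Mapping[str, int],
    all_three: int,
    at_least_one: int,
    n_reference_genes: int,
) -> pd.DataFrame:
    """Expressed/specific gene report with the conventional denominators.

    Detection percentages use the reference-gene count as denominator;
    stage-specific percentages use the respective stage's detected count.
    All percentages are rounded to 2 decimals.
    """
    rows = []
    for stage, n in detected.items():
        rows.append(("expressed", stage, n, pct(n, n_reference_genes)))
    rows.append(("expressed", "all_three_stages", all_three, pct(all_three, n_reference_genes)))
    rows.append(("expressed", "at_least_one_stage", at_least_one, pct(at_least_one, n_reference_genes)))
    for stage, n in specific.items():
        rows.append(("specific", stage, n, pct(n, detected[stage])))
    return pd.DataFrame(rows, columns=["category", "group", "n_genes", "percentage"])


def classify_stages(
    table: ExpressionTable,
    stages: Sequence[str] = ("MP", "HP", "PT"),
    min_tags: int = 1,
) -> pd.DataFrame:
    """Detection / stage-specificity summary over exactly three stage labels."""
    if sorted(stages) != sorted(table.stages):
        raise ValueError(f"expected stages {list(stages)}, table has {table.stages}")
    det = {s: table.detected(s, min_tags) for s in stages}
    n_det = {s: int(det[s].sum()) for s in stages}
    n_stages_detected = sum(det[s].astype(int) for s in stages)
    specific = {
        s: int((det[s] & (n_stages_detected == 1)).sum()) for s in stages
    }
    all_three = int((n_stages_detected == len(stages)).sum())
    at_least_one = int((n_stages_detected >= 1).sum())
    return stage_summary_from_counts(n_det, specific, all_three, at_least_one,
                                     table.n_reference_genes)


def saturation_curve(
    clean: TagLibrary,
    assignments: pd.DataFrame,
    depths: Sequence[int],
    n_reps: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean distinct tags and distinct detected genes under subsampling.

    Tags are subsampled without replacement (random permutation of the clean
    multiset; each rep's depths are prefixes of one permutation, so both
    curves are non-decreasing in depth within every rep).
    """
    total = clean.total
    depths = sorted(int(d) for d in depths)
    if depths[0] < 1:
        raise ValueError("depths must be >= 1")
    if depths[-1] > total:
        raise ValueError(f"depth {depths[-1]} exceeds clean total {total}")

    tags = list(clean.counts)
    counts = np.array([clean.counts[t] for t in tags])
    gene_of = assignments.set_index("tag_seq")
    gene_of = gene_of[gene_of.n_genes == 1]["gene_id"]
    gene_names = sorted(gene_of.unique())
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    tag_gene = np.array([gene_idx.get(gene_of.get(t, None), -1) for t in tags])

    expanded = np.repeat(np.arange(len(tags)), counts)
    rng = np.random.default_rng(seed)
    tag_curves = np.zeros((n_reps, len(depths)))
    gene_curves = np.zeros((n_reps, len(depths)))
    for r in range(n_reps):
        perm = rng.permutation(expanded)
        _, first = np.unique(perm, return_index=True)  # first position per tag
        tag_first = np.sort(first)
        tag_curves[r] = np.searchsorted(tag_first, depths, side="left")
        # first position at which each gene's first uniquely assigned tag appears
        g = tag_gene[perm]
        pos = np.arange(total)
        gene_first = np.full(len(gene_names), total + 1, dtype=np.int64)
        mask = g >= 0
        np.minimum.at(gene_first, g[mask], pos[mask])
        gene_first = np.sort(gene_first)
        gene_curves[r] = np.searchsorted(gene_first, depths, side="left")
    return pd.DataFrame({
        "depth": depths,
        "mean_distinct_tags": tag_curves.mean(axis=0),
        "mean_detected_genes": gene_curves.mean(axis=0),
    })


def expected_distinct_tags(counts: Sequence[int], depth: int) -> float:
    """Closed-form expected number of distinct tags in a without-replacement
    subsample of size ``depth``: sum_i 1 - C(T-c_i, d)/C(T, d)."""
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=np.int64)
    T = counts.sum()
    d = depth

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    miss = np.where(
        T - counts >= d,
        np.exp(logC(T - counts, d) - logC(T, d)),
        0.0,
    )
    return float(np.sum(1.0 - miss))


def foldchange_distribution(
    table: ExpressionTable,
    stage_a: str,
    stage_b: str,
    pseudo_tpm: float = 0.001,
) -> pd.Series:
    """Fraction of detected genes per fold-change bin (<2, 2-5, >=5 fold).

    The fold change is the larger of the two TPM ratios after adding the
    pseudo-TPM used for log ratios of zero counts; genes detected in neither
    stage are not binned.
    """
    det = table.detected(stage_a) | table.detected(stage_b)
    a = table.tpm.loc[det, stage_a] + pseudo_tpm
    b = table.tpm.loc[det, stage_b] + pseudo_tpm
    ratio = np.maximum(a / b, b / a)
    bins = pd.Series({
        "<2": float((ratio < 2).mean()),
        "2-5": float(((ratio >= 2) & (ratio < 5)).mean()),
        ">=5": float((ratio >= 5).mean()),
    })
    return bins
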