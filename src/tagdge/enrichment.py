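"""Hypergeometric term enrichment of DEG sets against an annotated background.

For a term annotated to K of N background genes, with n annotated DEGs of
which k carry the term, the enrichment p-value is the upper tail

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n),

evaluated term-by-term in log space (log-binomials via lgamma, summed with
fsum after rescaling by the largest term) so small tails keep >= 6
significant digits.  The background N is the set of genes with any
annotation of the ontology, not the whole reference; q-values are BH over
all tested terms of one ontology/comparison; significance is q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, fsum, lgamma
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffexpr import fdr_adjust


@dataclass
class AnnotationMap:
    """term_id -> (name, gene set); background = all annotated genes."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    @property
    def background(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        """Read ``gene_id<TAB>term_id<TAB>term_name`` (header optional)."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if str(df.iloc[0, 0]).lower() == "gene_id":
            df = df.iloc[1:]
        terms: dict[str, tuple[str, set[str]]] = {}
        for gene, term, name in df.itertuples(index=False):
            entry = terms.setdefault(term, (name, set()))
            entry[1].add(gene)
        return cls({t: (nm, frozenset(gs)) for t, (nm, gs) in terms.items()})


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X hypergeometric(population N, successes K, draws n)."""
    if not (0 <= k <= n <= N) or not (0 <= K <= N):
        raise ValueError(f"invalid contingency k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0
    lo = max(k, n - (N - K))  # i below this has n-i > N-K: zero probability
    denom = _log_binom(N, n)
    logs = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - denom
        for i in range(lo, hi + 1)
    ]
    m = max(logs)
    return min(1.0, exp(m) * fsum(exp(v - m) for v in logs))


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float = float("nan")
    significant: bool = False


def enrich(
    deg_genes: Iterable[str],
    annotations: AnnotationMap,
    q_threshold: float = 0.05,
    include_empty_terms: bool = False,
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every term against a DEG set; one row per term, sorted by p.

    ``n`` is the number of DEGs carrying any annotation (intersection with
    the background); q-values are BH over all tested terms.  Pass
    ``background`` to override the default all-annotated-genes universe.
    """
    deg_genes = set(deg_genes)
    if not deg_genes:
        raise ValueError("empty DEG set")
    bg = frozenset(background) if background is not None else annotations.background
    if not bg:
        raise ValueError("empty annotation background")
    N = len(bg)
    annotated_degs = deg_genes & bg
    n = len(annotated_degs)

    rows = []
    for term_id, (name, genes) in annotations.terms.items():
        genes = genes & bg
        k = len(annotated_degs & genes)
        if k == 0 and not include_empty_terms:
            continue
        K = len(genes)
        p = hypergeom_upper_tail(k, n, K, N)
        rows.append((term_id, name, k, n, K, N,
                     round(100.0 * k / n, 2) if n else 0.0,
                     round(100.0 * K / N, 2), p))
    out = pd.DataFrame(rows, columns=[
        "term_id", "term_name", "k", "n", "K", "N", "k_pct", "K_pct", "p"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = fdr_adjust(out["p"].to_numpy(), "BH")
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


def functional_category_tally(
    deg_sets: Mapping[str, Iterable[str]],
    category_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Count DEGs per functional category per direction series.

    ``deg_sets`` maps a series label (e.g. "MPvsHP_up") to its gene set;
    ``category_map`` maps gene -> categories.  A multi-label gene counts
    once per category, so per-series percentages may exceed 100.
    """
    rows = []
    for series, genes in deg_sets.items():
        genes = set(genes)
        n_series = len(genes)
        tally: dict[str, int] = {}
        for g in genes:
            for cat in category_map.get(g, ()):
                tally[cat] = tally.get(cat, 0) + 1
        for cat in sorted(tally):
            rows.append((series, cat, tally[cat],
                         round(100.0 * tally[cat] / n_series, 2) if n_series else 0.0))
    return pd.DataFrame(rows, columns=["series", "category", "n_genes", "pct_of_series"])
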