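"""Differential expression for tag counts: the Audic-Claverie exact test.

For a feature with x tags among N1 clean tags in one library and y among N2
in another, the conditional law of y given x under a common underlying rate
is

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

which is negative binomial with x+1 successes and success probability
N1/(N1+N2); tails are therefore evaluated through the regularized incomplete
beta function rather than term-by-term summation, which keeps them exact in
log space up to library sizes of 1e6 and beyond.  The two-sided p-value
doubles the smaller tail (capped at 1).  FDR control is Benjamini-Hochberg
step-up by default, Benjamini-Yekutieli optionally.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, log1p
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mapping import ExpressionTable, pct

#: thresholds used to call a gene differentially expressed
DEFAULT_THRESHOLDS = {"q_max": 0.001, "p_max": 0.0005, "min_abs_log2_ratio": 1.0}
#: pseudo-TPM added to both sides of the log2 ratio so stage-exclusive genes
#: get large finite ratios; the significance test itself uses raw counts
PSEUDO_TPM = 0.001


def _check_counts(x: int, y: int, n1: int, n2: int) -> None:
    if x < 0 or y < 0:
        raise ValueError(f"negative tag count: x={x}, y={y}")
    if n1 < 1 or n2 < 1:
        raise ValueError(f"library totals must be >= 1: N1={n1}, N2={n2}")


def ac_probability(x: int, y: int, n1: int, n2: int) -> float:
    """Conditional probability p(y | x) of the Audic-Claverie model."""
    _check_counts(x, y, n1, n2)
    r = log(n2) - log(n1)
    logp = (
        y * r
        + lgamma(x + y + 1)
        - lgamma(x + 1)
        - lgamma(y + 1)
        - (x + y + 1) * log1p(n2 / n1)
    )
    return float(np.exp(logp))


def ac_two_sided_p(x, y, n1: int, n2: int):
    """Two-sided Audic-Claverie p-value (vectorised over x, y).

    p = min(1, 2 * min(P[Y <= y | x], P[Y >= y | x])); the distribution of
    Y | x is nbinom(x+1, N1/(N1+N2)), so both tails come from its CDF/SF.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative tag count")
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be >= 1")
    prob = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, prob)
    upper = stats.nbinom.sf(y - 1, x + 1, prob)  # P[Y >= y]
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if p.ndim == 0 else p


def fdr_adjust(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Step-up adjusted q-values, Benjamini-Hochberg or Benjamini-Yekutieli."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    smethod = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if smethod is None:
        raise ValueError(f"unknown FDR method {method!r} (use BH or BY)")
    return multipletests(p, method=smethod)[1]


@dataclass
class DEGSummary:
    comparison: str
    n_tested: int
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float


def deg_summary_from_counts(comparison: str, n_up: int, n_down: int,
                            n_expressed: int, n_tested: int | None = None) -> DEGSummary:
    """Up/down tallies as percentages of the total-expressed-gene denominator,
    rounded to 2 decimals."""
    return DEGSummary(
        comparison=comparison,
        n_tested=n_tested if n_tested is not None else n_expressed,
        n_up=n_up,
        n_down=n_down,
        pct_up=pct(n_up, n_expressed),
        pct_down=pct(n_down, n_expressed),
    )


def call_degs(
    table: ExpressionTable,
    stage_a: str,
    stage_b: str,
    thresholds: Mapping[str, float] | None = None,
    fdr_method: str = "BH",
    n_expressed_denominator: int | None = None,
    two_sided: bool = True,
) -> tuple[pd.DataFrame, DEGSummary]:
    """Call DEGs for the stage_a -> stage_b transition.

    Genes detected in either stage are tested (zero-in-both genes carry no
    contrast); FDR is computed across all tested genes of the comparison.
    ``call`` is up when the gene is higher in the later stage (stage_b) and
    the q / p / |log2 ratio| thresholds all hold, symmetric for down.
    """
    for s in (stage_a, stage_b):
        if s not in table.stages:
            raise ValueError(f"unknown stage label {s!r}; table has {table.stages}")
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    tested = table.counts.index[(table.counts[stage_a] > 0) | (table.counts[stage_b] > 0)]
    x = table.counts.loc[tested, stage_a].to_numpy()
    y = table.counts.loc[tested, stage_b].to_numpy()
    n1 = table.clean_totals[stage_a]
    n2 = table.clean_totals[stage_b]
    tpm1 = table.tpm.loc[tested, stage_a].to_numpy()
    tpm2 = table.tpm.loc[tested, stage_b].to_numpy()
    log2_ratio = np.log2((tpm2 + PSEUDO_TPM) / (tpm1 + PSEUDO_TPM))

    if two_sided:
        p = ac_two_sided_p(x, y, n1, n2)
    else:
        prob = n1 / (n1 + n2)
        p = np.minimum(stats.nbinom.cdf(y, x + 1, prob),
                       stats.nbinom.sf(y - 1, x + 1, prob))
    q = fdr_adjust(p, fdr_method)

    significant = (q <= th["q_max"]) & (p < th["p_max"])
    call = np.where(significant & (log2_ratio >= th["min_abs_log2_ratio"]), "up",
                    np.where(significant & (log2_ratio <= -th["min_abs_log2_ratio"]),
                             "down", "unchanged"))
    de = pd.DataFrame({
        "gene_id": tested,
        "comparison": f"{stage_a}vs{stage_b}",
        "x": x, "y": y, "tpm1": tpm1, "tpm2": tpm2,
        "log2_ratio": log2_ratio, "p": p, "q": q, "call": call,
    }).set_index("gene_id")

    denom = (n_expressed_denominator if n_expressed_denominator is not None
             else int((table.counts.sum(axis=1) > 0).sum()))
    summary = deg_summary_from_counts(
        f"{stage_a}vs{stage_b}",
        int((call == "up").sum()), int((call == "down").sum()),
        denom, n_tested=len(tested),
    )
    return de, summary
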