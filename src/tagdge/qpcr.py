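"""Relative qRT-PCR quantification (2^-ddCt) and concordance with DGE ratios.

Each gene's Ct is normalised to the mean of the reference-gene mean Cts
within a sample (dCt), then to a calibrator sample (ddCt); the relative
expression is 2^-ddCt under the perfect-doubling assumption.  Replicate
standard errors are propagated through the linear combination of mean Cts.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import copysign, sqrt
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class CtTable:
    """Long-format Ct measurements plus the reference (internal-control) genes."""

    data: pd.DataFrame  # columns: sample, gene_id, replicate, ct
    reference_genes: list[str]

    def __post_init__(self) -> None:
        required = {"sample", "gene_id", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if (self.data.ct <= 0).any():
            raise ValueError("Ct values must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path, reference_genes: Sequence[str]) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), list(reference_genes))


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    m = float(values.mean())
    if len(values) < 2:
        return m, 0.0
    return m, float(values.std(ddof=1) / sqrt(len(values)))


def ddct_ratio(
    ct: CtTable,
    target_gene: str,
    calibrator: str,
    test: str,
) -> dict:
    """2^-ddCt relative expression of ``target_gene`` in test vs calibrator.

    dCt(sample) = mean Ct(target) - mean over reference genes of their mean
    Cts; ratio = 2^-(dCt_test - dCt_calibrator).  Returns the ratio, its
    log2 (= -ddCt) and a propagated SE on the log2 scale.
    """
    out: dict[str, tuple[float, float]] = {}
    for sample in (calibrator, test):
        sub = ct.data[ct.data["sample"] == sample]
        tgt = sub[sub.gene_id == target_gene]["ct"].to_numpy()
        if len(tgt) == 0:
            raise ValueError(f"target {target_gene!r} not measured in sample {sample!r}")
        t_mean, t_se = _mean_se(tgt)
        ref_means, ref_vars = [], []
        for ref in ct.reference_genes:
            r = sub[sub.gene_id == ref]["ct"].to_numpy()
            if len(r) == 0:
                raise ValueError(f"reference {ref!r} missing in sample {sample!r}")
            m, se = _mean_se(r)
            ref_means.append(m)
            ref_vars.append(se**2)
        n_ref = len(ref_means)
        dct = t_mean - float(np.mean(ref_means))
        var = t_se**2 + float(np.sum(ref_vars)) / n_ref**2
        out[sample] = (dct, var)

    ddct = out[test][0] - out[calibrator][0]
    se_log2 = sqrt(out[test][1] + out[calibrator][1])
    return {
        "gene_id": target_gene,
        "ratio": 2.0**-ddct,
        "log2_ratio": -ddct,
        "se_log2": se_log2,
        "ddct": ddct,
    }


def ddct_table(
    ct: CtTable, target_genes: Iterable[str], calibrator: str, test: str
) -> pd.DataFrame:
    rows = [ddct_ratio(ct, g, calibrator, test) for g in target_genes]
    return pd.DataFrame(rows).set_index("gene_id")


def concordance(
    qpcr_log2: pd.Series,
    dge_log2: pd.Series,
    genes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-gene sign agreement between qPCR and DGE log2 ratios.

    Both series must be oriented the same way (same test/calibrator order).
    Returns the per-gene table and the overall agreement fraction.
    """
    genes = list(genes) if genes is not None else sorted(
        set(qpcr_log2.index) & set(dge_log2.index)
    )
    rows = []
    for g in genes:
        a, b = float(qpcr_log2[g]), float(dge_log2[g])
        rows.append((g, a, b, copysign(1, a) == copysign(1, b)))
    df = pd.DataFrame(rows, columns=["gene_id", "qpcr_log2", "dge_log2", "agree"])
    frac = float(df.agree.mean()) if len(df) else float("nan")
    return df.set_index("gene_id"), frac
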