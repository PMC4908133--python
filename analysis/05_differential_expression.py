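#!/usr/bin/env python
"""Call differentially expressed genes for germination and tube growth.

Runs the Audic-Claverie exact test per gene for the MP->HP (germination)
and HP->PT (tube growth) transitions, with BH FDR control and the
FDR <= 0.001 / p < 0.0005 / |log2 ratio| >= 1 thresholds, then scores the
calls against the simulator's ground truth.  Writes de_<comparison>.tsv and
de_summaries.json under results/.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from tagdge import diffexpr, mapping

BASE = Path(__file__).resolve().parents[1] / "results"
COMPARISONS = {"MPvsHP": ("MP", "HP"), "HPvsPT": ("HP", "PT")}


def load_expression() -> mapping.ExpressionTable:
    df = pd.read_csv(BASE / "expression.tsv", sep="\t", index_col=0)
    stages = sorted({c.split("_", 1)[1] for c in df.columns})
    counts = df[[f"count_{s}" for s in stages]]
    counts.columns = stages
    totals = {s: int(counts[s].sum()) for s in stages}
    return mapping.ExpressionTable(counts, counts.div(pd.Series(totals)) * 1e6,
                                   totals, len(df))


def main() -> None:
    table = load_expression()
    summaries = {}
    for label, (a, b) in COMPARISONS.items():
        de, summary = diffexpr.call_degs(table, a, b)
        de.to_csv(BASE / f"de_{label}.tsv", sep="\t")
        summaries[label] = dataclasses.asdict(summary)
        print(f"{label}: {summary.n_up} up / {summary.n_down} down "
              f"({summary.pct_up}% / {summary.pct_down}% of expressed genes)")

        truth = pd.read_csv(BASE / "sim" / f"truth_de_{label}.tsv", sep="\t",
                            index_col=0)
        called = set(de.index[de.call != "unchanged"])
        truly = set(truth.index[truth.is_de])
        planted = set(truth.index[truth.planted])
        fdp = len(called - truly) / max(len(called), 1)
        sens = len(called & planted) / max(len(planted), 1)
        print(f"  vs ground truth: FDP {fdp:.3f}, planted-DEG sensitivity {sens:.2f}")
    (BASE / "de_summaries.json").write_text(json.dumps(summaries, indent=2) + "\n")


if __name__ == "__main__":
    main()
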