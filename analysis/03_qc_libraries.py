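#!/usr/bin/env python
"""Filter the raw tag libraries and account for every removed read.

For each stage, removes N-containing tags, adaptor tags and copy-number-1
singletons (in that order), checks the ledger conservation identities, and
tabulates the clean copy-number spectrum.  Writes per-stage clean TSVs,
ledger JSON and spectrum TSVs under results/.
"""

import json
from pathlib import Path

from tagdge import qc

BASE = Path(__file__).resolve().parents[1] / "results"
STAGES = ("MP", "HP", "PT")


def main() -> None:
    ledgers = {}
    for stage in STAGES:
        raw = qc.read_tag_tsv(BASE / "sim" / f"{stage}_raw.tsv", stage)
        clean, ledger = qc.filter_raw_tags(raw)
        qc.write_tag_tsv(clean, BASE / f"{stage}_clean.tsv")
        qc.copy_spectrum(clean).to_csv(BASE / f"{stage}_spectrum.tsv",
                                       sep="\t", index=False)
        ledgers[stage] = ledger.as_dict()
        low = qc.low_copy_fraction(clean)
        print(f"{stage}: raw {raw.distinct:,}/{raw.total:,} -> clean "
              f"{clean.distinct:,}/{clean.total:,} "
              f"(N {ledger.tags_containing_N.total:,}, singletons "
              f"{ledger.copy_lt_2.total:,}); {low:.0%} of distinct clean tags "
              f"under 20 copies")
    (BASE / "qc_ledgers.json").write_text(json.dumps(ledgers, indent=2) + "\n")
    print(f"ledgers -> {BASE / 'qc_ledgers.json'}")


if __name__ == "__main__":
    main()
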