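"""Virtual-tag reference database for NlaIII-anchored DGE profiling.

A DGE tag is the 21-mer starting at a CATG restriction site: the 4-nt anchor
plus the 17 nt immediately downstream.  The reference database enumerates
every such tag on both strands of every transcript ("all possible" sites, not
only the 3'-most one actually produced by the library chemistry), records its
origin, and classifies each tag sequence as ambiguous when it occurs in two
or more distinct genes.  Ambiguous tags are later excluded from gene-level
quantification.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

ANCHOR = "CATG"
TAG_LEN = 21
DNA_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript: unique gene id and an uppercase DNA sequence."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")
        bad = set(self.sequence) - DNA_BASES
        if bad:
            raise ValueError(
                f"non-DNA characters {sorted(bad)} in record {self.gene_id!r}"
            )


@dataclass(frozen=True)
class VirtualTag:
    """A single CATG+17nt tag occurrence in the reference.

    ``offset`` is the 0-based position of the C of CATG on the coordinate
    system of the stated strand (sense coordinates for sense tags, reverse-
    complement coordinates for antisense tags), so the tag is always
    recoverable by slicing that strand's sequence.
    """

    tag_seq: str
    gene_id: str
    strand: str  # "sense" | "antisense"
    offset: int
    ambiguous: bool = False


@dataclass
class ReferenceTagDB:
    """All virtual tags of a transcript set plus summary counts."""

    tags: list[VirtualTag]
    n_genes_total: int
    n_genes_with_catg: int
    n_tags_total: int
    n_tags_unambiguous: int
    n_tags_with_N_skipped: int = 0
    #: tag_seq -> sorted tuple of distinct gene_ids carrying it (either strand)
    tag_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: tag_seq -> list of (gene_id, strand) occurrences
    tag_hits: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts from a (possibly gzipped) FASTA file, uppercasing."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate gene_id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(TranscriptRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"empty reference: no FASTA records in {path}")
    return records


def _scan_strand(seq: str) -> Iterable[tuple[int, str]]:
    """Yield (offset, 21-mer) for every CATG site with >=17 downstream bases."""
    start = seq.find(ANCHOR)
    while start != -1:
        if start + TAG_LEN <= len(seq):
            yield start, seq[start : start + TAG_LEN]
        start = seq.find(ANCHOR, start + 1)


def scan_catg_tags(transcripts: Iterable[TranscriptRecord]) -> ReferenceTagDB:
    """Enumerate every CATG+17nt tag of every transcript on both strands.

    Tags whose 21-mer contains N are skipped (they can never match a clean
    tag) but tallied in ``n_tags_with_N_skipped``.  Ambiguity is computed
    over the union of both strands of all genes, at the level of distinct
    gene ids: a tag repeated within one gene remains unambiguous.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("empty reference")
    seen_ids = [t.gene_id for t in transcripts]
    if len(set(seen_ids)) != len(seen_ids):
        raise ValueError("duplicate gene_id in reference set")

    raw: list[VirtualTag] = []
    tag_hits: dict[str, list[tuple[str, str]]] = {}
    n_skipped = 0
    n_with_catg = 0
    for rec in transcripts:
        gene_has_tag = False
        for strand, seq in (("sense", rec.sequence),
                            ("antisense", reverse_complement(rec.sequence))):
            for offset, mer in _scan_strand(seq):
                if strand == "sense":
                    gene_has_tag = True
                if "N" in mer:
                    n_skipped += 1
                    continue
                raw.append(VirtualTag(mer, rec.gene_id, strand, offset))
                tag_hits.setdefault(mer, []).append((rec.gene_id, strand))
        if gene_has_tag:
            n_with_catg += 1

    tag_genes = {
        mer: tuple(sorted({g for g, _ in hits})) for mer, hits in tag_hits.items()
    }
    tags = [
        VirtualTag(t.tag_seq, t.gene_id, t.strand, t.offset,
                   ambiguous=len(tag_genes[t.tag_seq]) >= 2)
        for t in raw
    ]
    n_unamb = sum(1 for t in tags if not t.ambiguous)
    return ReferenceTagDB(
        tags=tags,
        n_genes_total=len(transcripts),
        n_genes_with_catg=n_with_catg,
        n_tags_total=len(tags),
        n_tags_unambiguous=n_unamb,
        n_tags_with_N_skipped=n_skipped,
        tag_genes=tag_genes,
        tag_hits=tag_hits,
    )


def reference_summary(db: ReferenceTagDB) -> dict:
    """Headline ratios of the reference database, denominators spelled out.

    Percentages are rounded to 1 decimal.  Both the unambiguous/total-tags
    ratio and the raw counts are reported so either convention for an
    "unambiguous tag percentage" can be reconstructed.
    """
    if db.n_tags_total == 0:
        raise ValueError("reference database holds no tags")
    return {
        "n_genes_total": db.n_genes_total,
        "n_genes_with_catg": db.n_genes_with_catg,
        "pct_genes_with_catg": round(100.0 * db.n_genes_with_catg / db.n_genes_total, 1),
        "n_tags_total": db.n_tags_total,
        "n_tags_unambiguous": db.n_tags_unambiguous,
        "pct_tags_unambiguous": round(100.0 * db.n_tags_unambiguous / db.n_tags_total, 1),
        "n_tags_with_N_skipped": db.n_tags_with_N_skipped,
        "denominators": {
            "pct_genes_with_catg": "n_genes_total",
            "pct_tags_unambiguous": "n_tags_total",
        },
    }


def write_refdb(db: ReferenceTagDB, tsv_path: str | Path) -> None:
    """Serialize as TSV (tag_seq, gene_id, strand, offset, ambiguous) + JSON sidecar."""
    tsv_path = Path(tsv_path)
    df = pd.DataFrame(
        [(t.tag_seq, t.gene_id, t.strand, t.offset, t.ambiguous) for t in db.tags],
        columns=["tag_seq", "gene_id", "strand", "offset", "ambiguous"],
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    sidecar = tsv_path.with_suffix(tsv_path.suffix + ".summary.json")
    sidecar.write_text(json.dumps(reference_summary(db), indent=2) + "\n")


def load_refdb(tsv_path: str | Path, n_genes_total: int | None = None) -> ReferenceTagDB:
    """Rebuild a ReferenceTagDB from its TSV serialization."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"tag_seq": str, "gene_id": str})
    tag_hits: dict[str, list[tuple[str, str]]] = {}
    tags = []
    for row in df.itertuples(index=False):
        tags.append(VirtualTag(row.tag_seq, row.gene_id, row.strand,
                               int(row.offset), bool(row.ambiguous)))
        tag_hits.setdefault(row.tag_seq, []).append((row.gene_id, row.strand))
    tag_genes = {m: tuple(sorted({g for g, _ in h})) for m, h in tag_hits.items()}
    genes = {t.gene_id for t in tags}
    return ReferenceTagDB(
        tags=tags,
        n_genes_total=n_genes_total if n_genes_total is not None else len(genes),
        n_genes_with_catg=len({t.gene_id for t in tags if t.strand == "sense"}),
        n_tags_total=len(tags),
        n_tags_unambiguous=sum(1 for t in tags if not t.ambiguous),
        tag_genes=tag_genes,
        tag_hits=tag_hits,
    )
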