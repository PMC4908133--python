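"""Synthetic DGE study generator with full ground truth.

Emulates a three-stage (MP/HP/PT: mature pollen, hydrated pollen, pollen
tube) NlaIII tag-profiling experiment: a transcriptome in which a set
fraction of genes carry a usable CATG site, stage expression profiles with
stage-specific and differentially expressed gene subsets, raw tag libraries
with sequencing errors, N-containing reads, adaptor reads and singleton
noise, term annotations with planted enrichment, and qRT-PCR Ct tables —
every artefact paired with the truth it was generated from, so each pipeline
stage can be scored for recovery.

The library chemistry is mirrored deliberately: each expressed transcript
emits its 3'-most CATG+17nt tag (the fragment the anchoring enzyme leaves on
the bead), while the reference database downstream indexes *all* CATG sites.
Sampling is multinomial per library; with one pooled library per stage there
is no replicate structure from which overdispersion could be identified, so
none is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationMap
from .qc import TagLibrary
from .qpcr import CtTable
from .reference import ANCHOR, TAG_LEN, TranscriptRecord, reverse_complement

STAGES = ("MP", "HP", "PT")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults are scaled-down analogues of the pollen study design: three
    stage libraries, ~90% of genes with a CATG site, stage-specific
    fractions of roughly 17/5/10% (MP/HP/PT), ~10% of genes differentially
    expressed per transition with 4-fold planted effects, 1.2% N-reads, no
    adaptor reads, a singleton-noise floor, and a minority antisense-
    transcribed fraction.
    """

    n_genes: int = 1000
    min_len: int = 300
    max_len: int = 1500
    catg_fraction: float = 0.90
    frac_specific: dict = field(
        default_factory=lambda: {"MP": 0.17, "HP": 0.05, "PT": 0.10}
    )
    frac_de: float = 0.10          # DE genes per transition, as fraction of n_genes
    frac_de_both: float = 0.03     # subset of genes DE in both transitions
    log2_effect: float = 2.0       # planted |log2 ratio| (4-fold)
    de_min_base_tpm: float = 100.0
    lognormal_sigma: float = 1.2
    depth: int = 500_000
    error_rate: float = 0.005      # per base
    n_read_rate: float = 0.012
    adaptor_rate: float = 0.0
    adaptor_seq: str = "CATGCGGCCGCTCGAGTCGAC"  # 21 nt, NotI/XhoI/SalI-like filler
    singleton_noise_rate: float = 0.02
    antisense_gene_fraction: float = 0.24  # genes with antisense transcription
    antisense_fraction: float = 0.4        # per-read antisense prob in those genes
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("catg_fraction", "frac_de", "frac_de_both", "error_rate",
                     "n_read_rate", "adaptor_rate", "singleton_noise_rate",
                     "antisense_gene_fraction", "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.min_len < TAG_LEN + 4 or self.max_len < self.min_len:
            raise ValueError("infeasible length range for CATG+17nt tags")
        if len(self.adaptor_seq) != TAG_LEN:
            raise ValueError("adaptor_seq must be 21 nt")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    tpm: pd.DataFrame                      # genes x stages, columns sum to 1e6
    specific: dict[str, set[str]]          # stage -> stage-exclusive genes
    #: comparison -> per-gene (planted, is_de, true_log2); ``planted`` marks the
    #: shared genes given an explicit effect, ``is_de`` every gene whose true
    #: ratio between the two stages reaches |log2| >= 1 (stage-exclusive genes
    #: have infinite ratios and are truly differential too)
    de: dict[str, pd.DataFrame]
    antisense_genes: set[str] = field(default_factory=set)
    planted_terms: dict[str, str] = field(default_factory=dict)
    qpcr_true_log2: pd.Series | None = None
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _has_valid_site(seq: str) -> bool:
    pos = seq.find(ANCHOR)
    while pos != -1:
        if pos + TAG_LEN <= len(seq):
            return True
        pos = seq.find(ANCHOR, pos + 1)
    return False


def _scrub_catg(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mutate sense-strand CATG occurrences away until none remain."""
    s = seq.tobytes().decode()
    while ANCHOR in s:
        pos = s.find(ANCHOR)
        repl = "ACGT"[rng.integers(0, 4)]
        while repl == "G":
            repl = "ACGT"[rng.integers(0, 4)]
        s = s[: pos + 3] + repl + s[pos + 4 :]
    return np.frombuffer(s.encode(), dtype=np.uint8).copy()


def simulate_transcriptome(config: SimulationConfig,
                           rng: np.random.Generator | None = None) -> list[TranscriptRecord]:
    """Random transcripts with exactly floor(catg_fraction * n) usable genes.

    "Usable" means >= 1 sense CATG with >= 17 downstream bases.  Designated
    carrier genes get a site planted if chance did not provide one;
    non-carriers have every sense CATG mutated away.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_with = int(np.floor(config.catg_fraction * config.n_genes))
    carrier = np.zeros(config.n_genes, dtype=bool)
    carrier[rng.permutation(config.n_genes)[:n_with]] = True

    anchor = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)
    records = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        length = int(rng.integers(config.min_len, config.max_len + 1))
        seq = _random_seq(rng, length)
        if carrier[i]:
            if not _has_valid_site(seq.tobytes().decode()):
                pos = int(rng.integers(0, length - TAG_LEN + 1))
                seq[pos : pos + 4] = anchor
        else:
            seq = _scrub_catg(seq, rng)
        records.append(TranscriptRecord(f"g{i:0{width}d}", seq.tobytes().decode()))
    return records


def write_fasta(records: Sequence[TranscriptRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def simulate_stage_profiles(config: SimulationConfig,
                            rng: np.random.Generator | None = None) -> GroundTruth:
    """TPM matrix for MP/HP/PT with planted stage-specific and DE genes.

    Genes are partitioned deterministically under the seed into stage-
    exclusive sets, shared DE sets per transition (with a both-transitions
    subset, so the three-stage DEG intersection used for clustering is non-
    empty), and a constitutive remainder.  Base abundances are lognormal;
    DE genes get a base-expression floor so planted effects are identifiable
    at the configured depth.  Each stage column is renormalised to 1e6, and
    the recorded true log2 ratios are the post-normalisation ones.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_genes
    width = len(str(n))
    genes = [f"g{i:0{width}d}" for i in range(n)]
    order = rng.permutation(n)

    counts = {s: int(np.floor(config.frac_specific[s] * n)) for s in STAGES}
    n_both = int(np.floor(config.frac_de_both * n))
    n_de = int(np.floor(config.frac_de * n))
    if n_de < n_both:
        raise ValueError("frac_de_both cannot exceed frac_de")

    cursor = 0
    specific: dict[str, set[str]] = {}
    spec_idx: dict[str, np.ndarray] = {}
    for s in STAGES:
        idx = order[cursor : cursor + counts[s]]
        cursor += counts[s]
        specific[s] = {genes[i] for i in idx}
        spec_idx[s] = idx
    both_idx = order[cursor : cursor + n_both]
    cursor += n_both
    pg_only = order[cursor : cursor + (n_de - n_both)]
    cursor += n_de - n_both
    ptg_only = order[cursor : cursor + (n_de - n_both)]
    cursor += n_de - n_both
    if cursor > n:
        raise ValueError("specific + DE fractions exceed the gene count")
    de_idx = {"MPvsHP": np.concatenate([both_idx, pg_only]),
              "HPvsPT": np.concatenate([both_idx, ptg_only])}

    base = np.exp(rng.normal(np.log(50.0), config.lognormal_sigma, size=n))
    de_all = np.unique(np.concatenate(list(de_idx.values())))
    base[de_all] = np.maximum(base[de_all], config.de_min_base_tpm)

    expr = np.tile(base[:, None], (1, 3)).astype(float)  # columns MP, HP, PT
    col = {s: j for j, s in enumerate(STAGES)}
    for s in STAGES:
        others = [c for c in range(3) if c != col[s]]
        expr[spec_idx[s][:, None], others] = 0.0

    sign = {cmp: rng.choice([-1.0, 1.0], size=len(de_idx[cmp])) for cmp in de_idx}
    # MP -> HP effect applied to HP and carried into PT; HP -> PT applied to PT
    expr[de_idx["MPvsHP"], col["HP"]] *= 2.0 ** (config.log2_effect * sign["MPvsHP"])
    expr[de_idx["MPvsHP"], col["PT"]] = expr[de_idx["MPvsHP"], col["HP"]]
    expr[de_idx["HPvsPT"], col["PT"]] *= 2.0 ** (config.log2_effect * sign["HPvsPT"])

    expr = expr / expr.sum(axis=0, keepdims=True) * 1e6
    tpm = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=list(STAGES))

    de_truth = {}
    for cmp, (a, b) in {"MPvsHP": ("MP", "HP"), "HPvsPT": ("HP", "PT")}.items():
        planted = np.zeros(n, dtype=bool)
        planted[de_idx[cmp]] = True
        with np.errstate(divide="ignore", invalid="ignore"):
            true_log2 = np.log2(expr[:, col[b]] / expr[:, col[a]])
        is_de = np.abs(true_log2) >= 1.0  # inf for stage-exclusive, nan -> False
        de_truth[cmp] = pd.DataFrame(
            {"planted": planted, "is_de": is_de, "true_log2": true_log2},
            index=tpm.index,
        )
    n_anti = int(np.floor(config.antisense_gene_fraction * n))
    antisense_genes = {genes[i] for i in rng.permutation(n)[:n_anti]}
    return GroundTruth(tpm=tpm, specific=specific, de=de_truth,
                       antisense_genes=antisense_genes, seed=config.seed)


def canonical_tags(transcripts: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """3'-most CATG+17nt tag per gene on each strand (the tag the chemistry
    actually produces).  Genes without a valid site on a strand get ``None``."""
    rows = []
    for rec in transcripts:
        tags = {}
        for strand, seq in (("sense", rec.sequence),
                            ("antisense", reverse_complement(rec.sequence))):
            best = None
            pos = seq.find(ANCHOR)
            while pos != -1:
                if pos + TAG_LEN <= len(seq):
                    best = seq[pos : pos + TAG_LEN]
                pos = seq.find(ANCHOR, pos + 1)
            tags[strand] = best
        rows.append((rec.gene_id, tags["sense"], tags["antisense"]))
    return pd.DataFrame(rows, columns=["gene_id", "sense_tag", "antisense_tag"]
                        ).set_index("gene_id")


def _apply_errors(tag_matrix: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitution errors on a (reads x 21) uint8 matrix."""
    if rate <= 0:
        return tag_matrix
    mask = rng.random(tag_matrix.shape) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    lut = np.full(256, 255, dtype=np.uint8)
    for j, b in enumerate(_BASES):
        lut[b] = j
    codes = lut[tag_matrix[mask]]
    tag_matrix[mask] = _BASES[(codes + shift) % 4]
    return tag_matrix


def simulate_tag_library(
    transcripts: Sequence[TranscriptRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    stage: str,
    rng: np.random.Generator | None = None,
    depth: int | None = None,
) -> tuple[TagLibrary, pd.DataFrame]:
    """One stage's raw tag multiset plus per-read provenance.

    Reads are drawn multinomially over expressed genes proportional to true
    TPM; each signal read carries the gene's 3'-most sense tag, or — for the
    minority of antisense-transcribed genes — its antisense tag with
    probability ``antisense_fraction``; per-base errors are applied
    independently.  N-containing reads, adaptor reads and
    unique random singleton noise tags are injected at the configured rates.
    Provenance is aggregated per (tag, class, source gene).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    depth = depth if depth is not None else config.depth
    ctags = canonical_tags(transcripts)
    tpm = truth.tpm[stage]
    expressed = tpm.index[(tpm > 0)]
    usable = [g for g in expressed if ctags.loc[g, "sense_tag"] is not None]
    dropped = sorted(set(expressed) - set(usable))
    p = tpm.loc[usable].to_numpy()
    p = p / p.sum()

    # read classes: signal / N-read / adaptor / noise
    u = rng.random(depth)
    noise_cut = config.singleton_noise_rate
    n_cut = noise_cut + config.n_read_rate
    a_cut = n_cut + config.adaptor_rate
    n_noise = int((u < noise_cut).sum())
    n_nread = int(((u >= noise_cut) & (u < n_cut)).sum())
    n_adapt = int(((u >= n_cut) & (u < a_cut)).sum())
    n_signal = depth - n_noise - n_nread - n_adapt

    gene_pick = rng.choice(len(usable), size=n_signal + n_nread, p=p)
    anti_active = np.array([g in truth.antisense_genes for g in usable])
    anti = anti_active[gene_pick] & (
        rng.random(n_signal + n_nread) < config.antisense_fraction
    )
    sense_arr = np.frombuffer(
        "".join(ctags.loc[g, "sense_tag"] for g in usable).encode(), dtype=np.uint8
    ).reshape(len(usable), TAG_LEN)
    anti_tags = [
        ctags.loc[g, "antisense_tag"] or ctags.loc[g, "sense_tag"] for g in usable
    ]
    anti_arr = np.frombuffer("".join(anti_tags).encode(), dtype=np.uint8
                             ).reshape(len(usable), TAG_LEN)
    reads = np.where(anti[:, None], anti_arr[gene_pick], sense_arr[gene_pick])
    reads = _apply_errors(reads.copy(), config.error_rate, rng)
    # N-reads: signal-shaped reads with one base replaced by N
    if n_nread:
        npos = rng.integers(0, TAG_LEN, size=n_nread)
        reads[n_signal + np.arange(n_nread), npos] = ord("N")

    tag_strings = [r.tobytes().decode() for r in reads]
    classes = ["signal"] * n_signal + ["n_read"] * n_nread
    sources = [usable[i] for i in gene_pick]
    strands = np.where(anti, "antisense", "sense").tolist()

    if n_adapt:
        tag_strings += [config.adaptor_seq] * n_adapt
        classes += ["adaptor"] * n_adapt
        sources += [""] * n_adapt
        strands += ["none"] * n_adapt
    if n_noise:
        noise = _BASES[rng.integers(0, 4, size=(n_noise, TAG_LEN - 4))]
        for row in noise:
            tag_strings.append(ANCHOR + row.tobytes().decode())
        classes += ["noise"] * n_noise
        sources += [""] * n_noise
        strands += ["none"] * n_noise

    prov = (
        pd.DataFrame({"tag_seq": tag_strings, "read_class": classes,
                      "source_gene": sources, "strand": strands})
        .groupby(["tag_seq", "read_class", "source_gene", "strand"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    counts = pd.Series(tag_strings).value_counts()
    lib = TagLibrary(stage, {t: int(c) for t, c in counts.items()})
    if dropped:
        prov.attrs["dropped_genes"] = dropped
    return lib, prov


def simulate_annotations(
    genes: Sequence[str],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_terms: int = 40,
    term_size: tuple[int, int] = (20, 60),
    planted_or: float = 8.0,
) -> AnnotationMap:
    """Term annotations with one planted enriched term per transition.

    Background terms draw genes uniformly; each planted term draws with DE
    genes of its transition weighted ``planted_or``-fold, so the expected
    DEG overlap k is size * OR*d / (OR*d + (G-d)) for d DE genes among G.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = list(genes)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        terms[f"term{t:03d}"] = (f"background term {t}",
                                 frozenset(genes[i] for i in members))
    planted: dict[str, str] = {}
    for cmp, de in truth.de.items():
        tid = f"planted_{cmp}"
        size = int(np.mean(term_size))
        w = np.where(de["is_de"].reindex(genes).to_numpy(), planted_or, 1.0)
        members = rng.choice(len(genes), size=size, replace=False, p=w / w.sum())
        terms[tid] = (f"planted enriched term ({cmp})",
                      frozenset(genes[i] for i in members))
        planted[cmp] = tid
    truth.planted_terms = planted
    return AnnotationMap(terms)


def simulate_qpcr(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_target_genes: int = 13,
    calibrator: str = "MP",
    test: str = "PT",
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    ct_baseline: float = 35.0,
) -> CtTable:
    """Ct tables from true abundances: Ct = baseline - log2(TPM) + noise.

    Targets are drawn from genes expressed in both samples with the largest
    |true log2 ratio| split across both signs; three constant reference
    genes mimic the usual actin / 18S rDNA / GAPDH internal controls.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tpm = truth.tpm
    both = tpm.index[(tpm[calibrator] > 0) & (tpm[test] > 0)]
    lr = np.log2(tpm.loc[both, test] / tpm.loc[both, calibrator])
    up = lr.sort_values(ascending=False).index[: (n_target_genes + 1) // 2]
    down = lr.sort_values().index[: n_target_genes // 2]
    targets = list(up) + list(down)

    refs = {"actin": 18.0, "rDNA18S": 12.0, "GAPDH": 20.0}
    rows = []
    for sample in (calibrator, test):
        for gene in targets:
            true_ct = ct_baseline - np.log2(tpm.loc[gene, sample])
            for rep in range(1, n_replicates + 1):
                rows.append((sample, gene, rep,
                             float(true_ct + rng.normal(0.0, noise_sd))))
        for ref, ct0 in refs.items():
            for rep in range(1, n_replicates + 1):
                rows.append((sample, ref, rep, float(ct0 + rng.normal(0.0, noise_sd))))
    data = pd.DataFrame(rows, columns=["sample", "gene_id", "replicate", "ct"])
    truth.qpcr_true_log2 = lr.loc[targets]
    return CtTable(data, list(refs))


def simulate_study(config: SimulationConfig) -> dict:
    """Full synthetic study bundle: transcriptome, truth, raw libraries per
    stage, annotations and Ct tables, all driven by one seed."""
    rng = np.random.default_rng(config.seed)
    transcripts = simulate_transcriptome(config, rng)
    truth = simulate_stage_profiles(config, rng)
    libraries, provenance = {}, {}
    for stage in STAGES:
        libraries[stage], provenance[stage] = simulate_tag_library(
            transcripts, truth, config, stage, rng
        )
    annotations = simulate_annotations(list(truth.tpm.index), truth, config, rng)
    ct = simulate_qpcr(truth, config, rng)
    return {
        "config": config,
        "transcripts": transcripts,
        "truth": truth,
        "libraries": libraries,
        "provenance": provenance,
        "annotations": annotations,
        "ct": ct,
    }
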