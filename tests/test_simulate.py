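import numpy as np
import pytest

from tagdge import simulate
from tagdge.qc import filter_raw_tags
from tagdge.reference import reverse_complement
from tagdge.simulate import SimulationConfig, simulate_transcriptome

from _oracles import regex_catg_gene_count


def test_catg_carrier_fraction_is_exact():
    cfg = SimulationConfig(n_genes=500, seed=1)
    recs = simulate_transcriptome(cfg)
    seqs = {r.gene_id: r.sequence for r in recs}
    n = regex_catg_gene_count(seqs)
    assert n == int(0.9 * 500)
    assert 435 <= n <= 465


def test_full_catg_fraction_puts_a_site_in_every_gene():
    cfg = SimulationConfig(n_genes=50, catg_fraction=1.0, seed=4)
    seqs = {r.gene_id: r.sequence for r in simulate_transcriptome(cfg)}
    assert regex_catg_gene_count(seqs) == 50


def test_transcriptome_generation_is_deterministic(tmp_path):
    cfg = SimulationConfig(n_genes=40, seed=9)
    a = simulate_transcriptome(cfg)
    b = simulate_transcriptome(cfg)
    assert [(r.gene_id, r.sequence) for r in a] == [(r.gene_id, r.sequence) for r in b]
    pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
    simulate.write_fasta(a, pa)
    simulate.write_fasta(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_infeasible_length_range_rejected():
    with pytest.raises(ValueError, match="length"):
        SimulationConfig(min_len=10, max_len=15)


def test_stage_profiles_structure():
    cfg = SimulationConfig(n_genes=1000, seed=11)
    truth = simulate.simulate_stage_profiles(cfg)
    # stage-exclusive genes: zero TPM outside their stage, exact planted counts
    assert len(truth.specific["MP"]) == 170
    for stage, genes in truth.specific.items():
        others = [s for s in simulate.STAGES if s != stage]
        sub = truth.tpm.loc[sorted(genes)]
        assert (sub[others] == 0).all().all()
        assert (sub[stage] > 0).all()
    # columns each renormalised to one million
    assert truth.tpm.sum(axis=0).to_numpy() == pytest.approx([1e6] * 3, rel=1e-9)
    # planted effects survive renormalisation at |log2| >= 1
    for cmp, de in truth.de.items():
        assert (de.loc[de.planted, "true_log2"].abs() >= 1.0).all()
        assert de.loc[de.planted, "is_de"].all()


def test_zero_de_fractions_give_identical_shared_profiles():
    cfg = SimulationConfig(n_genes=200, frac_de=0.0, frac_de_both=0.0, seed=2)
    truth = simulate.simulate_stage_profiles(cfg)
    shared = truth.tpm.index.difference(
        sorted(set().union(*truth.specific.values())))
    ratios = truth.tpm.loc[shared, "HP"] / truth.tpm.loc[shared, "MP"]
    # shared genes keep identical relative abundance; only the per-stage
    # renormalisation constant differs
    assert ratios.nunique() == 1 or ratios.std() / ratios.mean() < 1e-12


def test_error_free_library_reads_are_reference_sense_tags(small_study):
    cfg = SimulationConfig(n_genes=100, depth=20_000, seed=5, error_rate=0.0,
                           n_read_rate=0.0, singleton_noise_rate=0.0,
                           antisense_gene_fraction=0.0, antisense_fraction=0.0)
    rng = np.random.default_rng(cfg.seed)
    recs = simulate_transcriptome(cfg, rng)
    truth = simulate.simulate_stage_profiles(cfg, rng)
    lib, prov = simulate.simulate_tag_library(recs, truth, cfg, "MP", rng)
    ctags = simulate.canonical_tags(recs)
    sense = set(ctags.sense_tag.dropna())
    assert set(lib.counts) <= sense
    assert (prov.read_class == "signal").all()


def test_per_read_error_fraction_matches_binomial_closed_form():
    cfg = SimulationConfig(n_genes=100, depth=100_000, seed=6, error_rate=0.005,
                           n_read_rate=0.0, singleton_noise_rate=0.0,
                           antisense_gene_fraction=0.0, antisense_fraction=0.0)
    rng = np.random.default_rng(cfg.seed)
    recs = simulate_transcriptome(cfg, rng)
    truth = simulate.simulate_stage_profiles(cfg, rng)
    lib, prov = simulate.simulate_tag_library(recs, truth, cfg, "MP", rng)
    sense = set(simulate.canonical_tags(recs).sense_tag.dropna())
    n_errored = sum(c for t, c in lib.counts.items() if t not in sense)
    expect = 1 - (1 - 0.005) ** 21
    se = np.sqrt(expect * (1 - expect) / cfg.depth)
    assert abs(n_errored / cfg.depth - expect) <= 3 * se


def test_library_generation_is_deterministic(small_config, small_study):
    truth = small_study["truth"]
    a, _ = simulate.simulate_tag_library(small_study["transcripts"], truth,
                                         small_config, "HP",
                                         rng=np.random.default_rng(123))
    b, _ = simulate.simulate_tag_library(small_study["transcripts"], truth,
                                         small_config, "HP",
                                         rng=np.random.default_rng(123))
    assert a.counts == b.counts


def test_injected_read_classes_appear_at_configured_rates(small_study):
    cfg = SimulationConfig(n_genes=100, depth=50_000, seed=13,
                           n_read_rate=0.05, singleton_noise_rate=0.05,
                           adaptor_rate=0.02)
    rng = np.random.default_rng(cfg.seed)
    recs = simulate_transcriptome(cfg, rng)
    truth = simulate.simulate_stage_profiles(cfg, rng)
    lib, prov = simulate.simulate_tag_library(recs, truth, cfg, "PT", rng)
    by_class = prov.groupby("read_class")["count"].sum()
    for cls, rate in [("n_read", 0.05), ("noise", 0.05), ("adaptor", 0.02)]:
        se = np.sqrt(rate * (1 - rate) / cfg.depth)
        assert abs(by_class[cls] / cfg.depth - rate) <= 4 * se
    # N reads really contain N; noise tags are singletons after cleaning
    n_tags = set(prov.loc[prov.read_class == "n_read", "tag_seq"])
    assert all("N" in t for t in n_tags)
    clean, ledger = filter_raw_tags(lib)
    assert ledger.tags_containing_N.total >= by_class["n_read"]


def test_annotation_planting_hits_expected_overlap(small_study):
    cfg = SimulationConfig(n_genes=1000, seed=13)
    rng = np.random.default_rng(cfg.seed)
    truth = simulate.simulate_stage_profiles(cfg, rng)
    anno = simulate.simulate_annotations(list(truth.tpm.index), truth, cfg, rng,
                                         planted_or=8.0)
    cmp = "MPvsHP"
    term = anno.terms[truth.planted_terms[cmp]][1]
    de_genes = set(truth.de[cmp].index[truth.de[cmp].planted])
    k = len(term & de_genes)
    d, G, size = len(de_genes), 1000, len(term)
    expected_k = size * (8 * d) / (8 * d + (G - d))
    assert abs(k - expected_k) <= 3 * np.sqrt(expected_k)


def test_same_seed_reproduces_the_whole_study(small_config, small_study):
    again = simulate.simulate_study(small_config)
    assert again["libraries"]["MP"].counts == small_study["libraries"]["MP"].counts
    assert again["truth"].tpm.equals(small_study["truth"].tpm)
    assert again["ct"].data.equals(small_study["ct"].data)
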