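import numpy as np
import pandas as pd
import pytest

from tagdge import simulate
from tagdge.mapping import (ExpressionTable, classify_stages, expected_distinct_tags,
                            foldchange_distribution, map_tags, pct, quantify,
                            saturation_curve, stage_summary_from_counts)
from tagdge.qc import TagLibrary, filter_raw_tags
from tagdge.reference import TranscriptRecord, scan_catg_tags

from _oracles import brute_force_assign, expected_distinct_subsample


def _mutate(tag: str, pos: int, base: str) -> str:
    return tag[:pos] + base + tag[pos + 1 :]


def test_exact_unique_match_assigns_gene_and_strand():
    mer = "CATG" + "ACGTACGTACGTACGTA"
    db = scan_catg_tags([TranscriptRecord("g1", mer + "TT")])
    asg, summary = map_tags(TagLibrary("L", {mer: 5}), db)
    row = asg.iloc[0]
    assert (row.match_class, row.gene_id, row.strand) == ("exact", "g1", "sense")
    assert summary.classes["unambiguous_mapping"] == {"distinct": 1, "total": 5}


def test_one_mismatch_to_two_genes_is_excluded():
    m1 = "CATG" + "A" * 17
    m2 = "CATG" + "A" * 16 + "C"
    db = scan_catg_tags([TranscriptRecord("g1", m1), TranscriptRecord("g2", m2)])
    # query differs by 1 from both reference tags but matches neither exactly
    query = "CATG" + "A" * 16 + "G"
    asg, _ = map_tags(TagLibrary("L", {query: 2}), db)
    row = asg.iloc[0]
    assert row.match_class == "one_mismatch"
    assert row.excluded_multi_gene and row.n_genes == 2 and row.gene_id == ""


def test_exact_match_beats_one_mismatch():
    m1 = "CATG" + "A" * 17
    m2 = "CATG" + "A" * 16 + "C"  # Hamming 1 from m1
    db = scan_catg_tags([TranscriptRecord("g1", m1), TranscriptRecord("g2", m2)])
    asg, _ = map_tags(TagLibrary("L", {m1: 3}), db)
    row = asg.iloc[0]
    assert (row.match_class, row.gene_id, bool(row.excluded_multi_gene)) == ("exact", "g1", False)


def test_assignments_match_brute_force_hamming_scan(small_clean, small_db):
    clean = small_clean["MP"]
    sub = TagLibrary("MP", dict(list(clean.counts.items())[:400]))
    asg, _ = map_tags(sub, small_db)
    ref_tags = {t: set(g) for t, g in small_db.tag_genes.items()}
    for row in asg.itertuples():
        cls, genes = brute_force_assign(row.tag_seq, ref_tags)
        assert row.match_class == cls
        if len(genes) == 1:
            assert row.gene_id == next(iter(genes))
        else:
            assert row.excluded_multi_gene == (len(genes) >= 2)


def test_mapping_classes_partition_the_clean_library(small_clean, small_assignments):
    for stage, (asg, summary) in small_assignments.items():
        clean = small_clean[stage]
        parts = [summary.classes[c] for c in
                 ("unambiguous_mapping", "excluded_multi_gene", "unknown")]
        assert sum(p["distinct"] for p in parts) == clean.distinct
        assert sum(p["total"] for p in parts) == clean.total
        assert summary.classes["all_mapping"]["distinct"] + summary.classes["unknown"]["distinct"] == clean.distinct


def test_error_free_sense_only_library_maps_all_sense(small_config, small_study):
    cfg = simulate.SimulationConfig(
        n_genes=150, depth=50_000, seed=3, error_rate=0.0,
        n_read_rate=0.0, singleton_noise_rate=0.0,
        antisense_gene_fraction=0.0, antisense_fraction=0.0)
    study = simulate.simulate_study(cfg)
    db = scan_catg_tags(study["transcripts"])
    clean, _ = filter_raw_tags(study["libraries"]["MP"])
    asg, summary = map_tags(clean, db)
    assert summary.classes["unknown"]["distinct"] == 0
    assert (asg.loc[asg.n_genes == 1, "strand"] == "sense").all()


def test_one_mismatch_recovers_singly_errored_tags_on_separated_reference():
    # canonical tags >= 3 apart: each of 17 positions encodes a base triple
    rng = np.random.default_rng(11)
    picks = rng.permutation(4**5)[:30]  # distinct 5-symbol codes
    codes = [[("ACGT")[(v // 4**j) % 4] for j in range(5)] for v in picks]
    genes, tags = [], []
    for i, code in enumerate(codes):
        body = "".join(c * 3 for c in code) + "GG"  # 15 + 2 = 17 nt
        tags.append("CATG" + body)
        genes.append(TranscriptRecord(f"g{i}", tags[-1]))
    db = scan_catg_tags(genes)
    errored = {}
    for t in tags:
        pos = int(rng.integers(0, 21))
        alt = "ACGT"[(("ACGT".index(t[pos])) + 1) % 4]
        errored[_mutate(t, pos, alt)] = 2
    asg, _ = map_tags(TagLibrary("E", errored), db)
    recovered = asg[(asg.match_class == "one_mismatch") & (asg.n_genes == 1)]
    assert len(recovered) >= 0.9 * len(errored)


def test_quantify_toy_counts_and_tpm():
    asg = pd.DataFrame({
        "tag_seq": ["t1", "t2"], "count": [10, 40], "match_class": ["exact"] * 2,
        "gene_id": ["gA", "gA"], "strand": ["sense", "sense"],
        "excluded_multi_gene": [False] * 2, "n_genes": [1, 1],
    })
    lib = TagLibrary("S1", {"CATG" + "A" * 17: 1_000_000})
    table = quantify({"S1": asg}, {"S1": lib}, ["gA", "gB"])
    assert table.counts.loc["gA", "S1"] == 50
    assert table.tpm.loc["gA", "S1"] == pytest.approx(50.0)
    assert table.counts.loc["gB", "S1"] == 0
    assert not table.detected("S1")["gB"]


def test_quantified_tpm_tracks_simulated_truth(small_table, small_study):
    truth = small_study["truth"]
    for stage in ("MP", "HP", "PT"):
        t = truth.tpm[stage]
        m = small_table.tpm[stage].reindex(t.index)
        both = (t > 0) & (m > 0)
        r = np.corrcoef(np.log2(t[both]), np.log2(m[both]))[0, 1]
        assert r > 0.95


def test_sum_of_gene_counts_bounded_by_clean_total(small_table, small_clean):
    for stage in small_table.stages:
        assert small_table.counts[stage].sum() <= small_clean[stage].total


def test_stage_classification_on_toy_table():
    counts = pd.DataFrame(
        {"MP": [5, 2, 0], "HP": [0, 1, 3], "PT": [0, 4, 6]},
        index=pd.Index(["A", "B", "C"], name="gene_id"))
    totals = {"MP": 100, "HP": 100, "PT": 100}
    table = ExpressionTable(counts, counts / 100 * 1e6, totals, 3)
    summary = classify_stages(table)
    get = lambda cat, grp: summary.query("category == @cat and group == @grp").n_genes.iloc[0]
    assert get("specific", "MP") == 1
    assert get("specific", "HP") == 0 and get("specific", "PT") == 0
    assert get("expressed", "all_three_stages") == 1
    assert get("expressed", "at_least_one_stage") == 3


def test_stage_summary_percentage_denominators():
    summary = stage_summary_from_counts(
        detected={"MP": 11_751, "HP": 9_348, "PT": 9_644},
        specific={"MP": 2_006, "HP": 450, "PT": 958},
        all_three=6_996, at_least_one=13_017, n_reference_genes=41_404)
    vals = {(r.category, r.group): r.percentage for r in summary.itertuples()}
    assert vals[("expressed", "MP")] == 28.38
    assert vals[("specific", "MP")] == 17.07
    assert vals[("specific", "HP")] == 4.81


def test_saturation_endpoints_and_oracle(small_clean, small_assignments):
    clean = small_clean["PT"]
    asg, _ = small_assignments["PT"]
    total = clean.total
    depths = [1, total // 100, total // 10, total]
    curve = saturation_curve(clean, asg, depths, n_reps=8, seed=5)
    assert curve.mean_distinct_tags.iloc[0] == 1.0
    assert curve.mean_distinct_tags.iloc[-1] == clean.distinct
    assert curve.mean_distinct_tags.is_monotonic_increasing
    assert curve.mean_detected_genes.is_monotonic_increasing
    counts = list(clean.counts.values())
    for d, mean in zip(curve.depth[1:-1], curve.mean_distinct_tags[1:-1]):
        expected = expected_distinct_subsample(counts, int(d))
        # SD of distinct-tag count is < sqrt(distinct); 3 SE across 8 reps
        se = np.sqrt(clean.distinct) / np.sqrt(8)
        assert abs(mean - expected) <= 3 * se
        assert expected == pytest.approx(expected_distinct_tags(counts, int(d)), rel=1e-6)


def test_saturation_depth_beyond_total_errors(small_clean, small_assignments):
    with pytest.raises(ValueError, match="exceeds"):
        saturation_curve(small_clean["MP"], small_assignments["MP"][0],
                         [small_clean["MP"].total + 1], seed=0)


def test_foldchange_bins():
    counts = pd.DataFrame({"A": [10, 10, 10], "B": [10, 30, 100]},
                          index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
    totals = {"A": 1000, "B": 1000}
    table = ExpressionTable(counts, counts / 1000 * 1e6, totals, 3)
    bins = foldchange_distribution(table, "A", "B")
    assert bins["<2"] == pytest.approx(1 / 3)
    assert bins["2-5"] == pytest.approx(1 / 3)
    assert bins[">=5"] == pytest.approx(1 / 3)
    same = foldchange_distribution(table, "A", "A")
    assert same["<2"] == 1.0


def test_percentage_rounding_is_half_up():
    assert pct(13_017, 41_404) == 31.44
    assert pct(1, 8) == 12.5
    assert pct(1, 3, ndigits=2) == 33.33
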