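import numpy as np
import pandas as pd
import pytest

from haplocnv.rarecnv import (
    DEL,
    DIP,
    DUP,
    BayesFactorTrack,
    CNVCall,
    HMMConfig,
    annotate_plof,
    call_cnvs,
    combined_bf,
    compile_thresholds,
    emission_bf,
    emission_logbf_track,
    enumerate_posteriors,
    filter_calls,
    hmm_segment,
)


def _track(log_del, log_dup, sample="S0"):
    return BayesFactorTrack(sample, np.asarray(log_del, float), np.asarray(log_dup, float))


def _bins(n, bin_bp=100):
    return pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n) * bin_bp, "end": np.arange(n) * bin_bp + bin_bp}
    )


# ---------------------------------------------------------------------------
# emission Bayes factors
# ---------------------------------------------------------------------------

def test_emission_bf_diploid_is_one():
    assert emission_bf(17, 30.0, 10.0, "DIP") == 1.0


def test_emission_bf_matches_poisson_limit():
    # phi at the Poisson clip, mu=10, count=0: BF(DEL) = e^{-5}/e^{-10} = e^5
    bf = emission_bf(0, 10.0, 1e6, "DEL")
    assert abs(bf / np.exp(5.0) - 1) < 1e-3


def test_emission_bf_del_below_one_at_diploid_mean():
    assert emission_bf(10, 10.0, 10.0, "DEL") < 1.0


def test_emission_bf_copy_zero_uses_mean_floor():
    # a homozygous deletion keeps a proper likelihood via the 0.05*mu floor
    bf0 = emission_bf(0, 30.0, 10.0, "DEL", copy=0)
    assert np.isfinite(bf0) and bf0 > emission_bf(0, 30.0, 10.0, "DEL")


def test_emission_bf_rejects_bad_inputs():
    with pytest.raises(ValueError):
        emission_bf(np.nan, 30.0, 10.0, "DEL")
    with pytest.raises(ValueError):
        emission_bf(10, -1.0, 10.0, "DEL")
    with pytest.raises(ValueError):
        emission_logbf_track(np.array([1, 2]), np.array([10.0, 0.0]), 10.0)


# ---------------------------------------------------------------------------
# neighbor pooling
# ---------------------------------------------------------------------------

def test_combined_bf_with_no_neighbors_equals_target():
    t = _track([0.5, -0.2], [0.1, 0.3])
    c = combined_bf(t, [])
    assert np.array_equal(c.log_bf_del, t.log_bf_del)
    assert np.array_equal(c.n_neighbors_used, [0, 0])


def test_combined_bf_multiplies_bayes_factors():
    t = _track([np.log(2.0)], [0.0])
    n1 = (_track([np.log(3.0)], [0.0]), np.array([True]))
    n2 = (_track([np.log(5.0)], [0.0]), np.array([True]))
    c = combined_bf(t, [n1, n2])
    assert np.isclose(np.exp(c.log_bf_del[0]), 30.0)
    assert c.n_neighbors_used[0] == 2


def test_combined_bf_respects_tract_masks():
    t = _track([0.0, 0.0], [0.0, 0.0])
    n = (_track([1.0, 1.0], [0.0, 0.0]), np.array([True, False]))
    c = combined_bf(t, [n])
    assert c.log_bf_del[0] == 1.0 and c.log_bf_del[1] == 0.0
    with pytest.raises(ValueError, match="aligned"):
        combined_bf(t, [(_track([1.0], [0.0]), np.array([True]))])


# ---------------------------------------------------------------------------
# HMM segmentation
# ---------------------------------------------------------------------------

def test_hmm_neutral_track_stays_diploid():
    t = _track(np.zeros(20), np.zeros(20))
    post, path = hmm_segment(t, HMMConfig())
    assert np.all(post[:, DIP] > 0.99)
    assert np.all(path == DIP)


def test_hmm_dominant_evidence_segments_exactly():
    # flanking diploid bins carry mildly negative deletion evidence, as real
    # diploid read counts do; the event bins carry overwhelming evidence
    log_bf = np.full(10, -1.5)
    log_bf[3:8] = np.log(1e6)
    t = _track(log_bf, np.full(10, -1.5))
    cfg = HMMConfig()
    post, path = hmm_segment(t, cfg)
    assert np.array_equal(np.flatnonzero(path == DEL), np.arange(3, 8))
    ref_post, ref_path = enumerate_posteriors(t, cfg)
    assert np.array_equal(path, ref_path)
    assert np.abs(post - ref_post).max() < 1e-10


def test_hmm_matches_enumeration_on_random_short_tracks():
    rng = np.random.default_rng(0)
    cfg = HMMConfig()
    for _ in range(25):
        n = int(rng.integers(1, 8))
        t = _track(rng.normal(0, 2, n), rng.normal(0, 2, n))
        post, path = hmm_segment(t, cfg)
        ref_post, ref_path = enumerate_posteriors(t, cfg)
        assert np.abs(post - ref_post).max() < 1e-10
        assert np.array_equal(path, ref_path)


def test_hmm_rejects_nan_track():
    with pytest.raises(ValueError):
        hmm_segment(_track([np.nan], [0.0]), HMMConfig())


def test_transition_matrix_rows_sum_to_one():
    cfg = HMMConfig()
    assert np.allclose(cfg.transition_matrix().sum(axis=1), 1.0)
    pi = cfg.start_probs()
    assert np.allclose(pi @ cfg.transition_matrix(), pi)


# ---------------------------------------------------------------------------
# call emission
# ---------------------------------------------------------------------------

def test_call_cnvs_empty_path_emits_nothing():
    t = _track(np.zeros(5), np.zeros(5))
    post, path = hmm_segment(t, HMMConfig())
    assert call_cnvs(t, post, path, HMMConfig(), _bins(5)) == []


def test_call_cnvs_single_run():
    log_bf = np.full(12, -1.5)
    log_bf[4:10] = np.log(1e5)
    t = _track(log_bf, np.full(12, -1.5))
    cfg = HMMConfig()
    post, path = hmm_segment(t, cfg)
    calls = call_cnvs(t, post, path, cfg, _bins(12))
    assert len(calls) == 1
    c = calls[0]
    assert (c.type, c.n_bins, c.start, c.end) == ("DEL", 6, 400, 1000)
    assert c.score == pytest.approx(6 * np.log10(1e5))


def test_adjacent_del_and_dup_become_two_calls():
    log_del = np.full(11, -0.2)
    log_dup = np.full(11, -0.2)
    log_del[0:4] = np.log(1e6)
    log_dup[5:11] = np.log(1e6)
    t = _track(log_del, log_dup)
    cfg = HMMConfig()
    post, path = hmm_segment(t, cfg)
    ref_post, ref_path = enumerate_posteriors(t, cfg)
    assert np.array_equal(path, ref_path)
    calls = call_cnvs(t, post, path, cfg, _bins(11))
    assert [c.type for c in calls] == ["DEL", "DUP"]


# ---------------------------------------------------------------------------
# compilation and filtering
# ---------------------------------------------------------------------------

def _call(sample, start, end, type_="DEL", score=5.0, thr=1.0):
    return CNVCall(
        sample=sample, chrom="chr1", start=start, end=end, type=type_,
        score=score, ibd_threshold=thr, n_bins=(end - start) // 100,
    )


def test_compile_collapses_identical_calls_across_thresholds():
    merged = compile_thresholds(
        {2.0: [_call("S0", 1000, 1600, thr=2.0)], 1.0: [_call("S0", 1000, 1600, thr=1.0)]}
    )
    assert len(merged) == 1
    assert merged[0].thresholds == [2.0, 1.0]


def test_compile_keeps_different_types_apart():
    merged = compile_thresholds(
        {1.0: [_call("S0", 0, 500, "DEL"), _call("S0", 1000, 1500, "DUP")]}
    )
    assert len(merged) == 2


def test_compile_merges_nested_calls_with_sufficient_reciprocal_overlap():
    # 10-bin call vs nested 6-bin call: reciprocal overlap min(0.6, 1.0) = 0.6
    merged = compile_thresholds(
        {2.0: [_call("S0", 0, 1000, thr=2.0)], 1.0: [_call("S0", 200, 800, thr=1.0)]}
    )
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end) == (0, 1000)
    assert merged[0].thresholds == [2.0, 1.0]


def test_compiled_calls_do_not_overlap_per_sample():
    calls = {
        2.0: [_call("S0", 0, 1000, thr=2.0)],
        1.0: [_call("S0", 900, 2100, thr=1.0), _call("S0", 2000, 2400, "DUP", thr=1.0)],
    }
    merged = compile_thresholds(calls)
    by_sample = sorted((c.start, c.end) for c in merged if c.sample == "S0")
    for (s1, e1), (s2, e2) in zip(by_sample, by_sample[1:]):
        assert e1 <= s2


def test_filter_removes_hypercalled_samples_masked_and_low_score_calls():
    calls = [_call("S0", i * 1000, i * 1000 + 500) for i in range(301)]
    calls.append(_call("S1", 0, 500, score=5.0))
    calls.append(_call("S1", 5000, 5500, score=1.0))       # low score
    calls.append(_call("S2", 10_000, 10_500, score=9.0))   # masked below
    kept, excluded, reasons = filter_calls(
        calls, per_sample_cap=300, masks=[("chr1", 10_000, 11_000)], score_min=2.0
    )
    assert excluded == ["S0"]
    assert reasons["sample_cap"] == 301
    assert reasons["low_score"] == 1
    assert reasons["mask"] == 1
    assert [c.sample for c in kept] == ["S1"]


# ---------------------------------------------------------------------------
# pLOF annotation
# ---------------------------------------------------------------------------

@pytest.fixture()
def gene_models():
    genes = pd.DataFrame(
        {"gene": ["G1", "G2"], "chrom": ["chr1", "chr1"], "start": [1000, 10_000], "end": [5000, 12_000]}
    )
    exons = pd.DataFrame(
        {
            "gene": ["G1", "G1", "G2"],
            "start": [1200, 3000, 10_500],
            "end": [1307, 3200, 11_000],   # G1 first exon is 107 bp
        }
    )
    return genes, exons


def test_intronic_deletion_is_other(gene_models):
    df = annotate_plof([_call("S0", 1500, 1600, "DEL")], *gene_models)
    assert df.loc[0, "classification"] == "other"


def test_coding_deletion_is_plof(gene_models):
    df = annotate_plof([_call("S0", 1250, 1350, "DEL")], *gene_models)
    assert df.loc[0, "classification"] == "pLOF_del"
    assert df.loc[0, "n_exons"] == 1


def test_whole_gene_duplication(gene_models):
    df = annotate_plof([_call("S0", 900, 5100, "DUP")], *gene_models)
    assert df.loc[0, "classification"] == "whole_gene_dup"


def test_internal_single_exon_duplication_is_plof(gene_models):
    # 107-bp duplication spanning exactly one internal exon
    df = annotate_plof([_call("S0", 1200, 1307, "DUP")], *gene_models)
    assert df.loc[0, "classification"] == "internal_dup_pLOF"
    assert df.loc[0, "n_exons"] == 1


def test_intergenic_and_boundary_dup(gene_models):
    df = annotate_plof(
        [_call("S0", 6000, 6500, "DEL"), _call("S0", 500, 1500, "DUP")], *gene_models
    )
    assert df.loc[0, "classification"] == "intergenic"
    assert df.loc[1, "classification"] == "other"  # straddles one gene boundary


def test_malformed_gene_model_raises(gene_models):
    genes, exons = gene_models
    bad = exons.copy()
    bad.loc[0, "end"] = bad.loc[0, "start"]
    with pytest.raises(ValueError, match="malformed"):
        annotate_plof([_call("S0", 0, 100)], genes, bad)
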