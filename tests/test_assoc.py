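import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from haplocnv.assoc import (
    burden_collapse,
    inverse_normal_transform,
    ld_filter,
    prep_phenotype,
    test_association,
    validation_rate,
)
from haplocnv.rarecnv import CNVCall


def _call(type_="DEL", sample="S0"):
    return CNVCall(
        sample=sample, chrom="chr1", start=0, end=500, type=type_,
        score=5.0, ibd_threshold=1.0, n_bins=5,
    )


# ---------------------------------------------------------------------------
# phenotype preparation
# ---------------------------------------------------------------------------

def test_inverse_normal_transform_three_values():
    # quantiles at (r - 0.5)/n = 1/6, 3/6, 5/6
    out = inverse_normal_transform(np.array([7.0, 1.0, 3.0]))
    assert np.allclose(np.sort(out), [-0.9674216, 0.0, 0.9674216], atol=1e-6)


def test_inverse_normal_transform_symmetry_and_ties():
    out = inverse_normal_transform(np.arange(10.0))
    assert out.mean() == pytest.approx(0.0, abs=1e-12)
    tied = inverse_normal_transform(np.array([1.0, 2.0, 2.0, 5.0]))
    assert tied[1] == tied[2]  # midranks map ties to equal values


def test_prep_phenotype_standardizes_within_strata():
    rng = np.random.default_rng(0)
    raw = pd.Series(rng.lognormal(0, 1, 200))
    strata = pd.Series(["a"] * 100 + ["b"] * 100)
    prepared = prep_phenotype(raw, strata)
    for s in ("a", "b"):
        vals = prepared.values[strata == s]
        assert abs(vals.mean()) < 1e-9
        assert vals.std(ddof=1) == pytest.approx(1.0)


def test_prep_phenotype_removes_skew_at_large_n():
    rng = np.random.default_rng(1)
    raw = pd.Series(rng.exponential(2.0, 2000))
    prepared = prep_phenotype(raw)
    assert abs(skew(prepared.values)) < 0.05


def test_prep_phenotype_regresses_out_covariates():
    rng = np.random.default_rng(2)
    age = pd.DataFrame({"age": rng.normal(50, 8, 500)})
    raw = pd.Series(0.1 * age["age"].to_numpy() + rng.normal(0, 1, 500))
    prepared = prep_phenotype(raw, covariates=age)
    assert abs(np.corrcoef(prepared.values, age["age"])[0, 1]) < 1e-9


def test_prep_phenotype_errors():
    with pytest.raises(ValueError, match="constant"):
        prep_phenotype(pd.Series(np.ones(100)))
    with pytest.raises(ValueError, match="fewer than"):
        prep_phenotype(pd.Series(np.arange(10.0)))


# ---------------------------------------------------------------------------
# association test
# ---------------------------------------------------------------------------

def test_association_recovers_planted_effect():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(10_000)
    y = 0.5 * x + rng.standard_normal(10_000)
    res = test_association(x, y)
    assert abs(res.beta - 0.5) < 3 * res.se
    assert res.genome_wide


def test_association_rejects_degenerate_designs():
    y = np.random.default_rng(4).standard_normal(200)
    with pytest.raises(ValueError, match="constant predictor"):
        test_association(np.ones(200), y)
    x = np.random.default_rng(5).standard_normal(200)
    with pytest.raises(ValueError, match="collinear"):
        test_association(x, y, covariates=pd.DataFrame({"twin": x}))
    with pytest.raises(ValueError, match="minimum overlapping"):
        test_association(x[:50], y[:50])


# ---------------------------------------------------------------------------
# burden collapsing
# ---------------------------------------------------------------------------

def test_burden_union_counts_carriers_once():
    samples = [f"S{i}" for i in range(10)]
    masks = burden_collapse(
        "G1",
        {"CNV_pLOF": {"S0", "S1"}, "SNV_pLOF": {"S1", "S2", "S3"}},
        samples,
    )
    assert masks["all"].carrier_count == 4
    assert masks["all"].indicator.sum() == 4
    assert masks["snv_indel"].carrier_count == 3


def test_burden_empty_mask_is_none():
    masks = burden_collapse("G1", {"SNV_pLOF": set()}, ["S0", "S1"])
    assert masks["all"] is None and masks["snv_indel"] is None


def test_burden_cnv_only_gene_detectable_only_with_cnvs():
    rng = np.random.default_rng(6)
    samples = [f"S{i}" for i in range(2000)]
    carriers = set(rng.choice(samples, size=25, replace=False))
    y = pd.Series(rng.standard_normal(2000), index=samples)
    y[sorted(carriers)] -= 1.0
    masks = burden_collapse("G1", {"CNV_pLOF": carriers, "SNV_pLOF": set()}, samples)
    assert masks["snv_indel"] is None  # not testable without CNV carriers
    res = test_association(masks["all"].indicator, y, variant_id="G1")
    assert res.p_value < 1e-4 and res.beta < 0


# ---------------------------------------------------------------------------
# LD filter
# ---------------------------------------------------------------------------

def test_ld_filter_fails_on_perfect_tag():
    rng = np.random.default_rng(7)
    g = rng.binomial(1, 0.3, 2000).astype(float)
    y = 0.3 * g + rng.standard_normal(2000)
    res = ld_filter(pd.Series(g), pd.DataFrame({"same": g}), pd.Series(y))
    assert not res.passed
    assert res.max_r2 == pytest.approx(1.0)


def test_ld_filter_passes_with_no_linked_variants():
    rng = np.random.default_rng(8)
    g = rng.binomial(1, 0.3, 2000).astype(float)
    y = 0.3 * g + rng.standard_normal(2000)
    other = rng.binomial(1, 0.3, 2000).astype(float)
    res = ld_filter(pd.Series(g), pd.DataFrame({"indep": other}), pd.Series(y))
    assert res.passed
    assert res.conditional_beta == pytest.approx(res.marginal_beta)


def test_ld_filter_distinguishes_causal_from_tagging_target():
    from haplocnv.pipeline import ld_filter_accuracy

    out = ld_filter_accuracy(n_replicates=20, seed=9)
    assert out["accuracy"] >= 0.8


# ---------------------------------------------------------------------------
# validation rate
# ---------------------------------------------------------------------------

def test_validation_rate_worked_composition():
    calls = [_call("DEL", f"S{i}") for i in range(100)]
    est = [1.5] * 80 + [2.5] * 10 + [2.05] * 10
    v, table = validation_rate(calls, est)
    assert v == pytest.approx(0.70)
    assert (table["verdict"] == "ambiguous").sum() == 10


def test_validation_rate_all_correct_and_antisymmetry():
    calls = [_call("DEL"), _call("DUP")]
    v, _ = validation_rate(calls, [1.4, 2.6])
    assert v == 1.0
    flipped = [_call("DUP"), _call("DEL")]
    v2, _ = validation_rate(flipped, [1.4, 2.6])
    assert v2 == -v


def test_validation_rate_excludes_missing_estimates():
    calls = [_call("DEL"), _call("DEL"), _call("DEL")]
    v, table = validation_rate(calls, [1.5, np.nan, 1.5])
    assert v == 1.0
    assert (table["verdict"] == "missing").sum() == 1
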