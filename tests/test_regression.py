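"""Regression suite: exact recovery, calibration, permutation, GAM, batch."""

import numpy as np
import pandas as pd
import pytest

from denovotrio import place_dnms, sample_ages
from denovotrio.regression import (
    batch_effect_regression,
    bonferroni_outlier_test,
    bootstrap_slope_ci,
    cluster_robustness_scan,
    fit_exponential,
    fit_gam,
    fit_mlr,
    fit_per_chromosome,
    median_split_slopes,
    permutation_test_maternal,
    vif,
)


def test_mlr_exact_recovery_noise_free(paper_cohort):
    """y = 6.61 + 0.64 F + 0.35 M recovered to machine precision."""
    y = 6.61 + 0.64 * paper_cohort["father_age"] + 0.35 * paper_cohort["mother_age"]
    res = fit_mlr(paper_cohort.assign(n_dnm=y))
    assert res.estimate("const") == pytest.approx(6.61, abs=1e-8)
    assert res.estimate("father_age") == pytest.approx(0.64, abs=1e-10)
    assert res.estimate("mother_age") == pytest.approx(0.35, abs=1e-10)
    assert res.r2 == pytest.approx(1.0)


def test_mlr_null_slopes_within_error(paper_cohort):
    rng = np.random.default_rng(50)
    res = fit_mlr(paper_cohort.assign(n_dnm=rng.poisson(40.0, len(paper_cohort))))
    for term in ("father_age", "mother_age"):
        est = res.estimate(term)
        se = res.params.loc[term, "se"]
        assert abs(est) < 3 * se


def test_mlr_rank_deficiency_names_columns(paper_cohort):
    data = paper_cohort.assign(n_dnm=40.0, father_copy=paper_cohort["father_age"])
    with pytest.raises(ValueError, match="father"):
        fit_mlr(data, ("father_age", "father_copy"))


def test_vif_closed_form():
    rng = np.random.default_rng(51)
    n = 500
    x1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x1 = (x1 - x1.mean()) / x1.std()
    e -= (e @ x1 / (x1 @ x1)) * x1
    e = (e - e.mean()) / e.std()
    x2 = 0.71 * x1 + np.sqrt(1 - 0.71**2) * e  # sample r exactly 0.71
    v = vif(pd.DataFrame({"a": x1, "b": x2}))
    assert v["a"] == pytest.approx(1 / (1 - 0.71**2), rel=1e-6)
    # an orthogonal third covariate stays near 1
    x3 = rng.standard_normal(n)
    v3 = vif(pd.DataFrame({"a": x1, "c": x3}))
    assert v3["c"] == pytest.approx(1.0, abs=0.05)


def test_bonferroni_outlier_detection(linear_counts):
    res = fit_mlr(linear_counts)
    assert len(bonferroni_outlier_test(res)) == 0
    y = linear_counts["n_dnm"].to_numpy(float).copy()
    sigma = np.std(res.resid)
    y[10] += 10 * sigma
    y[200] -= 10 * sigma
    out = bonferroni_outlier_test(fit_mlr(linear_counts.assign(n_dnm=y)))
    assert set(out) == {10, 200}


def test_exponential_model_exact_and_zero_guard(paper_cohort):
    y = np.exp(1.0 + 0.02 * paper_cohort["father_age"])
    res = fit_exponential(paper_cohort.assign(n_dnm=y), ("father_age",))
    assert res.estimate("father_age") == pytest.approx(0.02, abs=1e-10)
    with pytest.raises(ValueError, match="positive"):
        fit_exponential(paper_cohort.assign(n_dnm=0.0))


def test_exponential_r2_close_to_linear_on_linear_truth(linear_counts):
    lin = fit_mlr(linear_counts)
    exp = fit_exponential(linear_counts)
    assert exp.r2 <= lin.r2 + 0.02


def test_per_chromosome_power_ordering(paper_config, paper_cohort):
    """Chromosome-proportional counts: large chromosomes detect the age
    signal, the smallest do not (pure power ordering)."""
    counts = pd.Series(
        (6.61 + 0.64 * paper_cohort["father_age"] + 0.35 * paper_cohort["mother_age"])
        .round().astype(int).to_numpy(),
        index=paper_cohort["trio_id"].to_numpy(),
    )
    truth = place_dnms(counts, paper_config, seed=52)
    wide = (
        truth.groupby(["trio_id", "chrom"]).size().unstack(fill_value=0)
        .reindex(paper_cohort["trio_id"], fill_value=0).reset_index()
    )
    res = fit_per_chromosome(wide, paper_cohort)
    assert len(res) == 22
    by_chrom = res.set_index("chrom")
    assert by_chrom.loc["chr1", "p_father"] < 0.05
    assert by_chrom.loc["chr21", "p_father"] > by_chrom.loc["chr1", "p_father"]


def test_per_chromosome_type_i_rate(paper_cohort):
    rng = np.random.default_rng(53)
    wide = pd.DataFrame(
        rng.poisson(2.0, size=(len(paper_cohort), 22)),
        columns=[f"chr{i+1}" for i in range(22)],
    )
    wide.insert(0, "trio_id", paper_cohort["trio_id"].to_numpy())
    res = fit_per_chromosome(wide, paper_cohort)
    fp = (res["p_father"] < 0.05).mean()
    assert fp < 0.2  # ~5% nominal, binomial noise over 22 tests


# -- permutation -------------------------------------------------------------

def test_permutation_preserves_difference_multiset(linear_counts):
    res = permutation_test_maternal(linear_counts, n_perm=200, seed=54)
    assert res.n_perm == 200 and len(res.permuted_t) == 200
    assert 0 <= res.p_value <= 1


def test_permutation_null_calibrated(paper_cohort):
    """Counts depending only on father's age: maternal permutation p uniform."""
    rng = np.random.default_rng(55)
    ps = []
    for rep in range(20):
        y = rng.poisson(5 + 0.9 * paper_cohort["father_age"])
        res = permutation_test_maternal(
            paper_cohort.assign(n_dnm=y), n_perm=300, seed=56 + rep
        )
        ps.append(res.p_value)
    assert 0.35 < np.mean(ps) < 0.65


def test_permutation_detects_strong_maternal_effect(linear_counts):
    res = permutation_test_maternal(linear_counts, n_perm=2000, seed=57)
    assert res.p_value <= 0.001


# -- bootstrap ---------------------------------------------------------------

def test_bootstrap_deterministic_and_tight_when_noise_free(paper_cohort):
    y = 6.61 + 0.64 * paper_cohort["father_age"] + 0.35 * paper_cohort["mother_age"]
    data = paper_cohort.assign(n_dnm=y)
    a = bootstrap_slope_ci(data, n_boot=200, seed=58)
    b = bootstrap_slope_ci(data, n_boot=200, seed=58)
    assert a["father_age"] == b["father_age"]
    lo, hi = a["father_age"]
    assert hi - lo < 1e-8
    assert lo <= 0.64 <= hi + 1e-12


def test_bootstrap_brackets_generative_slopes(linear_counts):
    ci = bootstrap_slope_ci(linear_counts, n_boot=500, seed=59)
    assert ci["father_age"][0] <= 0.64 <= ci["father_age"][1]
    assert ci["mother_age"][0] <= 0.35 <= ci["mother_age"][1]


# -- median split ------------------------------------------------------------

def test_median_split_linear_truth_equal_slopes(linear_counts):
    split = median_split_slopes(linear_counts, "father")
    b_y = split["younger"].estimate("father_age")
    b_o = split["older"].estimate("father_age")
    se = np.hypot(split["younger"].params.loc["father_age", "se"],
                  split["older"].params.loc["father_age", "se"])
    assert abs(b_y - b_o) < 3 * se


def test_median_split_quadratic_maternal_directional(paper_cohort):
    rng = np.random.default_rng(60)
    mu = (6.61 + 0.64 * paper_cohort["father_age"] + 0.35 * paper_cohort["mother_age"]
          + 0.04 * (paper_cohort["mother_age"] - 31.2) ** 2)
    data = paper_cohort.assign(n_dnm=rng.poisson(mu))
    split = median_split_slopes(data, "mother")
    assert split["older"].estimate("mother_age") > split["younger"].estimate("mother_age")


# -- GAM ---------------------------------------------------------------------

def test_gam_linear_limit_reduces_to_ols(linear_counts):
    """Forcing a huge penalty drives each smooth to a straight line."""
    big = np.array([1e9])
    g = fit_gam(linear_counts, alphas=big)
    assert g.terms["edf"].max() < 1.05
    lin = fit_mlr(linear_counts)
    rss_lin = float((lin.resid**2).sum())
    assert g.deviance == pytest.approx(rss_lin, rel=0.01)


def test_gam_gcv_keeps_linear_maternal_term_near_one(linear_counts):
    g = fit_gam(linear_counts)
    assert 1.0 <= g.terms.loc["mother_age", "edf"] < 1.1
    assert g.terms.loc["mother_age", "p"] < 0.01


def test_gam_detects_quadratic_maternal_effect(paper_cohort):
    rng = np.random.default_rng(61)
    mu = (6.61 + 0.64 * paper_cohort["father_age"] + 0.35 * paper_cohort["mother_age"]
          + 0.05 * (paper_cohort["mother_age"] - 31.2) ** 2)
    g = fit_gam(paper_cohort.assign(n_dnm=rng.poisson(mu)))
    assert g.terms.loc["mother_age", "edf"] > 1.1


def test_gam_agrees_with_mgcv_oracle(linear_counts, tmp_path):
    """Independent cross-check against R mgcv on the same data."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not on PATH")
    csv = tmp_path / "d.csv"
    linear_counts[["n_dnm", "father_age", "mother_age"]].to_csv(csv, index=False)
    script = tmp_path / "gam.R"
    script.write_text(
        "d <- read.csv(commandArgs(TRUE)[1])\n"
        "m <- mgcv::gam(n_dnm ~ s(father_age, k=10, bs='cr') + s(mother_age, k=10, bs='cr'),"
        " data=d, gamma=1.4)\n"
        "cat(summary(m)$edf, '\\n')\n"
        "cat(fitted(m), '\\n')\n"
    )
    out = subprocess.run(
        ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
    ).stdout.splitlines()
    edf_mgcv = [float(x) for x in out[0].split()]
    fitted_mgcv = np.array([float(x) for x in out[1].split()])
    g = fit_gam(linear_counts)
    # both smoothers agree the maternal term is (near-)linear ...
    assert abs(g.terms.loc["mother_age", "edf"] - edf_mgcv[1]) < 0.3
    # ... and produce essentially the same fitted surface
    assert np.corrcoef(g.fitted, fitted_mgcv)[0, 1] > 0.98


# -- batch and cluster scan --------------------------------------------------

def test_batch_term_significant_only_with_offset(paper_cohort):
    rng = np.random.default_rng(62)
    mu = 6.61 + 0.64 * paper_cohort["father_age"] + 0.35 * paper_cohort["mother_age"]
    offset = np.where(paper_cohort["batch_label"] == "2.0.3", 5.0, 0.0)
    with_batch = paper_cohort.assign(n_dnm=rng.poisson(mu + offset))
    without = paper_cohort.assign(n_dnm=rng.poisson(mu))
    res_b = batch_effect_regression(with_batch)["software_version"]
    res_0 = batch_effect_regression(without)["software_version"]
    assert res_b.pvalue("batch_label[2.0.3]") < 1e-4
    assert res_0.pvalue("batch_label[2.0.3]") > 0.05


def test_batch_single_level_dropped(paper_cohort, caplog):
    rng = np.random.default_rng(65)
    data = paper_cohort.assign(n_dnm=rng.poisson(40, len(paper_cohort)),
                               batch_label="2.0.2")
    with caplog.at_level("WARNING"):
        res = batch_effect_regression(data)["software_version"]
    assert not any(t.startswith("batch_label") for t in res.params.index)


def test_cluster_scan_shapes_and_extreme_window(paper_config, paper_cohort):
    from denovotrio import sample_counts
    from denovotrio.simulate import place_dnms as place

    cfg = paper_config.replace(n_trios=len(paper_cohort))
    counts = sample_counts(paper_cohort, cfg, seed=63)
    sites = place(counts, cfg, seed=64)[["trio_id", "chrom", "pos", "ref", "alt"]]
    scan = cluster_robustness_scan(sites, paper_cohort, windows=(10, 10**6, 10**9))
    assert len(scan) == 3
    # artifact-free data: significance stable through 1 Mb windows
    assert scan.loc[scan["window"] == 10, "p_father"].iloc[0] < 0.05
    assert scan.loc[scan["window"] == 10**6, "p_father"].iloc[0] < 0.05
    # a window longer than every chromosome keeps only per-chromosome
    # singletons: most sites vanish and the evidence weakens sharply
    extreme = scan.loc[scan["window"] == 10**9].iloc[0]
    assert extreme["n_sites"] < 0.25 * scan["n_sites"].max()
    assert extreme["p_mother"] > scan.loc[scan["window"] == 10, "p_mother"].iloc[0]
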