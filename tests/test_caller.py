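"""Filter cascades: rule-by-rule oracles, idempotence, positional filters."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_sites
from denovotrio.caller import (
    Masks,
    cgi_candidate_filter,
    chrx_male_filter,
    count_dnms,
    depth_filter_cgi,
    gatk_style_filter,
    population_filter,
    region_filters,
    remove_clusters,
    run_cascade,
    strelka_style_filter,
)
from denovotrio.intervals import IntervalSet


# -- CGI candidate rules -----------------------------------------------------

@pytest.mark.parametrize(
    "override,rule",
    [
        ({"call_rate": 0.98}, "call_rate"),
        ({"carrier_count": 2}, "not_private"),
        ({"ch_qual": "other"}, "proband_quality"),
        ({"fa_refscore": 0}, "parent_refscore"),
        ({"ch_alt1": 10, "ch_ref1": 30}, "alt_fraction"),  # 25% alt
        ({"chrom": "chrX"}, "autosomal"),
    ],
)
def test_cgi_candidate_rule_failures(override, rule):
    res = cgi_candidate_filter(make_sites({}, override))
    assert len(res.passed) == 1
    assert res.trace["verdict"].tolist() == ["pass", "fail"]
    assert res.trace["first_failed_rule"].iloc[1] == rule


def test_cgi_candidate_missing_annotation_names_field():
    sites = make_sites({}).drop(columns=["call_rate"])
    with pytest.raises(KeyError, match="call_rate"):
        cgi_candidate_filter(sites)


@pytest.mark.parametrize(
    "override,passes",
    [
        ({"ch_ref1": 20, "ch_alt1": 18, "ch_third": 0, "ch_dp1": 38}, True),
        ({"ch_alt1": 4, "ch_ref1": 36}, False),
        ({"ch_third": 3, "ch_dp1": 40}, False),  # 7.5% third allele
    ],
)
def test_cgi_depth_rules(override, passes):
    res = depth_filter_cgi(make_sites(override))
    assert (len(res.passed) == 1) == passes


@pytest.mark.parametrize(
    "override,passes",
    [
        ({"ch_dp1": 30, "ch_ref1": 0, "ch_alt1": 30}, True),
        ({"ch_dp1": 4, "ch_ref1": 0, "ch_alt1": 4}, False),
        ({"ch_dp1": 30, "ch_ref1": 3, "ch_alt1": 27}, False),  # ref fraction 10%
    ],
)
def test_chrx_male_rules(override, passes):
    sites = make_sites({"chrom": "chrX", **override})
    res = chrx_male_filter(sites)
    assert (len(res.passed) == 1) == passes


def test_chrx_rejects_female_proband():
    with pytest.raises(ValueError):
        chrx_male_filter(make_sites({}), proband_sex="F")


# -- Strelka-style -----------------------------------------------------------

@pytest.mark.parametrize(
    "override,rule",
    [
        ({"mo_dp1": 9}, "depth_all_members"),
        ({"ch_fbc": 10}, "filtered_basecalls"),  # 25% of depth 40
        ({"fa_sdl": 2}, "spanning_deletions"),
        ({"fa_ref1": 30, "fa_dp1": 40}, "father_ref_fraction"),
        ({"mo_alt1": 1, "mo_ref1": 39}, "mother_alt_reads"),
        ({"fa_ref1": 38, "fa_ref2": 48, "fa_dp2": 48}, "father_tier_ratio"),
        ({"ch_ref1": 20, "ch_alt1": 10, "ch_dp1": 40}, "proband_genotype_reads"),
        ({"ch_alt1": 10, "ch_alt2": 14, "ch_ref1": 26, "ch_dp1": 36},
         "proband_tier_ratio"),
        ({"ch_alt1": 11, "ch_ref1": 29, "ch_alt2": 11, "ch_ref2": 29},
         "minor_allele_fraction"),  # 27.5%
    ],
)
def test_strelka_rule_failures(override, rule):
    res = strelka_style_filter(make_sites({}, override))
    assert res.trace["verdict"].tolist() == ["pass", "fail"]
    assert res.trace["first_failed_rule"].iloc[1] == rule


def test_strelka_missing_tier2_channel_errors():
    with pytest.raises(KeyError, match="dp2"):
        strelka_style_filter(make_sites({}).drop(columns=["ch_dp2"]))


# -- GATK-style --------------------------------------------------------------

@pytest.mark.parametrize(
    "override,rule",
    [
        ({"tp": 25}, "transmission_probability"),
        ({"fa_dp1": 110}, "depth_all_members"),
        ({"ch_dp1": 9, "ch_ref1": 5, "ch_alt1": 4}, "depth_all_members"),
        ({"mo_pl0": 20}, "parent_homref_pl"),
        ({"ch_pl1": 30}, "proband_het_pl"),
        ({"fa_alt1": 1, "fa_ref1": 39}, "parent_alt_reads"),
        ({"ch_alt1": 4, "ch_ref1": 36}, "proband_allele_depth"),
    ],
)
def test_gatk_rule_failures(override, rule):
    res = gatk_style_filter(make_sites({}, override))
    assert res.trace["verdict"].tolist() == ["pass", "fail"]
    assert res.trace["first_failed_rule"].iloc[1] == rule


def test_gatk_missing_pl_errors():
    with pytest.raises(KeyError, match="pl"):
        gatk_style_filter(make_sites({}).drop(columns=["ch_pl1"]))


# -- positional filters ------------------------------------------------------

def test_remove_clusters_pairwise_oracle():
    sites = make_sites(
        {"pos": 100}, {"pos": 900}, {"pos": 5000},
    )
    out = remove_clusters(sites, 1000)
    assert out["pos"].tolist() == [5000]


def test_remove_clusters_window_zero_is_identity():
    sites = make_sites({"pos": 100}, {"pos": 101})
    assert len(remove_clusters(sites, 0)) == 2


def test_remove_clusters_is_per_proband():
    sites = make_sites({"pos": 100}, {"pos": 150, "trio_id": "T0001"})
    assert len(remove_clusters(sites, 1000)) == 2


def test_remove_clusters_idempotent():
    rng = np.random.default_rng(0)
    sites = make_sites(*({"pos": int(p)} for p in rng.integers(1, 10**6, 200)))
    once = remove_clusters(sites, 1000)
    twice = remove_clusters(once, 1000)
    pd.testing.assert_frame_equal(once, twice)


def test_region_filter_coordinate_convention():
    sites = make_sites({"pos": 100})
    # VCF pos 100 is 0-based base 99: mask [99,100) covers it, [100,200) does not
    assert len(region_filters(sites, alignability=IntervalSet([("chr1", 99, 100)]))) == 0
    assert len(region_filters(sites, alignability=IntervalSet([("chr1", 100, 200)]))) == 1
    assert len(region_filters(sites, alignability=IntervalSet([("chr1", 0, 99)]))) == 1
    assert len(region_filters(sites)) == 1  # no masks: identity


def test_region_and_population_filters_commute():
    sites = make_sites({"pos": 100}, {"pos": 500}, {"pos": 700})
    mask = IntervalSet([("chr1", 450, 550)])
    known = [("chr1", 700, "C", "T")]
    ab = population_filter(region_filters(sites, segdup=mask), known)
    ba = region_filters(population_filter(sites, known), segdup=mask)
    pd.testing.assert_frame_equal(ab.reset_index(drop=True), ba.reset_index(drop=True))


def test_population_filter_is_allele_aware():
    sites = make_sites({"pos": 100, "ref": "C", "alt": "T"})
    assert len(population_filter(sites, [("chr1", 100, "C", "T")])) == 0
    assert len(population_filter(sites, [("chr1", 100, "C", "A")])) == 1
    assert len(population_filter(sites, [])) == 1


# -- cascade-level properties ------------------------------------------------

@pytest.mark.parametrize("cascade", ["cgi", "strelka", "gatk"])
def test_cascades_monotone_and_idempotent(paper_config, cascade):
    from denovotrio import simulate_cohort

    cfg = paper_config.replace(n_trios=25)
    _, _, sites, _ = simulate_cohort(cfg, seed=30)
    once = run_cascade(sites, cascade)
    assert len(once) <= len(sites)
    twice = run_cascade(once, cascade)
    pd.testing.assert_frame_equal(once, twice)


def test_trace_partitions_input():
    sites = make_sites({}, {"call_rate": 0.5}, {"carrier_count": 3})
    res = cgi_candidate_filter(sites)
    assert len(res.trace) == len(sites)
    n_pass = (res.trace["verdict"] == "pass").sum()
    assert n_pass + (res.trace["verdict"] == "fail").sum() == len(sites)
    assert len(res.passed) == n_pass


def test_count_dnms_zero_fills_and_totals(paper_cohort):
    calls = make_sites(
        {"trio_id": "T0003"}, {"trio_id": "T0003", "pos": 99},
        {"trio_id": "T0003", "pos": 55}, {"trio_id": "T0007"},
    )
    tab = count_dnms(calls, paper_cohort)
    assert len(tab) == len(paper_cohort)
    got = tab.set_index("trio_id")["n_dnm"]
    assert got["T0003"] == 3 and got["T0007"] == 1
    assert got.drop(["T0003", "T0007"]).eq(0).all()
    empty = count_dnms(calls.iloc[:0], paper_cohort)
    assert empty["n_dnm"].eq(0).all()


def test_full_pipeline_count_mean_at_published_operating_point(paper_config):
    """Noise-free cascade counts average ~38.87 DNMs per proband."""
    from denovotrio import simulate_cohort

    cfg = paper_config.replace(
        n_trios=200, **{"detection.sensitivity": 1.0, "detection.precision": 1.0}
    )
    cohort, _, sites, _ = simulate_cohort(cfg, seed=31)
    counts = count_dnms(run_cascade(sites, "cgi"), cohort)["n_dnm"]
    se = counts.std() / np.sqrt(len(counts))
    assert abs(counts.mean() - 38.87) < 3 * se + 0.5  # + age-truncation shift


def test_count_dnms_unknown_trio_errors(paper_cohort):
    with pytest.raises(ValueError, match="unknown trio"):
        count_dnms(make_sites({"trio_id": "NOPE"}), paper_cohort)
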