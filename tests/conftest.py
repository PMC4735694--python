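import numpy as np
import pandas as pd
import pytest

from denovotrio import paper_cohort_config, sample_ages
from denovotrio.variants import SITE_COLUMNS

CLEAN_SITE = {
    "trio_id": "T0000", "chrom": "chr1", "pos": 10_000, "ref": "C", "alt": "T",
    "call_rate": 1.0, "carrier_count": 1, "tp": 60,
}
for _m in ("fa", "mo"):
    CLEAN_SITE.update({
        f"{_m}_gt": "0/0", f"{_m}_qual": "HIGH", f"{_m}_refscore": 40,
        f"{_m}_dp1": 40, f"{_m}_dp2": 40, f"{_m}_ref1": 40, f"{_m}_alt1": 0,
        f"{_m}_ref2": 40, f"{_m}_alt2": 0, f"{_m}_third": 0, f"{_m}_fbc": 0,
        f"{_m}_sdl": 0, f"{_m}_pl0": 0, f"{_m}_pl1": 60, f"{_m}_pl2": 600,
    })
CLEAN_SITE.update({
    "ch_gt": "0/1", "ch_qual": "HIGH", "ch_refscore": 0,
    "ch_dp1": 40, "ch_dp2": 40, "ch_ref1": 22, "ch_alt1": 18,
    "ch_ref2": 22, "ch_alt2": 18, "ch_third": 0, "ch_fbc": 0, "ch_sdl": 0,
    "ch_pl0": 60, "ch_pl1": 0, "ch_pl2": 600,
})


def make_sites(*rows) -> pd.DataFrame:
    """Build a VariantSite table from clean-site templates with overrides."""
    recs = []
    for overrides in rows:
        rec = dict(CLEAN_SITE)
        rec.update(overrides)
        recs.append(rec)
    return pd.DataFrame(recs, columns=SITE_COLUMNS)


@pytest.fixture(scope="session")
def paper_config():
    return paper_cohort_config()


@pytest.fixture(scope="session")
def paper_cohort(paper_config):
    """One fixed 693-trio covariate table at the published operating point."""
    return sample_ages(paper_config, seed=20_693)


@pytest.fixture(scope="session")
def linear_counts(paper_config, paper_cohort):
    """Counts Poisson around the published two-age linear predictor."""
    rng = np.random.default_rng(11)
    mu = (
        paper_config.count_model.beta0
        + paper_config.count_model.beta_father * paper_cohort["father_age"]
        + paper_config.count_model.beta_mother * paper_cohort["mother_age"]
    )
    return paper_cohort.assign(n_dnm=rng.poisson(mu))
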