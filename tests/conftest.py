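import numpy as np
import pandas as pd
import pytest

import bmidiscord as bd


@pytest.fixture(scope="session")
def sep_cohort():
    """Separated-scenario cohort with ground truth (n = 4,000)."""
    cfg = bd.default_config("separated", n_individuals=4000, seed=11)
    cohort, truth = bd.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def sep_fit(sep_cohort):
    """Fitted profile partition on the separated cohort."""
    _, cohort, truth = sep_cohort
    res = bd.DiscordanceProfileModel(cohort).fit(seed=0, n_leiden=10)
    truth = truth.set_index("id").loc[res.alloc.index]
    return res, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Concordant-only cohort (n = 20,000) for null calibration checks."""
    cfg = bd.default_config("null", n_individuals=20_000, seed=5)
    cohort, truth = bd.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def surv_fit():
    """Survival-scenario data with Cox fits using true-mixture log-ratios."""
    cfg = bd.default_config("survival", n_individuals=8000, seed=3)
    cohort, truth = bd.generate_cohort(cfg)
    rm = bd.residualize(cohort)
    tr = truth.set_index("id").loc[rm.ids]
    alloc = tr[[c for c in tr.columns if c.startswith("p_")]]
    alloc = alloc.rename(columns=lambda c: c[2:])
    lr = bd.log_contrast(alloc)
    base_cov = ["age", "smoking", "bmi"] + bd.BIOMARKERS
    design = pd.concat(
        [cohort.set_index("id").loc[rm.ids]
         [base_cov + ["fu_years_mace", "mace_event"]].reset_index(drop=True),
         lr.reset_index(drop=True)], axis=1)
    base = bd.fit_cox(design, "fu_years_mace", "mace_event", base_cov)
    full = bd.fit_cox(design, "fu_years_mace", "mace_event",
                      base_cov + list(lr.columns))
    return dict(cfg=cfg, cohort=cohort, truth=tr, rm=rm, alloc=alloc,
                lr=lr, design=design, base=base, full=full)


def hand_mixture(d: int = 10):
    """Small fixed mixture: concordant + two well-separated spikes."""
    from bmidiscord.cluster import Component, MixtureModel

    m1 = np.zeros(d); m1[0] = 3.5; m1[1] = -2.5
    m2 = np.zeros(d); m2[4] = 3.0; m2[5] = 3.0
    return MixtureModel([
        Component("concordant", np.zeros(d), np.eye(d), 0.8, True),
        Component("spike_a", m1, np.eye(d), 0.12),
        Component("spike_b", m2, np.eye(d), 0.08),
    ])


@pytest.fixture()
def small_mixture():
    return hand_mixture()
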