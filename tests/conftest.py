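import numpy as np
import pytest
from hypothesis import settings

import emaxrisk as er

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def explorys_params():
    """Published pediatric EHR-cohort estimates (gamma fixed at 1)."""
    return er.EmaxParams(p0=0.094, pmax=0.65, ec50=3730.0, gamma=1.0)


@pytest.fixture(scope="session")
def pcmr_params():
    """Published registry-cohort estimates (p0/pmax fixed at 0/1)."""
    return er.EmaxParams(p0=0.0, pmax=1.0, ec50=4200.0, gamma=1.21)


@pytest.fixture(scope="session")
def small_cohort_rows():
    """Deterministic 20-row cohort spanning the concentration range."""
    rng = np.random.default_rng(202)
    x = np.exp(rng.normal(np.log(1000), 1.3, 20))
    y = np.array([0, 1] * 10)
    return [er.AnalysisRow(nt_probnp=float(c), event=int(e)) for c, e in zip(x, y)]


@pytest.fixture(scope="session")
def explorys_like_fit():
    """One converged fit on a moderately large synthetic pediatric cohort."""
    from dataclasses import replace

    cfg = replace(er.preset_configs()["explorys_child"], n=2000, seed=11)
    cohort = er.generate_cohort(cfg)
    model = er.EmaxRiskModel.from_rows(cohort.analysis_rows)
    return model.fit(mask=er.FixedMask.gamma_fixed(1.0),
                     options=er.FitOptions(n_starts=2))
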