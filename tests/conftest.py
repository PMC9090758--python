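import numpy as np
import pandas as pd
import pytest

from affectpipe import cohort as cohort_mod
from affectpipe import lba


@pytest.fixture(scope="session")
def mv():
    return lba.model_variant("M_v")


@pytest.fixture(scope="session")
def base_params():
    """A representative subject-level parameter set."""
    return lba.LBAParams(A=0.5, B=0.5, t0=0.3,
                         v_true=[1.2, 1.2, 1.2, 1.2],
                         v_false=[0.6, 0.6, 0.6, 0.6], sv_true=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """6 + 6 subjects, behavior only (no BOLD), fixed seed."""
    cfg = cohort_mod.CohortConfig(n_controls=6, n_patients=6, seed=11)
    return cohort_mod.generate_cohort(cfg, include_bold=False)


@pytest.fixture(scope="session")
def pathway_fit():
    """Inverted reduced cohort with the generator's group deltas on the
    FFA<->LPFC, LPFC<->sgACC and sgACC->AMY pathway, plus the PEB and
    LOOCV results over the intrinsic couplings."""
    from affectpipe.dcm import (DCMPriors, build_design_matrix,
                                greedy_prune_and_average, loocv_classify,
                                peb_fit, variational_laplace)

    cfg = cohort_mod.CohortConfig(n_controls=10, n_patients=10, seed=17,
                                  n_volumes=168)
    coh = cohort_mod.generate_cohort(cfg)
    posteriors, order = [], []
    for sid, rec in coh.subjects.items():
        posteriors.append(variational_laplace(rec.bold, DCMPriors(),
                                              max_iter=32))
        order.append(sid)
    table = coh.participants.set_index("subject_id").loc[order].reset_index()
    X, names = build_design_matrix(table)
    peb = peb_fit(posteriors, X, param_subset="A", covariate_names=names)
    peb = greedy_prune_and_average(peb, max_enum=2 ** 12)
    loocv = loocv_classify(posteriors, X, names, param_subset="A",
                           seed=0, n_boot=100)
    return {"config": cfg, "posteriors": posteriors, "peb": peb,
            "loocv": loocv, "X": X, "covariate_names": names}


@pytest.fixture(scope="session")
def flat_design():
    """Simple 80-trial design without block structure."""
    return pd.DataFrame({
        "condition": np.repeat(lba.CONDITIONS, 20),
        "onset": np.arange(80.0) * 6.0,
    })
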