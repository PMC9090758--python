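"""Shared builders for second-level tests (synthetic subject posteriors)."""

import numpy as np

from affectpipe.dcm.invert import SubjectPosterior
from affectpipe.dcm.peb import peb_fit


def make_subject_posterior(mean, cov, prior_var, names=None):
    d = len(mean)
    names = names or tuple(f"A.p{i}" for i in range(d))
    return SubjectPosterior(mean=np.asarray(mean, float),
                            cov=np.asarray(cov, float), free_energy=0.0,
                            log_precision=4.0, param_names=names,
                            prior_mean=np.zeros(d),
                            prior_cov=np.diag(prior_var))


def make_one_param_peb(common, group_effect, se=0.05, n=40, seed=0):
    """PEB over one-parameter subjects with a configurable group effect."""
    rng = np.random.default_rng(seed)
    group = np.repeat([0.0, 1.0], n // 2)
    Xc = group - group.mean()
    subj = []
    for g in group:
        val = common + (g - 0.5) * group_effect + rng.normal(0, se)
        subj.append(make_subject_posterior([val], [[se ** 2]], [1.0]))
    X = np.column_stack([np.ones(n), Xc])
    return peb_fit(subj, X, param_subset=np.arange(1),
                   covariate_names=("common", "group"))


def synthetic_connectivity_posteriors(effect, n_per_group=10, d=3,
                                      between_sd=0.1, obs_sd=0.05, seed=0):
    """Subject posteriors with an optional group shift on parameter 0."""
    rng = np.random.default_rng(seed)
    posteriors, groups = [], []
    names = tuple(f"A.p{i}" for i in range(d))
    for g in (0, 1):
        for _ in range(n_per_group):
            truth = rng.normal(0.2, between_sd, d)
            truth[0] += g * effect
            m = truth + rng.normal(0, obs_sd, d)
            posteriors.append(SubjectPosterior(
                mean=m, cov=obs_sd ** 2 * np.eye(d), free_energy=0.0,
                log_precision=4.0, param_names=names,
                prior_mean=np.zeros(d), prior_cov=np.eye(d)))
            groups.append(g)
    groups = np.array(groups, float)
    X = np.column_stack([np.ones(len(groups)), groups - groups.mean()])
    return posteriors, X
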