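"""Hierarchical LBA estimation by DE-MCMC on a small synthetic cohort.

Generates 6 controls and 6 patients (the patients' neutral drift is
lower by the configured gap), fits the drift-varying model variant to
each group separately, checks convergence, and compares the group-level
neutral drifts via the 95% highest-posterior-density interval of the
difference distribution.
"""

from affectpipe.cohort import CohortConfig, generate_cohort
from affectpipe.hierarchical import (SamplerConfig, compare_groups,
                                     run_hierarchical)

cohort = generate_cohort(CohortConfig(n_controls=6, n_patients=6, seed=3,
                                      neutral_drift_gap=0.4),
                         include_bold=False)
trials = cohort.trials

fits = {}
for group in ("control", "MDD"):
    sub = trials[trials["group"] == group]
    post, report = run_hierarchical(
        sub, "M_v", SamplerConfig(burnin=300, samples=600, thin=10, seed=1))
    fits[group] = post
    print(f"{group:8s}: {post.group_draws.shape[0]} chains, "
          f"{post.n_stored} stored draws, "
          f"multivariate split-half R-hat = {report.mpsrf:.2f}")

diff = compare_groups(fits["control"], fits["MDD"], "v_true.neutral")
lo, hi = diff.interval
print(f"\nDelta v_neutral (control - patient) = {diff.mean:.2f}, "
      f"95% HPDI [{lo:.2f}, {hi:.2f}]")
print("significant" if diff.significant else "not significant",
      "- the interval excludes zero" if diff.significant
      else "- the interval covers zero")
print("(generating gap 0.4; a 6+6 demo recovers the direction but is")
print(" underpowered for the 95% HPDI rule - see docs/methods.md)")
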