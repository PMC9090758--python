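"""End-to-end orchestration of the synthetic study analysis.

``run_pipeline`` executes the stages in their scientific order —
cohort generation, hierarchical LBA fits per group, ELPD model
selection, group comparison, posterior-predictive check, DCM inversion,
PEB with model reduction, and LOOCV classification — and records a JSON
manifest of inputs, outputs, seeds and wall times.  A stage failure
aborts everything downstream and is recorded in the manifest.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cohort as cohort_mod, io, stats
from .diagnostics import elpd_compare
from .dcm import (DCMPriors, build_design_matrix, greedy_prune_and_average,
                  loocv_classify, peb_fit, variational_laplace)
from .hierarchical import (SamplerConfig, compare_groups,
                           posterior_predictive_cohort, run_hierarchical,
                           subsample_cohort)

STAGES = ("cohort", "lba_fit", "model_selection", "group_comparison",
          "ppc", "dcm_inversion", "peb", "loocv")


@dataclass
class RunConfig:
    out_dir: str = "affectpipe_run"
    seed: int = 0
    stages: tuple = STAGES
    data_dir: str | None = None         # required when "cohort" is skipped
    cohort: cohort_mod.CohortConfig = None
    sampler: SamplerConfig = None
    variants: tuple = ("M_v", "M_B", "M_null")
    selected_variant: str = "M_v"
    compare_parameters: tuple = ("v_true.neutral", "v_true.positive",
                                 "v_true.negative", "v_true.shapes")
    ppc_n_per_group: int = 50
    dcm_max_iter: int = 24
    peb_covariates: tuple = ("group", "SSRI", "sex", "age", "handedness")
    log_level: str = "INFO"

    def validate(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "cohort" not in self.stages and self.data_dir is None:
            raise ValueError("no cohort stage and no data_dir configured")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Build a run configuration from a YAML (or JSON) file.

        Top-level keys map to :class:`RunConfig` fields; the ``cohort``
        and ``sampler`` blocks map to their respective config
        dataclasses.
        """
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = cohort_mod.CohortConfig(**raw["cohort"])
        if "sampler" in raw and raw["sampler"] is not None:
            raw["sampler"] = SamplerConfig(**raw["sampler"])
        for key in ("stages", "variants", "compare_parameters",
                    "peb_covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    config.validate()
    from . import __version__
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "stages": {}, "outputs": []}
    state: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            files = _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:  # noqa: BLE001 - recorded, then aborted
            manifest["stages"][stage] = {"status": "failed", "error": str(exc),
                                         "seconds": round(time.time() - t0, 2)}
            break
        manifest["stages"][stage] = {"status": "completed",
                                     "seconds": round(time.time() - t0, 2)}
        manifest["outputs"] += [str(f) for f in files]
    path = io.write_json(manifest, out / "manifest.json")
    manifest["outputs"].append(str(path))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_cohort(config, state, out):
    cc = config.cohort or cohort_mod.CohortConfig(seed=config.seed)
    coh = cohort_mod.generate_cohort(cc)
    state["cohort"] = coh
    state["trials"] = coh.trials
    return [io.write_trials(coh.trials, out / "trials.tsv")]


def _stage_lba_fit(config, state, out):
    sc = config.sampler or SamplerConfig(seed=config.seed)
    trials = state["trials"]
    files = []
    state["fits"] = {}
    for gi, group in enumerate(sorted(trials["group"].unique())):
        gtrials = trials[trials["group"] == group]
        fits = {}
        for vi, variant in enumerate(config.variants):
            cfg = SamplerConfig(**{**sc.__dict__,
                                   "seed": sc.seed + 101 * gi + 7 * vi})
            post, report = run_hierarchical(gtrials, variant, cfg,
                                            label=f"{group}:{variant}")
            fits[variant] = (post, report)
            files.append(io.write_json(
                {"group": group, "variant": variant, "mpsrf": report.mpsrf,
                 "passed": report.passed,
                 "max_psrf": float(np.max(report.psrf))},
                out / f"fit_{group}_{variant}.json"))
        state["fits"][group] = fits
    return files


def _stage_model_selection(config, state, out):
    files = []
    state["selection"] = {}
    for group, fits in state["fits"].items():
        cmp_ = elpd_compare({v: post.pointwise_loglik
                             for v, (post, _) in fits.items()})
        state["selection"][group] = cmp_
        files.append(io.write_json(
            {"group": group, "names": cmp_.names, "elpd": cmp_.elpd,
             "se": cmp_.se, "winner": cmp_.winner},
            out / f"model_selection_{group}.json"))
    return files


def _stage_group_comparison(config, state, out):
    variant = config.selected_variant
    groups = sorted(state["fits"])  # MDD < control alphabetically
    ctrl = state["fits"]["control"][variant][0]
    pat = state["fits"]["MDD"][variant][0]
    rows = {}
    for par in config.compare_parameters:
        diff = compare_groups(ctrl, pat, par)
        rows[par] = {"mean": diff.mean, "hpdi": list(diff.interval),
                     "significant": diff.significant}
    state["group_comparison"] = rows
    return [io.write_json(rows, out / "group_comparison.json")]


def _stage_ppc(config, state, out):
    variant = config.selected_variant
    fits = {g: state["fits"][g][variant][0] for g in state["fits"]}
    sim = posterior_predictive_cohort(fits, n_per_group=config.ppc_n_per_group,
                                      seed=config.seed)
    n_c = min(33, config.ppc_n_per_group)
    n_p = min(30, config.ppc_n_per_group)
    sub = subsample_cohort(sim, n_controls=n_c, n_patients=n_p,
                           seed=config.seed)
    table = stats.behavioral_stats(sub)
    state["ppc_stats"] = table
    return [io.write_trials(sub, out / "ppc_subsample.tsv"),
            io.write_json(table.to_dict(orient="records"),
                          out / "ppc_stats.json")]


def _stage_dcm_inversion(config, state, out):
    coh = state["cohort"]
    priors = DCMPriors()
    posteriors, order = [], []
    for sid, rec in coh.subjects.items():
        post = variational_laplace(rec.bold, priors,
                                   max_iter=config.dcm_max_iter)
        posteriors.append(post)
        order.append(sid)
    state["posteriors"] = posteriors
    state["subject_order"] = order
    summary = {sid: {"F": p.free_energy, "iterations": p.n_iter}
               for sid, p in zip(order, posteriors)}
    return [io.write_json(summary, out / "dcm_inversion.json")]


def _stage_peb(config, state, out):
    coh = state["cohort"]
    table = coh.participants.set_index("subject_id").loc[
        state["subject_order"]].reset_index()
    X, names = build_design_matrix(table, covariates=config.peb_covariates)
    state["X"], state["covariate_names"] = X, names
    files = []
    state["peb"] = {}
    for block in ("A", "Bpos", "Bneg"):
        peb = peb_fit(state["posteriors"], X, param_subset=block,
                      covariate_names=names)
        peb = greedy_prune_and_average(peb)
        state["peb"][block] = peb
        files.append(io.write_json(
            {"block": block, "params": peb.param_names,
             "group_effect": peb.effect("group", "bma_mean"),
             "group_pp": peb.effect_pp("group")},
            out / f"peb_{block}.json"))
    return files


def _stage_loocv(config, state, out):
    res = loocv_classify(state["posteriors"], state["X"],
                         state["covariate_names"], param_subset="A",
                         seed=config.seed)
    state["loocv"] = res
    return [io.write_json(
        {"auc": res.auc, "ci": list(res.auc_ci),
         "probabilities": res.probabilities, "labels": res.labels,
         "skipped": list(res.skipped)}, out / "loocv.json")]


_STAGE_FUNCS = {
    "cohort": _stage_cohort,
    "lba_fit": _stage_lba_fit,
    "model_selection": _stage_model_selection,
    "group_comparison": _stage_group_comparison,
    "ppc": _stage_ppc,
    "dcm_inversion": _stage_dcm_inversion,
    "peb": _stage_peb,
    "loocv": _stage_loocv,
}
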