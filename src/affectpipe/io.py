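"""Plain-text I/O: trial tables, BIDS-style events, BOLD sessions, reports.

Everything is TSV or JSON so outputs diff cleanly in tests.  Floats are
written with 17 significant digits, which round-trips IEEE doubles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dcm.model import REGIONS, BoldSession, build_task_inputs

_FLOAT_FMT = "%.17g"

TRIAL_COLUMNS = ("subject_id", "group", "condition", "block", "onset",
                 "response", "rt", "correct")


def write_trials(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    trials.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(bool)
    return df


def write_events(events: pd.DataFrame, trials: pd.DataFrame, path) -> Path:
    """BIDS-style events.tsv: onset, duration, trial_type, response_time."""
    out = pd.DataFrame({
        "onset": events["onset"],
        "duration": events["duration"],
        "trial_type": events["condition"],
        "response_time": trials["rt"] if trials is not None else np.nan,
    })
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bold(session: BoldSession, path, sidecar_path=None) -> Path:
    path = Path(path)
    pd.DataFrame(session.data.T, columns=list(REGIONS)).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(
            {"tr": session.tr, "n_volumes": session.n_volumes,
             "seed": session.seed, "noise_sd": session.noise_sd,
             "units": "percent signal change"}, indent=1))
    return path


def read_bold(path, sidecar_path=None, events=None,
              oversample: int = 16) -> BoldSession:
    """Load a BOLD TSV (+ JSON sidecar); rebuilds task inputs from events."""
    df = pd.read_csv(path, sep="\t")
    tr, seed, noise_sd = 1.6, None, None
    if sidecar_path is not None:
        meta = json.loads(Path(sidecar_path).read_text())
        tr = meta.get("tr", tr)
        seed = meta.get("seed")
        noise_sd = meta.get("noise_sd")
    data = df.to_numpy(float).T
    inputs, micro_dt = None, None
    if events is not None:
        micro_dt = tr / oversample
        inputs = build_task_inputs(events, micro_dt, data.shape[1] * tr)
    return BoldSession(data=data, tr=tr, inputs=inputs, micro_dt=micro_dt,
                       seed=seed, noise_sd=noise_sd)


def write_group_draws(post, path) -> Path:
    """Columnar TSV of group-level draws: chain, iteration, parameter, value."""
    chains, stored, d = post.group_draws.shape
    names = post.group_param_names
    rows = {
        "chain": np.repeat(np.arange(chains), stored * d),
        "iteration": np.tile(np.repeat(np.arange(stored), d), chains),
        "parameter": np.tile(names, chains * stored),
        "value": post.group_draws.reshape(-1),
    }
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_subject_posterior(post, path) -> Path:
    """Serialise a DCM subject posterior (mean, covariance, F) as JSON."""
    return write_json({
        "param_names": list(post.param_names),
        "mean": post.mean,
        "cov": post.cov,
        "free_energy": post.free_energy,
        "log_precision": post.log_precision,
        "prior_mean": post.prior_mean,
        "prior_cov": post.prior_cov,
    }, path)


def read_subject_posterior(path):
    """Load a DCM subject posterior written by write_subject_posterior."""
    import json as _json

    from .dcm.invert import SubjectPosterior
    d = _json.loads(Path(path).read_text())
    return SubjectPosterior(
        mean=np.asarray(d["mean"]), cov=np.asarray(d["cov"]),
        free_energy=d["free_energy"], log_precision=d["log_precision"],
        param_names=tuple(d["param_names"]),
        prior_mean=np.asarray(d["prior_mean"]),
        prior_cov=np.asarray(d["prior_cov"]))
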