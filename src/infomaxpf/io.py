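"""File formats: trial tables (CSV), posteriors (JSON), configs (YAML).

Trial table dialect: comma-separated, UTF-8, mandatory header
``trial,x_1,...,x_d,response`` with '.' decimals and 1-based integer
response codes (an omission, if recorded, is mapped to the highest code by
convention).  Canonically formatted tables round-trip byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .laplace import GaussianPosterior
from .mcmc import SampleSet
from .model import ModelParams, ParamLayout
from .space import StimulusSpace, grid_candidates, normalize_space

__all__ = [
    "load_trial_csv",
    "save_trial_csv",
    "save_samples_csv",
    "posterior_to_dict",
    "posterior_from_dict",
    "save_posterior_json",
    "load_posterior_json",
    "space_from_spec",
    "load_config_yaml",
]


def save_trial_csv(path, stimuli: np.ndarray, responses: np.ndarray) -> None:
    """Write a trial table (raw stimuli, 1-based response codes)."""
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    responses = np.asarray(responses, dtype=int)
    d = stimuli.shape[1]
    df = pd.DataFrame(
        {"trial": np.arange(1, stimuli.shape[0] + 1)}
        | {f"x_{i+1}": stimuli[:, i] for i in range(d)}
        | {"response": responses}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def load_trial_csv(path, n_categories: int | None = None):
    """Read a trial table; returns (stimuli (n, d), responses 1-based).

    Validates that response codes are integers in 1..k (k inferred from the
    data when not given); offending rows are listed in the error.
    """
    df = pd.read_csv(path)
    xcols = [c for c in df.columns if c.startswith("x_")]
    required = {"trial", "response"}
    if not required.issubset(df.columns) or not xcols:
        raise ValueError(
            f"trial table must have columns trial, x_1..x_d, response; "
            f"got {list(df.columns)}"
        )
    responses = df["response"].to_numpy()
    if len(df):
        if not np.all(responses == responses.astype(int)):
            raise ValueError("response codes must be integers")
        responses = responses.astype(int)
        k = n_categories if n_categories is not None else int(responses.max())
        bad = np.nonzero((responses < 1) | (responses > k))[0]
        if bad.size:
            raise ValueError(
                f"response codes outside 1..{k} at rows "
                f"{(bad + 2).tolist()} (1-based, counting the header)"
            )
    else:
        responses = responses.astype(int)
    stimuli = df[sorted(xcols, key=lambda c: int(c.split("_")[1]))].to_numpy(
        dtype=float
    )
    return stimuli, responses


def save_samples_csv(path, samples: SampleSet) -> None:
    """Audit dump of an MH sample set: one row per posterior sample."""
    cols = {
        f"theta_{i+1}": samples.samples[:, i]
        for i in range(samples.samples.shape[1])
    }
    cols["log_post"] = samples.log_post_values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def _layout_dict(layout: ParamLayout) -> dict:
    return {
        "n_categories": layout.n_categories,
        "n_features": layout.n_features,
        "lapse_mode": layout.lapse_mode,
        "ref_category": layout.ref_category,
    }


def posterior_to_dict(state: GaussianPosterior | SampleSet) -> dict:
    """Serializable posterior representation (mode/cov or samples)."""
    if isinstance(state, GaussianPosterior):
        layout = state.layout
        return {
            "kind": "gaussian",
            "layout": _layout_dict(layout),
            "mode": layout.pack(state.mode).tolist(),
            "covariance": state.cov.ravel().tolist(),  # row-major
            "covariance_ww": state.cov_ww.ravel().tolist(),
        }
    return {
        "kind": "samples",
        "layout": _layout_dict(state.layout),
        "samples": state.samples.tolist(),
        "acceptance_rate": state.acceptance_rate,
    }


def posterior_from_dict(payload: dict):
    layout = ParamLayout(**payload["layout"])
    if payload["kind"] == "gaussian":
        n = layout.n_free
        nw = layout.n_weights
        cov = np.asarray(payload["covariance"], dtype=float).reshape(n, n)
        cov_ww = np.asarray(payload["covariance_ww"], dtype=float).reshape(nw, nw)
        sign, logdet = np.linalg.slogdet(cov)
        return GaussianPosterior(
            mode=layout.unpack(np.asarray(payload["mode"], dtype=float)),
            cov=cov,
            cov_ww=cov_ww,
            log_det_cov=float(logdet),
        )
    samples = np.asarray(payload["samples"], dtype=float)
    return SampleSet(
        samples=samples,
        log_post_values=np.full(samples.shape[0], np.nan),
        acceptance_rate=float(payload.get("acceptance_rate", np.nan)),
        proposal_cov_used=np.eye(layout.n_free),
        layout=layout,
    )


def save_posterior_json(path, state) -> None:
    Path(path).write_text(
        json.dumps(posterior_to_dict(state), sort_keys=True) + "\n"
    )


def load_posterior_json(path):
    return posterior_from_dict(json.loads(Path(path).read_text()))


def space_from_spec(spec: dict) -> StimulusSpace:
    """Build a stimulus space from a grid spec or explicit candidate list.

    Grid form: ``{"min": [...], "max": [...], "n_points": int or [...]}``;
    explicit form: ``{"candidates": [[...], ...]}``.  Optional key
    ``normalize`` (default true).
    """
    normalize = bool(spec.get("normalize", True))
    if "candidates" in spec:
        raw = np.asarray(spec["candidates"], dtype=float)
        if raw.ndim == 1:
            raw = raw[:, None]
    elif {"min", "max", "n_points"}.issubset(spec):
        raw = grid_candidates(spec["min"], spec["max"], spec["n_points"])
    else:
        raise ValueError(
            "space spec needs either 'candidates' or 'min'/'max'/'n_points'"
        )
    return normalize_space(raw, normalize=normalize)


def load_config_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg
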