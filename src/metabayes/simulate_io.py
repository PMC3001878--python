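"""Synthetic-observer simulation and trial-data file I/O.

The simulator runs the generative direction of the framework: draw a hidden
state, draw sensory inputs, run the subject's (Bayes-optimal) recognition and
decision, add Gaussian response noise.  A single integer seed fully
determines every draw, so two runs with the same configuration are
bit-identical.  Trial tables are exchanged as plain CSV
(``trial,input_0...,response_0...``) with a JSON sidecar carrying metadata;
round trips are lossless (floats written at 17 significant digits).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError
from .inversion import TrialData
from .toy_gauss import ToyObserverConfig, toy_optimal_n, toy_response_map

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Everything the simulator needs; the seed pins all randomness.

    ``input_generator`` describes the distribution of the true signal means:
    by default the subject is well calibrated, i.e. the world draws the
    hidden mean from the subject's own prior N(prior_mean, 1/beta).
    ``signal_scale`` multiplies the drawn sensory samples (used to study how
    input power affects experimenter-level identifiability).
    """

    observer: ToyObserverConfig
    n_trials: int
    seed: int
    input_generator: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        known = {"signal_mean_loc", "signal_mean_sd", "signal_scale"}
        unknown = set(self.input_generator) - known
        if unknown:
            raise ConfigError(f"unknown input_generator keys: {sorted(unknown)}")
        for key in ("signal_mean_sd", "signal_scale"):
            if key in self.input_generator and self.input_generator[key] <= 0:
                raise ConfigError(f"input_generator[{key!r}] must be positive")


def simulate_observer(config: SimulationConfig) -> TrialData:
    """Simulate trial-wise behaviour of the toy Bayesian observer.

    Per trial: draw the true signal mean, draw the subject's n* unit-variance
    samples, compute the deterministic optimal response (posterior-mean
    estimate, optimal sample size), then add zero-mean Gaussian response
    noise per channel.  Ground truth and settings land in ``meta``.
    """
    obs = config.observer
    gen = config.input_generator
    loc = gen.get("signal_mean_loc", obs.prior_mean)
    sd = gen.get("signal_mean_sd", 1.0 / np.sqrt(obs.beta))
    scale = gen.get("signal_scale", 1.0)
    rng = np.random.default_rng(config.seed)
    n_star = toy_optimal_n(obs.beta, obs.k)
    v_est, v_n = obs.channel_variances

    inputs, responses, truth_means = [], [], []
    for _ in range(config.n_trials):
        x = loc + sd * rng.standard_normal()
        u = scale * (x + np.sqrt(obs.signal_variance) * rng.standard_normal(n_star))
        if n_star > 0:
            est, n_chosen = toy_response_map(obs, x, u)
        else:
            est, n_chosen = obs.prior_mean, 0
        noise = rng.standard_normal(2) * np.sqrt([v_est, v_n])
        inputs.append(u)
        responses.append(np.array([est, float(n_chosen)]) + noise)
        truth_means.append(x)

    return TrialData(
        inputs=inputs,
        responses=responses,
        labels=("estimate", "sample_size"),
        meta={
            "seed": config.seed,
            "n_trials": config.n_trials,
            "true_parameters": {
                "beta": obs.beta, "k": obs.k, "sigma2": obs.sigma2,
                "prior_mean": obs.prior_mean,
            },
            "optimal_sample_size": n_star,
            "input_generator": dict(gen),
            "true_signal_means": truth_means,
        },
    )


# ---------------------------------------------------------------------------
# CSV / JSON round trip
# ---------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_trials(data: TrialData, path) -> None:
    """Write a trial table as CSV plus a JSON metadata sidecar.

    Columns: ``trial``, ``input_<j>``, ``response_<j>``; 0-based trial index;
    ragged inputs and missing responses appear as empty fields.
    """
    path = Path(path)
    n_in = max(u.size for u in data.inputs)
    n_resp = max(y.size for y in data.responses)
    rows = []
    for t, (u, y) in enumerate(zip(data.inputs, data.responses)):
        row: dict = {"trial": t}
        for j in range(n_in):
            row[f"input_{j}"] = u[j] if j < u.size else np.nan
        for j in range(n_resp):
            row[f"response_{j}"] = y[j] if j < y.size else np.nan
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {"labels": list(data.labels) if data.labels else None, "meta": data.meta}
    with open(_meta_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, default=float)


def read_trials(path) -> TrialData:
    """Read a trial table written by :func:`write_trials` (tolerant reader).

    Unknown columns are preserved in ``meta['extra_columns']`` with a
    warning; malformed cells raise :class:`ParseError` naming row and column;
    an empty table is a precondition violation.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    if "trial" not in frame.columns:
        raise ParseError("missing required column 'trial'")
    if len(frame) == 0:
        raise ParseError("trial file contains no rows (need T >= 1)")

    input_cols = sorted((c for c in frame.columns if c.startswith("input_")),
                        key=lambda c: int(c.split("_")[1]))
    resp_cols = sorted((c for c in frame.columns if c.startswith("response_")),
                       key=lambda c: int(c.split("_")[1]))
    known = {"trial", *input_cols, *resp_cols}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        warnings.warn(f"ignoring unknown columns {extra}; preserved in meta", UserWarning)
    if not input_cols or not resp_cols:
        raise ParseError("need at least one input_<j> and one response_<j> column")

    def parse_cell(value, row, col):
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            return np.nan
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ParseError(f"non-numeric cell at row {row}, column {col!r}: {value!r}")

    inputs, responses = [], []
    for idx, rec in frame.iterrows():
        t = parse_cell(rec["trial"], idx, "trial")
        if not float(t).is_integer() or int(t) != idx:
            raise ParseError(f"trial index at row {idx} is {rec['trial']!r}; expected {idx}")
        u = np.array([parse_cell(rec[c], idx, c) for c in input_cols])
        y = np.array([parse_cell(rec[c], idx, c) for c in resp_cols])
        inputs.append(u[~np.isnan(u)])  # ragged trials pad with empty fields
        responses.append(y)

    meta, labels = {}, None
    meta_file = _meta_path(path)
    if meta_file.exists():
        with open(meta_file, encoding="utf-8") as fh:
            side = json.load(fh)
        meta = side.get("meta", {})
        labels = side.get("labels")
    if extra:
        meta["extra_columns"] = {c: frame[c].tolist() for c in extra}
    return TrialData(inputs=inputs, responses=responses, labels=labels, meta=meta)
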