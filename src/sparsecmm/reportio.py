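"""Fit-report JSON serialization."""

from __future__ import annotations

import json
import math

import numpy as np

from .contingency import pattern_to_string, string_to_pattern
from .estimator import FitResult

__all__ = ["fit_report_dict", "write_fit_report", "read_fit_report"]


def _num(x):
    if x is None:
        return None
    x = float(x)
    if math.isnan(x):
        return None
    if math.isinf(x):
        return "inf"
    return x


def fit_report_dict(result: FitResult, cats) -> dict:
    """JSON-ready report: model, method, support sizes, m̂ by pattern,
    multipliers, fit statistics, parameters and diagnostics."""
    cats = tuple(int(c) for c in cats)
    m_map = {
        pattern_to_string(p, cats): float(v)
        for p, v in zip(result.support, result.m_hat)
    }
    return {
        "model": result.model_name,
        "method": result.method,
        "cats": list(cats),
        "N": result.N,
        "support_size": len(result.support),
        "n_observed_cells": int(np.sum(result.n > 0)),
        "m_hat": m_map,
        "lambda": [float(v) for v in result.lam],
        "G2": _num(result.G2),
        "G2_truncated": _num(result.G2_truncated),
        "X2": _num(result.X2),
        "df": result.df,
        "p_value": _num(result.p_value),
        "beta": None if result.beta is None else [float(b) for b in result.beta],
        "beta_se": None if result.beta_se is None else [float(b) for b in result.beta_se],
        "overall_mean": _num(result.overall_mean),
        "overall_mean_se": _num(result.overall_mean_se),
        "iterations": result.iterations,
        "converged": bool(result.converged),
        "boundary_cells": [
            pattern_to_string(result.support[i], cats) for i in result.boundary_cells
        ],
        "max_constraint_violation": _num(result.max_constraint),
        "seed": result.seed,
        "augmented_cells": None
        if result.plan is None
        else [pattern_to_string(p, cats) for p in result.plan.added_cells],
    }


def write_fit_report(result: FitResult, cats, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_report_dict(result, cats), fh, indent=2)


def read_fit_report(path) -> dict:
    """Reload a report; 'm_hat' keys are parsed back into patterns under
    'm_hat_patterns' for use as warm-start values."""
    with open(path) as fh:
        doc = json.load(fh)
    doc["m_hat_patterns"] = {
        string_to_pattern(k): v for k, v in doc.get("m_hat", {}).items()
    }
    return doc
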