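"""Assessment report orchestration.

``run_report`` wires the whole pipeline together for one score set: metric
suite with bootstrap CIs, ROC points, local calibration curve, evidence-level
score thresholds, and the prior-corrected fraction of variants reaching each
level. The result is a plain dict (JSON-serializable) with a text rendering
for terminals.
"""

from __future__ import annotations

import json
import math
from typing import Union

import numpy as np

from . import binary_metrics, continuous_metrics
from .data_io import AnalysisConfig, ContinuousPairs, LabeledScores
from .evidence_model import EvidenceModel, evidence_thresholds, fraction_reaching
from .local_calibration import local_posterior
from .prior_transfer import PriorSpec, transfer_report
from .uncertainty import bootstrap_metric

__all__ = ["run_report", "render_text", "to_json"]

_CONTINUOUS_METRICS = {
    "r2": continuous_metrics.r_squared,
    "rmse": continuous_metrics.rmse,
    "pearson": continuous_metrics.pearson,
    "spearman": continuous_metrics.spearman,
    "kendall_tau_b": continuous_metrics.kendall_tau_b,
}


def _json_safe(x):
    if isinstance(x, float) and not math.isfinite(x):
        return str(x)
    if isinstance(x, (np.floating, np.integer)):
        return _json_safe(float(x))
    if isinstance(x, np.ndarray):
        return [_json_safe(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    return x


def _with_ci(data, metric, config: AnalysisConfig, seed_offset: int) -> dict:
    res = bootstrap_metric(data, metric,
                           iterations=config.bootstrap_iterations,
                           level=config.ci_level,
                           seed=config.rng_seed + seed_offset)
    return {"value": res.point, "ci_low": res.ci_low, "ci_high": res.ci_high}


def run_report(config: AnalysisConfig,
               data: Union[LabeledScores, ContinuousPairs]) -> dict:
    """Full machine-readable report for a binary or continuous score set."""
    if isinstance(data, ContinuousPairs):
        metrics = {
            name: _with_ci(data, fn, config, i + 1)
            for i, (name, fn) in enumerate(_CONTINUOUS_METRICS.items())
        }
        return {"kind": "continuous", "n": len(data), "metrics": metrics}

    data.require_both_classes()
    if config.evidence_constant == "solve":
        raise ValueError("run_report needs a numeric evidence constant; "
                         "call solve_c with a rule list first")

    metrics = {
        "auc": _with_ci(data, binary_metrics.auc, config, 1),
        "truncated_auc": _with_ci(
            data, lambda d: binary_metrics.truncated_auc(d, config.truncation_fpr),
            config, 2),
    }
    curve = local_posterior(data, config=config)
    model = EvidenceModel(c=float(config.evidence_constant),
                          prior=config.target_prior)
    thresholds = evidence_thresholds(curve, model)
    fractions = fraction_reaching(data, thresholds, config.target_prior)
    prior = PriorSpec(alpha_target=config.target_prior, alpha_test=curve.test_prior)
    table = transfer_report(curve, data, prior, model=model)
    roc = binary_metrics.roc_curve(data)

    return {
        "kind": "binary",
        "n": len(data),
        "n_positive": data.n_positive,
        "test_prior": data.test_prior,
        "target_prior": config.target_prior,
        "evidence_constant": float(config.evidence_constant),
        "metrics": metrics,
        "roc": {
            "threshold": roc.thresholds.tolist(),
            "fpr": roc.fpr.tolist(),
            "tpr": roc.tpr.tolist(),
        },
        "calibration": {
            "score": curve.grid.tolist(),
            "posterior_test": curve.posterior_test.tolist(),
            "lr_plus": curve.lr_plus.tolist(),
            "window_count": curve.window_count.tolist(),
            "epsilon": curve.epsilon,
        },
        "evidence": {
            level: {
                "lr_requirement": model.level_requirements[level],
                "score_threshold": thresholds[level],
                "score_threshold_original": (
                    None if thresholds[level] is None
                    else data.to_original_scale(thresholds[level])),
                "fraction_reaching": fractions[level],
            }
            for level in model.level_requirements
        },
        "transfer_table": table.to_dict(orient="list"),
    }


def to_json(report: dict, path=None, indent: int = 2) -> str:
    text = json.dumps(_json_safe(report), indent=indent)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def render_text(report: dict) -> str:
    """Compact human-readable summary of a run_report result."""
    lines = [f"varcal report ({report['kind']}, n={report['n']})"]
    for name, m in report["metrics"].items():
        lines.append(f"  {name:>14s}: {m['value']:8.4f}  "
                     f"[{m['ci_low']:.4f}, {m['ci_high']:.4f}]")
    if report["kind"] == "binary":
        lines.append(f"  test prior alpha_D = {report['test_prior']:.4f}, "
                     f"target prior alpha = {report['target_prior']:.4f}, "
                     f"c = {report['evidence_constant']:g}")
        lines.append("  evidence level   lr+ required   score threshold   fraction reaching")
        for level, row in report["evidence"].items():
            tau = row["score_threshold_original"]
            tau_s = "   (not reached)" if tau is None else f"{tau:16.4f}"
            frac = row["fraction_reaching"]
            frac_s = "" if frac is None else f"{frac:12.3f}"
            lines.append(f"  {level:>14s} {row['lr_requirement']:14.2f} {tau_s} {frac_s}")
    return "\n".join(lines)
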