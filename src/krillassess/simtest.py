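"""Operating-model / estimating-model simulation tests.

A fitted configuration (the operating model) generates error-free
pseudo-data: its predicted indices, compositions and catches replace the
observations while years, CVs and effective sample sizes stay as in the
original bundle.  An estimating configuration is then refitted to the
pseudo-data from the standard initial values.  When operating and
estimating structures coincide this is a self-test (the refit should
recover the operating trajectories); when they differ it is a cross-test
(structural process error shows up as divergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
import copy

import numpy as np
import pandas as pd

from .config import Configuration
from .core import DataBundle, ModelStructure, PopulationTrajectory, project
from .errors import ConfigurationError
from .estimation import FitResult, ReplicateSummary, run_replicates, TIE_TOL

__all__ = ["SimTestReport", "generate_pseudodata", "self_test", "cross_test"]

#: Default recovery tolerance (relative error) for self-test trajectories.
RECOVERY_TOL = 0.01


def generate_pseudodata(fit: FitResult, data_template: DataBundle) -> DataBundle:
    """Error-free pseudo-data: model-predicted values in the template's design."""
    traj = project(fit.params, data_template)
    y0, y1 = data_template.year_range
    if traj.years[0] != y0 or traj.years[-1] != y1:
        raise ConfigurationError("data template years do not match the fitted model")
    pseudo = copy.deepcopy(data_template)
    for i, sv in enumerate(pseudo.surveys):
        sv.index_values = traj.predicted_index[i].copy()
        sv.comp_props = traj.predicted_comp[i].copy()
    pseudo.fishery.catches = traj.predicted_catch.copy()
    pseudo.fishery.comp_props = traj.predicted_fishery_comp.copy()
    pseudo.validate()
    return pseudo


@dataclass
class SimTestReport:
    """Recovery summary of one operating/estimating pair."""

    operating: str
    estimating: str
    is_self_test: bool
    replicate_nlls: list[float]
    n_tied_best: int
    rel_err: dict[str, np.ndarray]  # per-year relative errors, keyed by quantity
    max_abs_rel_err: dict[str, float]
    passes: dict[str, bool]
    f_bias_high: float  # mean signed rel. error of F in top-quartile-F years
    high_f_years: np.ndarray
    operating_fit: FitResult = field(repr=False, default=None)
    estimating_fit: FitResult = field(repr=False, default=None)
    estimating_summary: ReplicateSummary = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q, errs in self.rel_err.items():
            rows.append(
                {
                    "quantity": q,
                    "max_abs_rel_err": self.max_abs_rel_err[q],
                    "pass": self.passes[q],
                }
            )
        return pd.DataFrame(rows)


def _compare(
    op_traj: PopulationTrajectory,
    est_traj: PopulationTrajectory,
    tol: float,
    op_qf: float = 1.0,
    est_qf: float = 1.0,
) -> tuple[dict, dict, dict, float, np.ndarray]:
    # with catchability estimated, only the product q_f * F_y is identified
    # (q_f and F slide along a ridge); the effective-F series carries the
    # fishing-mortality comparison and the high-F bias summary
    quantities = {
        "R_y": (op_traj.R_y, est_traj.R_y),
        "SSB_y": (op_traj.SSB_y, est_traj.SSB_y),
        "F_y": (op_qf * op_traj.F_y, est_qf * est_traj.F_y),
        "catch": (op_traj.predicted_catch, est_traj.predicted_catch),
    }
    rel_err, max_err, passes = {}, {}, {}
    for q, (op, est) in quantities.items():
        err = (np.asarray(est) - np.asarray(op)) / np.maximum(np.abs(op), 1e-300)
        rel_err[q] = err
        max_err[q] = float(np.max(np.abs(err))) if len(err) else 0.0
        passes[q] = bool(max_err[q] <= tol)
    # top-quartile operating F years define the high-F bias summary
    q75 = np.quantile(op_traj.F_y, 0.75)
    high = op_traj.F_y >= q75
    f_bias = float(np.mean(rel_err["F_y"][high])) if high.any() else 0.0
    return rel_err, max_err, passes, f_bias, op_traj.years[high]


def cross_test(
    operating_config: Configuration,
    estimating_config: Configuration,
    data: DataBundle,
    structure: ModelStructure | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    tol: float = RECOVERY_TOL,
    operating_fit: FitResult | None = None,
    estimating_penalties=None,
    **fit_kwargs,
) -> SimTestReport:
    """Fit the operating configuration, generate pseudo-data, refit under the
    estimating configuration, and report trajectory recovery.

    ``operating_fit`` short-circuits the (expensive) operating fit when it
    has already been computed; ``estimating_penalties`` overrides the
    penalty stack of the refit only (used for the F-penalty experiments).
    Refit non-convergence is reported in the summary, not raised.
    """
    if operating_fit is None:
        _, op_summary = run_replicates(
            operating_config,
            data,
            structure,
            n_replicates=1,
            seed=seed,
            **fit_kwargs,
        )
        operating_fit = _[op_summary.best_index]
    pseudo = generate_pseudodata(operating_fit, data)
    est_cfg = estimating_config
    if estimating_penalties is not None:
        est_cfg = dc_replace(est_cfg, penalties=estimating_penalties)
    fits, summary = run_replicates(
        est_cfg,
        pseudo,
        structure,
        n_replicates=n_replicates,
        seed=seed + 1,
        **fit_kwargs,
    )
    best = fits[summary.best_index]
    op_traj = project(operating_fit.params, data)
    est_traj = project(best.params, pseudo)
    rel_err, max_err, passes, f_bias, high_years = _compare(
        op_traj,
        est_traj,
        tol,
        op_qf=float(np.exp(operating_fit.params.ln_q_f)),
        est_qf=float(np.exp(best.params.ln_q_f)),
    )
    nlls = [f.nll for f in fits]
    n_tied = int(np.sum(np.asarray(nlls) <= min(nlls) + TIE_TOL))
    return SimTestReport(
        operating=operating_config.name,
        estimating=estimating_config.name,
        is_self_test=(
            operating_config.estimated_groups == estimating_config.estimated_groups
            and operating_config.survey_sel_subset == estimating_config.survey_sel_subset
        ),
        replicate_nlls=nlls,
        n_tied_best=n_tied,
        rel_err=rel_err,
        max_abs_rel_err=max_err,
        passes=passes,
        f_bias_high=f_bias,
        high_f_years=high_years,
        operating_fit=operating_fit,
        estimating_fit=best,
        estimating_summary=summary,
    )


def self_test(
    config: Configuration,
    data: DataBundle,
    structure: ModelStructure | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    tol: float = RECOVERY_TOL,
    **kwargs,
) -> SimTestReport:
    """Cross-test of a configuration against itself."""
    return cross_test(
        config,
        config,
        data,
        structure,
        n_replicates=n_replicates,
        seed=seed,
        tol=tol,
        **kwargs,
    )
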