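"""Penalized negative log-likelihood of the assessment.

Data components: lognormal deviances for the survey biomass indices and the
fishery catches, multinomial deviances for survey and fishery length
compositions.  Penalty stack: Gaussian recruitment-deviation penalty (L1),
squared deviations of log recruitment from the deterministic Beverton-Holt
curve over model years (L2) and pre-data years (L3), a penalty on the mean
recruitment deviation (L4), a quadratic penalty on fishing-mortality
deviations (L5), and a one-sided quadratic penalty on annual F above a cap
(L6).  Density constants that do not depend on parameters are dropped
consistently, so breakdowns are comparable across configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DataBundle,
    ModelStructure,
    ParameterSet,
    PopulationTrajectory,
    beverton_holt,
    project,
)
from .errors import DataError, InvalidParameterError

__all__ = [
    "PenaltyStack",
    "NLLBreakdown",
    "lognormal_nll",
    "multinomial_nll",
    "recruitment_penalty",
    "f_penalty",
    "total_objective",
]

#: Floor applied to predicted proportions before taking logs, preventing
#: log(0) at knife-edge selectivities.
PROP_FLOOR = 1e-10


@dataclass
class PenaltyStack:
    """Weights of the six penalty components.

    ``lambda1`` scales the likelihood-like Gaussian deviation penalty and is
    normally left at 1.  Setting ``enable_f = False`` (or the L5/L6 weights
    to zero) removes the fishing-mortality penalties entirely.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    lambda4: float = 0.1
    lambda5: float = 0.1
    lambda6: float = 10.0
    f_cap: float = 1.5
    enable_recruitment: bool = True
    enable_f: bool = True

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5", "lambda6"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass
class NLLBreakdown:
    """Per-component negative log-likelihood values; ``total`` is their sum."""

    survey_index: np.ndarray  # per survey
    survey_comp: np.ndarray  # per survey
    fishery_comp: float
    catch: float
    penalties: dict = field(default_factory=dict)  # "L1".."L6"

    @property
    def data_total(self) -> float:
        return np.asarray(
            self.survey_index.sum() + self.survey_comp.sum() + self.fishery_comp + self.catch
        ).item()

    @property
    def penalty_total(self) -> float:
        return np.asarray(sum(self.penalties.values())).item()

    @property
    def total(self) -> float:
        return self.data_total + self.penalty_total

    def as_dict(self) -> dict:
        d = {f"index_survey{i + 1}": float(v) for i, v in enumerate(self.survey_index)}
        d.update({f"comp_survey{i + 1}": float(v) for i, v in enumerate(self.survey_comp)})
        d["comp_fishery"] = float(self.fishery_comp)
        d["catch"] = float(self.catch)
        d.update({k: float(v) for k, v in self.penalties.items()})
        d["total"] = self.total
        return d


def lognormal_nll(observed, predicted, cv, series: str = "", checked: bool = True) -> float:
    """Lognormal deviance with sigma^2 = ln(1 + CV^2), constants dropped.

    Retains the ``ln sigma`` normalization term (it matters when the CV is
    itself estimated); minimized at ``predicted = observed`` for fixed CV.
    ``checked=False`` skips the domain checks when the caller has already
    validated the series.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted)  # may be complex (complex-step gradients)
    cv = np.asarray(cv)
    if checked:
        cv = np.broadcast_to(cv, obs.shape)
        if np.any(obs <= 0) or np.any(np.real(pred) <= 0):
            raise DataError(f"non-positive value in lognormal series {series!r}")
        if np.any(np.real(cv) <= 0):
            raise DataError(f"non-positive CV in lognormal series {series!r}")
    sigma2 = np.log1p(cv**2)
    resid = np.log(obs) - np.log(pred)
    return np.asarray(
        np.sum(resid**2 / (2.0 * sigma2) + 0.5 * np.log(sigma2))
    ).item()


def multinomial_nll(
    observed_props, predicted_props, effective_n, series: str = "", checked: bool = True
) -> float:
    """Multinomial deviance ``-N * sum_b obs_b ln(pred_b)``, constants dropped.

    ``effective_n`` is the effective sample size per composition row;
    predicted proportions are floored at ``PROP_FLOOR`` before the log.
    """
    obs = np.atleast_2d(np.asarray(observed_props, dtype=float))
    pred = np.atleast_2d(np.asarray(predicted_props))
    n = np.broadcast_to(np.asarray(effective_n, dtype=float), obs.shape[:1])
    if checked:
        if np.any(n <= 0):
            raise DataError(f"non-positive effective N in composition series {series!r}")
        for name, arr in (("observed", obs), ("predicted", pred)):
            sums = np.real(arr).sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise DataError(f"{name} compositions in {series!r} must sum to 1")
    logp = np.log(np.where(np.real(pred) < PROP_FLOOR, PROP_FLOOR, pred))
    return np.asarray(-np.sum(n * np.sum(obs * logp, axis=1))).item()


def recruitment_penalty(
    params: ParameterSet,
    trajectory: PopulationTrajectory,
    stack: PenaltyStack,
    structure: ModelStructure | None = None,
) -> dict:
    """Penalties L1-L4 tying recruitment deviations to the stock-recruit curve.

    L1: Gaussian deviation penalty ``sum eps^2 / (2 sigma_R^2) + n ln sigma_R``.
    L2: squared difference between log R_y and log BH(SSB_y), model years.
    L3: the same for pre-data years, evaluated at first-year spawning biomass.
    L4: ``lambda4 * n * (mean eps)^2``, shrinking the mean deviation to zero.
    """
    s = structure or params.structure
    sigma_R = np.exp(params.ln_sigma_R)
    if np.real(sigma_R) <= 0:
        raise InvalidParameterError("sigma_R must be > 0")
    if not stack.enable_recruitment:
        return {"L1": 0.0, "L2": 0.0, "L3": 0.0, "L4": 0.0}
    eps = params.eps_R
    n_eps = eps.size
    l1 = stack.lambda1 * (np.sum(eps**2) / (2.0 * sigma_R**2) + n_eps * np.log(sigma_R))
    r0 = np.exp(params.ln_R0)
    b0 = trajectory.B0
    bh_model = beverton_holt(trajectory.SSB_y, params.h, r0, b0)
    bh_model = np.where(np.real(bh_model) < 1e-300, 1e-300, bh_model)
    l2 = stack.lambda2 * np.sum((np.log(trajectory.R_y) - np.log(bh_model)) ** 2)
    bh_pre = beverton_holt(trajectory.SSB_y[0], params.h, r0, b0)
    if np.real(bh_pre) < 1e-300:
        bh_pre = 1e-300
    l3 = stack.lambda3 * np.sum((np.log(trajectory.R_pre) - np.log(bh_pre)) ** 2)
    l4 = stack.lambda4 * n_eps * np.mean(eps) ** 2
    return {
        "L1": np.asarray(l1).item(),
        "L2": np.asarray(l2).item(),
        "L3": np.asarray(l3).item(),
        "L4": np.asarray(l4).item(),
    }


def f_penalty(
    eps_f: np.ndarray, F_y: np.ndarray, stack: PenaltyStack
) -> dict:
    """Penalties L5-L6 on fishing mortality.

    L5 is a quadratic shrinkage of the annual log-F deviations; L6 is a
    one-sided quadratic penalty on annual F exceeding ``f_cap``.  Both are
    zero when their weights are zero or ``enable_f`` is off.
    """
    if not stack.enable_f:
        return {"L5": 0.0, "L6": 0.0}
    l5 = stack.lambda5 * np.sum(np.asarray(eps_f) ** 2)
    F_y = np.asarray(F_y)
    excess = np.where(np.real(F_y) > stack.f_cap, F_y - stack.f_cap, 0.0)
    l6 = stack.lambda6 * np.sum(excess**2)
    return {"L5": np.asarray(l5).item(), "L6": np.asarray(l6).item()}


def total_objective(
    params: ParameterSet,
    data: DataBundle,
    penalties: PenaltyStack | None = None,
    structure: ModelStructure | None = None,
    trajectory: PopulationTrajectory | None = None,
) -> NLLBreakdown:
    """Full penalized negative log-likelihood with per-component breakdown."""
    stack = penalties if penalties is not None else PenaltyStack()
    if trajectory is None:
        trajectory = project(params, data, structure)
    n_s = len(data.surveys)
    idx_nll = np.zeros(n_s, dtype=trajectory.N.dtype)
    comp_nll = np.zeros(n_s, dtype=trajectory.N.dtype)
    for i, sv in enumerate(data.surveys):
        if len(sv.index_years):
            idx_nll[i] = lognormal_nll(
                sv.index_values,
                trajectory.predicted_index[i],
                sv.index_cvs,
                series=f"{sv.name} index",
                checked=False,
            )
        if len(sv.comp_years):
            comp_nll[i] = multinomial_nll(
                sv.comp_props,
                trajectory.predicted_comp[i],
                sv.effective_n,
                series=f"{sv.name} composition",
                checked=False,
            )
    f = data.fishery
    catch_nll = lognormal_nll(
        f.catches,
        trajectory.predicted_catch,
        params.sigma_C,
        series="fishery catch",
        checked=False,
    )
    fishery_comp_nll = 0.0
    if len(f.comp_years):
        fishery_comp_nll = multinomial_nll(
            f.comp_props,
            trajectory.predicted_fishery_comp,
            f.effective_n,
            series="fishery composition",
            checked=False,
        )
    pen = recruitment_penalty(params, trajectory, stack, structure)
    pen.update(f_penalty(params.eps_f, trajectory.F_y, stack))
    return NLLBreakdown(
        survey_index=idx_nll,
        survey_comp=comp_nll,
        fishery_comp=fishery_comp_nll,
        catch=catch_nll,
        penalties=pen,
    )
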