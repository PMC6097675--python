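"""Synthetic krill-like truths and noisy observations.

The default scenario emulates the structure of the Subarea 48.1 survey and
fishery series the assessment is designed for: six surveys (summer/winter
acoustic, summer/winter IKMT, summer/winter RMT8) contributing 54 years of
biomass indices and 35 years of length compositions, 41 years of fishery
catches and 13 years of fishery compositions (information-criterion sample
size 143).  Index and catch errors are lognormal; composition errors are
multinomial at the stated effective sample sizes.

True parameter values default to the pre-specified initial values of the
assessment, with recruitment deviations drawn at sigma_R = 0.7 and fishing
mortality ramping up over the catch years as a developing fishery would.
Acoustic index CVs default to 0.3 and trawl CVs to 0.4; effective sample
sizes default to 100.  These observation-error settings are scenario fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DataBundle,
    FisherySeries,
    ModelStructure,
    ParameterSet,
    PopulationTrajectory,
    SurveySeries,
    project,
)
from .errors import ConfigurationError

__all__ = ["Scenario", "default_scenario", "template_bundle", "simulate_truth", "observe"]

SURVEY_NAMES = (
    "acoustic_summer",
    "acoustic_winter",
    "ikmt_summer",
    "ikmt_winter",
    "rmt8_summer",
    "rmt8_winter",
)


@dataclass
class Scenario:
    """Design and noise settings for one synthetic data set."""

    params: ParameterSet
    survey_index_years: dict[str, np.ndarray]
    survey_comp_years: dict[str, np.ndarray]
    catch_years: np.ndarray
    fishery_comp_years: np.ndarray
    survey_cvs: dict[str, float]
    effective_n_survey: float = 100.0
    effective_n_fishery: float = 100.0
    index_noise: bool = True
    composition_noise: bool = True
    catch_noise: bool = True
    process_noise: bool = True  # recruitment and F-deviation randomness
    f_max: float = 0.35  # terminal-year target fishing mortality of the ramp
    f_ramp_power: float = 1.5
    f_jitter_sd: float = 0.15
    seed: int = 0
    structure: ModelStructure = field(default_factory=ModelStructure, repr=False)

    def design_counts(self) -> dict:
        return {
            "survey_index_years": int(sum(len(v) for v in self.survey_index_years.values())),
            "survey_comp_years": int(sum(len(v) for v in self.survey_comp_years.values())),
            "catch_years": int(len(self.catch_years)),
            "fishery_comp_years": int(len(self.fishery_comp_years)),
        }


def default_scenario(
    structure: ModelStructure | None = None, seed: int = 0, **kwargs
) -> Scenario:
    """The standard design: 54 index years, 35 composition years, 41 catch
    years and 13 fishery-composition years across six surveys."""
    s = structure or ModelStructure()
    # year layout follows the real survey eras: German-era trawls in the
    # 1980s, US research surveys 1992-2016, winter series in the 2010s
    idx = {
        "acoustic_summer": np.arange(2000, 2017),  # 17
        "acoustic_winter": np.arange(2012, 2017),  # 5
        "ikmt_summer": np.arange(1992, 2004),  # 12
        "ikmt_winter": np.arange(2009, 2017),  # 8
        "rmt8_summer": np.arange(1982, 1988),  # 6
        "rmt8_winter": np.arange(1983, 1989),  # 6
    }
    comp = {
        "acoustic_summer": np.arange(0),  # acoustic series carry no lengths
        "acoustic_winter": np.arange(0),
        "ikmt_summer": np.arange(1992, 2007),  # 15
        "ikmt_winter": np.arange(2009, 2017),  # 8
        "rmt8_summer": np.arange(1982, 1988),  # 6
        "rmt8_winter": np.arange(1983, 1989),  # 6
    }
    cvs = {name: (0.3 if name.startswith("acoustic") else 0.4) for name in SURVEY_NAMES}
    sc = Scenario(
        params=ParameterSet.defaults(s),
        survey_index_years=idx,
        survey_comp_years=comp,
        catch_years=s.years.copy(),  # 41
        fishery_comp_years=np.arange(2000, 2013),  # 13
        survey_cvs=cvs,
        seed=seed,
        structure=s,
    )
    return replace(sc, **kwargs) if kwargs else sc


def template_bundle(scenario: Scenario) -> DataBundle:
    """A data bundle with the scenario's design (years, CVs, effective N)
    and placeholder observations of one."""
    s = scenario.structure
    nb = s.n_bins
    surveys = []
    for name in SURVEY_NAMES:
        iy = np.asarray(scenario.survey_index_years[name], dtype=int)
        cy = np.asarray(scenario.survey_comp_years[name], dtype=int)
        surveys.append(
            SurveySeries(
                name=name,
                index_years=iy,
                index_values=np.ones(len(iy)),
                index_cvs=np.full(len(iy), scenario.survey_cvs[name]),
                comp_years=cy,
                comp_props=np.full((len(cy), nb), 1.0 / nb),
                effective_n=np.full(len(cy), scenario.effective_n_survey),
            )
        )
    fy = np.asarray(scenario.fishery_comp_years, dtype=int)
    fishery = FisherySeries(
        catch_years=np.asarray(scenario.catch_years, dtype=int),
        catches=np.ones(len(scenario.catch_years)),
        comp_years=fy,
        comp_props=np.full((len(fy), nb), 1.0 / nb),
        effective_n=np.full(len(fy), scenario.effective_n_fishery),
    )
    return DataBundle(
        surveys=surveys,
        fishery=fishery,
        length_bin_edges=s.length_bin_edges.copy(),
        year_range=(s.first_year, s.last_year),
    )


def simulate_truth(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> tuple[ParameterSet, PopulationTrajectory]:
    """Draw the true parameter realization and project its trajectory.

    Recruitment deviations are Normal(0, sigma_R) on the log scale (clipped
    to their bounds); log-F deviations follow a power ramp up to ``f_max``
    in the terminal year, with lognormal jitter.  With ``process_noise``
    off, all deviations are zero and the trajectory is the deterministic
    mean-recruitment population.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    s = scenario.structure
    params = scenario.params
    sigma_R = float(np.exp(params.ln_sigma_R))
    if scenario.process_noise:
        eps_R = np.clip(rng.normal(0.0, sigma_R, s.n_rec_devs), -14.9, 14.9)
        t = np.arange(1, s.n_years + 1) / s.n_years
        f_path = scenario.f_max * t**scenario.f_ramp_power
        eps_f = np.log(f_path) - params.mu_f + rng.normal(0.0, scenario.f_jitter_sd, s.n_years)
        eps_f = np.clip(eps_f, -11.9, 7.9)
    else:
        eps_R = np.zeros(s.n_rec_devs)
        eps_f = np.zeros(s.n_f_devs)
    truth = replace(params, eps_R=eps_R, eps_f=eps_f)
    trajectory = project(truth, template_bundle(scenario))
    return truth, trajectory


def observe(
    trajectory: PopulationTrajectory,
    scenario: Scenario,
    rng: np.random.Generator | None = None,
) -> DataBundle:
    """Overlay observation error on a trajectory's predicted values.

    Indices and catches get mean-unbiased lognormal multipliers at their
    nominal CVs; compositions are multinomial draws at the effective sample
    sizes.  With all noise switches off the result equals the noise-free
    predicted values.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 1)
    bundle = template_bundle(scenario)
    s = scenario.structure
    if any(
        len(sv.index_years)
        and (sv.index_years.min() < s.first_year or sv.index_years.max() > s.last_year)
        for sv in bundle.surveys
    ):
        raise ConfigurationError("design years outside the trajectory's year range")

    def lognoise(n, cv):
        sigma = np.sqrt(np.log1p(cv**2))
        return np.exp(rng.normal(0.0, 1.0, n) * sigma - 0.5 * sigma**2)

    for i, sv in enumerate(bundle.surveys):
        pred_idx = trajectory.predicted_index[i]
        mult = lognoise(len(pred_idx), sv.index_cvs) if scenario.index_noise else 1.0
        sv.index_values = pred_idx * mult
        pred_comp = trajectory.predicted_comp[i]
        if scenario.composition_noise and len(sv.comp_years):
            drawn = np.array(
                [
                    rng.multinomial(int(round(n)), p / p.sum())
                    for n, p in zip(sv.effective_n, pred_comp)
                ],
                dtype=float,
            )
            sv.comp_props = drawn / drawn.sum(axis=1, keepdims=True)
        else:
            sv.comp_props = pred_comp.copy()
    f = bundle.fishery
    sigma_C = scenario.params.sigma_C
    mult = lognoise(len(f.catch_years), sigma_C) if scenario.catch_noise else 1.0
    f.catches = trajectory.predicted_catch * mult
    pred_fcomp = trajectory.predicted_fishery_comp
    if scenario.composition_noise and len(f.comp_years):
        drawn = np.array(
            [
                rng.multinomial(int(round(n)), p / p.sum())
                for n, p in zip(f.effective_n, pred_fcomp)
            ],
            dtype=float,
        )
        f.comp_props = drawn / drawn.sum(axis=1, keepdims=True)
    else:
        f.comp_props = pred_fcomp.copy()
    bundle.validate()
    return bundle
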