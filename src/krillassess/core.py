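"""Age-structured population dynamics for the krill integrated assessment.

The model follows ages 1 through a plus group (default 7) over calendar
years (default 1976-2016).  Mortality is split into natural mortality M and
fishing mortality F_y applied through a logistic fishery selectivity;
removals follow the Baranov catch equation.  Annual recruitment is mean
recruitment times lognormal deviations, with deviations for a handful of
pre-data years building the initial age structure.  Lengths-at-age follow a
von Bertalanffy curve with normally distributed individual variability,
which converts model age compositions to the length bins observed by the
surveys and the fishery.

Everything in this module is deterministic: a parameter set and a data
design fully determine the trajectory and all predicted observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, ndtr

from .errors import (
    ConfigurationError,
    DataError,
    InvalidParameterError,
    InvalidStateError,
    NumericFailure,
)

__all__ = [
    "ModelStructure",
    "ParameterSet",
    "SurveySeries",
    "FisherySeries",
    "DataBundle",
    "PopulationTrajectory",
    "GROUP_LABELS",
    "logistic_selectivity",
    "age_length_matrix",
    "beverton_holt",
    "unfished_spawning_biomass",
    "project",
    "count_parameters",
]


# ---------------------------------------------------------------------------
# Model structure (dimensions and fixed biological conventions)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelStructure:
    """Dimensions and biological conventions of the assessment model.

    ``n_predata`` recruitment deviations before ``first_year`` build the
    initial age structure, so the deviation vector spans
    ``first_year - n_predata .. last_year``.  Length bins are half-open
    ``[lo, hi)`` in mm.  Weight-at-age is allometric ``w = c * L(a)**d``
    (tonnes); maturity is knife-edge at ``maturity_age``.
    """

    first_year: int = 1976
    last_year: int = 2016
    n_predata: int = 5
    plus_age: int = 7
    n_surveys: int = 6
    bin_lo: float = 10.0
    bin_hi: float = 70.0
    bin_width: float = 2.0
    maturity_age: int = 3
    weight_coef: float = 1e-9
    weight_exp: float = 3.0
    bias_correct: bool = True

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(1, self.plus_age + 1)

    @property
    def n_ages(self) -> int:
        return self.plus_age

    @property
    def rec_dev_years(self) -> np.ndarray:
        return np.arange(self.first_year - self.n_predata, self.last_year + 1)

    @property
    def n_rec_devs(self) -> int:
        return self.n_years + self.n_predata

    @property
    def n_f_devs(self) -> int:
        return self.n_years

    @property
    def length_bin_edges(self) -> np.ndarray:
        return np.arange(self.bin_lo, self.bin_hi + self.bin_width / 2, self.bin_width)

    @property
    def n_bins(self) -> int:
        return len(self.length_bin_edges) - 1

    def maturity(self) -> np.ndarray:
        return (self.ages >= self.maturity_age).astype(float)


DEFAULT_STRUCTURE = ModelStructure()


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: The 13 parameter groups.  The first 12 are the groups that appear in the
#: standard configuration grid; sigma_C (the fishery catch CV) completes the
#: 118-parameter census but is never activated in the shipped presets.
GROUP_LABELS = (
    "R0",
    "Rbar",
    "eps_R",
    "F",
    "M",
    "sel_f",
    "sel_s",
    "q_f",
    "sigma_R",
    "h",
    "q_s",
    "growth",
    "sigma_C",
)

_UNB = (-np.inf, np.inf)
# Numerical guard bounds on selectivity spreads and the catch CV: these have
# no stated bounds but must stay positive for the model to be defined.
_BETA_BOUNDS = (1e-3, 20.0)
_SIGMA_C_BOUNDS = (1e-4, 5.0)


@dataclass
class ParameterSet:
    """All potentially estimable quantities of the assessment (118 scalars
    at the default structure).

    Values are stored on their natural (possibly log) scales as named in the
    standard parameter table: log recruitment levels, log deviations,
    logistic selectivity locations/spreads per survey and for the fishery,
    log fishing mortality and deviations, catchabilities, steepness, and
    von Bertalanffy growth.
    """

    ln_R0: float
    ln_Rbar: float
    eps_R: np.ndarray
    ln_sigma_R: float
    ln_M: float
    alpha_s: np.ndarray
    beta_s: np.ndarray
    alpha_f: float
    beta_f: float
    mu_f: float
    eps_f: np.ndarray
    sigma_C: float
    ln_q_f: float
    h: float
    ln_q_s: np.ndarray
    ln_Linf: float
    ln_k: float
    ln_sigma_v: float
    structure: ModelStructure = field(default_factory=ModelStructure, repr=False)

    # -- construction -------------------------------------------------------

    @classmethod
    def defaults(cls, structure: ModelStructure = DEFAULT_STRUCTURE) -> "ParameterSet":
        """The pre-specified initial values of the standard parameter table."""
        n_s = structure.n_surveys
        alpha_s = np.full(n_s, 1.3)
        beta_s = np.full(n_s, 2.8)
        # survey 1 is the summer acoustic survey with a near-knife-edge
        # initial selectivity
        alpha_s[0], beta_s[0] = 3.3, 0.06
        return cls(
            ln_R0=16.0,
            ln_Rbar=16.0,
            eps_R=np.zeros(structure.n_rec_devs),
            ln_sigma_R=-0.3567,
            ln_M=-0.2232,
            alpha_s=alpha_s,
            beta_s=beta_s,
            alpha_f=1.3,
            beta_f=2.8,
            mu_f=-2.3026,
            eps_f=np.zeros(structure.n_f_devs),
            sigma_C=0.1,
            ln_q_f=0.0,
            h=0.85,
            ln_q_s=np.zeros(n_s),
            ln_Linf=4.11,
            ln_k=-0.799,
            ln_sigma_v=1.459,
            structure=structure,
        )

    # -- flat-vector interface ---------------------------------------------

    def _layout(self) -> list[tuple[str, int]]:
        s = self.structure
        return [
            ("ln_R0", 1),
            ("ln_Rbar", 1),
            ("eps_R", s.n_rec_devs),
            ("ln_sigma_R", 1),
            ("ln_M", 1),
            ("alpha_s", s.n_surveys),
            ("beta_s", s.n_surveys),
            ("alpha_f", 1),
            ("beta_f", 1),
            ("mu_f", 1),
            ("eps_f", s.n_f_devs),
            ("sigma_C", 1),
            ("ln_q_f", 1),
            ("h", 1),
            ("ln_q_s", s.n_surveys),
            ("ln_Linf", 1),
            ("ln_k", 1),
            ("ln_sigma_v", 1),
        ]

    @property
    def n_total(self) -> int:
        return sum(n for _, n in self._layout())

    def to_vector(self) -> np.ndarray:
        parts = []
        for name, n in self._layout():
            v = getattr(self, name)
            parts.append(np.atleast_1d(np.asarray(v, dtype=float)))
        return np.concatenate(parts)

    def with_vector(self, x: np.ndarray) -> "ParameterSet":
        """Return a copy with values taken from the flat vector ``x``.

        Complex vectors are preserved (complex-step differentiation).
        """
        x = np.asarray(x)
        if x.size != self.n_total:
            raise InvalidParameterError(
                f"expected vector of length {self.n_total}, got {x.size}"
            )
        out = {}
        i = 0
        for name, n in self._layout():
            chunk = x[i : i + n]
            out[name] = chunk.copy() if n > 1 else chunk[0].item()
            i += n
        return replace(self, **out)

    def slot_names(self) -> list[str]:
        """Scalar names aligned with :meth:`to_vector`."""
        s = self.structure
        names: list[str] = []
        for name, n in self._layout():
            if n == 1:
                names.append(name)
            elif name == "eps_R":
                names.extend(f"eps_R[{y}]" for y in s.rec_dev_years)
            elif name == "eps_f":
                names.extend(f"eps_f[{y}]" for y in s.years)
            else:
                names.extend(f"{name}[{i + 1}]" for i in range(n))
        return names

    def group_indices(self, survey_subset: tuple[int, ...] | None = None) -> dict[str, np.ndarray]:
        """Map each group label to its flat-vector indices.

        ``survey_subset`` (1-based survey numbers) restricts the "sel_s"
        group to the selectivities of those surveys; default all surveys.
        """
        s = self.structure
        offsets: dict[str, int] = {}
        i = 0
        for name, n in self._layout():
            offsets[name] = i
            i += n
        n_s = s.n_surveys
        if survey_subset is None:
            survey_subset = tuple(range(1, n_s + 1))
        for sv in survey_subset:
            if not 1 <= sv <= n_s:
                raise ConfigurationError(f"survey index {sv} out of range 1..{n_s}")
        sel_s_idx = []
        for sv in survey_subset:
            sel_s_idx.append(offsets["alpha_s"] + sv - 1)
            sel_s_idx.append(offsets["beta_s"] + sv - 1)
        return {
            "R0": np.array([offsets["ln_R0"]]),
            "Rbar": np.array([offsets["ln_Rbar"]]),
            "eps_R": np.arange(offsets["eps_R"], offsets["eps_R"] + s.n_rec_devs),
            "sigma_R": np.array([offsets["ln_sigma_R"]]),
            "M": np.array([offsets["ln_M"]]),
            "sel_s": np.array(sorted(sel_s_idx)),
            "sel_f": np.array([offsets["alpha_f"], offsets["beta_f"]]),
            "F": np.arange(offsets["mu_f"], offsets["mu_f"] + 1 + s.n_f_devs),
            "sigma_C": np.array([offsets["sigma_C"]]),
            "q_f": np.array([offsets["ln_q_f"]]),
            "h": np.array([offsets["h"]]),
            "q_s": np.arange(offsets["ln_q_s"], offsets["ln_q_s"] + n_s),
            "growth": np.array(
                [offsets["ln_Linf"], offsets["ln_k"], offsets["ln_sigma_v"]]
            ),
        }

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper bounds aligned with :meth:`to_vector`.

        Bounded parameters follow the standard parameter table; selectivity
        spreads and sigma_C carry narrow positivity guards.
        """
        s = self.structure
        lo_parts, hi_parts = [], []

        def add(bound, n=1):
            lo_parts.append(np.full(n, bound[0], dtype=float))
            hi_parts.append(np.full(n, bound[1], dtype=float))

        add(_UNB)  # ln_R0
        add(_UNB)  # ln_Rbar
        add((-15.0, 15.0), s.n_rec_devs)  # eps_R
        add(_UNB)  # ln_sigma_R
        add((-5.0, 5.0))  # ln_M
        add(_UNB, s.n_surveys)  # alpha_s
        add(_BETA_BOUNDS, s.n_surveys)  # beta_s
        add(_UNB)  # alpha_f
        add(_BETA_BOUNDS)  # beta_f
        add(_UNB)  # mu_f
        add((-12.0, 8.0), s.n_f_devs)  # eps_f
        add(_SIGMA_C_BOUNDS)  # sigma_C
        add(_UNB)  # ln_q_f
        add((0.21, 1.0))  # h
        add(_UNB, s.n_surveys)  # ln_q_s
        add((2.5, 5.0))  # ln_Linf
        add((-10.0, 5.0))  # ln_k
        add((0.2, 5.0))  # ln_sigma_v
        return np.concatenate(lo_parts), np.concatenate(hi_parts)

    # -- convenience --------------------------------------------------------

    def to_dict(self) -> dict:
        d = {}
        for name, n in self._layout():
            v = getattr(self, name)
            d[name] = [float(x) for x in np.atleast_1d(v)] if n > 1 else float(v)
        return d

    @classmethod
    def from_dict(cls, d: dict, structure: ModelStructure = DEFAULT_STRUCTURE) -> "ParameterSet":
        base = cls.defaults(structure)
        out = {}
        for name, n in base._layout():
            if name not in d:
                continue
            v = d[name]
            out[name] = np.asarray(v, dtype=float) if n > 1 else float(v)
        return replace(base, **out)


def count_parameters(config) -> int:
    """Number of scalar parameters activated by a configuration.

    The fishing-mortality group counts the mean plus all annual deviations;
    the survey-selectivity group counts two scalars per selected survey.
    """
    structure = getattr(config, "structure", None) or DEFAULT_STRUCTURE
    sizes = {
        "R0": 1,
        "Rbar": 1,
        "eps_R": structure.n_rec_devs,
        "F": 1 + structure.n_f_devs,
        "M": 1,
        "sel_f": 2,
        "sel_s": 2 * len(config.survey_sel_subset or range(structure.n_surveys)),
        "q_f": 1,
        "sigma_R": 1,
        "h": 1,
        "q_s": structure.n_surveys,
        "growth": 3,
        "sigma_C": 1,
    }
    total = 0
    for g in config.estimated_groups:
        if g not in sizes:
            raise ConfigurationError(f"unknown parameter group {g!r}")
        total += sizes[g]
    return total


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class SurveySeries:
    """One survey's biomass-index and length-composition series."""

    name: str
    index_years: np.ndarray
    index_values: np.ndarray
    index_cvs: np.ndarray
    comp_years: np.ndarray
    comp_props: np.ndarray  # (n_comp_years, n_bins)
    effective_n: np.ndarray  # per composition year


@dataclass
class FisherySeries:
    """Annual catches and fishery length compositions."""

    catch_years: np.ndarray
    catches: np.ndarray  # tonnes
    comp_years: np.ndarray
    comp_props: np.ndarray
    effective_n: np.ndarray


@dataclass
class DataBundle:
    """Observed (or synthetic) survey and fishery series fitted by the model."""

    surveys: list[SurveySeries]
    fishery: FisherySeries
    length_bin_edges: np.ndarray
    year_range: tuple[int, int]

    def validate(self, check_values: bool = True) -> None:
        y0, y1 = self.year_range
        for s in self.surveys:
            for yrs in (s.index_years, s.comp_years):
                if len(yrs) and (yrs.min() < y0 or yrs.max() > y1):
                    raise DataError(f"survey {s.name}: years outside {y0}-{y1}")
            if check_values:
                if np.any(s.index_cvs <= 0):
                    raise DataError(f"survey {s.name}: non-positive CV")
                if np.any(s.effective_n <= 0):
                    raise DataError(f"survey {s.name}: non-positive effective N")
                if len(s.comp_years) and not np.allclose(
                    s.comp_props.sum(axis=1), 1.0, atol=1e-9
                ):
                    raise DataError(f"survey {s.name}: composition rows must sum to 1")
        f = self.fishery
        if len(f.catch_years) and (f.catch_years.min() < y0 or f.catch_years.max() > y1):
            raise DataError(f"fishery: catch years outside {y0}-{y1}")
        if check_values:
            if np.any(f.effective_n <= 0):
                raise DataError("fishery: non-positive effective N")
            if len(f.comp_years) and not np.allclose(f.comp_props.sum(axis=1), 1.0, atol=1e-9):
                raise DataError("fishery: composition rows must sum to 1")


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------


@dataclass
class PopulationTrajectory:
    """Deterministic population state and predicted observations."""

    years: np.ndarray
    ages: np.ndarray
    N: np.ndarray  # (n_years, n_ages) numbers-at-age at start of year
    Z: np.ndarray  # total mortality-at-age
    catch_at_age: np.ndarray  # Baranov catch numbers
    F_y: np.ndarray
    SSB_y: np.ndarray  # spawning biomass (tonnes)
    B0: float
    R_y: np.ndarray  # recruit numbers per model year
    R_pre: np.ndarray  # pre-data recruit numbers (oldest first)
    predicted_index: list[np.ndarray]
    predicted_comp: list[np.ndarray]
    predicted_fishery_comp: np.ndarray
    predicted_catch: np.ndarray  # tonnes, aligned with fishery catch years


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def _expit(x):
    """Numerically stable logistic, usable with complex-step arguments."""
    x = np.asarray(x)
    if np.isrealobj(x):
        return expit(x)
    # stable complex branch: split on the real part
    pos = x.real >= 0
    out = np.empty_like(x)
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def logistic_selectivity(age, alpha: float, beta: float):
    """Logistic selectivity-at-age: ``1 / (1 + exp(-(age - alpha)/beta))``.

    ``alpha`` is the age at 50% selection and ``beta`` the spread; ``beta``
    must be positive.
    """
    if np.real(beta) <= 0:
        raise InvalidParameterError(f"selectivity spread beta must be > 0, got {beta}")
    return _expit((np.asarray(age, dtype=float) - alpha) / beta)


def mean_length_at_age(ages, ln_Linf: float, ln_k: float):
    """von Bertalanffy mean length (mm): ``L(a) = Linf * (1 - exp(-k a))``."""
    Linf, k = np.exp(ln_Linf), np.exp(ln_k)
    return Linf * (1.0 - np.exp(-k * np.asarray(ages, dtype=float)))


def age_length_matrix(
    ln_Linf: float,
    ln_k: float,
    ln_sigma_v: float,
    length_bin_edges: np.ndarray,
    ages: np.ndarray | None = None,
) -> np.ndarray:
    """Probability that an individual of each age falls into each length bin.

    Lengths at age ``a`` are Normal(L(a), sigma_v); bin probabilities are the
    normal CDF differences with both tails folded into the end bins, so each
    age row sums to one exactly.
    """
    edges = np.asarray(length_bin_edges, dtype=float)
    if edges.size < 2:
        raise ConfigurationError("need at least one length bin")
    if np.any(np.diff(edges) <= 0):
        raise ConfigurationError("length bin edges must be strictly increasing")
    if ages is None:
        ages = DEFAULT_STRUCTURE.ages
    mu = mean_length_at_age(ages, ln_Linf, ln_k)
    sigma = np.exp(ln_sigma_v)
    # interior edge CDFs; tails folded: first bin = cdf(e1), last = 1 - cdf(e_{B-1})
    cdf = ndtr((edges[None, 1:-1] - mu[:, None]) / sigma)
    probs = np.empty((len(mu), edges.size - 1))
    probs[:, 0] = cdf[:, 0] if cdf.shape[1] else 1.0
    if cdf.shape[1]:
        probs[:, 1:-1] = np.diff(cdf, axis=1)
        probs[:, -1] = 1.0 - cdf[:, -1]
    return probs


_ALM_CACHE: dict = {}


def _age_length_matrix_cached(ln_Linf, ln_k, ln_sigma_v, edges, ages) -> np.ndarray:
    # growth is fixed in most configurations, so the matrix rarely changes
    key = (float(ln_Linf), float(ln_k), float(ln_sigma_v), edges.tobytes(), ages.tobytes())
    hit = _ALM_CACHE.get(key)
    if hit is None:
        if len(_ALM_CACHE) > 64:
            _ALM_CACHE.clear()
        hit = age_length_matrix(ln_Linf, ln_k, ln_sigma_v, edges, ages)
        _ALM_CACHE[key] = hit
    return hit


def beverton_holt(ssb, h: float, r0: float, b0: float):
    """Beverton-Holt expected recruitment in the steepness parameterization.

    ``R(S) = 4 h R0 S / (B0 (1 - h) + (5 h - 1) S)``, so that R(B0) = R0 and
    R(0.2 B0) = h R0 (the definition of steepness).
    """
    if np.real(b0) <= 0:
        raise InvalidStateError(f"unfished spawning biomass must be > 0, got {b0}")
    if not 0.21 <= np.real(h) <= 1.0:
        raise InvalidParameterError(f"steepness h={h} outside [0.21, 1]")
    ssb = np.asarray(ssb)
    if np.any(np.real(ssb) < 0):
        raise InvalidStateError("spawning biomass must be >= 0")
    return 4.0 * h * r0 * ssb / (b0 * (1.0 - h) + (5.0 * h - 1.0) * ssb)


def _weights_and_maturity(params: ParameterSet):
    s = params.structure
    # growth parameters are real by construction (complex-step perturbation
    # is unsupported for the growth group; see estimation.ObjectiveAdapter)
    L = mean_length_at_age(s.ages, np.real(params.ln_Linf), np.real(params.ln_k))
    w = s.weight_coef * L**s.weight_exp
    m = s.maturity()
    return w, m


def unfished_spawning_biomass(params: ParameterSet) -> float:
    """B0: unfished recruitment times spawning biomass per recruit at F = 0."""
    s = params.structure
    M = np.exp(params.ln_M)
    w, m = _weights_and_maturity(params)
    surv = np.exp(-M * (s.ages - 1.0))
    surv[-1] = np.exp(-M * (s.plus_age - 1)) / (1.0 - np.exp(-M))
    return (np.exp(params.ln_R0) * np.sum(m * w * surv)).item()


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def project(
    params: ParameterSet,
    data: DataBundle | None = None,
    structure: ModelStructure | None = None,
) -> PopulationTrajectory:
    """Run the deterministic dynamics and compute all predicted observations.

    Recruitment in model year y is ``exp(ln_Rbar + eps_R[y] - sigma_R^2/2)``
    (the bias correction makes mean recruitment a mean rather than a
    median; switchable via the structure).  The initial age structure is
    built from the pre-data deviations under natural mortality only.
    Fishing mortality is ``exp(mu_f + eps_f[y])`` through the logistic
    fishery selectivity; catches follow the Baranov equation.  Predicted
    indices, compositions and catch biomass are evaluated at the years
    present in ``data``.
    """
    s = structure or params.structure
    n_y, n_a = s.n_years, s.n_ages
    if s.n_predata < n_a - 2:
        raise ConfigurationError(
            "need at least plus_age - 2 pre-data recruitment deviations "
            "to build the initial age structure"
        )
    ages = s.ages

    M = np.exp(params.ln_M)
    sigma_R = np.exp(params.ln_sigma_R)
    bc = 0.5 * sigma_R**2 if s.bias_correct else 0.0

    sel_f = logistic_selectivity(ages, params.alpha_f, params.beta_f)
    F_y = np.exp(params.mu_f + params.eps_f)
    w, m = _weights_and_maturity(params)
    Phi = _age_length_matrix_cached(
        float(np.real(params.ln_Linf)),
        float(np.real(params.ln_k)),
        float(np.real(params.ln_sigma_v)),
        s.length_bin_edges,
        ages,
    )

    eps_pre = params.eps_R[: s.n_predata]  # oldest first
    eps_model = params.eps_R[s.n_predata :]
    R_y = np.exp(params.ln_Rbar + eps_model - bc)
    R_pre = np.exp(params.ln_Rbar + eps_pre - bc)

    dtype = np.result_type(R_y, F_y, np.exp(params.ln_M))
    N = np.zeros((n_y, n_a), dtype=dtype)
    # initial year: age a was recruited a-1 years before first_year
    N[0, 0] = R_y[0]
    for a in range(2, n_a):
        # ages 2..plus_age-1 from the pre-data deviations (most recent first)
        N[0, a - 1] = R_pre[-(a - 1)] * np.exp(-M * (a - 1))
    N[0, n_a - 1] = (
        np.exp(params.ln_Rbar - bc) * np.exp(-M * (n_a - 1)) / (1.0 - np.exp(-M))
    )

    Z = M + sel_f[None, :] * F_y[:, None]
    exp_neg_Z = np.exp(-Z)
    for t in range(n_y - 1):
        surv = N[t] * exp_neg_Z[t]
        N[t + 1, 1:] = surv[:-1]
        N[t + 1, -1] += surv[-1]  # plus group accumulates
        N[t + 1, 0] = R_y[t + 1]
    if not np.all(np.isfinite(N)) or np.any(np.real(N) < 0):
        bad_y, bad_a = np.argwhere(~np.isfinite(N) | (np.real(N) < 0))[0]
        raise NumericFailure(
            f"non-finite or negative abundance in year {s.first_year + bad_y}, "
            f"age {bad_a + 1}",
            year=int(s.first_year + bad_y),
            age=int(bad_a + 1),
        )
    catch_at_age = (sel_f[None, :] * F_y[:, None] / Z) * (1.0 - exp_neg_Z) * N

    SSB_y = N @ (m * w)
    B0 = unfished_spawning_biomass(params)

    predicted_index: list[np.ndarray] = []
    predicted_comp: list[np.ndarray] = []
    predicted_fishery_comp = np.zeros((0, s.n_bins))
    predicted_catch = np.zeros(0)

    if data is not None:
        y0 = s.first_year
        q_f = np.exp(params.ln_q_f)
        catch_b = q_f * (catch_at_age @ w)
        for i, sv in enumerate(data.surveys):
            sel = logistic_selectivity(ages, params.alpha_s[i], params.beta_s[i])
            q = np.exp(params.ln_q_s[i])
            biom = q * (N * (sel * w)[None, :]).sum(axis=1)
            predicted_index.append(biom[sv.index_years - y0])
            if len(sv.comp_years):
                avail = N[sv.comp_years - y0] * sel[None, :]
                comp = avail @ Phi
                comp /= comp.sum(axis=1, keepdims=True)
            else:
                comp = np.zeros((0, s.n_bins))
            predicted_comp.append(comp)
        f = data.fishery
        predicted_catch = catch_b[f.catch_years - y0]
        if len(f.comp_years):
            cprop = catch_at_age[f.comp_years - y0] @ Phi
            cprop /= cprop.sum(axis=1, keepdims=True)
            predicted_fishery_comp = cprop
        else:
            predicted_fishery_comp = np.zeros((0, s.n_bins))

    return PopulationTrajectory(
        years=s.years,
        ages=ages,
        N=N,
        Z=Z,
        catch_at_age=catch_at_age,
        F_y=F_y,
        SSB_y=SSB_y,
        B0=B0,
        R_y=R_y,
        R_pre=R_pre,
        predicted_index=predicted_index,
        predicted_comp=predicted_comp,
        predicted_fishery_comp=predicted_fishery_comp,
        predicted_catch=predicted_catch,
    )
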