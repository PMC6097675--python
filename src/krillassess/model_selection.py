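"""Information-criterion comparison across configurations.

AIC = 2*NLL + 2k and BIC = 2*NLL + ln(n)*k, with the sample size n counted
as the total number of data-years across the six surveys and the fishery
(survey composition years + survey index years + catch years + fishery
composition years; 143 at the standard design).  Deltas are computed from
the unrounded criteria relative to the minimum-criterion configuration and
rounded half-up to integers for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import DataBundle
from .errors import ConfigurationError

__all__ = [
    "ComparisonRow",
    "information_criteria",
    "delta_table",
    "sample_size",
    "annual_mortality_fraction",
    "reference_fit_table",
]


@dataclass
class ComparisonRow:
    """One configuration's row in a comparison table."""

    name: str
    n_params: int
    nll: float
    delta_aic: int
    delta_bic: int
    median_reorderings: float | None = None
    pct_best: float | None = None
    max_gradient: float | None = None
    diagnostics_pass: bool | None = None


def information_criteria(nll: float, k: int, n: int) -> tuple[float, float]:
    """(AIC, BIC) for a fit with ``k`` estimated parameters and sample size ``n``."""
    if k < 0 or n < 1:
        raise ConfigurationError("need k >= 0 and n >= 1")
    return 2.0 * nll + 2.0 * k, 2.0 * nll + math.log(n) * k


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def delta_table(rows, n: int) -> pd.DataFrame:
    """Delta-AIC/BIC table for ``rows`` of ``(name, nll, k)`` tuples.

    Deltas are taken against the minimum-AIC (respectively minimum-BIC)
    row, computed unrounded, then rounded half-up for display.
    """
    rows = list(rows)
    if not rows:
        raise ConfigurationError("need at least one row")
    names = [r[0] for r in rows]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate configuration names")
    aic = np.array([information_criteria(nll, k, n)[0] for _, nll, k in rows])
    bic = np.array([information_criteria(nll, k, n)[1] for _, nll, k in rows])
    d_aic = aic - aic.min()
    d_bic = bic - bic.min()
    return pd.DataFrame(
        {
            "config": names,
            "nll": [r[1] for r in rows],
            "n_pars": [r[2] for r in rows],
            "delta_aic": [_round_half_up(v) for v in d_aic],
            "delta_bic": [_round_half_up(v) for v in d_bic],
        }
    )


def sample_size(data: DataBundle) -> int:
    """Information-criterion sample size: total data-years in the bundle."""
    n = 0
    for sv in data.surveys:
        n += len(sv.index_years) + len(sv.comp_years)
    n += len(data.fishery.catch_years) + len(data.fishery.comp_years)
    return n


def annual_mortality_fraction(m: float) -> int:
    """Instantaneous natural mortality (per year) as the percentage of the
    population dying each year, ``100 (1 - exp(-M))``, rounded for display."""
    if m < 0:
        raise ConfigurationError("M must be >= 0")
    return _round_half_up(100.0 * (1.0 - math.exp(-m)))


def reference_fit_table() -> pd.DataFrame:
    """Published per-configuration fit statistics for the Subarea 48.1 krill
    assessment (negative log-likelihoods, parameter counts, reordering and
    consistency metrics, printed information-criterion deltas).

    These are reference values for checking the comparison arithmetic; the
    underlying survey/fishery data are not public, so the NLL column cannot
    be recomputed here.
    """
    with resources.files("krillassess.data").joinpath("reference_fit_table.csv").open() as fh:
        return pd.read_csv(fh)
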