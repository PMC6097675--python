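"""Model configurations: which parameter groups are estimated.

A configuration fixes every parameter at its pre-specified initial value
except the groups it activates for estimation.  The 22 standard
configurations (cfgI..cfgXXII) reproduce the published grid, from a
48-parameter recruitment-only model up to 107 parameters; three of them
estimate only a subset of the survey selectivities, and cfgXVI/cfgXVII fix
the summer acoustic selectivity at one for all ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import GROUP_LABELS, ModelStructure, ParameterSet, count_parameters
from .errors import ConfigurationError
from .objective import PenaltyStack

__all__ = [
    "Configuration",
    "PRESETS",
    "preset",
    "apply_overrides",
    "initial_parameters_path",
]


def initial_parameters_path():
    """Path to the packaged pre-specified initial parameter values (YAML)."""
    from importlib import resources

    return resources.files("krillassess.data").joinpath("initial_parameters.yaml")


@dataclass
class Configuration:
    """A named choice of estimated parameter groups plus the replicate,
    phase, and penalty policy used to fit it."""

    name: str
    estimated_groups: tuple[str, ...]
    survey_sel_subset: tuple[int, ...] | None = None  # 1-based; None = all
    n_replicates: int = 20
    max_reorderings: int = 3000
    n_phases: int = 7
    terminal_phase: int = 9
    penalties: PenaltyStack = field(default_factory=PenaltyStack)
    fixed_overrides: dict = field(default_factory=dict)
    rng_seed: int | None = None
    structure: ModelStructure = field(default_factory=ModelStructure, repr=False)

    def __post_init__(self):
        if not self.estimated_groups:
            raise ConfigurationError("estimated_groups must be nonempty")
        for g in self.estimated_groups:
            if g not in GROUP_LABELS:
                raise ConfigurationError(f"unknown parameter group {g!r}")
        if self.n_phases < 1 or self.terminal_phase < self.n_phases:
            raise ConfigurationError("need 1 <= n_phases <= terminal_phase")

    @property
    def n_parameters(self) -> int:
        return count_parameters(self)

    def initial_parameters(self) -> ParameterSet:
        """Pre-specified initial values with this configuration's overrides."""
        return apply_overrides(ParameterSet.defaults(self.structure), self)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "estimated_groups": list(self.estimated_groups),
            "survey_sel_subset": list(self.survey_sel_subset)
            if self.survey_sel_subset
            else None,
            "n_replicates": self.n_replicates,
            "max_reorderings": self.max_reorderings,
            "n_phases": self.n_phases,
            "terminal_phase": self.terminal_phase,
            "penalties": {
                k: getattr(self.penalties, k)
                for k in (
                    "lambda1",
                    "lambda2",
                    "lambda3",
                    "lambda4",
                    "lambda5",
                    "lambda6",
                    "f_cap",
                    "enable_recruitment",
                    "enable_f",
                )
            },
            "fixed_overrides": self.fixed_overrides,
            "rng_seed": self.rng_seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict, structure: ModelStructure | None = None) -> "Configuration":
        known = {
            "name",
            "estimated_groups",
            "survey_sel_subset",
            "n_replicates",
            "max_reorderings",
            "n_phases",
            "terminal_phase",
            "penalties",
            "fixed_overrides",
            "rng_seed",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        kw = dict(d)
        kw["estimated_groups"] = tuple(kw["estimated_groups"])
        if kw.get("survey_sel_subset"):
            kw["survey_sel_subset"] = tuple(kw["survey_sel_subset"])
        if isinstance(kw.get("penalties"), dict):
            kw["penalties"] = PenaltyStack(**kw["penalties"])
        if structure is not None:
            kw["structure"] = structure
        return cls(**kw)


def apply_overrides(params: ParameterSet, config: Configuration) -> ParameterSet:
    """Apply a configuration's fixed-value overrides to a parameter set.

    Overrides map a field name to either a scalar or a ``{index: value}``
    mapping for array-valued fields (0-based indices).
    """
    changes = {}
    for name, val in config.fixed_overrides.items():
        if not hasattr(params, name):
            raise ConfigurationError(f"unknown parameter field {name!r} in overrides")
        current = getattr(params, name)
        if isinstance(val, dict):
            arr = np.array(current, dtype=float, copy=True)
            for i, v in val.items():
                arr[int(i)] = float(v)
            changes[name] = arr
        else:
            changes[name] = float(val)
    return replace(params, **changes) if changes else params


_BASE = ("R0", "Rbar", "eps_R")
_PRESET_SPECS: dict[str, tuple[tuple[str, ...], tuple[int, ...] | None, dict]] = {
    "cfgI": (_BASE, None, {}),
    "cfgII": (_BASE + ("M",), None, {}),
    "cfgIII": (_BASE + ("q_f",), None, {}),
    "cfgIV": (_BASE + ("sigma_R",), None, {}),
    "cfgV": (_BASE + ("h",), None, {}),
    "cfgVI": (_BASE + ("M", "sel_f"), None, {}),
    "cfgVII": (_BASE + ("q_s",), None, {}),
    "cfgVIII": (_BASE + ("M", "sel_f", "sel_s"), None, {}),
    "cfgIX": (_BASE + ("F",), None, {}),
    "cfgX": (_BASE + ("F", "M"), None, {}),
    "cfgXI": (_BASE + ("F", "q_f"), None, {}),
    "cfgXII": (_BASE + ("F", "q_f", "sigma_R"), None, {}),
    "cfgXIII": (_BASE + ("F", "M", "sel_f"), None, {}),
    "cfgXIV": (_BASE + ("F", "M", "sel_f", "q_f"), None, {}),
    "cfgXV": (_BASE + ("F", "M", "sel_f", "sel_s", "q_f"), (3,), {}),
    "cfgXVI": (_BASE + ("F", "M", "sel_f", "sel_s", "q_f"), (3,), {}),
    "cfgXVII": (_BASE + ("F", "M", "sel_f", "sel_s", "q_f"), (2, 3, 4, 5, 6), {}),
    "cfgXVIII": (_BASE + ("F", "sel_f", "sel_s"), None, {}),
    "cfgXIX": (_BASE + ("F", "M", "sel_f", "sel_s"), None, {}),
    "cfgXX": (_BASE + ("F", "M", "sel_f", "sel_s", "q_f"), None, {}),
    "cfgXXI": (_BASE + ("F", "M", "sel_f", "sel_s", "q_f", "h"), None, {}),
    "cfgXXII": (_BASE + ("F", "M", "sel_f", "sel_s", "q_f", "sigma_R"), None, {}),
}

#: Preset configuration names in increasing-parameter order.
PRESETS = tuple(_PRESET_SPECS)


def preset(name: str, structure: ModelStructure | None = None, **kwargs) -> Configuration:
    """Build one of the 22 standard configurations by name (e.g. ``"cfgXVI"``).

    Extra keyword arguments (``n_replicates``, ``penalties``, ...) override
    the defaults.
    """
    if name not in _PRESET_SPECS:
        raise ConfigurationError(f"unknown preset {name!r}; known: {', '.join(PRESETS)}")
    groups, subset, overrides = _PRESET_SPECS[name]
    kw = dict(
        name=name,
        estimated_groups=groups,
        survey_sel_subset=subset,
        fixed_overrides=dict(overrides),
    )
    if structure is not None:
        kw["structure"] = structure
    kw.update(kwargs)
    return Configuration(**kw)
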