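"""Serialization and run orchestration.

Data bundles are written as a directory of CSV files (one per series) with
a JSON manifest; configurations and parameter sets round-trip through YAML.
``run_pipeline`` chains the standard stages (simulate, fit, MCMC +
diagnostics, compare) with one master seed and writes every stage product
under a run directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import Configuration, PRESETS, preset
from .core import DataBundle, FisherySeries, ModelStructure, ParameterSet, SurveySeries
from .errors import ConfigurationError, DataError
from .estimation import FitResult, run_replicates
from .model_selection import delta_table, sample_size
from .synth import default_scenario, observe, simulate_truth
from .uncertainty import diagnose, mcmc_sample

__all__ = [
    "save_bundle",
    "load_bundle",
    "save_configuration",
    "load_configuration",
    "save_parameters",
    "load_parameters",
    "save_fit",
    "RunManifest",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Data bundles: CSV set + JSON manifest
# ---------------------------------------------------------------------------


def _bin_columns(edges: np.ndarray) -> list[str]:
    return [f"bin_{lo:g}" for lo in edges[:-1]]


def save_bundle(bundle: DataBundle, directory) -> Path:
    """Write a bundle as one CSV per series plus ``manifest.json``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cols = _bin_columns(bundle.length_bin_edges)
    files = {}
    for sv in bundle.surveys:
        idx_f = f"{sv.name}_index.csv"
        pd.DataFrame(
            {"year": sv.index_years, "value": sv.index_values, "cv": sv.index_cvs}
        ).to_csv(d / idx_f, index=False)
        comp_f = f"{sv.name}_comp.csv"
        comp = pd.DataFrame(sv.comp_props, columns=cols)
        comp.insert(0, "year", sv.comp_years)
        comp.insert(1, "effective_n", sv.effective_n)
        comp.to_csv(d / comp_f, index=False)
        files[sv.name] = {"index": idx_f, "comp": comp_f}
    pd.DataFrame(
        {"year": bundle.fishery.catch_years, "catch": bundle.fishery.catches}
    ).to_csv(d / "fishery_catch.csv", index=False)
    fcomp = pd.DataFrame(bundle.fishery.comp_props, columns=cols)
    fcomp.insert(0, "year", bundle.fishery.comp_years)
    fcomp.insert(1, "effective_n", bundle.fishery.effective_n)
    fcomp.to_csv(d / "fishery_comp.csv", index=False)
    manifest = {
        "format": "krillassess-bundle-v1",
        "year_range": list(bundle.year_range),
        "length_bin_edges": [float(e) for e in bundle.length_bin_edges],
        "surveys": files,
        "fishery": {"catch": "fishery_catch.csv", "comp": "fishery_comp.csv"},
    }
    path = d / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_bundle(path) -> DataBundle:
    """Read a bundle from a manifest path or its directory."""
    p = Path(path)
    if p.is_dir():
        p = p / "manifest.json"
    if not p.exists():
        raise DataError(f"no bundle manifest at {p}")
    manifest = json.loads(p.read_text())
    d = p.parent
    edges = np.asarray(manifest["length_bin_edges"], dtype=float)
    cols = _bin_columns(edges)
    surveys = []
    for name, files in manifest["surveys"].items():
        idx = pd.read_csv(d / files["index"])
        comp = pd.read_csv(d / files["comp"])
        surveys.append(
            SurveySeries(
                name=name,
                index_years=idx["year"].to_numpy(dtype=int),
                index_values=idx["value"].to_numpy(dtype=float),
                index_cvs=idx["cv"].to_numpy(dtype=float),
                comp_years=comp["year"].to_numpy(dtype=int),
                comp_props=comp[cols].to_numpy(dtype=float),
                effective_n=comp["effective_n"].to_numpy(dtype=float),
            )
        )
    catch = pd.read_csv(d / manifest["fishery"]["catch"])
    fcomp = pd.read_csv(d / manifest["fishery"]["comp"])
    bundle = DataBundle(
        surveys=surveys,
        fishery=FisherySeries(
            catch_years=catch["year"].to_numpy(dtype=int),
            catches=catch["catch"].to_numpy(dtype=float),
            comp_years=fcomp["year"].to_numpy(dtype=int),
            comp_props=fcomp[cols].to_numpy(dtype=float),
            effective_n=fcomp["effective_n"].to_numpy(dtype=float),
        ),
        length_bin_edges=edges,
        year_range=tuple(manifest["year_range"]),
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Configurations and parameters (YAML)
# ---------------------------------------------------------------------------


def save_configuration(config: Configuration, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_configuration(path_or_preset, structure: ModelStructure | None = None) -> Configuration:
    """Load a configuration from YAML, or by preset name (``cfgI``..``cfgXXII``)."""
    name = str(path_or_preset)
    if name in PRESETS:
        return preset(name, structure=structure)
    p = Path(name)
    if not p.exists():
        raise ConfigurationError(f"{name!r} is neither a preset nor an existing file")
    try:
        d = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise ConfigurationError(f"malformed configuration file {p}: {e}") from e
    if not isinstance(d, dict):
        raise ConfigurationError(f"configuration file {p} must contain a mapping")
    return Configuration.from_dict(d, structure=structure)


def save_parameters(params: ParameterSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def load_parameters(path, structure: ModelStructure | None = None) -> ParameterSet:
    d = yaml.safe_load(Path(path).read_text())
    return ParameterSet.from_dict(d, structure or ModelStructure())


def save_fit(fit: FitResult, directory) -> None:
    """Persist a fit: parameters (YAML), NLL breakdown, gradient/Hessian (CSV)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_parameters(fit.params, d / "params.yaml")
    pd.Series(fit.breakdown.as_dict()).to_csv(d / "nll_breakdown.csv", header=False)
    pd.DataFrame(
        {"name": fit.active_names, "gradient": fit.gradient}
    ).to_csv(d / "gradient.csv", index=False)
    if fit.hessian is not None:
        pd.DataFrame(fit.hessian, columns=fit.active_names).to_csv(
            d / "hessian.csv", index=False
        )
    (d / "fit.json").write_text(
        json.dumps(
            {
                "config": fit.config_name,
                "nll": fit.nll,
                "max_gradient": fit.max_gradient,
                "converged": fit.converged,
                "hessian_ok": fit.hessian_ok,
                "n_reorderings": fit.n_reorderings,
                "at_bounds": fit.at_bounds,
                "phases": fit.assignment.phases,
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Record of a pipeline run: inputs, seed, and every stage output."""

    seed: int
    config_names: list[str]
    data_path: str
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "configs": self.config_names,
                    "data": self.data_path,
                    "outputs": self.outputs,
                    "version": self.version,
                    "started": self.started,
                    "finished": self.finished,
                },
                indent=2,
            )
        )


def run_pipeline(
    configs,
    out_dir,
    data: DataBundle | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    with_mcmc: bool = False,
    mcmc_samples: int = 20_000,
    mcmc_thin: int = 10,
    max_reorderings: int | None = 5,
) -> RunManifest:
    """Simulate (if no data is given), fit each configuration, optionally run
    MCMC + diagnostics on the best replicate, and write a comparison table.

    Outputs land under ``out_dir``; re-running with the same seed reproduces
    every file bit-for-bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = [load_configuration(c) if not isinstance(c, Configuration) else c for c in configs]
    if max_reorderings is not None:
        from dataclasses import replace as dc_replace

        configs = [dc_replace(c, max_reorderings=max_reorderings) for c in configs]
    manifest = RunManifest(
        seed=seed,
        config_names=[c.name for c in configs],
        data_path=str(out / "data"),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    if data is None:
        scenario = default_scenario(seed=seed)
        rng = np.random.default_rng(seed)
        truth, trajectory = simulate_truth(scenario, rng)
        data = observe(trajectory, scenario, rng)
        save_bundle(data, out / "data")
        save_parameters(truth, out / "data" / "true_params.yaml")
        manifest.outputs["data"] = str(out / "data" / "manifest.json")
    rows = []
    n = sample_size(data)
    for cfg in configs:
        fits, summary = run_replicates(
            cfg, data, n_replicates=n_replicates, seed=seed
        )
        best = fits[summary.best_index]
        cfg_dir = out / cfg.name
        save_fit(best, cfg_dir)
        summary_d = summary.as_dict()
        if with_mcmc and best.converged:
            res = mcmc_sample(
                best, n_total=mcmc_samples, thin=mcmc_thin, rng=seed + 17
            )
            res.to_frame().to_csv(cfg_dir / "chains.csv", index=False)
            report = diagnose(res)
            report.rows.to_csv(cfg_dir / "diagnostics.csv", index=False)
            summary_d["coda_pass"] = report.overall_pass
            summary_d["acceptance_rate"] = res.acceptance_rate
        (cfg_dir / "summary.json").write_text(json.dumps(summary_d, indent=2))
        manifest.outputs[cfg.name] = str(cfg_dir)
        rows.append((cfg.name, summary.best_nll, cfg.n_parameters, summary_d))
    table = delta_table([(r[0], r[1], r[2]) for r in rows], n=n)
    extra = pd.DataFrame(
        [
            {
                "config": r[0],
                "median_iterations": r[3]["median_iterations"],
                "pct_best": r[3]["pct_best"],
                "max_g": r[3]["max_g"],
                "coda_pass": r[3].get("coda_pass", None),
            }
            for r in rows
        ]
    )
    table = table.merge(extra, on="config")
    table.to_csv(out / "comparison.csv", index=False)
    manifest.outputs["comparison"] = str(out / "comparison.csv")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out / "run_manifest.json")
    return manifest
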