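"""Configuration schema, file formats, CLI and the end-to-end workflow.

All tabular artifacts are plain delimited text with header rows so runs
are diffable and reproducible.  A single global seed deterministically
derives per-stage substreams by hashing the stage name, so any stage can
be re-run independently with identical results.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    DEFAULT_FREE_PARAMETERS,
    Experiment,
    FitResult,
    ParameterDistribution,
    TimeSeriesDataset,
    fit_parameters,
    monte_carlo_uncertainty,
)
from .doe_designs import (
    DEFAULT_FACTOR_SPACE,
    Design,
    Factor,
    FactorSpace,
    make_design,
)
from .kinetic_model import (
    CarrierSpec,
    CultureSetup,
    KineticParameters,
    simulate_batch,
)
from .mdoe_evaluation import (
    compare_designs,
    recommend_conditions,
)
from .synthetic_data import DEFAULT_CARRIER, GroundTruth, generate_modeling_set

logger = logging.getLogger("mdoe_carrier")

DESIGN_TYPES = ("ccd", "bbd", "lhs", "dopt", "iopt", "lhsd-dopt")


# --------------------------------------------------------------------------
# configuration


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed from the global seed."""
    return int(
        np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
        .generate_state(1)[0]
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config


def _carrier_from_config(config: dict) -> CarrierSpec:
    section = config.get("carrier")
    if section is None:
        return DEFAULT_CARRIER
    return CarrierSpec(
        name=section.get("name", "carrier"),
        area_per_gram=float(section["area_per_gram"]),
        max_area_density=float(section["max_area_density"]),
    )


def params_from_config(config: dict) -> KineticParameters:
    return KineticParameters(**config.get("model", {}))


def setup_from_config(config: dict) -> CultureSetup:
    section = dict(config.get("setup", {}))
    carrier = _carrier_from_config(config)
    section.setdefault("c_MC", 1.0)
    section.setdefault("seed_density", 6000.0)
    section.setdefault("c_Glc", 25.0)
    section.setdefault("c_Gln", 4.0)
    return CultureSetup(carrier=carrier, **section)


def space_from_config(config: dict) -> FactorSpace:
    section = config.get("factor_space")
    if section is None:
        return DEFAULT_FACTOR_SPACE
    return FactorSpace(
        factors=tuple(
            Factor(f["name"], float(f["lower"]), float(f["upper"]), f.get("units", ""))
            for f in section
        )
    )


def validate_config(config: dict) -> list[str]:
    """Collect every violation; an empty list means the config is runnable."""
    problems: list[str] = []
    if not isinstance(config, dict):
        return ["configuration must be a mapping"]

    for section in ("model", "carrier", "setup", "factor_space", "designs",
                    "synthesis", "calibration", "evaluation"):
        if section in config and config[section] is None:
            problems.append(f"section {section!r} is empty")

    try:
        params_from_config(config)
    except (TypeError, ValueError) as exc:
        problems.append(f"model: {exc}")
    try:
        _carrier_from_config(config)
    except (KeyError, TypeError, ValueError) as exc:
        problems.append(f"carrier: {exc}")
    try:
        setup_from_config(config)
    except (TypeError, ValueError) as exc:
        problems.append(f"setup: {exc}")

    for f in config.get("factor_space") or []:
        try:
            Factor(f["name"], float(f["lower"]), float(f["upper"]), f.get("units", ""))
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"factor {f.get('name', '?')}: {exc}")

    designs = config.get("designs", list(DESIGN_TYPES))
    if not designs:
        problems.append("designs: list must not be empty")
    for d in designs or []:
        if d not in DESIGN_TYPES:
            problems.append(f"designs: unknown type {d!r}")

    synthesis = config.get("synthesis", {}) or {}
    if float(synthesis.get("noise", 0.15)) < 0:
        problems.append("synthesis: noise must be >= 0")
    if float(synthesis.get("horizon", 264.0)) <= float(synthesis.get("sampling_interval", 24.0)):
        problems.append("synthesis: horizon must exceed sampling interval")

    calibration = config.get("calibration", {}) or {}
    if float(calibration.get("mc_noise", 0.15)) <= 0:
        problems.append("calibration: mc_noise must be > 0")
    if int(calibration.get("mc_n", 100)) < 2:
        problems.append("calibration: mc_n must be >= 2")

    evaluation = config.get("evaluation", {}) or {}
    if int(evaluation.get("n_sim", 100)) < 2:
        problems.append("evaluation: n_sim must be >= 2")

    if "seed" in config and not isinstance(config["seed"], int):
        problems.append("seed must be an integer")
    return problems


# --------------------------------------------------------------------------
# delimited-text artifacts


def write_trajectory(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def write_dataset(dataset: TimeSeriesDataset, out_dir: str | Path) -> Path:
    """Per-experiment CSV files plus a manifest describing each setup."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for exp in dataset:
        fname = f"{exp.name}.csv"
        exp.to_frame().to_csv(out_dir / fname, index=False)
        rows.append({
            "name": exp.name, "file": fname,
            "c_MC": exp.setup.c_MC, "seed_density": exp.setup.seed_density,
            "c_Glc": exp.setup.c_Glc, "c_Gln": exp.setup.c_Gln,
            "carrier": exp.setup.carrier.name,
            "area_per_gram": exp.setup.carrier.area_per_gram,
            "max_area_density": exp.setup.carrier.max_area_density,
            "relative_error": exp.relative_error.get("X_V", 0.15),
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> TimeSeriesDataset:
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    experiments = []
    for _, row in table.iterrows():
        frame = pd.read_csv(manifest_path.parent / row["file"])
        carrier = CarrierSpec(
            name=str(row.get("carrier", "carrier")),
            area_per_gram=float(row["area_per_gram"]),
            max_area_density=float(row["max_area_density"]),
        )
        setup = CultureSetup(
            carrier=carrier, c_MC=float(row["c_MC"]),
            seed_density=float(row["seed_density"]),
            c_Glc=float(row["c_Glc"]), c_Gln=float(row["c_Gln"]),
        )
        observed = {
            col: frame[col].to_numpy(dtype=float)
            for col in frame.columns if col != "time_h"
        }
        err = float(row.get("relative_error", 0.15))
        experiments.append(Experiment(
            name=str(row["name"]), setup=setup,
            times=frame["time_h"].to_numpy(dtype=float),
            observed=observed,
            relative_error={col: err for col in observed},
        ))
    return TimeSeriesDataset(experiments=experiments)


def write_design(design: Design, path: str | Path) -> None:
    path = Path(path)
    design.to_frame().to_csv(path, index=False)
    sidecar = {
        "design_type": design.design_type,
        "n_runs": design.n_runs,
        "factors": [asdict(f) for f in design.space.factors],
        "metadata": {k: (v if isinstance(v, (int, float, str, bool)) else str(v))
                     for k, v in design.metadata.items()},
    }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_design(path: str | Path) -> Design:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".meta.json").read_text())
    space = FactorSpace(factors=tuple(Factor(**f) for f in sidecar["factors"]))
    natural = pd.read_csv(path).to_numpy(dtype=float)
    return Design(
        design_type=sidecar["design_type"], space=space, natural=natural,
        metadata=sidecar.get("metadata", {}),
    )


def write_fit(fit: FitResult, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fit.summary_frame().to_csv(out_dir / "parameters.csv", index=False)
    pd.DataFrame(
        [{"observable": k, "r_squared": v} for k, v in fit.r_squared.items()]
    ).to_csv(out_dir / "r_squared.csv", index=False)
    (out_dir / "fit.json").write_text(json.dumps({
        "cost": fit.cost, "initial_cost": fit.initial_cost,
        "converged": fit.converged, "message": fit.message,
        "free": list(fit.free_names), "n_starts": fit.n_starts,
    }, indent=2))


def read_fitted_params(out_dir: str | Path, base: KineticParameters | None = None) -> KineticParameters:
    table = pd.read_csv(Path(out_dir) / "parameters.csv")
    values = dict(zip(table["parameter"], table["estimate"]))
    base = base or KineticParameters()
    return base.with_values(**values)


# --------------------------------------------------------------------------
# workflow


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"workflow stage '{stage}' failed: {cause}")
        self.stage = stage


def run_workflow(config: dict, out_dir: str | Path, seed: int | None = None) -> Path:
    """synth -> fit -> mc -> design -> evaluate -> recommend.

    Artifacts are written per stage; a stage failure halts with a
    stage-labelled error, keeping completed artifacts in place.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))

    truth_params = params_from_config(config)
    carrier = _carrier_from_config(config)
    synthesis = config.get("synthesis", {}) or {}
    calib = config.get("calibration", {}) or {}
    evaluation = config.get("evaluation", {}) or {}
    space = space_from_config(config)
    design_types = config.get("designs", list(DESIGN_TYPES))

    def stage(name):
        logger.info("stage %s (seed %d)", name, derive_seed(seed, name))

    # 1. synthesize a modeling campaign from the ground-truth fixture
    try:
        stage("synth")
        truth = GroundTruth(
            params=truth_params, carrier=carrier,
            noise=float(synthesis.get("noise", 0.15)),
            sampling_interval=float(synthesis.get("sampling_interval", 24.0)),
            horizon=float(synthesis.get("horizon", 264.0)),
        )
        train, verify = generate_modeling_set(truth, derive_seed(seed, "synth"))
        write_dataset(train, out_dir / "data" / "train")
        write_dataset(verify, out_dir / "data" / "verify")
    except Exception as exc:
        raise StageError("synth", exc) from exc

    # 2. least-squares calibration
    try:
        stage("fit")
        free = tuple(calib.get("free", DEFAULT_FREE_PARAMETERS))
        fit = fit_parameters(
            train, truth_params, free=free,
            n_starts=int(calib.get("n_starts", 2)),
            seed=derive_seed(seed, "fit"),
            max_nfev=calib.get("max_nfev"),
        )
        write_fit(fit, out_dir / "fit")
    except Exception as exc:
        raise StageError("fit", exc) from exc

    # 3. Monte-Carlo parameter uncertainty
    try:
        stage("mc")
        dist = monte_carlo_uncertainty(
            train, fit,
            n=int(calib.get("mc_n", 100)),
            noise=float(calib.get("mc_noise", 0.15)),
            seed=derive_seed(seed, "mc"),
            mode=str(calib.get("mc_mode", "refit")),
            max_nfev=int(calib.get("mc_max_nfev", 20)),
        )
        dist.to_frame().to_csv(out_dir / "fit" / "parameter_samples.csv", index=False)
    except Exception as exc:
        raise StageError("mc", exc) from exc

    # 4. design generation
    try:
        stage("design")
        designs = {
            dt: make_design(dt, space, n=int(evaluation.get("n_optimal", 16)),
                            seed=derive_seed(seed, f"design:{dt}"))
            for dt in design_types
        }
        (out_dir / "designs").mkdir(exist_ok=True)
        for label, design in designs.items():
            write_design(design, out_dir / "designs" / f"{label}.csv")
    except Exception as exc:
        raise StageError("design", exc) from exc

    # 5. model-based evaluation under parameter uncertainty
    try:
        stage("evaluate")
        template = setup_from_config(config)
        table, evaluated = compare_designs(
            space, designs, template, dist,
            n_sim=int(evaluation.get("n_sim", 100)),
            seed=derive_seed(seed, "evaluate"),
            horizon=float(evaluation.get("horizon", synthesis.get("horizon", 264.0))),
        )
        (out_dir / "evaluation").mkdir(exist_ok=True)
        table.to_csv(out_dir / "evaluation" / "design_comparison.csv", index=False)
        for label, ev in evaluated.items():
            ev.to_frame().to_csv(out_dir / "evaluation" / f"{label}_points.csv", index=False)
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    # 6. recommendation
    try:
        stage("recommend")
        recs = recommend_conditions(evaluated, top_k=int(evaluation.get("top_k", 2)))
        recs.to_csv(out_dir / "recommendations.csv", index=False)
    except Exception as exc:
        raise StageError("recommend", exc) from exc

    summary = {
        "seed": seed,
        "version": __version__,
        "config_hash": f"{zlib.crc32(json.dumps(config, sort_keys=True, default=str).encode()):08x}",
        "r_squared": fit.r_squared,
        "n_parameter_samples": len(dist),
        "designs": {label: d.n_runs for label, d in designs.items()},
        "best_design": str(table.iloc[0]["design"]),
        "recommended": recs.iloc[0].to_dict(),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return out_dir


# --------------------------------------------------------------------------
# CLI


@click.group()
@click.version_option(version=__version__, prog_name="mdoe-carrier")
@click.option("--log-level", default="INFO", show_default=True,
              type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"], case_sensitive=False))
def main(log_level: str) -> None:
    """Model-assisted design of microcarrier-based cell expansion processes."""
    logging.basicConfig(level=getattr(logging, log_level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")


@main.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--t-end", default=264.0, show_default=True, help="horizon in hours")
@click.option("--dt", default=4.0, show_default=True, help="output step in hours")
def simulate(config_path, out_path, t_end, dt):
    """Integrate one batch culture and write the trajectory as CSV."""
    config = load_config(config_path)
    setup = setup_from_config(config)
    params = params_from_config(config)
    t_grid = np.arange(0.0, t_end + 1e-9, dt)
    traj = simulate_batch(setup, params, t_grid)
    write_trajectory(traj.to_frame(), out_path)
    click.echo(f"wrote {out_path}")


@main.command()
@click.option("--truth", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True)
def synth(config_path, out_dir, seed):
    """Generate a synthetic modeling campaign (train + verification)."""
    config = load_config(config_path)
    synthesis = config.get("synthesis", {}) or {}
    truth = GroundTruth(
        params=params_from_config(config), carrier=_carrier_from_config(config),
        noise=float(synthesis.get("noise", 0.15)),
        sampling_interval=float(synthesis.get("sampling_interval", 24.0)),
        horizon=float(synthesis.get("horizon", 264.0)),
    )
    train, verify = generate_modeling_set(truth, seed)
    write_dataset(train, Path(out_dir) / "train")
    write_dataset(verify, Path(out_dir) / "verify")
    click.echo(f"wrote {out_dir}/train and {out_dir}/verify")


@main.command()
@click.option("--data", "manifest", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--n-starts", default=2, show_default=True)
@click.option("--seed", default=0, show_default=True)
def fit(manifest, out_dir, n_starts, seed):
    """Fit kinetic parameters to a dataset manifest by least squares."""
    data = read_dataset(manifest)
    result = fit_parameters(data, KineticParameters(), n_starts=n_starts, seed=seed)
    write_fit(result, out_dir)
    click.echo(f"cost {result.cost:.4g}; R^2 " +
               ", ".join(f"{k}={v:.3f}" for k, v in result.r_squared.items()))


@main.command()
@click.option("--data", "manifest", required=True, type=click.Path(exists=True))
@click.option("--fit", "fit_dir", required=True, type=click.Path(exists=True))
@click.option("--n", default=1000, show_default=True)
@click.option("--noise", default=0.15, show_default=True)
@click.option("--mode", default="refit", show_default=True,
              type=click.Choice(["refit", "jitter"]))
@click.option("--seed", default=0, show_default=True)
def mc(manifest, fit_dir, n, noise, mode, seed):
    """Monte-Carlo parameter uncertainty around a fitted point estimate."""
    data = read_dataset(manifest)
    params = read_fitted_params(fit_dir)
    info = json.loads((Path(fit_dir) / "fit.json").read_text())
    point = FitResult(
        params=params, free_names=tuple(info["free"]), cost=info["cost"],
        initial_cost=info["initial_cost"], r_squared={}, residuals=np.empty(0),
        converged=info["converged"], message=info["message"],
    )
    dist = monte_carlo_uncertainty(data, point, n=n, noise=noise, seed=seed, mode=mode)
    out = Path(fit_dir) / "parameter_samples.csv"
    dist.to_frame().to_csv(out, index=False)
    click.echo(f"wrote {out} ({len(dist)} samples, {dist.n_failed} failures)")


@main.command()
@click.option("--type", "design_type", required=True,
              type=click.Choice(list(DESIGN_TYPES)))
@click.option("--space", "config_path", type=click.Path(exists=True))
@click.option("--n", default=16, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def design(design_type, config_path, n, seed, out_path):
    """Generate an experimental design and write it with a metadata sidecar."""
    space = space_from_config(load_config(config_path)) if config_path else DEFAULT_FACTOR_SPACE
    d = make_design(design_type, space, n=n, seed=seed)
    write_design(d, out_path)
    click.echo(f"wrote {out_path} ({d.n_runs} runs)")


@main.command()
@click.option("--design", "design_paths", required=True, multiple=True,
              type=click.Path(exists=True))
@click.option("--params", "samples_path", required=True, type=click.Path(exists=True))
@click.option("--space", "config_path", type=click.Path(exists=True))
@click.option("--n-sim", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def evaluate(design_paths, samples_path, config_path, n_sim, seed, out_dir):
    """Evaluate design(s) under parameter uncertainty; write comparison tables."""
    config = load_config(config_path) if config_path else {}
    space = space_from_config(config)
    template = setup_from_config(config)
    dist = ParameterDistribution.from_frame(
        pd.read_csv(samples_path), params_from_config(config)
    )
    designs = {Path(p).stem: read_design(p) for p in design_paths}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(designs) == 1:
        from .mdoe_evaluation import attach_desirability, simulate_design

        ((label, d),) = designs.items()
        ev = attach_desirability(simulate_design(d, template, dist, n_sim=n_sim, seed=seed))
        ev.to_frame().to_csv(out_dir / f"{label}_points.csv", index=False)
    else:
        table, evaluated = compare_designs(space, designs, template, dist,
                                           n_sim=n_sim, seed=seed)
        table.to_csv(out_dir / "design_comparison.csv", index=False)
        for label, ev in evaluated.items():
            ev.to_frame().to_csv(out_dir / f"{label}_points.csv", index=False)
    click.echo(f"wrote {out_dir}")


@main.command()
@click.option("--evaluations", "eval_dir", required=True, type=click.Path(exists=True))
@click.option("--designs", "design_dir", required=True, type=click.Path(exists=True))
@click.option("--params", "samples_path", required=True, type=click.Path(exists=True))
@click.option("--space", "config_path", type=click.Path(exists=True))
@click.option("--top", "top_k", default=2, show_default=True)
@click.option("--n-sim", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
def recommend(eval_dir, design_dir, samples_path, config_path, top_k, n_sim, seed):
    """Re-evaluate stored designs and print ranked recommended conditions."""
    config = load_config(config_path) if config_path else {}
    space = space_from_config(config)
    template = setup_from_config(config)
    dist = ParameterDistribution.from_frame(
        pd.read_csv(samples_path), params_from_config(config)
    )
    designs = {p.stem: read_design(p)
               for p in sorted(Path(design_dir).glob("*.csv"))
               if not p.name.endswith(".meta.json")}
    _, evaluated = compare_designs(space, designs, template, dist,
                                   n_sim=n_sim, seed=seed)
    recs = recommend_conditions(evaluated, top_k=top_k)
    out = Path(eval_dir) / "recommendations.csv"
    recs.to_csv(out, index=False)
    click.echo(recs.to_string(index=False))


@main.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--seed", default=None, type=int)
def workflow(config_path, out_dir, seed):
    """Run the full pipeline: synth, fit, mc, design, evaluate, recommend."""
    config = load_config(config_path)
    path = run_workflow(config, out_dir, seed=seed)
    click.echo(f"workflow complete: {path / 'summary.json'}")


if __name__ == "__main__":
    main()
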