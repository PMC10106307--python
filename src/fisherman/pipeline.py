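"""End-to-end orchestration: cohort -> simulate -> fit -> analyse -> report.

Stages communicate only through files under the run directory, each stage
is deterministic given the master seed (sub-seeds are derived with
``numpy.random.SeedSequence``), and a manifest records the configuration
hash and per-stage seeds so a bundle can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, generate_cohort, simulate_cohort_experiment, subjects_frame
from .fitting import fit_cohort
from .stats import (
    apathy_regression,
    correlation_battery,
    fit_latency_lmm,
    prepare_long_table,
    rod_fix_comparison,
)
from .task import DEFAULT_PRICES, TaskSchedule

logger = logging.getLogger("fisherman")

STAGES = ("cohort", "simulate", "fit", "analyse", "report")
_FLOAT_FORMAT = "%.10g"  # stable CSV formatting for byte-identical reruns


@dataclass
class RunConfig:
    seed: int = 1
    n: int = 45
    coupling: float = 0.6
    young_weight: float = 1.0
    price_set: tuple = tuple(DEFAULT_PRICES)
    interval_bounds: tuple = (12.0, 13.0)
    age_band: str = "young"
    mad_k: float = 3.0
    fit_restarts: int = 10
    out_dir: str = "runs/default"
    cohort_overrides: dict = field(default_factory=dict)  # extra CohortSpec fields

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["price_set"] = [float(p) for p in self.price_set]
        d["interval_bounds"] = [float(b) for b in self.interval_bounds]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "price_set" in d:
            d["price_set"] = tuple(d["price_set"])
        if "interval_bounds" in d:
            d["interval_bounds"] = tuple(d["interval_bounds"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(3)
        return {
            "cohort": int(children[0].generate_state(1)[0] % (2**31)),
            "simulate": int(children[1].generate_state(1)[0] % (2**31)),
            "fit": int(children[2].generate_state(1)[0] % (2**31)),
        }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage in order; returns the paths of the bundle files.

    A stage failure aborts with the stage name while earlier outputs stay
    on disk for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seeds = config.stage_seeds()
    paths = {
        "config": out / "config.yaml",
        "subjects": out / "subjects.csv",
        "schedules": out / "schedules.json",
        "records": out / "records.csv",
        "fits": out / "fits.csv",
        "slopes": out / "subject_slopes.csv",
        "results": out / "results.json",
        "manifest": out / "manifest.json",
        "log": log_path,
    }
    stage = "cohort"
    try:
        config.to_yaml(paths["config"])

        # -- cohort -----------------------------------------------------
        spec = CohortSpec(
            n=config.n,
            seed=seeds["cohort"],
            apathy_sr_coupling=config.coupling,
            young_weight=config.young_weight,
            **config.cohort_overrides,
        )
        profiles, params_list = generate_cohort(spec)
        subjects = subjects_frame(profiles, params_list, with_truth=True)
        subjects.to_csv(paths["subjects"], index=False, float_format=_FLOAT_FORMAT)
        logger.info("cohort: %d subjects (coupling target %.2f)", config.n, config.coupling)

        # -- simulate ---------------------------------------------------
        stage = "simulate"
        records, schedules = simulate_cohort_experiment(
            profiles, params_list, seed=seeds["simulate"],
            price_set=config.price_set, interval_bounds=config.interval_bounds,
        )
        records.to_csv(paths["records"], index=False, float_format=_FLOAT_FORMAT)
        _write_json(
            paths["schedules"], {pid: s.to_dict() for pid, s in schedules.items()}
        )
        logger.info("simulate: %d taps recorded", len(records))

        # -- fit --------------------------------------------------------
        stage = "fit"
        fits = fit_cohort(
            records, schedules, seed=seeds["fit"], n_restarts=config.fit_restarts,
            mad_k=config.mad_k,
        )
        fits.to_csv(paths["fits"], index=False, float_format=_FLOAT_FORMAT)
        logger.info("fit: %d/%d converged", int(fits["converged"].sum()), len(fits))

        # -- analyse ----------------------------------------------------
        stage = "analyse"
        results = analyse_bundle(
            records, subjects, fits, age_band=config.age_band, mad_k=config.mad_k,
            slopes_path=paths["slopes"],
        )
        _write_json(paths["results"], results)
        logger.info("analyse: results written")
    except Exception as err:  # noqa: BLE001 - annotate with the failing stage
        logger.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "stages": [s for s in STAGES if s != "report"],
        "files": {k: p.name for k, p in paths.items()},
    }
    _write_json(paths["manifest"], manifest)
    return paths


def analyse_bundle(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    fits: pd.DataFrame,
    age_band: str = "young",
    mad_k: float = 3.0,
    slopes_path: Path | None = None,
) -> dict:
    """The full statistical chain on in-memory tables; returns the results
    dictionary serialised as the bundle's ``results.json``."""
    table = prepare_long_table(records, k=mad_k)
    lmm = fit_latency_lmm(table)
    slopes = lmm.subject_slopes
    if slopes_path is not None:
        slopes.to_csv(slopes_path, index=False, float_format=_FLOAT_FORMAT)

    rod = rod_fix_comparison(records)
    correlations = correlation_battery(fits, slopes, subjects, age_band=age_band)

    apathy = {}
    for outcome in ("bAMI", "sAMI", "eAMI"):
        for predictor in ("price_slope", "environment_slope"):
            try:
                res = apathy_regression(
                    slopes, subjects, outcome=outcome, predictor=predictor, age_band=age_band
                )
            except ValueError as err:
                apathy[f"{outcome}_on_{predictor}"] = {"error": str(err)}
                continue
            apathy[f"{outcome}_on_{predictor}"] = {
                "beta": res.beta, "t": res.t, "p": res.p,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n,
            }

    return {
        "lmm": {
            "fixed_effects": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in lmm.fixed_effects.iterrows()
            },
            "fit_method": lmm.fit_method,
            "converged": lmm.converged,
        },
        "rod_fix": {"t": rod.t, "p": rod.p, "df": rod.df},
        "apathy_glm": apathy,
        "correlations": {
            row["measure"]: {"rho": row["rho"], "p": row["p"], "n": int(row["n"])}
            for _, row in correlations.iterrows()
        },
        "age_band": age_band,
        "n_subjects": int(subjects.shape[0]),
    }


def make_report(out_dir) -> dict[str, Path]:
    """Render figures and a text summary from a completed bundle (no
    recomputation). Raises naming the missing stage if the bundle is
    incomplete."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    needed = {
        "simulate": out / "records.csv",
        "fit": out / "fits.csv",
        "cohort": out / "subjects.csv",
        "analyse": out / "results.json",
    }
    for stage_name, path in needed.items():
        if not path.exists():
            raise FileNotFoundError(f"bundle incomplete: stage {stage_name!r} output missing ({path.name})")
    records = pd.read_csv(needed["simulate"])
    fits = pd.read_csv(needed["fit"])
    subjects = pd.read_csv(needed["cohort"])
    with open(needed["analyse"]) as fh:
        results = json.load(fh)
    slopes = pd.read_csv(out / "subject_slopes.csv")

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    # latency by price and environment
    fish = records[(records["action_type"] == "fish") & (records["straddles_boundary"] == 0)]
    curve = fish.groupby(["environment", "price"])["latency_s"].mean().unstack(0)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for env, style in (("high", "o-"), ("low", "s--")):
        ax.plot(curve.index, curve[env], style, label=f"{env} value")
    ax.set_xlabel("price (yen/tap)")
    ax.set_ylabel("mean latency (s)")
    ax.legend()
    fig.tight_layout()
    paths["latency_by_price"] = figdir / "latency_by_price.png"
    fig.savefig(paths["latency_by_price"], dpi=120)
    plt.close(fig)

    # rod fixing paired plot
    rod = records[records["action_type"] == "rod"]
    rod_means = (
        rod.assign(log_latency=np.log(rod["latency_s"]))
        .groupby(["participant_id", "environment"])["log_latency"].mean().unstack()
    )
    fig, ax = plt.subplots(figsize=(3.8, 3.8))
    ax.scatter(rod_means["high"], rod_means["low"], color="0.4", s=18)
    lims = [rod_means.min().min() - 0.1, rod_means.max().max() + 0.1]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("mean log rod latency, high value")
    ax.set_ylabel("mean log rod latency, low value")
    fig.tight_layout()
    paths["rod_fix"] = figdir / "rod_fix_paired.png"
    fig.savefig(paths["rod_fix"], dpi=120)
    plt.close(fig)

    # apathy scatters
    merged = subjects.merge(slopes, on="participant_id").merge(fits, on="participant_id")
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    axes[0].scatter(merged["bAMI"], merged["price_slope"], color="0.3", s=18)
    axes[0].set_xlabel("bAMI")
    axes[0].set_ylabel("price sensitivity slope")
    axes[1].scatter(merged["bAMI"], merged["reward_sensitivity_hat"], color="0.3", s=18)
    axes[1].set_xlabel("bAMI")
    axes[1].set_ylabel("fitted reward sensitivity")
    fig.tight_layout()
    paths["apathy"] = figdir / "apathy_scatter.png"
    fig.savefig(paths["apathy"], dpi=120)
    plt.close(fig)

    lines = [
        f"subjects: {results['n_subjects']} (band analysed: {results['age_band']})",
        "LMM fixed effects (log latency):",
    ]
    for name, row in results["lmm"]["fixed_effects"].items():
        lines.append(
            f"  {name}: {row['estimate']:+.4g} [{row['ci_low']:.4g}, {row['ci_high']:.4g}] p={row['p']:.3g}"
        )
    lines.append(
        f"rod fixing (high - low): t({results['rod_fix']['df']}) = {results['rod_fix']['t']:.2f}, "
        f"p = {results['rod_fix']['p']:.3g}"
    )
    lines.append("Spearman correlations with bAMI:")
    for name, row in results["correlations"].items():
        lines.append(f"  {name}: rho = {row['rho']:+.2f}, p = {row['p']:.3g}")
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    paths["summary"] = summary
    return paths


def load_schedules(path) -> dict[str, TaskSchedule]:
    with open(path) as fh:
        raw = json.load(fh)
    return {pid: TaskSchedule.from_dict(d) for pid, d in raw.items()}
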