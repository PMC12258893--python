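"""Configuration-driven orchestration: simulate -> half-life -> model -> report.

A run is described by a :class:`RunConfig` (usually loaded from YAML): either
a scoring CSV or a synthetic-experiment design as input, per-environment
generation schedules, the analysis settings (threshold, axes, model family,
contrast family), an output directory and a seed. ``run_analysis`` executes
every stage, writes all result tables plus a manifest with checksums, and is
idempotent for a fixed config and seed. ``report`` renders a human-readable
summary from the saved artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import RnaiMemoryError, ScheduleError, ValidationError
from .glmm import (
    GlmmSpec,
    contrasts_frame,
    filter_singleton_strains,
    fit_glmm,
    marginal_means,
    simulate_residual_check,
    tukey_contrasts,
    wald_test_term,
)
from .scoring import group_replicates, read_scoring_table, write_scoring_table
from .simulate import (
    EnvironmentScenario,
    SimulationDesign,
    schedules_of,
    simulate_experiment,
)
from .trajectories import (
    GenerationSchedule,
    build_trajectory,
    halflife_table,
    summarize_trajectories,
)

logger = logging.getLogger("rnai_memory")


@dataclass(frozen=True)
class AnalysisSettings:
    threshold: float = 50.0
    axes: tuple[str, ...] = ("generations",)
    family: str = "gamma_log"
    contrasts: str = "auto"  # auto | strain | environment_within_strain
    include_singleton_strains: bool = False
    diagnostics: bool = True
    n_sim: int = 250

    def __post_init__(self) -> None:
        object.__setattr__(self, "axes", tuple(self.axes))
        for axis in self.axes:
            if axis not in ("generations", "days"):
                raise ValidationError(f"unknown axis {axis!r}")
        if self.contrasts not in ("auto", "strain", "environment_within_strain"):
            raise ValidationError(f"unknown contrast family {self.contrasts!r}")


@dataclass(frozen=True)
class RunConfig:
    """Exactly one of ``scoring_csv`` / ``design`` supplies the input."""

    design: SimulationDesign | None = None
    scoring_csv: str | None = None
    schedules: Mapping[str, tuple[GenerationSchedule, str]] = field(default_factory=dict)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.design is None) == (self.scoring_csv is None):
            raise ValidationError(
                "exactly one input source (design or scoring_csv) must be set"
            )
        object.__setattr__(self, "schedules", dict(self.schedules))

    def resolved_schedules(self) -> dict[str, tuple[GenerationSchedule, str]]:
        out: dict[str, tuple[GenerationSchedule, str]] = {}
        if self.design is not None:
            out.update(schedules_of(self.design))
        out.update(self.schedules)
        return out


def _schedule_from_dict(d: Mapping) -> tuple[GenerationSchedule, str]:
    schedule = GenerationSchedule(
        base_days=d.get("base_days", None) or GenerationSchedule().base_days,
        arrests=tuple((int(g), float(x)) for g, x in d.get("arrests", [])),
    )
    return schedule, str(d.get("temperature", "20C"))


def design_from_dict(d: Mapping) -> SimulationDesign:
    """Build a :class:`SimulationDesign` from plain config keys."""
    envs = []
    for e in d.get("environments", []) or []:
        schedule, temperature = _schedule_from_dict(e)
        envs.append(
            EnvironmentScenario(
                name=str(e.get("name", "20C_OP50")),
                temperature=temperature,
                schedule=schedule,
                halflife_multiplier=float(e.get("halflife_multiplier", 1.0)),
            )
        )
    kwargs = dict(
        strain_halflives={str(k): float(v) for k, v in d["strain_halflives"].items()},
        seed=int(d.get("seed", 0)),
    )
    for key in (
        "slope",
        "sd_block",
        "sd_rep",
        "dim_fraction",
        "g0_leak",
    ):
        if key in d:
            kwargs[key] = float(d[key])
    for key in ("n_scored", "n_blocks", "n_replicates"):
        if key in d:
            kwargs[key] = int(d[key])
    if "generations" in d:
        kwargs["generations"] = tuple(int(g) for g in d["generations"])
    if envs:
        kwargs["environments"] = tuple(envs)
    return SimulationDesign(**kwargs)


def load_config(path, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; ``seed`` overrides the file's seed."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("run configuration must be a mapping")
    use_seed = int(seed if seed is not None else raw.get("seed", 0))
    design = None
    if "design" in raw:
        d = dict(raw["design"])
        d["seed"] = use_seed
        design = design_from_dict(d)
    schedules = {
        str(name): _schedule_from_dict(sd)
        for name, sd in (raw.get("schedules") or {}).items()
    }
    analysis = AnalysisSettings(**(raw.get("analysis") or {}))
    return RunConfig(
        design=design,
        scoring_csv=raw.get("scoring_csv"),
        schedules=schedules,
        analysis=analysis,
        seed=use_seed,
    )


def _config_fingerprint(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items() if not k.startswith("_")}
        if isinstance(o, (tuple, set)):
            return list(o)
        return str(o)

    blob = json.dumps(config, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RnaiMemoryError):
    """Wraps a stage failure with the stage name (and group key when known)."""


@dataclass
class RunArtifacts:
    outdir: Path
    files: dict[str, Path]
    manifest: dict


def run_analysis(config: RunConfig, outdir) -> RunArtifacts:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Stages: input (simulate or read) -> per-replicate half-lives on every
    requested axis -> per-strain trajectory summaries -> mixed-model fit,
    term tests and Tukey contrasts per axis -> residual diagnostics ->
    manifest. Any stage error removes the partial outputs and re-raises as
    :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    settings = config.analysis

    def emit(name: str, path: Path) -> None:
        files[name] = path

    try:
        # --- stage: input -------------------------------------------------
        stage = "input"
        if config.design is not None:
            table = simulate_experiment(config.design)
            scoring_path = outdir / "scoring.csv"
            write_scoring_table(table, scoring_path)
            emit("scoring", scoring_path)
        else:
            table = read_scoring_table(config.scoring_csv)
        schedules = config.resolved_schedules()
        groups = group_replicates(table)
        for key in groups:
            if key.environment not in schedules:
                raise ScheduleError(
                    f"group {tuple(key)}: no schedule for environment "
                    f"{key.environment!r}"
                )
        logger.info("input: %d records in %d replicate groups", len(table), len(groups))

        # --- stage: halflife ----------------------------------------------
        stage = "halflife"
        hl = halflife_table(
            groups, schedules, axes=settings.axes, threshold=settings.threshold
        )
        hl_path = outdir / "halflife.csv"
        hl.to_csv(hl_path, index=False)
        emit("halflife", hl_path)
        for _, row in hl.iterrows():
            if row["status"] == "censored":
                logger.warning(
                    "censored half-life: block=%s strain=%s environment=%s replicate=%s",
                    row["block"], row["strain"], row["environment"], row["replicate"],
                )

        # --- stage: summary -----------------------------------------------
        stage = "summary"
        summaries = []
        by_cell: dict[tuple[str, str], list] = {}
        for key, records in groups.items():
            schedule, temperature = schedules[key.environment]
            by_cell.setdefault((key.strain, key.environment), []).append(
                build_trajectory(records, schedule, temperature)
            )
        for (strain, environment), trajs in sorted(by_cell.items()):
            s = summarize_trajectories(trajs)
            s.insert(0, "environment", environment)
            s.insert(0, "strain", strain)
            summaries.append(s)
        summary = pd.concat(summaries, ignore_index=True)
        summary_path = outdir / "trajectory_summary.csv"
        summary.to_csv(summary_path, index=False)
        emit("trajectory_summary", summary_path)

        # --- stage: model (per axis) ---------------------------------------
        n_envs = hl["environment"].nunique()
        two_factor = n_envs > 1
        contrast_kind = settings.contrasts
        if contrast_kind == "auto":
            contrast_kind = "environment_within_strain" if two_factor else "strain"
        fit_reports = {}
        for axis in settings.axes:
            stage = f"model[{axis}]"
            data = hl[(hl["axis"] == axis) & (hl["status"] != "censored")].copy()
            n_censored = int((hl["axis"] == axis).sum() - len(data))
            dropped: list[str] = []
            if not settings.include_singleton_strains:
                data, dropped = filter_singleton_strains(data)
            spec = GlmmSpec(
                response="value",
                factors=("strain", "environment") if two_factor else ("strain",),
                interaction=two_factor,
                family=settings.family,
            )
            fit = fit_glmm(data, spec)
            tests = [wald_test_term(fit, "strain")]
            if two_factor:
                tests.append(wald_test_term(fit, "environment"))
                tests.append(wald_test_term(fit, "strain:environment"))
            if contrast_kind == "strain":
                mm = marginal_means(fit, "strain")
            else:
                mm = marginal_means(fit, "environment", by="strain")
            contrasts = contrasts_frame(tukey_contrasts(mm))
            cpath = outdir / f"contrasts_{axis}.csv"
            contrasts.to_csv(cpath, index=False)
            emit(f"contrasts_{axis}", cpath)

            report = {
                "axis": axis,
                "model": fit.summary_dict(),
                "term_tests": [
                    {"term": t.term, "stat": t.stat, "df": t.df, "p": t.p, "kind": t.kind}
                    for t in tests
                ],
                "n_censored": n_censored,
                "dropped_singleton_strains": dropped,
                "contrast_family": contrast_kind,
            }
            if settings.family == "gamma_log" and two_factor:
                report["model"]["family_note"] = (
                    "gamma_log used for the environment model for consistency "
                    "with the strain model; a gaussian_identity fit is available "
                    "via the family setting"
                )
            if settings.diagnostics:
                stage = f"diagnostics[{axis}]"
                diag = simulate_residual_check(
                    fit, n_sim=settings.n_sim, seed=config.seed
                )
                report["diagnostics"] = diag.summary_dict()
            fit_reports[axis] = report
            fpath = outdir / f"fit_{axis}.json"
            fpath.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            emit(f"fit_{axis}", fpath)

        # --- stage: manifest ------------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_sha256": _config_fingerprint(config),
            "n_records": len(table),
            "n_groups": len(groups),
            "axes": list(settings.axes),
            "files": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in files.items()},
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        emit("manifest", manifest_path)
        return RunArtifacts(outdir=outdir, files=files, manifest=manifest)
    except RnaiMemoryError as exc:
        for p in files.values():
            p.unlink(missing_ok=True)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def verify_manifest(outdir) -> bool:
    """Re-checksum every artifact listed in the manifest."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, entry in manifest["files"].items():
        if name == "manifest":
            continue
        p = outdir / entry["path"]
        if not p.exists() or _sha256(p) != entry["sha256"]:
            return False
    return True


def report(outdir, plots: bool = False) -> str:
    """Render a human-readable summary from a completed run's artifacts."""
    outdir = Path(outdir)
    missing = [n for n in ("halflife.csv", "manifest.json") if not (outdir / n).exists()]
    if missing:
        raise ValidationError(f"missing run artifacts: {missing}")
    hl = pd.read_csv(outdir / "halflife.csv")
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = [
        f"RNAi silencing-memory analysis (seed {manifest['seed']}, "
        f"{manifest['n_records']} records, {manifest['n_groups']} replicate groups)",
        "",
    ]
    for axis in manifest["axes"]:
        sub = hl[hl["axis"] == axis]
        modelled = sub[sub["status"] != "censored"]
        lines.append(f"Half-life of silencing memory ({axis}):")
        med = modelled.groupby(["strain", "environment"])["value"].agg(
            ["median", "min", "max", "count"]
        )
        for (strain, env), row in med.iterrows():
            lines.append(
                f"  {strain:>12s} | {env:<12s} median {row['median']:6.2f} "
                f"range [{row['min']:.2f}, {row['max']:.2f}] n={int(row['count'])}"
            )
        n_cens = int((sub["status"] == "censored").sum())
        n_anchor = int((sub["status"] == "left_anchored").sum())
        lines.append(
            f"  censored replicates (excluded from the model): {n_cens}; "
            f"left-anchored at G0: {n_anchor}"
        )
        fit_path = outdir / f"fit_{axis}.json"
        if fit_path.exists():
            fit = json.loads(fit_path.read_text())
            for t in fit["term_tests"]:
                lines.append(
                    f"  {t['kind']} test of {t['term']}: chi2={t['stat']:.2f} "
                    f"df={t['df']} p={t['p']:.3g}"
                )
            if "diagnostics" in fit:
                d = fit["diagnostics"]
                lines.append(
                    f"  residual uniformity KS p={d['ks_p']:.3f}, "
                    f"dispersion ratio {d['dispersion_ratio']:.2f}"
                )
        cpath = outdir / f"contrasts_{axis}.csv"
        if cpath.exists():
            con = pd.read_csv(cpath).sort_values("p_adj")
            lines.append("  top contrasts (Tukey-adjusted):")
            for _, r in con.head(5).iterrows():
                lines.append(
                    f"    {r['term']}: {r['level_a']} vs {r['level_b']} "
                    f"log-ratio {r['log_ratio']:+.3f} (se {r['se']:.3f}) "
                    f"p_adj={r['p_adj']:.3g}"
                )
        lines.append("")
    if plots:
        plot_paths = render_plots(outdir)
        lines.append("plots: " + ", ".join(p.name for p in plot_paths))
    return "\n".join(lines)


def render_plots(outdir) -> list[Path]:
    """Optional figures: mean +/- SD trajectories and half-life boxplots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    out = []
    summary = pd.read_csv(outdir / "trajectory_summary.csv")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (strain, env), sub in summary.groupby(["strain", "environment"]):
        label = strain if summary["environment"].nunique() == 1 else f"{strain} ({env})"
        ax.errorbar(sub["generation"], sub["mean_pct"], yerr=sub["sd_pct"], label=label, capsize=2)
    ax.axhline(50.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("generations after RNAi removal")
    ax.set_ylabel("% GFP-positive (mean +/- SD)")
    ax.legend(fontsize=8)
    p = outdir / "trajectories.png"
    fig.tight_layout()
    fig.savefig(p, dpi=150)
    plt.close(fig)
    out.append(p)

    hl = pd.read_csv(outdir / "halflife.csv")
    for axis, sub in hl.groupby("axis"):
        sub = sub[sub["status"] != "censored"]
        fig, ax = plt.subplots(figsize=(6, 4))
        labels, values = [], []
        for (strain, env), cell in sub.groupby(["strain", "environment"]):
            labels.append(strain if sub["environment"].nunique() == 1 else f"{strain}\n{env}")
            values.append(cell["value"].to_numpy())
        ax.boxplot(values, tick_labels=labels)
        ax.set_ylabel(f"silencing-memory half-life ({axis})")
        p = outdir / f"halflife_boxplot_{axis}.png"
        fig.tight_layout()
        fig.savefig(p, dpi=150)
        plt.close(fig)
        out.append(p)
    return out
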