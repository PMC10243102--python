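"""End-to-end study orchestration behind a YAML configuration.

``run_study`` drives the full flow — simulate or load a cohort, preprocess
(contaminant exclusion, total-area normalisation), PCA overview, per-pair
OPLS-DA with Monte-Carlo cross-validation and permutation testing,
univariate screening and panel construction, panel ROC assessment, and the
ensemble risk classification of the external cohort — writing every table
and report into a run directory. A single global seed deterministically
spawns per-stage seeds, so identical configurations yield byte-identical
outputs and individual stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import roc as roc_mod
from . import univariate as uni
from .multivariate import OplsDaSpec, fit_pca, select_components
from .profiles import (DEFAULT_EXCLUSIONS, ProfileMatrix, exclude_metabolites,
                       normalize_total_area, read_profiles, scale)
from .synthetic import CohortConfig, generate_cohort
from .validation import format_p_value, monte_carlo_cv, permutation_test

__all__ = ["RunConfig", "run_study", "render_reports"]

log = logging.getLogger("metabrisk")

SCHEMA_VERSION = 1

_DEFAULT_CONFIG: dict[str, Any] = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "output_dir": "metabrisk_run",
    "log_level": "INFO",
    "input": {"path": None, "synthetic": {}},
    "preprocess": {"exclude": list(DEFAULT_EXCLUSIONS), "scaling": "unit-variance"},
    "comparisons": [
        ["HC", "PC I+II"], ["HC", "PC III"], ["HC", "PC IV"],
        ["DM2", "PC I+II"], ["DM2", "PC III"], ["DM2", "PC IV"],
    ],
    "validation": {"n_cv": 100, "n_perm": 1000, "n_perm_inner": 20,
                   "max_components": 3, "train_fraction": 0.9},
    "univariate": {"threshold": 0.05, "stage_groups": ["PC I+II", "PC III", "PC IV"]},
    "roc": {"n_repeats": 100, "classifier": "random-forest", "train_fraction": 2 / 3},
    "ensemble": {"stages": ["PC I+II", "PC III", "PC IV"], "control": "DM2",
                 "external_group": "RODM", "n_models": 20, "min_accuracy": 80.0,
                 "external_subsample_size": 25, "k_ortho": 1, "n_cv": 20},
}


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


def _merge(defaults: Mapping[str, Any], given: Mapping[str, Any], path: str = "") -> dict:
    out = dict(defaults)
    for key, value in given.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and key != "synthetic":
            if not isinstance(value, Mapping):
                raise ConfigError(f"{where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Validated study configuration (see ``_DEFAULT_CONFIG`` for the schema)."""

    data: dict[str, Any]

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        merged = _merge(_DEFAULT_CONFIG, dict(d))
        if merged["schema_version"] != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {merged['schema_version']} "
                f"(expected {SCHEMA_VERSION})"
            )
        return cls(merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


def _load_cohort(cfg: RunConfig, seed: int, outdir: Path) -> ProfileMatrix:
    inp = cfg["input"]
    if inp.get("path"):
        log.info("reading cohort from %s", inp["path"])
        return read_profiles(inp["path"])
    overrides = dict(inp.get("synthetic") or {})
    overrides.setdefault("seed", seed)
    config = CohortConfig(**overrides)
    matrix, truth = generate_cohort(config)
    matrix.to_csv(outdir / "cohort.csv")
    truth.to_csv(outdir / "truth_labels.csv")
    return matrix


def _check_groups(cfg: RunConfig, matrix: ProfileMatrix) -> None:
    present = set(matrix.groups.unique())
    wanted = {g for pair in cfg["comparisons"] for g in pair}
    e = cfg["ensemble"]
    wanted |= set(e["stages"]) | {e["control"], e["external_group"]}
    wanted |= set(cfg["univariate"]["stage_groups"])
    missing = wanted - present
    if missing:
        raise ConfigError(f"configured group(s) absent from the data: {sorted(missing)}")


def run_study(config: "RunConfig | Mapping[str, Any] | str | Path") -> Path:
    """Run every stage and write all artifacts into the output directory."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, Mapping):
        config = RunConfig.from_dict(config)
    logging.basicConfig(level=getattr(logging, str(config["log_level"]).upper(), logging.INFO))
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(int(config["seed"]))
    stage_seeds = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(
            ["cohort", "discriminate", "permutation", "roc", "risk"], master.spawn(5)
        )
    }

    try:
        matrix = _load_cohort(config, stage_seeds["cohort"], outdir)
        _check_groups(config, matrix)
    except Exception:
        log.exception("stage 'input' failed")
        raise

    # -- preprocess ----------------------------------------------------------
    pre = config["preprocess"]
    try:
        matrix = exclude_metabolites(matrix, [n for n in pre["exclude"]
                                              if n in matrix.metabolite_names])
        matrix = normalize_total_area(matrix)
        matrix.to_csv(outdir / "profiles_preprocessed.csv")
    except Exception:
        log.exception("stage 'preprocess' failed")
        raise

    # -- PCA overview --------------------------------------------------------
    pca = fit_pca(scale(matrix, pre["scaling"]), k=min(5, matrix.n_samples - 1,
                                                       matrix.n_metabolites))
    (outdir / "pca.json").write_text(json.dumps(
        {"explained_variance_ratio": [round(float(v), 6)
                                      for v in pca.explained_variance_ratio]}, indent=2))

    # -- OPLS-DA per pair + validation ---------------------------------------
    val = config["validation"]
    rows = []
    perm_children = np.random.SeedSequence(stage_seeds["permutation"]).spawn(
        len(config["comparisons"]))
    disc_children = np.random.SeedSequence(stage_seeds["discriminate"]).spawn(
        len(config["comparisons"]))
    for (control, case), pchild, dchild in zip(config["comparisons"], perm_children,
                                               disc_children):
        log.info("discriminating %s vs %s", control, case)
        sub = matrix.select_groups([control, case])
        x, y = sub.values, sub.groups.to_numpy()
        dseed = int(dchild.generate_state(1)[0] % 2**31)
        n_total = select_components(x, y, val["max_components"], seed=dseed,
                                    n_iterations=min(val["n_cv"], 20),
                                    train_fraction=val["train_fraction"],
                                    scaling=pre["scaling"])
        spec = OplsDaSpec(k_ortho=n_total - 1, scaling=pre["scaling"],
                          classes=(control, case))
        cv = monte_carlo_cv(x, y, spec, n_iterations=val["n_cv"],
                            train_fraction=val["train_fraction"], seed=dseed,
                            positive_class=case)
        perm = permutation_test(x, y, spec, n_permutations=val["n_perm"],
                                seed=int(pchild.generate_state(1)[0] % 2**31),
                                n_iterations=val["n_perm_inner"],
                                train_fraction=val["train_fraction"],
                                positive_class=case,
                                observed=cv.mean_performance.accuracy)
        mp = cv.mean_performance
        rows.append({
            "comparison": f"{control} vs {case}", "components": n_total,
            "accuracy": round(mp.accuracy, 1), "sensitivity": round(mp.sensitivity, 1),
            "specificity": round(mp.specificity, 1), "p_value": perm.p_value,
            "p_formatted": perm.formatted_p(),
        })
    performance = pd.DataFrame(rows)
    performance.to_csv(outdir / "performance.csv", index=False)

    # -- univariate + panel ---------------------------------------------------
    u = config["univariate"]
    tables = [uni.compare_groups(matrix, control, case)
              for control, case in config["comparisons"]]
    for t in tables:
        slug = t.comparison.replace(" ", "_").replace("+", "plus")
        t.to_csv(outdir / f"univariate_{slug}.csv")
    panel = uni.panel_overlap(tables, threshold=u["threshold"])
    (outdir / "panel.json").write_text(json.dumps(
        {"metabolites": list(panel.metabolites), "threshold": panel.threshold,
         "comparisons": list(panel.comparisons)}, indent=2))
    trends = uni.stage_trend_screen(matrix, u["stage_groups"])
    trends.to_csv(outdir / "stage_trends.csv", index=False)

    # -- panel ROC ------------------------------------------------------------
    r = config["roc"]
    roc_json: dict[str, Any] = {}
    if panel.metabolites:
        for control, case in config["comparisons"]:
            sub = matrix.select_groups([control, case])
            res = roc_mod.panel_auc(sub, sub.groups.to_numpy(), panel.metabolites,
                                    n_repeats=r["n_repeats"], seed=stage_seeds["roc"],
                                    classifier=r["classifier"],
                                    train_fraction=r["train_fraction"],
                                    positive_class=case)
            roc_json[f"{control} vs {case}"] = res.to_dict()
    (outdir / "roc.json").write_text(json.dumps(roc_json, indent=2))

    # -- risk ensemble --------------------------------------------------------
    e = config["ensemble"]
    report = ens.run_risk_analysis(
        matrix, stages=e["stages"], control=e["control"],
        external_group=e["external_group"], n_models=e["n_models"],
        min_accuracy=e["min_accuracy"],
        external_subsample_size=e["external_subsample_size"],
        k_ortho=e["k_ortho"], n_cv=e["n_cv"], seed=stage_seeds["risk"])
    report.to_csv(outdir / "risk_report.csv")
    report.to_json(outdir / "risk_report.json")

    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.data, sort_keys=True))
    render_reports(outdir)
    return outdir


def render_reports(run_dir: str | Path) -> str:
    """Render a human-readable markdown summary of a completed run."""
    run_dir = Path(run_dir)
    lines = ["# Study summary", ""]

    perf_path = run_dir / "performance.csv"
    if not perf_path.exists():
        raise FileNotFoundError(f"missing artifact: {perf_path}")
    perf = pd.read_csv(perf_path)
    lines += ["## Discrimination performance (Monte-Carlo CV)", ""]
    lines.append("| comparison | components | accuracy % | sensitivity % | specificity % | P |")
    lines.append("|---|---|---|---|---|---|")
    for _, row in perf.iterrows():
        lines.append(
            f"| {row['comparison']} | {row['components']} | {row['accuracy']:.1f} "
            f"| {row['sensitivity']:.1f} | {row['specificity']:.1f} | {row['p_formatted']} |"
        )
    lines.append("")

    panel_path = run_dir / "panel.json"
    if panel_path.exists():
        panel = json.loads(panel_path.read_text())
        lines += ["## Biomarker panel", "",
                  f"{len(panel['metabolites'])} metabolite(s) significant in every "
                  f"comparison at adjusted P < {panel['threshold']}:",
                  ", ".join(panel["metabolites"]) or "(none)", ""]

    roc_path = run_dir / "roc.json"
    if roc_path.exists():
        roc_data = json.loads(roc_path.read_text())
        if roc_data:
            lines += ["## Panel ROC", ""]
            for comp, d in roc_data.items():
                lines.append(
                    f"- {comp}: AUC {d['auc']:.3f} (95% CI {d['ci_lower']:.3f}-"
                    f"{d['ci_upper']:.3f}){' — acceptable' if d['acceptable'] else ''}"
                )
            lines.append("")

    risk_path = run_dir / "risk_report.json"
    if not risk_path.exists():
        raise FileNotFoundError(f"missing artifact: {risk_path}")
    risk = json.loads(risk_path.read_text())
    lines += ["## External-cohort risk classification", ""]
    lines.append(f"Models built: {risk['n_models_total']}; qualifying per ensemble: "
                 + ", ".join(f"{k}: {v}" for k, v in risk["n_qualifying"].items()))
    if risk["at_risk_overall"]:
        lines.append(f"At-risk samples ({len(risk['at_risk_overall'])}): "
                     + ", ".join(risk["at_risk_overall"]))
        for name, sel in risk["at_risk"].items():
            lines.append(f"- {name}: {len(sel)} selected")
        if risk["agreement"] is not None:
            lines.append(
                f"Stage assignment: {risk['n_early']} early, {risk['n_late']} late; "
                f"agreement between sources {risk['agreement']:.1f}%"
            )
    else:
        lines.append("At-risk samples: none selected")
    lines.append("")

    text = "\n".join(lines)
    (run_dir / "summary.md").write_text(text)
    return text
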