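"""Ensemble vote-ratio risk classification of an external cohort.

The scheme builds, for each disease-stage group, an ensemble of two-class
OPLS-DA models discriminating that stage from the type-2-diabetes control
group (default 20 models per ensemble; three stage ensembles give 60 models
in total). Each model is trained on its own random stratified resample and
its quality is the mean Monte-Carlo cross-validated accuracy of the same
resampling scheme; only models whose accuracy exceeds a floor (default 80%)
may vote.

Every qualifying model then scores an independent random subsample of the
external recent-onset-diabetes cohort (default 25 of its samples, keeping
group sizes balanced). For each external sample the *classification ratio*
is the percentage of cancer-class votes among the models in whose subsample
the sample appeared: ratio = 100 * votes / applications. A sample is flagged
at risk by an ensemble as soon as its ratio is positive, i.e. at least one
qualifying model called it cancer-like. Flagged samples are finally assigned
an early/late stage label two ways — (a) by whether the early-stage ensemble
itself flagged them, and (b) by the majority vote of a separate
early-vs-late-stage ensemble — and the agreement between the two assignments
is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .multivariate import OplsDaSpec, OPLSDA, OPLSDAResults
from .profiles import ProfileMatrix
from .validation import monte_carlo_cv, _stratified_train_indices

__all__ = [
    "EnsembleSpec",
    "FittedEnsembleModel",
    "EnsembleResult",
    "VoteRecord",
    "AtRiskSelection",
    "StageAssignment",
    "RiskReport",
    "build_ensemble",
    "classify_external",
    "select_at_risk",
    "assign_stage",
    "run_risk_analysis",
    "format_ratio",
]

EARLY, LATE = "early", "late"


def format_ratio(votes: int, applications: int) -> str:
    """Render a vote ratio as e.g. ``"38.5% (5/13)"`` (one decimal place)."""
    if applications == 0:
        return "n/a (0/0)"
    return f"{100.0 * votes / applications:.1f}% ({votes}/{applications})"


@dataclass(frozen=True)
class EnsembleSpec:
    """Configuration of one discrimination ensemble.

    ``control`` is coded 0 and ``case`` (the cancer-stage group, whose votes
    are counted) is coded 1.
    """

    control: str
    case: str
    n_models: int = 20
    min_accuracy: float = 80.0
    external_subsample_size: int = 25
    k_ortho: int = 1
    n_cv: int = 20
    train_fraction: float = 0.9
    scaling: "str | None" = "unit-variance"

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.external_subsample_size < 1:
            raise ValueError("external_subsample_size must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.control} vs {self.case}"


@dataclass
class FittedEnsembleModel:
    model: OPLSDAResults
    accuracy: float
    seed: int

    def qualifies(self, min_accuracy: float) -> bool:
        return self.accuracy > min_accuracy


@dataclass
class EnsembleResult:
    spec: EnsembleSpec
    models: list[FittedEnsembleModel]

    @property
    def qualifying(self) -> list[FittedEnsembleModel]:
        return [m for m in self.models if m.qualifies(self.spec.min_accuracy)]

    @property
    def n_qualifying(self) -> int:
        return len(self.qualifying)


@dataclass
class VoteRecord:
    """Votes for one external sample in one ensemble."""

    sample_id: str
    votes: int
    applications: int

    def __post_init__(self) -> None:
        if not 0 <= self.votes <= self.applications:
            raise ValueError(
                f"votes ({self.votes}) must lie in [0, applications={self.applications}] "
                f"for sample {self.sample_id}"
            )

    @property
    def ratio(self) -> "float | None":
        """Percentage of cancer votes among applications; None if never applied."""
        if self.applications == 0:
            return None
        return 100.0 * self.votes / self.applications

    def formatted(self) -> str:
        return format_ratio(self.votes, self.applications)


def build_ensemble(m: ProfileMatrix, spec: EnsembleSpec,
                   seed: "int | None" = None) -> EnsembleResult:
    """Fit ``spec.n_models`` OPLS-DA models on independent stratified resamples.

    Each model's accuracy is the mean accuracy of a Monte-Carlo
    cross-validation run with its own seed; the model itself is fitted on a
    fresh stratified training resample. An ensemble may end up with zero
    qualifying models (e.g. on null data); downstream code must check
    ``n_qualifying``.
    """
    sub = m.select_groups([spec.control, spec.case])
    counts = sub.group_counts()
    if min(counts.values()) < 5:
        raise ValueError(f"both groups need >= 5 samples, got {counts}")
    x = sub.values
    y = sub.groups.to_numpy()
    model_spec = OplsDaSpec(k_ortho=spec.k_ortho, scaling=spec.scaling,
                            classes=(spec.control, spec.case))
    children = np.random.SeedSequence(seed).spawn(spec.n_models)
    models: list[FittedEnsembleModel] = []
    arr = x.to_numpy(dtype=float)
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        cv = monte_carlo_cv(arr, y, model_spec, n_iterations=spec.n_cv,
                            train_fraction=spec.train_fraction, seed=child_seed,
                            positive_class=spec.case)
        rng = np.random.default_rng(child_seed)
        train = _stratified_train_indices(y, spec.train_fraction, rng)
        fitted = OPLSDA(arr[train], y[train], classes=(spec.control, spec.case),
                        scaling=spec.scaling).fit(spec.k_ortho)
        fitted.column_names = sub.metabolite_names
        models.append(FittedEnsembleModel(fitted, cv.mean_performance.accuracy, child_seed))
    return EnsembleResult(spec, models)


def classify_external(ensemble: "EnsembleResult | Sequence[FittedEnsembleModel]",
                      external: ProfileMatrix, spec: "EnsembleSpec | None" = None,
                      seed: "int | None" = None) -> list[VoteRecord]:
    """Score external samples with every qualifying model of an ensemble.

    Each qualifying model draws its own random subsample (without
    replacement) of ``spec.external_subsample_size`` external samples and
    classifies them; votes (case-class calls) and applications are
    accumulated per sample. Denominators therefore vary from sample to
    sample. Returns one VoteRecord per external sample (possibly with zero
    applications).
    """
    if isinstance(ensemble, EnsembleResult):
        if spec is None:
            spec = ensemble.spec
        models = ensemble.qualifying
    else:
        models = list(ensemble)
    if spec is None:
        raise ValueError("spec is required when passing a bare model list")
    if not models:
        raise ValueError("no qualifying models: ensemble cannot classify the external cohort")
    n_ext = external.n_samples
    size = min(spec.external_subsample_size, n_ext)
    sample_ids = external.sample_ids
    arr = external.values.to_numpy(dtype=float)
    votes = np.zeros(n_ext, dtype=int)
    apps = np.zeros(n_ext, dtype=int)
    children = np.random.SeedSequence(seed).spawn(len(models))
    for fm, child in zip(models, children):
        rng = np.random.default_rng(child)
        idx = rng.choice(n_ext, size=size, replace=False)
        pred = fm.model.predict(arr[idx])
        apps[idx] += 1
        votes[idx] += (pred == spec.case).astype(int)
    return [VoteRecord(sid, int(v), int(a)) for sid, v, a in zip(sample_ids, votes, apps)]


@dataclass
class AtRiskSelection:
    per_ensemble: dict[str, tuple[str, ...]]
    overall: tuple[str, ...]


def select_at_risk(records_by_ensemble: Mapping[str, Sequence[VoteRecord]],
                   rule: str = "any-positive") -> AtRiskSelection:
    """Flag external samples: selected by an ensemble iff its ratio is > 0.

    The overall at-risk set is the union over ensembles. ``rule`` is kept
    explicit for future variants; only ``"any-positive"`` is defined.
    """
    if rule != "any-positive":
        raise ValueError(f"unknown selection rule {rule!r}")
    per: dict[str, tuple[str, ...]] = {}
    overall: list[str] = []
    for name, records in records_by_ensemble.items():
        sel = tuple(r.sample_id for r in records if r.ratio is not None and r.ratio > 0)
        per[name] = sel
        for s in sel:
            if s not in overall:
                overall.append(s)
    return AtRiskSelection(per, tuple(overall))


@dataclass
class StageAssignment:
    """Early/late stage labels for the at-risk samples from two sources.

    Source A: early iff the sample was flagged by the early-stage-vs-control
    ensemble. Source B: the early-vs-late ensemble's majority classification
    (ties resolved to late). Agreement is the percentage of concordant
    samples.
    """

    table: pd.DataFrame  # index sample_id; columns source_a, source_b
    agreement: float

    @property
    def n_early_b(self) -> int:
        return int((self.table["source_b"] == EARLY).sum())

    @property
    def n_late_b(self) -> int:
        return int((self.table["source_b"] == LATE).sum())


def assign_stage(at_risk: Sequence[str], early_records: Sequence[VoteRecord],
                 late_source: "Mapping[str, str] | Sequence[VoteRecord]") -> StageAssignment:
    """Assign early/late labels to at-risk samples from two sources.

    ``early_records`` are the early-stage-vs-control ensemble's vote records
    (source A: early iff flagged there). ``late_source`` is either an explicit
    sample -> "early"/"late" mapping or the early-vs-late ensemble's vote
    records with votes counting *late*-class calls (majority -> late; ties
    -> late).
    """
    at_risk = [str(s) for s in at_risk]
    if not at_risk:
        raise ValueError("at-risk set is empty")
    early_sel = {
        r.sample_id for r in early_records if r.ratio is not None and r.ratio > 0
    }
    if isinstance(late_source, Mapping):
        labels_b = {str(k): str(v) for k, v in late_source.items()}
    else:
        labels_b = {}
        for r in late_source:
            if r.applications > 0:
                labels_b[r.sample_id] = LATE if r.ratio >= 50.0 else EARLY
    missing = [s for s in at_risk if s not in labels_b]
    if missing:
        raise ValueError(f"no early-vs-late classification for sample(s): {missing}")
    rows = []
    concordant = 0
    for s in at_risk:
        a = EARLY if s in early_sel else LATE
        b = labels_b[s]
        concordant += a == b
        rows.append((s, a, b))
    table = pd.DataFrame(rows, columns=["sample_id", "source_a", "source_b"]).set_index("sample_id")
    return StageAssignment(table, 100.0 * concordant / len(at_risk))


@dataclass
class RiskReport:
    """Full risk-classification result for an external cohort."""

    records_by_ensemble: dict[str, list[VoteRecord]]
    early_late_records: list[VoteRecord]
    selection: AtRiskSelection
    stages: "StageAssignment | None"
    n_models_total: int
    n_qualifying: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """One row per external sample: ratios and votes per ensemble plus
        the final stage label (mirrors the vote-ratio report layout)."""
        ids = [r.sample_id for r in next(iter(self.records_by_ensemble.values()))]
        data: dict[str, list] = {"sample_id": ids}
        for name, records in self.records_by_ensemble.items():
            by_id = {r.sample_id: r for r in records}
            data[f"{name} ratio"] = [by_id[i].formatted() for i in ids]
        by_id_el = {r.sample_id: r for r in self.early_late_records}
        data["early vs late ratio"] = [
            by_id_el[i].formatted() if i in by_id_el else "n/a (0/0)" for i in ids
        ]
        data["at_risk"] = [i in self.selection.overall for i in ids]
        stage_col = []
        for i in ids:
            if self.stages is not None and i in self.stages.table.index:
                stage_col.append(self.stages.table.loc[i, "source_b"])
            else:
                stage_col.append("")
        data["stage"] = stage_col
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = {
            "n_models_total": self.n_models_total,
            "n_qualifying": self.n_qualifying,
            "at_risk": {k: list(v) for k, v in self.selection.per_ensemble.items()},
            "at_risk_overall": list(self.selection.overall),
            "agreement": None if self.stages is None else self.stages.agreement,
            "n_early": None if self.stages is None else self.stages.n_early_b,
            "n_late": None if self.stages is None else self.stages.n_late_b,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_risk_analysis(m: ProfileMatrix, *, stages: Sequence[str] = ("PC I+II", "PC III", "PC IV"),
                      control: str = "DM2", external_group: str = "RODM",
                      early_stage: "str | None" = None, late_stage: "str | None" = None,
                      n_models: int = 20, min_accuracy: float = 80.0,
                      external_subsample_size: int = 25, k_ortho: int = 1,
                      n_cv: int = 20, seed: "int | None" = None) -> RiskReport:
    """The full prediction scheme: stage-vs-control ensembles classify the
    external cohort; the early-vs-late ensemble stages the flagged samples.

    The early/late ensemble's votes count *late*-stage calls, so its majority
    classification (tie -> late) provides the source-B label.
    """
    stages = list(stages)
    early_stage = early_stage or stages[0]
    late_stage = late_stage or stages[-1]
    children = np.random.SeedSequence(seed).spawn(2 * (len(stages) + 1))
    records_by_ensemble: dict[str, list[VoteRecord]] = {}
    n_qualifying: dict[str, int] = {}
    external = m.select_groups([external_group])
    total = 0
    for i, stage in enumerate(stages):
        spec = EnsembleSpec(control=control, case=stage, n_models=n_models,
                            min_accuracy=min_accuracy,
                            external_subsample_size=external_subsample_size,
                            k_ortho=k_ortho, n_cv=n_cv)
        ens = build_ensemble(m, spec, seed=int(children[2 * i].generate_state(1)[0] % 2**31))
        total += len(ens.models)
        n_qualifying[spec.name] = ens.n_qualifying
        if ens.n_qualifying:
            records = classify_external(
                ens, external, seed=int(children[2 * i + 1].generate_state(1)[0] % 2**31)
            )
        else:
            records = [VoteRecord(s, 0, 0) for s in external.sample_ids]
        records_by_ensemble[spec.name] = records

    el_spec = EnsembleSpec(control=early_stage, case=late_stage, n_models=n_models,
                           min_accuracy=min_accuracy,
                           external_subsample_size=external_subsample_size,
                           k_ortho=k_ortho, n_cv=n_cv)
    el_ens = build_ensemble(m, el_spec, seed=int(children[-2].generate_state(1)[0] % 2**31))
    n_qualifying[el_spec.name] = el_ens.n_qualifying
    if el_ens.n_qualifying:
        el_records = classify_external(
            el_ens, external, seed=int(children[-1].generate_state(1)[0] % 2**31)
        )
    else:
        el_records = [VoteRecord(s, 0, 0) for s in external.sample_ids]

    selection = select_at_risk(records_by_ensemble)
    stages_assign = None
    if selection.overall:
        early_name = f"{control} vs {early_stage}"
        assignable = [
            s for s in selection.overall
            if any(r.sample_id == s and r.applications > 0 for r in el_records)
        ]
        if assignable:
            stages_assign = assign_stage(
                assignable, records_by_ensemble[early_name], el_records
            )
    return RiskReport(records_by_ensemble, el_records, selection, stages_assign,
                      n_models_total=total, n_qualifying=n_qualifying)
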