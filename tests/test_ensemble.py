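import numpy as np
import pytest

from metabrisk.datasets import reference_vote_records
from metabrisk.ensemble import (
    EARLY,
    LATE,
    EnsembleSpec,
    VoteRecord,
    assign_stage,
    build_ensemble,
    classify_external,
    format_ratio,
    select_at_risk,
)
from metabrisk.profiles import exclude_metabolites, normalize_total_area
from metabrisk.synthetic import CohortConfig, generate_cohort


class TestVoteRecord:
    @pytest.mark.parametrize("votes,apps,expected", [
        (5, 13, 38.5), (12, 13, 92.3), (0, 12, 0.0), (8, 9, 88.9), (5, 6, 83.3),
    ])
    def test_ratio_arithmetic(self, votes, apps, expected):
        r = VoteRecord("s", votes, apps)
        assert round(r.ratio, 1) == expected
        assert r.formatted() == f"{expected:.1f}% ({votes}/{apps})"

    def test_votes_cannot_exceed_applications(self):
        with pytest.raises(ValueError, match="votes"):
            VoteRecord("s", 3, 2)

    def test_zero_applications_means_undefined_ratio(self):
        assert VoteRecord("s", 0, 0).ratio is None

    def test_format_ratio_rendering(self):
        assert format_ratio(5, 13) == "38.5% (5/13)"


class TestSelectionRules:
    def test_reference_records_reproduce_published_selection_counts(self):
        records, _ = reference_vote_records()
        sel = select_at_risk(records)
        assert len(sel.per_ensemble["DM2 vs PC I+II"]) == 4
        assert len(sel.per_ensemble["DM2 vs PC III"]) == 5
        assert len(sel.per_ensemble["DM2 vs PC IV"]) == 12
        assert len(sel.overall) == 12
        assert set(sel.per_ensemble["DM2 vs PC I+II"]) == {
            "RODM 048", "RODM 061", "RODM 065", "RODM 071"}

    def test_all_zero_ratios_select_nothing(self):
        sel = select_at_risk({"e": [VoteRecord("a", 0, 5), VoteRecord("b", 0, 3)]})
        assert sel.overall == ()

    def test_stage_assignment_agreement(self):
        records, labels = reference_vote_records()
        sel = select_at_risk(records)
        sa = assign_stage(sel.overall, records["DM2 vs PC I+II"], labels)
        assert sa.agreement == pytest.approx(75.0)
        assert sa.n_early_b == 5 and sa.n_late_b == 7

    def test_identical_sources_agree_fully(self):
        early = [VoteRecord("a", 2, 4), VoteRecord("b", 0, 4)]
        sa = assign_stage(["a", "b"], early, {"a": EARLY, "b": LATE})
        assert sa.agreement == 100.0

    def test_majority_rule_with_tie_to_late(self):
        # votes count late-stage calls: 2/4 is a tie -> late; 1/4 -> early
        late_records = [VoteRecord("a", 2, 4), VoteRecord("b", 1, 4)]
        sa = assign_stage(["a", "b"], [VoteRecord("a", 0, 1), VoteRecord("b", 0, 1)],
                          late_records)
        assert list(sa.table["source_b"]) == [LATE, EARLY]

    def test_empty_at_risk_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_stage([], [], {})


@pytest.fixture(scope="module")
def two_group_cohort():
    cfg = CohortConfig(
        group_sizes={"HC": 4, "DM2": 20, "PC I+II": 16, "PC III": 16, "PC IV": 16,
                     "RODM": 30},
        effect_size=2.0, rodm_pc_fraction=0.2, seed=13,
    )
    matrix, truth = generate_cohort(cfg)
    matrix = normalize_total_area(
        exclude_metabolites(matrix, ["Glycerol", "Propylene glycol"]))
    return matrix, truth


class TestBuildEnsemble:
    def test_three_stage_ensembles_total_sixty_models(self, two_group_cohort):
        matrix, _ = two_group_cohort
        total = 0
        for stage in ("PC I+II", "PC III", "PC IV"):
            spec = EnsembleSpec(control="DM2", case=stage, n_models=20, n_cv=3)
            total += len(build_ensemble(matrix, spec, seed=1).models)
        assert total == 60

    def test_seed_determinism(self, two_group_cohort):
        matrix, _ = two_group_cohort
        spec = EnsembleSpec(control="DM2", case="PC IV", n_models=6, n_cv=5)
        a = build_ensemble(matrix, spec, seed=2)
        b = build_ensemble(matrix, spec, seed=2)
        assert [m.accuracy for m in a.models] == [m.accuracy for m in b.models]
        assert [m.seed for m in a.qualifying] == [m.seed for m in b.qualifying]

    def test_null_groups_yield_no_qualifying_models(self):
        cfg = CohortConfig(
            group_sizes={"HC": 4, "DM2": 20, "PC I+II": 4, "PC III": 4, "PC IV": 20,
                         "RODM": 4},
            effect_size=1.0, rodm_pc_fraction=0.0, seed=21,
        )
        matrix, _ = generate_cohort(cfg)
        matrix = normalize_total_area(
            exclude_metabolites(matrix, ["Glycerol", "Propylene glycol"]))
        spec = EnsembleSpec(control="DM2", case="PC IV", n_models=10, n_cv=10)
        ens = build_ensemble(matrix, spec, seed=3)
        assert ens.n_qualifying <= 1  # ~0 expected at the 80% accuracy floor


class TestClassifyExternal:
    def test_votes_bounded_and_applications_near_expectation(self, two_group_cohort):
        matrix, _ = two_group_cohort
        spec = EnsembleSpec(control="DM2", case="PC IV", n_models=12, n_cv=5,
                            external_subsample_size=15)
        ens = build_ensemble(matrix, spec, seed=4)
        external = matrix.select_groups(["RODM"])
        records = classify_external(ens, external, seed=5)
        assert all(0 <= r.votes <= r.applications for r in records)
        n_q = ens.n_qualifying
        expected = n_q * 15 / external.n_samples
        sd = np.sqrt(n_q * (15 / external.n_samples) * (1 - 15 / external.n_samples))
        mean_apps = np.mean([r.applications for r in records])
        assert abs(mean_apps - expected) <= max(3 * sd, 1e-9)

    def test_no_qualifying_models_is_explicit_error(self, two_group_cohort):
        matrix, _ = two_group_cohort
        spec = EnsembleSpec(control="DM2", case="PC IV", n_models=2, n_cv=3,
                            min_accuracy=101.0)  # nothing can qualify
        ens = build_ensemble(matrix, spec, seed=6)
        assert ens.n_qualifying == 0
        with pytest.raises(ValueError, match="qualifying"):
            classify_external(ens, matrix.select_groups(["RODM"]))
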