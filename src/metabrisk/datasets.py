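"""Bundled reference worked-example data.

Two small reference tables from a published pancreatic-cancer staging study
of plasma NMR metabolomic profiles are bundled so the panel-selection and
vote-ratio arithmetic can be validated against known printed results:

* ``reference_panel_pvalues`` — adjusted Wilcoxon P-values of 13 plasma
  metabolites across the six stage-vs-control comparisons; exactly nine of
  the thirteen are significant (P < 0.05) in all six.
* ``reference_vote_records`` — ensemble vote records (cancer votes /
  applications) of the 12 recent-onset-diabetes samples flagged by at least
  one stage-vs-control ensemble, plus their early/late label from the
  early-vs-late-stage ensemble. Fed through the selection and stage
  assignment rules these reproduce the published counts: 4, 5 and 12 samples
  flagged per ensemble, 5 early and 7 late labels, and 75% agreement.
"""

from __future__ import annotations

from .ensemble import EARLY, LATE, VoteRecord
from .univariate import UnivariateTable

__all__ = [
    "REFERENCE_COMPARISONS",
    "REFERENCE_PANEL_PVALUES",
    "REFERENCE_VOTES",
    "reference_panel_tables",
    "reference_vote_records",
]

REFERENCE_COMPARISONS = (
    "HC vs PC I+II",
    "HC vs PC III",
    "HC vs PC IV",
    "DM2 vs PC I+II",
    "DM2 vs PC III",
    "DM2 vs PC IV",
)

# metabolite -> adjusted P-values in REFERENCE_COMPARISONS order.
# Values printed as 0.0000 mean "< 0.0001" and are stored as 0.0.
REFERENCE_PANEL_PVALUES: dict[str, tuple[float, ...]] = {
    "3-hydroxyisovalerate": (0.0211, 0.0377, 0.0190, 0.0231, 0.0452, 0.0187),
    "creatine": (0.0001, 0.0001, 0.0001, 0.0003, 0.0006, 0.0004),
    "fumarate": (0.0026, 0.0014, 0.0005, 0.0122, 0.0160, 0.0052),
    "gluconate": (0.0285, 0.0039, 0.0003, 0.0003, 0.0000, 0.0000),
    "lysine": (0.0000, 0.0000, 0.0004, 0.0059, 0.0055, 0.0269),
    "mannose": (0.0000, 0.0001, 0.0000, 0.0004, 0.0041, 0.0000),
    "N-acetylcysteine": (0.0047, 0.0007, 0.0009, 0.0428, 0.0123, 0.0204),
    "proline": (0.0187, 0.0100, 0.0313, 0.0059, 0.0032, 0.0187),
    "propionate": (0.0147, 0.0279, 0.0089, 0.0004, 0.0032, 0.0000),
    "3-hydroxybutyrate": (0.0085, 0.0008, 0.0001, 0.0030, 0.0304, 0.0950),
    "alanine": (0.1401, 0.1352, 0.0002, 0.1651, 0.2362, 0.0021),
    "glutamate": (0.0497, 0.2666, 0.0792, 0.1598, 0.3952, 0.1838),
    "valine": (0.4274, 0.3973, 0.0444, 0.7576, 0.8943, 0.2436),
}

# sample -> ((votes, applications) per stage ensemble, early/late label from
# the early-vs-late ensemble). Ensembles in order: DM2 vs PC I+II,
# DM2 vs PC III, DM2 vs PC IV.
REFERENCE_VOTES: dict[str, tuple[tuple[int, int], tuple[int, int], tuple[int, int], str]] = {
    "RODM 001": ((0, 12), (0, 10), (9, 9), LATE),
    "RODM 008": ((0, 8), (11, 11), (5, 7), LATE),
    "RODM 011": ((0, 7), (0, 13), (11, 11), LATE),
    "RODM 015": ((0, 7), (0, 6), (11, 11), LATE),
    "RODM 032": ((0, 7), (0, 10), (8, 8), EARLY),
    "RODM 036": ((0, 11), (0, 7), (11, 11), LATE),
    "RODM 037": ((0, 9), (0, 10), (7, 7), LATE),
    "RODM 048": ((12, 13), (12, 12), (9, 9), EARLY),
    "RODM 061": ((8, 8), (10, 10), (5, 13), EARLY),
    "RODM 065": ((5, 6), (6, 9), (8, 8), LATE),
    "RODM 066": ((0, 8), (0, 8), (9, 11), EARLY),
    "RODM 071": ((8, 9), (7, 7), (15, 16), EARLY),
}

_STAGE_ENSEMBLES = ("DM2 vs PC I+II", "DM2 vs PC III", "DM2 vs PC IV")


def reference_panel_tables() -> list[UnivariateTable]:
    """The reference P-value matrix as one UnivariateTable per comparison."""
    tables = []
    for i, comp in enumerate(REFERENCE_COMPARISONS):
        tables.append(
            UnivariateTable.from_adjusted_pvalues(
                comp, {m: ps[i] for m, ps in REFERENCE_PANEL_PVALUES.items()}
            )
        )
    return tables


def reference_vote_records() -> tuple[dict[str, list[VoteRecord]], dict[str, str]]:
    """The reference vote records per stage ensemble plus early/late labels.

    Returns ``(records_by_ensemble, early_late_labels)``; the labels come
    from the early-vs-late-stage ensemble's published classification.
    """
    records: dict[str, list[VoteRecord]] = {name: [] for name in _STAGE_ENSEMBLES}
    labels: dict[str, str] = {}
    for sample, (*pairs, label) in REFERENCE_VOTES.items():
        for name, (votes, apps) in zip(_STAGE_ENSEMBLES, pairs):
            records[name].append(VoteRecord(sample, votes, apps))
        labels[sample] = label
    return records, labels
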