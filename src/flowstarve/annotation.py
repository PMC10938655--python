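"""Multi-expert vote aggregation and inter-rater agreement.

Each breath carries exactly five expert votes in ``{normal_mild, moderate,
severe, wrong_confusing}``. Consensus is 3-of-5 majority voting with two
exclusion rules applied first:

(a) at least 2 of the 5 raters flagged the breath as wrong/confusing
    (technical invalidity trumps any severity majority), and
(b) the severity vote pattern 2 normal-mild / 1 moderate / 2 severe, a
    polarized split that no adjudication can make reliable.

Breaths with no ≥3 plurality route to senior adjudication, represented here
as a pre-recorded data field rather than an interactive step.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .io import SEVERITY_CLASSES

WRONG_CONFUSING = "wrong_confusing"
VOTE_VALUES = SEVERITY_CLASSES + (WRONG_CONFUSING,)
N_RATERS = 5

#: short codes used in annotation CSV files
VOTE_CODES = {"N": "normal_mild", "M": "moderate", "S": "severe", "W": WRONG_CONFUSING}
ADJUDICATION_CODES = {**{k: v for k, v in VOTE_CODES.items() if k != "W"}, "X": "exclude"}


@dataclass
class AnnotationRecord:
    """Five expert votes for one breath, plus any senior adjudication."""

    breath_id: str
    votes: Sequence[str]
    adjudicated_label: Optional[str] = None  # severity class or "exclude"

    def __post_init__(self) -> None:
        if len(self.votes) != N_RATERS:
            raise ValueError(
                f"breath '{self.breath_id}': expected {N_RATERS} votes, "
                f"got {len(self.votes)}"
            )
        bad = set(self.votes) - set(VOTE_VALUES)
        if bad:
            raise ValueError(f"breath '{self.breath_id}': unknown votes {sorted(bad)}")


@dataclass
class AggregationResult:
    breath_id: str
    outcome: str  # labeled | needs_adjudication | excluded
    label: Optional[str]
    reason: str


def aggregate_votes(record: AnnotationRecord) -> AggregationResult:
    """Deterministic consensus for one breath.

    Order of application: exclusion rule (a), exclusion rule (b), 3-of-5
    majority, then adjudication for anything left over. The result depends
    only on the vote multiset, never on rater order.
    """
    counts = Counter(record.votes)
    if counts[WRONG_CONFUSING] >= 2:
        return AggregationResult(
            record.breath_id, "excluded", None,
            f"{counts[WRONG_CONFUSING]} of {N_RATERS} raters flagged wrong/confusing",
        )
    sev = tuple(counts[c] for c in SEVERITY_CLASSES)
    if sev == (2, 1, 2):
        return AggregationResult(
            record.breath_id, "excluded", None,
            "polarized 2 normal-mild / 1 moderate / 2 severe pattern",
        )
    for cls in SEVERITY_CLASSES:
        if counts[cls] >= 3:
            return AggregationResult(
                record.breath_id, "labeled", cls, f"{counts[cls]}-of-5 majority"
            )
    if record.adjudicated_label is not None:
        if record.adjudicated_label == "exclude":
            return AggregationResult(
                record.breath_id, "excluded", None, "excluded by senior adjudication"
            )
        return AggregationResult(
            record.breath_id, "labeled", record.adjudicated_label,
            "labeled by senior adjudication",
        )
    return AggregationResult(
        record.breath_id, "needs_adjudication", None, "no 3-of-5 majority"
    )


def percentage_agreement(records: Sequence[AnnotationRecord]) -> float:
    """Percent of breaths labeled by 3-of-5 majority without adjudication."""
    if not records:
        raise ValueError("cannot compute agreement on an empty set of records")
    n_majority = 0
    for rec in records:
        bare = AnnotationRecord(rec.breath_id, rec.votes)  # ignore adjudication
        if aggregate_votes(bare).outcome == "labeled":
            n_majority += 1
    return 100.0 * n_majority / len(records)


def vote_count_table(records: Sequence[AnnotationRecord]) -> np.ndarray:
    """(n_items, 3) matrix of severity-vote counts, for kappa computation.

    Records containing any wrong/confusing vote are dropped: the chance-
    corrected agreement statistic assumes a constant number of raters per
    item over the same category set.
    """
    rows = []
    for rec in records:
        counts = Counter(rec.votes)
        if counts[WRONG_CONFUSING] > 0:
            continue
        rows.append([counts[c] for c in SEVERITY_CLASSES])
    return np.asarray(rows, dtype=float)


def fleiss_kappa(records: Sequence[AnnotationRecord]) -> float:
    """Fleiss' (1971) chance-corrected multi-rater agreement.

    κ = (P̄ − P̄e) / (1 − P̄e) with per-item agreement
    P_i = (Σ_j n_ij² − n) / (n (n−1)), n = 5 raters. Returns ``nan`` when
    every vote falls in a single category across all items (P̄e = 1, the
    statistic is undefined).
    """
    table = vote_count_table(records)
    if table.size == 0:
        raise ValueError("no records with 5 severity votes")
    p_cat = table.sum(axis=0) / table.sum()
    if np.isclose((p_cat**2).sum(), 1.0):
        return float("nan")
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def agreement_report(records: Sequence[AnnotationRecord]) -> dict:
    """Summary dict: item count, majority-agreement %, Fleiss' kappa."""
    return {
        "n_breaths": len(records),
        "pct_majority_agreement": percentage_agreement(records),
        "fleiss_kappa": fleiss_kappa(records),
    }


def read_annotations(path) -> list[AnnotationRecord]:
    """Read an annotation CSV (breath_id, rater1..rater5, adjudicated)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    rater_cols = [f"rater{i}" for i in range(1, N_RATERS + 1)]
    for col in ["breath_id"] + rater_cols:
        if col not in df.columns:
            raise ValueError(f"annotation table missing column '{col}'")
    records = []
    for _, row in df.iterrows():
        votes = []
        for col in rater_cols:
            code = str(row[col]).strip()
            if code not in VOTE_CODES:
                raise ValueError(
                    f"breath '{row['breath_id']}': unknown vote code '{code}'"
                )
            votes.append(VOTE_CODES[code])
        adj = None
        if "adjudicated" in df.columns and pd.notna(row.get("adjudicated")):
            code = str(row["adjudicated"]).strip()
            if code:
                if code not in ADJUDICATION_CODES:
                    raise ValueError(
                        f"breath '{row['breath_id']}': unknown adjudication '{code}'"
                    )
                adj = ADJUDICATION_CODES[code]
        records.append(AnnotationRecord(str(row["breath_id"]), votes, adj))
    return records


def aggregate_table(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Aggregate a batch of records into a tidy outcome table."""
    results = [aggregate_votes(r) for r in records]
    return pd.DataFrame(
        {
            "breath_id": [r.breath_id for r in results],
            "outcome": [r.outcome for r in results],
            "label": [r.label for r in results],
            "reason": [r.reason for r in results],
        }
    )
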