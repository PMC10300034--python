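"""Sample-retention quality control.

A sample passes outright when all four amplified fragments have mean
coverage above a threshold (default 15x) *and* its haplogroup-classifier
quality score is above a threshold (default 0.85). A sample that fails
*only* the score condition is rescued if its minimum depth across the
whole reference is at least 5x. Kinship exclusions (one member of each
detected relative pair, flagged upstream) are removed from the retained
set last.

Note: applying the rescue clause to *every* failure category would also
rescue coverage failures; restricting it to score-only failures is what
reproduces the published 302-to-264 accounting, so that is the rule
implemented here (the report carries a note to that effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class QcError(ValueError):
    pass


@dataclass(frozen=True)
class QcRecord:
    """Per-sample QC measurements for the four amplified fragments."""

    sample_id: str
    fragment_mean_coverage: tuple[float, float, float, float]
    classifier_score: float
    min_coverage: float
    kinship_excluded: bool = False

    def __post_init__(self) -> None:
        if len(self.fragment_mean_coverage) != 4:
            raise QcError(f"sample {self.sample_id}: expected 4 fragment coverages")
        if not 0.0 <= self.classifier_score <= 1.0:
            raise QcError(f"sample {self.sample_id}: score {self.classifier_score} outside [0,1]")
        if self.min_coverage < 0 or any(c < 0 for c in self.fragment_mean_coverage):
            raise QcError(f"sample {self.sample_id}: negative coverage")


@dataclass
class QcReport:
    """Filter accounting: disjoint, exhaustive categories over the input."""

    n_input: int
    n_fail_both: int
    n_fail_coverage_only: int
    n_fail_score_only: int
    n_rescued: int
    n_kinship_removed: int
    n_retained: int
    retained_ids: list[str] = field(default_factory=list)
    note: str = (
        "rescue (min coverage >= 5x) applied to score-only failures; "
        "coverage failures are discarded regardless of the rescue clause"
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_input", self.n_input),
            ("n_fail_both", self.n_fail_both),
            ("n_fail_coverage_only", self.n_fail_coverage_only),
            ("n_fail_score_only", self.n_fail_score_only),
            ("n_rescued", self.n_rescued),
            ("n_kinship_removed", self.n_kinship_removed),
            ("n_retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["category", "count"])


def apply_sample_qc(
    records: Sequence[QcRecord],
    frag_threshold: float = 15.0,
    score_threshold: float = 0.85,
    rescue_min_coverage: float = 5.0,
    strict: bool = True,
) -> QcReport:
    """Apply the retention rule and report per-category counts.

    ``strict`` uses ``>`` for the fragment-coverage and score thresholds
    (the published wording "above"); set False for ``>=``.
    """
    if not records:
        raise QcError("no QC records supplied")
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise QcError(f"duplicate sample ids {dup}")
    if frag_threshold <= 0 or score_threshold <= 0 or rescue_min_coverage <= 0:
        raise QcError("thresholds must be positive")

    def above(value: float, thr: float) -> bool:
        return value > thr if strict else value >= thr

    n_both = n_cov = n_score_dropped = n_rescued = n_kin = 0
    retained: list[str] = []
    for rec in records:
        cov_ok = all(above(c, frag_threshold) for c in rec.fragment_mean_coverage)
        score_ok = above(rec.classifier_score, score_threshold)
        if cov_ok and score_ok:
            keep = True
        elif not cov_ok and not score_ok:
            n_both += 1
            keep = False
        elif not cov_ok:
            n_cov += 1
            keep = False
        else:  # score-only failure: rescue on whole-reference depth
            if rec.min_coverage >= rescue_min_coverage:
                n_rescued += 1
                keep = True
            else:
                n_score_dropped += 1
                keep = False
        if keep:
            if rec.kinship_excluded:
                n_kin += 1
            else:
                retained.append(rec.sample_id)

    return QcReport(
        n_input=len(records),
        n_fail_both=n_both,
        n_fail_coverage_only=n_cov,
        n_fail_score_only=n_score_dropped + n_rescued,
        n_rescued=n_rescued,
        n_kinship_removed=n_kin,
        n_retained=len(retained),
        retained_ids=retained,
    )


def read_qc_table(path: str | Path) -> list[QcRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "frag1", "frag2", "frag3", "frag4", "classifier_score",
              "min_coverage", "kinship_excluded"}
    if not needed <= set(df.columns):
        raise QcError(f"QC table missing columns {sorted(needed - set(df.columns))}")
    return [
        QcRecord(
            sample_id=str(r.sample_id),
            fragment_mean_coverage=(r.frag1, r.frag2, r.frag3, r.frag4),
            classifier_score=float(r.classifier_score),
            min_coverage=float(r.min_coverage),
            kinship_excluded=bool(r.kinship_excluded),
        )
        for r in df.itertuples(index=False)
    ]


def write_qc_table(path: str | Path, records: Iterable[QcRecord]) -> None:
    rows = [
        (r.sample_id, *r.fragment_mean_coverage, r.classifier_score, r.min_coverage,
         int(r.kinship_excluded))
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "frag1", "frag2", "frag3", "frag4", "classifier_score",
                 "min_coverage", "kinship_excluded"],
    ).to_csv(path, sep="\t", index=False)
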