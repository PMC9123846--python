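"""Seizure-outcome pooling and the outcome-weighted voxel efficacy map.

Per-study seizure-reduction outcomes (percent decrease in seizure frequency
from baseline) are pooled into one mean seizure reduction per stimulation
target; study medians are accepted as means without distributional
correction. Each target's binarised connectivity map is then weighted by its
pooled seizure reduction and the weighted maps are combined voxelwise into
an efficacy map of percent improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .seedmap import GridMismatchError, StatMap, _check_grid

__all__ = [
    "StudyRecord",
    "OutcomeTable",
    "EfficacyMap",
    "pool_seizure_reduction",
    "pool_all_targets",
    "combine_weighted",
    "read_study_table",
    "write_study_table",
    "synthetic_study_records",
]

STUDY_COLUMNS = ["target", "n_patients", "outcome_value", "outcome_kind",
                 "followup_months"]


@dataclass
class StudyRecord:
    """One clinical study's pooled outcome for one stimulation target."""

    target: str
    n_patients: int
    outcome_value: float          # percent seizure reduction
    outcome_kind: str = "mean"    # "mean" or "median" (medians taken as means)
    followup_months: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not -100.0 <= self.outcome_value <= 100.0:
            raise ValueError("outcome_value must lie in [-100, 100] percent")
        if self.outcome_kind not in ("mean", "median"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")


@dataclass
class OutcomeTable:
    """Pooled mean seizure reduction per target, with study bookkeeping."""

    weights: Dict[str, float]             # target -> pooled percent
    n_studies: Dict[str, int] = field(default_factory=dict)
    total_patients: Dict[str, int] = field(default_factory=dict)
    weighting: str = "simple"

    def __post_init__(self) -> None:
        for target, w in self.weights.items():
            if not -100.0 <= w <= 100.0:
                raise ValueError(f"pooled value for {target!r} outside [-100, 100]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": t,
                "pooled_seizure_reduction": self.weights[t],
                "n_studies": self.n_studies.get(t, np.nan),
                "total_patients": self.total_patients.get(t, np.nan),
            }
            for t in self.weights
        ]
        return pd.DataFrame(rows)


@dataclass
class EfficacyMap:
    """Voxelwise percent-improvement map combined from weighted binary maps."""

    data: np.ndarray
    affine: np.ndarray
    contributing_targets: List[str]
    mode: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.mode not in ("mean", "sum"):
            raise ValueError(f"unknown efficacy mode {self.mode!r}")


def pool_seizure_reduction(
    studies: List[StudyRecord], target: str, weighting: str = "simple"
) -> float:
    """Pooled mean seizure reduction (percent) for one target.

    ``weighting="simple"`` averages per-study outcomes with equal weight;
    ``weighting="by_n"`` weights each study by its patient count. Study
    medians enter as if they were means. Raises if the target has no studies.
    """
    if weighting not in ("simple", "by_n"):
        raise ValueError(f"unknown weighting {weighting!r}")
    values = np.array([s.outcome_value for s in studies if s.target == target])
    ns = np.array([s.n_patients for s in studies if s.target == target], dtype=float)
    if values.size == 0:
        raise ValueError(f"no studies for target {target!r}")
    if weighting == "simple":
        return float(values.mean())
    return float(np.average(values, weights=ns))


def pool_all_targets(
    studies: List[StudyRecord], weighting: str = "simple"
) -> OutcomeTable:
    """Pool every target present in the study list into an OutcomeTable."""
    targets = sorted({s.target for s in studies})
    weights, counts, totals = {}, {}, {}
    for t in targets:
        weights[t] = pool_seizure_reduction(studies, t, weighting)
        counts[t] = sum(1 for s in studies if s.target == t)
        totals[t] = sum(s.n_patients for s in studies if s.target == t)
    return OutcomeTable(weights=weights, n_studies=counts,
                        total_patients=totals, weighting=weighting)


def combine_weighted(
    maps: Dict[str, StatMap], weights: OutcomeTable, mode: str = "mean"
) -> EfficacyMap:
    """Combine binarised target maps, weighted by pooled seizure reduction.

    mode="sum": voxel value sum_i w_i * b_i(v); mode="mean": that sum divided
    by the number of maps covering the voxel (zero where none do). Every map
    must share a grid and have a weight; target order is irrelevant.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown efficacy mode {mode!r}")
    if not maps:
        raise ValueError("no maps to combine")
    targets = sorted(maps)
    missing = [t for t in targets if t not in weights.weights]
    if missing:
        raise ValueError(f"no pooled outcome for targets: {missing}")
    first = maps[targets[0]]
    weighted = np.zeros(first.grid_shape)
    coverage = np.zeros(first.grid_shape)
    for t in targets:
        m = maps[t]
        if m.kind != "binary":
            raise ValueError(f"map for {t!r} is not binary")
        _check_grid(first.grid_shape, first.affine, m.grid_shape, m.affine)
        weighted += weights.weights[t] * m.data
        coverage += m.data
    if mode == "mean":
        out = np.divide(weighted, coverage, out=np.zeros_like(weighted),
                        where=coverage > 0)
    else:
        out = weighted
    return EfficacyMap(data=out, affine=first.affine,
                       contributing_targets=targets, mode=mode)


def read_study_table(path) -> List[StudyRecord]:
    """Read study records from delimited text (TSV/CSV, sniffed by pandas)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    return [
        StudyRecord(
            target=str(row.target),
            n_patients=int(row.n_patients),
            outcome_value=float(row.outcome_value),
            outcome_kind=str(row.outcome_kind),
            followup_months=float(row.followup_months),
        )
        for row in df.itertuples()
    ]


def write_study_table(studies: List[StudyRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "target": s.target,
                "n_patients": s.n_patients,
                "outcome_value": s.outcome_value,
                "outcome_kind": s.outcome_kind,
                "followup_months": s.followup_months,
            }
            for s in studies
        ]
    ).to_csv(path, sep="\t", index=False)


# Published per-target review summaries for the three established epilepsy
# stimulation targets: (number of studies, total patients, pooled mean
# seizure reduction %, mean follow-up months).
_TARGET_SUMMARIES = {
    "ANT": (23, 330, 59.6, 34.2),
    "CMT": (8, 90, 69.3, 28.7),
    "HC": (13, 107, 64.6, 33.9),
}


def synthetic_study_records() -> List[StudyRecord]:
    """Synthetic per-study outcome list consistent with the published review.

    The underlying review reports, per target, only the pooled summaries
    (study count, total patients, pooled mean seizure reduction); the
    per-study outcomes themselves are not reproduced here. This constructs a
    synthetic stand-in study list deterministically: for each target the
    study outcomes are a symmetric spread about the pooled mean (so their
    simple average reproduces it exactly) and patient counts partition the
    reported total. Suitable for exercising the pooling and weighting
    machinery; not a source of real per-study data.
    """
    records: List[StudyRecord] = []
    for target, (k, total_n, mean_sr, followup) in _TARGET_SUMMARIES.items():
        step = 30.0 / max(k - 1, 1)      # plausible between-study spread
        base, rem = divmod(total_n, k)
        for i in range(k):
            offset = step * (i - (k - 1) / 2.0)
            records.append(
                StudyRecord(
                    target=target,
                    n_patients=base + (1 if i < rem else 0),
                    outcome_value=mean_sr + offset,
                    outcome_kind="mean" if i % 2 == 0 else "median",
                    followup_months=followup,
                )
            )
    return records
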