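"""Deterministic, auditable allocation of subjects to project phases.

Phase 1 holds training data; Phases 2 and 3 validation data.  iTIMM-cohort
subjects go to Phase 3 unconditionally.  The rest are stratified by coalesced
disease category: within each category, subject ids are sorted, shuffled by a
seeded RNG and the first ``round_half_up(fraction * n)`` go to Phase 1, the
remainder to Phase 2.  Allocation is per subject (never per session) so no
subject leaks between training and validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DiseasePattern, ValidationError, aggregate_pattern_counts, render_pattern

__all__ = ["AllocationPlan", "allocate_phases", "summarize_allocation", "round_half_up"]

CATEGORIES = ("F", "D", "I", "H")
ITIMM_COHORT = "b_iTIMM"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class AllocationPlan:
    phase_by_subject: dict[str, int]
    category_by_subject: dict[str, str]
    seed: int
    fractions: dict[str, float]
    counts: pd.DataFrame = field(repr=False, default=None)

    def subjects_in_phase(self, phase: int) -> list[str]:
        return sorted(s for s, p in self.phase_by_subject.items() if p == phase)


def allocate_phases(
    subjects: Sequence[tuple[str, str, str]],
    fractions: Mapping[str, float] | float = 0.5,
    seed: int = 0,
) -> AllocationPlan:
    """Allocate ``(subject_id, cohort, category)`` rows to phases 1/2/3."""
    if isinstance(fractions, (int, float)):
        fractions = {c: float(fractions) for c in CATEGORIES}
    fractions = {c: float(fractions.get(c, 0.5)) for c in CATEGORIES}
    for c, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"fraction for {c} must be in [0, 1]")

    seen: set[str] = set()
    by_category: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    phase: dict[str, int] = {}
    category: dict[str, str] = {}
    for subject_id, cohort, cat in subjects:
        if subject_id in seen:
            raise ValidationError(f"duplicate subject_id {subject_id!r}")
        seen.add(subject_id)
        if cat not in CATEGORIES:
            raise ValidationError(f"unknown category {cat!r}")
        category[subject_id] = cat
        if cohort == ITIMM_COHORT:
            phase[subject_id] = 3
        else:
            by_category[cat].append(subject_id)

    rng = np.random.default_rng(seed)
    for cat in CATEGORIES:  # fixed iteration order => deterministic draws
        ids = sorted(by_category[cat])
        order = rng.permutation(len(ids))
        k = round_half_up(fractions[cat] * len(ids))
        for rank, idx in enumerate(order):
            phase[ids[idx]] = 1 if rank < k else 2

    counts = (
        pd.DataFrame(
            {"category": [category[s] for s in phase], "phase": list(phase.values())}
        )
        .pivot_table(index="category", columns="phase", aggfunc="size", fill_value=0)
        if phase
        else pd.DataFrame()
    )
    return AllocationPlan(
        phase_by_subject=phase,
        category_by_subject=category,
        seed=seed,
        fractions=fractions,
        counts=counts,
    )


def summarize_allocation(
    plan: AllocationPlan,
    session_table: Sequence[tuple[str, str, DiseasePattern]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category table (per subject) and pattern table (per session).

    ``session_table`` rows are ``(session_id, subject_id, pattern)``.  Every
    session's subject must appear in the plan.
    """
    cat_rows = []
    for subject_id, phase in plan.phase_by_subject.items():
        cat_rows.append({"category": plan.category_by_subject[subject_id], "phase": phase})
    if cat_rows:
        cat_table = pd.DataFrame(cat_rows).pivot_table(
            index="category", columns="phase", aggfunc="size", fill_value=0
        )
        cat_table.columns = [int(c) for c in cat_table.columns]
        cat_table["Total"] = cat_table.sum(axis=1)
        cat_table.loc["Total"] = cat_table.sum(axis=0)
    else:
        cat_table = pd.DataFrame(
            [[0]], index=pd.Index(["Total"], name="category"), columns=["Total"]
        )

    records = []
    for session_id, subject_id, pattern in session_table:
        if subject_id not in plan.phase_by_subject:
            raise ValidationError(f"orphan session {session_id!r}: subject not in plan")
        records.append((session_id, plan.phase_by_subject[subject_id], pattern))
    pattern_table = aggregate_pattern_counts(records)
    return cat_table, pattern_table


def plan_to_frame(plan: AllocationPlan) -> pd.DataFrame:
    """allocation.csv layout: subject_id, category, phase."""
    rows = [
        {
            "subject_id": s,
            "category": plan.category_by_subject[s],
            "phase": p,
        }
        for s, p in sorted(plan.phase_by_subject.items())
    ]
    return pd.DataFrame(rows, columns=["subject_id", "category", "phase"])
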