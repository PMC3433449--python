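"""Group-level summaries: t-tests, rhythm proportions, condition reports.

Comparisons follow the classical Student's t-test (pooled-variance unpaired
form, difference-based paired form), two-sided, with the usual star coding
(* for P<0.05, ** for P<0.01). Welch's correction is available behind a flag
but is not the default. Data are summarised as mean ± SEM. No multiple-testing
correction is applied; reports footnote the number of comparisons instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .calcium import RhythmClassification
from .errors import ContractError

__all__ = [
    "TTestResult",
    "ConditionSummary",
    "CellResult",
    "compare_groups",
    "category_proportions",
    "build_report",
]

CONDITIONS = ("baseline", "baseline_paced", "adrenaline", "adrenaline_paced")
RHYTHM_CATEGORIES = ("R", "Ra", "I", "Ia")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    paired: bool
    significance_stars: str  # "ns" | "*" | "**"


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n_cells: int
    metrics: dict  # name -> {"mean": .., "sem": ..}


@dataclass(frozen=True)
class CellResult:
    """Per-cell, per-condition analysis output fed into the cohort report."""

    cell_id: str
    condition: str
    metrics: dict = field(default_factory=dict)  # name -> float
    rhythm: Optional[str] = None
    has_dads: bool = False
    has_eads: bool = False
    has_bursts: bool = False


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    a: Sequence[float], b: Sequence[float], paired: bool = False, welch: bool = False
) -> TTestResult:
    """Two-sided Student's t-test between two samples.

    Unpaired uses the pooled-variance form (``welch=True`` switches to the
    Welch unequal-variance form); paired requires equal lengths. Two samples
    with zero variance and equal means give statistic 0 and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("need at least 2 observations per group")
    if paired and a.size != b.size:
        raise ContractError("paired comparison requires equal-length samples")
    if paired:
        diff = a - b
        if np.all(diff == diff[0]):
            if diff[0] == 0:
                return TTestResult(0.0, a.size - 1, 1.0, True, "ns")
            return TTestResult(float("inf") * np.sign(diff[0]), a.size - 1, 0.0, True, "**")
        res = sps.ttest_rel(a, b)
        dof = a.size - 1
    else:
        if np.std(a) == 0 and np.std(b) == 0:
            if a[0] == b[0]:
                return TTestResult(0.0, a.size + b.size - 2, 1.0, False, "ns")
            return TTestResult(float("inf") * np.sign(a[0] - b[0]),
                               a.size + b.size - 2, 0.0, False, "**")
        res = sps.ttest_ind(a, b, equal_var=not welch)
        if welch:
            dof = float(res.df)
        else:
            dof = a.size + b.size - 2
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), dof, p, paired, _stars(p))


def category_proportions(
    classifications: Sequence[RhythmClassification | str],
) -> dict:
    """Fraction of cells per rhythm category plus the abnormal fraction.

    ``abnormal`` is everything that is not plain regular-stable R — the
    doughnut-chart summary of how many cells cycle Ca2+ abnormally.
    """
    if not classifications:
        raise ContractError("no classifications to summarise")
    cats = [c.category if isinstance(c, RhythmClassification) else str(c)
            for c in classifications]
    unknown = set(cats) - set(RHYTHM_CATEGORIES)
    if unknown:
        raise ContractError(f"unknown rhythm categories: {sorted(unknown)}")
    n = len(cats)
    props = {k: cats.count(k) / n for k in RHYTHM_CATEGORIES}
    props["abnormal"] = 1.0 - props["R"]
    return props


def _mean_sem(values: Sequence[float]) -> dict:
    v = np.asarray(values, dtype=float)
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return {"mean": float(np.mean(v)), "sem": sem, "n": int(v.size)}


def build_report(
    results: Sequence[CellResult],
    comparisons: Optional[Sequence[tuple]] = None,
) -> dict:
    """Assemble a JSON-serialisable cohort report.

    Produces per-condition mean ± SEM feature tables, rhythm-category
    proportions, pairwise condition comparisons with t-tests and stars
    (paired when the two conditions share cell ids, unpaired otherwise),
    and event-prevalence counts. ``comparisons`` restricts which condition
    pairs are tested; by default every pair present in the data is tested
    for every shared metric.
    """
    if not results:
        raise ContractError("no per-cell results supplied")
    by_cond: dict[str, list[CellResult]] = {}
    for r in results:
        by_cond.setdefault(r.condition, []).append(r)
    conditions = [c for c in CONDITIONS if c in by_cond] + [
        c for c in sorted(by_cond) if c not in CONDITIONS
    ]

    summaries = {}
    for cond in conditions:
        cells = by_cond[cond]
        metric_names = sorted({m for c in cells for m in c.metrics})
        summaries[cond] = {
            "n_cells": len(cells),
            "metrics": {
                m: _mean_sem([c.metrics[m] for c in cells if m in c.metrics])
                for m in metric_names
            },
        }

    rhythm = {}
    for cond in conditions:
        cats = [c.rhythm for c in by_cond[cond] if c.rhythm is not None]
        if cats:
            rhythm[cond] = category_proportions(cats)

    pairs = list(comparisons) if comparisons is not None else [
        (a, b) for i, a in enumerate(conditions) for b in conditions[i + 1:]
    ]
    tests = []
    for ca, cb in pairs:
        if ca not in by_cond or cb not in by_cond:
            continue
        cells_a = {c.cell_id: c for c in by_cond[ca]}
        cells_b = {c.cell_id: c for c in by_cond[cb]}
        shared_cells = sorted(set(cells_a) & set(cells_b))
        shared_metrics = sorted(
            {m for c in by_cond[ca] for m in c.metrics}
            & {m for c in by_cond[cb] for m in c.metrics}
        )
        for m in shared_metrics:
            if len(shared_cells) >= 2:
                ids = [i for i in shared_cells
                       if m in cells_a[i].metrics and m in cells_b[i].metrics]
                if len(ids) < 2:
                    continue
                a = [cells_a[i].metrics[m] for i in ids]
                b = [cells_b[i].metrics[m] for i in ids]
                paired = True
            else:
                a = [c.metrics[m] for c in by_cond[ca] if m in c.metrics]
                b = [c.metrics[m] for c in by_cond[cb] if m in c.metrics]
                if len(a) < 2 or len(b) < 2:
                    continue
                paired = False
            t = compare_groups(a, b, paired=paired)
            tests.append(
                {
                    "metric": m,
                    "condition_a": ca,
                    "condition_b": cb,
                    "paired": paired,
                    "statistic": t.statistic,
                    "degrees_of_freedom": t.degrees_of_freedom,
                    "p_value": t.p_value,
                    "stars": t.significance_stars,
                }
            )

    all_cells = {c.cell_id for c in results}
    prevalence = {
        "n_cells": len(all_cells),
        "cells_with_dads": len({c.cell_id for c in results if c.has_dads}),
        "cells_with_eads": len({c.cell_id for c in results if c.has_eads}),
        "cells_with_bursts": len({c.cell_id for c in results if c.has_bursts}),
    }
    return {
        "conditions": summaries,
        "rhythm_proportions": rhythm,
        "comparisons": tests,
        "event_prevalence": prevalence,
        "notes": {
            "n_comparisons": len(tests),
            "multiple_testing_correction": "none applied",
            "error_bars": "SEM",
        },
    }
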