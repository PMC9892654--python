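"""Drop-out importance scores, greedy forward feature selection, panel search.

Phase 1 of the discovery framework.  A reference classifier is trained on a
feature pool (typically the ANOVA-selected DEPs) and each feature is dropped
out in turn; the importance score of feature *i* is the relative accuracy
loss its removal causes,

    IS_i = -(PA_i - PA_O) / PA_O,

where PA_O is the reference accuracy and PA_i the accuracy without feature
*i* (same holdout split seeds, so the comparison is paired).  IS > 0 marks a
positive-impact feature.  Greedy forward feature selection (GFFS) then walks
once through the positive-impact features in descending IS order, keeping a
feature only if adding it strictly increases mean holdout accuracy.  Because
the ranking is computed once, the whole procedure costs at most ~2n
classifier evaluations for n pool features, versus O(n^2) for classical
forward selection or recursive elimination.

Finally, compact panels are found by exhaustively evaluating every subset of
the selected markers at the requested sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .classify import HoldoutPlan, accuracy_summary, evaluate_features
from .data_io import ExpressionMatrix, ResponseLabels


@dataclass(frozen=True)
class ImportanceEntry:
    feature_id: str
    importance: float
    pa_dropout: float
    pa_original: float


@dataclass
class ImportanceTable:
    """Per-feature drop-out importance scores, sorted descending by score."""

    entries: list[ImportanceEntry]

    def positive(self) -> list[str]:
        """Positive-impact feature IDs in descending importance order."""
        return [e.feature_id for e in self.entries if e.importance > 0]

    @property
    def pa_original(self) -> float:
        return self.entries[0].pa_original


@dataclass
class GffsStep:
    candidate: str
    accuracy_with_candidate: float
    accepted: bool


@dataclass
class GffsTrace:
    steps: list[GffsStep]
    selected: list[str]
    final_accuracy: float
    model_evaluations: int


@dataclass(frozen=True)
class PanelEvaluation:
    panel: tuple[str, ...]
    mean_accuracy: float
    accuracy_sd: float


def importance_score(pa_dropout: float, pa_original: float) -> float:
    """Relative accuracy loss caused by removing one feature.

    Positive when the drop-out model is worse than the reference model.
    Undefined (error) when the reference accuracy is zero.
    """
    if pa_original == 0:
        raise ValueError("importance score undefined: reference accuracy is 0")
    return -(pa_dropout - pa_original) / pa_original


def importance_scores(
    m: ExpressionMatrix,
    labels: ResponseLabels,
    feature_pool: list[str],
    plan: HoldoutPlan,
) -> ImportanceTable:
    """Drop-out analysis over ``feature_pool`` under a shared holdout plan.

    Sorting is by importance descending; ties keep the pool order.
    """
    if len(feature_pool) < 2:
        raise ValueError("feature pool must contain at least two features")
    pa_original = accuracy_summary(evaluate_features(m, labels, feature_pool, plan))
    if pa_original == 0:
        raise ValueError("importance score undefined: reference accuracy is 0")
    entries = []
    for i, fid in enumerate(feature_pool):
        reduced = feature_pool[:i] + feature_pool[i + 1:]
        pa_i = accuracy_summary(evaluate_features(m, labels, reduced, plan))
        entries.append(
            ImportanceEntry(
                feature_id=fid,
                importance=importance_score(pa_i, pa_original),
                pa_dropout=pa_i,
                pa_original=pa_original,
            )
        )
    pool_rank = {f: i for i, f in enumerate(feature_pool)}
    entries.sort(key=lambda e: (-e.importance, pool_rank[e.feature_id]))
    return ImportanceTable(entries=entries)


def gffs(
    m: ExpressionMatrix,
    labels: ResponseLabels,
    ranked_positive: list[str],
    plan: HoldoutPlan,
) -> GffsTrace:
    """Single-pass greedy forward selection over importance-ranked features.

    Seeds the model with the top-ranked feature, then considers each
    remaining feature once in rank order, accepting it iff the mean holdout
    accuracy strictly increases.  Accepted-step accuracies are therefore
    strictly increasing.  An empty input yields an empty trace.
    """
    if not ranked_positive:
        return GffsTrace(steps=[], selected=[], final_accuracy=0.0, model_evaluations=0)
    evaluations = 0
    selected = [ranked_positive[0]]
    best = accuracy_summary(evaluate_features(m, labels, selected, plan))
    evaluations += 1
    steps = [GffsStep(ranked_positive[0], best, True)]
    for fid in ranked_positive[1:]:
        acc = accuracy_summary(evaluate_features(m, labels, selected + [fid], plan))
        evaluations += 1
        accepted = acc > best
        steps.append(GffsStep(fid, acc, accepted))
        if accepted:
            selected.append(fid)
            best = acc
    return GffsTrace(
        steps=steps,
        selected=selected,
        final_accuracy=best,
        model_evaluations=evaluations,
    )


def enumerate_panels(pool: list[str], size: int):
    """Yield all C(|pool|, size) panels of ``size``, lexicographic by pool order."""
    if not 1 <= size <= len(pool):
        raise ValueError(f"size must lie in [1, {len(pool)}], got {size}")
    return itertools.combinations(pool, size)


def panel_search(
    m: ExpressionMatrix,
    labels: ResponseLabels,
    pool: list[str],
    sizes: list[int],
    plan: HoldoutPlan,
    cap: int = 100_000,
) -> tuple[dict[int, list[PanelEvaluation]], dict[int, PanelEvaluation]]:
    """Exhaustively evaluate every panel of each requested size.

    Returns ``(all_evaluations_by_size, best_panel_by_size)``; ties on mean
    accuracy are broken lexicographically by panel (pool order).  Errors if
    the total number of panels exceeds ``cap``.
    """
    total = sum(math.comb(len(pool), s) for s in sizes)
    if total > cap:
        raise ValueError(
            f"{total} panels requested, exceeding cap {cap}; "
            "reduce the sizes or raise the cap"
        )
    by_size: dict[int, list[PanelEvaluation]] = {}
    best: dict[int, PanelEvaluation] = {}
    for size in sizes:
        evals = []
        for panel in enumerate_panels(pool, size):
            report = evaluate_features(m, labels, list(panel), plan)
            acc = report.per_replicate_accuracy
            evals.append(
                PanelEvaluation(
                    panel=panel,
                    mean_accuracy=float(acc.mean()),
                    accuracy_sd=float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
                )
            )
        by_size[size] = evals
        pool_rank = {f: i for i, f in enumerate(pool)}
        best[size] = min(
            evals,
            key=lambda e: (-e.mean_accuracy, tuple(pool_rank[f] for f in e.panel)),
        )
    return by_size, best


def discover_panel(
    m: ExpressionMatrix,
    labels: ResponseLabels,
    plan: HoldoutPlan,
    alpha: float = 0.05,
) -> dict:
    """End-to-end phase 1: ANOVA DEP filter -> importance scores -> GFFS.

    Returns a dict with keys ``deps`` (the filtered pool), ``importance``
    (the ImportanceTable), ``trace`` (the GffsTrace) and ``panel`` (the
    selected marker list).
    """
    from .dep import anova_scan, filter_deps

    deps = filter_deps(anova_scan(m, labels), alpha=alpha)
    if len(deps) < 2:
        raise ValueError(
            f"only {len(deps)} feature(s) pass the ANOVA filter at alpha={alpha}"
        )
    table = importance_scores(m, labels, deps, plan)
    # when the reference model is already at ceiling every drop-out score is
    # zero; fall back to the full importance ranking so selection can proceed
    ranked = table.positive() or [e.feature_id for e in table.entries]
    trace = gffs(m, labels, ranked, plan)
    return {"deps": deps, "importance": table, "trace": trace,
            "panel": trace.selected}
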