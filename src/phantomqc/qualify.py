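"""Feature-level sequential totals and phantom-level pass/fail.

National QA rules: within each feature (fibers, speck groups, masses),
lesions are graded from the largest downward; consecutive 1.0 grades
each add a point, the first non-1.0 grade adds its own value, and every
smaller lesion is ignored.  A phantom qualifies when the fiber total is
at least 4.0 and both the speck and mass totals are at least 3.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .layout import DEFAULT_LAYOUT, FIBER, MASS, QUALIFY_THRESHOLDS, SPECKS, TYPE_COUNTS, GridLayout
from .scores import Score


@dataclass
class FeatureResult:
    lesion_type: str
    total: float
    contributing_ranks: list[int]
    passed: bool


@dataclass
class QualificationResult:
    per_feature: dict  # lesion_type -> FeatureResult
    qualified: bool

    @property
    def totals(self) -> tuple[float, float, float]:
        return tuple(self.per_feature[t].total for t in (FIBER, SPECKS, MASS))


def feature_total(
    scores: Sequence[Score | float | str],
    lesion_type: str,
    na_value: float = 0.0,
) -> FeatureResult:
    """Sequential total for one feature, scores ordered largest first.

    Walks from rank 1: each consecutive 1.0 adds a point; the first
    non-1.0 grade adds its value (N/A adds ``na_value``, 0.0 by
    default) and stops the walk; smaller lesions are ignored.
    """
    if lesion_type not in TYPE_COUNTS:
        raise ValueError(f"unknown lesion type {lesion_type!r}")
    expected = TYPE_COUNTS[lesion_type]
    if len(scores) != expected:
        raise ValueError(
            f"{lesion_type} needs {expected} scores, got {len(scores)}"
        )
    scores = [Score.from_value(s) for s in scores]
    total = 0.0
    ranks: list[int] = []
    for rank, s in enumerate(scores, start=1):
        if s is Score.FULL:
            total += 1.0
            ranks.append(rank)
            continue
        total += na_value if s.is_na else s.points
        ranks.append(rank)
        break
    return FeatureResult(
        lesion_type=lesion_type,
        total=total,
        contributing_ranks=ranks,
        passed=total >= QUALIFY_THRESHOLDS[lesion_type],
    )


def _by_feature(scores: Sequence, layout: GridLayout) -> dict:
    """Group a row-major 16-score vector by feature, rank order."""
    if len(scores) != 16:
        raise ValueError("need all 16 lesion scores")
    out = {t: [None] * n for t, n in TYPE_COUNTS.items()}
    for cell, s in enumerate(scores):
        t, rank = layout.lesion_at(cell)
        out[t][rank - 1] = s
    return out


def qualify_phantom(
    scores: Sequence[Score | float | str],
    layout: GridLayout = DEFAULT_LAYOUT,
    na_value: float = 0.0,
) -> QualificationResult:
    """Phantom verdict from all 16 cell scores (row-major order)."""
    grouped = _by_feature(scores, layout)
    per = {
        t: feature_total(grouped[t], t, na_value=na_value) for t in TYPE_COUNTS
    }
    return QualificationResult(
        per_feature=per, qualified=all(r.passed for r in per.values())
    )


def qualify_early_stop(
    scorer: Callable,
    subimages_by_feature: dict,
    na_value: float = 0.0,
) -> QualificationResult:
    """Qualification with per-feature early termination.

    ``subimages_by_feature`` maps lesion type to its tiles in rank
    order (largest first).  The scorer is not invoked for ranks after
    the first non-1.0 grade of a feature, yet the verdict is identical
    to scoring everything: ignored lesions cannot change a sequential
    total.
    """
    per = {}
    for t, subs in subimages_by_feature.items():
        if len(subs) != TYPE_COUNTS[t]:
            raise ValueError(f"{t} needs {TYPE_COUNTS[t]} tiles in rank order")
        total = 0.0
        ranks: list[int] = []
        for rank, sub in enumerate(subs, start=1):
            s = Score.from_value(scorer(sub))
            if s is Score.FULL:
                total += 1.0
                ranks.append(rank)
                continue
            total += na_value if s.is_na else s.points
            ranks.append(rank)
            break
        per[t] = FeatureResult(
            lesion_type=t,
            total=total,
            contributing_ranks=ranks,
            passed=total >= QUALIFY_THRESHOLDS[t],
        )
    if set(per) != set(TYPE_COUNTS):
        raise ValueError("tiles for all three features are required")
    return QualificationResult(
        per_feature=per, qualified=all(r.passed for r in per.values())
    )


def achievable_totals(lesion_type: str) -> list[float]:
    """All feature totals realizable under the sequential rule."""
    n = TYPE_COUNTS[lesion_type]
    return [k / 2.0 for k in range(2 * n + 1)]


def realize_total(lesion_type: str, total: float) -> list[Score]:
    """Construct a score vector whose sequential total equals ``total``."""
    n = TYPE_COUNTS[lesion_type]
    if total < 0 or total > n or (total * 2) % 1:
        raise ValueError(f"total {total} not achievable for {lesion_type}")
    full = int(total)
    rest = total - full
    scores = [Score.FULL] * full
    if full < n:
        scores.append(Score.HALF if rest else Score.ZERO)
    scores += [Score.ZERO] * (n - len(scores))
    return scores
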