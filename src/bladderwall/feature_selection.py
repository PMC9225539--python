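"""Sequential floating feature selection over the 40-feature vector.

SFFS grows a subset from the empty set, at each step adding the feature
whose inclusion maximizes the objective; with floating enabled, a
conditional backward step removes a feature whenever doing so strictly
beats the best score recorded at the smaller size.  SBFS is the mirror:
it starts from the full set, removes the least useful feature, and
conditionally re-includes.  The objective is any deterministic function
of a feature-index subset — in the pipeline, the mean stratified 5-fold
cross-validated accuracy of the configured classifier.

With ``floating=False`` the algorithms reduce to plain sequential
forward/backward selection.  Ties are broken toward the lowest feature
index; the objective is memoized so no subset is evaluated twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

__all__ = ["SelectionConfig", "SelectionResult", "sffs", "sbfs"]

Objective = Callable[[frozenset[int]], float]


@dataclass(frozen=True)
class SelectionConfig:
    n_features: int = 40
    floating: bool = True
    min_size: int = 1
    max_size: int | None = None    # default: n_features

    def __post_init__(self) -> None:
        max_size = self.max_size if self.max_size is not None else self.n_features
        if not (1 <= self.min_size <= max_size <= self.n_features):
            raise ValueError(
                f"need 1 <= min_size <= max_size <= {self.n_features}, "
                f"got min={self.min_size}, max={max_size}"
            )
        object.__setattr__(self, "max_size", max_size)


@dataclass
class SelectionResult:
    selected: tuple[int, ...]
    best_score: float
    history: list[tuple[tuple[int, ...], float]] = field(default_factory=list)


class _Memo:
    """Memoized objective that rejects non-finite scores."""

    def __init__(self, objective: Objective):
        self._fn = objective
        self._cache: dict[frozenset[int], float] = {}
        self.calls = 0

    def __call__(self, subset: frozenset[int]) -> float:
        if subset not in self._cache:
            self.calls += 1
            score = float(self._fn(subset))
            if score != score or score in (float("inf"), float("-inf")):
                raise ValueError(f"objective returned non-finite score for subset {sorted(subset)}")
            self._cache[subset] = score
        return self._cache[subset]


def _argbest(candidates: list[tuple[int, float]]) -> tuple[int, float]:
    """Highest score; ties broken toward the lowest feature index."""
    best_idx, best_score = candidates[0]
    for idx, score in candidates[1:]:
        if score > best_score or (score == best_score and idx < best_idx):
            best_idx, best_score = idx, score
    return best_idx, best_score


def sffs(objective: Objective, config: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Sequential (floating) forward selection; returns the best visited subset."""
    memo = _Memo(objective)
    all_features = range(config.n_features)
    current: frozenset[int] = frozenset()
    history: list[tuple[tuple[int, ...], float]] = []
    best_at_size: dict[int, tuple[float, frozenset[int]]] = {}

    def record(subset: frozenset[int], score: float) -> None:
        history.append((tuple(sorted(subset)), score))
        k = len(subset)
        if k not in best_at_size or score > best_at_size[k][0]:
            best_at_size[k] = (score, subset)

    while len(current) < config.max_size:
        # forward: add the argmax feature
        cands = [(f, memo(current | {f})) for f in all_features if f not in current]
        f_add, score = _argbest(cands)
        current = current | {f_add}
        record(current, score)

        # conditional floating exclusion
        while config.floating and len(current) >= 2 and len(current) - 1 >= config.min_size:
            cands = [(f, memo(current - {f})) for f in sorted(current)]
            f_rm, score_rm = _argbest(cands)
            k = len(current) - 1
            if k >= config.min_size and (k not in best_at_size or score_rm > best_at_size[k][0]):
                current = current - {f_rm}
                record(current, score_rm)
            else:
                break

    return _finalize(best_at_size, history, config)


def sbfs(objective: Objective, config: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Sequential (floating) backward selection from the full feature set."""
    memo = _Memo(objective)
    all_features = range(config.n_features)
    current = frozenset(all_features)
    history: list[tuple[tuple[int, ...], float]] = []
    best_at_size: dict[int, tuple[float, frozenset[int]]] = {}

    def record(subset: frozenset[int], score: float) -> None:
        history.append((tuple(sorted(subset)), score))
        k = len(subset)
        if k not in best_at_size or score > best_at_size[k][0]:
            best_at_size[k] = (score, subset)

    record(current, memo(current))
    while len(current) > config.min_size:
        # backward: remove the feature with the smallest score decrease
        cands = [(f, memo(current - {f})) for f in sorted(current)]
        f_rm, score = _argbest(cands)
        current = current - {f_rm}
        record(current, score)

        # conditional floating inclusion
        while config.floating and len(current) < config.max_size:
            outside = [f for f in all_features if f not in current]
            if not outside:
                break
            cands = [(f, memo(current | {f})) for f in outside]
            f_add, score_add = _argbest(cands)
            k = len(current) + 1
            if k <= config.max_size and (k not in best_at_size or score_add > best_at_size[k][0]):
                current = current | {f_add}
                record(current, score_add)
            else:
                break

    return _finalize(best_at_size, history, config)


def _finalize(best_at_size, history, config) -> SelectionResult:
    eligible = {k: v for k, v in best_at_size.items() if config.min_size <= k <= config.max_size}
    if not eligible:
        raise RuntimeError("selection visited no subset within the size bounds")
    best_score, best_subset = max(
        eligible.values(), key=lambda sv: (sv[0], -len(sv[1]), tuple(sorted(sv[1])))
    )
    filtered = [(s, sc) for s, sc in history if config.min_size <= len(s) <= config.max_size]
    return SelectionResult(selected=tuple(sorted(best_subset)), best_score=best_score,
                           history=filtered)
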