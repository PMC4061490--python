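"""Sequential forward floating selection (SFFS) over EEG channels.

The search greedily adds the channel that maximizes the criterion
J(X_k) = 1/RMSE, then conditionally removes "least significant" channels
whenever doing so improves on the best recorded criterion at the smaller
subset size — the floating property that lets the search escape local
maxima of the plain greedy forward pass. The run terminates when the
subset-size cap is reached, the criterion-evaluation budget is exhausted,
or the candidate pool is empty; the result is the subset with the largest
criterion seen anywhere in the trace.

Criterion evaluations are memoized, so revisiting a subset costs nothing
and does not consume the evaluation budget. Ties in the criterion are
broken toward the earliest candidate in the caller-supplied (canonical
montage) order, which makes the search fully deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .containers import PSDTimeSeries
from ._pcr import CriterionEvaluator, criterion_from_predictions  # noqa: F401
from .errors import ParameterError

DEFAULT_MAX_ITER = 500
DEFAULT_K_MAX = 12


@dataclass
class SFFSResult:
    """Ranked channel subsets with criterion trace and the optimal subset."""

    best_subset: tuple
    best_J: float
    J_trace: dict      # subset size -> best criterion value seen at that size
    subset_trace: dict  # subset size -> best subset of that size
    history: list = field(default_factory=list)  # ("add"|"remove", channel)
    n_evaluations: int = 0
    budget_exhausted: bool = False


class _BudgetExhausted(Exception):
    pass


def sffs_select(candidates, j_func, k_max: int = DEFAULT_K_MAX,
                max_iter: int = DEFAULT_MAX_ITER) -> SFFSResult:
    """Run SFFS over ``candidates`` maximizing ``j_func(subset_tuple)``.

    ``j_func`` receives a tuple of candidate items ordered as in
    ``candidates``. ``max_iter`` caps the number of *fresh* criterion
    evaluations (the expensive unit); memoized repeats are free.
    """
    candidates = list(candidates)
    if not candidates:
        raise ParameterError("need at least one candidate channel")
    k_max = min(k_max, len(candidates))

    memo: dict[tuple, float] = {}
    trace: dict[int, tuple] = {}  # size -> (J, subset)
    history: list = []
    state = {"evals": 0}

    def J(subset: tuple) -> float:
        if subset in memo:
            return memo[subset]
        if state["evals"] >= max_iter:
            raise _BudgetExhausted
        state["evals"] += 1
        value = float(j_func(subset))
        memo[subset] = value
        size = len(subset)
        if size not in trace or value > trace[size][0]:
            trace[size] = (value, subset)
        return value

    def with_item(subset, item):
        return tuple(c for c in candidates if c in subset or c == item)

    def without_item(subset, item):
        return tuple(c for c in subset if c != item)

    def best_at(size: int) -> float:
        return trace[size][0] if size in trace else float("-inf")

    current: tuple = ()
    exhausted = False
    max_steps = 20 * max(max_iter, 1)
    steps = 0
    try:
        while len(current) < k_max and steps < max_steps:
            steps += 1
            remaining = [c for c in candidates if c not in current]
            if not remaining:
                break
            # Forward: most significant next channel (ties -> earliest).
            best_c, best_v = None, float("-inf")
            for c in remaining:
                v = J(with_item(current, c))
                if v > best_v:
                    best_c, best_v = c, v
            trial = with_item(current, best_c)
            history.append(("add", best_c))
            if len(trial) <= 2:
                current = trial
                continue
            # Conditional exclusion: is the newest channel least significant?
            removal = {c: J(without_item(trial, c)) for c in trial}
            others_best = max(v for c, v in removal.items() if c != best_c)
            if removal[best_c] >= others_best:
                current = trial
                continue
            worst = max((c for c in trial if c != best_c), key=lambda c: removal[c])
            pruned = without_item(trial, worst)
            history.append(("remove", worst))
            # Keep floating backward while removal improves the recorded best.
            while len(pruned) >= 2 and steps < max_steps:
                steps += 1
                removal = {c: J(without_item(pruned, c)) for c in pruned}
                least = max(pruned, key=lambda c: removal[c])
                if removal[least] <= best_at(len(pruned) - 1):
                    break
                pruned = without_item(pruned, least)
                history.append(("remove", least))
            current = pruned
    except _BudgetExhausted:
        exhausted = True

    if not trace:
        # Budget too small even for the first forward sweep: evaluate
        # singletons outside the budget accounting would break the contract,
        # so fall back to whatever memo holds (possibly nothing).
        raise ParameterError("max_iter too small: no subset was evaluated")

    best_size = max(trace, key=lambda s: trace[s][0])
    best_J, best_subset = trace[best_size]
    return SFFSResult(
        best_subset=best_subset,
        best_J=best_J,
        J_trace={s: trace[s][0] for s in sorted(trace)},
        subset_trace={s: trace[s][1] for s in sorted(trace)},
        history=history,
        n_evaluations=state["evals"],
        budget_exhausted=exhausted,
    )


def criterion_J(channels, psd: PSDTimeSeries, y, protocol: str = "inner-cv",
                **kwargs) -> float:
    """Criterion J = 1/RMSE for one channel subset under ``protocol``.

    Convenience wrapper building a fresh :class:`CriterionEvaluator`; for
    repeated evaluations construct the evaluator once and call it.
    """
    channels = tuple(channels)
    evaluator = CriterionEvaluator(psd, y, candidates=list(channels),
                                   protocol=protocol, **kwargs)
    return evaluator(channels)


def sffs_channels(psd: PSDTimeSeries, y, candidates=None,
                  protocol: str = "inner-cv", k_max: int = DEFAULT_K_MAX,
                  max_iter: int = DEFAULT_MAX_ITER,
                  **evaluator_kwargs) -> SFFSResult:
    """SFFS over PSD channels with the cached criterion evaluator."""
    evaluator = CriterionEvaluator(psd, y, candidates=candidates,
                                   protocol=protocol, **evaluator_kwargs)
    return sffs_select(evaluator.candidates, evaluator, k_max=k_max,
                       max_iter=max_iter)
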