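"""Informative training-subset selection — the "one-step method" trainer.

Given the same compositions measured on one or more lysates, find the
small subset (default 20 of 102) whose trained models best predict the
held-out remainder, averaged across lysates. The search is plain random
subset sampling with best-so-far bookkeeping: at the default sizes there
are C(102, 20) ≈ 4e20 subsets, so enumeration is hopeless but random
search finds strong subsets quickly because many subsets that cover the
influential compounds' levels score similarly.

The held-out score of a subset is the R² of ensemble-mean predictions on
the complement, matching how predictive accuracy is reported on the
82-composition test set. The inner loop uses a reduced ensemble for
tractability; the winner is re-evaluated at full fidelity on request.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import r2_score

from .ensemble import EnsembleConfig, train_ensemble
from .exceptions import CapacityError

#: protocol constants of the one-step method
PRESET_N_REPRESENTATIVE = 102
PRESET_TRAIN_SIZE = 20
PRESET_TEST_SIZE = 82
PRESET_EXTENDED_TRAIN_SIZE = 25

#: instances with at most this many subsets are searched exhaustively
EXHAUSTIVE_LIMIT = 5000


@dataclass
class LysateDataset:
    """One lysate's measurements of a shared composition panel."""

    lysate_id: str
    X: np.ndarray  # (n, d) normalized fractions
    y: np.ndarray  # (n,) yield means
    y_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must align")


@dataclass(frozen=True)
class SubsetSearchConfig:
    subset_size: int = PRESET_TRAIN_SIZE
    iterations: int = 1000
    checkpoint_every: int = 100
    seed: int = 0
    model_config: EnsembleConfig = field(default_factory=EnsembleConfig.reduced)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class SubsetResult:
    indices: tuple[int, ...]
    per_lysate_scores: dict[str, float]
    mean_score: float
    iteration_found: int
    trace: list[float] = field(default_factory=list)  # best-so-far per iteration
    #: runner-up subsets (indices, mean score), best first — useful for
    #: re-scoring the search's shortlist with a stronger model
    runners_up: list[tuple[tuple[int, ...], float]] = field(default_factory=list)


def evaluate_subset(
    indices: Sequence[int],
    datasets: Sequence[LysateDataset],
    model_config: EnsembleConfig | None = None,
) -> tuple[dict[str, float], float]:
    """Train on the subset, score R² on the complement, per lysate.

    The subset/complement partition is checked exactly on every call.
    """
    model_config = model_config or EnsembleConfig.reduced()
    n = len(datasets[0].y)
    idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
    if len(idx) != len(indices):
        raise ValueError("subset indices must be unique")
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("subset indices out of range")
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    if mask.all():
        raise CapacityError("subset covers the whole dataset; no test set remains")
    assert mask.sum() + (~mask).sum() == n
    scores: dict[str, float] = {}
    for ds in datasets:
        if len(ds.y) != n:
            raise ValueError("all lysate datasets must share the composition panel")
        ens = train_ensemble(ds.X[mask], ds.y[mask], model_config)
        pred = ens.predict(ds.X[~mask])
        scores[ds.lysate_id] = float(r2_score(ds.y[~mask], pred.mean))
    return scores, float(np.mean(list(scores.values())))


def _iter_subsets(n: int, size: int, config: SubsetSearchConfig):
    """Candidate subsets: exhaustive when the instance is tiny, random
    uniform without replacement otherwise (repeats across iterations are
    not deduplicated — astronomically unlikely at protocol sizes)."""
    if math.comb(n, size) <= min(EXHAUSTIVE_LIMIT, config.iterations):
        for comb in itertools.combinations(range(n), size):
            yield comb
        return
    rng = np.random.default_rng(config.seed)
    for _ in range(config.iterations):
        yield tuple(int(i) for i in rng.choice(n, size=size, replace=False))


def search_informative(
    datasets: Sequence[LysateDataset],
    config: SubsetSearchConfig | None = None,
    checkpoint_path=None,
    keep_runners_up: int = 0,
) -> SubsetResult:
    """Best-of-``iterations`` random subsets by mean held-out score.

    On tiny instances (at most ``EXHAUSTIVE_LIMIT`` possible subsets, and
    no more than the iteration budget) every subset is evaluated, making
    the search an exact optimizer there. Checkpoints (iteration, subset,
    scores) are appended as JSON lines every ``checkpoint_every``
    iterations when a path is given. ``keep_runners_up`` retains that
    many additional top-scoring subsets for later re-scoring.
    """
    config = config or SubsetSearchConfig()
    if not datasets:
        raise ValueError("at least one lysate dataset required")
    n = len(datasets[0].y)
    best: SubsetResult | None = None
    trace: list[float] = []
    shortlist: list[tuple[tuple[int, ...], float]] = []
    ckpt = Path(checkpoint_path) if checkpoint_path is not None else None
    if ckpt is not None:
        ckpt.parent.mkdir(parents=True, exist_ok=True)
    for it, sub in enumerate(_iter_subsets(n, config.subset_size, config), start=1):
        # same model seeds for every subset: candidates compete on equal,
        # reproducible footing and the exhaustive mode is an exact argmax
        scores, mean = evaluate_subset(sub, datasets, config.model_config)
        if best is None or mean > best.mean_score:
            best = SubsetResult(
                indices=tuple(sub),
                per_lysate_scores=scores,
                mean_score=mean,
                iteration_found=it,
            )
        if keep_runners_up:
            shortlist.append((tuple(sub), mean))
            shortlist.sort(key=lambda t: -t[1])
            del shortlist[keep_runners_up + 1:]
        trace.append(best.mean_score)
        if ckpt is not None and it % config.checkpoint_every == 0:
            with open(ckpt, "a") as fh:
                fh.write(
                    json.dumps(
                        {
                            "iteration": it,
                            "best_indices": list(best.indices),
                            "best_mean_score": best.mean_score,
                            "per_lysate": best.per_lysate_scores,
                        }
                    )
                    + "\n"
                )
    best.trace = trace
    if keep_runners_up:
        best.runners_up = [s for s in shortlist if s[0] != best.indices]
    return best


def extend_subset(
    base: SubsetResult | Sequence[int],
    extra_size: int,
    datasets: Sequence[LysateDataset],
    config: SubsetSearchConfig | None = None,
) -> SubsetResult:
    """Search ``extra_size`` additions to a fixed base subset.

    Low-quality lysates (capped or weak) need more training information;
    the base 20 stay fixed so earlier measurements remain valid, and only
    the extras are optimized on the new lysates' data.
    """
    config = config or SubsetSearchConfig()
    base_idx = tuple(base.indices) if isinstance(base, SubsetResult) else tuple(base)
    n = len(datasets[0].y)
    complement = sorted(set(range(n)) - set(base_idx))
    if extra_size == 0:
        scores, mean = evaluate_subset(base_idx, datasets, config.model_config)
        return SubsetResult(base_idx, scores, mean, 0)
    if len(complement) < extra_size:
        raise CapacityError("complement smaller than the requested extension")
    rng = np.random.default_rng(config.seed)
    best: SubsetResult | None = None
    exhaustive = math.comb(len(complement), extra_size) <= min(
        EXHAUSTIVE_LIMIT, config.iterations
    )
    if exhaustive:
        candidates = itertools.combinations(complement, extra_size)
    else:
        candidates = (
            tuple(int(i) for i in rng.choice(complement, size=extra_size, replace=False))
            for _ in range(config.iterations)
        )
    for it, extra in enumerate(candidates, start=1):
        sub = tuple(sorted(base_idx + tuple(extra)))
        scores, mean = evaluate_subset(sub, datasets, config.model_config)
        if best is None or mean > best.mean_score:
            best = SubsetResult(sub, scores, mean, it)
    return best


# ---------------------------------------------------------------------------
# representative panel preset


def representative_subset(
    X: np.ndarray,
    y: np.ndarray,
    n: int = PRESET_N_REPRESENTATIVE,
    strategy: str = "yield_stratified",
) -> np.ndarray:
    """Pick ``n`` representative rows from a measurement history.

    ``yield_stratified`` spreads the picks uniformly over the observed
    yield range (nearest unused history point to each of ``n`` evenly
    spaced yield targets), so the panel spans low, intermediate and high
    producers rather than following the history's skew.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < n:
        raise CapacityError(f"history of {len(y)} rows cannot yield {n} representatives")
    if strategy != "yield_stratified":
        raise ValueError(f"unknown strategy {strategy!r}")
    targets = np.linspace(y.min(), y.max(), n)
    used: set[int] = set()
    picks: list[int] = []
    for t in targets:
        order = np.argsort(np.abs(y - t), kind="stable")
        for j in order:
            if int(j) not in used:
                used.add(int(j))
                picks.append(int(j))
                break
    return np.asarray(picks, dtype=int)
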