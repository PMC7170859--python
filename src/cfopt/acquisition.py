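"""Upper-confidence-bound query selection over the composition grid.

Each acquisition round draws up to N (default 100,000) unseen candidate
compositions, scores them with the ensemble, and ranks them three ways:
by predicted mean (pure exploitation), by predicted dispersion (pure
exploration) and by the UCB score

    ucb = exploitation * mean + exploration * std

with exploitation = 1 and exploration = sqrt(2) by default. The UCB list
feeds the next plate; the other two are emitted for users who want to
push purely for yield or purely for model improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ensemble import Ensemble
from .exceptions import CapacityError
from .plate import PlateDesign
from .space import Composition, CompositionSpace, ENUMERATION_LIMIT


@dataclass(frozen=True)
class AcquisitionConfig:
    n_candidate_draws: int = 100_000
    exploitation: float = 1.0
    exploration: float = math.sqrt(2.0)
    top_k: int = 500
    plate_size: int = 102
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_candidate_draws >= self.top_k >= self.plate_size >= 0):
            raise ValueError("need n_candidate_draws >= top_k >= plate_size")
        if self.exploitation < 0 or self.exploration < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class CandidateScore:
    composition: Composition
    pred_mean: float
    pred_std: float
    ucb: float


@dataclass
class ProposalSet:
    """Three ranked candidate lists; ``ucb`` drives the default workflow."""

    exploit: list[CandidateScore]
    explore: list[CandidateScore]
    ucb: list[CandidateScore]


def draw_candidates(
    space: CompositionSpace,
    seen: Iterable[Composition],
    config: AcquisitionConfig,
) -> list[Composition]:
    """Up to N unique unseen compositions.

    Matches uniform sampling with rejection of previously seen or
    already-drawn points. Spaces small enough to enumerate are handled
    exactly: when the unseen pool is not larger than N the whole pool is
    returned, otherwise N points are drawn from it without replacement.
    """
    seen_set = {c.levels for c in seen}
    n_unseen = space.size() - len(seen_set)
    if n_unseen <= 0:
        raise CapacityError("no unseen compositions remain")
    if space.size() <= ENUMERATION_LIMIT:
        pool = [c for c in space.enumerate() if c.levels not in seen_set]
        if len(pool) <= config.n_candidate_draws:
            return pool
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(len(pool), size=config.n_candidate_draws, replace=False)
        return [pool[i] for i in idx]
    n = min(config.n_candidate_draws, n_unseen)
    return space.sample_unseen(n, config.seed, exclude=[Composition(t) for t in seen_set])


def score_candidates(
    ensemble: Ensemble,
    candidates: Sequence[Composition],
    space: CompositionSpace,
    config: AcquisitionConfig,
) -> list[CandidateScore]:
    """UCB-score candidates; a pure function of predictions and weights."""
    X = space.normalize_many(candidates)
    pred = ensemble.predict(X)
    ucb = config.exploitation * pred.mean + config.exploration * pred.std
    return [
        CandidateScore(c, float(m), float(s), float(u))
        for c, m, s, u in zip(candidates, pred.mean, pred.std, ucb)
    ]


def _ranked(scores: Sequence[CandidateScore], key, k: int) -> list[CandidateScore]:
    # descending by criterion; ties broken lexicographically on the level
    # tuple so rankings are deterministic on a symmetric landscape
    return sorted(scores, key=lambda s: (-key(s), s.composition.levels))[:k]


def rank_and_select(scores: Sequence[CandidateScore], config: AcquisitionConfig) -> ProposalSet:
    if not scores:
        raise ValueError("no candidate scores to rank")
    k = min(config.top_k, len(scores))
    return ProposalSet(
        exploit=_ranked(scores, lambda s: s.pred_mean, k),
        explore=_ranked(scores, lambda s: s.pred_std, k),
        ucb=_ranked(scores, lambda s: s.ucb, k),
    )


def build_next_plate(
    proposals: ProposalSet,
    controls: Sequence[Composition],
    plate_size: int | None = None,
    replicates: int = 3,
) -> PlateDesign:
    """Top ``plate_size`` UCB candidates in triplicate plus the controls."""
    plate_size = 102 if plate_size is None else plate_size
    if len(proposals.ucb) < plate_size:
        raise CapacityError(
            f"only {len(proposals.ucb)} proposals for a {plate_size}-composition plate"
        )
    comps = [s.composition for s in proposals.ucb[:plate_size]]
    return PlateDesign(compositions=comps, controls=list(controls), replicates=replicates)


def proposals_to_frames(
    proposals: ProposalSet, space: CompositionSpace
) -> dict[str, pd.DataFrame]:
    """Serialize the three lists: fraction columns + pred_mean/pred_std/score."""
    out = {}
    for name, lst, score_of in (
        ("exploitation", proposals.exploit, lambda s: s.pred_mean),
        ("exploration", proposals.explore, lambda s: s.pred_std),
        ("ucb", proposals.ucb, lambda s: s.ucb),
    ):
        df = space.compositions_to_frame([s.composition for s in lst])
        df["pred_mean"] = [s.pred_mean for s in lst]
        df["pred_std"] = [s.pred_std for s in lst]
        df["score"] = [score_of(s) for s in lst]
        out[name] = df
    return out


def write_proposals(proposals: ProposalSet, space: CompositionSpace, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in proposals_to_frames(proposals, space).items():
        df.to_csv(outdir / f"{name}.csv", index=False)
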