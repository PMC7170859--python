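"""Campaign orchestration: the iterative explore–measure–train–acquire
loop, and the one-step workflow for a new lysate.

A campaign starts from a structured-plus-random seed plate (22
one-factor-at-a-time points and 80 random ones for an 11-compound
space), then alternates measurement ingestion, ensemble training and
UCB acquisition. It halts at a maximum iteration count (default 10) or
when neither the best observed yield nor the cross-validation score has
improved by more than 1 % for two consecutive iterations.

All randomness flows from one campaign seed through named substreams
(sampling, member initialization, acquisition), so runs are exactly
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .acquisition import (
    AcquisitionConfig,
    draw_candidates,
    rank_and_select,
    score_candidates,
    write_proposals,
)
from .ensemble import (
    EnsembleConfig,
    cross_validate,
    regression_metrics,
    train_ensemble,
)
from .exceptions import UnderdeterminedError
from .plate import YieldRecord, frame_to_yields, yields_to_frame
from .space import Composition, CompositionSpace
from .synthetic import LysateProfile, measure_compositions

logger = logging.getLogger("cfopt")


@dataclass(frozen=True)
class CampaignConfig:
    max_iterations: int = 10
    plate_size: int = 102
    stagnation_tol: float = 0.01
    stagnation_patience: int = 2
    run_cv: bool = False
    cv_folds: int = 5


@dataclass
class IterationStats:
    iteration: int
    n_new: int
    n_outliers_removed: int
    max_yield: float
    cv_score: float | None = None


@dataclass
class CampaignState:
    """Cumulative record of a campaign: unique measured compositions,
    their yields, and per-iteration statistics."""

    space: CompositionSpace
    history: list[YieldRecord] = field(default_factory=list)
    stats: list[IterationStats] = field(default_factory=list)
    iteration: int = 0

    @property
    def seen(self) -> set[tuple[int, ...]]:
        return {r.composition.levels for r in self.history}

    @property
    def max_yield(self) -> float:
        return max((r.yield_mean for r in self.history), default=-np.inf)

    def training_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        comps = [r.composition for r in self.history]
        X = self.space.normalize_many(comps)
        y = np.array([r.yield_mean for r in self.history])
        return X, y

    # -- persistence ----------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        yields_to_frame(self.history, self.space).to_csv(d / "history.csv", index=False)
        manifest = {
            "iteration": self.iteration,
            "stats": [dataclasses.asdict(s) for s in self.stats],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        self.space.to_yaml(d / "space.yaml")

    @classmethod
    def load(cls, directory) -> "CampaignState":
        d = Path(directory)
        space = CompositionSpace.from_yaml(d / "space.yaml")
        history = frame_to_yields(pd.read_csv(d / "history.csv"), space)
        manifest = json.loads((d / "manifest.json").read_text())
        stats = [IterationStats(**s) for s in manifest["stats"]]
        return cls(space=space, history=history, stats=stats, iteration=manifest["iteration"])


MeasureFn = Callable[[Sequence[Composition], int], list[YieldRecord]]
"""Measurement source: (compositions, iteration) -> yield records."""


def synthetic_measure_fn(profile: LysateProfile, seed: int) -> MeasureFn:
    """Wrap a synthetic lysate profile as a campaign measurement source."""

    def measure(comps: Sequence[Composition], iteration: int) -> list[YieldRecord]:
        return measure_compositions(comps, profile, seed=seed + 7919 * iteration)

    return measure


def _stagnated(values: list[float], patience: int, tol: float) -> bool:
    # no relative improvement > tol over the last `patience` steps
    if len(values) < patience + 1:
        return False
    base = values[-patience - 1]
    scale = max(abs(base), 1e-12)
    return all((v - base) / scale <= tol for v in values[-patience:])


def run_campaign(
    space: CompositionSpace,
    measure: MeasureFn,
    ensemble_config: EnsembleConfig | None = None,
    acquisition_config: AcquisitionConfig | None = None,
    campaign_config: CampaignConfig | None = None,
    seed: int = 0,
    outdir=None,
) -> CampaignState:
    """Run the active-learning loop against a measurement source.

    Iteration 1 measures the structured initial design topped up with
    random unseen compositions to ``plate_size``. Every later iteration
    trains the ensemble on the full history, scores fresh candidate
    draws, and measures the top UCB picks. State is persisted per
    iteration when ``outdir`` is given.
    """
    ensemble_config = ensemble_config or EnsembleConfig()
    acquisition_config = acquisition_config or AcquisitionConfig()
    cfg = campaign_config or CampaignConfig()
    ss = np.random.SeedSequence(seed)
    sample_seed, member_seed, acq_seed = (int(s) for s in ss.generate_state(3) % (2**31 - 1))

    state = CampaignState(space=space)
    max_trace: list[float] = []
    cv_trace: list[float] = []
    next_batch: list[Composition] | None = None

    for it in range(1, cfg.max_iterations + 1):
        state.iteration = it
        if it == 1:
            batch = space.initial_design()
            topup = cfg.plate_size - len(batch)
            if topup > 0:
                batch += space.sample_unseen(topup, sample_seed, exclude=batch)
            batch = batch[: cfg.plate_size] if cfg.plate_size else batch
        else:
            batch = next_batch
        records = measure(batch, it)
        seen = state.seen
        new = [r for r in records if r.composition.levels not in seen]
        state.history.extend(new)
        n_outliers = sum(1 for r in new if r.n_used < 3)

        X, y = state.training_arrays()
        ens_cfg = dataclasses.replace(ensemble_config, base_seed=member_seed + it)
        ensemble = train_ensemble(X, y, ens_cfg)
        cv_score = None
        if cfg.run_cv and len(y) >= cfg.cv_folds:
            cv = cross_validate(X, y, ens_cfg, k=cfg.cv_folds, seed=member_seed)
            cv_score = cv.mean
            cv_trace.append(cv.mean)

        stats = IterationStats(
            iteration=it,
            n_new=len(new),
            n_outliers_removed=n_outliers,
            max_yield=state.max_yield,
            cv_score=cv_score,
        )
        state.stats.append(stats)
        max_trace.append(state.max_yield)
        logger.info(
            "iteration %d: %d new compositions, %d outliers, max yield %.2f%s",
            it, len(new), n_outliers, state.max_yield,
            f", CV {cv_score:.3f}" if cv_score is not None else "",
        )
        if outdir is not None:
            state.save(Path(outdir) / f"iteration_{it:02d}")

        if it == cfg.max_iterations:
            break
        yield_stalled = _stagnated(max_trace, cfg.stagnation_patience, cfg.stagnation_tol)
        cv_stalled = (not cfg.run_cv) or _stagnated(
            cv_trace, cfg.stagnation_patience, cfg.stagnation_tol
        )
        if yield_stalled and cv_stalled:
            logger.info("stopping: no yield or accuracy improvement for %d iterations",
                        cfg.stagnation_patience)
            break

        acq = dataclasses.replace(acquisition_config, seed=acq_seed + it,
                                  plate_size=cfg.plate_size)
        candidates = draw_candidates(space, [r.composition for r in state.history], acq)
        scores = score_candidates(ensemble, candidates, space, acq)
        proposals = rank_and_select(scores, acq)
        take = min(cfg.plate_size, len(proposals.ucb))
        next_batch = [s.composition for s in proposals.ucb[:take]]

    if outdir is not None:
        state.save(outdir)
    return state


def predict_for_new_lysate(
    train_df: pd.DataFrame,
    space: CompositionSpace,
    ensemble_config: EnsembleConfig | None = None,
    acquisition_config: AcquisitionConfig | None = None,
    seed: int = 0,
    test_df: pd.DataFrame | None = None,
    outdir=None,
):
    """One-step workflow: train on a small measured panel, emit ranked
    proposals, and score against a test panel when one is supplied.

    ``train_df`` needs one normalized-fraction column per compound plus a
    ``yield_mean`` column (absolute fluorescence works too — only the
    ranking of proposals changes scale). Returns
    ``(proposals, metrics_or_None)``; for maximal yield, follow the
    exploitation list.
    """
    ensemble_config = ensemble_config or EnsembleConfig()
    acquisition_config = acquisition_config or AcquisitionConfig()
    if len(train_df) < 2:
        raise UnderdeterminedError("at least 2 training rows required")
    comps = space.frame_to_compositions(train_df)
    X = space.normalize_many(comps)
    y = train_df["yield_mean"].to_numpy(dtype=float)
    ens_cfg = dataclasses.replace(ensemble_config, base_seed=seed)
    ensemble = train_ensemble(X, y, ens_cfg)

    acq = dataclasses.replace(acquisition_config, seed=seed)
    candidates = draw_candidates(space, comps, acq)
    scores = score_candidates(ensemble, candidates, space, acq)
    proposals = rank_and_select(scores, acq)
    if outdir is not None:
        write_proposals(proposals, space, outdir)

    metrics = None
    if test_df is not None:
        test_comps = space.frame_to_compositions(test_df)
        Xt = space.normalize_many(test_comps)
        yt = test_df["yield_mean"].to_numpy(dtype=float)
        pred_all = ensemble.predict(np.vstack([X, Xt]))
        observed = np.concatenate([y, yt])
        train_mask = np.array([True] * len(y) + [False] * len(yt))
        metrics = regression_metrics(pred_all.mean, observed, train_mask)
        if outdir is not None:
            (Path(outdir) / "metrics.json").write_text(
                json.dumps(dataclasses.asdict(metrics), indent=2)
            )
    return proposals, metrics
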