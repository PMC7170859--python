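"""Synthetic lysate simulator: ground-truth yield landscapes and noisy
plate measurements.

Every pipeline stage is testable against this module without lab data.
A lysate profile assigns each compound a response curve on the
normalized (0, 1] concentration scale — activating compounds follow a
saturating Hill-type increase, inhibiting compounds the mirrored
decrease, neutral compounds contribute nothing — and the ground-truth
yield is the product of the per-compound curves, rescaled so the
reference composition scores exactly 1 and optionally clipped by a
translation-impairment ceiling:

    yield(x) = min(cap, scale * prod_j f_j(x_j)),  scale = 1 / prod_j f_j(ref_j)

Multiplicative (rather than additive) compound effects reflect buffer
components acting on sequential steps of coupled transcription–
translation, and reproduce fold-change yields spanning roughly 0–35x
the reference — a modelling choice of this simulator, not a measured
fact. Measurement noise is multiplicative lognormal per replicate (so
fluorescence stays positive), with a configurable rate of gross
outliers (a replicate doubled), which is what the 30 %-CV triplicate
filter exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import plate as plate_io
from .plate import YieldRecord, make_yield_record
from .space import Composition, CompositionSpace, default_space


@dataclass(frozen=True)
class CompoundResponse:
    """Effect of one compound. ``direction`` is +1 (activating), -1
    (inhibiting) or 0 (neutral); ``strength`` is the Hill-curve exponent
    and ``half_effect`` the concentration fraction of half saturation."""

    direction: int = 0
    strength: float = 1.0
    half_effect: float = 0.5

    def curve(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.direction == 0:
            return np.ones_like(x)
        if self.direction > 0:
            base = x / (x + self.half_effect)
        else:
            base = self.half_effect / (x + self.half_effect)
        return base**self.strength


@dataclass
class LysateProfile:
    """Ground-truth response model of one simulated lysate.

    ``quality`` scales absolute fluorescence only (a poor lysate emits
    less light for the same relative yield); relative yields are pinned
    to 1 at the reference composition by construction. ``yield_cap``
    models translation impairment as a hard ceiling on attainable yield.
    """

    name: str
    space: CompositionSpace
    responses: tuple[CompoundResponse, ...]
    yield_cap: float = np.inf
    noise_cv: float = 0.10
    quality: float = 1.0
    autofluorescence: float = 1000.0
    reference_fluorescence_gain: float = 20000.0
    outlier_rate: float = 0.01
    outlier_factor: float = 2.0

    def __post_init__(self) -> None:
        if len(self.responses) != self.space.n_compounds:
            raise ValueError("one response per compound required")
        ref = self.space.normalize(self.space.reference_levels)
        raw_ref = 1.0
        for r, x in zip(self.responses, ref):
            raw_ref *= float(r.curve(x))
        self._raw_ref = raw_ref

    @property
    def reference_fluorescence(self) -> float:
        return self.autofluorescence + self.quality * self.reference_fluorescence_gain

    def ground_truth_yield(self, c: Composition) -> float:
        """Deterministic noise-free yield; 1.0 exactly at the reference."""
        x = self.space.normalize(c)
        raw = 1.0
        for r, xi in zip(self.responses, x):
            raw *= float(r.curve(xi))
        # single division so the reference composition is exactly 1
        return float(min(self.yield_cap, raw / self._raw_ref))

    def ground_truth_yields(self, comps) -> np.ndarray:
        return np.array([self.ground_truth_yield(c) for c in comps])

    @property
    def influential_compounds(self) -> list[str]:
        return [
            n for n, r in zip(self.space.names, self.responses) if r.direction != 0
        ]


def simulate_measurement(
    c: Composition,
    profile: LysateProfile,
    replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Noisy replicate fluorescences for one composition.

    Inverts the yield normalization: fluorescence = autofluorescence +
    yield * (reference - autofluorescence) * noise, with lognormal noise
    of the profile's CV and, with probability ``outlier_rate`` per
    replicate, a gross multiplicative error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = profile.ground_truth_yield(c)
    span = profile.reference_fluorescence - profile.autofluorescence
    if profile.noise_cv > 0:
        sigma = np.sqrt(np.log1p(profile.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=replicates)
    else:
        noise = np.ones(replicates)
    f = profile.autofluorescence + y * span * noise
    if profile.outlier_rate > 0:
        gross = rng.random(replicates) < profile.outlier_rate
        f = np.where(gross, profile.autofluorescence + y * span * noise * profile.outlier_factor, f)
    return f


def measure_compositions(
    comps,
    profile: LysateProfile,
    seed: int = 0,
    replicates: int = 3,
    cv_filter: bool = True,
) -> list[YieldRecord]:
    """Simulate triplicates for many compositions and run them through the
    standard ingestion path (CV outlier filter, then yield normalization)."""
    rng = np.random.default_rng(seed)
    out = []
    for c in comps:
        f = simulate_measurement(c, profile, replicates=replicates, seed=rng)
        if cv_filter and replicates == 3:
            rec = make_yield_record(
                c, f, profile.reference_fluorescence, profile.autofluorescence,
                lysate_id=profile.name,
            )
        else:
            mean, std, n = plate_io.compute_yield(
                f, profile.reference_fluorescence, profile.autofluorescence
            )
            rec = YieldRecord(c, tuple(f), mean, std, n, profile.name)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# benchmark suite

#: index layout of the default 11-compound space:
#: 0 mg_glutamate, 1 k_glutamate, 2 amino_acids, 3 ntps (activators)
#: 4 spermidine, 5 pga_3 (inhibitors); 6..10 neutral
_ACT = (0, 1, 2, 3)
_INH = (4, 5)


def simulate_reader_export(
    comps,
    profile: LysateProfile,
    seed: int = 0,
    replicates: int = 3,
    n_reads: int = 5,
    read_jitter_cv: float = 0.005,
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Emit a plate-reader export and its well map, schema-identical to
    real ingestion inputs.

    Wells are laid out as a standard plate design (test rows only); each
    well carries ``n_reads`` reads of the same simulated fluorescence
    with a small reader jitter. Returns ``(well_map, reader_export)``
    ready for :func:`cfopt.plate.match_measurements`.
    """
    import pandas as pd

    from .plate import PlateDesign

    design = PlateDesign(compositions=list(comps), controls=[], replicates=replicates)
    well_map = design.well_map()
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for c in comps:
        f = simulate_measurement(c, profile, replicates=replicates, seed=rng)
        for rep in range(replicates):
            well = well_map.iloc[k]["Destination Well"]
            reads = f[rep] * (1.0 + read_jitter_cv * rng.standard_normal(n_reads))
            rows.append({"Well": well, **{f"Read{i+1}": reads[i] for i in range(n_reads)}})
            k += 1
    return well_map, pd.DataFrame(rows)


def profile_to_yaml(profile: LysateProfile, path) -> None:
    """Persist a lysate profile in the same declarative style as the
    composition-space config (compound names map to response curves)."""
    import yaml

    doc = {
        "name": profile.name,
        "yield_cap": None if np.isinf(profile.yield_cap) else float(profile.yield_cap),
        "noise_cv": float(profile.noise_cv),
        "quality": float(profile.quality),
        "autofluorescence": float(profile.autofluorescence),
        "reference_fluorescence_gain": float(profile.reference_fluorescence_gain),
        "outlier_rate": float(profile.outlier_rate),
        "outlier_factor": float(profile.outlier_factor),
        "responses": {
            name: {
                "direction": r.direction,
                "strength": float(r.strength),
                "half_effect": float(r.half_effect),
            }
            for name, r in zip(profile.space.names, profile.responses)
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def profile_from_yaml(path, space: CompositionSpace) -> LysateProfile:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    responses = tuple(
        CompoundResponse(
            direction=int(doc["responses"][name]["direction"]),
            strength=float(doc["responses"][name]["strength"]),
            half_effect=float(doc["responses"][name]["half_effect"]),
        )
        for name in space.names
    )
    cap = doc.get("yield_cap")
    return LysateProfile(
        name=doc["name"],
        space=space,
        responses=responses,
        yield_cap=np.inf if cap is None else float(cap),
        noise_cv=float(doc.get("noise_cv", 0.1)),
        quality=float(doc.get("quality", 1.0)),
        autofluorescence=float(doc.get("autofluorescence", 1000.0)),
        reference_fluorescence_gain=float(doc.get("reference_fluorescence_gain", 20000.0)),
        outlier_rate=float(doc.get("outlier_rate", 0.01)),
        outlier_factor=float(doc.get("outlier_factor", 2.0)),
    )


def standard_responses(
    act_strengths, inh_strengths, n_compounds: int = 11
) -> tuple[CompoundResponse, ...]:
    """Response tuple with the standard influential layout: the first four
    compounds activate, the next two inhibit, the rest are neutral."""
    responses = [CompoundResponse() for _ in range(n_compounds)]
    for j, s in zip(_ACT, act_strengths):
        if j < n_compounds:
            responses[j] = CompoundResponse(direction=+1, strength=s, half_effect=0.5)
    for j, s in zip(_INH, inh_strengths):
        if j < n_compounds:
            responses[j] = CompoundResponse(direction=-1, strength=s, half_effect=0.5)
    return tuple(responses)


def reduced_space(n_compounds: int = 8, space: CompositionSpace | None = None) -> CompositionSpace:
    """A truncation of the default space to its first ``n_compounds``
    compounds (keeps the 4 activators and 2 inhibitors for n >= 6) —
    small enough for exhaustive ground-truth enumeration."""
    space = space or default_space()
    sub = CompositionSpace(
        compounds=list(space.compounds[:n_compounds]),
        fixed_components=dict(space.fixed_components),
    )
    return sub


def truncate_profile(profile: LysateProfile, space: CompositionSpace) -> LysateProfile:
    """The same lysate restricted to a smaller compound space."""
    return LysateProfile(
        name=profile.name,
        space=space,
        responses=profile.responses[: space.n_compounds],
        yield_cap=profile.yield_cap,
        noise_cv=profile.noise_cv,
        quality=profile.quality,
        autofluorescence=profile.autofluorescence,
        reference_fluorescence_gain=profile.reference_fluorescence_gain,
        outlier_rate=profile.outlier_rate,
        outlier_factor=profile.outlier_factor,
    )


@dataclass
class BenchmarkSuite:
    """Named profiles spanning the phenomenology the pipeline must handle:
    a high-quality original lysate, two sister lysates with the same
    influential compounds but different sensitivities, a transcription-
    impaired variant (absolute signal down, relative headroom intact), a
    translation-impaired variant (yield hard-capped) and a low-quality
    strain variant."""

    profiles: dict[str, LysateProfile]

    def __getitem__(self, name: str) -> LysateProfile:
        return self.profiles[name]

    @property
    def names(self) -> list[str]:
        return list(self.profiles)


def make_benchmark(seed: int = 0, space: CompositionSpace | None = None) -> BenchmarkSuite:
    """The five reference profiles. Parameters are fixed constants; the
    seed only affects nothing here and is accepted for interface
    symmetry with the samplers.

    The original-lysate landscape has exactly 6 influential compounds
    (4 activators, 2 inhibitors) and a global maximum of ~34x the
    reference yield. Sister profiles share the influential set with
    shifted strengths, so cross-lysate analyses see correlated but not
    identical landscapes.
    """
    space = space or default_space()
    n = space.n_compounds
    profiles = {
        "ori": LysateProfile(
            name="ori",
            space=space,
            responses=standard_responses((1.4, 1.25, 1.35, 1.3), (2.0, 1.95), n),
            quality=1.0,
        ),
        "ps": LysateProfile(
            name="ps",
            space=space,
            responses=standard_responses((1.15, 1.45, 1.3, 1.1), (2.1, 1.7), n),
            quality=0.9,
        ),
        "ab": LysateProfile(
            name="ab",
            space=space,
            responses=standard_responses((1.3, 1.15, 1.45, 1.25), (1.8, 2.0), n),
            quality=0.6,
        ),
        # transcription impaired: absolute signal collapses, relative
        # landscape (and headroom) preserved
        "transcription_impaired": LysateProfile(
            name="transcription_impaired",
            space=space,
            responses=standard_responses((1.25, 1.4, 1.35, 1.2), (1.9, 1.85), n),
            quality=0.15,
        ),
        # translation impaired: yield hard-capped at 15x the reference
        "translation_impaired": LysateProfile(
            name="translation_impaired",
            space=space,
            responses=standard_responses((1.15, 1.45, 1.3, 1.1), (2.1, 1.7), n),
            yield_cap=15.0,
            quality=0.5,
        ),
        "dh5a": LysateProfile(
            name="dh5a",
            space=space,
            responses=standard_responses((1.0, 1.05, 1.5, 0.95), (1.7, 1.5), n),
            yield_cap=10.0,
            quality=0.3,
        ),
    }
    return BenchmarkSuite(profiles=profiles)


def sample_history(
    profile: LysateProfile,
    n: int,
    seed: int = 0,
    explore_frac: float = 0.3,
) -> list[Composition]:
    """Compositions distributed like an exploitation-enriched campaign
    history.

    An upper-confidence-bound campaign spends most of its budget near the
    high-yield ridge and a minority on uncertain regions. This sampler
    emulates that end state cheaply: a fraction ``explore_frac`` of draws
    is uniform; the rest biases activating compounds toward high levels
    and inhibiting compounds toward low levels. Used to build realistic
    measurement histories (e.g. for representative-subset presets)
    without paying for a full campaign.
    """
    rng = np.random.default_rng(seed)
    space = profile.space
    n_levels = np.array([c.n_levels for c in space.compounds])
    if not np.all(n_levels == 4):
        return space.sample_unseen(min(n, space.size()), rng)
    p_up = np.array([0.1, 0.1, 0.2, 0.6])
    p_down = p_up[::-1]
    p_flat = np.full(4, 0.25)
    out, seen = [], set()
    while len(out) < n:
        levels = np.empty(space.n_compounds, dtype=int)
        u = rng.random() < explore_frac
        for j, resp in enumerate(profile.responses):
            if u or resp.direction == 0:
                p = p_flat
            elif resp.direction > 0:
                p = p_up
            else:
                p = p_down
            levels[j] = rng.choice(4, p=p)
        t = tuple(int(v) for v in levels)
        if t in seen:
            continue
        seen.add(t)
        out.append(Composition(t))
    return out
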