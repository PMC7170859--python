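"""Discrete combinatorial space of cell-free buffer compositions.

A buffer composition is a choice of one concentration *level* per variable
compound. Levels are expressed as fractions of each compound's maximal
concentration (by default 10, 30, 50 and 100 %), so an 11-compound,
4-level grid spans ``4**11 = 4,194,304`` candidate buffers. The space
object owns the grid definition, the fixed additives present in every
reaction (HEPES, PEG-8000, lysate, plasmid) and the reference buffer all
yields are normalized against.

Compositions are identified by their exact level tuple: the grid is
discrete, so set membership (the "seen" set of an active-learning
campaign) never needs tolerance comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import CapacityError, InvalidCompositionError

DEFAULT_LEVEL_FRACTIONS: tuple[float, ...] = (0.10, 0.30, 0.50, 1.00)

#: Spaces up to this many points may be exhaustively enumerated.
ENUMERATION_LIMIT = 2**20


@dataclass(frozen=True)
class CompoundSpec:
    """One variable compound of the buffer: its name, maximal concentration
    and the ordered level fractions it can take.

    ``fluid_class`` is dispenser metadata (acoustic dispensers calibrate
    droplet ejection per fluid type); it is carried through to picklists
    untouched.
    """

    name: str
    max_conc: float
    unit: str = "mM"
    level_fractions: tuple[float, ...] = DEFAULT_LEVEL_FRACTIONS
    fluid_class: str = "BP2"

    def __post_init__(self) -> None:
        if self.max_conc <= 0:
            raise ValueError(f"{self.name}: max_conc must be positive")
        fr = tuple(float(f) for f in self.level_fractions)
        if len(fr) < 1:
            raise ValueError(f"{self.name}: at least one level required")
        if any(not (0.0 < f <= 1.0) for f in fr):
            raise ValueError(f"{self.name}: level fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError(f"{self.name}: level fractions must be strictly increasing")
        if fr[-1] != 1.0:
            raise ValueError(f"{self.name}: last level fraction must be 1.0")
        object.__setattr__(self, "level_fractions", fr)

    @property
    def n_levels(self) -> int:
        return len(self.level_fractions)


@dataclass(frozen=True)
class Composition:
    """A point of the grid: one level index per compound (0 = lowest)."""

    levels: tuple[int, ...]

    def __init__(self, levels: Iterable[int]):
        object.__setattr__(self, "levels", tuple(int(v) for v in levels))

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self) -> Iterator[int]:
        return iter(self.levels)

    def __getitem__(self, j: int) -> int:
        return self.levels[j]


@dataclass
class CompositionSpace:
    """The combinatorial search space plus the fixed context of a reaction.

    Parameters
    ----------
    compounds
        Ordered variable compounds; order defines the composition vector.
    fixed_components
        Additives held constant in every reaction, mapped to
        ``(value, unit)`` pairs.
    reference_levels
        The reference buffer (yield 1 by definition). Defaults to the
        50 %-of-maximum level for every compound, matching a protocol
        buffer sitting mid-grid with headroom in both directions.
    """

    compounds: list[CompoundSpec]
    fixed_components: dict[str, tuple[float, str]] = field(default_factory=dict)
    reference_levels: Composition | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique")
        if self.reference_levels is None:
            ref = []
            for c in self.compounds:
                # closest level to the 50% fraction, favouring the lower one
                fr = np.asarray(c.level_fractions)
                ref.append(int(np.argmin(np.abs(fr - 0.5))))
            self.reference_levels = Composition(ref)
        self.validate(self.reference_levels)

    # -- basic geometry -------------------------------------------------

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def size(self) -> int:
        """Number of grid points, ``prod_j L_j``."""
        n = 1
        for c in self.compounds:
            n *= c.n_levels
        return n

    def validate(self, c: Composition) -> None:
        if len(c) != self.n_compounds:
            raise InvalidCompositionError(
                f"composition has {len(c)} levels, space has {self.n_compounds} compounds"
            )
        for j, (lv, spec) in enumerate(zip(c, self.compounds)):
            if not 0 <= lv < spec.n_levels:
                raise InvalidCompositionError(
                    f"level {lv} out of range for compound {spec.name!r} (index {j})"
                )

    # -- normalization --------------------------------------------------

    def normalize(self, c: Composition) -> np.ndarray:
        """Map a composition to its level-fraction vector in ``(0, 1]``.

        This is the model-facing representation: each compound's maximal
        concentration maps to 1 and the lower levels to their fractions.
        """
        self.validate(c)
        return np.array(
            [spec.level_fractions[lv] for lv, spec in zip(c, self.compounds)]
        )

    def normalize_many(self, comps: Sequence[Composition]) -> np.ndarray:
        if not comps:
            return np.empty((0, self.n_compounds))
        levels = np.array([c.levels for c in comps], dtype=int)
        if levels.shape[1] != self.n_compounds:
            raise InvalidCompositionError("composition length mismatch")
        out = np.empty(levels.shape, dtype=float)
        for j, spec in enumerate(self.compounds):
            fr = np.asarray(spec.level_fractions)
            col = levels[:, j]
            if col.min() < 0 or col.max() >= spec.n_levels:
                raise InvalidCompositionError(
                    f"level index out of range for compound {spec.name!r}"
                )
            out[:, j] = fr[col]
        return out

    def denormalize(self, fractions: Sequence[float]) -> Composition:
        """Inverse of :meth:`normalize`; fractions must sit on the grid."""
        if len(fractions) != self.n_compounds:
            raise InvalidCompositionError("fraction vector length mismatch")
        levels = []
        for f, spec in zip(fractions, self.compounds):
            fr = np.asarray(spec.level_fractions)
            j = int(np.argmin(np.abs(fr - f)))
            if not np.isclose(fr[j], f, rtol=1e-6, atol=1e-9):
                raise InvalidCompositionError(
                    f"fraction {f} is not a level of compound {spec.name!r}"
                )
            levels.append(j)
        return Composition(levels)

    def to_concentrations(self, c: Composition) -> dict[str, tuple[float, str]]:
        """Concrete concentrations of a composition, fixed additives included."""
        self.validate(c)
        out = {
            spec.name: (spec.max_conc * spec.level_fractions[lv], spec.unit)
            for lv, spec in zip(c, self.compounds)
        }
        out.update(self.fixed_components)
        return out

    # -- designs and sampling -------------------------------------------

    def initial_design(self) -> list[Composition]:
        """The structured seed design of an exploration campaign.

        Two one-factor-at-a-time families: all compounds at the top level
        except one at the bottom, and all at the bottom except one at the
        top — 22 unique points for 11 compounds. Ordering is fixed
        (max-family by compound index, then min-family) so downstream
        plate layouts are reproducible.
        """
        if self.n_compounds < 2:
            raise ValueError("initial design needs at least 2 compounds")
        tops = [c.n_levels - 1 for c in self.compounds]
        out: list[Composition] = []
        seen: set[tuple[int, ...]] = set()
        for family in ("max", "min"):
            for j in range(self.n_compounds):
                levels = list(tops) if family == "max" else [0] * self.n_compounds
                levels[j] = 0 if family == "max" else tops[j]
                c = Composition(levels)
                if c.levels not in seen:
                    seen.add(c.levels)
                    out.append(c)
        return out

    def enumerate(self) -> Iterator[Composition]:
        """Yield every grid point (guarded against huge spaces)."""
        if self.size() > ENUMERATION_LIMIT:
            raise CapacityError(
                f"space of {self.size()} points exceeds the enumeration limit"
            )
        ranges = [range(c.n_levels) for c in self.compounds]
        for levels in itertools.product(*ranges):
            yield Composition(levels)

    def sample_unseen(
        self,
        n: int,
        seed: int | np.random.Generator,
        exclude: Iterable[Composition] = (),
    ) -> list[Composition]:
        """Draw ``n`` distinct compositions not in ``exclude``.

        Small spaces are enumerated so the draw is exact; on large spaces
        uniform rejection sampling is used (duplicates and excluded points
        are redrawn), which is how a sparse seen set is handled in a
        multi-million point grid.
        """
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        excl = {c.levels if isinstance(c, Composition) else tuple(c) for c in exclude}
        total = self.size()
        if n > total - len(excl):
            raise CapacityError(
                f"requested {n} unseen compositions, only {total - len(excl)} available"
            )
        if total <= ENUMERATION_LIMIT:
            pool = [c for c in self.enumerate() if c.levels not in excl]
            idx = rng.choice(len(pool), size=n, replace=False)
            return [pool[i] for i in idx]
        n_levels = np.array([c.n_levels for c in self.compounds])
        out: list[Composition] = []
        chosen: set[tuple[int, ...]] = set()
        while len(out) < n:
            batch = rng.integers(0, n_levels, size=(max(n - len(out), 64), self.n_compounds))
            for row in batch:
                t = tuple(int(v) for v in row)
                if t in excl or t in chosen:
                    continue
                chosen.add(t)
                out.append(Composition(t))
                if len(out) == n:
                    break
        return out

    # -- serialization --------------------------------------------------

    def compositions_to_frame(
        self, comps: Sequence[Composition], ids: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Tabulate compositions as normalized fractions, one column per compound."""
        df = pd.DataFrame(self.normalize_many(comps), columns=self.names)
        if ids is not None:
            df.insert(0, "id", list(ids))
        return df

    def frame_to_compositions(self, df: pd.DataFrame) -> list[Composition]:
        return [self.denormalize([row[n] for n in self.names]) for _, row in df.iterrows()]

    def to_yaml(self, path) -> None:
        doc = {
            "compounds": [
                {
                    "name": c.name,
                    "max_conc": c.max_conc,
                    "unit": c.unit,
                    "level_fractions": list(c.level_fractions),
                    "fluid_class": c.fluid_class,
                }
                for c in self.compounds
            ],
            "fixed_components": {
                k: {"value": v, "unit": u} for k, (v, u) in self.fixed_components.items()
            },
            "reference_fractions": [float(f) for f in self.normalize(self.reference_levels)],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CompositionSpace":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        compounds = [
            CompoundSpec(
                name=c["name"],
                max_conc=float(c["max_conc"]),
                unit=c.get("unit", "mM"),
                level_fractions=tuple(c.get("level_fractions", DEFAULT_LEVEL_FRACTIONS)),
                fluid_class=c.get("fluid_class", "BP2"),
            )
            for c in doc["compounds"]
        ]
        fixed = {
            k: (float(v["value"]), v.get("unit", ""))
            for k, v in doc.get("fixed_components", {}).items()
        }
        space = cls(compounds=compounds, fixed_components=fixed)
        if "reference_fractions" in doc:
            space.reference_levels = space.denormalize(doc["reference_fractions"])
        return space


def default_space() -> CompositionSpace:
    """The 11-compound TXTL buffer space.

    Maximal concentrations are an editable placeholder table (protocol
    buffers differ between labs); they are set to twice a typical
    protocol value so the reference buffer sits at the 50 % level.
    Mg-/K-glutamate maxima are treated as given configuration, fixed by a
    prior single-compound buffer calibration. Fluid classes follow
    acoustic-dispenser practice: aqueous BP2 for most stocks, CP for the
    viscous K-glutamate and 3-PGA stocks.
    """
    compounds = [
        CompoundSpec("mg_glutamate", 8.0, "mM"),
        CompoundSpec("k_glutamate", 160.0, "mM", fluid_class="CP"),
        CompoundSpec("amino_acids", 3.0, "mM"),
        CompoundSpec("ntps", 3.0, "mM"),
        CompoundSpec("spermidine", 2.0, "mM"),
        CompoundSpec("pga_3", 60.0, "mM", fluid_class="CP"),
        CompoundSpec("trna", 0.4, "mg/mL"),
        CompoundSpec("coa", 0.52, "mM"),
        CompoundSpec("nad", 0.66, "mM"),
        CompoundSpec("camp", 1.5, "mM"),
        CompoundSpec("folinic_acid", 0.136, "mM"),
    ]
    fixed = {
        "hepes": (50.0, "mM"),
        "peg_8000": (2.0, "%"),
        "lysate": (33.0, "% v/v"),
        "plasmid": (10.0, "nM"),
    }
    return CompositionSpace(compounds=compounds, fixed_components=fixed)


# module-level aliases mirroring the functional surface


def space_size(space: CompositionSpace) -> int:
    return space.size()


def normalize(c: Composition, space: CompositionSpace) -> np.ndarray:
    return space.normalize(c)


def to_concentrations(c: Composition, space: CompositionSpace) -> dict[str, tuple[float, str]]:
    return space.to_concentrations(c)


def initial_design(space: CompositionSpace) -> list[Composition]:
    return space.initial_design()


def sample_unseen(
    space: CompositionSpace,
    n: int,
    seed: int,
    exclude: Iterable[Composition] = (),
) -> list[Composition]:
    return space.sample_unseen(n, seed, exclude)
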