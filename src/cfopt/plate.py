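"""Plate-level I/O: dispenser instructions, fluorescence ingestion,
triplicate outlier filtering, yield normalization and plate QC.

Volumes are handled in nanolitres. An acoustic dispenser ejects discrete
2.5 nL droplets, and at least five droplets (12.5 nL) per transfer;
volumes above 1 µL are routed to a manual-pipetting sheet instead of the
picklist. Reactions are 10.5 µL in a 384-well plate; rows A and P are
reserved for the 13 triplicate control compositions.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateReferenceError,
    IngestionError,
    InsufficientControlsError,
    LayoutError,
    NonPositiveSignalError,
    OverVolumeError,
    SchemaError,
    StockConcentrationError,
)
from .space import Composition, CompositionSpace

DROPLET_NL = 2.5
MIN_TRANSFER_NL = 12.5
MANUAL_THRESHOLD_NL = 1000.0
FINAL_VOLUME_UL = 10.5
PLATE_ROWS = 16
PLATE_COLS = 24
N_CONTROLS = 13
DEFAULT_REPLICATES = 3
CV_THRESHOLD = 0.30
QC_R2_THRESHOLD = 0.75

ROW_LETTERS = string.ascii_uppercase[:PLATE_ROWS]
CONTROL_ROWS = ("A", "P")
TEST_ROWS = tuple(r for r in ROW_LETTERS if r not in CONTROL_ROWS)


@dataclass(frozen=True)
class TransferInstruction:
    source_well: str
    destination_well: str
    volume_nl: float
    reagent: str
    fluid_class: str = "BP2"
    manual: bool = False


@dataclass(frozen=True)
class FluorescenceRecord:
    """Five raw reads of one well plus their aggregate (mean)."""

    well: str
    reads: tuple[float, ...]
    aggregate: float


@dataclass
class YieldRecord:
    """Normalized yield of one composition on one lysate.

    ``replicate_fluorescences`` keeps the raw triplicate with a removed
    outlier encoded as -1, the convention used when persisting
    fluorescence files.
    """

    composition: Composition
    replicate_fluorescences: tuple[float, ...]
    yield_mean: float
    yield_std: float
    n_used: int
    lysate_id: str = ""


@dataclass
class QCReport:
    plate_id: str
    r2_vs_previous: dict[str, float]
    systematic_bias: dict[str, int]  # plate -> -1 (all below), 0, +1 (all above)
    passed: bool


@dataclass
class PlateDesign:
    """Test compositions (in triplicate) plus control layout for one plate."""

    compositions: list[Composition]
    controls: list[Composition] = field(default_factory=list)
    replicates: int = DEFAULT_REPLICATES

    def __post_init__(self) -> None:
        total = (len(self.compositions) + len(self.controls)) * self.replicates
        if total > PLATE_ROWS * PLATE_COLS:
            raise OverVolumeError(f"{total} wells exceed plate capacity")
        ctrl_capacity = len(CONTROL_ROWS) * PLATE_COLS
        if len(self.controls) * self.replicates > ctrl_capacity:
            raise OverVolumeError("control rows cannot hold all control replicates")
        test_capacity = len(TEST_ROWS) * PLATE_COLS
        if len(self.compositions) * self.replicates > test_capacity:
            raise OverVolumeError("test rows cannot hold all test replicates")

    def well_map(self) -> pd.DataFrame:
        """Assign wells: tests fill rows B..O left-to-right, controls rows A/P."""
        rows = []
        test_wells = [f"{r}{c}" for r in TEST_ROWS for c in range(1, PLATE_COLS + 1)]
        k = 0
        for i, comp in enumerate(self.compositions):
            for rep in range(1, self.replicates + 1):
                rows.append((test_wells[k], f"C{i:03d}", rep))
                k += 1
        ctrl_wells = [f"{r}{c}" for r in CONTROL_ROWS for c in range(1, PLATE_COLS + 1)]
        k = 0
        for i, comp in enumerate(self.controls):
            for rep in range(1, self.replicates + 1):
                rows.append((ctrl_wells[k], f"K{i:02d}", rep))
                k += 1
        return pd.DataFrame(rows, columns=["Destination Well", "Composition ID", "Replicate"])

    def composition_by_id(self) -> dict[str, Composition]:
        out = {f"C{i:03d}": c for i, c in enumerate(self.compositions)}
        out.update({f"K{i:02d}": c for i, c in enumerate(self.controls)})
        return out


# ---------------------------------------------------------------------------
# concentrations -> volumes -> picklist


def complete_concentrations(
    partial: pd.DataFrame, constants: Mapping[str, float], space: CompositionSpace | None = None
) -> pd.DataFrame:
    """Append constant-reagent columns to a table of variable concentrations.

    Raises :class:`SchemaError` if the table carries columns that are
    neither known compounds nor bookkeeping (``id``).
    """
    if space is not None:
        known = set(space.names) | {"id"}
        unknown = [c for c in partial.columns if c not in known]
        if unknown:
            raise SchemaError(f"unknown compound columns: {unknown}")
    out = partial.copy()
    for name, value in constants.items():
        out[name] = value
    return out


def _quantize(v_nl: float) -> float:
    return np.floor(v_nl / DROPLET_NL + 0.5) * DROPLET_NL


def concentrations_to_volumes(
    table: pd.DataFrame,
    stocks: Mapping[str, float],
    final_volume_ul: float = FINAL_VOLUME_UL,
    replicates: int = DEFAULT_REPLICATES,
    lysate_volume_ul: float | None = None,
    sort_by_water: bool = False,
) -> pd.DataFrame:
    """Convert final concentrations to per-well transfer volumes (nL).

    For each reagent column present in ``stocks``,
    ``volume = final_conc * final_volume / stock_conc``, quantized to the
    nearest 2.5 nL droplet multiple. Water absorbs the residual volume and
    is reported unquantized (it is pipetted manually). Each input row is
    replicated ``replicates`` times.

    Raises
    ------
    StockConcentrationError
        if a nonzero quantized volume falls below 12.5 nL; the error names
        the reagent and the maximum stock concentration that would fix it.
    OverVolumeError
        if reagents plus lysate exceed the reaction volume.
    """
    final_nl = final_volume_ul * 1000.0
    lysate_nl = (lysate_volume_ul or 0.0) * 1000.0
    reagents = [c for c in table.columns if c in stocks]
    vol = pd.DataFrame(index=table.index)
    for r in reagents:
        conc = table[r].to_numpy(dtype=float)
        raw = conc * final_nl / float(stocks[r])
        q = np.array([_quantize(v) for v in raw])
        bad = (q > 0) & (q < MIN_TRANSFER_NL)
        if bad.any():
            worst = conc[bad].min()
            max_stock = worst * final_nl / MIN_TRANSFER_NL
            raise StockConcentrationError(
                r,
                max_stock,
                f"reagent {r!r}: {q[bad][0]:.1f} nL is below the {MIN_TRANSFER_NL} nL "
                f"minimum transfer; dilute the stock to <= {max_stock:.4g} "
                f"(same unit as the concentration table)",
            )
        vol[r] = q
    water = final_nl - vol.sum(axis=1) - lysate_nl
    if (water < -1e-9).any():
        raise OverVolumeError("reagent volumes exceed the reaction volume")
    vol["lysate"] = lysate_nl
    vol["water"] = water.clip(lower=0.0)
    if "id" in table.columns:
        vol.insert(0, "id", table["id"].to_numpy())
    else:
        vol.insert(0, "id", [f"C{i:03d}" for i in range(len(table))])
    vol = vol.loc[vol.index.repeat(replicates)].reset_index(drop=True)
    vol["replicate"] = list(range(1, replicates + 1)) * len(table)
    if sort_by_water:
        vol = vol.sort_values("water", ascending=False, kind="stable").reset_index(drop=True)
    return vol


def volumes_to_picklist(
    volumes: pd.DataFrame,
    source_layout: Mapping[str, str],
    fluid_classes: Mapping[str, str] | None = None,
    destination_plate: str = "destination[1]",
    source_plate: str = "source[1]",
    destination_wells: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build the dispenser picklist, the manual-pipetting sheet and the
    well map from a volume table.

    Returns ``(picklist, manual_sheet, well_map)``. Zero volumes emit no
    instruction; volumes above 1 µL go to the manual sheet (hand pipetting
    is faster and more accurate there).
    """
    fluid_classes = fluid_classes or {}
    reagents = [c for c in volumes.columns if c not in ("id", "replicate")]
    missing = [r for r in reagents if r not in source_layout]
    if missing:
        raise LayoutError(f"no source well for reagents: {missing}")
    if destination_wells is None:
        destination_wells = [f"{r}{c}" for r in TEST_ROWS for c in range(1, PLATE_COLS + 1)]
    if len(volumes) > len(destination_wells):
        raise OverVolumeError("more volume rows than destination wells")
    pick, manual, wmap = [], [], []
    for i, (_, row) in enumerate(volumes.iterrows()):
        dest = destination_wells[i]
        wmap.append((dest, row["id"], int(row.get("replicate", 1))))
        for r in reagents:
            v = float(row[r])
            if v <= 0:
                continue
            rec = {
                "Source Plate Name": source_plate,
                "Source Well": source_layout[r],
                "Destination Plate Name": destination_plate,
                "Destination Well": dest,
                "Transfer Volume": v,
                "Fluid Class": fluid_classes.get(r, "BP2"),
                "Reagent": r,
            }
            (manual if v > MANUAL_THRESHOLD_NL else pick).append(rec)
    cols = [
        "Source Plate Name", "Source Well", "Destination Plate Name",
        "Destination Well", "Transfer Volume", "Fluid Class", "Reagent",
    ]
    return (
        pd.DataFrame(pick, columns=cols),
        pd.DataFrame(manual, columns=cols),
        pd.DataFrame(wmap, columns=["Destination Well", "Composition ID", "Replicate"]),
    )


# ---------------------------------------------------------------------------
# ingestion


READ_COLUMNS = [f"Read{i}" for i in range(1, 6)]


def match_measurements(
    well_map: pd.DataFrame, reader_export: pd.DataFrame, max_spread: float | None = None
) -> pd.DataFrame:
    """Join the well map with a reader export on well id.

    Each well carries five reads (a reader quality control); they are
    aggregated by their mean. Wells in the map but absent from the export
    raise :class:`IngestionError`; extra exported wells are ignored.
    """
    missing = set(well_map["Destination Well"]) - set(reader_export["Well"])
    if missing:
        raise IngestionError(f"wells absent from reader export: {sorted(missing)}")
    merged = well_map.merge(
        reader_export, left_on="Destination Well", right_on="Well", how="left"
    )
    reads = merged[READ_COLUMNS].to_numpy(dtype=float)
    merged["fluorescence"] = reads.mean(axis=1)
    if max_spread is not None:
        spread = reads.max(axis=1) - reads.min(axis=1)
        wide = spread > max_spread * np.abs(merged["fluorescence"])
        if wide.any():
            warnings.warn(
                f"{int(wide.sum())} wells exceed the read-spread threshold", stacklevel=2
            )
    return merged[["Destination Well", "Composition ID", "Replicate", "fluorescence"]]


def remove_outliers(
    values: Sequence[float], cv_threshold: float = CV_THRESHOLD
) -> tuple[np.ndarray, int | None]:
    """Single-outlier filter for a fluorescence triplicate.

    If the coefficient of variation (sample std / mean) strictly exceeds
    ``cv_threshold``, the value farthest from the median of the three is
    dropped (for three points, "farthest from the other two" and
    "farthest from the median" coincide). Ties drop the larger value,
    inflated signal being the more likely artefact. At most one value is
    ever removed.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (3,) or not np.isfinite(v).all():
        raise ValueError("exactly 3 finite replicate values required")
    mean = v.mean()
    if mean <= 0:
        raise NonPositiveSignalError("non-positive mean fluorescence")
    cv = v.std(ddof=1) / mean
    if cv <= cv_threshold:
        return v, None
    dist = np.abs(v - np.median(v))
    far = np.flatnonzero(dist == dist.max())
    idx = int(far[np.argmax(v[far])])
    return np.delete(v, idx), idx


def compute_yield(
    fluorescences: Sequence[float],
    reference_fluorescence: float,
    autofluorescence: float,
) -> tuple[float, float, int]:
    """Normalize replicate fluorescences to yields and aggregate.

    ``yield = (F_composition - F_auto) / (F_reference - F_auto)`` per
    replicate, then mean and sample std over the kept replicates. The
    reference composition has yield 1 and a blank has yield 0 by
    construction; with a global reference lysate's values this computes
    the cross-lysate G-yield.
    """
    if reference_fluorescence <= autofluorescence:
        raise DegenerateReferenceError(
            "reference fluorescence must exceed autofluorescence"
        )
    f = np.asarray(fluorescences, dtype=float)
    y = (f - autofluorescence) / (reference_fluorescence - autofluorescence)
    std = float(y.std(ddof=1)) if y.size > 1 else 0.0
    return float(y.mean()), std, int(y.size)


def make_yield_record(
    composition: Composition,
    replicate_fluorescences: Sequence[float],
    reference_fluorescence: float,
    autofluorescence: float,
    lysate_id: str = "",
    cv_threshold: float = CV_THRESHOLD,
) -> YieldRecord:
    """Outlier-filter a triplicate then normalize it into a YieldRecord."""
    kept, removed = remove_outliers(replicate_fluorescences, cv_threshold)
    mean, std, n = compute_yield(kept, reference_fluorescence, autofluorescence)
    persisted = list(map(float, replicate_fluorescences))
    if removed is not None:
        persisted[removed] = -1.0
    return YieldRecord(
        composition=composition,
        replicate_fluorescences=tuple(persisted),
        yield_mean=mean,
        yield_std=std,
        n_used=n,
        lysate_id=lysate_id,
    )


def plate_qc(
    new_controls: Mapping[str, float],
    previous_plates: Mapping[str, Mapping[str, float]],
    r2_threshold: float = QC_R2_THRESHOLD,
    plate_id: str = "",
) -> QCReport:
    """Control-based plate acceptance.

    For each previous plate, the squared Pearson correlation between
    shared control yields is computed; the plate passes only if every R²
    exceeds the threshold and no previous plate is strictly dominated
    (all shared controls above, or all below — a systematic gain shift
    that correlation alone would miss).
    """
    r2s: dict[str, float] = {}
    bias: dict[str, int] = {}
    for pid, prev in previous_plates.items():
        shared = sorted(set(new_controls) & set(prev))
        if len(shared) < 2:
            raise InsufficientControlsError(
                f"fewer than 2 shared controls with plate {pid!r}"
            )
        a = np.array([new_controls[c] for c in shared])
        b = np.array([prev[c] for c in shared])
        r = stats.pearsonr(a, b).statistic if a.std() > 0 and b.std() > 0 else 0.0
        r2s[pid] = float(r**2)
        if np.all(a > b):
            bias[pid] = 1
        elif np.all(a < b):
            bias[pid] = -1
        else:
            bias[pid] = 0
    passed = all(v > r2_threshold for v in r2s.values()) and all(
        v == 0 for v in bias.values()
    )
    return QCReport(plate_id=plate_id, r2_vs_previous=r2s, systematic_bias=bias, passed=passed)


# ---------------------------------------------------------------------------
# yields table round-trip


def yields_to_frame(records: Sequence[YieldRecord], space: CompositionSpace) -> pd.DataFrame:
    """Persist yield records: one fraction column per compound plus stats."""
    comp_df = space.compositions_to_frame([r.composition for r in records])
    comp_df["yield_mean"] = [r.yield_mean for r in records]
    comp_df["yield_std"] = [r.yield_std for r in records]
    comp_df["n_used"] = [r.n_used for r in records]
    comp_df["lysate_id"] = [r.lysate_id for r in records]
    return comp_df


def frame_to_yields(df: pd.DataFrame, space: CompositionSpace) -> list[YieldRecord]:
    out = []
    for _, row in df.iterrows():
        comp = space.denormalize([row[n] for n in space.names])
        out.append(
            YieldRecord(
                composition=comp,
                replicate_fluorescences=(),
                yield_mean=float(row["yield_mean"]),
                yield_std=float(row.get("yield_std", 0.0)),
                n_used=int(row.get("n_used", 3)),
                lysate_id=str(row.get("lysate_id", "")),
            )
        )
    return out
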