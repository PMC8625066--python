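"""From raw kinetic curves to consumption levels.

The reader records one colorimetric signal time series per well over 72 h.
Consumption of the sole nitrogen source in a well is summarized as the
area under that curve (trapezoid rule on the recorded grid, no smoothing).
Replicate AUCs are averaged, blanked against the plate's negative control
(floored at zero, to discount spontaneous dye reduction), and expressed as
a percentage of the same strain/plate's blanked L-glutamine AUC, which
defines 100 % consumption.  Percentages are binned into discrete levels:

====== ===========
level  % of L-Gln
====== ===========
0      0–20
1      >20–40
2      >40–60
3      >60–80
4      >80–100
5      >100
====== ===========

A substrate counts as *utilized* when its value exceeds 20 % of the
glutamine control, i.e. level ≥ 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import PlateLayout, substrate_lookup, universe
from .errors import DegeneratePlateError, MissingControlError, ValidationError
from .peptides import Peptide, parse_peptide_name

#: Upper bin edges for levels 0..4; anything above the last edge is level 5.
LEVEL_EDGES = (20.0, 40.0, 60.0, 80.0, 100.0)

#: Utilization threshold: consumption must exceed this percent of L-Gln.
CONSUMPTION_THRESHOLD_PCT = 20.0

MAX_TIME_H = 72.0

KINETIC_COLUMNS = ("strain_id", "plate_id", "well", "replicate_id", "time_h", "signal")


@dataclass
class KineticCurve:
    """One well's signal time series."""

    times: np.ndarray
    signal: np.ndarray
    well: str = ""
    plate_id: str = ""
    strain_id: str = ""
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size < 2:
            raise ValidationError("kinetic curve needs at least 2 timepoints")
        if self.times.size != self.signal.size:
            raise ValidationError("times and signal differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > MAX_TIME_H:
            raise ValidationError(f"times must lie within [0, {MAX_TIME_H}] h")
        if np.any(self.signal < 0):
            raise ValidationError("signal values must be non-negative")


@dataclass
class ConsumptionValue:
    """Area under one well's curve (signal · hours)."""

    auc: float
    strain_id: str = ""
    plate_id: str = ""
    substrate: Peptide | str | None = None


def area_under_curve(curve: KineticCurve) -> ConsumptionValue:
    """Trapezoidal integral of signal over the recorded time grid."""
    auc = float(np.trapezoid(curve.signal, curve.times))
    return ConsumptionValue(
        auc=auc, strain_id=curve.strain_id, plate_id=curve.plate_id
    )


def aggregate_replicates(values: Sequence[ConsumptionValue]) -> ConsumptionValue:
    """Arithmetic mean of replicate AUCs (same strain/plate/substrate)."""
    if len(values) == 0:
        raise ValidationError("cannot aggregate an empty replicate list")
    first = values[0]
    for v in values[1:]:
        if (v.strain_id, v.plate_id) != (first.strain_id, first.plate_id):
            raise ValidationError("replicates must share strain and plate")
    return ConsumptionValue(
        auc=float(np.mean([v.auc for v in values])),
        strain_id=first.strain_id,
        plate_id=first.plate_id,
        substrate=first.substrate,
    )


def blank_and_normalize(
    v: ConsumptionValue,
    neg: ConsumptionValue,
    gln: ConsumptionValue,
    blank: bool = True,
) -> float:
    """Express a well's AUC as percent of the L-glutamine positive control.

    With blanking (default) the negative-control AUC is subtracted from
    both the well and the control, and negative blanked values are floored
    at 0.  Without blanking, raw AUCs are ratioed directly.
    """
    if blank:
        denom = gln.auc - neg.auc
        if denom <= 0:
            raise DegeneratePlateError(
                f"positive control failed on strain {v.strain_id!r} plate "
                f"{v.plate_id!r}: glutamine AUC {gln.auc:g} <= negative {neg.auc:g}"
            )
        return 100.0 * max(v.auc - neg.auc, 0.0) / denom
    if gln.auc <= 0:
        raise DegeneratePlateError(
            f"positive control AUC is non-positive on strain {v.strain_id!r} "
            f"plate {v.plate_id!r}"
        )
    return 100.0 * v.auc / gln.auc


def assign_level(percent: float) -> int:
    """Discretize a percent-of-glutamine value into a 0–5 level.

    Exactly 20.0 % is level 0: utilization requires *more than* 20 %.
    """
    if percent < 0:
        raise ValidationError(f"negative percent {percent!r}")
    return int(np.searchsorted(LEVEL_EDGES, percent, side="left"))


def assign_levels(percents: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_level`; NaN maps to -1."""
    arr = np.asarray(percents, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValidationError("negative percent value")
    lev = np.searchsorted(LEVEL_EDGES, arr, side="left").astype(float)
    lev[np.isnan(arr)] = np.nan
    return lev


@dataclass
class ConsumptionCall:
    """Normalized consumption for one strain × substrate."""

    percent_of_gln: float
    level: int
    consumed: bool

    @classmethod
    def from_percent(cls, percent: float) -> "ConsumptionCall":
        level = assign_level(percent)
        return cls(percent_of_gln=percent, level=level, consumed=level >= 1)


@dataclass
class ProfileMatrix:
    """Strains × substrates consumption matrix (levels plus raw percents).

    ``levels`` is an integer DataFrame (pandas nullable ``Int64``; missing
    wells are <NA>, never 0) indexed by strain, with substrate display
    names as columns.  ``percents`` is a parallel float DataFrame (may be
    None when a matrix was built from levels alone).  ``substrates`` holds
    the column peptides in column order.
    """

    levels: pd.DataFrame
    substrates: list[Peptide]
    percents: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        names = [p.display_name for p in self.substrates]
        if list(self.levels.columns) != names:
            raise ValidationError("levels columns do not match substrate order")
        if self.percents is not None and (
            self.percents.shape != self.levels.shape
            or list(self.percents.columns) != names
        ):
            raise ValidationError("percents matrix does not parallel levels")

    @property
    def strains(self) -> list[str]:
        return list(self.levels.index)

    @classmethod
    def from_levels(
        cls, levels: pd.DataFrame, substrates: Sequence[Peptide] | None = None
    ) -> "ProfileMatrix":
        if substrates is None:
            substrates = [parse_peptide_name(c) for c in levels.columns]
        return cls(levels=levels.astype("Int64"), substrates=list(substrates))


def build_profile_matrix(
    kinetics: pd.DataFrame,
    catalog: Iterable[PlateLayout],
    blank: bool = True,
) -> ProfileMatrix:
    """Run the full scoring pipeline on a long-format kinetics table.

    Replicate curves are integrated individually, averaged at the AUC
    stage, blanked and normalized per strain × plate, and binned into
    levels.  Substrate wells absent for a strain yield missing values.

    Raises
    ------
    MissingControlError
        If a strain/plate lacks either control well.
    DegeneratePlateError
        If a plate's positive control does not exceed its negative control.
    """
    catalog = list(catalog)
    df = kinetics.copy()
    missing_cols = set(KINETIC_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"kinetics table missing columns {sorted(missing_cols)}")
    for col in ("strain_id", "plate_id", "well", "replicate_id"):
        df[col] = df[col].astype(str)
    df["time_h"] = df["time_h"].astype(float)
    df["signal"] = df["signal"].astype(float)
    if df["time_h"].min() < 0 or df["time_h"].max() > MAX_TIME_H:
        raise ValidationError(f"time_h values must lie within [0, {MAX_TIME_H}]")
    if (df["signal"] < 0).any():
        raise ValidationError("negative signal values in kinetics table")

    keys = ["strain_id", "plate_id", "well", "replicate_id"]
    df = df.sort_values(keys + ["time_h"], kind="mergesort").reset_index(drop=True)

    sizes = df.groupby(keys, sort=False)["time_h"].transform("size")
    if (sizes < 2).any():
        bad = df.loc[sizes < 2, keys].iloc[0].tolist()
        raise ValidationError(f"curve {bad} has fewer than 2 timepoints")

    same = (df[keys] == df[keys].shift()).all(axis=1)
    dt = df["time_h"].diff()
    if ((dt <= 0) & same).any():
        raise ValidationError("non-increasing or duplicate timepoints within a curve")
    contrib = (0.5 * (df["signal"] + df["signal"].shift()) * dt).where(same, 0.0)
    auc = contrib.groupby([df[k] for k in keys], sort=False).sum()

    # replicate mean at the AUC stage
    mean_auc = auc.groupby(level=[0, 1, 2]).mean()

    lookup = substrate_lookup(catalog)
    controls = {
        p.plate_id: (p.negative_well, p.positive_well) for p in catalog
    }

    percent_rows: dict[str, dict[str, float]] = {}
    for (strain, plate), grp in mean_auc.groupby(level=[0, 1]):
        if plate not in controls:
            raise ValidationError(f"plate {plate!r} not present in catalog")
        neg_w, pos_w = controls[plate]
        wells = grp.droplevel([0, 1])
        if neg_w not in wells.index or pos_w not in wells.index:
            raise MissingControlError(
                f"strain {strain!r} plate {plate!r}: control well(s) missing"
            )
        neg = ConsumptionValue(float(wells[neg_w]), strain, plate)
        gln = ConsumptionValue(float(wells[pos_w]), strain, plate)
        row = percent_rows.setdefault(strain, {})
        for well, value in wells.items():
            pep = lookup.get((plate, well))
            if pep is None:
                continue  # control or unmapped well
            v = ConsumptionValue(float(value), strain, plate)
            row[pep.display_name] = blank_and_normalize(v, neg, gln, blank=blank)

    substrates = universe(catalog)
    names = [p.display_name for p in substrates]
    strains = sorted(percent_rows)
    percents = pd.DataFrame(
        [[percent_rows[s].get(n, np.nan) for n in names] for s in strains],
        index=pd.Index(strains, name="strain_id"),
        columns=names,
    )
    levels = pd.DataFrame(
        assign_levels(percents.to_numpy()), index=percents.index, columns=names
    ).astype("Int64")
    return ProfileMatrix(levels=levels, substrates=substrates, percents=percents)


# ---------------------------------------------------------------------------
# Kinetic-table and profile I/O

def read_kinetics(path: str) -> pd.DataFrame:
    """Read a kinetics table, auto-detecting the dialect from the header.

    Long format has columns strain_id/plate_id/well/replicate_id/time_h/
    signal.  The wide OmniLog-export-like dialect has strain_id/plate_id/
    replicate_id/time_h followed by one column per well, and is melted to
    long form.
    """
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "signal" in df.columns and "well" in df.columns:
        return df
    id_cols = ["strain_id", "plate_id", "replicate_id", "time_h"]
    if not set(id_cols).issubset(df.columns):
        raise ValidationError(
            f"unrecognized kinetics header in {path!r}: expected long "
            "(…, well, signal) or wide (…, time_h, <wells>) dialect"
        )
    well_cols = [c for c in df.columns if c not in id_cols]
    long = df.melt(
        id_vars=id_cols, value_vars=well_cols, var_name="well", value_name="signal"
    )
    return long[list(KINETIC_COLUMNS)]


def write_kinetics(df: pd.DataFrame, path: str) -> None:
    sep = "," if path.endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)


def write_profile(
    m: ProfileMatrix, levels_path: str, percents_path: str | None = None
) -> None:
    m.levels.to_csv(levels_path, sep="\t")
    if percents_path is not None:
        if m.percents is None:
            raise ValidationError("matrix carries no percents to write")
        m.percents.to_csv(percents_path, sep="\t", float_format="%.6f")


def read_profile(
    levels_path: str, percents_path: str | None = None
) -> ProfileMatrix:
    levels = pd.read_csv(levels_path, sep="\t", index_col=0).astype("Int64")
    levels.index = levels.index.astype(str)
    substrates = [parse_peptide_name(c) for c in levels.columns]
    percents = None
    if percents_path is not None:
        percents = pd.read_csv(percents_path, sep="\t", index_col=0)
        percents.index = percents.index.astype(str)
    return ProfileMatrix(levels=levels, substrates=substrates, percents=percents)
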