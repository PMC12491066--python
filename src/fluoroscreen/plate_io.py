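"""Data model and CSV interchange for dye-screen plate runs and kinetic reads.

A paDSF screen heats a 384-well plate on a thermal ramp while fluorescence is
recorded in several optical channels; each well holds one dye mixed with one
sample (a fibril preparation, or one of three counter-screen controls: dye
alone, dye + polyanion inducer, or dye + monomeric protein).  This module
defines the in-memory objects the scoring stage consumes and a long ("tidy")
CSV format that round-trips them byte-identically.

The canonical CSV is our own convention: the thermal cycler's native export
layout varies by vendor and is converted to this format by the user.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fluoroscreen")

#: Absolute tolerance (degC) when validating temperature grids.
TEMP_TOL_C = 1e-6


class FormatError(ValueError):
    """A file does not conform to the canonical CSV schema."""


class ValidationError(ValueError):
    """Data are schema-conformant but violate a domain invariant."""


# ---------------------------------------------------------------------------
# Channel tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """One excitation/emission filter pair of the instrument.

    Parameters
    ----------
    name : str
        Channel label, e.g. the reporter-dye name used by qPCR software.
    ex_nm, em_nm : float
        Excitation and emission wavelengths in nanometres.
    cutoff_nm : float, optional
        Emission cutoff filter, where the plate reader uses one.
    """

    name: str
    ex_nm: float
    em_nm: float
    cutoff_nm: float | None = None

    def __post_init__(self) -> None:
        if not self.em_nm > self.ex_nm:
            raise ValidationError(
                f"channel {self.name!r}: em_nm ({self.em_nm}) must exceed "
                f"ex_nm ({self.ex_nm})"
            )


#: The six-channel filter set of the melt-screen instrument.
DEFAULT_PADSF_CHANNELS: tuple[ChannelSpec, ...] = (
    ChannelSpec("FAM", 470, 520),
    ChannelSpec("JOE", 515, 545),
    ChannelSpec("TAMRA", 535, 580),
    ChannelSpec("ROX", 565, 605),
    ChannelSpec("Cy5", 630, 670),
    ChannelSpec("Cy5.5", 660, 705),
)

#: The four-channel set used for kinetic (ThT-like) aggregation reads.
DEFAULT_KINETIC_CHANNELS: tuple[ChannelSpec, ...] = (
    ChannelSpec("444/482", 444, 482, cutoff_nm=475),
    ChannelSpec("470/520", 470, 520, cutoff_nm=515),
    ChannelSpec("515/545", 515, 545, cutoff_nm=530),
    ChannelSpec("565/605", 565, 605, cutoff_nm=590),
)

_CHANNEL_INDEX = {c.name.lower(): c for c in DEFAULT_PADSF_CHANNELS + DEFAULT_KINETIC_CHANNELS}

_EX_EM_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*$")


def resolve_channel(label: str) -> ChannelSpec:
    """Map a channel label to a :class:`ChannelSpec`.

    Known labels (the default tables) are matched case-insensitively.  An
    unknown ``"ex/em"`` label is parsed into a new spec; anything else is
    allowed but flagged in the log and given a nominal 1-nm Stokes shift.
    """
    known = _CHANNEL_INDEX.get(label.strip().lower())
    if known is not None:
        return known
    m = _EX_EM_RE.match(label)
    if m is not None:
        logger.warning("channel %r not in the default table; parsed as ex/em", label)
        return ChannelSpec(label.strip(), float(m.group(1)), float(m.group(2)))
    logger.warning("unknown channel label %r; wavelengths unavailable", label)
    return ChannelSpec(label.strip(), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

def default_ramp() -> np.ndarray:
    """The default melt protocol: 25..95 degC inclusive, 1 degC steps (71 points)."""
    return np.arange(25.0, 96.0, 1.0)


@dataclass
class MeltCurve:
    """Temperature-vs-fluorescence series for one well in one channel."""

    temperatures_c: np.ndarray
    rfu: np.ndarray
    channel: ChannelSpec

    def __post_init__(self) -> None:
        self.temperatures_c = np.asarray(self.temperatures_c, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.temperatures_c.shape != self.rfu.shape:
            raise ValidationError(
                f"temperature grid ({self.temperatures_c.size}) and rfu "
                f"({self.rfu.size}) lengths differ"
            )
        if self.temperatures_c.size >= 2 and not np.all(
            np.diff(self.temperatures_c) > TEMP_TOL_C
        ):
            raise ValidationError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return self.temperatures_c.size


SAMPLE_TYPES = ("fibril", "no_protein", "polyanion_only", "monomer")


@dataclass
class Well:
    """One plate well: a dye against a sample, with one curve per channel."""

    dye_id: str
    sample_id: str
    sample_type: str
    curves: dict[str, MeltCurve] = field(default_factory=dict)
    protein_variant: str | None = None
    inducer_id: int | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"well ({self.dye_id}, {self.sample_id}): sample_type "
                f"{self.sample_type!r} not one of {SAMPLE_TYPES}"
            )
        if self.sample_type == "fibril" and self.inducer_id is None:
            raise ValidationError(
                f"fibril well ({self.dye_id}, {self.sample_id}) requires inducer_id"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.dye_id, self.sample_id, self.sample_type)


@dataclass
class ScreenRun:
    """One replicate screen: a collection of wells under a run identifier."""

    run_id: str
    replicate_index: int
    wells: list[Well] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")
        seen: set[tuple[str, str, str]] = set()
        for w in self.wells:
            if w.key in seen:
                raise ValidationError(f"duplicate well key {w.key} in run {self.run_id}")
            seen.add(w.key)

    def well(self, dye_id: str, sample_id: str, sample_type: str) -> Well:
        for w in self.wells:
            if w.key == (dye_id, sample_id, sample_type):
                return w
        raise KeyError((dye_id, sample_id, sample_type))

    def wells_of_type(self, sample_type: str) -> list[Well]:
        return [w for w in self.wells if w.sample_type == sample_type]


@dataclass
class KineticRead:
    """Fluorescence-vs-time series for one dye/condition/channel."""

    times_h: np.ndarray
    rfu: np.ndarray
    channel: ChannelSpec
    dye_id: str
    condition_id: str

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.times_h.shape != self.rfu.shape:
            raise ValidationError("time grid and rfu lengths differ")
        if self.times_h.size >= 2 and not np.all(np.diff(self.times_h) > 0):
            raise ValidationError(
                f"times must be strictly increasing for "
                f"({self.dye_id}, {self.condition_id}, {self.channel.name})"
            )

    def __len__(self) -> int:
        return self.times_h.size


# ---------------------------------------------------------------------------
# Screen CSV
# ---------------------------------------------------------------------------

SCREEN_COLUMNS = (
    "run_id", "replicate", "well", "dye_id", "sample_id", "sample_type",
    "channel", "temperature_c", "rfu",
)
_OPTIONAL_SCREEN_COLUMNS = ("protein_variant", "inducer_id")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_screen_csv(path: str | Path) -> ScreenRun:
    """Read one replicate screen from the canonical long CSV.

    Raises
    ------
    FormatError
        If a required column is absent.
    ValidationError
        If temperatures within a well/channel are not strictly increasing,
        naming the offending well.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SCREEN_COLUMNS, path)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    run_ids = df["run_id"].unique()
    reps = df["replicate"].unique()
    if len(run_ids) != 1 or len(reps) != 1:
        raise FormatError(
            f"{path}: expected a single (run_id, replicate) per file, found "
            f"runs {list(run_ids)} replicates {list(reps)}"
        )
    wells: list[Well] = []
    group_cols = ["dye_id", "sample_id", "sample_type"]
    for (dye, sample, stype), wdf in df.groupby(group_cols, sort=True):
        curves: dict[str, MeltCurve] = {}
        for channel_label, cdf in wdf.groupby("channel", sort=True):
            temps = cdf["temperature_c"].to_numpy(dtype=float)
            if temps.size >= 2 and not np.all(np.diff(temps) > TEMP_TOL_C):
                raise ValidationError(
                    f"{path}: non-monotone temperatures in well "
                    f"({dye}, {sample}, {stype}) channel {channel_label}"
                )
            curves[str(channel_label)] = MeltCurve(
                temps, cdf["rfu"].to_numpy(dtype=float), resolve_channel(str(channel_label))
            )
        variant = None
        inducer = None
        if "protein_variant" in wdf.columns:
            v = wdf["protein_variant"].iloc[0]
            variant = None if pd.isna(v) else str(v)
        if "inducer_id" in wdf.columns:
            v = wdf["inducer_id"].iloc[0]
            inducer = None if pd.isna(v) else int(v)
        wells.append(
            Well(str(dye), str(sample), str(stype), curves,
                 protein_variant=variant, inducer_id=inducer)
        )
    return ScreenRun(str(run_ids[0]), int(reps[0]), wells)


def write_screen_csv(run: ScreenRun, path: str | Path) -> None:
    """Write a run to the canonical long CSV (deterministic row order)."""
    path = Path(path)
    records: list[dict] = []
    for w in sorted(run.wells, key=lambda w: w.key):
        for channel_label in sorted(w.curves):
            curve = w.curves[channel_label]
            for t, y in zip(curve.temperatures_c, curve.rfu):
                records.append({
                    "run_id": run.run_id,
                    "replicate": run.replicate_index,
                    "well": f"{w.dye_id}:{w.sample_id}",
                    "dye_id": w.dye_id,
                    "sample_id": w.sample_id,
                    "sample_type": w.sample_type,
                    "channel": channel_label,
                    "temperature_c": t,
                    "rfu": y,
                    "protein_variant": w.protein_variant,
                    "inducer_id": w.inducer_id,
                })
    frame = pd.DataFrame.from_records(
        records, columns=list(SCREEN_COLUMNS) + list(_OPTIONAL_SCREEN_COLUMNS)
    )
    frame.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Kinetics CSV
# ---------------------------------------------------------------------------

KINETIC_COLUMNS = ("dye_id", "condition_id", "channel", "time_h", "rfu")


def read_kinetics_csv(path: str | Path) -> list[KineticRead]:
    """Read kinetic aggregation reads, one per (dye, condition, channel).

    Times are sorted ascending within each read.  Duplicate
    (dye, condition, channel, time) rows raise a :class:`ValidationError`
    listing the duplicates.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, KINETIC_COLUMNS, path)
    if df.empty:
        return []
    dup_mask = df.duplicated(subset=["dye_id", "condition_id", "channel", "time_h"], keep=False)
    if dup_mask.any():
        dups = (
            df.loc[dup_mask, ["dye_id", "condition_id", "channel", "time_h"]]
            .drop_duplicates()
            .to_records(index=False)
        )
        raise ValidationError(f"{path}: duplicate timepoint rows: {list(dups)}")
    reads: list[KineticRead] = []
    for (dye, cond, channel_label), g in df.groupby(
        ["dye_id", "condition_id", "channel"], sort=True
    ):
        g = g.sort_values("time_h")
        reads.append(
            KineticRead(
                g["time_h"].to_numpy(dtype=float),
                g["rfu"].to_numpy(dtype=float),
                resolve_channel(str(channel_label)),
                str(dye),
                str(cond),
            )
        )
    return reads


def write_kinetics_csv(reads: Iterable[KineticRead], path: str | Path) -> None:
    records = []
    for r in sorted(reads, key=lambda r: (r.dye_id, r.condition_id, r.channel.name)):
        for t, y in zip(r.times_h, r.rfu):
            records.append({
                "dye_id": r.dye_id,
                "condition_id": r.condition_id,
                "channel": r.channel.name,
                "time_h": t,
                "rfu": y,
            })
    pd.DataFrame.from_records(records, columns=list(KINETIC_COLUMNS)).to_csv(
        Path(path), index=False, lineterminator="\n"
    )


def validate_screen_csv(path: str | Path) -> ScreenRun:
    """Parse and validate a screen CSV, additionally checking the default ramp.

    Curves on a grid other than the default 71-point 25-95 degC ramp are
    allowed but logged, since custom protocols are legitimate.
    """
    run = read_screen_csv(path)
    ramp = default_ramp()
    for w in run.wells:
        for label, curve in w.curves.items():
            if len(curve) != ramp.size or not np.allclose(
                curve.temperatures_c, ramp, atol=TEMP_TOL_C
            ):
                logger.info(
                    "well %s channel %s uses a non-default ramp (%d points)",
                    w.key, label, len(curve),
                )
    return run
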