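"""Isotope measurement data model, table IO, replicate QC and diet offsets.

Compound-specific isotope analysis of amino acids (CSIA-AA) reports one
carbon isotope ratio per amino acid per analytical replicate, expressed as
``delta13C`` in per-mil (permil) deviation from the VPDB reference scale.
This module defines the measurement schema, readers/writers for delimited
text tables, replicate aggregation with quality control, and the
diet-normalized offset (consumer minus diet) on which the microbial
provisioning screen is based.

The canonical on-disk layout is long format: one row per
``(sample, analyte, replicate)``.  A wide layout (one column per analyte)
is supported for convenience by :func:`read_measurements_wide` /
:func:`write_measurements_wide`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Essential amino acids measured in the study design, in canonical order.
EAA_CODES: tuple[str, ...] = ("Ile", "Leu", "Lys", "Phe", "Thr", "Val")

#: Optional non-essential amino acid codes accepted by the schema.
NEAA_CODES: tuple[str, ...] = (
    "Ala", "Asp", "Asx", "Glu", "Glx", "Gly", "Pro", "Ser", "Tyr",
)

ANALYTE_CODES: tuple[str, ...] = EAA_CODES + NEAA_CODES

GROUPS: tuple[str, ...] = ("GF", "CVZ", "DIET", "ENDMEMBER")
ORGANS: tuple[str, ...] = ("liver", "kidney", "muscle", "brain", "none")

#: Physically plausible range for delta13C of amino acids (permil vs VPDB).
DELTA13C_MIN = -80.0
DELTA13C_MAX = 20.0

#: Default analytical quality-control bound on replicate SD (permil).
DEFAULT_QC_BOUND = 0.4

#: Default screening threshold on diet-normalized offsets (permil).
DEFAULT_SCREEN_THRESHOLD = 1.0

MEASUREMENT_COLUMNS = ("sample_id", "group", "organ", "analyte", "delta13C", "replicate")


class SchemaError(ValueError):
    """A table is missing required columns or uses an unknown layout."""


class ValidationError(ValueError):
    """A row violates the measurement data model."""


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One analytical replicate of one amino acid in one specimen.

    Attributes
    ----------
    sample_id : str
        Specimen identifier (mouse x organ, a diet batch, or an endmember).
    group : str
        Treatment arm or material class: one of ``GF``, ``CVZ``, ``DIET``,
        ``ENDMEMBER``.
    organ : str
        ``liver``, ``kidney``, ``muscle``, ``brain`` or ``none`` for
        non-tissue materials.
    analyte : str
        Amino-acid code from the controlled vocabulary (``Ile``, ``Leu``,
        ``Lys``, ``Phe``, ``Thr``, ``Val`` plus optional non-essentials).
    delta13C : float
        Carbon isotope ratio, permil vs VPDB.
    replicate : int
        1-based analytical replicate index.
    """

    sample_id: str
    group: str
    organ: str
    analyte: str
    delta13C: float
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.organ not in ORGANS:
            raise ValidationError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if self.analyte not in ANALYTE_CODES:
            raise ValidationError(
                f"unknown analyte {self.analyte!r}; expected one of {ANALYTE_CODES}"
            )
        if not np.isfinite(self.delta13C):
            raise ValidationError(f"delta13C must be finite, got {self.delta13C!r}")
        if not (DELTA13C_MIN <= self.delta13C <= DELTA13C_MAX):
            raise ValidationError(
                f"delta13C {self.delta13C} permil outside plausible range "
                f"[{DELTA13C_MIN}, {DELTA13C_MAX}]"
            )
        if int(self.replicate) < 1:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate}")


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Map header names case-insensitively onto the canonical schema."""
    mapping = {}
    lowered = {c.lower().strip(): c for c in df.columns}
    for canonical in MEASUREMENT_COLUMNS:
        key = canonical.lower()
        if key in lowered:
            mapping[lowered[key]] = canonical
    return df.rename(columns=mapping)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format measurement table against the data model.

    Returns a copy with canonical dtypes.  Raises :class:`SchemaError` for
    missing columns and :class:`ValidationError` naming the first offending
    row (0-based within the data section) for value violations.
    """
    df = _normalise_columns(df)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = df.loc[:, list(MEASUREMENT_COLUMNS)].copy()
    if out.empty:
        out["delta13C"] = out["delta13C"].astype(float)
        out["replicate"] = out["replicate"].astype(int)
        return out.reset_index(drop=True)

    for col in ("sample_id", "group", "organ", "analyte"):
        out[col] = out[col].astype(str).str.strip()
    out["delta13C"] = pd.to_numeric(out["delta13C"], errors="coerce")
    out["replicate"] = pd.to_numeric(out["replicate"], errors="coerce")

    def _first_bad(mask: pd.Series, message: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise ValidationError(f"row {row}: {message} ({out.iloc[row].to_dict()})")

    _first_bad(~out["group"].isin(GROUPS), "unknown group")
    _first_bad(~out["organ"].isin(ORGANS), "unknown organ")
    _first_bad(~out["analyte"].isin(ANALYTE_CODES), "unknown analyte")
    _first_bad(~np.isfinite(out["delta13C"]), "delta13C not a finite number")
    _first_bad(
        (out["delta13C"] < DELTA13C_MIN) | (out["delta13C"] > DELTA13C_MAX),
        f"delta13C outside [{DELTA13C_MIN}, {DELTA13C_MAX}] permil",
    )
    _first_bad(
        out["replicate"].isna() | (out["replicate"] < 1) | (out["replicate"] % 1 != 0),
        "replicate must be a positive integer",
    )
    out["replicate"] = out["replicate"].astype(int)

    dup = out.duplicated(subset=["sample_id", "analyte", "replicate"])
    _first_bad(dup, "duplicate (sample_id, analyte, replicate)")
    return out.reset_index(drop=True)


def read_measurements(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a long-format measurement table (CSV or TSV, auto-detected).

    Column names are matched case-insensitively; row order is preserved.
    """
    path = Path(path)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=delimiter)
    return validate_measurements(df)


def write_measurements(df: pd.DataFrame, path: str | Path, delimiter: str = ",",
                       float_format: str | None = None) -> None:
    """Write a validated long-format measurement table.

    With the default ``float_format=None`` the round trip through
    :func:`read_measurements` is exact field-for-field.
    """
    df = validate_measurements(df)
    df.to_csv(path, sep=delimiter, index=False, float_format=float_format)


def read_measurements_wide(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a wide table (one column per analyte) into the long schema."""
    path = Path(path)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=delimiter)
    df = _normalise_columns(df)
    id_cols = [c for c in ("sample_id", "group", "organ", "replicate") if c in df.columns]
    missing = [c for c in ("sample_id", "group", "organ", "replicate") if c not in id_cols]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    value_cols = [c for c in df.columns if c not in id_cols]
    long = df.melt(id_vars=id_cols, value_vars=value_cols,
                   var_name="analyte", value_name="delta13C")
    long = long.dropna(subset=["delta13C"])
    return validate_measurements(long)


def write_measurements_wide(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write measurements as one column per analyte (convenience layout)."""
    df = validate_measurements(df)
    wide = df.pivot_table(index=["sample_id", "group", "organ", "replicate"],
                          columns="analyte", values="delta13C", aggfunc="first")
    wide = wide.reset_index()
    wide.columns.name = None
    wide.to_csv(path, sep=delimiter, index=False)


def measurements_from_records(records: Iterable[IsotopeMeasurement]) -> pd.DataFrame:
    """Build a validated table from :class:`IsotopeMeasurement` records."""
    rows = [
        (m.sample_id, m.group, m.organ, m.analyte, m.delta13C, m.replicate)
        for m in records
    ]
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    return validate_measurements(df)


def aggregate_replicates(measurements: pd.DataFrame,
                         qc_bound: float = DEFAULT_QC_BOUND) -> pd.DataFrame:
    """Collapse analytical replicates into per-sample, per-analyte profiles.

    Returns a tidy profile table with columns ``sample_id, group, organ,
    analyte, delta13C_mean, delta13C_sd, n_replicates, single_replicate,
    qc_flagged``.  The SD is the sample (n-1) standard deviation; a single
    replicate yields SD 0 by convention and is marked ``single_replicate``.
    ``qc_flagged`` is per sample: true iff any analyte SD exceeds
    ``qc_bound`` (permil).
    """
    if qc_bound <= 0:
        raise ValueError(f"qc_bound must be positive, got {qc_bound}")
    measurements = validate_measurements(measurements)
    grouped = measurements.groupby(["sample_id", "group", "organ", "analyte"], sort=True)
    prof = grouped["delta13C"].agg(delta13C_mean="mean", delta13C_sd="std",
                                   n_replicates="count").reset_index()
    prof["single_replicate"] = prof["n_replicates"] == 1
    prof["delta13C_sd"] = prof["delta13C_sd"].fillna(0.0)
    flagged = prof.groupby("sample_id")["delta13C_sd"].transform(lambda s: (s > qc_bound).any())
    prof["qc_flagged"] = flagged.astype(bool)
    return prof


def profiles_to_matrix(profiles: pd.DataFrame,
                       analytes: Sequence[str] = EAA_CODES
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Pivot tidy profiles into a (samples x analytes) mean-value matrix.

    Returns ``(meta, X)`` where ``meta`` has one row per sample
    (``sample_id, group, organ``) aligned with the rows of ``X``.  Samples
    missing any requested analyte raise :class:`ValidationError`.
    """
    wide = profiles.pivot_table(index=["sample_id", "group", "organ"],
                                columns="analyte", values="delta13C_mean",
                                aggfunc="first")
    missing = [a for a in analytes if a not in wide.columns]
    if missing:
        raise ValidationError(f"analyte(s) absent from all profiles: {', '.join(missing)}")
    wide = wide.loc[:, list(analytes)]
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index[0][0]
        raise ValidationError(f"sample {bad!r} is missing one or more requested analytes")
    meta = wide.index.to_frame(index=False)
    return meta, wide.to_numpy(dtype=float)


def diet_means(diet_profiles: pd.DataFrame) -> pd.Series:
    """Per-analyte mean delta13C over the diet's replicate profiles."""
    diet_profiles = diet_profiles[diet_profiles["group"] == "DIET"]
    if diet_profiles.empty:
        raise ValidationError("no DIET profiles supplied")
    return diet_profiles.groupby("analyte")["delta13C_mean"].mean()


def diet_normalize(consumers: pd.DataFrame, diet: pd.DataFrame,
                   diet_reference_id: str | None = None) -> pd.DataFrame:
    """Compute diet-normalized offsets: consumer delta13C minus diet delta13C.

    Parameters
    ----------
    consumers : DataFrame
        Tidy profile table (from :func:`aggregate_replicates`) for consumer
        tissues.
    diet : DataFrame
        Tidy profile table for the reference diet; per-analyte means are
        averaged over the diet's replicate profiles.
    diet_reference_id : str, optional
        Label recorded with the offsets; defaults to the joined diet sample
        ids.

    Returns a tidy offset table ``sample_id, group, organ, analyte,
    offset, diet_reference_id`` covering the analytes shared between
    consumer and diet.  Consumer analytes absent from the diet are dropped
    with a logged warning; zero shared analytes is an error.
    """
    ref = diet_means(diet)
    if diet_reference_id is None:
        diet_reference_id = "+".join(sorted(diet[diet["group"] == "DIET"]["sample_id"].unique()))
    shared = consumers["analyte"].isin(ref.index)
    dropped = sorted(set(consumers.loc[~shared, "analyte"]))
    if dropped:
        logger.warning("analytes absent from diet reference dropped: %s", ", ".join(dropped))
    offsets = consumers.loc[shared, ["sample_id", "group", "organ", "analyte"]].copy()
    if offsets.empty:
        raise ValidationError("consumer and diet profiles share no analytes")
    offsets["offset"] = (
        consumers.loc[shared, "delta13C_mean"].to_numpy()
        - ref.loc[offsets["analyte"]].to_numpy()
    )
    offsets["diet_reference_id"] = diet_reference_id
    return offsets.reset_index(drop=True)


def provisioning_screen(offsets: pd.DataFrame,
                        threshold: float = DEFAULT_SCREEN_THRESHOLD) -> pd.DataFrame:
    """Screen per-analyte mean offsets against the provisioning threshold.

    An analyte ``exceeds`` the screen when its mean offset across the
    supplied profiles is strictly greater than ``threshold`` (permil).
    Offsets beyond about 1 permil in essential amino acids are the
    conventional flag for a non-dietary (e.g. gut microbial) source.
    Callers subset ``offsets`` to one group/organ before screening.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if offsets.empty:
        raise ValidationError("empty offset collection")
    table = (offsets.groupby("analyte", sort=True)["offset"]
             .agg(mean_offset="mean", n="count").reset_index())
    table["exceeds"] = table["mean_offset"] > threshold
    return table
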