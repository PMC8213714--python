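"""CSV/JSON readers and writers, and batch harmonization of heterogeneous
published tolerance data.

Dialects (CSV, header row, UTF-8, "." decimal, column order free):

* static assays — ``temp_C, time_min[, label]``
* ramp assays — ``t0_C, rate_C_per_min, dctmax_C[, label]``
* temperature profiles — ``temp_C`` and ``time_min`` or ``time_s``
* mixed literature records — ``assay_kind, source_label`` plus the static
  or dynamic columns above and optional ``acclimation_C, assumed_z``

Curves are stored as JSON (see :meth:`tdtkit.curves.TDTCurve.to_dict`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import RampObservation, StaticObservation, TDTCurve
from .dose import TemperatureProfile
from .exceptions import ParseError, TDTValidationError
from .fitting import curve_from_single, fit_dynamic, fit_static
from .models import harmonize_to_reference

__all__ = [
    "read_static_csv",
    "write_static_csv",
    "read_ramp_csv",
    "write_ramp_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_curve_json",
    "write_curve_json",
    "MixedToleranceRecord",
    "read_mixed_csv",
    "harmonize_batch",
]


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: missing column(s) {sorted(missing)}; found "
            f"{list(df.columns)}"
        )


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any() or vals.isna().any():
        row = int(np.nonzero(vals.isna().to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric or missing value in column {col!r}, "
            f"row {row + 2} (1-based, incl. header)"
        )
    return vals.to_numpy(dtype=float)


def read_static_csv(path: str | Path) -> list[StaticObservation]:
    df = pd.read_csv(path)
    _require_columns(df, {"temp_C", "time_min"}, path)
    temps = _numeric(df, "temp_C", path)
    times = _numeric(df, "time_min", path)
    labels = df["label"].astype(str) if "label" in df.columns else None
    out = []
    for i in range(len(df)):
        try:
            out.append(
                StaticObservation(
                    temp=temps[i],
                    time=times[i],
                    label=labels.iloc[i] if labels is not None else None,
                )
            )
        except TDTValidationError as e:
            raise ParseError(f"{path}: row {i + 2}: {e}") from e
    return out


def write_static_csv(path: str | Path, obs: list[StaticObservation]) -> None:
    df = pd.DataFrame(
        {
            "temp_C": [o.temp for o in obs],
            "time_min": [o.time for o in obs],
            "label": [o.label for o in obs],
        }
    )
    if df["label"].isna().all():
        df = df.drop(columns="label")
    df.to_csv(path, index=False)


def read_ramp_csv(path: str | Path) -> list[RampObservation]:
    df = pd.read_csv(path)
    _require_columns(df, {"t0_C", "rate_C_per_min", "dctmax_C"}, path)
    t0 = _numeric(df, "t0_C", path)
    rate = _numeric(df, "rate_C_per_min", path)
    dct = _numeric(df, "dctmax_C", path)
    labels = df["label"].astype(str) if "label" in df.columns else None
    out = []
    for i in range(len(df)):
        try:
            out.append(
                RampObservation(
                    t0=t0[i],
                    rate=rate[i],
                    dctmax=dct[i],
                    label=labels.iloc[i] if labels is not None else None,
                )
            )
        except TDTValidationError as e:
            raise ParseError(f"{path}: row {i + 2}: {e}") from e
    return out


def write_ramp_csv(path: str | Path, obs: list[RampObservation]) -> None:
    df = pd.DataFrame(
        {
            "t0_C": [o.t0 for o in obs],
            "rate_C_per_min": [o.rate for o in obs],
            "dctmax_C": [o.dctmax for o in obs],
            "label": [o.label for o in obs],
        }
    )
    if df["label"].isna().all():
        df = df.drop(columns="label")
    df.to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> TemperatureProfile:
    df = pd.read_csv(path)
    if "time_min" not in df.columns and "time_s" not in df.columns:
        raise ParseError(f"{path}: needs a time_min or time_s column")
    _require_columns(df, {"temp_C"}, path)
    tcol = "time_min" if "time_min" in df.columns else "time_s"
    _numeric(df, tcol, path)
    _numeric(df, "temp_C", path)
    try:
        return TemperatureProfile.from_dataframe(df)
    except TDTValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_profile_csv(path: str | Path, profile: TemperatureProfile) -> None:
    profile.to_dataframe().to_csv(path, index=False)


def read_curve_json(path: str | Path) -> TDTCurve:
    return TDTCurve.from_json(path)


def write_curve_json(path: str | Path, curve: TDTCurve) -> None:
    curve.to_json(path)


# -- literature harmonization -------------------------------------------


@dataclass(frozen=True)
class MixedToleranceRecord:
    """One published tolerance measurement of either assay kind.

    Static records carry (temp_C, time_min); dynamic records carry
    (t0_C, rate_C_per_min, dctmax_C).  ``assumed_z`` is required for
    sources contributing a single record, since one point cannot identify
    the TDT slope.
    """

    assay_kind: str  # "static" | "dynamic"
    source_label: str
    temp_C: float | None = None
    time_min: float | None = None
    t0_C: float | None = None
    rate_C_per_min: float | None = None
    dctmax_C: float | None = None
    acclimation_C: float | None = None
    assumed_z: float | None = None

    def __post_init__(self):
        if self.assay_kind == "static":
            if self.temp_C is None or self.time_min is None:
                raise TDTValidationError(
                    f"static record {self.source_label!r} needs temp_C and "
                    "time_min"
                )
            if any(
                v is not None
                for v in (self.t0_C, self.rate_C_per_min, self.dctmax_C)
            ):
                raise TDTValidationError(
                    f"static record {self.source_label!r} must not carry "
                    "dynamic fields"
                )
        elif self.assay_kind == "dynamic":
            if (
                self.t0_C is None
                or self.rate_C_per_min is None
                or self.dctmax_C is None
            ):
                raise TDTValidationError(
                    f"dynamic record {self.source_label!r} needs t0_C, "
                    "rate_C_per_min and dctmax_C"
                )
            if self.temp_C is not None or self.time_min is not None:
                raise TDTValidationError(
                    f"dynamic record {self.source_label!r} must not carry "
                    "static fields"
                )
        else:
            raise TDTValidationError(
                f"assay_kind must be 'static' or 'dynamic', got "
                f"{self.assay_kind!r}"
            )
        if self.assumed_z is not None and not self.assumed_z > 0:
            raise TDTValidationError("assumed_z must be > 0 when given")

    def to_observation(self) -> StaticObservation | RampObservation:
        if self.assay_kind == "static":
            return StaticObservation(
                temp=self.temp_C, time=self.time_min, label=self.source_label
            )
        return RampObservation(
            t0=self.t0_C,
            rate=self.rate_C_per_min,
            dctmax=self.dctmax_C,
            label=self.source_label,
        )


def read_mixed_csv(path: str | Path) -> list[MixedToleranceRecord]:
    df = pd.read_csv(path)
    _require_columns(df, {"assay_kind", "source_label"}, path)

    def get(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    out = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            out.append(
                MixedToleranceRecord(
                    assay_kind=str(row["assay_kind"]).strip(),
                    source_label=str(row["source_label"]).strip(),
                    temp_C=get(row, "temp_C"),
                    time_min=get(row, "time_min"),
                    t0_C=get(row, "t0_C"),
                    rate_C_per_min=get(row, "rate_C_per_min"),
                    dctmax_C=get(row, "dctmax_C"),
                    acclimation_C=get(row, "acclimation_C"),
                    assumed_z=get(row, "assumed_z"),
                )
            )
        except (TDTValidationError, ValueError) as e:
            raise ParseError(f"{path}: row {i + 2}: {e}") from e
    return out


def harmonize_batch(
    records: list[MixedToleranceRecord], duration: float = 60.0
) -> pd.DataFrame:
    """Standardize heterogeneous tolerance records to sCT_max(duration).

    Records are grouped by ``source_label`` and, within a source, by assay
    kind.  Kinds with >= 2 records are fitted properly (static OLS or
    dynamic solve); a lone record requires ``assumed_z`` and yields a
    flagged assumed-z estimate.  A source mixing both kinds reports one row
    per kind, so within-source agreement between assay types can be read
    off directly.

    Returns a DataFrame with columns ``source_label``, ``assay_kind``,
    ``sctmax_C``, ``method``, ``flags``.
    """
    rows = []
    by_source: dict[str, list[MixedToleranceRecord]] = {}
    for r in records:
        by_source.setdefault(r.source_label, []).append(r)

    for label, group in by_source.items():
        for kind in ("static", "dynamic"):
            sub = [r for r in group if r.assay_kind == kind]
            if not sub:
                continue
            if len(sub) >= 2:
                obs = [r.to_observation() for r in sub]
                fit = (
                    fit_static(obs, t_ref=duration)
                    if kind == "static"
                    else fit_dynamic(obs, t_ref=duration)
                )
            else:
                (rec,) = sub
                if rec.assumed_z is None:
                    raise TDTValidationError(
                        f"source {label!r} has a single {kind} record: an "
                        "assumed_z column value is required to build a TDT "
                        "curve from one measurement"
                    )
                fit = curve_from_single(
                    rec.to_observation(), rec.assumed_z, t_ref=duration
                )
            h = harmonize_to_reference(fit, duration)
            rows.append(
                {
                    "source_label": label,
                    "assay_kind": kind,
                    "sctmax_C": h.sctmax,
                    "method": h.method,
                    "flags": ";".join(h.flags),
                }
            )
    return pd.DataFrame(rows, columns=[
        "source_label", "assay_kind", "sctmax_C", "method", "flags",
    ])
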