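"""Force-curve data model, tabular dialect I/O and preprocessing.

A force–distance curve is the raw record of an AFM indentation: the piezo
extension ``z`` (µm, increasing toward the sample during approach) versus
the cantilever deflection signal (photodiode volts, or nanometres if the
deflection sensitivity has already been applied). Curves are stored in a
plain-text tab-separated dialect with a ``#``-prefixed ``key: value``
metadata header, columns ``z_um``, ``deflection`` and ``segment``
(approach/retract). Multiple curves live in one file as blank-line
separated blocks, each with its own header.

Canonical internal units: µm (z), nm or V (deflection), N/m (spring
constant), nm/V (sensitivity), K (temperature).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, ParameterError, ValidationError

APPROACH = "approach"
RETRACT = "retract"

#: header keys recognised by the dialect, mapped to ForceCurve attributes
_HEADER_KEYS = {
    "spring_constant_N_per_m": ("spring_constant", float),
    "deflection_sensitivity_nm_per_V": ("deflection_sensitivity", float),
    "temperature_K": ("temperature", float),
    "approach_speed_um_per_s": ("approach_speed", float),
    "deflection_units": ("deflection_units", str),
    "probe_radius_um": ("_probe_radius", float),
    "probe_spring_constant_N_per_m": ("_probe_k", float),
    "curve_id": ("curve_id", str),
    "cell_id": ("cell_id", str),
    "location_id": ("location_id", str),
}


@dataclass(frozen=True)
class ProbeSpec:
    """Spherical AFM probe: radius (µm) and nominal spring constant (N/m)."""

    radius_um: float
    nominal_spring_constant: float
    geometry: str = "sphere"

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValidationError("probe radius must be > 0")
        if self.nominal_spring_constant <= 0:
            raise ValidationError("nominal spring constant must be > 0")
        if self.geometry != "sphere":
            raise ValidationError(
                f"unsupported probe geometry {self.geometry!r}; only 'sphere'"
            )


@dataclass
class CurveDialect:
    """Description of the plain-text force-curve table layout."""

    delimiter: str = "\t"
    metadata_prefix: str = "#"
    z_column: str = "z_um"
    deflection_column: str = "deflection"
    segment_column: str = "segment"
    z_units: str = "um"          # um | nm | m
    deflection_units: str = "nm"  # nm | V (header may override)

    def __post_init__(self) -> None:
        if not self.z_column or not self.deflection_column:
            raise ValidationError("dialect column_map must cover z and deflection")
        if self.z_units not in ("um", "nm", "m"):
            raise ValidationError(f"unsupported z units {self.z_units!r}")
        if self.deflection_units not in ("nm", "V"):
            raise ValidationError(
                f"unsupported deflection units {self.deflection_units!r}"
            )


_Z_TO_UM = {"um": 1.0, "nm": 1e-3, "m": 1e6}


@dataclass
class ForceCurve:
    """One approach/retract indentation record with calibration metadata.

    ``deflection`` is in the units given by ``deflection_units`` ("V" raw
    photodiode signal, "nm" after the sensitivity has been applied).
    ``baseline`` records the slope/offset subtracted by
    :func:`baseline_correct`, or None if uncorrected.
    """

    piezo_position_um: np.ndarray
    deflection: np.ndarray
    segment: np.ndarray
    deflection_units: str = "nm"
    deflection_sensitivity: float | None = None  # nm/V
    spring_constant: float | None = None         # N/m
    probe: ProbeSpec | None = None
    temperature: float = 310.15                   # K
    approach_speed: float | None = None           # µm/s
    curve_id: str | None = None
    cell_id: str | None = None
    location_id: str | None = None
    baseline: dict | None = None

    def __post_init__(self) -> None:
        self.piezo_position_um = np.asarray(self.piezo_position_um, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        n = self.piezo_position_um.size
        if self.deflection.size != n:
            raise ValidationError(
                f"curve {self.curve_id!r}: z and deflection lengths differ "
                f"({n} vs {self.deflection.size})"
            )
        if self.segment.size != n:
            raise ValidationError(
                f"curve {self.curve_id!r}: segment labels length mismatch"
            )
        if n < 16:
            raise ValidationError(
                f"curve {self.curve_id!r}: need at least 16 samples, got {n}"
            )
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        z_app = self.piezo_position_um[self.approach_mask]
        if z_app.size >= 2:
            dz = np.diff(z_app)
            if not (np.all(dz > 0) or np.all(dz < 0)):
                raise ValidationError(
                    f"curve {self.curve_id!r}: approach z is not strictly monotone"
                )

    @property
    def approach_mask(self) -> np.ndarray:
        return self.segment == APPROACH

    @property
    def n_approach(self) -> int:
        return int(self.approach_mask.sum())

    def deflection_nm(self) -> np.ndarray:
        """Deflection in nm, applying the sensitivity to a V-signal curve."""
        if self.deflection_units == "nm":
            return self.deflection
        if self.deflection_sensitivity is None:
            raise CalibrationUnsetError(
                f"curve {self.curve_id!r}: deflection is in V but no "
                "deflection_sensitivity is set; calibrate on a hard surface "
                "first (cellelast.calibration)"
            )
        return self.deflection * self.deflection_sensitivity


class CalibrationUnsetError(ValidationError):
    """Force conversion requested without the needed calibration metadata."""


def segment_approach(curve: ForceCurve) -> ForceCurve:
    """Return an approach-only view, ordered with z increasing toward the sample.

    Idempotent: applying it to an already approach-only curve returns an
    identical record.
    """
    mask = curve.approach_mask
    if not mask.any():
        raise ValidationError(f"curve {curve.curve_id!r}: no approach samples")
    if mask.sum() < 16:
        raise ValidationError(
            f"curve {curve.curve_id!r}: fewer than 16 approach samples"
        )
    z = curve.piezo_position_um[mask]
    d = curve.deflection[mask]
    if z.size >= 2 and z[1] < z[0]:  # recorded tip-first; flip to increasing z
        z, d = z[::-1], d[::-1]
    return replace(
        curve,
        piezo_position_um=z,
        deflection=d,
        segment=np.array([APPROACH] * z.size, dtype=object),
    )


def baseline_correct(curve: ForceCurve, baseline_fraction: float = 0.3) -> ForceCurve:
    """Subtract a straight-line baseline fit from the deflection channel.

    The line is fit to the first ``baseline_fraction`` of approach samples
    (those farthest from the sample, i.e. smallest z) and subtracted from
    the whole deflection array as a function of z, so approach and retract
    stay consistent. The subtracted slope/offset is recorded on
    ``curve.baseline``. Idempotent to numerical precision.
    """
    if not (0 < baseline_fraction <= 0.5):
        raise ParameterError(
            f"baseline_fraction must be in (0, 0.5], got {baseline_fraction}"
        )
    app = segment_approach(curve)
    n_base = max(2, int(round(baseline_fraction * app.n_approach)))
    zb = app.piezo_position_um[:n_base]
    db = app.deflection[:n_base]
    slope, offset = np.polyfit(zb, db, 1)
    corrected = curve.deflection - (slope * curve.piezo_position_um + offset)
    prior = curve.baseline or {"slope": 0.0, "offset": 0.0}
    return replace(
        curve,
        deflection=corrected,
        baseline={
            "slope": prior["slope"] + float(slope),
            "offset": prior["offset"] + float(offset),
            "n_baseline": n_base,
        },
    )


# ---------------------------------------------------------------------------
# dialect I/O

def _parse_block(
    header: dict[str, str],
    rows: list[Sequence[str]],
    columns: list[str],
    dialect: CurveDialect,
    block_index: int,
) -> ForceCurve:
    for col in (dialect.z_column, dialect.deflection_column):
        if col not in columns:
            raise FormatError(f"missing mandatory column {col!r}")
    if not rows:
        raise FormatError(f"curve block {block_index}: empty data section")
    iz = columns.index(dialect.z_column)
    idefl = columns.index(dialect.deflection_column)
    iseg = columns.index(dialect.segment_column) if dialect.segment_column in columns else None
    try:
        z = np.array([float(r[iz]) for r in rows])
        d = np.array([float(r[idefl]) for r in rows])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"curve block {block_index}: bad data row ({exc})") from exc
    if iseg is None:
        seg = np.array([APPROACH] * len(rows), dtype=object)
    else:
        seg = np.array([r[iseg] for r in rows], dtype=object)

    meta: dict = {"deflection_units": dialect.deflection_units}
    probe_kwargs: dict = {}
    for key, raw in header.items():
        if key not in _HEADER_KEYS:
            continue
        attr, cast = _HEADER_KEYS[key]
        value = cast(raw)
        if attr == "_probe_radius":
            probe_kwargs["radius_um"] = value
        elif attr == "_probe_k":
            probe_kwargs["nominal_spring_constant"] = value
        else:
            meta[attr] = value
    probe = ProbeSpec(**probe_kwargs) if len(probe_kwargs) == 2 else None
    meta.setdefault("curve_id", f"curve{block_index}")
    return ForceCurve(
        piezo_position_um=z * _Z_TO_UM[dialect.z_units],
        deflection=d,
        segment=seg,
        probe=probe,
        **meta,
    )


def read_force_curves(
    path: str | Path, dialect: CurveDialect | None = None
) -> list[ForceCurve]:
    """Read every curve block from a dialect file.

    Metadata fields present in a block header populate the ForceCurve;
    absent calibration fields are left unset. z is converted to µm.
    """
    dialect = dialect or CurveDialect()
    text = Path(path).read_text()
    curves: list[ForceCurve] = []
    header: dict[str, str] = {}
    columns: list[str] | None = None
    rows: list[Sequence[str]] = []
    block_index = 0

    def flush() -> None:
        nonlocal header, columns, rows, block_index
        if columns is None and not rows and not header:
            return
        if columns is None:
            raise FormatError(f"curve block {block_index}: no column header line")
        curves.append(_parse_block(header, rows, columns, dialect, block_index))
        header, columns, rows = {}, None, []
        block_index += 1

    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            if columns is not None or header:
                flush()
            continue
        if stripped.startswith(dialect.metadata_prefix):
            body = stripped[len(dialect.metadata_prefix):].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
            continue
        fields = stripped.split(dialect.delimiter)
        if columns is None:
            columns = [f.strip() for f in fields]
        else:
            rows.append(fields)
    flush()
    if not curves:
        raise FormatError(f"{path}: no curve blocks found")
    return curves


def write_force_curves(
    path: str | Path, curves: Iterable[ForceCurve], dialect: CurveDialect | None = None
) -> None:
    """Write curves in the dialect; floats at full repr precision (round-trips)."""
    dialect = dialect or CurveDialect()
    buf = _io.StringIO()
    for curve in curves:
        if curve.curve_id is not None:
            buf.write(f"{dialect.metadata_prefix} curve_id: {curve.curve_id}\n")
        for key, (attr, _) in _HEADER_KEYS.items():
            if attr in ("_probe_radius", "_probe_k", "curve_id"):
                continue
            value = getattr(curve, attr, None)
            if value is not None:
                buf.write(f"{dialect.metadata_prefix} {key}: {value}\n")
        if curve.probe is not None:
            buf.write(
                f"{dialect.metadata_prefix} probe_radius_um: {curve.probe.radius_um!r}\n"
                f"{dialect.metadata_prefix} probe_spring_constant_N_per_m: "
                f"{curve.probe.nominal_spring_constant!r}\n"
            )
        buf.write(
            dialect.delimiter.join(
                (dialect.z_column, dialect.deflection_column, dialect.segment_column)
            )
            + "\n"
        )
        z = curve.piezo_position_um / _Z_TO_UM[dialect.z_units]
        for zi, di, si in zip(z, curve.deflection, curve.segment):
            buf.write(
                f"{float(zi)!r}{dialect.delimiter}{float(di)!r}"
                f"{dialect.delimiter}{si}\n"
            )
        buf.write("\n")
    Path(path).write_text(buf.getvalue())
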