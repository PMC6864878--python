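"""Feature-value case representation for pest-management decision support.

A case describes one pest incident on a crop as attribute-value pairs:
pest identifiers (pest type, crop name), pest state (quantity, life-cycle
stage, infected area), crop state (growth stage, planting density) and
environment (temperature interval, humidity, rainfall probability,
sunlight, wind speed), optionally with the treatment that solved it.

Before similarity computation each case is standardized into an
11-component numeric vector: numeric attributes are min-max scaled onto
[0, 1] over schema-declared ranges (a z-score scheme fitted on a case base
is available as an alternative), ordinal stages are mapped to their
1-based life-cycle index and scaled the same way, the temperature interval
contributes its minimum and maximum as two components, and identifiers are
excluded.  All attributes are equally weighted.

Case bases round-trip through a canonical JSON document and a flat CSV
dialect.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PEST_STAGES",
    "GROWTH_STAGES",
    "STANDARDIZED_COMPONENTS",
    "AttributeSchema",
    "CaseSchema",
    "CaseRecord",
    "StandardizedCase",
    "CaseBase",
    "CaseValidationError",
    "default_schema",
    "validate_case",
    "Standardizer",
    "standardize_case",
    "load_case_base",
    "save_case_base",
    "import_deposited_case_base",
    "CSV_FIELDS",
]

#: Pest life-cycle stages, in order.
PEST_STAGES = ("Egg", "Larvae", "Pupae", "Adult")
#: Crop growth stages (vegetative, reproductive, ripening), in order.
GROWTH_STAGES = ("Vege", "Repro", "Ripen")

#: Vector layout produced by the standardizer, in order.
STANDARDIZED_COMPONENTS = (
    "pest_quantity",
    "pest_stage",
    "infected_area",
    "growth_stage",
    "planting_density",
    "temp_min",
    "temp_max",
    "humidity",
    "rainfall",
    "sunlight",
    "wind_speed",
)

CSV_FIELDS = (
    "case_id",
    "pest_type",
    "pest_quantity",
    "pest_stage",
    "infected_area",
    "crop_name",
    "growth_stage",
    "planting_density",
    "temp_min",
    "temp_max",
    "humidity",
    "rainfall",
    "sunlight",
    "wind_speed",
    "solution",
)


class CaseValidationError(ValueError):
    """One or more case fields violate the schema; ``errors`` lists them."""

    def __init__(self, case_id, errors: list[str]):
        self.case_id = case_id
        self.errors = errors
        super().__init__(f"case {case_id}: " + "; ".join(errors))


@dataclass(frozen=True)
class AttributeSchema:
    """Declaration of one case attribute.

    ``kind`` is one of ``numeric`` (scalar, min-max range), ``ordinal``
    (ordered token levels), ``interval`` (a [min, max] pair that expands to
    two vector components) or ``identifier`` (used for filtering, never
    standardized).
    """

    name: str
    kind: str
    unit: str = ""
    standardization_range: tuple[float, float] | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("numeric", "interval", "ordinal", "identifier"):
            raise ValueError(f"{self.name}: unknown attribute kind {self.kind!r}")
        if self.kind in ("numeric", "interval"):
            if self.standardization_range is None:
                raise ValueError(f"{self.name}: {self.kind} attribute needs a range")
            lo, hi = self.standardization_range
            if not lo < hi:
                raise ValueError(
                    f"{self.name}: require low < high, got [{lo}, {hi}]"
                )
        if self.kind == "ordinal":
            if not self.levels or len(set(self.levels)) != len(self.levels):
                raise ValueError(f"{self.name}: ordinal levels must be non-empty and unique")


@dataclass(frozen=True)
class CaseSchema:
    """The full attribute schema of a case base."""

    attributes: tuple[AttributeSchema, ...]

    def __getitem__(self, name: str) -> AttributeSchema:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def dimension(self) -> int:
        """Length of the standardized vector (intervals count twice)."""
        n = 0
        for a in self.attributes:
            if a.kind == "interval":
                n += 2
            elif a.kind != "identifier":
                n += 1
        return n


def default_schema() -> CaseSchema:
    """Schema for the rice pest-management case study.

    Numeric standardization ranges cover the spans observed in the study's
    test cases (planting density from the agronomic 180-525 seeds/m²
    interval; wind speed over the full Beaufort 0-12 scale).
    """
    return CaseSchema(
        attributes=(
            AttributeSchema("pest_type", "identifier"),
            AttributeSchema("crop_name", "identifier"),
            AttributeSchema("pest_quantity", "numeric", "pests", (309.0, 458.0)),
            AttributeSchema("pest_stage", "ordinal", levels=PEST_STAGES),
            AttributeSchema("infected_area", "numeric", "m^2", (56.0, 168.0)),
            AttributeSchema("growth_stage", "ordinal", levels=GROWTH_STAGES),
            AttributeSchema("planting_density", "numeric", "seeds/m^2", (180.0, 525.0)),
            AttributeSchema("temperature", "interval", "Celsius", (15.0, 32.0)),
            AttributeSchema("humidity", "numeric", "fraction", (0.2573, 0.8706)),
            AttributeSchema("rainfall", "numeric", "fraction", (0.1250, 0.8290)),
            AttributeSchema("sunlight", "numeric", "lux", (831.0, 4830.0)),
            AttributeSchema("wind_speed", "numeric", "degree", (0.0, 12.0)),
        )
    )


#: Standardization ranges for the two temperature components; tighter than
#: the interval attribute's overall span so each endpoint maps to 0/1.
TEMP_MIN_RANGE = (15.0, 22.0)
TEMP_MAX_RANGE = (24.0, 32.0)


def _parse_fraction(value) -> float:
    """Accept 0.5749 or the string form '57.49%'; return a fraction."""
    if isinstance(value, str) and value.strip().endswith("%"):
        return float(value.strip().rstrip("%")) / 100.0
    return float(value)


@dataclass(frozen=True)
class CaseRecord:
    """One feature-value pest-management case."""

    case_id: int
    pest_type: str
    crop_name: str
    pest_quantity: float
    pest_stage: str
    infected_area: float
    growth_stage: str
    planting_density: float
    temperature: tuple[float, float]
    humidity: float
    rainfall: float
    sunlight: float
    wind_speed: float
    solution: str | None = None

    def to_dict(self) -> dict:
        d = {
            "case_id": self.case_id,
            "pest_type": self.pest_type,
            "crop_name": self.crop_name,
            "pest_quantity": self.pest_quantity,
            "pest_stage": self.pest_stage,
            "infected_area": self.infected_area,
            "growth_stage": self.growth_stage,
            "planting_density": self.planting_density,
            "temperature": list(self.temperature),
            "humidity": self.humidity,
            "rainfall": self.rainfall,
            "sunlight": self.sunlight,
            "wind_speed": self.wind_speed,
        }
        if self.solution is not None:
            d["solution"] = self.solution
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CaseRecord":
        temp = d["temperature"]
        return cls(
            case_id=int(d["case_id"]),
            pest_type=str(d["pest_type"]),
            crop_name=str(d["crop_name"]),
            pest_quantity=float(d["pest_quantity"]),
            pest_stage=str(d["pest_stage"]),
            infected_area=float(d["infected_area"]),
            growth_stage=str(d["growth_stage"]),
            planting_density=float(d["planting_density"]),
            temperature=(float(temp[0]), float(temp[1])),
            humidity=_parse_fraction(d["humidity"]),
            rainfall=_parse_fraction(d["rainfall"]),
            sunlight=float(d["sunlight"]),
            wind_speed=float(d["wind_speed"]),
            solution=d.get("solution"),
        )


@dataclass(frozen=True)
class StandardizedCase:
    """A case reduced to its identifiers and standardized numeric vector."""

    case_id: int
    pest_type: str
    crop_name: str
    vector: np.ndarray

    def __eq__(self, other):
        if not isinstance(other, StandardizedCase):
            return NotImplemented
        return (
            self.case_id == other.case_id
            and self.pest_type == other.pest_type
            and self.crop_name == other.crop_name
            and np.array_equal(self.vector, other.vector)
        )


def validate_case(record: CaseRecord, schema: CaseSchema | None = None) -> CaseRecord:
    """Check every invariant of a case; return it unchanged if valid.

    Raises :class:`CaseValidationError` listing every violated field.
    """
    schema = schema or default_schema()
    errors: list[str] = []
    if record.pest_stage not in schema["pest_stage"].levels:
        errors.append(
            f"pest_stage {record.pest_stage!r} not in {schema['pest_stage'].levels}"
        )
    if record.growth_stage not in schema["growth_stage"].levels:
        errors.append(
            f"growth_stage {record.growth_stage!r} not in {schema['growth_stage'].levels}"
        )
    tmin, tmax = record.temperature
    if not tmin <= tmax:
        errors.append(f"temperature min {tmin} > max {tmax}")
    for name, value, lo, hi in (
        ("humidity", record.humidity, 0.0, 1.0),
        ("rainfall", record.rainfall, 0.0, 1.0),
    ):
        if not lo <= value <= hi:
            errors.append(f"{name} {value} outside [{lo}, {hi}]")
    for name, value in (
        ("pest_quantity", record.pest_quantity),
        ("infected_area", record.infected_area),
        ("planting_density", record.planting_density),
        ("sunlight", record.sunlight),
        ("wind_speed", record.wind_speed),
    ):
        if value < 0:
            errors.append(f"{name} {value} must be >= 0")
    if errors:
        raise CaseValidationError(record.case_id, errors)
    return record


class Standardizer:
    """Maps validated cases onto fixed-length numeric vectors.

    ``scheme="minmax"`` (default) scales each component onto [0, 1] over
    its schema-declared range, clipping (with a log message) values that
    fall outside it.  ``scheme="zscore"`` centres and scales each component
    by the mean and standard deviation of a reference case base; call
    :meth:`fit` first.
    """

    def __init__(self, schema: CaseSchema | None = None, scheme: str = "minmax"):
        if scheme not in ("minmax", "zscore"):
            raise ValueError(f"unknown scheme {scheme!r}")
        self.schema = schema or default_schema()
        self.scheme = scheme
        self._mean: np.ndarray | None = None
        self._std: np.ndarray | None = None

    # -- raw encoding -----------------------------------------------------
    def _encode(self, record: CaseRecord) -> np.ndarray:
        """Raw numeric encoding, ordinals as 1-based level indices."""
        s = self.schema
        pest_levels = s["pest_stage"].levels
        growth_levels = s["growth_stage"].levels
        return np.array(
            [
                record.pest_quantity,
                pest_levels.index(record.pest_stage) + 1,
                record.infected_area,
                growth_levels.index(record.growth_stage) + 1,
                record.planting_density,
                record.temperature[0],
                record.temperature[1],
                record.humidity,
                record.rainfall,
                record.sunlight,
                record.wind_speed,
            ],
            dtype=float,
        )

    def _component_ranges(self) -> list[tuple[str, float, float]]:
        s = self.schema
        return [
            ("pest_quantity", *s["pest_quantity"].standardization_range),
            ("pest_stage", 1.0, float(len(s["pest_stage"].levels))),
            ("infected_area", *s["infected_area"].standardization_range),
            ("growth_stage", 1.0, float(len(s["growth_stage"].levels))),
            ("planting_density", *s["planting_density"].standardization_range),
            ("temp_min", *TEMP_MIN_RANGE),
            ("temp_max", *TEMP_MAX_RANGE),
            ("humidity", *s["humidity"].standardization_range),
            ("rainfall", *s["rainfall"].standardization_range),
            ("sunlight", *s["sunlight"].standardization_range),
            ("wind_speed", *s["wind_speed"].standardization_range),
        ]

    def fit(self, cases: Iterable[CaseRecord]) -> "Standardizer":
        """Fit z-score statistics on a reference collection (no-op for minmax)."""
        raw = np.array([self._encode(c) for c in cases], dtype=float)
        if raw.size == 0:
            raise ValueError("cannot fit a standardizer on an empty case base")
        self._mean = raw.mean(axis=0)
        std = raw.std(axis=0, ddof=0)
        std[std == 0.0] = 1.0  # constant columns map to 0
        self._std = std
        return self

    def transform(self, record: CaseRecord) -> StandardizedCase:
        raw = self._encode(validate_case(record, self.schema))
        if self.scheme == "minmax":
            vec = np.empty_like(raw)
            for i, (name, lo, hi) in enumerate(self._component_ranges()):
                x = raw[i]
                if x < lo or x > hi:
                    logger.warning(
                        "case %s: %s=%.4g outside standardization range [%g, %g]; clipped",
                        record.case_id, name, x, lo, hi,
                    )
                    x = min(max(x, lo), hi)
                vec[i] = (x - lo) / (hi - lo)
        else:
            if self._mean is None:
                raise RuntimeError("zscore standardizer must be fitted first")
            vec = (raw - self._mean) / self._std
        if not np.any(vec):
            logger.warning(
                "case %s standardizes to the zero vector; angle-dependent "
                "measures will reject it", record.case_id,
            )
        return StandardizedCase(
            case_id=record.case_id,
            pest_type=record.pest_type,
            crop_name=record.crop_name,
            vector=vec,
        )

    def transform_all(self, cases: Iterable[CaseRecord]) -> list[StandardizedCase]:
        return [self.transform(c) for c in cases]


def standardize_case(
    record: CaseRecord,
    schema: CaseSchema | None = None,
    scheme: str = "minmax",
) -> StandardizedCase:
    """Standardize a single case (min-max scheme unless stated otherwise)."""
    return Standardizer(schema, scheme).transform(record)


@dataclass
class CaseBase:
    """A collection of validated cases with unique ids, order-preserving."""

    cases: list[CaseRecord] = field(default_factory=list)
    schema: CaseSchema = field(default_factory=default_schema)

    def __post_init__(self):
        from collections import Counter

        counts = Counter(c.case_id for c in self.cases)
        dupes = sorted(i for i, k in counts.items() if k > 1)
        if dupes:
            raise ValueError(f"duplicate case ids: {dupes}")
        for c in self.cases:
            validate_case(c, self.schema)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.cases)

    def __getitem__(self, case_id: int) -> CaseRecord:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def retain(self, record: CaseRecord) -> CaseRecord:
        """Append a solved case under a fresh id (the retention step).

        The record is stored with the next free id; no forgetting policy.
        """
        next_id = max((c.case_id for c in self.cases), default=0) + 1
        stored = replace(record, case_id=next_id)
        validate_case(stored, self.schema)
        self.cases.append(stored)
        return stored


# -- I/O ------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def load_case_base(source: str | Path, format: str | None = None) -> CaseBase:
    """Read a case base from canonical JSON or the flat CSV dialect."""
    path = Path(source)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = json.loads(path.read_text())
        records = [CaseRecord.from_dict(d) for d in doc["cases"]]
    elif fmt == "csv":
        records = []
        with path.open(newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                try:
                    records.append(_record_from_csv_row(row, i))
                except (KeyError, ValueError) as exc:
                    raise ValueError(f"{path.name} row {i + 2}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return CaseBase(cases=records)


def _record_from_csv_row(row: dict, index: int) -> CaseRecord:
    case_id = int(row["case_id"]) if row.get("case_id") not in (None, "") else index + 1
    solution = row.get("solution") or None
    return CaseRecord(
        case_id=case_id,
        pest_type=row["pest_type"],
        crop_name=row["crop_name"],
        pest_quantity=float(row["pest_quantity"]),
        pest_stage=row["pest_stage"],
        infected_area=float(row["infected_area"]),
        growth_stage=row["growth_stage"],
        planting_density=float(row["planting_density"]),
        temperature=(float(row["temp_min"]), float(row["temp_max"])),
        humidity=_parse_fraction(row["humidity"]),
        rainfall=_parse_fraction(row["rainfall"]),
        sunlight=float(row["sunlight"]),
        wind_speed=float(row["wind_speed"]),
        solution=solution,
    )


def save_case_base(base: CaseBase, target: str | Path, format: str | None = None) -> None:
    """Write a case base; ``load_case_base`` inverts it field-for-field."""
    path = Path(target)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {"format": "tricase-case-base", "version": 1,
               "cases": [c.to_dict() for c in base.cases]}
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
            writer.writeheader()
            for c in base.cases:
                d = c.to_dict()
                tmin, tmax = d.pop("temperature")
                d["temp_min"], d["temp_max"] = tmin, tmax
                d.setdefault("solution", "")
                writer.writerow(d)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_deposited_case_base(source: str | Path) -> CaseBase:
    """Best-effort import of an externally deposited case-base file.

    The upstream deposit's format is undocumented; this adapter accepts
    canonical JSON, the flat CSV dialect, or a delimited text table whose
    columns follow the case attribute order (with or without a header).
    Unmappable rows are reported with their line numbers.
    """
    path = Path(source)
    text = path.read_text()
    try:
        json.loads(text)
    except json.JSONDecodeError:
        pass
    else:
        return load_case_base(path, "json")

    first = text.lstrip().splitlines()[0] if text.strip() else ""
    delim = "\t" if "\t" in first else ","
    rows = [r for r in csv.reader(text.splitlines(), delimiter=delim) if r]
    if not rows:
        return CaseBase(cases=[])
    header = [h.strip().lower().replace(" ", "_") for h in rows[0]]
    has_header = "pest_type" in header
    records: list[CaseRecord] = []
    if has_header:
        reader = csv.DictReader(text.splitlines(), delimiter=delim)
        for i, row in enumerate(reader):
            records.append(_record_from_csv_row({k.strip().lower().replace(" ", "_"): v
                                                 for k, v in row.items()}, i))
    else:
        for i, row in enumerate(rows):
            vals = [v.strip() for v in row]
            if len(vals) < 14:
                raise ValueError(
                    f"{path.name} line {i + 1}: expected >= 14 columns, got {len(vals)}"
                )
            keys = CSV_FIELDS[: len(vals)]
            records.append(_record_from_csv_row(dict(zip(keys, vals)), i))
    logger.info("imported %d cases from deposited file %s", len(records), path)
    return CaseBase(cases=records)
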