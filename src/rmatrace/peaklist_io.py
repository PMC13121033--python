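"""Reading and writing feature tables, sample metadata, rule files and results.

All formats are delimited text (comma or tab, auto-detected) in UTF-8.
The canonical in-memory feature is a neutral-mass :class:`Peak`; readers can
convert singly charged m/z columns on the way in so everything downstream
works on neutral monoisotopic masses.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .chem import PROTON_MASS


class SchemaError(ValueError):
    """A required column is missing or the schema map is inconsistent."""


class ParseError(ValueError):
    """A cell could not be parsed; the message cites the offending row."""


class ValidationError(ValueError):
    """A table violates a domain invariant (duplicate ids, bad role, ...)."""


class ConfigError(ValueError):
    """The run configuration is unusable (e.g. no labeled samples)."""


class Polarity(str, enum.Enum):
    positive = "positive"
    negative = "negative"


class Role(str, enum.Enum):
    labeled_mix = "labeled_mix"
    unlabeled_control = "unlabeled_control"
    blank = "blank"


@dataclass
class Peak:
    """One aligned LC-MS feature.

    ``areas`` maps sample id -> integrated ion count; a sample absent from
    the map means the feature was not detected in that sample.
    """

    peak_id: str
    polarity: Polarity
    neutral_mass: float
    rt: float
    areas: dict[str, float] = field(default_factory=dict)
    annotations: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.polarity = Polarity(self.polarity)
        if self.neutral_mass <= 0:
            raise ValidationError(f"peak {self.peak_id}: neutral_mass must be > 0")
        if self.rt < 0:
            raise ValidationError(f"peak {self.peak_id}: rt must be >= 0")
        for sample, area in self.areas.items():
            if area < 0:
                raise ValidationError(
                    f"peak {self.peak_id}: negative area for sample {sample}"
                )

    def area(self, sample_id: str) -> float:
        """Ion count in ``sample_id`` (0.0 if not detected)."""
        return self.areas.get(sample_id, 0.0)

    def max_area(self, sample_ids: Iterable[str]) -> float:
        return max((self.areas.get(s, 0.0) for s in sample_ids), default=0.0)

    def total_area(self) -> float:
        return sum(self.areas.values())


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    role: Role
    group: str = ""


@dataclass
class SampleTable:
    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise ValidationError(f"duplicate sample_id(s): {', '.join(dup)}")

    def ids_with_role(self, role: Role) -> list[str]:
        return [e.sample_id for e in self.entries if e.role == role]

    @property
    def labeled_ids(self) -> list[str]:
        return self.ids_with_role(Role.labeled_mix)

    @property
    def blank_ids(self) -> list[str]:
        return self.ids_with_role(Role.blank)

    @property
    def nonblank_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries if e.role != Role.blank]


@dataclass
class PeakTableSchema:
    """Column-name map for :func:`read_peak_table`.

    ``mass_kind`` may be ``"neutral"`` (default) or ``"mz"``; in the latter
    case masses are converted to neutral assuming singly charged ions
    (M+H in positive mode, M-H in negative mode).
    """

    mass: str = "neutral_mass"
    rt: str = "rt_min"
    polarity: str = "polarity"
    peak_id: str | None = "peak_id"
    sample_columns: Sequence[str] | None = None  # None -> every other column
    mass_kind: str = "neutral"


def _sniff_reader(path: str | Path) -> csv.DictReader:
    text = Path(path).read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    return csv.DictReader(io.StringIO(text), delimiter=delimiter)


def _parse_float(value: str, what: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"row {row}: cannot parse {what} value {value!r}") from None


_POLARITY_ALIASES = {
    "positive": Polarity.positive, "pos": Polarity.positive, "+": Polarity.positive,
    "negative": Polarity.negative, "neg": Polarity.negative, "-": Polarity.negative,
}


def read_peak_table(
    path: str | Path, schema: PeakTableSchema | None = None
) -> list[Peak]:
    """Read a wide feature table (one area column per sample) into Peaks.

    Missing or empty area cells become "not detected"; negative areas are
    rejected. Rows are returned in file order.
    """
    schema = schema or PeakTableSchema()
    reader = _sniff_reader(path)
    columns = reader.fieldnames or []
    for required in (schema.mass, schema.rt, schema.polarity):
        if required not in columns:
            raise SchemaError(f"missing required column {required!r}")
    known = {schema.mass, schema.rt, schema.polarity}
    if schema.peak_id and schema.peak_id in columns:
        known.add(schema.peak_id)
    sample_cols = (
        list(schema.sample_columns)
        if schema.sample_columns is not None
        else [c for c in columns if c not in known]
    )
    missing = [c for c in sample_cols if c not in columns]
    if missing:
        raise SchemaError(f"missing sample column(s) {missing}")
    if not sample_cols:
        raise SchemaError("no sample area columns found")

    peaks: list[Peak] = []
    seen: set[str] = set()
    for i, row in enumerate(reader, start=1):
        pol_raw = (row[schema.polarity] or "").strip().lower()
        if pol_raw not in _POLARITY_ALIASES:
            raise ParseError(f"row {i}: unknown polarity {row[schema.polarity]!r}")
        polarity = _POLARITY_ALIASES[pol_raw]
        mass = _parse_float(row[schema.mass], "mass", i)
        if schema.mass_kind == "mz":
            mass = mass - PROTON_MASS if polarity is Polarity.positive else mass + PROTON_MASS
        elif schema.mass_kind != "neutral":
            raise SchemaError(f"unknown mass_kind {schema.mass_kind!r}")
        rt = _parse_float(row[schema.rt], "rt", i)
        areas: dict[str, float] = {}
        for col in sample_cols:
            cell = (row.get(col) or "").strip()
            if cell:
                areas[col] = _parse_float(cell, f"area ({col})", i)
        peak_id = (
            row[schema.peak_id].strip()
            if schema.peak_id and schema.peak_id in row and row[schema.peak_id]
            else f"pk{i:05d}"
        )
        if peak_id in seen:
            raise ValidationError(f"row {i}: duplicate peak_id {peak_id!r}")
        seen.add(peak_id)
        peaks.append(Peak(peak_id, polarity, mass, rt, areas))
    return peaks


def write_peak_table(
    peaks: Sequence[Peak], path: str | Path, sample_ids: Sequence[str] | None = None
) -> None:
    """Write peaks as a wide CSV; masses at full precision (repr)."""
    if sample_ids is None:
        ordered: list[str] = []
        for p in peaks:
            for s in p.areas:
                if s not in ordered:
                    ordered.append(s)
        sample_ids = ordered
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["peak_id", "polarity", "neutral_mass", "rt_min", "annotations"]
            + list(sample_ids)
        )
        for p in peaks:
            writer.writerow(
                [p.peak_id, p.polarity.value, repr(p.neutral_mass), repr(p.rt),
                 ";".join(sorted(p.annotations))]
                + [repr(p.areas[s]) if s in p.areas else "" for s in sample_ids]
            )


def read_sample_table(path: str | Path) -> SampleTable:
    """Read sample metadata (sample_id, role[, group]); roles matched
    case-insensitively."""
    reader = _sniff_reader(path)
    columns = reader.fieldnames or []
    for required in ("sample_id", "role"):
        if required not in columns:
            raise SchemaError(f"missing required column {required!r}")
    entries = []
    for i, row in enumerate(reader, start=1):
        role_raw = (row["role"] or "").strip().lower()
        try:
            role = Role(role_raw)
        except ValueError:
            raise ValidationError(
                f"row {i}: unknown role {row['role']!r} "
                f"(expected one of {[r.value for r in Role]})"
            ) from None
        entries.append(
            SampleEntry(row["sample_id"].strip(), role, (row.get("group") or "").strip())
        )
    return SampleTable(entries)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "role", "group"])
        for e in samples.entries:
            writer.writerow([e.sample_id, e.role.value, e.group])


_PAIR_COLUMNS = [
    "feature_name", "parent_id", "partner_id", "parent_mass", "partner_mass",
    "parent_rt", "partner_rt", "delta_ppm", "delta_rt", "qualifying_window",
    "fractions", "flags", "status",
]


def _encode_map(values: Mapping[str, float]) -> str:
    return ";".join(f"{k}={repr(v)}" for k, v in sorted(values.items()))


def _decode_map(cell: str) -> dict[str, float]:
    if not cell:
        return {}
    out = {}
    for item in cell.split(";"):
        key, _, value = item.partition("=")
        out[key] = float(value)
    return out


def write_pair_table(pairs: Sequence, path: str | Path) -> None:
    """Serialize PeakPairs with full diagnostics; lossless round-trip via
    :func:`read_pair_table`."""
    from .artifact_screen import name_feature

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PAIR_COLUMNS)
        for pair in pairs:
            writer.writerow([
                name_feature(pair.parent_mass, pair.parent_rt),
                pair.parent_id, pair.partner_id,
                repr(pair.parent_mass), repr(pair.partner_mass),
                repr(pair.parent_rt), repr(pair.partner_rt),
                repr(pair.delta_ppm), repr(pair.delta_rt),
                pair.qualifying_window,
                _encode_map(pair.fractions),
                ";".join(sorted(pair.flags)),
                pair.status.value,
            ])


def read_pair_table(path: str | Path) -> list:
    from .pair_detection import PairStatus, PeakPair

    reader = _sniff_reader(path)
    missing = [c for c in _PAIR_COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise SchemaError(f"missing pair-table column(s) {missing}")
    pairs = []
    for row in reader:
        pairs.append(
            PeakPair(
                parent_id=row["parent_id"],
                partner_id=row["partner_id"],
                parent_mass=float(row["parent_mass"]),
                partner_mass=float(row["partner_mass"]),
                parent_rt=float(row["parent_rt"]),
                partner_rt=float(row["partner_rt"]),
                delta_ppm=float(row["delta_ppm"]),
                delta_rt=float(row["delta_rt"]),
                fractions=_decode_map(row["fractions"]),
                qualifying_window=int(row["qualifying_window"]),
                flags=set(filter(None, row["flags"].split(";"))),
                status=PairStatus(row["status"]),
            )
        )
    return pairs
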