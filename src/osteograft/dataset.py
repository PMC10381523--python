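"""In-study dataset of seven commercial intra-oral bone graft materials.

Houses the quantitative table the empirical model is built on: chemical
composition (wt%), macroporosity, profile roughness parameters (Pa, Pt, Pq),
and the six-month in vivo outcomes (bone-to-material contact, regenerated
area), each as mean ± SD group summaries. The table can be exported to and
re-read from CSV/JSON, and turned into a numeric design matrix for the
regression engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "FormatError",
    "SchemaError",
    "RangeError",
    "Composition",
    "SummaryStat",
    "BiomaterialRecord",
    "StudyTable",
    "DesignMatrix",
    "COMPOSITION_FIELDS",
    "MEASURED_PROPS",
    "PREDICTOR_NAMES",
    "RESPONSE",
    "load_builtin",
    "design_matrix",
    "read_table",
    "write_table",
]


class DatasetError(ValueError):
    """Base class for dataset-layer failures."""


class FormatError(DatasetError):
    """The file could not be parsed at all (malformed CSV/JSON)."""


class SchemaError(DatasetError):
    """A required column/field is missing or an identifier is unknown."""


class RangeError(DatasetError):
    """A value violates a physical range or ordering invariant."""


COMPOSITION_FIELDS = ("hap_wt", "btcp_wt", "caco3_wt", "collagen_wt", "h2o_wt", "ti_wt")

#: Measured mean ± SD properties carried by every record, in schema order.
MEASURED_PROPS = ("macroporosity", "pa", "pt", "pq", "bmc_6mo", "regenerated_area_6mo")

#: Fields usable as model predictors (composition wt% plus scalar summaries).
PREDICTOR_NAMES = COMPOSITION_FIELDS + ("macroporosity", "pa", "pt", "pq")

#: The modeled response: bone-to-material contact at 6 months (% of perimeter).
RESPONSE = "bmc_6mo"

_ORIGINS = ("bovine", "porcine", "bovine/porcine", "synthetic")


@dataclass(frozen=True)
class Composition:
    """Chemical composition of one graft in weight percent.

    Fields cover hydroxyapatite (HAp), beta-tricalcium phosphate, calcium
    carbonate, collagen, water and titanium. Each must lie in [0, 100] and
    the sum must fall in [95, 105] (slack for rounded manufacturer figures).
    """

    hap_wt: float = 0.0
    btcp_wt: float = 0.0
    caco3_wt: float = 0.0
    collagen_wt: float = 0.0
    h2o_wt: float = 0.0
    ti_wt: float = 0.0

    def __post_init__(self) -> None:
        total = 0.0
        for f in fields(self):
            v = float(getattr(self, f.name))
            if not math.isfinite(v) or not (0.0 <= v <= 100.0):
                raise RangeError(f"composition field {f.name}={v!r} outside [0, 100]")
            object.__setattr__(self, f.name, v)
            total += v
        if not (95.0 <= total <= 105.0):
            raise RangeError(f"composition sums to {total:.2f} wt%, outside [95, 105]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SummaryStat:
    """A group summary: mean ± SD of n samples (SD with n−1 denominator)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise RangeError(f"summary mean {self.mean!r} is not finite")
        if not (math.isfinite(self.sd) and self.sd >= 0.0):
            raise RangeError(f"summary sd {self.sd!r} must be ≥ 0")
        if int(self.n) < 1:
            raise RangeError(f"summary n {self.n!r} must be ≥ 1")
        object.__setattr__(self, "n", int(self.n))


_PERCENT_PROPS = ("macroporosity", "bmc_6mo", "regenerated_area_6mo")


@dataclass(frozen=True)
class BiomaterialRecord:
    """One graft material: identity, composition and measured properties.

    Percent-valued means must lie in [0, 100]; the roughness summaries must
    respect the power-mean ordering pa ≤ pq ≤ pt. Particle size is stored as
    a (min, max) µm interval and is never used as a numeric predictor.
    """

    name: str
    composition: Composition
    origin: str
    particle_size_um: tuple[float, float]
    macroporosity: SummaryStat
    pa: SummaryStat
    pt: SummaryStat
    pq: SummaryStat
    bmc_6mo: SummaryStat
    regenerated_area_6mo: SummaryStat

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("record name must be non-empty")
        if self.origin not in _ORIGINS:
            raise RangeError(f"origin {self.origin!r} not one of {_ORIGINS}")
        lo, hi = self.particle_size_um
        if not (0 < lo <= hi):
            raise RangeError(f"particle size interval {self.particle_size_um!r} invalid")
        object.__setattr__(self, "particle_size_um", (float(lo), float(hi)))
        for prop in _PERCENT_PROPS:
            m = getattr(self, prop).mean
            if not (0.0 <= m <= 100.0):
                raise RangeError(f"{self.name}: {prop} mean {m!r} outside [0, 100]")
        if not (self.pa.mean <= self.pq.mean <= self.pt.mean):
            raise RangeError(
                f"{self.name}: roughness ordering violated "
                f"(pa={self.pa.mean} ≤ pq={self.pq.mean} ≤ pt={self.pt.mean} required)"
            )

    def predictor_value(self, name: str) -> float:
        """Scalar value of a predictor field (SummaryStats contribute their mean)."""
        if name in COMPOSITION_FIELDS:
            return getattr(self.composition, name)
        if name in ("macroporosity", "pa", "pt", "pq"):
            return getattr(self, name).mean
        raise SchemaError(f"unknown predictor name {name!r}; choose from {PREDICTOR_NAMES}")


@dataclass(frozen=True)
class StudyTable:
    """Ordered collection of biomaterial records with unique names."""

    records: tuple[BiomaterialRecord, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise SchemaError("record names must be unique")
        object.__setattr__(self, "records", tuple(self.records))

    def __iter__(self) -> Iterator[BiomaterialRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.records)

    def get(self, name: str) -> BiomaterialRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise SchemaError(f"no record named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-biomaterial DataFrame in the CSV schema."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {"name": r.name, "origin": r.origin}
            row.update(r.composition.as_dict())
            row["size_min_um"], row["size_max_um"] = r.particle_size_um
            for prop in MEASURED_PROPS:
                s: SummaryStat = getattr(r, prop)
                row[f"{prop}_mean"] = s.mean
                row[f"{prop}_sd"] = s.sd
                row[f"{prop}_n"] = s.n
            rows.append(row)
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric design for the regression engine: X (n×p), y (n), labels, rows."""

    X: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __iter__(self):  # allows X, y, labels = design_matrix(...)
        return iter((self.X, self.y, self.labels))


# --------------------------------------------------------------------------
# Builtin study table
#
# Composition (wt%), origin and particle size follow the manufacturers'
# figures; macroporosity, roughness (3 ESEM images per graft) and the
# 6-month histomorphometry outcomes (n = 6) are the published group
# summaries. The composite grafts need a coercion convention:
#   rescaled — BioOss-Collagen = 90 % BioOss mineral + 10 % collagen, all
#              mineral fractions rescaled (caco3 3.06);
#   nominal  — keep the printed caco3 3.4 for the mineral phase.
# MP3's "bone mix" is coded as pure HAp (90 %) plus 10 % collagen; the
# pre-hydration water is not quantified by the manufacturer and is set to 0.
# --------------------------------------------------------------------------

def _builtin_rows(convention: str) -> list[tuple]:
    if convention == "rescaled":
        biooss_col = dict(hap_wt=84.24, caco3_wt=3.06, collagen_wt=12.7)
    elif convention == "nominal":
        biooss_col = dict(hap_wt=84.24, caco3_wt=3.4, collagen_wt=12.7)
    else:
        raise SchemaError(f"unknown composition convention {convention!r}")
    # name, composition kwargs, origin, (size lo, hi), MP, Pa, Pt, Pq, BMC, RA
    return [
        ("BioOss", dict(hap_wt=93.6, caco3_wt=3.4, collagen_wt=3.0), "bovine",
         (250, 1000), (58.79, 2.72), (0.54, 0.19), (3.40, 1.04), (0.67, 0.24),
         (49.01, 4.4), (96.42, 3.27)),
        ("BioOss-Collagen", biooss_col, "bovine/porcine",
         (250, 1000), (65.73, 4.07), (0.67, 0.10), (3.70, 1.77), (0.84, 0.20),
         (48.99, 4.3), (95.87, 4.57)),
        ("MP3", dict(hap_wt=90.0, collagen_wt=10.0), "porcine",
         (600, 1000), (58.12, 9.02), (0.95, 0.02), (6.80, 2.12), (1.26, 0.11),
         (33.68, 8.3), (85.02, 15.43)),
        ("Ostim", dict(hap_wt=35.0, h2o_wt=65.0), "synthetic",
         (0.001, 0.05), (15.81, 3.18), (0.90, 0.07), (5.40, 0.65), (1.13, 0.14),
         (53.98, 14.7), (49.47, 16.14)),
        ("Cerasorb", dict(btcp_wt=100.0), "synthetic",
         (500, 1000), (63.44, 3.83), (1.35, 0.17), (5.81, 0.66), (1.52, 0.16),
         (44.17, 16.5), (93.83, 6.17)),
        ("BoneCeramic", dict(hap_wt=60.0, btcp_wt=40.0), "synthetic",
         (400, 700), (70.23, 5.21), (0.39, 0.01), (2.18, 0.28), (0.47, 0.04),
         (25.94, 10.9), (95.63, 5.09)),
        ("Natix", dict(ti_wt=100.0), "synthetic",
         (700, 1000), (67.12, 1.94), (1.29, 0.04), (6.85, 0.72), (1.55, 0.07),
         (14.12, 4.8), (95.95, 4.44)),
    ]


def load_builtin(convention: str = "rescaled") -> StudyTable:
    """The seven-graft study table.

    Parameters
    ----------
    convention:
        Composition coercion for the composite grafts: ``"rescaled"``
        (default, mass-balance rescaling of BioOss-Collagen) or
        ``"nominal"`` (keep the printed 3.4 wt% CaCO3).
    """
    records = []
    for name, comp, origin, size, mp, pa, pt, pq, bmc, ra in _builtin_rows(convention):
        records.append(
            BiomaterialRecord(
                name=name,
                composition=Composition(**comp),
                origin=origin,
                particle_size_um=size,
                macroporosity=SummaryStat(*mp, n=6),
                pa=SummaryStat(*pa, n=3),
                pt=SummaryStat(*pt, n=3),
                pq=SummaryStat(*pq, n=3),
                bmc_6mo=SummaryStat(*bmc, n=6),
                regenerated_area_6mo=SummaryStat(*ra, n=6),
            )
        )
    return StudyTable(tuple(records))


def design_matrix(
    table: StudyTable,
    predictors: Sequence[str],
    exclude: Iterable[str] = (),
) -> DesignMatrix:
    """Build the numeric design: one row per non-excluded biomaterial.

    ``predictors`` are drawn from :data:`PREDICTOR_NAMES`; measured
    properties contribute their group mean. The response is always the
    6-month BMC mean.
    """
    predictors = tuple(predictors)
    if not predictors:
        raise SchemaError("at least one predictor is required")
    for p in predictors:
        if p not in PREDICTOR_NAMES:
            raise SchemaError(f"unknown predictor name {p!r}; choose from {PREDICTOR_NAMES}")
    exclude = tuple(exclude)
    known = set(table.names)
    for e in exclude:
        if e not in known:
            raise SchemaError(f"unknown exclusion name {e!r}; table has {table.names}")
    rows = [r for r in table if r.name not in exclude]
    if not rows:
        raise SchemaError("design matrix is empty: every record was excluded")
    X = np.array([[r.predictor_value(p) for p in predictors] for r in rows], dtype=float)
    y = np.array([r.bmc_6mo.mean for r in rows], dtype=float)
    return DesignMatrix(X=X, y=y, labels=predictors, rows=tuple(r.name for r in rows))


# --------------------------------------------------------------------------
# Tabular IO
# --------------------------------------------------------------------------

_CSV_COLUMNS = (
    ["name", "origin"]
    + list(COMPOSITION_FIELDS)
    + ["size_min_um", "size_max_um"]
    + [f"{p}_{s}" for p in MEASURED_PROPS for s in ("mean", "sd", "n")]
)


def _record_from_flat(row: dict) -> BiomaterialRecord:
    comp = Composition(**{f: float(row[f]) for f in COMPOSITION_FIELDS})
    stats = {}
    for prop in MEASURED_PROPS:
        stats[prop] = SummaryStat(
            mean=float(row[f"{prop}_mean"]),
            sd=float(row[f"{prop}_sd"]),
            n=int(row[f"{prop}_n"]),
        )
    return BiomaterialRecord(
        name=str(row["name"]),
        composition=comp,
        origin=str(row["origin"]),
        particle_size_um=(float(row["size_min_um"]), float(row["size_max_um"])),
        **stats,
    )


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    p = str(path).lower()
    if p.endswith(".json"):
        return "json"
    return "csv"


def write_table(table: StudyTable, path, fmt: str | None = None) -> None:
    """Write a study table as CSV (flat schema) or JSON (record objects)."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        table.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        objs = []
        for r in table:
            obj = {
                "name": r.name,
                "origin": r.origin,
                "composition": r.composition.as_dict(),
                "particle_size_um": list(r.particle_size_um),
            }
            for prop in MEASURED_PROPS:
                s: SummaryStat = getattr(r, prop)
                obj[prop] = {"mean": s.mean, "sd": s.sd, "n": s.n}
            objs.append(obj)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(objs, fh, indent=1)
    else:
        raise SchemaError(f"unknown table format {fmt!r} (csv or json)")


def read_table(path, fmt: str | None = None) -> StudyTable:
    """Read a study table written by :func:`write_table`.

    Raises :class:`FormatError` for an unparseable file, :class:`SchemaError`
    for missing columns/fields and :class:`RangeError` for values that
    violate the type invariants.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path)
        except (pd.errors.ParserError, UnicodeDecodeError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"could not parse CSV {path}: {exc}") from exc
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"CSV {path} is missing columns {missing}")
        records = []
        for _, row in frame.iterrows():
            try:
                records.append(_record_from_flat(row.to_dict()))
            except (TypeError, KeyError) as exc:
                raise SchemaError(f"bad row in {path}: {exc}") from exc
        return StudyTable(tuple(records))
    if fmt == "json":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                objs = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"could not parse JSON {path}: {exc}") from exc
        records = []
        for obj in objs:
            try:
                comp = Composition(**obj["composition"])
                stats = {
                    prop: SummaryStat(**obj[prop]) for prop in MEASURED_PROPS
                }
                records.append(
                    BiomaterialRecord(
                        name=obj["name"],
                        origin=obj["origin"],
                        composition=comp,
                        particle_size_um=tuple(obj["particle_size_um"]),
                        **stats,
                    )
                )
            except KeyError as exc:
                raise SchemaError(f"JSON record missing field {exc}") from exc
        return StudyTable(tuple(records))
    raise SchemaError(f"unknown table format {fmt!r} (csv or json)")
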