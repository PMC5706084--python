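"""Data model and I/O for sediment monitoring campaigns.

The central container is :class:`ContaminationMatrix`, a positions x chemicals
table of concentrations in mg/kg dry weight (or dimensionless quotients after
normalisation).  Raw campaign data arrive as per-sample records which are
aggregated to one row per *position* — a fixed sampling location that may have
been visited several times across campaigns, possibly under aliased names
(e.g. ``F2`` and ``F2bis`` denoting the same spot).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ChemClass",
    "ChemicalProfile",
    "ChemicalRegistry",
    "SampleRecord",
    "AliasTable",
    "ContaminationMatrix",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "canonical_positions",
    "aggregate_to_matrix",
    "compute_hq",
]


class SchemaError(ValueError):
    """A required column or header is missing or malformed."""


class ValidationError(ValueError):
    """A record violates a data invariant (e.g. negative concentration)."""


class ChemClass(str, Enum):
    HEAVY_METAL = "heavy_metal"
    PAH = "pah"
    HYDROCARBON = "hydrocarbon"
    AGGREGATE = "aggregate"


@dataclass(frozen=True)
class ChemicalProfile:
    """Per-chemical metadata: class, regulatory limit and ecotox parameters.

    Parameters
    ----------
    lcl_limit : float, optional
        Regulatory sediment limit (mg/kg dry weight) used as the hazard
        quotient denominator.
    pnec_water : float, optional
        Predicted no-effect concentration in the water phase (mg/L).
    kp : float, optional
        Sediment-water partition coefficient (L/kg).
    pnec_sediment : float, optional
        Explicit sediment PNEC (mg/kg); overrides any derivation.
    toxicity_endpoints : tuple of (float, float), optional
        Acute aquatic toxicity endpoints as (concentration mg/L,
        assessment factor) pairs, for assessment-factor PNEC derivation.
    """

    name: str
    chem_class: ChemClass
    lcl_limit: float | None = None
    pnec_water: float | None = None
    kp: float | None = None
    pnec_sediment: float | None = None
    toxicity_endpoints: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.chem_class, str) and not isinstance(self.chem_class, ChemClass):
            object.__setattr__(self, "chem_class", ChemClass(self.chem_class))
        for attr in ("lcl_limit", "kp", "pnec_water", "pnec_sediment"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValidationError(f"{self.name}: {attr} must be > 0, got {v!r}")
        if self.toxicity_endpoints is not None:
            object.__setattr__(
                self,
                "toxicity_endpoints",
                tuple((float(c), float(af)) for c, af in self.toxicity_endpoints),
            )


class ChemicalRegistry(Mapping[str, ChemicalProfile]):
    """Ordered name -> :class:`ChemicalProfile` lookup."""

    def __init__(self, profiles: Iterable[ChemicalProfile]):
        self._profiles: dict[str, ChemicalProfile] = {}
        for p in profiles:
            if p.name in self._profiles:
                raise ValidationError(f"duplicate chemical {p.name!r}")
            self._profiles[p.name] = p

    def __getitem__(self, name: str) -> ChemicalProfile:
        return self._profiles[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._profiles)

    def __len__(self) -> int:
        return len(self._profiles)

    @property
    def names(self) -> list[str]:
        return list(self._profiles)

    def of_classes(self, classes: Iterable[ChemClass | str]) -> list[str]:
        """Chemical names belonging to any of the given classes, in registry order."""
        wanted = {ChemClass(c) for c in classes}
        return [n for n, p in self._profiles.items() if p.chem_class in wanted]


@dataclass
class SampleRecord:
    """One physical sediment sample and its measured concentrations.

    ``concentrations`` maps chemical name to mg/kg dry weight; ``None`` means
    the chemical was not measured in this sample.  Names in ``bdl`` were
    reported below the detection limit; their stored value is the detection
    limit itself (substitution happens at aggregation time).
    """

    sample_id: str
    point_id: str
    campaign_id: str
    concentrations: dict[str, float | None]
    bdl: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.bdl = frozenset(self.bdl)
        for chem, v in self.concentrations.items():
            if v is not None and v < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative concentration "
                    f"{v} for {chem!r}"
                )


@dataclass(frozen=True)
class AliasTable:
    """Map raw sampling-point names onto canonical position ids."""

    mappings: Mapping[str, str] = field(default_factory=dict)

    def resolve(self, raw_name: str) -> str:
        return self.mappings.get(raw_name, raw_name)

    @classmethod
    def identity(cls) -> "AliasTable":
        return cls({})


_VALUE_KINDS = ("raw", "hq", "risk_quotient")


@dataclass
class ContaminationMatrix:
    """Positions x chemicals concentration table with provenance.

    Attributes
    ----------
    data : pandas.DataFrame
        Rows indexed by canonical position id, columns by chemical name.
        NaN marks an unmeasured cell.
    value_kind : {"raw", "hq", "risk_quotient"}
        mg/kg for ``raw``; dimensionless quotients otherwise.
    bdl_mask : pandas.DataFrame of bool
        True where the aggregated cell rests entirely on below-detection-limit
        readings; such cells are excluded from ratio fingerprints.
    campaign_coverage : pandas.DataFrame of str
        Comma-joined campaign ids contributing to each cell ("" if none).
    """

    data: pd.DataFrame
    value_kind: str = "raw"
    bdl_mask: pd.DataFrame | None = None
    campaign_coverage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in _VALUE_KINDS:
            raise ValidationError(f"value_kind must be one of {_VALUE_KINDS}")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValidationError("contamination matrix contains negative values")
        if self.bdl_mask is None:
            self.bdl_mask = pd.DataFrame(
                False, index=self.data.index, columns=self.data.columns
            )

    @property
    def points(self) -> list[str]:
        return list(self.data.index)

    @property
    def chemicals(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, chemicals: Sequence[str]) -> "ContaminationMatrix":
        missing = [c for c in chemicals if c not in self.data.columns]
        if missing:
            raise KeyError(f"chemicals not in matrix: {missing}")
        cov = None
        if self.campaign_coverage is not None:
            cov = self.campaign_coverage[list(chemicals)]
        return ContaminationMatrix(
            self.data[list(chemicals)].copy(),
            value_kind=self.value_kind,
            bdl_mask=self.bdl_mask[list(chemicals)].copy(),
            campaign_coverage=cov,
        )

    def drop_chemical(self, name: str) -> "ContaminationMatrix":
        if name not in self.data.columns:
            raise KeyError(f"chemical {name!r} not in matrix")
        keep = [c for c in self.data.columns if c != name]
        return self.subset(keep)


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

_SAMPLE_META_COLS = ("sample_id", "point_id", "campaign_id")
_UNIT_FACTORS = {"mg/kg": 1.0, "ug/kg": 1e-3, "µg/kg": 1e-3}


def _parse_cell(raw: object, sample_id: str, chem: str) -> tuple[float | None, bool]:
    """Parse one concentration cell -> (value, is_bdl)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None, False
    s = str(raw).strip()
    if s == "" or s.lower() in ("na", "nan", "nd"):
        return None, False
    bdl = s.startswith("<")
    if bdl:
        s = s[1:].strip()
    try:
        v = float(s)
    except ValueError as exc:
        raise ValidationError(
            f"sample {sample_id!r}: cannot parse concentration {raw!r} for {chem!r}"
        ) from exc
    if v < 0:
        raise ValidationError(
            f"sample {sample_id!r}: negative concentration {v} for {chem!r}"
        )
    return v, bdl


def _read_chemicals_csv(path) -> ChemicalRegistry:
    df = pd.read_csv(path, dtype=str)
    for col in ("name", "class"):
        if col not in df.columns:
            raise SchemaError(f"chemicals file missing column {col!r}")

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return None
        return float(v)

    profiles = []
    for _, row in df.iterrows():
        endpoints = None
        raw_ep = row.get("endpoints")
        if isinstance(raw_ep, str) and raw_ep.strip():
            pairs = []
            for chunk in raw_ep.split(";"):
                conc, af = chunk.split(":")
                pairs.append((float(conc), float(af)))
            endpoints = tuple(pairs)
        profiles.append(
            ChemicalProfile(
                name=str(row["name"]).strip(),
                chem_class=ChemClass(str(row["class"]).strip()),
                lcl_limit=_opt(row, "lcl_limit"),
                pnec_water=_opt(row, "pnec_water"),
                kp=_opt(row, "kp"),
                pnec_sediment=_opt(row, "pnec_sediment"),
                toxicity_endpoints=endpoints,
            )
        )
    return ChemicalRegistry(profiles)


def read_dataset(
    samples_path,
    chemicals_path,
    alias_path=None,
) -> tuple[list[SampleRecord], ChemicalRegistry, AliasTable]:
    """Read samples, chemical metadata and optional alias CSVs.

    The samples file carries one row per sample with columns ``sample_id``,
    ``point_id``, ``campaign_id`` followed by one column per chemical.  An
    optional row whose ``sample_id`` equals ``units`` declares per-column
    units (``mg/kg`` canonical, ``ug/kg`` converted).  Cells of the form
    ``<x`` flag a below-detection-limit reading with detection limit ``x``.
    """
    registry = _read_chemicals_csv(chemicals_path)

    df = pd.read_csv(samples_path, dtype=str)
    for col in _SAMPLE_META_COLS:
        if col not in df.columns:
            raise SchemaError(f"samples file missing column {col!r}")
    chem_cols = [c for c in df.columns if c not in _SAMPLE_META_COLS]
    unknown = [c for c in chem_cols if c not in registry]
    if unknown:
        raise SchemaError(f"unknown chemicals in samples file: {unknown}")

    factors = {c: 1.0 for c in chem_cols}
    if len(df) and str(df.iloc[0]["sample_id"]).strip().lower() == "units":
        for c in chem_cols:
            unit = str(df.iloc[0][c]).strip()
            if unit not in _UNIT_FACTORS:
                raise SchemaError(f"unknown unit {unit!r} for column {c!r}")
            factors[c] = _UNIT_FACTORS[unit]
        df = df.iloc[1:]

    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        conc: dict[str, float | None] = {}
        bdl: set[str] = set()
        for c in chem_cols:
            v, is_bdl = _parse_cell(row[c], sid, c)
            conc[c] = None if v is None else v * factors[c]
            if is_bdl:
                bdl.add(c)
        records.append(
            SampleRecord(
                sample_id=sid,
                point_id=str(row["point_id"]).strip(),
                campaign_id=str(row["campaign_id"]).strip(),
                concentrations=conc,
                bdl=frozenset(bdl),
            )
        )

    if alias_path is not None:
        adf = pd.read_csv(alias_path, dtype=str)
        for col in ("raw_name", "canonical_name"):
            if col not in adf.columns:
                raise SchemaError(f"alias file missing column {col!r}")
        aliases = AliasTable(
            {
                str(r["raw_name"]).strip(): str(r["canonical_name"]).strip()
                for _, r in adf.iterrows()
            }
        )
    else:
        aliases = AliasTable.identity()
    return records, registry, aliases


# ---------------------------------------------------------------------------
# Aggregation and normalisation
# ---------------------------------------------------------------------------


def canonical_positions(
    records: Sequence[SampleRecord], aliases: AliasTable | None = None
) -> list[str]:
    """Sorted unique canonical position ids covered by the records.

    Repeat visits across campaigns and aliased names collapse to a single
    position; the function is idempotent on its own output.
    """
    if not records:
        raise ValidationError("no records")
    aliases = aliases or AliasTable.identity()
    return sorted({aliases.resolve(r.point_id) for r in records})


def aggregate_to_matrix(
    records: Sequence[SampleRecord],
    aliases: AliasTable | None = None,
    aggregator: str = "mean",
    bdl_substitution: float = 0.5,
) -> ContaminationMatrix:
    """Collapse replicate samples to one row per canonical position.

    Below-detection-limit readings enter the aggregate at
    ``bdl_substitution`` x detection limit (default: half), the usual
    chemometric convention; a cell is flagged BDL only if every contributing
    reading was BDL, so that downstream ratio fingerprints can mask it.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    aliases = aliases or AliasTable.identity()
    positions = canonical_positions(records, aliases)
    chemicals: list[str] = []
    for r in records:
        for c in r.concentrations:
            if c not in chemicals:
                chemicals.append(c)

    values = pd.DataFrame(np.nan, index=positions, columns=chemicals)
    bdl_mask = pd.DataFrame(False, index=positions, columns=chemicals)
    coverage = pd.DataFrame("", index=positions, columns=chemicals)

    by_pos: dict[str, list[SampleRecord]] = {p: [] for p in positions}
    for r in records:
        by_pos[aliases.resolve(r.point_id)].append(r)

    agg = np.mean if aggregator == "mean" else np.median
    for p, recs in by_pos.items():
        for c in chemicals:
            vals, all_bdl, camps = [], True, set()
            for r in recs:
                v = r.concentrations.get(c)
                if v is None:
                    continue
                if c in r.bdl:
                    vals.append(v * bdl_substitution)
                else:
                    vals.append(v)
                    all_bdl = False
                camps.add(r.campaign_id)
            if vals:
                values.loc[p, c] = agg(vals)
                bdl_mask.loc[p, c] = all_bdl
                coverage.loc[p, c] = ",".join(sorted(camps))

    for c in chemicals:
        if values[c].isna().all():
            warnings.warn(f"chemical {c!r} has no measured values", stacklevel=2)

    return ContaminationMatrix(
        values, value_kind="raw", bdl_mask=bdl_mask, campaign_coverage=coverage
    )


def compute_hq(
    matrix: ContaminationMatrix, registry: ChemicalRegistry
) -> ContaminationMatrix:
    """Express concentrations as hazard quotients against regulatory limits.

    Each cell is divided by its chemical's sediment limit (LCL); HQ > 1 marks
    an exceedance.  All later multivariate stages operate on this scale so
    that chemicals with very different natural abundances are comparable.
    """
    if matrix.value_kind != "raw":
        raise ValidationError("compute_hq expects a raw concentration matrix")
    limits = {}
    for c in matrix.chemicals:
        prof = registry.get(c)
        if prof is None or prof.lcl_limit is None:
            raise ValidationError(f"no regulatory limit for chemical {c!r}")
        limits[c] = prof.lcl_limit
    data = matrix.data / pd.Series(limits)
    return ContaminationMatrix(
        data,
        value_kind="hq",
        bdl_mask=matrix.bdl_mask.copy(),
        campaign_coverage=matrix.campaign_coverage,
    )
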