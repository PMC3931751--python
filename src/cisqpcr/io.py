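"""CSV/YAML/JSON interchange: wells tables, expression tables, run config.

CSV is the instrument-export lingua franca, so it is the interchange format
for measurements; reports are JSON; configuration is YAML or JSON.  An
undetermined Cq is encoded in CSV as an empty field or the literal token
``UNDETERMINED`` (case-insensitive) and becomes NaN in memory; write-then-read
round-trips preserve it.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, LoadError
from .diagnostics import DEFAULT_INDEX_FORMULA
from .limiting_dilution import DilutionLevel, DilutionSeries
from .standards import (
    DEFAULT_GENES,
    DEFAULT_REFERENCE,
    MixEntry,
    StandardsMix,
    default_catalog,
    default_esm_mixes,
)

WELL_COLUMNS = ["plate_id", "well_id", "sample_id", "role", "ism_id", "gene", "nt_cq", "is_cq"]
_UNDETERMINED_TOKENS = {"", "undetermined", "na", "nan"}


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the measurements themselves."""

    genes: tuple[str, ...] = DEFAULT_GENES
    reference_gene: str = DEFAULT_REFERENCE
    fold_limit: float = 10.0
    esm_pooling: str = "per_plate"  # or "pooled"
    lcdt_formula: str = DEFAULT_INDEX_FORMULA
    r2_threshold: float = 0.99
    slope_tolerance: float = 0.05
    cross_threshold: float = 0.10
    output_sig_figs: int | None = None
    catalog: dict[str, StandardsMix] = field(default_factory=default_catalog)
    esm_mixes: list[StandardsMix] = field(default_factory=default_esm_mixes)

    def __post_init__(self) -> None:
        if self.reference_gene not in self.genes:
            raise ConfigurationError(
                f"reference gene {self.reference_gene!r} not in gene list {self.genes}"
            )
        if self.fold_limit <= 1 or self.cross_threshold <= 0 or self.r2_threshold <= 0:
            raise ConfigurationError("thresholds must be positive (fold_limit > 1)")


def _parse_cq(value: Any, row: int, column: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    text = str(value).strip()
    if text.lower() in _UNDETERMINED_TOKENS:
        return float("nan")
    try:
        cq = float(text)
    except ValueError:
        raise LoadError(f"row {row}: unparseable {column} value {value!r}") from None
    if cq <= 0:
        raise LoadError(f"row {row}: {column} must be > 0 or undetermined, got {cq}")
    return cq


def read_wells(path: str | Path, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Load and validate a wells CSV.

    Empty or ``UNDETERMINED`` Cq fields become NaN.  Duplicate
    (plate, well, gene) rows and, when ``genes`` is given, unknown gene
    symbols are rejected with the offending row number.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in WELL_COLUMNS if c not in raw.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    records = []
    for i, row in raw.iterrows():
        rowno = i + 2  # 1-based plus header
        gene = row["gene"].strip()
        if genes is not None and gene not in genes:
            raise LoadError(f"row {rowno}: unknown gene {gene!r}")
        role = row["role"].strip().lower()
        if role not in ("sample", "esm", "ntc"):
            raise LoadError(f"row {rowno}: unknown role {row['role']!r}")
        records.append(
            dict(
                plate_id=row["plate_id"].strip(),
                well_id=row["well_id"].strip(),
                sample_id=row["sample_id"].strip(),
                role=role,
                ism_id=row["ism_id"].strip() or None,
                gene=gene,
                nt_cq=_parse_cq(row["nt_cq"], rowno, "nt_cq"),
                is_cq=_parse_cq(row["is_cq"], rowno, "is_cq"),
            )
        )
    wells = pd.DataFrame(records, columns=WELL_COLUMNS)
    dup = wells.duplicated(subset=["plate_id", "well_id", "gene"])
    if dup.any():
        first = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise LoadError(f"row {first}: duplicate (plate_id, well_id, gene)")
    return wells


def write_wells(wells: pd.DataFrame, path: str | Path) -> None:
    """Write a wells table; NaN Cq and absent mixture ids become empty fields."""
    out = wells.copy()
    for col in ("nt_cq", "is_cq"):
        out[col] = out[col].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v)))
    out["ism_id"] = out["ism_id"].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else v)
    out.to_csv(path, index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Load a per-sample expression CSV (sample_id, class_label, gene columns)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise LoadError(f"{path}: missing sample_id column")
    return df


def read_dilution_series(path: str | Path) -> list[DilutionSeries]:
    """Load a dilution-series CSV: gene, expected_copies, n_replicates, n_positive."""
    df = pd.read_csv(path)
    needed = ["gene", "expected_copies", "n_replicates", "n_positive"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    out = []
    for gene, grp in df.groupby("gene", sort=False):
        levels = [
            DilutionLevel(float(r.expected_copies), int(r.n_replicates), int(r.n_positive))
            for r in grp.itertuples()
        ]
        out.append(DilutionSeries(str(gene), levels))
    return out


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_report(obj: Any, path: str | Path) -> None:
    """Serialize a result object (dataclasses allowed) as indented JSON."""
    Path(path).write_text(json.dumps(_to_jsonable(obj), indent=2) + "\n")


# ---------------------------------------------------------------------------
# configuration


def _mix_from_dict(mix_id: str, spec: Mapping[str, Any]) -> StandardsMix:
    kind = spec.get("kind")
    entries = {}
    for gene, e in spec.get("entries", {}).items():
        entries[gene] = MixEntry(
            is_molar=float(e["is_molar"]),
            volume_ul=float(e.get("volume_ul", 1.0)),
            nt_molar=float(e["nt_molar"]) if "nt_molar" in e and e["nt_molar"] is not None else None,
        )
    return StandardsMix(mix_id=mix_id, kind=kind, entries=entries)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration; unspecified fields keep defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: config must be a mapping")
    kwargs: dict[str, Any] = {}
    simple = (
        "reference_gene", "fold_limit", "esm_pooling", "lcdt_formula",
        "r2_threshold", "slope_tolerance", "cross_threshold", "output_sig_figs",
    )
    for key in simple:
        if key in data:
            kwargs[key] = data[key]
    if "genes" in data:
        kwargs["genes"] = tuple(data["genes"])
    if "mixtures" in data:
        catalog, esm = {}, []
        for mix_id, spec in data["mixtures"].items():
            mix = _mix_from_dict(mix_id, spec)
            if mix.kind == "ESM":
                esm.append(mix)
            else:
                catalog[mix_id] = mix
        kwargs["catalog"] = catalog
        if esm:
            kwargs["esm_mixes"] = esm
    return RunConfig(**kwargs)
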