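"""Tidy time-series tables and result serialization.

One long-format CSV schema serves both metabolite and transcript measurements:

    tissue,entity,day,replicate,value

``value`` is a non-negative number or the literal token ``BD`` (below detection,
used for intermediates under the instrument threshold).  Days are plain numbers
(days after sowing).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__ as _version
from .errors import InputError
from .topology import PathwayTopology

BELOW_DETECTION = "BD"

_COLUMNS = ["tissue", "entity", "day", "replicate", "value"]

#: aglycone-class names accepted in metabolite tables, mapped to the modeled
#: glycosylated end-product state (measurements sum all glycosylated/methylated
#: derivatives of each aglycone class)
END_PRODUCT_ALIASES = {
    "kaempferol": "KMPg",
    "quercetin": "QUEg",
    "myricetin": "MYRg",
    "anthocyanin": "ANT",
    "anthocyanins": "ANT",
    "delphinidin": "ANT",
}


class TimeSeriesTable:
    """Replicate-level tidy measurements for one tissue.

    Wraps a DataFrame with columns tissue, entity, day, replicate, value,
    below_detection.  ``value`` is NaN where below_detection is True.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"table missing column(s): {missing}")
        if "below_detection" not in df.columns:
            df["below_detection"] = False
        df["day"] = df["day"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            bad = df.index[df["replicate"] < 1][0]
            raise InputError(f"row {bad}: replicate must be >= 1")
        numeric = df.loc[~df["below_detection"], "value"].astype(float)
        if (numeric < 0).any():
            bad = numeric.index[numeric < 0][0]
            raise InputError(f"row {bad}: negative value {numeric[bad]}")
        if not numeric.map(np.isfinite).all():
            bad = numeric.index[~numeric.map(np.isfinite)][0]
            raise InputError(f"row {bad}: non-finite value")
        key = df[["tissue", "entity", "day", "replicate"]]
        dup = key.duplicated()
        if dup.any():
            bad = df.index[dup][0]
            raise InputError(
                f"row {bad}: duplicate (tissue, entity, day, replicate) key "
                f"{tuple(key.iloc[bad])}"
            )
        df["value"] = df["value"].astype(float)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeSeriesTable):
            return NotImplemented
        a = self.df.sort_values(_COLUMNS[:4]).reset_index(drop=True)
        b = other.df.sort_values(_COLUMNS[:4]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        same_meta = (
            (a[["tissue", "entity"]] == b[["tissue", "entity"]]).all().all()
            and np.allclose(a["day"], b["day"])
            and (a["replicate"] == b["replicate"]).all()
            and (a["below_detection"] == b["below_detection"]).all()
        )
        av, bv = a["value"].to_numpy(), b["value"].to_numpy()
        both_nan = np.isnan(av) & np.isnan(bv)
        return bool(same_meta and np.all(both_nan | np.isclose(av, bv, rtol=0, atol=0)))

    @property
    def tissues(self) -> list[str]:
        return sorted(self.df["tissue"].unique())

    @property
    def entities(self) -> list[str]:
        return sorted(self.df["entity"].unique())

    @property
    def days(self) -> list[float]:
        return sorted(self.df["day"].unique())

    def means(self) -> pd.DataFrame:
        """Replicate means per (tissue, entity, day); below-detection rows excluded."""
        obs = self.df[~self.df["below_detection"]]
        return (
            obs.groupby(["tissue", "entity", "day"], as_index=False)["value"]
            .mean()
            .sort_values(["tissue", "entity", "day"])
            .reset_index(drop=True)
        )

    def for_tissue(self, tissue: str) -> "TimeSeriesTable":
        sub = self.df[self.df["tissue"] == tissue]
        if sub.empty:
            raise InputError(f"no rows for tissue {tissue!r}")
        return TimeSeriesTable(sub)

    def to_csv(self, path: str | Path) -> None:
        out = self.df[_COLUMNS].copy()
        out["value"] = [
            BELOW_DETECTION if bd else repr(float(v))
            for v, bd in zip(self.df["value"], self.df["below_detection"])
        ]
        out.to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path) -> "TimeSeriesTable":
        return _parse_table(path)


def _parse_table(path: str | Path) -> TimeSeriesTable:
    try:
        raw = pd.read_csv(path, dtype={"value": str})
    except Exception as e:  # malformed CSV
        raise InputError(f"{path}: cannot parse CSV ({e})") from e
    missing = [c for c in _COLUMNS if c not in raw.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    bd = raw["value"].str.strip().str.upper() == BELOW_DETECTION

    def parse(s):  # exact round-trip for repr-formatted floats
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    vals = raw["value"].where(~bd).map(parse)
    bad = (~bd) & vals.isna()
    if bad.any():
        row = raw.index[bad][0]
        raise InputError(f"{path}: row {row}: unparseable value {raw['value'][row]!r}")
    df = raw.copy()
    df["value"] = vals
    df["below_detection"] = bd
    try:
        return TimeSeriesTable(df)
    except InputError as e:
        raise InputError(f"{path}: {e}") from e


def split_by_tissue(table: TimeSeriesTable) -> dict[str, TimeSeriesTable]:
    return {t: table.for_tissue(t) for t in table.tissues}


def read_metabolite_table(
    path: str | Path, topology: PathwayTopology
) -> dict[str, TimeSeriesTable]:
    """Read end-product concentration measurements; one table per tissue.

    Entities may be end-product species ids or aglycone-class names
    (e.g. ``kaempferol``), which map onto the glycosylated end-product state.
    """
    table = _parse_table(path)
    ends = set(topology.end_products)
    species = set(topology.species_ids)

    def resolve(entity: str, row: int) -> str:
        if entity in species:
            return entity
        mapped = END_PRODUCT_ALIASES.get(entity.lower())
        if mapped is not None and mapped in ends:
            return mapped
        raise InputError(f"{path}: row {row}: unknown metabolite entity {entity!r}")

    table.df["entity"] = [
        resolve(e, i) for i, e in zip(table.df.index, table.df["entity"])
    ]
    # re-validate after mapping (aliases could collide with explicit ids)
    table = TimeSeriesTable(table.df)
    return split_by_tissue(table)


def read_transcript_table(
    path: str | Path, topology: PathwayTopology
) -> dict[str, TimeSeriesTable]:
    """Read relative transcript abundance measurements; one table per tissue."""
    table = _parse_table(path)
    enzymes = set(topology.enzymes)
    for i, e in zip(table.df.index, table.df["entity"]):
        if e not in enzymes:
            raise InputError(f"{path}: row {i}: entity {e!r} is not a pathway enzyme")
    return split_by_tissue(table)


# -- result serialization -----------------------------------------------------


def _jsonify(obj: Any) -> Any:
    if hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def canonical_json(obj: Any) -> str:
    """Deterministic JSON text: sorted keys, repr-exact floats, no whitespace drift."""
    return json.dumps(_jsonify(obj), sort_keys=True, indent=1)


def config_hash(config: Any) -> str:
    """Short sha256 fingerprint of a configuration object."""
    return hashlib.sha256(canonical_json(config).encode()).hexdigest()[:16]


def write_results(result: Any, path: str | Path, config: Any | None = None) -> Path:
    """Serialize a fit/ensemble/flux result to JSON with provenance.

    Side CSV tables (edge usage for ensembles, per-reaction flux for flux maps)
    are written next to the JSON file by the objects' own ``to_csv`` hooks when
    present.  Output is byte-stable for fixed inputs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "result": _jsonify(result),
        "tool": "flavopath",
        "version": _version,
    }
    if config is not None:
        payload["config_hash"] = config_hash(config)
    try:
        path.write_text(canonical_json(payload) + "\n")
    except OSError as e:
        raise InputError(f"cannot write results to {path}: {e}") from e
    if hasattr(result, "to_csv"):
        result.to_csv(path.with_suffix(".csv"))
    return path


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
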