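"""Reading and writing the tidy measurement, config, and result tables.

All tables are comma-delimited UTF-8 with a header row and "." decimals.
Censored spot counts are written as the literal token ``LAWN``. Floats are
serialized with shortest round-trip ``repr``, so write/read cycles are
bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    LAWN,
    AnalysisConfig,
    ConfigError,
    Genotype,
    GrowthMeasurement,
    InvariantError,
    Locus,
    PanelError,
    SchemaError,
    StrainRecord,
    Timecourse,
    ViabilityMeasurement,
    parse_genotype_token,
)

__all__ = [
    "GROWTH_COLUMNS",
    "TIMECOURSE_COLUMNS",
    "VIABILITY_COLUMNS",
    "ParseResult",
    "read_measurements",
    "write_measurements",
    "read_config",
    "write_results",
    "results_to_frame",
]

GROWTH_COLUMNS = (
    "strain_id",
    "genotype",
    "temperature_C",
    "replicate",
    "day",
    "od_initial",
    "od_final",
    "duration_h",
)
TIMECOURSE_COLUMNS = ("strain_id", "temperature_C", "replicate", "day", "od")
VIABILITY_COLUMNS = (
    "strain_id",
    "temperature_C",
    "replicate",
    "dilution_exponent",
    "tech_rep",
    "colonies_or_LAWN",
    "od_end",
    "spot_volume_ml",
)

_SCHEMAS = {
    "growth": GROWTH_COLUMNS,
    "timecourse": TIMECOURSE_COLUMNS,
    "viability": VIABILITY_COLUMNS,
}


@dataclass
class ParseResult:
    """Typed records plus the raw table and a report of skipped rows."""

    schema: str
    records: list
    table: pd.DataFrame
    skipped: list[tuple[int, str]]


def _check_header(df: pd.DataFrame, schema: str) -> None:
    expected = _SCHEMAS[schema]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema} table is missing mandatory column(s): {missing}"
        )


def _growth_record(row: pd.Series) -> GrowthMeasurement:
    return GrowthMeasurement(
        strain_id=str(row["strain_id"]),
        temperature=float(row["temperature_C"]),
        replicate_id=str(row["replicate"]),
        day_id=str(row["day"]),
        od_initial=float(row["od_initial"]),
        od_final=float(row["od_final"]),
        duration=float(row["duration_h"]),
    )


def read_measurements(
    path, schema: str, on_invalid: str = "raise"
) -> ParseResult:
    """Read a measurement table and convert every row to its domain type.

    Parameters
    ----------
    path:
        CSV file location.
    schema:
        One of ``growth``, ``timecourse``, ``viability``. Timecourse and
        viability tables are long-format; their rows are grouped into one
        record per (strain, temperature, replicate).
    on_invalid:
        ``"raise"`` (default) aborts on the first invariant violation with
        the offending row index; ``"skip"`` drops the violating record and
        lists it in the parse report.
    """
    if schema not in _SCHEMAS:
        raise ConfigError(f"unknown schema {schema!r}")
    if on_invalid not in ("raise", "skip"):
        raise ConfigError(f"on_invalid must be 'raise' or 'skip'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"colonies_or_LAWN": str} if schema == "viability" else None,
        float_precision="round_trip",  # bit-exact write/read cycles
    )
    _check_header(df, schema)

    records: list = []
    skipped: list[tuple[int, str]] = []

    def handle(idx: int, err: Exception):
        if on_invalid == "raise":
            raise InvariantError(str(err), row=idx) from err
        skipped.append((idx, str(err)))

    if schema == "growth":
        for idx, row in df.iterrows():
            try:
                # validate genotype token alongside the measurement
                parse_genotype_token(str(row["genotype"]))
                records.append(_growth_record(row))
            except PanelError as err:
                handle(int(idx), err)
    elif schema == "timecourse":
        for (sid, temp, rep), grp in df.groupby(
            ["strain_id", "temperature_C", "replicate"], sort=False
        ):
            grp = grp.sort_values("day")
            try:
                records.append(
                    Timecourse(
                        strain_id=str(sid),
                        temperature=float(temp),
                        replicate_id=str(rep),
                        times=tuple(float(d) for d in grp["day"]),
                        ods=tuple(float(o) for o in grp["od"]),
                    )
                )
            except PanelError as err:
                handle(int(grp.index[0]), err)
    else:  # viability
        for (sid, temp, rep), grp in df.groupby(
            ["strain_id", "temperature_C", "replicate"], sort=False
        ):
            grp = grp.sort_values(
                ["dilution_exponent", "tech_rep"], ascending=[False, True]
            )
            try:
                counts: list[tuple] = []
                dilutions: list[float] = []
                for exponent, sub in grp.groupby("dilution_exponent", sort=False):
                    # decimal parse, so 1e-5 round-trips bit-exactly
                    dilutions.append(float(f"1e{int(round(float(exponent)))}"))
                    counts.append(
                        tuple(
                            LAWN if str(c).strip() == LAWN else int(c)
                            for c in sub["colonies_or_LAWN"]
                        )
                    )
                records.append(
                    ViabilityMeasurement(
                        strain_id=str(sid),
                        temperature=float(temp),
                        replicate_id=str(rep),
                        spot_volume=float(grp["spot_volume_ml"].iloc[0]),
                        dilution_factors=tuple(dilutions),
                        spot_counts=tuple(counts),
                        od_end=float(grp["od_end"].iloc[0]),
                    )
                )
            except (PanelError, ValueError) as err:
                handle(int(grp.index[0]), err)

    return ParseResult(schema=schema, records=records, table=df, skipped=skipped)


def _growth_frame(
    records: Iterable[GrowthMeasurement],
    genotypes: dict[str, str] | None = None,
) -> pd.DataFrame:
    genotypes = genotypes or {}
    rows = [
        {
            "strain_id": m.strain_id,
            "genotype": genotypes.get(m.strain_id, ""),
            "temperature_C": m.temperature,
            "replicate": m.replicate_id,
            "day": m.day_id,
            "od_initial": m.od_initial,
            "od_final": m.od_final,
            "duration_h": m.duration,
        }
        for m in records
    ]
    return pd.DataFrame(rows, columns=list(GROWTH_COLUMNS))


def write_measurements(records: Sequence, path, genotypes=None) -> None:
    """Write domain records back to their tidy CSV layout."""
    path = Path(path)
    if not records:
        raise PanelError("no records to write")
    first = records[0]
    if isinstance(first, GrowthMeasurement):
        df = _growth_frame(records, genotypes)
    elif isinstance(first, Timecourse):
        rows = [
            {
                "strain_id": tc.strain_id,
                "temperature_C": tc.temperature,
                "replicate": tc.replicate_id,
                "day": t,
                "od": od,
            }
            for tc in records
            for t, od in zip(tc.times, tc.ods)
        ]
        df = pd.DataFrame(rows, columns=list(TIMECOURSE_COLUMNS))
    elif isinstance(first, ViabilityMeasurement):
        rows = []
        for v in records:
            for d, counts in zip(v.dilution_factors, v.spot_counts):
                for ti, c in enumerate(counts, start=1):
                    rows.append(
                        {
                            "strain_id": v.strain_id,
                            "temperature_C": v.temperature,
                            "replicate": v.replicate_id,
                            "dilution_exponent": round(np.log10(d)),
                            "tech_rep": ti,
                            "colonies_or_LAWN": c,
                            "od_end": v.od_end,
                            "spot_volume_ml": v.spot_volume,
                        }
                    )
        df = pd.DataFrame(rows, columns=list(VIABILITY_COLUMNS))
    else:
        raise PanelError(f"unsupported record type {type(first).__name__}")
    df.to_csv(path, index=False)


def read_config(path) -> AnalysisConfig:
    """Read an analysis config from YAML, applying documented defaults."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "loci" not in raw:
        raise ConfigError("config must declare 'loci'")
    loci = []
    for item in raw["loci"]:
        if isinstance(item, str):
            loci.append(Locus(item))
        else:
            loci.append(
                Locus(item["name"], item.get("functional_class", "other"))
            )
    kwargs = dict(
        loci=tuple(loci),
        path_order=tuple(raw.get("path_order", [l.name for l in loci])),
    )
    for key in (
        "recipient_wt_id",
        "donor_wt_id",
        "transgenic_id",
        "n_boot",
        "alpha",
        "ci_level",
        "rng_seed",
        "sidedness",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "temperatures" in raw:
        kwargs["temperatures"] = tuple(float(t) for t in raw["temperatures"])
    try:
        return AnalysisConfig(**kwargs)
    except TypeError as err:
        raise ConfigError(str(err)) from err


def _to_jsonable(x):
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(x).items()}
    if isinstance(x, Genotype):
        return str(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {str(k): _to_jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_to_jsonable(v) for v in x]
    return x


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Flatten a list of stage-result dataclasses into a tidy table.

    Bootstrap arrays are summarized (length only); genotypes become
    bit-strings. An empty result list yields a header-only frame when the
    caller supplies dataclass instances elsewhere, else an empty frame.
    """
    rows = []
    for r in results:
        if not dataclasses.is_dataclass(r):
            raise PanelError("results must be dataclass instances")
        row = {}
        for f in dataclasses.fields(r):
            v = getattr(r, f.name)
            if isinstance(v, np.ndarray):
                row[f"n_{f.name}"] = int(v.size)
            elif isinstance(v, Genotype):
                row[f.name] = str(v)
            elif isinstance(v, tuple) and len(v) == 2 and all(
                isinstance(x, (int, float, np.floating)) for x in v
            ):
                row[f"{f.name}_lo"], row[f"{f.name}_hi"] = float(v[0]), float(v[1])
            elif v is None or isinstance(v, (str, int, float, bool, np.floating, np.integer)):
                row[f.name] = v
            else:
                row[f.name] = str(v)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results, path, columns: Sequence[str] | None = None) -> None:
    """Write a stage's results: tidy CSV table plus a JSON summary document.

    ``results`` may be a DataFrame or a sequence of result dataclasses.
    ``columns`` supplies the header for an empty result set. The JSON
    sidecar (``<path stem>.summary.json``) holds the full nested structure
    (bootstrap arrays excluded) at full float precision.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        df = results
        summary = {"n_rows": int(len(df)), "columns": list(df.columns)}
    else:
        results = list(results)
        df = results_to_frame(results)
        if df.empty and columns is not None:
            df = pd.DataFrame(columns=list(columns))
        summary = {
            "n_rows": len(results),
            "records": [
                {
                    k: v
                    for k, v in _to_jsonable(r).items()
                    if not isinstance(v, list) or len(v) <= 10
                }
                for r in results
            ],
        }
    try:
        df.to_csv(path, index=False)
        with open(path.with_suffix(".summary.json"), "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, default=str)
    except OSError as err:
        raise PanelError(f"cannot write results to {path}: {err}") from err
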