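"""Table and config I/O, run reports, and reproducibility plumbing.

Delimited text dialect is pinned throughout: comma separator, "." decimal,
header row, UTF-8, numerics unquoted.  Run reports are a JSON summary, a
replicate-level CSV and a run log carrying the seed and a hash of the
canonicalized configuration, so identical inputs reproduce identical output
(timestamps excluded by construction — none are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .bias_params import BiasModel
from .effects import EffectSummary
from .engine import EngineConfig, ORDraws, PbamSummary

__all__ = [
    "TableSchema",
    "CaseControlTable",
    "read_table",
    "write_report",
    "load_config",
    "config_hash",
]

logger = logging.getLogger("pbam")

REPORT_FILES = ("summary.json", "replicates.csv", "run_log.json")


@dataclass
class TableSchema:
    """Column declaration for a subject-level case-control table.

    ``value_maps`` optionally maps a column to a recode dictionary (e.g.
    ``{"exposure_observed": {"yes": 1, "no": 0}}``).  ``missing`` is the
    missing-data policy: ``"fail"`` (default) or ``"drop"`` complete-case
    removal with a logged count.
    """

    outcome: str = "outcome"
    exposure: str = "exposure_observed"
    confounders: Mapping[str, str] = field(default_factory=dict)
    value_maps: Mapping[str, Mapping[Any, int]] = field(default_factory=dict)
    missing: str = "fail"


@dataclass
class CaseControlTable:
    """Parsed subject-level records with provenance metadata."""

    data: pd.DataFrame
    schema: TableSchema
    source: str = ""

    @property
    def n_cases(self) -> int:
        return int((self.data[self.schema.outcome] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data[self.schema.outcome] == 0).sum())


def read_table(path: str | Path, schema: TableSchema | None = None) -> CaseControlTable:
    """Read and validate a delimited case-control table.

    Outcome and exposure must be strictly binary after recoding; analysis
    columns must be complete under policy "fail" (offending row numbers are
    reported).  Categorical confounder levels are recorded in order of first
    appearance; group margins are logged.
    """
    schema = schema or TableSchema()
    path = Path(path)
    df = pd.read_csv(path)
    analysis_cols = [schema.outcome, schema.exposure, *schema.confounders]
    missing_cols = [c for c in analysis_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing declared columns {missing_cols}")
    for col, mapping in schema.value_maps.items():
        df[col] = df[col].map(lambda v, m=mapping: m.get(v, v))

    na_rows = df[analysis_cols].isna().any(axis=1)
    if na_rows.any():
        rows = list(np.flatnonzero(na_rows.to_numpy())[:20])
        if schema.missing == "drop":
            logger.info("dropping %d incomplete rows from %s", na_rows.sum(), path)
            df = df[~na_rows].reset_index(drop=True)
        else:
            raise ValueError(
                f"{path}: missing values in analysis columns at rows {rows} "
                f"({int(na_rows.sum())} total; policy 'fail')"
            )
    for col in (schema.outcome, schema.exposure):
        values = set(pd.unique(df[col]))
        if not values <= {0, 1}:
            bad = sorted(v for v in values if v not in (0, 1))
            rows = list(np.flatnonzero(df[col].isin(bad).to_numpy())[:20])
            raise ValueError(f"{path}: column {col!r} not binary 0/1, e.g. "
                             f"values {bad[:5]} at rows {rows}")
        df[col] = df[col].astype(np.int8)
    for col, kind in schema.confounders.items():
        if kind == "categorical":
            df[col] = pd.Categorical(df[col])

    table = CaseControlTable(df, schema, source=str(path))
    logger.info("read %s: %d cases / %d controls, %d columns",
                path, table.n_cases, table.n_controls, df.shape[1])
    return table


def _canonical(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _canonical(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config: Any) -> str:
    """SHA-256 over the canonical JSON form of any (nested) configuration."""
    payload = json.dumps(_canonical(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def write_report(
    out_dir: str | Path,
    summary: PbamSummary,
    draws: ORDraws,
    effects: EffectSummary | None = None,
    config: Any = None,
    seed: int | None = None,
) -> list[Path]:
    """Write summary.json, replicates.csv and run_log.json to ``out_dir``.

    Re-running with identical inputs reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_obj: dict[str, Any] = {
        "odds_ratio": {
            "point": summary.point,
            "mcsa_low": summary.mcsa_low,
            "mcsa_high": summary.mcsa_high,
        },
        "n_replicates": summary.n_replicates,
        "skipped": summary.skipped,
        "acceptance_rate": draws.acceptance_rate,
    }
    if effects is not None:
        summary_obj["paf_percent"] = {
            "point": effects.paf_point,
            "mcsa_low": effects.paf_low,
            "mcsa_high": effects.paf_high,
        }
        summary_obj["evalue"] = {
            "point": effects.evalue_point,
            "interval_limit": effects.evalue_low,
        }
    paths = [out / name for name in REPORT_FILES]
    paths[0].write_text(json.dumps(summary_obj, indent=2) + "\n", encoding="utf-8")
    pd.DataFrame({
        "adjusted_or": draws.values,
        "pe_case": draws.pe_case,
    }).to_csv(paths[1], index=False, float_format="%.12g")
    run_log = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "n_slots": draws.n_slots,
        "n_replicates": int(len(draws.values)),
        "skipped": draws.skipped,
        "acceptance_rate": draws.acceptance_rate,
    }
    paths[2].write_text(json.dumps(run_log, indent=2) + "\n", encoding="utf-8")
    logger.info("wrote report to %s", out)
    return paths


def load_config(path: str | Path) -> tuple[BiasModel, EngineConfig]:
    """Load a YAML/JSON run configuration.

    Schema::

        bias:
          family: beta                  # triangular | beta | logit_logistic
          differential: true
          correlation: 0.8
          correlate: across_groups      # or within_group
          case:    {sensitivity: {estimate: 0.65, ci: [0.41, 0.89]},
                    specificity: {estimate: 0.93, ci: [0.80, 1.00]}}
          control: {...}                # or `total: {...}` if non-differential
        engine:
          n_bootstrap: 500
          n_monte_carlo: 1000
          include_random_error: true
          seed: 42
          max_redraws: 100000
          confounders: {age: numeric, smoking: categorical, ...}
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    bias = raw.get("bias", {})
    model = BiasModel.from_pooled(
        bias["family"],
        case=bias.get("case"),
        control=bias.get("control"),
        total=bias.get("total"),
        differential=bool(bias.get("differential", False)),
        correlation=float(bias.get("correlation", 0.0)),
        correlate=bias.get("correlate", "across_groups"),
        link=bias.get("link", "identity"),
    )
    eng = raw.get("engine", {})
    config = EngineConfig(
        n_bootstrap=int(eng.get("n_bootstrap", 500)),
        n_monte_carlo=int(eng.get("n_monte_carlo", 1000)),
        confounders=dict(eng.get("confounders", {})),
        include_random_error=bool(eng.get("include_random_error", True)),
        seed=int(eng.get("seed", 0)),
        max_redraws=int(eng.get("max_redraws", 100_000)),
    )
    return model, config
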