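"""CSV readers/writers with schema validation and provenance headers.

All tabular interchange uses headered CSV.  Files written by the package
carry comment lines (``# key: value``) recording the tool version, the
configuration hash and the seed, which every reader skips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clinical import Disorder, PatientRecord
from .kinetics import FitResult, FluorescenceTrace, Ligand

__all__ = [
    "SchemaError",
    "config_hash",
    "provenance_lines",
    "write_csv",
    "read_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "fit_results_frame",
]

TRACE_COLUMNS = ["time_s", "fluorescence", "variant", "ligand", "replicate"]
COHORT_COLUMNS = ["patient_id", "mutation", "onset_days", "disorder"]


class SchemaError(ValueError):
    """Malformed input file (missing columns, bad values, bad ordering)."""


def config_hash(config: Mapping) -> str:
    """Stable sha256 of a configuration mapping (order-insensitive)."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def provenance_lines(seed: Optional[int] = None, cfg_hash: str = "") -> list[str]:
    lines = [f"# gnao1kit {__version__}"]
    if cfg_hash:
        lines.append(f"# config_sha256: {cfg_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_csv(
    frame: pd.DataFrame,
    path: Path | str,
    seed: Optional[int] = None,
    cfg_hash: str = "",
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, cfg_hash):
            fh.write(line + "\n")
        frame.to_csv(fh, index=index)


def read_csv(path: Path | str, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, comment="#", **kwargs)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# traces


def write_trace_csv(
    traces: Iterable[FluorescenceTrace],
    path: Path | str,
    seed: Optional[int] = None,
    cfg_hash: str = "",
) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append((repr(float(t)), repr(float(v)), tr.variant,
                         tr.ligand.value, tr.replicate))
    frame = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    write_csv(frame, path, seed=seed, cfg_hash=cfg_hash)


def read_trace_csv(path: Path | str) -> list[FluorescenceTrace]:
    """Parse a trace CSV into per-(variant, ligand, replicate) traces.

    Validates the schema and strictly-increasing time within each trace;
    violations are reported with the offending data line number.
    """
    path = Path(path)
    frame = read_csv(path)
    _require_columns(frame, TRACE_COLUMNS, path)
    try:
        frame["time_s"] = frame["time_s"].astype(float)
        frame["fluorescence"] = frame["fluorescence"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric time/fluorescence ({exc})") from exc
    if frame[["time_s", "fluorescence"]].isna().any().any():
        bad = int(frame[["time_s", "fluorescence"]].isna().any(axis=1).idxmax())
        raise SchemaError(f"{path}: missing value in data row {bad + 1}")
    traces = []
    for (variant, ligand, replicate), grp in frame.groupby(
        ["variant", "ligand", "replicate"], sort=True
    ):
        t = grp["time_s"].to_numpy()
        steps = np.diff(t)
        if np.any(steps <= 0):
            row = int(grp.index[int(np.argmax(steps <= 0)) + 1])
            raise SchemaError(
                f"{path}: time not strictly increasing for trace "
                f"({variant}, {ligand}, {replicate}) at data row {row + 1}"
            )
        traces.append(
            FluorescenceTrace(
                times=t,
                values=grp["fluorescence"].to_numpy(),
                ligand=Ligand(ligand),
                variant=str(variant),
                replicate=int(replicate),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# cohorts


def write_cohort_csv(
    records: Iterable[PatientRecord],
    path: Path | str,
    seed: Optional[int] = None,
    cfg_hash: str = "",
) -> None:
    frame = pd.DataFrame(
        [(r.patient_id, r.mutation, r.onset_days, r.disorder.value) for r in records],
        columns=COHORT_COLUMNS,
    )
    write_csv(frame, path, seed=seed, cfg_hash=cfg_hash)


def read_cohort_csv(path: Path | str) -> list[PatientRecord]:
    path = Path(path)
    frame = read_csv(path)
    _require_columns(frame, COHORT_COLUMNS, path)
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    mutation=str(row["mutation"]),
                    onset_days=int(row["onset_days"]),
                    disorder=Disorder(row["disorder"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{path}: bad record at data row {i + 1}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# phenotype tables


def write_phenotype_csv(
    table: pd.DataFrame,
    path: Path | str,
    seed: Optional[int] = None,
    cfg_hash: str = "",
) -> None:
    write_csv(table.reset_index(), path, seed=seed, cfg_hash=cfg_hash)


def read_phenotype_csv(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    frame = read_csv(path)
    _require_columns(frame, ["variant", "onset_median_days"], path)
    if frame["variant"].duplicated().any():
        dup = frame.loc[frame["variant"].duplicated(), "variant"].iloc[0]
        raise SchemaError(f"{path}: duplicate variant {dup!r}")
    return frame.set_index("variant")


# ---------------------------------------------------------------------------
# fit results


def fit_results_frame(results: Mapping[tuple[str, str], FitResult]) -> pd.DataFrame:
    """Flatten {(variant, ligand): FitResult} into the fitted-constants table."""
    rows = []
    for (variant, ligand), res in sorted(results.items()):
        rows.append(
            dict(
                variant=variant,
                ligand=ligand,
                **{
                    "k_bind_s-1": res.params.k_bind,
                    "k_hydr_s-1": res.params.k_hydr,
                },
                amplitude=res.params.amplitude,
                baseline=res.params.baseline,
                method=res.method.value,
                activity=res.activity.value,
                rmse=res.rmse,
                converged=res.converged,
            )
        )
    return pd.DataFrame(rows)
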