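"""File formats and run reporting.

Plain-text formats only:

* rate table CSV — ``shift,respiratory_type,arrival_rate_per_min,mean_duration_min``
* mix distribution JSON — ``{"occupancy_pmf": {...}, "type_probs": {...}}``
* staffing plan JSON — ``{"fixed": {...}}`` or ``{"flexible": {...}}``
* observation CSV + per-day context CSV (work-sampling records)
* census CSV — one row per day with per-type patient counts

Every reporting helper writes a run manifest (inputs, seeds, resolved
configuration) next to its outputs so staffing recommendations stay
auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import CareSegment, ObservationInterval
from .mix import RESPIRATORY_TYPES, MixDistribution, RateTable
from .policy import FixedPlan, FlexiblePlan, PolicyConfig, StaffingPlan
from .queueing import VariabilityParams

__all__ = [
    "load_rate_table",
    "write_rate_table",
    "load_mix_distribution",
    "write_mix_distribution",
    "load_plan",
    "write_observation_study",
    "read_observations",
    "write_census",
    "read_census",
    "frontier_frame",
    "report",
]


def load_rate_table(path) -> RateTable:
    """Load and validate a 12-cell rate-table CSV."""
    return RateTable.from_csv(path)


def write_rate_table(table: RateTable, path) -> None:
    table.to_csv(path)


def load_mix_distribution(path) -> MixDistribution:
    return MixDistribution.from_json(path)


def write_mix_distribution(dist: MixDistribution, path) -> None:
    dist.to_json(path)


def load_plan(path, table: RateTable | None = None) -> StaffingPlan:
    """Load a staffing-plan JSON: a fixed per-shift map or a flexible rule.

    Flexible plans need the ``table`` argument; recognised flexible keys
    are the :class:`PolicyConfig` fields (``threshold_min``,
    ``min_staff``, ``max_staff``, ``night_model``, ``cv_arrival``,
    ``cv_service``, ...).
    """
    with open(path) as fh:
        payload = json.load(fh)
    if "fixed" in payload:
        return FixedPlan({k: int(v) for k, v in payload["fixed"].items()})
    if "flexible" in payload:
        if table is None:
            raise ValueError("a flexible plan needs a rate table")
        params = dict(payload["flexible"])
        var = VariabilityParams(
            params.pop("cv_arrival", 1.0), params.pop("cv_service", 1.0)
        )
        params.pop("deviation_cap", None)  # handled by the caller via --cap
        config = PolicyConfig(variability=var, **params)
        return FlexiblePlan(table, config)
    raise ValueError("plan JSON must contain a 'fixed' or 'flexible' entry")


def write_observation_study(
    observations: pd.DataFrame, context: pd.DataFrame, out_dir
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obs_path = out_dir / "observations.csv"
    ctx_path = out_dir / "context.csv"
    observations.to_csv(obs_path, index=False)
    context.to_csv(ctx_path, index=False)
    return obs_path, ctx_path


def read_observations(obs_path, ctx_path) -> list[ObservationInterval]:
    """Parse observation + context CSVs into validated observation intervals."""
    obs = pd.read_csv(obs_path)
    ctx = pd.read_csv(ctx_path).set_index(["day", "shift"])
    intervals: dict[tuple, ObservationInterval] = {}
    for _, row in obs.iterrows():
        key = (row["day"], row["shift"], row["nurse_id"], row["interval_start"])
        if key not in intervals:
            try:
                context_row = ctx.loc[(row["day"], row["shift"])]
            except KeyError as exc:
                raise ValueError(
                    f"no context for day {row['day']} shift {row['shift']}"
                ) from exc
            intervals[key] = ObservationInterval(
                day=int(row["day"]),
                shift=str(row["shift"]),
                nurse_id=str(row["nurse_id"]),
                start_min=float(row["interval_start"]),
                length_min=float(row["interval_len_min"]),
                nurses_on_duty=float(context_row["nurses_on_duty"]),
                patients={
                    t: float(context_row[f"n_{t}"]) for t in RESPIRATORY_TYPES
                },
            )
        if pd.isna(row["segment_start"]):
            continue
        intervals[key].segments.append(
            CareSegment(
                patient_type=str(row["patient_type"]),
                start_min=float(row["segment_start"]),
                end_min=float(row["segment_end"]),
                left_censored=bool(row["left_censored"]),
                right_censored=bool(row["right_censored"]),
                category=str(row["category"]),
                patient_id=str(row.get("patient_id", "")),
            )
        )
    result = list(intervals.values())
    for iv in result:
        iv.validate_segments()
    return result


def write_census(census: pd.DataFrame, path) -> None:
    census.to_csv(path)


def read_census(path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("day")


def frontier_frame(results) -> pd.DataFrame:
    """Tabulate frontier evaluation results, sorted by expected nurse-hours."""
    rows = [
        {
            "threshold_min": r.threshold_min,
            "expected_hours": r.expected_nurse_hours,
            "expected_tuca": r.expected_tuca,
            "relative_hours": r.relative_hours,
            "relative_tuca": r.relative_tuca,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values("expected_hours").reset_index(drop=True)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report(results: dict, out_dir, config: dict | None = None) -> Path:
    """Write results as JSON (CSV for DataFrames) plus a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            path = out_dir / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(_jsonable(obj), fh, indent=2)
        written.append(path.name)
    manifest = {
        "outputs": written,
        "config": _jsonable(config or {}),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
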