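"""Delimited-text serialization, run manifests, and the end-to-end pipeline.

All tabular outputs are UTF-8 CSV with '.' decimals (locale-independent);
configs and cohort specs are YAML or JSON. Event logs use one row per event:

    rat_id, sex, session_index, cod_s, event_index, time_s, event_type,
    patch_side, volume_ul, termination_reason

with times in seconds to >= 3 decimals and volumes in uL. Reading validates
the schema and the session-log invariants and round-trips bit-identically
with writing.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cohort import CohortSpec, StudyResult, run_study
from .simulator import EVENT_TYPES, Event, SessionLog
from .task_core import TaskConfig

__all__ = ["read_event_log", "write_event_log", "RunManifest", "pipeline"]

logger = logging.getLogger(__name__)

LOG_COLUMNS = ["rat_id", "sex", "session_index", "cod_s", "event_index",
               "time_s", "event_type", "patch_side", "volume_ul",
               "termination_reason"]


def _fmt(x: float, decimals: int = 6) -> str:
    return f"{x:.{decimals}f}"


def write_event_log(logs: Sequence[SessionLog], path: str | Path) -> None:
    """Write session logs as one flat CSV (header above)."""
    lines = [",".join(LOG_COLUMNS)]
    for log in logs:
        for e in log.events:
            lines.append(",".join([
                log.rat_id,
                log.sex,
                str(log.session_index),
                _fmt(log.cod, 3),
                str(e.index),
                _fmt(e.time),
                e.event_type,
                e.patch_side or "",
                _fmt(e.volume) if e.volume is not None else "",
                log.termination_reason or "",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_log(
    path: str | Path, config: TaskConfig | None = None, validate: bool = True
) -> list[SessionLog]:
    """Parse an event-log CSV back into :class:`SessionLog` objects.

    Schema violations raise with the offending row and field named; with
    ``validate`` the structural invariants (ordering, schedule conformity
    when a config is given) are checked per session.
    """
    df = pd.read_csv(path, dtype={"rat_id": str, "patch_side": str,
                                  "termination_reason": str})
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    logs: list[SessionLog] = []
    for (rat_id, session_index), g in df.groupby(["rat_id", "session_index"], sort=False):
        g = g.sort_values("event_index")
        events = []
        for row in g.itertuples():
            etype = row.event_type
            if etype not in EVENT_TYPES:
                raise ValueError(
                    f"{path} row {row.Index + 2}: unknown event_type {etype!r}")
            vol = None if pd.isna(row.volume_ul) else float(row.volume_ul)
            if etype == "reward" and vol is None:
                raise ValueError(f"{path} row {row.Index + 2}: reward without volume_ul")
            side = None if pd.isna(row.patch_side) or row.patch_side == "" else row.patch_side
            events.append(Event(index=int(row.event_index), time=float(row.time_s),
                                event_type=etype, patch_side=side, volume=vol))
        reason = g["termination_reason"].iloc[-1]
        log = SessionLog(
            rat_id=str(rat_id),
            sex=str(g["sex"].iloc[0]),
            session_index=int(session_index),
            cod=float(g["cod_s"].iloc[0]),
            events=events,
            termination_reason=None if pd.isna(reason) else str(reason),
        )
        if validate:
            log.validate(config)
        logs.append(log)
    return logs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    seed: int
    config_hash: str
    spec_hash: str
    stages: dict = field(default_factory=dict)  # stage -> ISO timestamp
    files: dict = field(default_factory=dict)  # relative path -> sha256

    def write(self, out_dir: Path) -> Path:
        """Atomic write (temp file + rename) of manifest.json."""
        target = out_dir / "manifest.json"
        tmp = out_dir / "manifest.json.tmp"
        tmp.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        os.replace(tmp, target)
        return target


def _hash_obj(obj: dict) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest, root: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.files[str(path.relative_to(root))] = _sha256(path)


def pipeline(
    config: TaskConfig,
    cohort_spec: CohortSpec,
    seed: int,
    out_dir: str | Path,
    write_logs: bool = False,
) -> RunManifest:
    """simulate -> metrics -> fits -> stats, all artifacts to ``out_dir``.

    ``seed`` overrides the spec's seed so a run is fully determined by
    (config, spec, seed); re-running reproduces every checksum. Event logs
    are bulky and only written on request.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(**{**cohort_spec.to_dict(), "seed": int(seed)})
    manifest = RunManifest(
        version=__version__, seed=int(seed),
        config_hash=_hash_obj(config.to_dict()), spec_hash=_hash_obj(spec.to_dict()),
    )
    try:
        config.to_file(out / "task_config.yaml")
        spec.to_file(out / "cohort_spec.yaml")
        manifest.files["task_config.yaml"] = _sha256(out / "task_config.yaml")
        manifest.files["cohort_spec.yaml"] = _sha256(out / "cohort_spec.yaml")

        result: StudyResult = run_study(spec, config, keep_logs=write_logs)
        manifest.stages["simulate_and_metrics"] = _now()
        if write_logs:
            all_logs = [log for logs in result.logs_by_rat.values() for log in logs]
            write_event_log(all_logs, out / "event_logs.csv")
            manifest.files["event_logs.csv"] = _sha256(out / "event_logs.csv")

        _write_csv(result.metrics, out / "metrics.csv", manifest, out)
        _write_csv(result.fits, out / "fits.csv", manifest, out)
        manifest.stages["fits"] = _now()
        _write_csv(result.scores, out / "composite_scores.csv", manifest, out)
        _write_csv(result.delay_curves, out / "delay_curves.csv", manifest, out)
        _write_csv(result.harvest_freq, out / "harvest_frequencies.csv", manifest, out)
        for sex in ("male", "female"):
            _write_csv(result.correlations[sex].reset_index(names="variable"),
                       out / f"correlations_{sex}.csv", manifest, out)
            _write_csv(result.comparisons[sex], out / f"meng_z_{sex}.csv", manifest, out)
        for dv, table in result.anova.items():
            _write_csv(table, out / f"anova_{dv}.csv", manifest, out)
            _write_csv(result.posthoc[dv]["between"],
                       out / f"posthoc_between_{dv}.csv", manifest, out)
            _write_csv(result.posthoc[dv]["within"],
                       out / f"posthoc_within_{dv}.csv", manifest, out)
        manifest.stages["stats"] = _now()
    finally:
        # a failed stage still leaves a partial manifest for diagnosis
        manifest.write(out)
    return manifest
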