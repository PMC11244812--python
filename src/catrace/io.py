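"""File formats, configuration, and the end-to-end pipeline driver.

Formats are plain text wherever practical: trace matrices as TSV (frames x
neurons, a ``#``-prefixed metadata line, then a header row of neuron IDs)
or HDF5 with the same metadata as attributes; behavior as ``state start_s
end_s`` TSV with half-open 0-based intervals; events, records and ratio
reports as TSV with headers.  Every output the pipeline writes can be read
back by the readers in this module.
"""

from __future__ import annotations

import csv
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (FREEZING, NONFREEZING, STATES, BehaviorTrack, FormatError,
                   InvalidConfigError, TraceMatrix)
from .counts import overlap_ratios, validate_count_table
from .events import DetectionParams, auc_table, detect_transients, events_to_frame
from .population import (chi2_proportion_test, classify_activity,
                         composition_table, records_from_session)
from .selectivity import classify_population
from .traces import BaselineParams, process_traces

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# trace matrices

def write_trace_matrix(trace: TraceMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("traces", data=trace.values)
            d.attrs["frame_rate_hz"] = trace.frame_rate_hz
            d.attrs["stage"] = trace.stage
            d.attrs["neuron_ids"] = list(trace.neuron_ids)
        return
    with open(path, "w", newline="") as f:
        f.write(f"# frame_rate_hz={trace.frame_rate_hz!r} stage={trace.stage}\n")
        w = csv.writer(f, delimiter="\t", lineterminator="\n")
        w.writerow(trace.neuron_ids)
        for row in trace.values:
            w.writerow([repr(float(v)) for v in row])


def read_trace_matrix(path: str | Path, frame_rate_hz: float | None = None,
                      assume_default_rate: bool = False) -> TraceMatrix:
    """Read a trace matrix from TSV or HDF5.

    The frame rate must come from file metadata or ``frame_rate_hz``;
    falling back to 10 Hz requires the explicit ``assume_default_rate``
    flag.  Malformed text files fail with the offending line and field
    named.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f["traces"]
            values = d[...]
            rate = float(d.attrs.get("frame_rate_hz", 0)) or frame_rate_hz
            stage = str(d.attrs.get("stage", "raw"))
            ids = tuple(str(s) for s in d.attrs.get("neuron_ids", ()))
        if not rate:
            rate = _fallback_rate(path, assume_default_rate)
        return TraceMatrix(values, frame_rate_hz=rate, stage=stage, neuron_ids=ids)

    stage = "raw"
    rate = frame_rate_hz
    with open(path) as f:
        first = f.readline()
        lineno = 1
        if first.startswith("#"):
            meta = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
            if "frame_rate_hz" in meta:
                rate = float(meta["frame_rate_hz"])
            stage = meta.get("stage", "raw")
            header = f.readline().rstrip("\n")
            lineno = 2
        else:
            header = first.rstrip("\n")
        ids = tuple(header.split("\t"))
        rows = []
        for line in f:
            lineno += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(ids):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(ids)} fields, got {len(fields)}")
            row = []
            for col, tok in enumerate(fields):
                try:
                    v = float(tok)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {tok!r} in column "
                        f"{ids[col]!r}") from None
                if not np.isfinite(v):
                    raise FormatError(
                        f"{path}:{lineno}: non-finite value {tok!r} in column "
                        f"{ids[col]!r}")
                row.append(v)
            rows.append(row)
    if rate is None:
        rate = _fallback_rate(path, assume_default_rate)
    return TraceMatrix(np.array(rows), frame_rate_hz=rate, stage=stage, neuron_ids=ids)


def _fallback_rate(path: Path, assume_default: bool) -> float:
    if assume_default:
        logger.warning("%s: no frame rate in file; assuming 10 Hz", path)
        return 10.0
    raise FormatError(
        f"{path}: frame rate missing; pass frame_rate_hz or assume_default_rate=True")


# ---------------------------------------------------------------------------
# behavior tracks

def write_behavior(behavior: BehaviorTrack, path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t", lineterminator="\n")
        w.writerow(["state", "start_s", "end_s"])
        for state, s, e in behavior.bouts:
            w.writerow([state, repr(float(s)), repr(float(e))])


def read_behavior_intervals(path: str | Path, fill_gaps: bool = False
                            ) -> BehaviorTrack:
    """Read a ``state start_s end_s`` TSV into a validated BehaviorTrack.

    Rows are sorted by start time before validation.  Gaps between bouts
    are an error unless ``fill_gaps`` is set, in which case they become
    non-freezing bouts.
    """
    path = Path(path)
    rows: list[tuple[str, float, float]] = []
    with open(path) as f:
        reader = csv.reader(f, delimiter="\t")
        for lineno, rec in enumerate(reader, start=1):
            if not rec or rec[0].startswith("#"):
                continue
            if lineno == 1 and rec[0] == "state":
                continue
            if len(rec) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(rec)}")
            state, s_tok, e_tok = rec
            if state not in STATES:
                raise FormatError(f"{path}:{lineno}: unknown state {state!r}")
            try:
                s, e = float(s_tok), float(e_tok)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric interval") from None
            if s < 0 or e <= s:
                raise FormatError(f"{path}:{lineno}: bad interval [{s}, {e})")
            rows.append((state, s, e))
    if not rows:
        raise FormatError(f"{path}: no intervals")
    rows.sort(key=lambda r: r[1])
    filled: list[tuple[str, float, float]] = []
    t = 0.0
    for state, s, e in rows:
        if s > t + 1e-9:
            if not fill_gaps:
                raise FormatError(f"{path}: gap in coverage at [{t}, {s})")
            filled.append((NONFREEZING, t, s))
        elif s < t - 1e-9:
            raise FormatError(f"{path}: overlapping intervals at {s} < {t}")
        filled.append((state, s, e))
        t = e
    return BehaviorTrack(tuple(filled))


# ---------------------------------------------------------------------------
# labels / ground truth / counts

def write_labels(neuron_ids, engram_labels, path: str | Path,
                 selectivity_labels=None) -> None:
    df = pd.DataFrame({"neuron_id": list(neuron_ids),
                       "engram": [int(b) for b in engram_labels]})
    if selectivity_labels is not None:
        df["selectivity"] = list(selectivity_labels)
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"neuron_id": str})
    if "neuron_id" not in df.columns or "engram" not in df.columns:
        raise FormatError(f"{path}: need neuron_id and engram columns")
    df["engram"] = df["engram"].astype(bool)
    return df


def read_count_table(path: str | Path) -> pd.DataFrame:
    return validate_count_table(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# pipeline configuration and driver

@dataclass
class PipelineConfig:
    """Everything one ``run`` needs; file paths plus analysis parameters."""

    traces: str
    behavior: str | None = None
    labels: str | None = None
    counts: str | None = None
    out_dir: str = "catrace_out"
    baseline: BaselineParams = field(default_factory=BaselineParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    analysis_stage: str = "standardized"   # trace used for AUC + selectivity
    n_iter: int = 10_000
    alpha: float = 0.01
    active_fraction: float = 0.10
    seed: int = 0
    frame_rate_hz: float | None = None
    assume_default_rate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must be in (0, 1)")
        if not 0.0 < self.active_fraction < 1.0:
            raise InvalidConfigError("active_fraction must be in (0, 1)")
        if self.n_iter < 99:
            raise InvalidConfigError("n_iter must be >= 99")
        if self.analysis_stage not in ("standardized", "zscored"):
            raise InvalidConfigError("analysis_stage must be standardized or zscored")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("baseline"), dict):
            raw["baseline"] = BaselineParams(**raw["baseline"])
        if isinstance(raw.get("detection"), dict):
            raw["detection"] = DetectionParams(**raw["detection"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute process -> detect -> rank -> composition -> selectivity.

    Writes all intermediate tables under ``config.out_dir`` plus a
    machine-readable ``summary.json`` and a ``run.log`` echoing versions,
    seed and parameters.  Reruns with identical inputs and seed produce
    bit-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"catrace {__version__} python {platform.python_version()} "
        f"numpy {np.__version__}",
        f"seed={config.seed}",
        f"config={json.dumps(asdict(config), default=str, sort_keys=True)}",
    ]
    summary: dict = {"seed": config.seed, "version": __version__}

    def _stage(name):
        log_lines.append(f"stage: {name}")

    try:
        _stage("read")
        raw = read_trace_matrix(config.traces, frame_rate_hz=config.frame_rate_hz,
                                assume_default_rate=config.assume_default_rate)

        _stage("process")
        stages = process_traces(raw, config.baseline,
                                t_half_s=config.detection.t_half_s)
        write_trace_matrix(stages["dff"], out / "dff.tsv")
        write_trace_matrix(stages["standardized"], out / "standardized.tsv")
        write_trace_matrix(stages["zscored"], out / "zscored.tsv")
        analysis = stages[config.analysis_stage]

        _stage("detect")
        events = detect_transients(analysis, config.detection)
        events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
        auc = auc_table(analysis, events)
        summary["n_events"] = len(events)

        _stage("classify-activity")
        if config.labels:
            labels = read_labels(config.labels).set_index("neuron_id")
            engram = labels.loc[list(analysis.neuron_ids), "engram"].to_numpy()
        else:
            engram = np.zeros(analysis.n_neurons, dtype=bool)
        records = records_from_session(auc, engram)
        classify_activity(records, config.active_fraction)

        if config.labels:
            _stage("composition")
            table = composition_table(records)
            table.to_csv(out / "composition.tsv", sep="\t")
            if (table.to_numpy().sum(axis=0) > 0).all():
                stat, p = chi2_proportion_test(table.to_numpy())
                summary["composition_chi2"] = {"statistic": stat, "p_value": p}

        _stage("selectivity")
        sel_rows = []
        if config.behavior:
            behavior = read_behavior_intervals(config.behavior)
            results = classify_population(analysis, behavior,
                                          n_iter=config.n_iter,
                                          alpha=config.alpha, seed=config.seed)
            by_id = {r.neuron_id: r for r in results}
            for rec in records:
                rec.selectivity_class = by_id[rec.neuron_id].selectivity_class
            sel_rows = [{"neuron_id": r.neuron_id,
                         "observed_diff": r.observed_diff,
                         "p_value": r.p_value,
                         "selectivity_class": r.selectivity_class}
                        for r in results]
            pd.DataFrame(sel_rows).to_csv(out / "selectivity.tsv", sep="\t",
                                          index=False)
            summary["n_freezing"] = sum(
                1 for r in results if r.selectivity_class == FREEZING)

        rec_df = pd.DataFrame([{
            "neuron_id": r.neuron_id, "engram": int(r.engram),
            "auc_per_sec": r.auc_per_sec, "activity_class": r.activity_class,
            "selectivity_class": r.selectivity_class or ""} for r in records])
        rec_df.to_csv(out / "records.tsv", sep="\t", index=False)
        summary["n_active"] = int((rec_df["activity_class"] == "active").sum())
        summary["n_neurons"] = len(rec_df)

        if config.counts:
            _stage("counts")
            counts = read_count_table(config.counts)
            ratios = overlap_ratios(counts)
            ratios.to_csv(out / "ratios.tsv", sep="\t")
            summary["ratio_means"] = {k: float(v) for k, v in ratios.mean().items()}
    except Exception as exc:
        failing = log_lines[-1].removeprefix("stage: ")
        raise RuntimeError(f"pipeline failed at stage {failing!r}: {exc}") from exc

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
        f.write("\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
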