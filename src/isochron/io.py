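"""Formats, run configuration, and end-to-end pipeline orchestration.

Everything is plain text: interval tables and traces as CSV, per-set
statistics as TSV, fit reports as JSON.  ``run_pipeline`` chains the
stages — simulate (or read) interval series, assign tempo ranks, compute
per-set variability and windowed-autocorrelation statistics, fit the
variance models — and collects the result tables into a
:class:`ReportBundle` whose on-disk form is byte-stable for a fixed seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .kinematics import ExtractionConfig
from .series import AccelTrace, CASES, IntervalSeries
from .stats import (
    classify_timing_mode,
    coefficient_of_variation,
    differential_percent,
    summarize_wgamma,
    windowed_lag_one,
)
from .synthetic import StudyDesign, gen_study
from .tempo import SPEED_THRESHOLD_MS, assign_rank, classify_speed
from .variance import (
    fit_hetero_lmm,
    fit_wgamma_anova,
    lrt_heteroscedasticity,
)

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = [
    "subject",
    "case",
    "condition",
    "tempo_ms_expected",
    "set_index",
    "interval_index",
    "duration_ms",
    "regime_label",
]

TRACE_COLUMNS = ["t_s", "ax", "ay", "az"]

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Interval and trace CSV round trips
# ---------------------------------------------------------------------------


def series_to_frame(series: List[IntervalSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        labels = (
            s.regime_labels
            if s.regime_labels is not None
            else np.full(len(s), "", dtype=object)
        )
        for i, (d, lab) in enumerate(zip(s.durations_ms, labels)):
            rows.append(
                (s.subject, s.case, s.condition, s.expected_ms, s.set_index, i, d, lab)
            )
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_intervals(series: List[IntervalSeries], path: Union[str, Path]) -> None:
    """Write interval series to CSV (one row per interval)."""
    series_to_frame(series).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_intervals(path: Union[str, Path]) -> List[IntervalSeries]:
    """Read and validate an interval CSV back into series objects.

    Malformed rows are reported with their (1-based, header-inclusive)
    line numbers.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    missing = [c for c in INTERVAL_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    dur = pd.to_numeric(df["duration_ms"], errors="coerce")
    bad = df.index[~(dur > 0)].tolist()
    if bad:
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValidationError(
            f"{path}: non-positive or non-numeric duration_ms at line(s) {lines}"
        )
    df["duration_ms"] = dur

    out: List[IntervalSeries] = []
    keys = ["subject", "case", "condition", "tempo_ms_expected", "set_index"]
    for (subject, case, condition, tempo, set_index), grp in df.groupby(
        keys, dropna=False, sort=True
    ):
        grp = grp.sort_values("interval_index")
        labels = None
        if "regime_label" in grp.columns and grp["regime_label"].notna().any():
            labels = grp["regime_label"].fillna("").to_numpy(dtype=object)
        out.append(
            IntervalSeries(
                grp["duration_ms"].to_numpy(dtype=float),
                subject=str(subject),
                case=str(case),
                condition=str(condition),
                expected_ms=None if pd.isna(tempo) else float(tempo),
                set_index=int(set_index),
                regime_labels=labels,
            )
        )
    return out


def write_trace(trace: AccelTrace, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "t_s": trace.t_s,
            "ax": trace.channels[:, 0],
            "ay": trace.channels[:, 1],
            "az": trace.channels[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")


def read_trace(path: Union[str, Path]) -> AccelTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError(f"{path}: trace needs at least 2 samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return AccelTrace(
        t_s=t,
        channels=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        sample_rate_hz=rate,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``intervals_path`` reads an existing interval CSV; otherwise a study is
    simulated from ``design`` with ``seed``.
    """

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    intervals_path: Optional[str] = None
    window_length: int = 30
    wgamma_step: int = 1
    nested_mean: bool = False
    speed_threshold_ms: float = SPEED_THRESHOLD_MS
    mode_threshold_pct: float = 60.0
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    def __post_init__(self) -> None:
        if self.speed_threshold_ms <= 0:
            raise ValidationError("speed_threshold_ms must be positive")
        if self.window_length < 3:
            raise ValidationError("window_length must be at least 3")
        if self.intervals_path is not None and not Path(self.intervals_path).exists():
            raise ValidationError(f"intervals_path does not exist: {self.intervals_path}")

    @classmethod
    def from_dict(cls, cfg: Dict) -> "RunConfig":
        cfg = dict(cfg)
        if "design" in cfg and isinstance(cfg["design"], dict):
            d = dict(cfg["design"])
            for k in ("conditions", "reference_tempi_ms", "cases"):
                if k in d:
                    d[k] = tuple(d[k])
            cfg["design"] = StudyDesign(**d)
        if "extraction" in cfg and isinstance(cfg["extraction"], dict):
            cfg["extraction"] = ExtractionConfig(**cfg["extraction"])
        return cls(**cfg)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance."""

    set_stats: pd.DataFrame
    cv_by_range: pd.DataFrame
    wgamma_by_range: pd.DataFrame
    differential: pd.DataFrame
    fits: Dict
    provenance: Dict

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.set_stats.to_csv(outdir / "set_stats.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        self.cv_by_range.to_csv(outdir / "cv_by_range.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        self.wgamma_by_range.to_csv(outdir / "wgamma_by_range.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        self.differential.to_csv(outdir / "differential_percent.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        (outdir / "fits.json").write_text(json.dumps(self.fits, indent=2, sort_keys=True))
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=2, sort_keys=True))


def observations_from_series(
    series: List[IntervalSeries], speed_threshold_ms: float = SPEED_THRESHOLD_MS
) -> pd.DataFrame:
    """Build the per-interval observation table for the variance models."""
    rows = []
    for s in series:
        set_id = f"{s.subject}|{s.case}|{s.condition}|{s.expected_ms}|{s.set_index}"
        ref = s.expected_ms if s.expected_ms is not None else s.mean_ms
        speed = classify_speed(ref, speed_threshold_ms)
        for resp in s.errors_s():
            rows.append(
                (s.subject, set_id, s.case, s.condition, int(s.case == "KTT"), speed, resp)
            )
    return pd.DataFrame(
        rows, columns=["subject", "set", "case", "condition", "ktt", "speed", "response_s"]
    )


def per_set_stats(
    series: List[IntervalSeries], config: RunConfig
) -> Tuple[pd.DataFrame, Dict[int, np.ndarray]]:
    """Per-set CV, windowed wg1 summary, and timing-mode label.

    Sets shorter than ``window_length + 1`` get CV only, with a warning;
    the pipeline keeps running.  Returns the table plus the raw windowed
    values per table row (for condition-level pooling).
    """
    rows = []
    pooled: Dict[int, np.ndarray] = {}
    skipped = 0
    for s in series:
        ref = s.expected_ms if s.expected_ms is not None else s.mean_ms
        row = {
            "subject": s.subject,
            "case": s.case,
            "condition": s.condition,
            "tempo_ms_expected": s.expected_ms,
            "set_index": s.set_index,
            "rank": assign_rank(s.mean_ms),
            "speed": classify_speed(ref, config.speed_threshold_ms),
            "n": len(s),
            "mean_ms": s.mean_ms,
            "cv_pct": coefficient_of_variation(s) if len(s) >= 2 else np.nan,
        }
        if len(s) >= config.window_length + 1:
            w = windowed_lag_one(
                s,
                window_length=config.window_length,
                step=config.wgamma_step,
                nested_mean=config.nested_mean,
            )
            summ = summarize_wgamma(w, window_length=config.window_length)
            row.update(
                mean_wgamma=summ.mean_wgamma,
                mean_wgamma_raw=summ.mean_wgamma_raw,
                mean_z=summ.mean_z,
                pct_positive=summ.pct_positive,
                pct_negative=summ.pct_negative,
                n_windows=summ.n_windows,
                mode=classify_timing_mode(summ, config.mode_threshold_pct),
            )
            pooled[len(rows)] = w
        else:
            skipped += 1
            row.update(
                mean_wgamma=np.nan,
                mean_wgamma_raw=np.nan,
                mean_z=np.nan,
                pct_positive=np.nan,
                pct_negative=np.nan,
                n_windows=0,
                mode="",
            )
        rows.append(row)
    if skipped:
        logger.warning(
            "%d set(s) shorter than window %d + 1; wg1 skipped for them",
            skipped,
            config.window_length,
        )
    return pd.DataFrame(rows), pooled


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and return the report bundle."""
    if config.intervals_path is not None:
        series = read_intervals(config.intervals_path)
        logger.info("read %d interval series from %s", len(series), config.intervals_path)
    else:
        study = gen_study(config.design, config.seed)
        series = study.series
        logger.info("simulated %d interval series (seed %d)", len(series), config.seed)

    stats_df, pooled = per_set_stats(series, config)
    logger.info("per-set statistics: %d sets", len(stats_df))

    cv_by_range = (
        stats_df.dropna(subset=["rank"])
        .groupby(["condition", "case", "rank"], sort=True)
        .agg(n_sets=("cv_pct", "size"), cv_pct=("cv_pct", "mean"))
        .reset_index()
    )
    wg = stats_df.dropna(subset=["mean_wgamma"])
    wgamma_by_range = (
        wg.dropna(subset=["rank"])
        .groupby(["condition", "case", "rank"], sort=True)
        .agg(
            n_sets=("mean_wgamma", "size"),
            mean_wgamma=("mean_wgamma", "mean"),
            pct_positive=("pct_positive", "mean"),
            pct_negative=("pct_negative", "mean"),
        )
        .reset_index()
    )

    # condition-level pooled percentages of positive windowed values
    diff_rows = []
    for condition in sorted(stats_df["condition"].unique()):
        pcts = {}
        for case in CASES:
            idx = stats_df.index[
                (stats_df["condition"] == condition) & (stats_df["case"] == case)
            ]
            values = [pooled[i] for i in idx if i in pooled]
            if not values:
                continue
            allw = np.concatenate(values)
            pcts[case] = 100.0 * np.count_nonzero(allw > 0) / allw.size
        if len(pcts) == 2 and pcts["N/KTT"] > 0:
            diff, incr = differential_percent(pcts["KTT"], pcts["N/KTT"])
            diff_rows.append(
                {
                    "condition": condition,
                    "pct_positive_nktt": pcts["N/KTT"],
                    "pct_positive_ktt": pcts["KTT"],
                    "differential_pct": diff,
                    "equivalent_increase_pct": incr,
                }
            )
    differential = pd.DataFrame(
        diff_rows,
        columns=[
            "condition",
            "pct_positive_nktt",
            "pct_positive_ktt",
            "differential_pct",
            "equivalent_increase_pct",
        ],
    )

    obs = observations_from_series(series, config.speed_threshold_ms)
    fits: Dict = {}
    for condition in sorted(obs["condition"].unique()):
        sub = obs[obs["condition"] == condition]
        entry: Dict = {}
        try:
            full = fit_hetero_lmm(sub, heteroscedastic=True)
            restricted = fit_hetero_lmm(sub, heteroscedastic=False, compute_ci=False)
            lrt = lrt_heteroscedasticity(restricted, full)
            entry["hetero"] = full.to_dict()
            entry["lrt_vs_homoscedastic"] = {
                "statistic": lrt.statistic,
                "df": lrt.df,
                "p_value": lrt.p_value,
            }
        except Exception as exc:  # noqa: BLE001 - reported per stage
            logger.warning("variance fit failed for %s: %s", condition, exc)
            entry["hetero"] = None
        zdata = wg[wg["condition"] == condition][["subject", "case", "speed", "mean_z"]]
        if len(zdata) and zdata["case"].nunique() == 2:
            zdata = zdata.assign(ktt=(zdata["case"] == "KTT").astype(int), z=zdata["mean_z"])
            try:
                anova = fit_wgamma_anova(zdata)
                entry["wgamma_anova"] = anova.table.reset_index().to_dict(orient="records")
            except Exception as exc:  # noqa: BLE001
                logger.warning("wg1 ANOVA failed for %s: %s", condition, exc)
        fits[condition] = entry

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "n_series": len(series),
        "n_observations": int(len(obs)),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return ReportBundle(
        set_stats=stats_df,
        cv_by_range=cv_by_range,
        wgamma_by_range=wgamma_by_range,
        differential=differential,
        fits=fits,
        provenance=provenance,
    )
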