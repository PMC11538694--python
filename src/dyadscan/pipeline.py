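"""End-to-end orchestration: simulate -> preprocess -> spectra -> coupling
-> directionality -> attention -> statistics, from one validated config.

Every run writes its resolved configuration and seed next to the outputs
(``manifest.json``) and tags every table row with dyad/day/condition, the
seed and the package version, so any number in a results table can be
regenerated bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

import dyadscan
from dyadscan._rng import child_rng
from dyadscan.coupling import interbrain_matrix, pseudo_pair_null
from dyadscan.directionality import dyad_gpdc
from dyadscan.group_stats import exposure_regression, friedman, holm_sidak, logistic_growth_fit, mann_whitney
from dyadscan.preprocess import preprocess_dyad, train_artifact_ann
from dyadscan.spectral import session_region_series, session_tbr
from dyadscan.synthetic import CONDITIONS, StudyDesign, build_study
from dyadscan.validation import labeled_segment_pool

logger = logging.getLogger(__name__)


class StudyConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    n_dyads: int = Field(default=2, ge=1)
    days: int = Field(default=5, ge=1)
    conditions: tuple[str, ...] = CONDITIONS
    duration: float = Field(default=60.0, ge=10.0)
    fs: float = Field(default=500.0, ge=200.0)
    strength: float = Field(default=0.5, ge=0.0, le=1.0)
    lag: int = Field(default=500, ge=0)
    leader: str = "human"
    channels_per_region: int = Field(default=4, ge=1)
    artifact_contamination: float = Field(default=0.0, ge=0.0, le=0.5)
    attention_theta_gain: float = Field(default=0.7, gt=0.0)
    schedule: str = "logistic"  # day schedule of coupling: logistic | constant
    seed: int = 0
    amplitude_threshold_uv: float = Field(default=300.0, gt=0.0)
    lowpass_cutoff_hz: float = Field(default=245.0, gt=0.0)
    gpdc_band: tuple[float, float] = (0.01, 0.4)
    gpdc_min_windows: int = Field(default=48, ge=30)
    gpdc_pmax: int = Field(default=8, ge=1)

    @field_validator("schedule")
    @classmethod
    def _known_schedule(cls, v):
        if v not in ("logistic", "constant"):
            raise ValueError("schedule must be 'logistic' or 'constant'")
        return v

    @field_validator("conditions")
    @classmethod
    def _known_conditions(cls, v):
        unknown = set(v) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}; expected subset of {CONDITIONS}")
        if not v:
            raise ValueError("need at least one condition")
        return v


def _row_tags(session, config: StudyConfig) -> dict:
    return {
        "dyad": session.meta.get("dyad"),
        "day": session.meta.get("day"),
        "condition": session.meta.get("condition"),
        "seed": config.seed,
        "pipeline_version": dyadscan.__version__,
    }


def run_pipeline(config: StudyConfig, out_dir: str | Path) -> dict:
    """Run the full analysis on a simulated study; returns the result
    bundle (DataFrames + stats dict) and writes CSV/JSON tables to
    ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        design = StudyDesign(
            n_dyads=config.n_dyads,
            days=config.days,
            conditions=config.conditions,
            duration=config.duration,
            fs=config.fs,
            strength=config.strength,
            lag=config.lag,
            leader=config.leader,
            attention_theta_gain=config.attention_theta_gain,
            artifact_contamination=config.artifact_contamination,
            channels_per_region=config.channels_per_region,
            schedule=None if config.schedule == "logistic" else (lambda day: 1.0),
        )
        sessions = build_study(design, seed=config.seed)

        stage = "train-artifact-ann"
        classifier = None
        if config.artifact_contamination > 0:
            montage = sessions[0][0].human.montage
            segs, labels = labeled_segment_pool(
                80, seed=int(child_rng(config.seed, "ann-pool").integers(2**31)), montage=montage
            )
            classifier = train_artifact_ann(segs, labels, fs=config.fs, seed=config.seed % (2**31))

        stage = "preprocess"
        cleaned = []
        artifact_rows = []
        for session, truth in sessions:
            clean, reports = preprocess_dyad(
                session,
                classifier=classifier,
                cutoff=config.lowpass_cutoff_hz,
                threshold=config.amplitude_threshold_uv,
            )
            cleaned.append((clean, truth))
            for subject, rep in reports.items():
                artifact_rows.append(
                    {
                        **_row_tags(session, config),
                        "subject": subject,
                        "fraction_removed": rep.fraction_removed,
                        "n_windows": rep.n_windows,
                    }
                )
        pd.DataFrame(artifact_rows).to_csv(out / "artifact_report.csv", index=False)

        stage = "spectra"
        series_rows = []
        all_series = []
        for session, truth in cleaned:
            ser = session_region_series(session)
            all_series.append((session, ser))
            for subject, regions in ser.items():
                for region, values in regions.items():
                    for w, v in enumerate(values):
                        series_rows.append(
                            {
                                **_row_tags(session, config),
                                "subject": subject,
                                "region": region,
                                "window_t": w,
                                "value": v,
                            }
                        )
        pd.DataFrame(series_rows).to_csv(out / "region_series.csv", index=False)

        stage = "coupling"
        tables = []
        for session, ser in all_series:
            tab = interbrain_matrix(ser["human"], ser["dog"], meta=_row_tags(session, config))
            tables.append(tab)
        coupling_table = pd.concat(tables, ignore_index=True)
        coupling_table.to_csv(out / "coupling_table.csv", index=False)

        stage = "pseudo-pair-null"
        null_rows = []
        if config.n_dyads >= 2 and "interaction" in config.conditions:
            for day in range(1, config.days + 1):
                hs, ds = [], []
                for session, ser in all_series:
                    if session.meta["day"] == day and session.meta["condition"] == "interaction":
                        if "frontal" in ser["human"] and "frontal" in ser["dog"]:
                            hs.append(ser["human"]["frontal"])
                            ds.append(ser["dog"]["frontal"])
                if len(hs) >= 2:
                    res = pseudo_pair_null(hs, ds)
                    null_rows.append(
                        {
                            "day": day,
                            "real_mean_r": float(np.nanmean(res.real_r)),
                            "null_mean_r": float(np.nanmean(res.null_r)),
                            "mw_p": res.test.p,
                            "n_real": res.real_r.size,
                            "n_null": res.null_r.size,
                        }
                    )
        pd.DataFrame(null_rows).to_csv(out / "pseudo_pair_null.csv", index=False)

        stage = "directionality"
        gpdc_rows = []
        for session, ser in all_series:
            if session.meta["condition"] != "interaction":
                continue
            for region in ("frontal", "parietal"):
                if region not in ser["human"] or region not in ser["dog"]:
                    continue
                n = min(len(ser["human"][region]), len(ser["dog"][region]))
                if n < config.gpdc_min_windows:
                    logger.warning("session %s: %d windows < %d; GPDC skipped", session.meta, n, config.gpdc_min_windows)
                    continue
                g = dyad_gpdc(
                    ser["human"][region],
                    ser["dog"][region],
                    band=config.gpdc_band,
                    pmax=config.gpdc_pmax,
                    min_windows=config.gpdc_min_windows,
                )
                gpdc_rows.append(
                    {
                        **_row_tags(session, config),
                        "region": region,
                        "gpdc_human_to_dog": g.human_to_dog,
                        "gpdc_dog_to_human": g.dog_to_human,
                        "order": g.order,
                        "stable": g.model.stable,
                    }
                )
        gpdc_table = pd.DataFrame(gpdc_rows)
        gpdc_table.to_csv(out / "gpdc_table.csv", index=False)

        stage = "attention-tbr"
        tbr_rows = []
        baselines: dict[tuple[int, int], dict] = {}
        for session, _ in cleaned:
            if session.meta["condition"] == "same_room":
                raw = session_tbr(session)
                baselines[(session.meta["dyad"], session.meta["day"])] = {
                    subj: {reg: s.mean() for reg, s in regs.items()} for subj, regs in raw.items()
                }
        for session, _ in cleaned:
            key = (session.meta["dyad"], session.meta["day"])
            baseline = baselines.get(key)
            res = session_tbr(session, baseline=baseline)
            for subject, regions in res.items():
                for region, s in regions.items():
                    tbr_rows.append(
                        {
                            **_row_tags(session, config),
                            "subject": subject,
                            "region": region,
                            "mean_tbr": s.mean(),
                            "mean_normalized_tbr": float(np.nanmean(s.normalized_tbr))
                            if s.normalized_tbr is not None
                            else np.nan,
                        }
                    )
        tbr_table = pd.DataFrame(tbr_rows)
        tbr_table.to_csv(out / "tbr_table.csv", index=False)

        stage = "stats"
        stats_report = _stats_battery(coupling_table, gpdc_table, tbr_table, config)
        (out / "stats_report.json").write_text(json.dumps(stats_report, indent=1))

        manifest = {
            "config": json.loads(config.model_dump_json()),
            "seed": config.seed,
            "pipeline_version": dyadscan.__version__,
            "n_sessions": len(sessions),
            "outputs": sorted(p.name for p in out.glob("*.csv")) + ["stats_report.json"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {
        "coupling": coupling_table,
        "gpdc": gpdc_table,
        "tbr": tbr_table,
        "stats": stats_report,
        "manifest": manifest,
    }


def _stats_battery(coupling: pd.DataFrame, gpdc_tab: pd.DataFrame, tbr_tab: pd.DataFrame, config: StudyConfig) -> dict:
    """The standard test battery over the run's endpoint tables."""
    report: dict = {}
    ff = coupling.query("region_human == 'frontal' and region_dog == 'frontal'")
    inter = ff[ff.condition == "interaction"]

    # Friedman across days (interaction condition, frontal-frontal r)
    if config.days >= 2 and config.n_dyads >= 2 and len(inter):
        pivot = inter.pivot_table(index="dyad", columns="day", values="r")
        if not pivot.isna().any().any():
            res = friedman(pivot.to_numpy())
            report["friedman_r_over_days"] = {"statistic": res.statistic, "p": res.p, "n": res.n}

    # condition contrast: interaction vs separate rooms (Mann-Whitney)
    sep = ff[ff.condition == "separate_room"]
    if len(inter) and len(sep):
        res = mann_whitney(inter["r"].dropna(), sep["r"].dropna())
        report["mw_interaction_vs_separate"] = {"statistic": res.statistic, "p": res.p}

    # exposure regression of r and leader->follower GPDC on day
    if config.days >= 3 and len(inter) >= 3:
        fit = exposure_regression(inter["r"].to_numpy(), inter["day"].to_numpy())
        report["exposure_regression_r"] = {"beta": fit.beta, "sem": fit.sem, "p": fit.p}
    if config.days >= 3 and len(gpdc_tab) >= 3:
        gf = gpdc_tab.query("region == 'frontal'")
        if len(gf) >= 3:
            fit = exposure_regression(gf["gpdc_human_to_dog"].to_numpy(), gf["day"].to_numpy())
            report["exposure_regression_gpdc"] = {"beta": fit.beta, "sem": fit.sem, "p": fit.p}

    # logistic growth fit over day means (needs >= 5 distinct days)
    if config.days >= 5 and len(inter):
        day_means = inter.groupby("day")["r"].mean()
        fit = logistic_growth_fit(day_means.index.to_numpy(), day_means.to_numpy())
        report["logistic_growth_r"] = {
            "L": fit.L,
            "k": fit.k,
            "t0": fit.t0,
            "plateau_day": fit.plateau_day,
            "converged": fit.converged,
        }

    # per-region TBR shift during interaction vs same-room baseline,
    # Holm-Sidak adjusted over regions x subjects
    if len(tbr_tab):
        names, ps = [], []
        for (subject, region), grp in tbr_tab.groupby(["subject", "region"]):
            a = grp[grp.condition == "interaction"]["mean_tbr"].dropna()
            b = grp[grp.condition == "same_room"]["mean_tbr"].dropna()
            if len(a) and len(b):
                res = mann_whitney(a, b)
                names.append(f"tbr_{subject}_{region}")
                ps.append(res.p)
        if ps:
            adj = holm_sidak(ps)
            report["tbr_interaction_shift"] = {
                name: {"p": float(p), "p_adjusted": float(q)} for name, p, q in zip(names, ps, adj)
            }
    return report
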