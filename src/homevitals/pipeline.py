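"""End-to-end pipeline: preprocess -> compliance -> alerts -> summaries -> group stats.

Each stage writes plain CSV outputs into the run directory and the run ends
with a ``manifest.json`` recording the configuration snapshot, input file
digests, per-stage row counts and a SHA-256 digest of every output, so a
re-run on the same inputs can be verified byte-for-byte.  A stage failure
aborts the run with the stage name after removing that stage's partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alerts import burden, score_measurements, score_stream
from .compliance import summarize_cohort as compliance_cohort
from .config import StudyConfig
from .io import read_cohort
from .model import Domain
from .preprocess import preprocess
from .schemes import load_scheme
from .stats import one_way_anova, spearman, tukey_hsd
from .summaries import summarize_cohort as physio_cohort
from .summaries import grand_summary

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class _Run:
    outdir: Path
    manifest: dict = field(default_factory=dict)
    stage_files: list[Path] = field(default_factory=list)

    def write_csv(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False)
        self.stage_files.append(path)
        return path


def subtype_group_stats(
    physio: pd.DataFrame,
    compliance_summary: pd.DataFrame,
    profiles: pd.DataFrame,
    cohort_compliance: dict,
) -> pd.DataFrame:
    """Between-subtype ANOVA (+ Tukey) and SMMSE Spearman correlations.

    Measures: per-domain within-subject means and SDs (eligible domains
    only), compliance day fractions and engagement slopes.  No family-wise
    multiple-comparison correction is applied.
    """
    prof = profiles.set_index("participant_id")
    rows: list[dict] = []

    def add_anova(measure: str, values: pd.Series) -> None:
        joined = pd.DataFrame({"value": values}).join(prof["subtype"], how="inner").dropna()
        groups = {
            name: g["value"].to_numpy()
            for name, g in joined.groupby("subtype")
            if len(g) >= 2
        }
        if len(groups) < 2:
            return
        res = one_way_anova(groups)
        rows.append(
            {
                "measure": measure, "test": "one_way_anova", "detail": "|".join(sorted(groups)),
                "statistic": res.F, "df1": res.df_between, "df2": res.df_within,
                "p": res.p, "n": sum(res.group_ns.values()),
            }
        )
        if res.p < 0.05:
            tk = tukey_hsd(groups)
            for pr in tk.pairs:
                rows.append(
                    {
                        "measure": measure, "test": "tukey_hsd",
                        "detail": f"{pr.group_a}-{pr.group_b}",
                        "statistic": pr.q, "df1": len(groups), "df2": tk.df_within,
                        "p": pr.p_adj, "n": sum(len(g) for g in groups.values()),
                    }
                )

    def add_spearman(measure: str, values: pd.Series) -> None:
        joined = pd.DataFrame({"value": values}).join(
            prof["smmse"].astype(float), how="inner"
        )
        if len(joined) < 3:
            return
        try:
            res = spearman(joined["value"], joined["smmse"])
        except ValueError:
            return
        if np.isnan(res.rho):
            return
        rows.append(
            {
                "measure": measure, "test": "spearman_vs_smmse", "detail": "",
                "statistic": res.rho, "df1": np.nan, "df2": res.n - 2,
                "p": res.p, "n": res.n,
            }
        )

    eligible = physio[physio["eligible"]]
    for dom in Domain:
        sub = eligible[eligible["domain"] == dom.value].set_index("participant_id")
        if len(sub):
            add_anova(f"mean_{dom.value}", sub["mean"])
            add_spearman(f"mean_{dom.value}", sub["mean"])
            sds = sub["sd"].dropna()
            if len(sds):
                add_anova(f"sd_{dom.value}", sds)

    comp = compliance_summary.set_index("participant_id")
    if len(comp):
        add_anova("frac_any_days", comp["frac_any_days"])
        add_anova("frac_full_set_days", comp["frac_full_set_days"])
        add_spearman("frac_any_days", comp["frac_any_days"])
        add_spearman("frac_full_set_days", comp["frac_full_set_days"])
        slopes = comp["slope"].dropna()
        if len(slopes):
            add_spearman("weekly_slope", slopes)
    if "slope_t" in cohort_compliance:
        rows.append(
            {
                "measure": "weekly_slope", "test": "one_sample_t_vs_zero", "detail": "",
                "statistic": cohort_compliance["slope_t"], "df1": np.nan,
                "df2": cohort_compliance["slope_df"], "p": cohort_compliance["slope_p"],
                "n": cohort_compliance["n_slopes"],
            }
        )
    return pd.DataFrame(rows, columns=["measure", "test", "detail", "statistic", "df1", "df2", "p", "n"])


def run_pipeline(
    measurements_path: str | Path,
    profiles_path: str | Path,
    outdir: str | Path,
    config: StudyConfig | None = None,
    schemes: tuple[str, ...] = ("news2", "minder"),
    tiers: tuple[int, ...] = (1, 2),
    make_plots: bool = False,
) -> Path:
    """Execute the full analysis and return the output directory."""
    config = config or StudyConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    manifest: dict = {
        "software": {"name": "homevitals", "version": __version__},
        "created": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "inputs": {
            "measurements": {"path": str(measurements_path), "sha256": _sha256(Path(measurements_path))},
            "profiles": {"path": str(profiles_path), "sha256": _sha256(Path(profiles_path))},
        },
        "stages": {},
        "metadata": {"multiple_comparison_correction": "none"},
    }

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                run.stage_files = []
                return run

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    for f in run.stage_files:
                        f.unlink(missing_ok=True)
                    raise PipelineError(name, exc) from exc
                return False

        return _Stage()

    tz = config.timezone

    with stage("read"):
        dataset = read_cohort(measurements_path, profiles_path)
        manifest["stages"]["read"] = {
            "n_measurements": dataset.n_measurements,
            "n_participants": dataset.n_participants,
        }

    with stage("preprocess"):
        if dataset.n_measurements == 0:
            raise ValueError("no measurements to analyse")
        clean, report = preprocess(dataset.measurements, config)
        run.write_csv(clean.assign(timestamp=clean["timestamp"].map(lambda t: t.isoformat())),
                      "measurements_clean.csv")
        run.write_csv(
            report.removed.assign(
                timestamp=report.removed["timestamp"].map(lambda t: t.isoformat())
            )
            if len(report.removed)
            else report.removed,
            "filter_report.csv",
        )
        manifest["stages"]["preprocess"] = {
            "n_input": report.n_input,
            "n_removed_duplicates": report.n_removed_duplicates,
            "n_removed_outliers": report.n_removed_outliers,
            "n_output": report.n_output,
        }

    with stage("compliance"):
        comp_summary, hourly, cohort_comp = compliance_cohort(clean, tz=tz)
        run.write_csv(comp_summary, "compliance_summary.csv")
        run.write_csv(hourly, "hourly_histogram.csv")
        manifest["stages"]["compliance"] = cohort_comp

    with stage("alerts"):
        obs_days = comp_summary.set_index("participant_id")["days_of_observation"]
        manifest["stages"]["alerts"] = {}
        burdens = {}
        for scheme_name in schemes:
            scheme = load_scheme(scheme_name)
            scheme_tiers = tiers if scheme.max_score >= 2 else (1,)
            events = score_stream(clean, scheme, scheme_tiers)
            scored = score_measurements(clean, scheme)
            b = burden(events, scored, obs_days, scheme.name)
            burdens[scheme_name] = b
            ev_out = events.copy()
            if len(ev_out):
                ev_out["timestamp"] = ev_out["timestamp"].map(lambda t: t.isoformat())
            run.write_csv(ev_out, f"alerts_{scheme_name}.csv")
            run.write_csv(b.per_participant, f"burden_{scheme_name}.csv")
            run.write_csv(b.cohort, f"burden_cohort_{scheme_name}.csv")
            manifest["stages"]["alerts"][scheme_name] = {
                "n_events": int(len(events)),
                "n_scored": int(len(scored)),
            }

    with stage("summaries"):
        physio, bp_table, weight_points, summaries = physio_cohort(clean, config)
        run.write_csv(physio, "physio_summary.csv")
        run.write_csv(bp_table, "bp_classification.csv")
        wp = weight_points.copy()
        if len(wp):
            wp["timestamp"] = wp["timestamp"].map(lambda t: t.isoformat())
            wp["ref_timestamp"] = wp["ref_timestamp"].map(
                lambda t: "" if pd.isna(t) else t.isoformat()
            )
        run.write_csv(wp, "weight_segments.csv")
        run.write_csv(grand_summary(summaries), "grand_summary.csv")
        manifest["stages"]["summaries"] = {
            "n_participants": int(physio["participant_id"].nunique()) if len(physio) else 0,
            "n_bp_classified": int((bp_table["bp_class"] != "").sum()) if len(bp_table) else 0,
        }

    with stage("groupstats"):
        gs = subtype_group_stats(physio, comp_summary, dataset.profiles, cohort_comp)
        run.write_csv(gs, "group_stats.csv")
        manifest["stages"]["groupstats"] = {"n_tests": int(len(gs))}

    if make_plots:
        with stage("plots"):
            from .plots import plot_burden_histograms, plot_hourly_histogram, plot_weight_trajectories

            plot_hourly_histogram(hourly, outdir / "hourly_histogram.png")
            plot_weight_trajectories(weight_points, outdir / "weight_trajectories.png")
            plot_burden_histograms(
                {name: b.per_participant for name, b in burdens.items()},
                outdir / "alert_burden.png",
            )

    outputs = sorted(p for p in outdir.iterdir() if p.suffix == ".csv")
    manifest["outputs"] = {p.name: _sha256(p) for p in outputs}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str, sort_keys=True))
    return outdir
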