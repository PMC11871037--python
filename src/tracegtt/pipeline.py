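"""End-to-end cohort analysis: measurements in, report tables out.

``analyze_dataset`` chains every stage per animal — MID correction ->
tracer fit -> insulin fit -> EGP reconstruction -> sensitivity indices —
and never lets one animal's failure abort the cohort: failed stages are
logged, the animal is flagged, and the pipeline continues.
``run_pipeline`` adds dataset I/O, dam-averaged group summaries, the
group statistics, and optional plots.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tracegtt import cohort as coh
from tracegtt import stats as st
from tracegtt.egp import reconstruct_egp, unlabeled_glucose
from tracegtt.errors import TraceGTTError
from tracegtt.indices import (
    NG_ML_TO_UU_ML,
    homa_ir,
    is_liver,
    is_peripheral,
    matsuda,
)
from tracegtt.insulin import average_insulin, blood_spot_to_plasma, fit_insulin
from tracegtt.mid import correct_mid, enrichment_from_mid, natural_abundance_matrix
from tracegtt.tracer import (
    POOL_VOLUME_PER_G,
    TracerCurve,
    dose_to_concentration,
    fit_tracer,
)

log = logging.getLogger("tracegtt")

#: Endpoints carried into group summaries and statistics.
ENDPOINTS = [
    "ka", "k2", "F", "egp_overall", "egp_steady", "ins_avg_0_120",
    "is_p", "is_l", "homa_ir", "matsuda", "auc_glucose_0_30",
    "auc_insulin_0_30", "fasting_glucose",
]

ISL_WINDOW = (5.0, 120.0)


def _pivot_animal(sub: pd.DataFrame):
    """Split one animal's long rows into glucose/MID/insulin series."""
    glu = sub[sub.analyte == "glucose"].sort_values("time_min")
    ins = sub[sub.analyte == "insulin"].sort_values("time_min")
    mids = sub[sub.analyte.str.startswith("mid_m")]
    mid_wide = mids.pivot(index="time_min", columns="analyte", values="value")
    mid_wide = mid_wide[[f"mid_m{k}" for k in range(mid_wide.shape[1])]].sort_index()
    return glu, ins, mid_wide


def analyze_animal(
    sub: pd.DataFrame,
    na_matrix: np.ndarray,
    pool_volume_per_g: float = POOL_VOLUME_PER_G,
) -> dict:
    """Run the full per-animal chain; returns one result row as a dict."""
    meta = sub.iloc[0]
    body_weight = float(meta["body_weight_g"])
    pool_volume = pool_volume_per_g * body_weight
    dose_total_mg = coh.DOSE_MG_PER_G_BW * body_weight
    dose_tracer_mg = coh.TRACER_FRACTION * dose_total_mg

    glu, ins, mid_wide = _pivot_animal(sub)
    g_times = glu.time_min.to_numpy(float)
    glucose = glu.value.to_numpy(float)

    enrichment = np.array([
        enrichment_from_mid(correct_mid(mid_wide.loc[t].to_numpy(float), na_matrix))
        for t in g_times
    ])
    enrichment = np.clip(enrichment, 0.0, None)

    row: dict = {
        "animal_id": meta["animal_id"],
        "dam_id": meta.get("dam_id", meta["animal_id"]),
        "group": meta.get("group", "NA"),
        "sex": meta.get("sex", "NA"),
        "protocol": meta.get("protocol", "OGTT"),
        "body_weight_g": body_weight,
        "fasting_glucose": float(glucose[0]),
        "status": "ok",
    }

    # tracer kinetics
    curve = TracerCurve(
        times=g_times,
        tracer_conc=glucose * enrichment,
        dose_tracer_mg=dose_tracer_mg,
        body_weight_g=body_weight,
    )
    tfit = fit_tracer(curve, pool_volume_ml=pool_volume)
    row.update(ka=tfit.ka, k2=tfit.k2, F=tfit.F, k1=tfit.k1, kL=tfit.kL,
               tracer_sse=tfit.residual_sse, tracer_converged=tfit.converged)

    # insulin response (blood-spot -> plasma scale first)
    i_times = ins.time_min.to_numpy(float)
    ins_plasma = np.asarray(blood_spot_to_plasma(ins.value.to_numpy(float)))
    ifit = fit_insulin(i_times, ins_plasma)
    ins_avg = average_insulin(ifit, 0.0, 120.0, include_baseline=True)
    row.update(ins_C=ifit.C, ins_ke=ifit.ke, ins_ka=ifit.ka_ins,
               ins_baseline=ifit.baseline, ins_avg_0_120=ins_avg,
               insulin_converged=ifit.converged)
    row["ins_avg_window"] = average_insulin(
        ifit, ISL_WINDOW[0], ISL_WINDOW[1], include_baseline=True
    )

    # EGP reconstruction
    q_u = unlabeled_glucose(glucose, enrichment)
    dose_unlabeled_conc = dose_to_concentration(
        (1 - coh.TRACER_FRACTION) * dose_total_mg, pool_volume
    )
    profile = reconstruct_egp(g_times, q_u, tfit, dose_unlabeled_conc)
    row.update(egp_steady=profile.egp_steady, egp_overall=profile.egp_overall,
               egp_negative_fraction=profile.negative_fraction)

    # whole-body surrogates and AUC summaries
    fasting_ins_uu = ins_plasma[0] * NG_ML_TO_UU_ML
    row["homa_ir"] = homa_ir(row["fasting_glucose"], fasting_ins_uu)
    glu_at_ins_times = np.interp(i_times, g_times, glucose)
    row["matsuda"] = matsuda(glu_at_ins_times, ins_plasma * NG_ML_TO_UU_ML, i_times)
    row["is_p"] = is_peripheral(tfit.k2, ins_avg)
    row["auc_glucose_0_30"] = st.auc_partial(g_times, glucose, 0.0, 30.0)
    row["auc_insulin_0_30"] = st.auc_partial(i_times, ins_plasma, 0.0, 30.0)
    return row


def analyze_dataset(
    df: pd.DataFrame,
    pool_volume_per_g: float = POOL_VOLUME_PER_G,
    isl_reference: tuple[str, ...] = ("sex", "protocol"),
) -> pd.DataFrame:
    """Per-animal analysis of a long-format cohort table.

    IS-L is attached afterwards because its reference (arithmetic mean of
    EGP and average insulin) is taken over the analysed cohort, grouped by
    ``isl_reference`` (per sex and per test by default).
    """
    na_matrix = natural_abundance_matrix()
    rows = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        try:
            rows.append(analyze_animal(sub, na_matrix, pool_volume_per_g))
        except (TraceGTTError, ValueError) as exc:
            log.warning("animal %s failed: %s", animal_id, exc)
            rows.append({"animal_id": animal_id, "status": f"failed: {exc}"})
    out = pd.DataFrame(rows)

    ok = out.status == "ok"
    if ok.any():
        ref_cols = [c for c in isl_reference if c in out.columns]
        grouped = out[ok].groupby(ref_cols)[["egp_overall", "ins_avg_window"]] \
            if ref_cols else None
        if grouped is not None:
            refs = grouped.mean().rename(
                columns={"egp_overall": "egp_ref", "ins_avg_window": "ins_ref"}
            )
            merged = out.loc[ok].join(refs, on=ref_cols)
        else:
            merged = out.loc[ok].copy()
            merged["egp_ref"] = merged.egp_overall.mean()
            merged["ins_ref"] = merged.ins_avg_window.mean()
        isl = [
            is_liver(r.egp_overall, r.ins_avg_window, r.egp_ref, r.ins_ref)
            for r in merged.itertuples()
        ]
        out.loc[merged.index, "is_l"] = isl
    return out


def group_summary(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Dam-averaged mean +/- SEM per group x sex for every endpoint."""
    ok = per_animal[per_animal.status == "ok"]
    rows = []
    for endpoint in ENDPOINTS:
        if endpoint not in ok.columns:
            continue
        dams = st.dam_average(ok, endpoint)
        for (group, sex), sub in dams.groupby(["group", "sex"], observed=True):
            vals = sub[endpoint].to_numpy(float)
            rows.append({
                "endpoint": endpoint, "group": group, "sex": sex,
                "n_dams": vals.size, "mean": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
            })
    return pd.DataFrame(rows)


def group_statistics(per_animal: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA + Tukey per sex and two-way sex x group per endpoint."""
    ok = per_animal[per_animal.status == "ok"]
    tables = []
    for endpoint in ENDPOINTS:
        if endpoint not in ok.columns:
            continue
        dams = st.dam_average(ok, endpoint)
        for sex, sub in dams.groupby("sex", observed=True):
            groups = {g: s[endpoint].to_numpy(float)
                      for g, s in sub.groupby("group", observed=True)}
            if len(groups) < 2 or min(len(v) for v in groups.values()) < 2:
                continue
            tab = st.one_way_anova_tukey(groups)
            tab.insert(0, "endpoint", endpoint)
            tab.insert(1, "sex", sex)
            tab.insert(2, "test", "one-way ANOVA / Tukey")
            tables.append(tab)
        try:
            tw = st.two_way_anova(dams, endpoint)
        except TraceGTTError:
            continue
        tw = tw.rename(columns={"effect": "contrast", "F": "statistic"})
        tw["p_adjusted"] = tw["p"]
        tw.insert(0, "endpoint", endpoint)
        tw.insert(1, "sex", "both")
        tw.insert(2, "test", "two-way ANOVA (type II)")
        tables.append(tw)
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def _plot_report(df: pd.DataFrame, per_animal: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for analyte, ax in zip(("glucose", "insulin"), axes):
        sub = df[df.analyte == analyte]
        meta = df[["animal_id", "group"]].drop_duplicates().set_index("animal_id")
        sub = sub.join(meta["group"].rename("grp"), on="animal_id", rsuffix="_m") \
            if "group" not in sub.columns else sub
        for group, g in sub.groupby("group"):
            prof = g.groupby("time_min").value.mean()
            ax.plot(prof.index, prof.values, marker="o", label=group)
        ax.set_xlabel("time (min)")
        ax.set_ylabel(f"{analyte} ({'mM' if analyte == 'glucose' else 'ng/mL spot'})")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "time_courses.png", dpi=120)
    plt.close(fig)

    ok = per_animal[per_animal.status == "ok"]
    idx_cols = [c for c in ("is_p", "is_l", "homa_ir", "matsuda") if c in ok.columns]
    fig, axes = plt.subplots(1, len(idx_cols), figsize=(3 * len(idx_cols), 4))
    for col, ax in zip(idx_cols, np.atleast_1d(axes)):
        for i, (group, g) in enumerate(ok.groupby("group")):
            ax.scatter(np.full(len(g), i) + np.linspace(-0.15, 0.15, len(g)),
                       g[col], s=18, label=group if col == idx_cols[0] else None)
        ax.set_xticks(range(ok.group.nunique()))
        ax.set_xticklabels(sorted(ok.group.unique()))
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(out / "indices.png", dpi=120)
    plt.close(fig)


def load_config(path: str | Path) -> dict:
    """Read a YAML config mirroring CohortDesign plus pipeline options."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def design_from_config(config: dict) -> coh.CohortDesign:
    keys = {f.name for f in coh.CohortDesign.__dataclass_fields__.values()}
    return coh.CohortDesign(**{k: v for k, v in config.items() if k in keys})


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "tracegtt_report",
    dataset: str | Path | None = None,
    plots: bool = True,
) -> dict[str, pd.DataFrame]:
    """Simulate (or load) a cohort, analyse it, and write the report.

    Writes measurements.csv + ground_truth.json (when simulating),
    per_animal.csv, group_summary.csv, statistics.csv and plots into
    ``out_dir``. Returns the tables. Numeric CSVs are written with a fixed
    format so reruns under the same seed are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or {}

    if dataset is not None:
        df, _ = coh.read_dataset(dataset)
    else:
        design = design_from_config(config)
        mice, records = coh.simulate_cohort(design)
        coh.write_dataset(records, mice, out, protocol=design.protocol)
        df, _ = coh.read_dataset(out)

    per_animal = analyze_dataset(df)
    n_failed = int((per_animal.status != "ok").sum())
    if n_failed:
        log.warning("%d animals failed the analysis chain", n_failed)

    summary = group_summary(per_animal)
    statistics = group_statistics(per_animal)

    per_animal.to_csv(out / "per_animal.csv", index=False, float_format="%.12g")
    summary.to_csv(out / "group_summary.csv", index=False, float_format="%.12g")
    statistics.to_csv(out / "statistics.csv", index=False, float_format="%.12g")
    if plots:
        _plot_report(df, per_animal, out)

    return {"per_animal": per_animal, "group_summary": summary,
            "statistics": statistics}
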