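"""End-to-end cohort analysis: baseline table, stratified ratio panels,
model table, and the patient-by-pathogen matrix.

Each stage consumes the outputs of the upstream modules and emits plain
DataFrames (written as CSV/JSON by :func:`run_full`), so a complete run
is reproducible from the two input tables, a config, and a seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import ratio_series, stratify, zscore_sort
from .cohort_io import InfectionRecord, PatientRecord, apply_eligibility
from .episodes import WaitingListPolicy, tabulate_episodes
from .models import fit_prediction_models, roc_table
from .severity import absi_category, compute_scores
from .stats import (anova_dunnett, fisher_exact_2x2, mann_whitney,
                    t_test_equal_var)

__all__ = [
    "build_analysis_frame",
    "run_baseline_table",
    "run_severity_stratification",
    "run_pathogen_matrix",
    "run_full",
]

log = logging.getLogger("burncohort")


def tabulate_all(infections: list[InfectionRecord],
                 policy: WaitingListPolicy | None = None) -> dict:
    """Episode tallies for every patient present in the infection table."""
    policy = policy or WaitingListPolicy()
    by_pid: dict[str, list[InfectionRecord]] = {}
    for rec in infections:
        by_pid.setdefault(rec.patient_id, []).append(rec)
    return {pid: tabulate_episodes(recs, policy) for pid, recs in by_pid.items()}


def build_analysis_frame(patients: list[PatientRecord],
                         infections: list[InfectionRecord],
                         policy: WaitingListPolicy | None = None) -> pd.DataFrame:
    """Merge patients, episode tallies, severity scores, and the cytokine
    ratio into the single per-patient frame the analyses run on."""
    tallies = tabulate_all(infections, policy)
    series = ratio_series(patients)
    ratios = dict(zip(series.patient_ids, series.ratios))
    first_day = {}
    itypes: dict[str, set[str]] = {}
    for rec in infections:
        d = first_day.get(rec.patient_id)
        if d is None or rec.day < d:
            first_day[rec.patient_id] = rec.day
        itypes.setdefault(rec.patient_id, set()).add(rec.itype)

    rows = []
    for p in patients:
        s = compute_scores(p)
        n_ep = tallies[p.patient_id].n_episodes if p.patient_id in tallies else 0
        row = {
            **vars(p),
            "ratio": ratios[p.patient_id],
            "ryan": s.ryan, "absi": s.absi, "baux": s.baux, "rbaux": s.rbaux,
            "absi_band": absi_category(s.absi),
            "n_episodes": n_ep,
            "hypersusceptible": n_ep >= 3,
            "first_infection_day": first_day.get(p.patient_id, np.nan),
        }
        for it in ("pneumonia", "bloodstream", "urinary tract", "burn wound",
                   "catheter-related bloodstream", "endocarditis",
                   "pseudomembranous colitis", "other"):
            row["inf_" + it.replace(" ", "_").replace("-", "_")] = \
                it in itypes.get(p.patient_id, set())
        row["nosocomial"] = bool(itypes.get(p.patient_id, set()) - {"burn wound"})
        rows.append(row)
    return pd.DataFrame(rows)


def _cont_row(frame, col, label, survivors_only=False, infected_only=False):
    df = frame
    note = ""
    if survivors_only:
        df = df[~df["died"]]
        note = f"among survivors (n={len(df)})"
    if infected_only:
        df = df[df["n_episodes"] > 0]
        note = f"among infected (n={len(df)})"
    a = df.loc[df["hypersusceptible"], col].dropna()
    b = df.loc[~df["hypersusceptible"], col].dropna()
    row = {"variable": label, "kind": "mean_sd", "test": "t", "note": note,
           "overall": f"{df[col].mean():.3g} ± {df[col].std(ddof=1):.3g}",
           "noncase": f"{b.mean():.3g} ± {b.std(ddof=1):.3g}",
           "case": f"{a.mean():.3g} ± {a.std(ddof=1):.3g}"}
    try:
        row["p"] = t_test_equal_var(a, b).p_two_tailed
    except ValueError:
        row["test"], row["p"] = "omitted", np.nan
    return row


def _median_row(frame, col, label):
    a = frame.loc[frame["hypersusceptible"], col]
    b = frame.loc[~frame["hypersusceptible"], col]

    def miqr(v):
        return (f"{np.median(v):g} [{np.quantile(v, 0.25):g}-"
                f"{np.quantile(v, 0.75):g}]")

    row = {"variable": label, "kind": "median_iqr", "test": "mann-whitney",
           "overall": miqr(frame[col]), "noncase": miqr(b), "case": miqr(a),
           "note": ""}
    try:
        row["p"] = mann_whitney(a, b).p_two_tailed
    except ValueError:
        row["test"], row["p"] = "omitted", np.nan
    return row


def _prop_row(frame, mask_col, label, positive=True):
    m = frame[mask_col].astype(bool) == positive
    a = m[frame["hypersusceptible"]]
    b = m[~frame["hypersusceptible"]]

    def npc(v):
        return f"{int(v.sum())} ({100 * v.mean():.1f}%)" if len(v) else "0"

    table = [[int(a.sum()), int(len(a) - a.sum())],
             [int(b.sum()), int(len(b) - b.sum())]]
    row = {"variable": label, "kind": "n_pct", "test": "fisher", "note": "",
           "overall": npc(m), "noncase": npc(b), "case": npc(a),
           "p": fisher_exact_2x2(table).p_two_tailed}
    return row


def run_baseline_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-variable overall/non-case/case summaries with the matching test.

    Continuous variables: mean +/- SD with equal-variance t-test; ordinal
    counts and scores: median [IQR] with Mann-Whitney; proportions:
    n (%) with Fisher's exact test. Hospital stay is summarized among
    survivors only; first infection day among patients with at least one
    recorded infection.
    """
    rows = [
        {"section": "demographics", **_cont_row(frame, "age", "age (years)")},
        {"section": "demographics",
         **_prop_row(frame.assign(male=frame["sex"] == "male"), "male", "sex (male)")},
        {"section": "demographics", **_cont_row(frame, "bmi", "bmi (kg/m2)")},
        {"section": "demographics",
         **_cont_row(frame, "admission_delay_h", "time to admission (h)")},
    ]
    for et in sorted(frame["etiology"].unique()):
        rows.append({"section": "burn injury",
                     **_prop_row(frame.assign(_et=frame["etiology"] == et),
                                 "_et", f"etiology: {et}")})
    rows += [
        {"section": "burn injury", **_cont_row(frame, "tbsa", "tbsa (%)")},
        {"section": "burn injury",
         **_prop_row(frame, "second_degree", "second-degree burn")},
        {"section": "burn injury",
         **_prop_row(frame, "third_degree", "third-degree burn")},
        {"section": "burn injury",
         **_prop_row(frame, "inhalation", "inhalation injury")},
        {"section": "burn injury", **_cont_row(frame, "apacheii", "apacheii")},
        {"section": "burn injury", **_cont_row(frame, "baux", "baux")},
        {"section": "burn injury", **_cont_row(frame, "rbaux", "r-baux")},
        {"section": "burn injury", **_median_row(frame, "ryan", "ryan score")},
        {"section": "burn injury", **_median_row(frame, "absi", "absi")},
        {"section": "plasma collection",
         **_cont_row(frame, "blood_draw_h", "first blood collection (h)")},
        {"section": "plasma collection",
         **_cont_row(frame, "ratio", "tnf-alpha/il-10 ratio")},
        {"section": "infections",
         **_cont_row(frame, "first_infection_day",
                     "first infection day", infected_only=True)},
        {"section": "infections",
         **_median_row(frame, "n_episodes", "number of infection episodes")},
    ]
    for col, label in [("inf_burn_wound", "burn wound infection"),
                       ("nosocomial", "nosocomial infection"),
                       ("inf_pneumonia", "pneumonia"),
                       ("inf_bloodstream", "bloodstream infection"),
                       ("inf_urinary_tract", "urinary tract infection"),
                       ("inf_catheter_related_bloodstream",
                        "catheter-related bloodstream infection")]:
        rows.append({"section": "infections", **_prop_row(frame, col, label)})
    rows += [
        {"section": "outcomes", **_prop_row(frame, "died", "death")},
        {"section": "outcomes",
         **_cont_row(frame, "hospital_days", "hospital stay (days)",
                     survivors_only=True)},
    ]
    return pd.DataFrame(rows)


def _panel_binary(frame, mask, name, lo_label, hi_label):
    lo = frame.loc[~mask, "ratio"]
    hi = frame.loc[mask, "ratio"]
    rows = []
    for label, v in ((lo_label, lo), (hi_label, hi)):
        rows.append({"panel": name, "stratum": label, "n": len(v),
                     "mean": v.mean() if len(v) else np.nan,
                     "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                     "se": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan})
    p = np.nan
    test = "t"
    try:
        p = t_test_equal_var(lo, hi).p_two_tailed
    except ValueError:
        test = "omitted"
    for r in rows:
        r["test"], r["p"] = test, p
    return rows


def run_severity_stratification(frame: pd.DataFrame,
                                dunnett_seed: int | None = 0) -> pd.DataFrame:
    """Stratified mean-ratio panels across the severity measures.

    Mean-split TBSA/APACHEII/Baux/R-Baux and the binary inhalation and
    full-thickness strata are compared by t-test; Ryan score levels and
    ABSI bands by one-way ANOVA with Dunnett comparisons against the
    first (least severe) category; quartile variants of the continuous
    measures are included as separate panels.
    """
    rows: list[dict] = []
    ids = frame["patient_id"].tolist()
    for col, name in [("tbsa", "tbsa"), ("apacheii", "apacheii"),
                      ("baux", "baux"), ("rbaux", "rbaux")]:
        cut = int(np.floor(frame[col].mean()))
        rows += _panel_binary(frame, frame[col] > cut, f"{name}_mean_split",
                              f"<={cut}", f">={cut + 1}")
        strat = stratify(ids, frame[col].to_numpy(), "quartile",
                         values=frame["ratio"].to_numpy())
        q = strat.summaries.assign(panel=f"{name}_quartiles", test="", p=np.nan)
        rows += q.to_dict("records")
    rows += _panel_binary(frame, frame["inhalation"].astype(bool),
                          "inhalation", "no", "yes")
    rows += _panel_binary(frame, frame["third_degree"].astype(bool),
                          "full_thickness", "no", "yes")

    for col, name in [("ryan", "ryan"), ("absi_band", "absi_band")]:
        order = (sorted(frame[col].unique()) if col == "ryan"
                 else [b for b in ("low", "moderately severe", "serious",
                                   "severe", "maximum")
                       if b in set(frame[col])])
        groups = [frame.loc[frame[col] == lev, "ratio"].to_numpy()
                  for lev in order]
        usable = [i for i, g in enumerate(groups) if len(g) >= 2]
        adj: dict = {}
        p = np.nan
        test = "anova+dunnett"
        if len(usable) >= 2 and 0 in usable:
            sub = [groups[i] for i in usable]
            res = anova_dunnett(sub, reference_index=0, seed=dunnett_seed)
            p = res.p_two_tailed
            adj = {usable[i]: pv for i, pv in res.adjusted_p.items()}
            dropped = [order[i] for i in range(len(order)) if i not in usable]
            if dropped:
                log.warning("%s: categories %s omitted from Dunnett (n<2)",
                            name, dropped)
        else:
            test = "omitted"
        for i, lev in enumerate(order):
            g = groups[i]
            rows.append({"panel": name, "stratum": str(lev), "n": len(g),
                         "mean": g.mean() if len(g) else np.nan,
                         "sd": g.std(ddof=1) if len(g) > 1 else np.nan,
                         "se": (g.std(ddof=1) / np.sqrt(len(g))
                                if len(g) > 1 else np.nan),
                         "test": test, "p": p,
                         "dunnett_p": adj.get(i, np.nan)})
    return pd.DataFrame(rows)


def run_pathogen_matrix(frame: pd.DataFrame,
                        infections: list[InfectionRecord]) -> pd.DataFrame:
    """Patient-by-pathogen presence matrix sorted by ratio z-score.

    Rows are patients in ascending ratio z-score order (the visual
    "clustering" is this sorting, not an algorithmic clustering);
    pathogen columns carry their overall prevalence in the header;
    severity scores appear as population z-scores alongside the
    hypersusceptibility flag.
    """
    from .biomarker import RatioSeries
    series = RatioSeries(frame["patient_id"].tolist(),
                         frame["ratio"].to_numpy())
    order = zscore_sort(series)

    seen: dict[str, set[str]] = {}
    for rec in infections:
        seen.setdefault(rec.patient_id, set()).add(rec.pathogen)
    pathogens = sorted({p for s in seen.values() for p in s})

    idx = frame.set_index("patient_id")
    n = len(frame)
    rows = []
    for pid, z in zip(order["patient_id"], order["zscore"]):
        row = {"patient_id": pid, "ratio_zscore": float(z),
               "hypersusceptible": bool(idx.loc[pid, "hypersusceptible"])}
        for pg in pathogens:
            prev = 100 * sum(pg in s for s in seen.values()) / n
            row[f"{pg} ({prev:.1f}%)"] = int(pg in seen.get(pid, set()))
        for col in ("tbsa", "apacheii", "baux", "rbaux"):
            v = idx[col].astype(float)
            row[f"{col}_zscore"] = float((idx.loc[pid, col] - v.mean())
                                         / v.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def run_full(patients: list[PatientRecord],
             infections: list[InfectionRecord],
             out_dir, *, seed: int = 0, n_boot: int = 10_000,
             policy: WaitingListPolicy | None = None,
             config_blob: str | None = None) -> dict:
    """Run every stage on an eligible cohort and write the artifacts.

    Writes eligibility.json, analysis_frame.csv, baseline_table.csv,
    stratification.csv, model_table.csv, pathogen_matrix.csv, and a
    provenance.json holding the seed, a config hash, and the package
    version. Returns the in-memory artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("input: %d patients, %d infection records",
             len(patients), len(infections))

    report = apply_eligibility(patients, infections)
    report.to_json(out / "eligibility.json")
    keep = set(report.eligible)
    patients = [p for p in patients if p.patient_id in keep]
    infections = [r for r in infections if r.patient_id in keep]
    log.info("eligible: %d patients", len(patients))

    frame = build_analysis_frame(patients, infections, policy)
    frame.to_csv(out / "analysis_frame.csv", index=False)

    baseline = run_baseline_table(frame)
    baseline.to_csv(out / "baseline_table.csv", index=False)

    strat = run_severity_stratification(frame, dunnett_seed=seed)
    strat.to_csv(out / "stratification.csv", index=False)

    models = fit_prediction_models(frame, n_boot=n_boot, seed=seed)
    mtable = roc_table(models)
    mtable.to_csv(out / "model_table.csv", index=False)

    matrix = run_pathogen_matrix(frame, infections)
    matrix.to_csv(out / "pathogen_matrix.csv", index=False)

    blob = config_blob if config_blob is not None else ""
    provenance = {
        "seed": seed,
        "n_boot": n_boot,
        "version": __version__,
        "n_patients": len(patients),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("wrote artifacts to %s", out)
    return {"frame": frame, "baseline": baseline, "stratification": strat,
            "models": mtable, "matrix": matrix, "provenance": provenance}
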