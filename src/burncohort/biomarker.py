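"""TNF-alpha/IL-10 plasma cytokine ratio: computation, z-scoring, stratification.

The ratio of the pro-inflammatory cytokine TNF-alpha to the
anti-inflammatory cytokine IL-10 (both pg/mL, so the ratio is
dimensionless) summarizes early pro- vs anti-inflammatory balance; a low
ratio after severe burn trauma marks relative immunosuppression. The
module also stratifies patients by clinical variables (mean split,
quartiles, or explicit categories) and summarizes the ratio per stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatioSeries",
    "Stratification",
    "UndefinedRatioError",
    "tnf_il10_ratio",
    "ratio_series",
    "stratify",
    "zscore_sort",
]


class UndefinedRatioError(ValueError):
    """The ratio is undefined (non-positive concentration)."""


def tnf_il10_ratio(tnf_pg_ml: float, il10_pg_ml: float, *,
                   il10_lod: float | None = None) -> float:
    """TNF-alpha / IL-10 concentration ratio.

    Both concentrations must be positive. If IL-10 is zero or negative
    and ``il10_lod`` (assay limit of detection, pg/mL) is given, IL-10
    is substituted by LOD/2; otherwise an :class:`UndefinedRatioError`
    is raised — detection-limit policy belongs to the caller.
    """
    if tnf_pg_ml <= 0 or not math.isfinite(tnf_pg_ml):
        raise UndefinedRatioError(f"TNF-alpha must be positive, got {tnf_pg_ml}")
    if il10_pg_ml <= 0 or not math.isfinite(il10_pg_ml):
        if il10_lod is not None and il10_lod > 0:
            il10_pg_ml = il10_lod / 2.0
        else:
            raise UndefinedRatioError(f"IL-10 must be positive, got {il10_pg_ml}")
    return tnf_pg_ml / il10_pg_ml


@dataclass
class RatioSeries:
    """Per-patient ratios with sample z-scores (mean 0, SD 1, ddof=1)."""

    patient_ids: list[str]
    ratios: np.ndarray
    zscores: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if np.any(~np.isfinite(self.ratios)) or np.any(self.ratios <= 0):
            raise UndefinedRatioError("ratios must be positive and finite")
        if len(self.patient_ids) != len(self.ratios):
            raise ValueError("patient_ids and ratios length mismatch")
        if len(self.ratios) >= 2:
            sd = self.ratios.std(ddof=1)
            if sd == 0:
                raise ValueError("zero standard deviation: z-scores undefined")
            self.zscores = (self.ratios - self.ratios.mean()) / sd
        else:
            self.zscores = np.zeros_like(self.ratios)


def ratio_series(patients: Sequence, **ratio_kwargs) -> RatioSeries:
    """Build a :class:`RatioSeries` from patient records."""
    return RatioSeries(
        patient_ids=[p.patient_id for p in patients],
        ratios=np.array([tnf_il10_ratio(p.tnf_pg_ml, p.il10_pg_ml, **ratio_kwargs)
                         for p in patients]),
    )


@dataclass
class Stratification:
    """Partition of patients into strata with per-stratum ratio summaries.

    ``summaries`` has one row per stratum: n, mean, sd, se (= sd/sqrt(n))
    of the comparison variable. Strata with n = 0 appear with no summary.
    """

    scheme: str
    labels: dict[str, str]
    summaries: pd.DataFrame


def _summaries(strata: Mapping[str, np.ndarray], scheme: str,
               order: Sequence[str]) -> pd.DataFrame:
    rows = []
    for name in order:
        v = strata[name]
        row: dict = {"stratum": name, "n": len(v)}
        if len(v) >= 1:
            row["mean"] = float(np.mean(v))
        if len(v) >= 2:
            sd = float(np.std(v, ddof=1))
            row["sd"] = sd
            row["se"] = sd / math.sqrt(len(v))
        rows.append(row)
    return pd.DataFrame(rows, columns=["stratum", "n", "mean", "sd", "se"])


def stratify(patient_ids: Sequence[str], by: Sequence[float],
             scheme: str = "mean_split", *,
             values: Sequence[float] | None = None,
             categories: Mapping[str, str] | None = None) -> Stratification:
    """Partition patients by ``by`` and summarize ``values`` per stratum.

    Schemes:

    ``mean_split``
        split at floor(mean of ``by``) — reproducing printed integer
        cutpoints such as TBSA <=41 vs >=42 around a mean of 41.6;
        the low stratum is ``by <= floor(mean)``.
    ``quartile``
        four bins at Q1/median/Q3 (linear-interpolation quartiles);
        values tied with a cut fall in the lower bin.
    ``categories``
        explicit label per patient via the ``categories`` mapping.
    """
    ids = list(patient_ids)
    by_arr = np.asarray(by, dtype=float)
    val_arr = by_arr if values is None else np.asarray(values, dtype=float)
    if len(ids) != len(by_arr) or len(ids) != len(val_arr):
        raise ValueError("length mismatch among ids, by, values")

    labels: dict[str, str] = {}
    if scheme == "mean_split":
        if len(ids) < 2:
            raise ValueError("mean_split needs >= 2 patients")
        cut = math.floor(by_arr.mean())
        lo_name, hi_name = f"<={cut}", f">={cut + 1}"
        for pid, b in zip(ids, by_arr):
            labels[pid] = lo_name if b <= cut else hi_name
        order = [lo_name, hi_name]
    elif scheme == "quartile":
        if len(ids) < 4:
            raise ValueError("quartile scheme needs >= 4 patients")
        q1, q2, q3 = np.quantile(by_arr, [0.25, 0.5, 0.75])
        names = ["Q1", "Q2", "Q3", "Q4"]
        for pid, b in zip(ids, by_arr):
            if b <= q1:
                labels[pid] = "Q1"
            elif b <= q2:
                labels[pid] = "Q2"
            elif b <= q3:
                labels[pid] = "Q3"
            else:
                labels[pid] = "Q4"
        order = names
    elif scheme == "categories":
        if categories is None:
            raise ValueError("categories scheme requires the categories mapping")
        labels = {pid: str(categories[pid]) for pid in ids}
        order = sorted(set(labels.values()))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    strata = {name: val_arr[[labels[pid] == name for pid in ids]] for name in order}
    return Stratification(scheme=scheme, labels=labels,
                          summaries=_summaries(strata, scheme, order))


def zscore_sort(series: RatioSeries) -> pd.DataFrame:
    """Patients ordered ascending by ratio z-score (ties by patient_id).

    This is the ordering used to lay out the patient-by-pathogen matrix:
    most immunosuppressed (lowest ratio) first.
    """
    if len(series.patient_ids) < 2:
        raise ValueError("need >= 2 patients to standardize")
    df = pd.DataFrame({
        "patient_id": series.patient_ids,
        "ratio": series.ratios,
        "zscore": series.zscores,
    })
    return df.sort_values(["zscore", "patient_id"], kind="stable").reset_index(drop=True)
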