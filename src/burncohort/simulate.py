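"""Synthetic burn cohort generator calibrated to the study population.

The study's patient-level data are not public, so this module generates
cohorts with the same statistical structure: 17 hypersusceptible cases
and 17 non-cases; per-group TNF-alpha/IL-10 ratios drawn log-normal and
moment-matched to the printed group summaries (non-case 0.200 +/- 0.154,
case 0.067 +/- 0.072); TBSA, age, timing, and APACHEII from truncated
normals on their clinical supports; inhalation and other flags Bernoulli
at the printed group prevalences; per-group episode counts whose medians
and IQRs bracket the printed 1 [0-2] and 6 [5-10].

IL-10 is drawn log-normal and TNF-alpha emitted as ratio x IL-10, so
downstream code computes the ratio from concentrations rather than
receiving it. Infection histories plant exactly the drawn number of
episodes: records within a cluster share type/mode/pathogen with gaps
inside the dissimilar window, and clusters are separated by more than
the similar window, so the waiting-list tabulation recovers the planted
count exactly. Every generated patient passes the eligibility filter by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import stats as sps

from ._units import days_to_hours
from .cohort_io import InfectionRecord, PatientRecord
from .episodes import WaitingListPolicy

__all__ = [
    "CohortConfig",
    "ConfigError",
    "lognormal_params",
    "generate_cohort",
    "generate_infection_history",
    "PATHOGEN_PREVALENCE",
]


class ConfigError(ValueError):
    pass


# Overall per-patient pathogen prevalences (%) observed in the cohort;
# used (renormalized) as per-episode sampling weights — a documented
# independence simplification.
PATHOGEN_PREVALENCE: dict[str, float] = {
    "enterococcus": 50.0,
    "coagulase-negative staphylococci": 47.1,
    "s. aureus": 44.1,
    "candida": 35.3,
    "p. aeruginosa": 26.5,
    "gram-positive nos": 26.5,
    "gram-negative nos": 26.5,
    "acinetobacter": 23.5,
    "e. coli": 23.5,
    "k. pneumoniae": 23.5,
    "s. viridans": 20.6,
    "fungi nos": 20.6,
    "s. pneumoniae": 17.6,
    "h. influenza": 14.7,
    "enterobacter": 11.8,
    "unknown": 8.8,
    "aspergillus": 5.9,
    "clostridium": 5.9,
    "stenotrophomonas": 5.9,
    "proteus": 2.9,
}

_ITYPES = ("pneumonia", "bloodstream", "urinary tract", "burn wound",
           "catheter-related bloodstream", "other")
_ITYPE_WEIGHTS = (19, 13, 15, 18, 6, 7)  # cohort per-patient counts as weights


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ConfigError("log-normal moment matching needs positive mean and SD")
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the study-population values.

    Two-tuples are (mean, SD); supports are closed intervals on which
    normal draws are truncated. ``episode_noncase_probs`` is the pmf of
    counts 0/1/2 in the non-case group; case counts are 3 plus a
    negative binomial with ``episode_case_nb`` = (r, mean).
    """

    n_cases: int = 17
    n_noncases: int = 17
    ratio_noncase: tuple[float, float] = (0.200, 0.154)
    ratio_case: tuple[float, float] = (0.067, 0.072)
    il10_pg_ml: tuple[float, float] = (40.0, 40.0)
    tbsa_noncase: tuple[float, float] = (31.9, 11.2)
    tbsa_case: tuple[float, float] = (51.2, 20.0)
    tbsa_support: tuple[float, float] = (20.0, 100.0)
    age: tuple[float, float] = (40.6, 17.2)
    age_support: tuple[float, float] = (16.0, 90.0)
    bmi: tuple[float, float] = (26.3, 6.9)
    bmi_support: tuple[float, float] = (14.0, 60.0)
    blood_draw_h: tuple[float, float] = (19.9, 12.0)
    blood_draw_support: tuple[float, float] = (0.5, 48.0)
    admission_delay_h: tuple[float, float] = (4.1, 2.5)
    admission_delay_support: tuple[float, float] = (0.25, 24.0)
    apacheii_noncase: tuple[float, float] = (14.1, 7.8)
    apacheii_case: tuple[float, float] = (23.8, 5.2)
    apacheii_support: tuple[float, float] = (0.0, 71.0)
    inhalation_p: tuple[float, float] = (5 / 17, 10 / 17)  # (non-case, case)
    male_p: tuple[float, float] = (12 / 17, 10 / 17)
    second_degree_p: tuple[float, float] = (13 / 17, 14 / 17)
    third_degree_p: tuple[float, float] = (14 / 17, 17 / 17)
    died_p: tuple[float, float] = (1 / 17, 5 / 17)
    etiology_weights: dict[str, float] = field(default_factory=lambda: {
        "flame": 23, "flash": 5, "scald": 2, "other": 4})
    first_infection_day: tuple[float, float] = (5.4, 3.0)
    first_infection_min_day: float = 1.0
    episode_noncase_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    episode_case_nb: tuple[float, float] = (1.7, 4.5)  # (r, mean), shifted +3
    # Gaussian-copula correlation between the (log) ratio and each of
    # TBSA and APACHEII within group; negative = more severe, lower ratio.
    severity_ratio_coupling: float = -0.5
    hospital_days_noncase: tuple[float, float] = (27.2, 15.4)
    hospital_days_case: tuple[float, float] = (92.2, 63.7)
    policy: WaitingListPolicy = field(default_factory=WaitingListPolicy)

    def validate(self) -> None:
        if self.n_cases < 2 or self.n_noncases < 2:
            raise ConfigError("need >= 2 patients per group")
        for name in ("tbsa_noncase", "tbsa_case"):
            self._check_truncation(getattr(self, name), self.tbsa_support, name)
        self._check_truncation(self.age, self.age_support, "age")
        self._check_truncation(self.blood_draw_h, self.blood_draw_support,
                               "blood_draw_h")
        if abs(sum(self.episode_noncase_probs) - 1.0) > 1e-9:
            raise ConfigError("episode_noncase_probs must sum to 1")
        for p in (*self.inhalation_p, *self.male_p, *self.third_degree_p,
                  *self.second_degree_p, *self.died_p):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        if not -1 < self.severity_ratio_coupling < 1:
            raise ConfigError("severity_ratio_coupling must lie in (-1, 1)")

    @staticmethod
    def _check_truncation(ms: tuple[float, float], support: tuple[float, float],
                          name: str) -> None:
        mean, sd = ms
        lo, hi = support
        if not lo <= mean <= hi:
            raise ConfigError(
                f"{name}: mean {mean} outside truncation support [{lo}, {hi}]")
        if sd <= 0:
            raise ConfigError(f"{name}: SD must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["policy"] = {"similar_window": self.policy.similar_window,
                       "dissimilar_window": self.policy.dissimilar_window,
                       "similarity_fields": list(self.policy.similarity_fields)}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "policy" in d:
            pol = d["policy"]
            if "similarity_fields" in pol:
                pol["similarity_fields"] = tuple(pol["similarity_fields"])
            d["policy"] = WaitingListPolicy(**pol)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float,
                   lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_infection_history(n_episodes: int,
                               policy: WaitingListPolicy,
                               rng: np.random.Generator, *,
                               patient_id: str = "P",
                               first_day: float = 5.0) -> list[InfectionRecord]:
    """Plant exactly ``n_episodes`` independent episodes for one patient.

    Records inside a cluster share type, mode, and pathogen, with
    successive gaps no larger than the dissimilar window (so they merge
    under any similarity verdict); clusters are separated by strictly
    more than the similar window. Tabulation under ``policy`` therefore
    returns exactly ``n_episodes``.
    """
    if n_episodes < 0:
        raise ValueError("n_episodes must be >= 0")
    records: list[InfectionRecord] = []
    pathogens = list(PATHOGEN_PREVALENCE)
    pweights = np.array(list(PATHOGEN_PREVALENCE.values()))
    pweights = pweights / pweights.sum()
    iweights = np.array(_ITYPE_WEIGHTS, dtype=float)
    iweights = iweights / iweights.sum()

    day = float(first_day)
    for _ in range(n_episodes):
        itype = _ITYPES[rng.choice(len(_ITYPES), p=iweights)]
        mode = "burn wound" if itype == "burn wound" else "nosocomial"
        pathogen = pathogens[rng.choice(len(pathogens), p=pweights)]
        n_rec = int(rng.integers(1, 4))
        t = day
        for j in range(n_rec):
            records.append(InfectionRecord(patient_id=patient_id, day=round(t, 3),
                                           itype=itype, mode=mode,
                                           pathogen=pathogen))
            if j < n_rec - 1:
                t += rng.uniform(0.25, policy.dissimilar_window)
        # next cluster opens strictly beyond the similar window of the
        # last record in this one
        day = t + policy.similar_window + rng.uniform(0.5, 3.0)
    return records


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = 0
                    ) -> tuple[list[PatientRecord], list[InfectionRecord]]:
    """Draw one synthetic cohort; deterministic under (config, seed)."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    patients: list[PatientRecord] = []
    infections: list[InfectionRecord] = []
    etio_names = list(config.etiology_weights)
    etio_w = np.array(list(config.etiology_weights.values()), dtype=float)
    etio_w = etio_w / etio_w.sum()

    specs = [("C", True, config.n_cases), ("N", False, config.n_noncases)]
    for prefix, is_case, n in specs:
        g = 1 if is_case else 0
        ratio_mu, ratio_sg = lognormal_params(
            *(config.ratio_case if is_case else config.ratio_noncase))
        il10_mu, il10_sg = lognormal_params(*config.il10_pg_ml)
        tbsa_ms = config.tbsa_case if is_case else config.tbsa_noncase
        apache_ms = config.apacheii_case if is_case else config.apacheii_noncase
        hosp_ms = (config.hospital_days_case if is_case
                   else config.hospital_days_noncase)

        # Gaussian copula: the ratio's normal score drives TBSA and
        # APACHEII with loading rho, so the inverse ratio-severity
        # correlation seen in the stratified comparisons is planted
        # within group while every marginal stays exactly as configured.
        rho = config.severity_ratio_coupling
        z_r = rng.standard_normal(n)
        z_t = rho * z_r + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
        z_a = rho * z_r + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
        ratios = np.exp(ratio_mu + ratio_sg * z_r)
        il10 = rng.lognormal(il10_mu, il10_sg, n)
        tbsa = _truncnorm_ppf(sps.norm.cdf(z_t), *tbsa_ms, *config.tbsa_support)
        age = _truncnorm(rng, *config.age, *config.age_support, n)
        bmi = _truncnorm(rng, *config.bmi, *config.bmi_support, n)
        draw_h = _truncnorm(rng, *config.blood_draw_h,
                            *config.blood_draw_support, n)
        adm_h = _truncnorm(rng, *config.admission_delay_h,
                           *config.admission_delay_support, n)
        apache = np.clip(np.rint(_truncnorm_ppf(sps.norm.cdf(z_a), *apache_ms,
                                                *config.apacheii_support)),
                         *config.apacheii_support).astype(int)
        inhal = rng.random(n) < config.inhalation_p[g]
        male = rng.random(n) < config.male_p[g]
        second = rng.random(n) < config.second_degree_p[g]
        third = rng.random(n) < config.third_degree_p[g]
        died = rng.random(n) < config.died_p[g]
        hosp = _truncnorm(rng, *hosp_ms, 1.0, 400.0, n)

        if is_case:
            r_nb, mean_nb = config.episode_case_nb
            p_nb = r_nb / (r_nb + mean_nb)
            counts = 3 + rng.negative_binomial(r_nb, p_nb, n)
        else:
            counts = rng.choice(3, size=n, p=config.episode_noncase_probs)

        for i in range(n):
            pid = f"{prefix}{i + 1:03d}"
            k = int(counts[i])
            if k > 0:
                # eligibility by construction: first infection no sooner
                # than 24 h after the blood draw
                lo = max(config.first_infection_min_day,
                         (draw_h[i] + 24.0) / 24.0)
                m, s = config.first_infection_day
                first = float(_truncnorm(rng, max(m, lo), s, lo, lo + 30.0, 1)[0])
                infections.extend(generate_infection_history(
                    k, config.policy, rng, patient_id=pid, first_day=first))
            patients.append(PatientRecord(
                patient_id=pid,
                age=float(age[i]),
                sex="male" if male[i] else "female",
                bmi=float(bmi[i]),
                etiology=etio_names[rng.choice(len(etio_names), p=etio_w)],
                tbsa=float(tbsa[i]),
                second_degree=bool(second[i]),
                third_degree=bool(third[i]),
                inhalation=bool(inhal[i]),
                admission_delay_h=float(adm_h[i]),
                blood_draw_h=float(draw_h[i]),
                tnf_pg_ml=float(ratios[i] * il10[i]),
                il10_pg_ml=float(il10[i]),
                apacheii=int(apache[i]),
                icu_days=float(max(1.0, rng.normal(20.0, 10.0))),
                died=bool(died[i]),
                hospital_days=float(hosp[i]),
            ))
    return patients, infections
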