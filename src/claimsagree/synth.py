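"""Seedable synthetic cohort emulating a 1974 Quebec birth cohort with a
30-year administrative-claims lookback and a balanced stratified survey.

The generator produces, for a configurable cohort size, per-person latent
asthma classes (never / transient childhood / persistent / adult-onset),
dated asthma physician claims (from 1983) and hospitalizations (from 1987)
until a 2012 interview, self-reports whose accuracy increases with disease
duration and hospitalization, Table-1-style categorical covariates with
realistic missingness, provincial-coverage gaps, and BCG status.  Strata for
the survey cross BCG with childhood asthma under the pre-1995 claims
definition; near-equal numbers are drawn per stratum, a participation rate
thins the invitees, and design weights follow from realized counts.  The
latent ground truth is retained so recovery tests can compare survey-weighted
estimates with full-cohort values.

Default rates were chosen once so that, in the sampled survey, the crude
prevalence of the claims algorithms sits near one half (by design, half the
strata have childhood asthma) and the design-corrected prevalence sits in the
low teens, with self-reported ever-asthma a few points higher — the regime
the analysis pipeline is meant for.  They are configuration, not estimates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .ascertainment import AlgorithmSpec, SAMPLING_DEFINITION, classify_cohort
from .design import DesignWeights, assign_stratum, compute_weights
from .events import EVENT_COLUMNS, normalize_events

__all__ = ["CohortConfig", "CohortDataset", "SurveySample", "generate_cohort", "sample_survey"]

_ANCHOR = np.datetime64("1974-07-01")  # common birth anchor for age arithmetic
_CLAIMS_START = np.datetime64("1983-01-01")
_HOSP_START = np.datetime64("1987-01-01")
_ICD10_START = np.datetime64("2006-01-01")

CLASSES = ("never", "transient", "persistent", "adult_onset")

#: Table-1-like categorical covariate distributions for the cohort
#: (category -> probability; "" is the missing marker).
DEFAULT_COVARIATES: dict[str, dict[str, float]] = {
    "sex": {"male": 0.44, "female": 0.56},
    "language": {"French": 0.935, "English": 0.065},
    "parental_birthplace": {
        "In Quebec": 0.834, "Outside Quebec": 0.074,
        "In and outside Quebec": 0.049, "": 0.043,
    },
    "area_of_residence": {
        "All urban": 0.588, "All rural": 0.104, "Urban and rural": 0.301, "": 0.007,
    },
    "income_quartile": {
        "Q1": 0.091, "Q2": 0.289, "Q3": 0.372, "Q4": 0.235, "": 0.013,
    },
    "material_deprivation": {
        "1": 0.090, "2": 0.229, "3": 0.281, "4": 0.235, "5": 0.055, "": 0.110,
    },
    "social_deprivation": {
        "1": 0.083, "2": 0.297, "3": 0.260, "4": 0.210, "5": 0.039, "": 0.110,
    },
    "maternal_education": {
        "Elementary": 0.275, "Secondary": 0.362, "College": 0.133,
        "University": 0.134, "": 0.096,
    },
    "paternal_education": {
        "Elementary": 0.305, "Secondary": 0.288, "College": 0.093,
        "University": 0.192, "": 0.122,
    },
}


@dataclass
class CohortConfig:
    """Study conditions for the generator; probabilities are per person."""

    n_cohort: int = 80_000
    seed: int = 0
    # latent class mix
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "never": 0.835, "transient": 0.095, "persistent": 0.040,
            "adult_onset": 0.030,
        }
    )
    # yearly asthma claim intensity while the disease is active
    claim_rate: dict[str, float] = field(
        default_factory=lambda: {"transient": 0.9, "persistent": 0.7, "adult_onset": 0.7}
    )
    # yearly hospitalization intensity while active (hospital data era only)
    hosp_rate: dict[str, float] = field(
        default_factory=lambda: {"transient": 0.015, "persistent": 0.02, "adult_onset": 0.012}
    )
    # stray claims among the never class: P(0), P(1), P(2)
    stray_claim_probs: tuple[float, float, float] = (0.885, 0.100, 0.015)
    # self-report sensitivity: expit(b0 + b1*duration_years + b2*any_hosp)
    report_intercept: float = -0.8
    report_duration_slope: float = 0.20
    report_hospital_bonus: float = 1.5
    false_positive_report: float = 0.055
    physician_confirm_true: float = 0.95
    physician_confirm_false_positive: float = 0.55
    ever_missing: float = 0.002
    physician_missing: float = 0.001
    bcg_prob: float = 0.5
    participation: float = 0.56
    exclude_single_claim: bool = True
    coverage_gap_prob: float = 0.02
    # allergy-services covariate: higher among source-discordant persons
    allergy_rate_concordant: float = 0.42
    allergy_rate_discordant: float = 0.70
    parental_asthma_given_disease: float = 0.25
    parental_asthma_given_never: float = 0.135
    parental_asthma_missing: float = 0.06
    covariates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()}
    )

    def validate(self) -> None:
        probs = np.array([self.class_probs[c] for c in CLASSES])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class probabilities must be nonnegative and sum to 1")
        for name, val in (
            ("participation", self.participation),
            ("false_positive_report", self.false_positive_report),
            ("bcg_prob", self.bcg_prob),
            ("coverage_gap_prob", self.coverage_gap_prob),
        ):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.stray_claim_probs) - 1.0) > 1e-9:
            raise ValueError("stray claim probabilities must sum to 1")
        for var, dist in self.covariates.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 5e-3:
                raise ValueError(f"covariate {var!r} distribution sums to {tot}")

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class CohortDataset:
    """Linked persons / events / self-reports bundle with latent truth."""

    persons: pd.DataFrame
    events: pd.DataFrame
    self_reports: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        persons = self.persons.copy()
        persons["interview_date"] = pd.to_datetime(
            persons["interview_date"]
        ).dt.strftime("%Y-%m-%d")
        persons.to_csv(outdir / "persons.csv", index=False)
        ev = self.events.copy()
        ev["date"] = pd.to_datetime(ev["date"]).dt.strftime("%Y-%m-%d")
        ev.to_csv(outdir / "events.csv", index=False)
        self.self_reports.to_csv(outdir / "self_reports.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


@dataclass
class SurveySample:
    """Participants of one simulated survey draw with their design weights."""

    participants: pd.DataFrame  # person_id, stratum, weight, childhood_asthma
    design: DesignWeights


def _uniform_dates(rng, starts: np.ndarray, ends: np.ndarray, counts: np.ndarray):
    """Uniform integer-day draws per person inside [start, end] windows."""
    person_idx = np.repeat(np.arange(len(counts)), counts)
    lo = starts[person_idx].astype("datetime64[D]").astype(np.int64)
    hi = ends[person_idx].astype("datetime64[D]").astype(np.int64)
    days = lo + np.floor(rng.random(len(person_idx)) * (hi - lo + 1)).astype(np.int64)
    return person_idx, days.astype("datetime64[D]")


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> CohortDataset:
    """Draw one full cohort; deterministic given (config, seed)."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_cohort

    ids = np.array([f"P{i:06d}" for i in range(n)])
    bcg = rng.random(n) < config.bcg_prob
    interview = np.datetime64("2012-01-01") + rng.integers(0, 365, n).astype("timedelta64[D]")

    classes = rng.choice(len(CLASSES), size=n, p=[config.class_probs[c] for c in CLASSES])
    cls = np.array(CLASSES)[classes]

    onset = np.zeros(n)
    duration = np.zeros(n)
    interview_age = (interview - _ANCHOR).astype("timedelta64[D]").astype(float) / 365.25
    m = cls == "transient"
    onset[m] = rng.uniform(2, 8, m.sum())
    duration[m] = rng.uniform(3, 12, m.sum())
    m = cls == "persistent"
    onset[m] = rng.uniform(2, 12, m.sum())
    duration[m] = interview_age[m] - onset[m]
    m = cls == "adult_onset"
    onset[m] = rng.uniform(18, 35, m.sum())
    duration[m] = interview_age[m] - onset[m]

    active_start = _ANCHOR + (onset * 365.25).astype("timedelta64[D]")
    active_end = _ANCHOR + ((onset + duration) * 365.25).astype("timedelta64[D]")
    active_end = np.minimum(active_end, interview)

    # physician claims inside the active window, claims era only
    c_lo = np.maximum(active_start, _CLAIMS_START)
    c_hi = np.minimum(active_end, interview)
    c_years = np.maximum(
        (c_hi - c_lo).astype("timedelta64[D]").astype(float) / 365.25, 0.0
    )
    rate = np.array([config.claim_rate.get(c, 0.0) for c in cls])
    n_claims = rng.poisson(rate * c_years)
    n_claims[cls == "never"] = 0

    # stray claims among the never class
    never = cls == "never"
    strays = rng.choice([0, 1, 2], size=n, p=list(config.stray_claim_probs))
    strays[~never] = 0

    # hospitalizations, hospital-data era only
    h_lo = np.maximum(active_start, _HOSP_START)
    h_hi = np.minimum(active_end, interview)
    h_years = np.maximum(
        (h_hi - h_lo).astype("timedelta64[D]").astype(float) / 365.25, 0.0
    )
    hrate = np.array([config.hosp_rate.get(c, 0.0) for c in cls])
    n_hosp = rng.poisson(hrate * h_years)

    pi, claim_dates = _uniform_dates(rng, c_lo, c_hi, np.where(c_years > 0, n_claims, 0))
    si, stray_dates = _uniform_dates(
        rng, np.full(n, _CLAIMS_START), interview, strays
    )
    hi_, hosp_dates = _uniform_dates(rng, h_lo, h_hi, np.where(h_years > 0, n_hosp, 0))

    claim_idx = np.concatenate([pi, si])
    claim_days = np.concatenate([claim_dates, stray_dates])
    events = pd.DataFrame(
        {
            "person_id": np.concatenate([ids[claim_idx], ids[hi_]]),
            "date": pd.to_datetime(np.concatenate([claim_days, hosp_dates])),
            "kind": ["physician_claim"] * len(claim_idx)
            + ["hospitalization"] * len(hi_),
        }
    )
    is_hosp = events["kind"].eq("hospitalization").to_numpy()
    icd10 = is_hosp & (events["date"].to_numpy() >= _ICD10_START)
    events["code"] = np.where(icd10, "J45", "493")
    events["code_system"] = np.where(icd10, "ICD10", "ICD9")
    events = events.sort_values(["person_id", "date", "kind"]).reset_index(drop=True)
    events = events[EVENT_COLUMNS]

    # self-report: accuracy rises with duration and hospitalization
    any_hosp = np.zeros(n, dtype=bool)
    any_hosp[hi_] = True  # repeated assignment is fine: any index present => True
    sens = expit(
        config.report_intercept
        + config.report_duration_slope * duration
        + config.report_hospital_bonus * any_hosp
    )
    u = rng.random(n)
    ever = np.where(never, u < config.false_positive_report, u < sens)
    confirm_p = np.where(never, config.physician_confirm_false_positive, config.physician_confirm_true)
    physician = ever & (rng.random(n) < confirm_p)
    ever_obj = pd.array(ever, dtype="boolean")
    phys_obj = pd.array(physician, dtype="boolean")
    miss_ever = rng.random(n) < config.ever_missing
    miss_phys = miss_ever | (rng.random(n) < config.physician_missing)
    ever_obj[miss_ever] = pd.NA
    phys_obj[miss_phys] = pd.NA

    # coverage gaps (information available 1983-1994 only)
    gap = rng.random(n) < config.coverage_gap_prob
    gap_start = np.datetime64("1983-01-01") + rng.integers(0, 365 * 10, n).astype("timedelta64[D]")
    gap_len = rng.integers(180, 730, n).astype("timedelta64[D]")
    gap_end = np.minimum(gap_start + gap_len, np.datetime64("1994-12-31"))
    gaps = np.where(
        gap,
        np.char.add(
            np.char.add(gap_start.astype("datetime64[D]").astype(str), "/"),
            gap_end.astype("datetime64[D]").astype(str),
        ),
        "",
    )

    persons = pd.DataFrame(
        {
            "person_id": ids,
            "birth_year": 1974,
            "interview_date": pd.to_datetime(interview),
            "bcg": bcg,
            "coverage_gaps": gaps,
        }
    )

    # covariates: independent Table-1-style draws ...
    for var, dist in config.covariates.items():
        levels = list(dist)
        p = np.array([dist[k] for k in levels], dtype=float)
        p = p / p.sum()
        draw = rng.choice(len(levels), size=n, p=p)
        persons[var] = pd.array(
            [levels[j] if levels[j] else None for j in draw], dtype="string"
        )

    # ... parental asthma linked to the latent class ...
    pa_p = np.where(never, config.parental_asthma_given_never, config.parental_asthma_given_disease)
    pa = np.where(rng.random(n) < pa_p, "Yes", "No")
    pa_missing = rng.random(n) < config.parental_asthma_missing
    persons["parental_asthma"] = pd.array(
        np.where(pa_missing, None, pa), dtype="string"
    )

    # ... allergy services enriched among persons whose two sources disagree,
    # which requires the 30-year administrative status
    asthma_events = normalize_events(events)
    k30 = classify_cohort(asthma_events, persons, AlgorithmSpec(window_years=30))
    admin30 = k30.set_index("person_id")["status"].reindex(ids).to_numpy()
    discordant = admin30 != np.asarray(ever)
    al_p = np.where(
        discordant, config.allergy_rate_discordant, config.allergy_rate_concordant
    )
    persons["allergy_services"] = pd.array(
        np.where(rng.random(n) < al_p, ">=1", "0"), dtype="string"
    )

    self_reports = pd.DataFrame(
        {"person_id": ids, "ever_asthma": ever_obj, "physician_diagnosed": phys_obj}
    )

    truth = pd.DataFrame(
        {
            "person_id": ids,
            "latent_class": cls,
            "onset_age": onset,
            "duration_years": duration,
            "any_hospitalization": any_hosp,
            "admin_status_30y": admin30,
        }
    )

    return CohortDataset(persons, events, self_reports, truth, config)


def _sampling_classification(cohort: CohortDataset) -> pd.DataFrame:
    """Pre-1995 classification of the whole cohort, cached on the dataset
    (repeated survey draws from one cohort reuse it)."""
    if "sampling" not in cohort._cache:
        asthma_events = normalize_events(cohort.events)
        res = classify_cohort(asthma_events, cohort.persons, SAMPLING_DEFINITION)
        cohort._cache["sampling"] = res.set_index("person_id")
    return cohort._cache["sampling"]


def childhood_asthma_status(cohort: CohortDataset) -> pd.Series:
    """Pre-1995 sampling definition status per person, indexed by person_id."""
    return _sampling_classification(cohort)["status"]


def single_claim_non_asthma(cohort: CohortDataset) -> pd.Series:
    """Persons negative under the sampling definition with exactly one claim
    and no hospitalization before 1995 (excluded from the original frame)."""
    res = _sampling_classification(cohort)
    return (~res["status"]) & (res["n_claims"] == 1) & (res["n_hosp"] == 0)


def sample_survey(
    cohort: CohortDataset,
    per_stratum_target: int = 410,
    seed: int = 0,
    *,
    participation: float | None = None,
    exclude_single_claim: bool | None = None,
) -> SurveySample:
    """Draw one balanced stratified survey from a generated cohort.

    Invitations per stratum are scaled up by the participation rate so the
    realized count lands near ``per_stratum_target``; nonresponse is folded
    into the realized survey counts, and weights are computed from the
    eligible-frame stratum counts over realized participant counts.
    """
    rng = np.random.default_rng(seed)
    cfg = cohort.config
    participation = cfg.participation if participation is None else participation
    if exclude_single_claim is None:
        exclude_single_claim = cfg.exclude_single_claim

    status = childhood_asthma_status(cohort)
    frame = cohort.persons[["person_id", "bcg"]].copy()
    frame["childhood_asthma"] = frame["person_id"].map(status).astype(bool)
    if exclude_single_claim:
        single = single_claim_non_asthma(cohort)
        frame = frame[~frame["person_id"].map(single).fillna(False)]
    frame["stratum"] = [
        assign_stratum(b, a) for b, a in zip(frame["bcg"], frame["childhood_asthma"])
    ]

    invited = max(1, round(per_stratum_target / participation))
    parts = []
    cohort_counts: dict[str, int] = {}
    for stratum, grp in frame.groupby("stratum"):
        cohort_counts[stratum] = len(grp)
        take = min(invited, len(grp))
        if take < invited:
            import warnings

            warnings.warn(
                f"stratum {stratum} smaller than invitation target; capped at {take}"
            )
        pick = grp.sample(n=take, random_state=np.random.RandomState(rng.integers(2**31)))
        responded = rng.random(len(pick)) < participation
        parts.append(pick[responded])
    participants = pd.concat(parts).reset_index(drop=True)

    survey_counts = participants["stratum"].value_counts().to_dict()
    design = compute_weights(cohort_counts, survey_counts)
    participants["weight"] = design.person_weights(participants["stratum"])
    return SurveySample(participants[["person_id", "stratum", "weight", "childhood_asthma"]], design)
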