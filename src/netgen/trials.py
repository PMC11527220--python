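"""Emulated target trials on longitudinal patient records.

Observational prescription and diagnosis tables are structured to mimic a
randomized trial of a candidate drug: eligibility filters, a disease
"initiation" date (six months before the first disease diagnosis, to absorb
diagnostic latency), an index date at first exposure, an active-comparator
control arm drawn from the same ATC level-3 drug class, ridge-penalized
logistic propensity scores with 1:1 nearest-neighbor matching, standardized
mean-difference balance gates, and a Cox proportional-hazards estimate of
the hazard ratio with patient-level bootstrap confidence intervals. Many
trial replicates are emulated by re-subsampling the control pool; a drug's
reported effect is the median hazard ratio over its balanced replicates.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

SIX_MONTHS_DAYS = 182  # deterministic stand-in for "six calendar months"
DEFAULT_MIN_USERS = 100
DEFAULT_N_EMULATIONS = 100
DEFAULT_N_BOOT = 1000
SMD_THRESHOLD = 0.2
MAX_UNBALANCED_FRACTION = 0.02
MIN_BALANCED_TRIALS = 10


@dataclass
class PatientTables:
    """The three longitudinal inputs, with dates parsed to Timestamps.

    patients: columns id, birth_date, sex, race
    diagnoses: columns id, icd, date
    prescriptions: columns id, ingredient, atc, date
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame

    def __post_init__(self) -> None:
        self.patients = self.patients.copy()
        self.patients["birth_date"] = pd.to_datetime(self.patients["birth_date"], errors="coerce")
        self.diagnoses = self.diagnoses.copy()
        self.diagnoses["date"] = pd.to_datetime(self.diagnoses["date"])
        self.prescriptions = self.prescriptions.copy()
        self.prescriptions["date"] = pd.to_datetime(self.prescriptions["date"])

    @classmethod
    def from_csvs(cls, patients_csv, diagnoses_csv, prescriptions_csv) -> "PatientTables":
        return cls(
            patients=pd.read_csv(patients_csv, dtype={"id": str}),
            diagnoses=pd.read_csv(diagnoses_csv, dtype={"id": str, "icd": str}),
            prescriptions=pd.read_csv(
                prescriptions_csv, dtype={"id": str, "ingredient": str, "atc": str}
            ),
        )

    def last_encounter(self) -> pd.Series:
        """Per-patient date of the last recorded event (censoring date)."""
        dx = self.diagnoses.groupby("id")["date"].max()
        rx = self.prescriptions.groupby("id")["date"].max()
        return pd.concat([dx, rx], axis=1).max(axis=1)


@dataclass
class TrialSpec:
    """Configuration of one emulated-trial family for a tested drug."""

    drug: str                      # ingredient code of the tested drug
    outcome_codes: tuple[str, ...]  # ICD prefixes defining the outcome
    disease_codes: tuple[str, ...]  # ICD prefixes defining the index disease
    exclusion_codes: tuple[str, ...] = ()  # prior diagnoses that exclude a patient
    comorbidity_codes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    medication_ingredients: tuple[str, ...] = ()
    min_age: float = 50.0
    min_users: int = DEFAULT_MIN_USERS
    n_emulations: int = DEFAULT_N_EMULATIONS
    control_subsample_fraction: float = 0.8


def _codes_match(icd: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    if not prefixes:
        return pd.Series(False, index=icd.index)
    return icd.str.startswith(tuple(prefixes))


def apply_eligibility(tables: PatientTables, spec: TrialSpec) -> pd.DataFrame:
    """Eligible patients with their first disease-diagnosis date.

    Keeps patients having at least one disease code, aged at least
    ``min_age`` at that first diagnosis, and with no exclusion diagnosis
    strictly before it. Patients with a missing birth date are excluded and
    counted in the log.
    """
    dx = tables.diagnoses
    disease = dx[_codes_match(dx["icd"], spec.disease_codes)]
    first_dx = disease.groupby("id")["date"].min().rename("first_disease_date")
    out = tables.patients.set_index("id").join(first_dx, how="inner")

    n_missing_birth = int(out["birth_date"].isna().sum())
    if n_missing_birth:
        logger.warning("apply_eligibility: %d patients lack a birth date; excluded", n_missing_birth)
    out = out[out["birth_date"].notna()]

    age = (out["first_disease_date"] - out["birth_date"]).dt.days / 365.25
    out = out[age >= spec.min_age]

    if spec.exclusion_codes:
        excl = dx[_codes_match(dx["icd"], spec.exclusion_codes)]
        first_excl = excl.groupby("id")["date"].min()
        joined = out.join(first_excl.rename("first_excl_date"))
        out = out[~(joined["first_excl_date"] < joined["first_disease_date"])]
    return out.reset_index()[["id", "birth_date", "sex", "race", "first_disease_date"]]


def assign_dates(
    eligible: pd.DataFrame, tables: PatientTables, drug: str, spec: TrialSpec
) -> pd.DataFrame:
    """Initiation, index and baseline window for patients exposed to ``drug``.

    Initiation = first disease diagnosis minus six months; index = first
    prescription of the drug. Patients are kept only if the index follows
    initiation and the first outcome (if any) is strictly after the index.
    The baseline window is [initiation, index).
    """
    rx = tables.prescriptions
    first_rx = (
        rx[rx["ingredient"] == drug].groupby("id")["date"].min().rename("index_date")
    )
    df = eligible.set_index("id").join(first_rx, how="inner")
    df["initiation_date"] = df["first_disease_date"] - pd.Timedelta(days=SIX_MONTHS_DAYS)
    df = df[df["index_date"] > df["initiation_date"]]

    dx = tables.diagnoses
    outcome = dx[_codes_match(dx["icd"], spec.outcome_codes)]
    first_outcome = outcome.groupby("id")["date"].min().rename("first_outcome_date")
    df = df.join(first_outcome)
    df = df[~(df["first_outcome_date"] <= df["index_date"])]
    return df.reset_index()


@dataclass
class TrialCohorts:
    treated: pd.DataFrame   # date-assigned rows for the tested drug
    controls: pd.DataFrame  # date-assigned rows for comparator exposure
    skipped: bool = False   # tested drug below the minimum-user threshold


def build_trial_cohorts(
    eligible: pd.DataFrame,
    tables: PatientTables,
    drug: str,
    spec: TrialSpec,
) -> TrialCohorts:
    """Treated and candidate-control cohorts for a tested drug.

    Controls are eligible patients exposed to another drug of the same ATC
    level-3 class (first four ATC characters); a patient exposed to both the
    tested drug and a comparator counts as treated. The tested drug and any
    comparator used by fewer than ``min_users`` patients are skipped.
    """
    rx = tables.prescriptions
    drug_rows = rx[rx["ingredient"] == drug]
    if drug_rows.empty:
        raise ValueError(f"drug {drug!r} absent from the prescription table")
    n_users = drug_rows["id"].nunique()
    if n_users < spec.min_users:
        logger.warning("build_trial_cohorts: %s used by %d (<%d) patients; skipped",
                       drug, n_users, spec.min_users)
        return TrialCohorts(pd.DataFrame(), pd.DataFrame(), skipped=True)

    atc_l3 = {a[:4] for a in drug_rows["atc"].dropna().unique()}
    same_class = rx[rx["atc"].str[:4].isin(atc_l3) & (rx["ingredient"] != drug)]
    comp_users = same_class.groupby("ingredient")["id"].nunique()
    valid_comps = set(comp_users[comp_users >= spec.min_users].index)
    same_class = same_class[same_class["ingredient"].isin(valid_comps)]

    treated = assign_dates(eligible, tables, drug, spec)
    treated_ids = set(treated["id"])

    control_frames = []
    for comp in sorted(valid_comps):
        control_frames.append(assign_dates(eligible, tables, comp, spec))
    if control_frames:
        controls = pd.concat(control_frames).sort_values("index_date")
        controls = controls.drop_duplicates("id", keep="first")
        controls = controls[~controls["id"].isin(treated_ids)]
    else:
        controls = pd.DataFrame(columns=treated.columns)
    return TrialCohorts(treated=treated.reset_index(drop=True),
                        controls=controls.reset_index(drop=True))


def extract_covariates(
    cohort: pd.DataFrame, tables: PatientTables, spec: TrialSpec
) -> pd.DataFrame:
    """Baseline covariate matrix for date-assigned patients.

    Binary comorbidity flags (ICD prefix hits inside the baseline window),
    binary medication flags, male sex, continuous age at index and days from
    initiation to index. Absence of evidence codes to 0.
    """
    idx = cohort.set_index("id")
    out = pd.DataFrame(index=idx.index)

    dx = tables.diagnoses.merge(
        idx[["initiation_date", "index_date"]], left_on="id", right_index=True
    )
    in_window_dx = dx[(dx["date"] >= dx["initiation_date"]) & (dx["date"] < dx["index_date"])]
    for name, prefixes in spec.comorbidity_codes.items():
        hit_ids = set(in_window_dx.loc[_codes_match(in_window_dx["icd"], prefixes), "id"])
        out[f"cm_{name}"] = out.index.isin(hit_ids).astype(float)

    rx = tables.prescriptions.merge(
        idx[["initiation_date", "index_date"]], left_on="id", right_index=True
    )
    in_window_rx = rx[(rx["date"] >= rx["initiation_date"]) & (rx["date"] < rx["index_date"])]
    for ingredient in spec.medication_ingredients:
        hit_ids = set(in_window_rx.loc[in_window_rx["ingredient"] == ingredient, "id"])
        out[f"med_{ingredient}"] = out.index.isin(hit_ids).astype(float)

    out["male"] = (idx["sex"].astype(str).str.upper().str[0] == "M").astype(float)
    out["age"] = (idx["index_date"] - idx["birth_date"]).dt.days / 365.25
    out["days_to_index"] = (idx["index_date"] - idx["initiation_date"]).dt.days.astype(float)
    return out


def standardized_mean_differences(x1: pd.DataFrame, x0: pd.DataFrame) -> pd.Series:
    """Per-covariate |mean1 - mean0| / sqrt((v1 + v0) / 2); 0 when both variances vanish."""
    m1, m0 = x1.mean(), x0.mean()
    v1, v0 = x1.var(ddof=1), x0.var(ddof=1)
    denom = np.sqrt((v1 + v0) / 2.0)
    smd = (m1 - m0).abs() / denom
    return smd.where(denom > 0, 0.0)


@dataclass
class MatchedTrial:
    """One matched treated/control cohort with balance diagnostics."""

    treated_ids: list[str]
    control_ids: list[str]
    propensity: pd.Series          # over all candidates, treated + controls
    iptw: pd.Series                # inverse-probability weights (exported, unused by default HR)
    smd: pd.Series
    balanced: bool
    shortfall: int                 # treated without a match

    @property
    def n_pairs(self) -> int:
        return len(self.control_ids)


def estimate_propensity_and_match(
    treated_x: pd.DataFrame,
    control_x: pd.DataFrame,
    seed: int = 0,
    ridge_c: float = 1.0,
    caliper: float | None = 0.2,
) -> MatchedTrial:
    """Ridge-logistic propensity scores and greedy 1:1 nearest-neighbor matching.

    Continuous covariates are standardized before the fit. Matching runs
    without replacement over treated patients in descending propensity
    order; if controls run out the shortfall is flagged. ``caliper`` is the
    maximum allowed match distance in units of the standard deviation of the
    logit propensity (0.2 by default, the usual choice); treated patients
    with no control inside the caliper go unmatched. Balance is assessed by
    SMD on the matched sample: the trial is balanced if at most 2% of
    covariates exceed SMD 0.2.
    """
    if treated_x.empty or control_x.empty:
        raise ValueError("both arms must be nonempty")
    x = pd.concat([treated_x, control_x])
    y = np.r_[np.ones(len(treated_x)), np.zeros(len(control_x))]
    mu, sd = x.mean(), x.std(ddof=0).replace(0.0, 1.0)
    xs = (x - mu) / sd
    # L2 (ridge) penalty is sklearn's default for LogisticRegression
    model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=1000, random_state=seed)
    model.fit(xs.to_numpy(), y)
    ps = pd.Series(model.predict_proba(xs.to_numpy())[:, 1], index=x.index, name="propensity")

    # match on the logit-propensity scale, the scale the caliper is defined on
    ps_safe = ps.clip(1e-9, 1 - 1e-9)
    logit_ps = np.log(ps_safe / (1.0 - ps_safe))
    max_dist = np.inf
    if caliper is not None:
        max_dist = caliper * float(logit_ps.std(ddof=1))
    ps_treated = logit_ps.iloc[: len(treated_x)].sort_values(ascending=False)
    ps_control = logit_ps.iloc[len(treated_x):]
    ctrl_ids = np.array(ps_control.index)
    ctrl_ps = ps_control.to_numpy()
    used = np.zeros(len(ctrl_ids), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for t_id, t_ps in ps_treated.items():
        if used.all():
            break
        diffs = np.abs(ctrl_ps - t_ps)
        diffs[used] = np.inf
        j = int(np.argmin(diffs))
        if diffs[j] > max_dist:
            continue
        used[j] = True
        pairs.append((t_id, ctrl_ids[j]))
    shortfall = len(treated_x) - len(pairs)
    if shortfall:
        logger.warning("matching: %d treated patients left unmatched", shortfall)

    m_treated = [t for t, _ in pairs]
    m_control = [c for _, c in pairs]
    smd = standardized_mean_differences(treated_x.loc[m_treated], control_x.loc[m_control])
    balanced = (smd > SMD_THRESHOLD).mean() <= MAX_UNBALANCED_FRACTION

    with np.errstate(divide="ignore"):
        iptw = pd.Series(np.where(y == 1, 1.0 / ps, 1.0 / (1.0 - ps)), index=x.index)
    return MatchedTrial(
        treated_ids=m_treated,
        control_ids=m_control,
        propensity=ps,
        iptw=iptw,
        smd=smd,
        balanced=bool(balanced),
        shortfall=shortfall,
    )


def _survival_frame(
    trial: MatchedTrial, cohort_dates: pd.DataFrame, tables: PatientTables, spec: TrialSpec
) -> pd.DataFrame:
    """Duration/event/treatment table for the matched sample.

    Follow-up runs from the index date to the first outcome or to the last
    recorded encounter (censoring), whichever comes first.
    """
    ids = trial.treated_ids + trial.control_ids
    dates = cohort_dates.set_index("id").loc[ids]
    last = tables.last_encounter().reindex(ids)
    dx = tables.diagnoses
    outcome = dx[_codes_match(dx["icd"], spec.outcome_codes)]
    first_outcome = outcome.groupby("id")["date"].min().reindex(ids)

    event = first_outcome.notna() & (first_outcome <= last)
    end = first_outcome.where(event, last)
    duration = (end - dates["index_date"]).dt.days.astype(float).clip(lower=0.5)
    return pd.DataFrame(
        {
            "duration": duration,
            "event": event.astype(int),
            "treated": [1.0] * len(trial.treated_ids) + [0.0] * len(trial.control_ids),
        },
        index=ids,
    )


@dataclass
class EffectEstimate:
    hr: float
    ci_lower: float
    ci_upper: float
    pvalue: float
    n_events: int
    inestimable: bool = False


def estimate_treatment_effect(
    trial: MatchedTrial,
    cohort_dates: pd.DataFrame,
    tables: PatientTables,
    spec: TrialSpec,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> EffectEstimate:
    """Cox hazard ratio (treatment as sole covariate) with bootstrap CI.

    The 95% CI is a percentile interval over patient-level bootstrap
    resamples of the matched sample. Trials with zero outcome events in an
    arm are flagged inestimable.
    """
    surv = _survival_frame(trial, cohort_dates, tables, spec)
    events_by_arm = surv.groupby("treated")["event"].sum()
    if (events_by_arm == 0).any() or len(events_by_arm) < 2:
        return EffectEstimate(np.nan, np.nan, np.nan, np.nan,
                              int(surv["event"].sum()), inestimable=True)
    cph = CoxPHFitter()
    cph.fit(surv, duration_col="duration", event_col="event")
    hr = float(np.exp(cph.params_["treated"]))
    pvalue = float(cph.summary.loc["treated", "p"])

    rng = np.random.default_rng(seed)
    boot_hrs = []
    n = len(surv)
    for _ in range(n_boot):
        sample = surv.iloc[rng.integers(0, n, size=n)]
        by_arm = sample.groupby("treated")["event"].sum()
        if len(by_arm) < 2 or (by_arm == 0).any():
            continue
        try:
            b = CoxPHFitter().fit(sample.reset_index(drop=True),
                                  duration_col="duration", event_col="event")
            boot_hrs.append(float(np.exp(b.params_["treated"])))
        except Exception:  # non-converged resample
            continue
    if len(boot_hrs) >= max(10, n_boot // 10):
        lo, hi = np.percentile(boot_hrs, [2.5, 97.5])
    else:
        lo, hi = np.exp(cph.confidence_intervals_.loc["treated"]).to_numpy()
    return EffectEstimate(hr=hr, ci_lower=float(lo), ci_upper=float(hi),
                          pvalue=pvalue, n_events=int(surv["event"].sum()))


def _emulation_seed(master_seed: int, replicate: int) -> int:
    digest = hashlib.blake2b(f"{master_seed}:trial:{replicate}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass
class DrugTrialSummary:
    """Aggregate of the emulated trials of one drug."""

    drug: str
    n_emulations: int
    n_balanced: int
    median_hr: float
    ci_lower: float
    ci_upper: float
    excluded: bool               # fewer than the minimum balanced trials
    trials: list[EffectEstimate]


def run_emulations(
    tables: PatientTables,
    spec: TrialSpec,
    seed: int = 0,
    n_boot: int = DEFAULT_N_BOOT,
) -> DrugTrialSummary:
    """Full pipeline for one drug: eligibility, cohorts, repeated matched trials.

    Each of ``spec.n_emulations`` replicates subsamples the control pool
    (fraction ``control_subsample_fraction``) before propensity matching, so
    replicates differ only through their seed-derived subsample. Drugs with
    fewer than 10 balanced replicates are excluded. The reported estimate is
    the median hazard ratio over balanced replicates; the CI endpoints are
    the medians of the per-replicate bootstrap CI endpoints.
    """
    eligible = apply_eligibility(tables, spec)
    cohorts = build_trial_cohorts(eligible, tables, spec.drug, spec)
    if cohorts.skipped or cohorts.treated.empty or cohorts.controls.empty:
        return DrugTrialSummary(spec.drug, 0, 0, np.nan, np.nan, np.nan, True, [])

    treated_x = extract_covariates(cohorts.treated, tables, spec)
    control_x_full = extract_covariates(cohorts.controls, tables, spec)
    all_dates = pd.concat([cohorts.treated, cohorts.controls], ignore_index=True)

    estimates: list[EffectEstimate] = []
    n_balanced = 0
    for rep in range(spec.n_emulations):
        rep_seed = _emulation_seed(seed, rep)
        rng = np.random.default_rng(rep_seed)
        n_sub = max(1, int(round(spec.control_subsample_fraction * len(control_x_full))))
        sub_idx = rng.choice(len(control_x_full), size=n_sub, replace=False)
        control_x = control_x_full.iloc[np.sort(sub_idx)]
        trial = estimate_propensity_and_match(treated_x, control_x, seed=rep_seed)
        if not trial.balanced:
            continue
        n_balanced += 1
        est = estimate_treatment_effect(trial, all_dates, tables, spec,
                                        n_boot=n_boot, seed=rep_seed)
        if not est.inestimable:
            estimates.append(est)

    usable = [e for e in estimates if np.isfinite(e.hr)]
    excluded = n_balanced < MIN_BALANCED_TRIALS
    if usable:
        median_hr = float(np.median([e.hr for e in usable]))
        ci_lo = float(np.median([e.ci_lower for e in usable]))
        ci_hi = float(np.median([e.ci_upper for e in usable]))
    else:
        median_hr = ci_lo = ci_hi = np.nan
    return DrugTrialSummary(
        drug=spec.drug,
        n_emulations=spec.n_emulations,
        n_balanced=n_balanced,
        median_hr=median_hr,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        excluded=excluded,
        trials=usable,
    )
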