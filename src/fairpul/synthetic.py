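"""Seeded synthetic EHR cohort generator with group-biased labeling.

The generator emulates the statistical setting of positive-unlabeled disease
phenotyping in a multi-group EHR cohort:

* each patient belongs to a self-reported race/ethnicity group with a
  group-specific true disease prevalence (the generative class prior);
* only a fraction of true cases carry the disease diagnosis code, with a
  group-specific labeling sensitivity (underdiagnosis) that is additionally
  biased toward feature-rich patients — the "selected at random" labeling
  mechanism, under which labeled cases are a biased, not i.i.d., sample of
  all cases;
* binary diagnosis features are far more prevalent in true cases than in
  controls for neurological codes, mildly enriched for vascular/metabolic
  risk factors, and uninformative for background noise codes;
* continuous utilization covariates (record length, encounter density,
  diagnosis count) are shifted upward in cases;
* a subset of unlabeled true cases carries proxy diagnosis codes or
  disease-specific medications, providing silver-standard validation labels.

All randomness flows from a single seed, so identical configurations yield
identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import CohortTables, write_cohort  # noqa: F401  (write_cohort re-exported)

__all__ = [
    "FeatureSpec",
    "CovariateSpec",
    "SimConfig",
    "default_sim_config",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_GROUPS",
]

DEFAULT_GROUPS = ("NH-white", "NH-AfAm", "HL", "EA")

#: Disease diagnosis code carried by labeled positives.
DISEASE_ICD = "G30.9"

#: Proxy ICD codes a latent (unlabeled) case may carry instead of a diagnosis.
PROXY_POOL_ICDS = ("F01.51", "F03.90", "F03.91", "G31.84", "G31.85", "R41.3", "F02.81")
#: Disease-specific medications serving as proxy evidence.
PROXY_POOL_MEDS = (
    "donepezil",
    "rivastigmine",
    "galantamine",
    "memantine",
    "memantine/donepezil",
)
#: Medications unrelated to the disease, given to random patients as noise.
NOISE_MEDS = ("atorvastatin", "metformin", "lisinopril")

#: Fixed last-visit reference date; only relative event ordering matters.
REFERENCE_DATE = pd.Timestamp("2023-06-30")


class ConfigurationError(ValueError):
    """Raised for non-finite or out-of-range simulation parameters."""


@dataclass(frozen=True)
class FeatureSpec:
    """One binary diagnosis feature: ICD code with class-conditional prevalence."""

    code: str
    prevalence_in_cases: float
    prevalence_in_controls: float


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution parameters for the continuous utilization covariates.

    Record length (years) and encounter density (encounters/year) are
    offset-gamma distributed with an additive shift for true cases;
    diagnosis counts are Poisson with separate case/control rates. Ages are
    uniform over ``age_range`` so every patient passes the 65–90 eligibility
    window by default.
    """

    age_range: tuple[float, float] = (65.0, 90.0)
    record_length_shape: float = 2.0
    record_length_scale: float = 4.0
    record_length_min: float = 5.0
    record_length_case_shift: float = 2.0
    density_shape: float = 2.0
    density_scale: float = 1.2
    density_min: float = 1.0
    density_case_shift: float = 0.8
    n_diagnoses_control: float = 20.0
    n_diagnoses_case: float = 34.0


def _default_feature_spec() -> tuple[FeatureSpec, ...]:
    rows = [
        # neurological / cognitive codes: near-absent in controls
        ("R41.3", 0.35, 0.010),
        ("F03.90", 0.22, 0.004),
        ("G31.84", 0.18, 0.005),
        ("F32.9", 0.25, 0.080),
        ("G47.00", 0.22, 0.100),
        ("R26.81", 0.15, 0.030),
        ("W19", 0.20, 0.050),
        # vascular / metabolic risk factors: mildly enriched in cases
        ("I10", 0.65, 0.500),
        ("E78.5", 0.55, 0.450),
        ("E11.9", 0.30, 0.200),
        ("E11.40", 0.08, 0.030),
        # background comorbidity noise: uninformative
        ("M54.5", 0.30, 0.300),
        ("K21.9", 0.30, 0.280),
        ("N39.0", 0.15, 0.120),
        ("J06.9", 0.18, 0.180),
        ("H52.4", 0.25, 0.250),
        # codes removed by record-level filtering / unmapped codes
        ("Y92.9", 0.05, 0.050),
        ("Z00.00", 0.40, 0.400),
    ]
    return tuple(FeatureSpec(*row) for row in rows)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Defaults encode the study conditions this package targets: four
    race/ethnicity groups with population prevalences 10% (NH-white),
    18.6% (NH-AfAm), 14% (HL) and 7.4% (EA), and labeling sensitivities
    chosen so that the labeled (diagnosed) prevalence lands at the
    underdiagnosed EHR rates of 4.3%, 5.8%, 4.3% and 3.9% respectively.
    """

    n_patients: int = 20_000
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {"NH-white": 0.66, "NH-AfAm": 0.08, "HL": 0.16, "EA": 0.10}
    )
    true_prevalence: dict[str, float] = field(
        default_factory=lambda: {"NH-white": 0.100, "NH-AfAm": 0.186, "HL": 0.140, "EA": 0.074}
    )
    label_sensitivity: dict[str, float] = field(
        default_factory=lambda: {"NH-white": 0.430, "NH-AfAm": 0.312, "HL": 0.307, "EA": 0.527}
    )
    proxy_rate: float = 0.85
    label_bias_weight: float = 1.0
    feature_spec: tuple[FeatureSpec, ...] = field(default_factory=_default_feature_spec)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    female_fraction: float = 0.58
    proxy_med_fraction: float = 0.30
    noise_med_rate: float = 0.08
    ineligible_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        fracs = np.array(list(self.group_fractions.values()), dtype=float)
        if not np.all(np.isfinite(fracs)) or np.any(fracs < 0):
            raise ConfigurationError("group_fractions must be finite and non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("group_fractions must sum to 1")
        for name, mapping in (
            ("true_prevalence", self.true_prevalence),
            ("label_sensitivity", self.label_sensitivity),
        ):
            if set(mapping) != set(self.group_fractions):
                raise ConfigurationError(f"{name} must cover exactly the configured groups")
            vals = np.array(list(mapping.values()), dtype=float)
            if not np.all(np.isfinite(vals)) or np.any((vals < 0) | (vals > 1)):
                raise ConfigurationError(f"{name} values must be probabilities in [0, 1]")
        for prob in (
            self.proxy_rate,
            self.female_fraction,
            self.proxy_med_fraction,
            self.noise_med_rate,
            self.ineligible_fraction,
        ):
            if not (math.isfinite(prob) and 0.0 <= prob <= 1.0):
                raise ConfigurationError("probabilities must be finite and in [0, 1]")
        if not (math.isfinite(self.label_bias_weight) and self.label_bias_weight >= 0):
            raise ConfigurationError("label_bias_weight must be finite and >= 0")
        for spec in self.feature_spec:
            for p in (spec.prevalence_in_cases, spec.prevalence_in_controls):
                if not (math.isfinite(p) and 0.0 <= p <= 1.0):
                    raise ConfigurationError(f"feature {spec.code}: prevalence outside [0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        """Build a config from a plain (YAML/JSON-loaded) dictionary."""
        data = dict(data)
        if "feature_spec" in data:
            data["feature_spec"] = tuple(
                FeatureSpec(str(r["code"]), float(r["prevalence_in_cases"]), float(r["prevalence_in_controls"]))
                if isinstance(r, dict)
                else FeatureSpec(str(r[0]), float(r[1]), float(r[2]))
                for r in data["feature_spec"]
            )
        if "covariate_spec" in data and isinstance(data["covariate_spec"], dict):
            cov = dict(data["covariate_spec"])
            if "age_range" in cov:
                cov["age_range"] = tuple(float(v) for v in cov["age_range"])
            data["covariate_spec"] = CovariateSpec(**cov)
        return cls(**data)


def default_sim_config(n_patients: int = 20_000, seed: int = 0, **overrides) -> SimConfig:
    """The default study-condition configuration with optional overrides."""
    return replace(SimConfig(n_patients=n_patients, seed=seed), **overrides)


def surplus_candidate_config(n_patients: int = 20_000, seed: int = 0) -> SimConfig:
    """Deeper-underdiagnosis conditions for the prevalence-matching study.

    Keeps the labeled (diagnosed) prevalence of every group at the default
    EHR rates (≈4.3%, 5.8%, 4.3%, 3.9%) but raises the latent true
    prevalence, so each group has a surplus of unlabeled true cases whose
    step-2 probabilistic gaps exceed the group threshold. Under these
    conditions the prevalence-matched pseudo-labeling can always fill a
    group's positive labels up to its population target (the default config
    has just enough latent cases, leaving no slack for classifier error).
    """
    return replace(
        SimConfig(n_patients=n_patients, seed=seed),
        true_prevalence={"NH-white": 0.130, "NH-AfAm": 0.240, "HL": 0.180, "EA": 0.110},
        label_sensitivity={"NH-white": 0.331, "NH-AfAm": 0.242, "HL": 0.239, "EA": 0.355},
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimConfig) -> CohortTables:
    """Draw a full synthetic cohort from ``config``.

    Per patient: group, then ``true_case ~ Bernoulli(true_prevalence[group])``.
    True cases receive the disease code with propensity
    ``label_sensitivity[group] * 2*sigmoid(w * z)`` (clipped to [0, 1]) where
    ``z`` is the z-score of the patient's informative-feature burden among
    true cases; ``w = 0`` recovers the "selected completely at random"
    mechanism, and for symmetric burden distributions the labeled prevalence
    per group equals ``true_prevalence * label_sensitivity`` in expectation.
    Unlabeled true cases carry at least one proxy ICD or proxy medication
    with probability ``proxy_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    groups = np.array(list(config.group_fractions))
    group_p = np.array([config.group_fractions[g] for g in groups])

    group = rng.choice(groups, size=n, p=group_p)
    prev = np.array([config.true_prevalence[g] for g in group])
    true_case = rng.random(n) < prev

    # binary feature draws, class-conditional
    codes = [s.code for s in config.feature_spec]
    p_case = np.array([s.prevalence_in_cases for s in config.feature_spec])
    p_ctrl = np.array([s.prevalence_in_controls for s in config.feature_spec])
    p_matrix = np.where(true_case[:, None], p_case[None, :], p_ctrl[None, :])
    has_feature = rng.random((n, len(codes))) < p_matrix

    # feature burden over informative features only (case-enriched codes)
    informative = p_case > p_ctrl
    burden = has_feature[:, informative].sum(axis=1).astype(float)
    if true_case.any():
        mu = burden[true_case].mean()
        sd = burden[true_case].std()
        z = (burden - mu) / sd if sd > 0 else np.zeros(n)
    else:
        z = np.zeros(n)

    sens = np.array([config.label_sensitivity[g] for g in group])
    propensity = np.clip(sens * 2.0 * _sigmoid(config.label_bias_weight * z), 0.0, 1.0)
    labeled = true_case & (rng.random(n) < propensity)

    unlabeled_case = true_case & ~labeled
    has_proxy = unlabeled_case & (rng.random(n) < config.proxy_rate)
    proxy_is_med = rng.random(n) < config.proxy_med_fraction
    proxy_icd_choice = rng.integers(0, len(PROXY_POOL_ICDS), size=n)
    proxy_med_choice = rng.integers(0, len(PROXY_POOL_MEDS), size=n)

    # continuous covariates
    cov = config.covariate_spec
    age = rng.uniform(cov.age_range[0], cov.age_range[1], size=n)
    record_length = (
        cov.record_length_min
        + rng.gamma(cov.record_length_shape, cov.record_length_scale, size=n)
        + cov.record_length_case_shift * true_case
    )
    record_length = np.round(np.minimum(record_length, 40.0), 3)
    density = (
        cov.density_min
        + rng.gamma(cov.density_shape, cov.density_scale, size=n)
        + cov.density_case_shift * true_case
    )
    n_encounters = np.ceil(density * record_length).astype(int)
    n_diagnoses = rng.poisson(np.where(true_case, cov.n_diagnoses_case, cov.n_diagnoses_control))
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")

    # optional injection of patients violating the eligibility filters
    missing_sex = np.zeros(n, dtype=bool)
    missing_group = np.zeros(n, dtype=bool)
    if config.ineligible_fraction > 0:
        k = int(round(config.ineligible_fraction * n))
        chosen = rng.choice(n, size=k, replace=False)
        kinds = np.arange(k) % 5
        idx = chosen[kinds == 0]
        age[idx] = rng.uniform(91.0, 100.0, size=idx.size)
        idx = chosen[kinds == 1]
        record_length[idx] = rng.uniform(1.0, 4.5, size=idx.size)
        idx = chosen[kinds == 2]
        n_encounters[idx] = np.floor(0.5 * record_length[idx]).astype(int)
        missing_sex[chosen[kinds == 3]] = True
        missing_group[chosen[kinds == 4]] = True
    n_encounters = np.maximum(n_encounters, 0)
    record_density = n_encounters / record_length

    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "sex": np.where(missing_sex, "", sex),
            "group": np.where(missing_group, "", group),
            "age_last_visit": np.round(age, 3),
            "record_length": record_length,
            "n_encounters": n_encounters,
            "n_diagnoses": n_diagnoses,
            "record_density": np.round(record_density, 6),
        }
    )

    # diagnosis events: one synthetic encounter date per code, uniform over
    # the record span (dates matter only for first-encounter retention)
    span_days = np.maximum((record_length * 365.25).astype(int), 1)

    def _event_dates(patient_rows: np.ndarray) -> np.ndarray:
        offsets = rng.integers(0, span_days[patient_rows])
        return (REFERENCE_DATE - pd.to_timedelta(offsets, unit="D")).strftime("%Y-%m-%d")

    dx_pid: list[np.ndarray] = []
    dx_code: list[np.ndarray] = []
    dx_date: list[np.ndarray] = []
    for j, code in enumerate(codes):
        rows = np.flatnonzero(has_feature[:, j])
        if rows.size == 0:
            continue
        dx_pid.append(patient_id[rows])
        dx_code.append(np.full(rows.size, code))
        dx_date.append(_event_dates(rows))

    rows = np.flatnonzero(labeled)
    if rows.size:
        dx_pid.append(patient_id[rows])
        dx_code.append(np.full(rows.size, DISEASE_ICD))
        dx_date.append(_event_dates(rows))

    med_pid: list[np.ndarray] = []
    med_name: list[np.ndarray] = []
    med_date: list[np.ndarray] = []
    rows = np.flatnonzero(has_proxy & proxy_is_med)
    if rows.size:
        med_pid.append(patient_id[rows])
        med_name.append(np.array(PROXY_POOL_MEDS)[proxy_med_choice[rows]])
        med_date.append(_event_dates(rows))
    rows = np.flatnonzero(has_proxy & ~proxy_is_med)
    if rows.size:
        dx_pid.append(patient_id[rows])
        dx_code.append(np.array(PROXY_POOL_ICDS)[proxy_icd_choice[rows]])
        dx_date.append(_event_dates(rows))
    for med in NOISE_MEDS:
        rows = np.flatnonzero(rng.random(n) < config.noise_med_rate)
        if rows.size:
            med_pid.append(patient_id[rows])
            med_name.append(np.full(rows.size, med))
            med_date.append(_event_dates(rows))

    def _assemble(pids, values, dates, value_col) -> pd.DataFrame:
        if not pids:
            return pd.DataFrame(columns=["patient_id", value_col, "date"])
        frame = pd.DataFrame(
            {
                "patient_id": np.concatenate(pids),
                value_col: np.concatenate(values),
                "date": np.concatenate(dates),
            }
        )
        return frame.sort_values(["patient_id", value_col, "date"], kind="mergesort").reset_index(
            drop=True
        )

    diagnoses = _assemble(dx_pid, dx_code, dx_date, "icd10cm")
    medications = _assemble(med_pid, med_name, med_date, "drug_name")
    truth = pd.DataFrame({"patient_id": patient_id, "true_case": true_case.astype(int)})

    tables = CohortTables(patients=patients, diagnoses=diagnoses, medications=medications, truth=truth)
    tables.validate()
    return tables
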