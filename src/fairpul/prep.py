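"""Cohort preparation: eligibility filters, ICD hygiene, phecode mapping,
label assignment, stratified splitting, feature building and the per-phecode
enrichment screen.

The preparation stage turns raw patient/diagnosis/medication tables into the
modeling inputs of the positive-unlabeled pipeline: a binary label vector
(labeled positive vs unlabeled), a train/validation/test split stratified by
that label, and a feature matrix of binary phecode indicators plus min-max
scaled utilization covariates, sex, and group indicators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phecodes import DISEASE_PHECODE, in_exclusion_range
from .tables import CohortTables

logger = logging.getLogger(__name__)

#: Continuous covariates min-max scaled into the feature matrix.
COVARIATE_COLUMNS = [
    "age_last_visit",
    "record_length",
    "record_density",
    "n_encounters",
    "n_diagnoses",
]

#: ICD-10-CM first letters removed from the diagnosis table: pregnancy /
#: perinatal / congenital chapters (O, P, Q) and external causes (V, X, Y).
#: W-prefixed external causes (slips, trips and falls) are retained.
_EXCLUDED_PREFIXES = ("O", "P", "Q", "V", "X", "Y")

#: Concurrent dementia code excluded because it duplicates the disease code.
_EXCLUDED_EXACT = frozenset({"F02.80"})

#: Prefix identifying the disease diagnosis (any G30 child counts).
DISEASE_ICD_PREFIX = "G30"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class SplitError(ValueError):
    """Too few labeled positives to populate three non-empty partitions."""


class MappingError(ValueError):
    """The ICD→phecode map is unusable (e.g. empty)."""


def filter_patients(tables: CohortTables) -> pd.Index:
    """Eligible patient ids: regular users of the health system with
    complete demographics.

    Criteria: age at last visit between 65 and 90 inclusive, record length
    of at least 5 years, an average of at least one encounter per year, and
    non-missing sex and group.
    """
    pat = tables.patients
    required = {"patient_id", "sex", "group", *COVARIATE_COLUMNS} - {"record_density"}
    missing = required - set(pat.columns)
    if missing:
        raise SchemaError(f"patients table missing columns {sorted(missing)}")
    density = pat["n_encounters"] / pat["record_length"]
    for col in ("age_last_visit", "record_length", "n_encounters"):
        if not np.isfinite(pat[col].to_numpy(dtype=float)).all():
            raise SchemaError(f"non-finite values in covariate {col!r}")

    def _present(col: pd.Series) -> pd.Series:
        return col.notna() & (col.astype(str).str.strip() != "")

    keep = (
        pat["age_last_visit"].between(65.0, 90.0)
        & (pat["record_length"] >= 5.0)
        & (density >= 1.0)
        & _present(pat["sex"])
        & _present(pat["group"])
    )
    return pd.Index(pat.loc[keep, "patient_id"])


def filter_diagnoses(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Drop diagnosis codes excluded from feature construction.

    Removes pregnancy/perinatal/congenital chapters (O*, P*, Q*), external
    causes except falls (V*, X*, Y* dropped, W* kept), and the concurrent
    dementia code F02.80. Unknown codes pass through.
    """
    codes = diagnoses["icd10cm"].astype(str)
    drop = codes.str.upper().str.startswith(_EXCLUDED_PREFIXES) | codes.isin(_EXCLUDED_EXACT)
    return diagnoses.loc[~drop].reset_index(drop=True)


def map_to_phecodes(
    diagnoses: pd.DataFrame, phecode_map: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Map cleaned diagnoses to phecode events, keeping the first encounter.

    Matching is maximum-granularity: an exact ICD match is tried first, then
    trailing characters are truncated until a parent code matches. Unmapped
    codes are dropped (their count is returned). Per patient only the
    earliest event for each phecode is retained; same-day ties are broken by
    lexicographic ICD order, which cannot change the resulting event.
    """
    if phecode_map is None or len(phecode_map) == 0:
        raise MappingError("empty ICD→phecode map")
    lookup = dict(zip(phecode_map["icd10cm"].astype(str), phecode_map["phecode"].astype(str)))

    def _match(code: str) -> str | None:
        probe = code
        while probe:
            hit = lookup.get(probe)
            if hit is not None:
                return hit
            probe = probe[:-1].rstrip(".")
        return None

    unique_codes = diagnoses["icd10cm"].astype(str).unique()
    code_to_phecode = {c: _match(c) for c in unique_codes}
    phecode = diagnoses["icd10cm"].astype(str).map(code_to_phecode)
    mapped = diagnoses.assign(phecode=phecode).dropna(subset=["phecode"])
    n_unmapped = len(diagnoses) - len(mapped)
    if n_unmapped:
        logger.info("dropped %d diagnosis events with unmapped ICD codes", n_unmapped)
    events = (
        mapped.sort_values(["patient_id", "phecode", "date", "icd10cm"], kind="mergesort")
        .drop_duplicates(subset=["patient_id", "phecode"], keep="first")
        .loc[:, ["patient_id", "phecode", "date"]]
        .reset_index(drop=True)
    )
    return events, n_unmapped


def assign_initial_labels(diagnoses: pd.DataFrame, patient_ids: pd.Index) -> pd.Series:
    """Initial label per patient: ``LP`` iff at least one raw disease
    diagnosis (any G30 code), otherwise ``U``.

    Labels come from raw diagnosis codes before phecode mapping; proxy codes
    never define a labeled positive.
    """
    codes = diagnoses["icd10cm"].astype(str)
    lp_ids = set(diagnoses.loc[codes.str.startswith(DISEASE_ICD_PREFIX), "patient_id"])
    labels = pd.Series(
        np.where(pd.Index(patient_ids).isin(lp_ids), "LP", "U"),
        index=pd.Index(patient_ids, name="patient_id"),
        name="label",
    )
    return labels


def stratified_split(
    labels: pd.Series,
    seed: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> pd.Series:
    """Random train/validation/test assignment stratified by label.

    Labeled positives and unlabeled patients are permuted independently with
    the seed and allocated 80/10/10 within each stratum (floor counts for
    train and validation, remainder to test), keeping the labeled fraction
    equal across partitions up to one patient.
    """
    rng = np.random.default_rng(seed)
    parts = pd.Series(index=labels.index, dtype=object, name="partition")
    n_lp = int((labels == "LP").sum())
    if n_lp < 10:
        raise SplitError(f"need at least 10 labeled positives for 3 non-empty strata, got {n_lp}")
    for stratum in ("LP", "U"):
        ids = labels.index[labels == stratum].to_numpy()
        ids = ids[rng.permutation(ids.size)]
        n_train = int(np.floor(fractions[0] * ids.size))
        n_val = int(np.floor(fractions[1] * ids.size))
        parts[ids[:n_train]] = "train"
        parts[ids[n_train : n_train + n_val]] = "validation"
        parts[ids[n_train + n_val :]] = "test"
    return parts


@dataclass
class FeatureMatrix:
    """Model-ready feature matrix aligned to a split.

    ``X`` holds binary phecode indicator columns, min-max scaled covariates
    (bounds fit on the training partition, values clipped to [0, 1]
    elsewhere), a female-sex indicator and one-hot group indicators. The
    disease phecode itself is never a feature column. Raw group and age are
    kept alongside for thresholding and reliable-negative criteria.
    """

    X: pd.DataFrame
    groups: pd.Series
    age_last_visit: pd.Series
    partition: pd.Series
    phecode_columns: list[str]
    covariate_columns: list[str]
    group_columns: dict[str, str]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def partition_index(self, name: str) -> pd.Index:
        return self.partition.index[self.partition == name]


def build_feature_matrix(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    split: pd.Series,
    fit_partition: str = "train",
) -> FeatureMatrix:
    """Assemble the feature matrix for every patient in ``split``.

    Min-max bounds for the continuous covariates are fit on ``fit_partition``
    only and applied everywhere, with out-of-range values clipped to [0, 1].
    A zero-variance covariate on the fitting partition scales to a column of
    zeros (with a warning).
    """
    ids = split.index
    pat = patients.set_index("patient_id").loc[ids]

    ev = events[events["patient_id"].isin(ids)]
    ev = ev[ev["phecode"] != DISEASE_PHECODE]
    indicator = (
        ev.assign(value=np.uint8(1))
        .pivot_table(index="patient_id", columns="phecode", values="value", fill_value=0)
        .astype(np.uint8)
        .reindex(ids, fill_value=0)
    )
    phecode_columns = sorted(indicator.columns)
    indicator = indicator[phecode_columns]

    covs = pat[COVARIATE_COLUMNS].astype(float)
    bounds: dict[str, tuple[float, float]] = {}
    fit_ids = split.index[split == fit_partition]
    scaled = {}
    for col in COVARIATE_COLUMNS:
        lo = float(covs.loc[fit_ids, col].min())
        hi = float(covs.loc[fit_ids, col].max())
        bounds[col] = (lo, hi)
        if hi > lo:
            scaled[col] = ((covs[col] - lo) / (hi - lo)).clip(0.0, 1.0)
        else:
            logger.warning("covariate %r constant on %s partition; scaled to 0", col, fit_partition)
            scaled[col] = pd.Series(0.0, index=ids)
    scaled_df = pd.DataFrame(scaled, index=ids)

    sex_female = (pat["sex"].astype(str) == "F").astype(np.uint8).rename("sex_female")
    group = pat["group"].astype(str).rename("group")
    group_columns = {g: f"group_{g}" for g in sorted(group.unique())}
    group_dummies = pd.DataFrame(
        {col: (group == g).astype(np.uint8) for g, col in group_columns.items()}, index=ids
    )

    X = pd.concat([indicator, scaled_df, sex_female, group_dummies], axis=1)
    X.index.name = "patient_id"
    return FeatureMatrix(
        X=X,
        groups=group,
        age_last_visit=pat["age_last_visit"].astype(float),
        partition=split,
        phecode_columns=phecode_columns,
        covariate_columns=list(COVARIATE_COLUMNS),
        group_columns=group_columns,
        bounds=bounds,
    )


def phecode_screen(
    phecode_indicators: pd.DataFrame,
    adjusters: pd.DataFrame,
    y: np.ndarray | pd.Series,
    prevalence: pd.Series,
    alpha: float = 0.05,
    min_prevalence: float = 0.01,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> list[str]:
    """Per-phecode logistic enrichment screen with Bonferroni control.

    For each candidate phecode a logistic regression of the positive label
    on that phecode plus the adjuster columns (scaled covariates, sex, group
    indicators) is fit by unpenalized maximum likelihood; the phecode is
    kept when its Wald p-value is below ``alpha / K`` (K = phecodes tested)
    and its prevalence in ``prevalence`` (computed over all eligible
    patients) is at least ``min_prevalence``. Phecodes whose fit fails to
    converge (e.g. perfect separation) are excluded and logged.
    """
    y = np.asarray(y, dtype=float)
    candidates = [c for c in phecode_indicators.columns if c != DISEASE_PHECODE]
    k_tested = len(candidates)
    if k_tested == 0:
        return []
    threshold = alpha / k_tested
    adj = adjusters.to_numpy(dtype=float)
    selected: list[str] = []
    for code in candidates:
        x = phecode_indicators[code].to_numpy(dtype=float)
        design = sm.add_constant(np.column_stack([x, adj]), has_constant="add")
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=maxiter, tol=tol)
            converged = bool(res.mle_retvals.get("converged", False))
            pval = float(res.pvalues[1])
        except Exception:  # separation, singular hessian, ...
            converged, pval = False, np.nan
        if not converged or not np.isfinite(pval):
            logger.info("phecode %s excluded from screen (non-convergent fit)", code)
            continue
        if pval < threshold and float(prevalence.get(code, 0.0)) >= min_prevalence:
            selected.append(code)
    return sorted(selected)


def select_features(
    fm: FeatureMatrix,
    labels: pd.Series,
    prevalence: pd.Series,
    alpha: float = 0.05,
    min_prevalence: float = 0.01,
) -> list[str]:
    """Run the enrichment screen on the training partition of ``fm``.

    Unlabeled patients are treated as controls; the adjusters are the scaled
    utilization covariates, sex, and group indicators (first group dropped
    to avoid collinearity with the intercept).
    """
    train_ids = fm.partition_index("train")
    group_cols = sorted(fm.group_columns.values())[1:]
    adj_cols = fm.covariate_columns + ["sex_female"] + group_cols
    y = (labels.loc[train_ids] == "LP").astype(float)
    return phecode_screen(
        fm.X.loc[train_ids, fm.phecode_columns],
        fm.X.loc[train_ids, adj_cols],
        y,
        prevalence,
        alpha=alpha,
        min_prevalence=min_prevalence,
    )


def phecode_prevalence(events: pd.DataFrame, patient_ids: pd.Index) -> pd.Series:
    """Fraction of patients carrying each phecode, over all eligible patients."""
    ev = events[events["patient_id"].isin(patient_ids)]
    counts = ev.groupby("phecode")["patient_id"].nunique()
    return counts / float(len(patient_ids))
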