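"""Proxy-label validation and the discrimination / calibration / fairness
metric suite.

Gold-standard outcomes are unavailable for unlabeled patients, so test-set
predictions are validated against silver-standard proxies: alternative
dementia diagnosis codes and disease-specific medications. On top of the
validated labels the suite computes standard discrimination metrics,
class-stratified (balanced) Brier scores, expected calibration error, and
group-fairness summaries (signed metric differences against a privileged
group, per-metric parity losses, and their cumulative sum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ProxyDefinition",
    "DEFAULT_PROXY_ICDS",
    "DEFAULT_PROXY_MEDS",
    "proxy_validate",
    "discrimination_metrics",
    "balanced_brier",
    "expected_calibration_error",
    "fairness_differences",
    "parity_losses",
    "FAIRNESS_METRICS",
    "group_metric_report",
]

#: Proxy diagnosis codes: vascular dementia, cerebral degenerations, memory
#: loss, mild cognitive impairment, unspecified/senile dementias.
DEFAULT_PROXY_ICDS = frozenset(
    {
        "F01", "F01.5", "F01.50", "F01.51", "F01.0", "F01.1", "F01.2", "F01.3",
        "F01.9", "F01.511", "F01.518",
        "G31.0", "G31.01", "G31.09", "G31.1", "G31.83",
        "R41.1", "R41.2", "R41.3",
        "G31.84",
        "F03.9", "F03.90", "F03.91", "F03.911", "F03.918",
        "F02", "F02.8", "F02.80", "F02.81", "F02.0", "F02.811", "F02.818",
        "F03",
        "G31.85",
    }
)

#: Disease-specific medications accepted as proxy evidence.
DEFAULT_PROXY_MEDS = frozenset(
    {
        "donepezil",
        "rivastigmine",
        "galantamine",
        "memantine",
        "memantine/donepezil",
        "aducanumab",
        "lecanemab",
    }
)

#: Metrics entering the fairness comparison (EO is the sensitivity gap).
FAIRNESS_METRICS = ("specificity", "precision", "balanced_accuracy", "sensitivity", "gbe")


@dataclass(frozen=True)
class ProxyDefinition:
    """Configurable proxy code sets used for silver-standard validation."""

    proxy_icds: frozenset[str] = DEFAULT_PROXY_ICDS
    proxy_meds: frozenset[str] = DEFAULT_PROXY_MEDS

    def drop_icds(self, codes) -> "ProxyDefinition":
        return ProxyDefinition(self.proxy_icds - set(codes), self.proxy_meds)

    def drop_all_meds(self) -> "ProxyDefinition":
        return ProxyDefinition(self.proxy_icds, frozenset())


def proxy_validate(
    diagnoses: pd.DataFrame,
    medications: pd.DataFrame,
    unlabeled_ids: pd.Index,
    proxies: ProxyDefinition | None = None,
) -> pd.Series:
    """Silver-standard labels for unlabeled patients.

    A patient is validated positive iff they carry at least one proxy ICD
    code (exact or descendant match: ``F01.511`` matches a listed ``F01.5``)
    or at least one proxy medication (matched case-insensitively, combo
    formulations included); otherwise they are considered a healthy control.
    Labeled positives are positives by definition and should not be passed
    in. The raw, pre-filtering diagnosis table must be used — proxy codes
    include codes that record-level filtering removes from the feature set.
    """
    proxies = proxies or ProxyDefinition()
    icd_prefixes = tuple(sorted(proxies.proxy_icds))
    dx = diagnoses[diagnoses["patient_id"].isin(unlabeled_ids)]
    icd_hit: set[str] = set()
    if icd_prefixes and len(dx):
        codes = dx["icd10cm"].astype(str)
        hit = codes.str.startswith(icd_prefixes)
        icd_hit = set(dx.loc[hit, "patient_id"])
    med_hit: set[str] = set()
    if proxies.proxy_meds and len(medications):
        meds = medications[medications["patient_id"].isin(unlabeled_ids)]
        names = meds["drug_name"].astype(str).str.lower()
        tokens = [m.lower() for m in proxies.proxy_meds]
        hit = names.map(lambda s: any(t in s for t in tokens))
        med_hit = set(meds.loc[hit, "patient_id"])
    positive = icd_hit | med_hit
    return pd.Series(
        pd.Index(unlabeled_ids).isin(list(positive)),
        index=pd.Index(unlabeled_ids, name="patient_id"),
        name="proxy_positive",
    )


def discrimination_metrics(y_true, y_pred, probabilities=None) -> dict:
    """Confusion-matrix rates plus rank-based AUC and step-integrated AUCPR.

    Precision is reported as ``None`` (missing) when there are no predicted
    positives rather than 0, so that downstream parity losses are not
    corrupted. AUC/AUCPR require both classes and ``probabilities``.
    """
    y = np.asarray(y_true, dtype=bool)
    pred = np.asarray(y_pred, dtype=bool)
    tp = int((y & pred).sum())
    fp = int((~y & pred).sum())
    fn = int((y & ~pred).sum())
    tn = int((~y & ~pred).sum())
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    precision = tp / (tp + fp) if (tp + fp) else None
    ba = (sens + spec) / 2.0 if np.isfinite(sens) and np.isfinite(spec) else np.nan
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "precision": precision,
        "balanced_accuracy": ba,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }
    if probabilities is not None and y.any() and not y.all():
        p = np.asarray(probabilities, dtype=float)
        out["auc"] = float(roc_auc_score(y, p))
        out["aucpr"] = float(average_precision_score(y, p))
    else:
        out["auc"] = np.nan
        out["aucpr"] = np.nan
    return out


def balanced_brier(y_true, probabilities) -> tuple[float, float, float]:
    """Class-stratified Brier scores and their sum.

    ``Brier+`` averages squared errors over positives, ``Brier−`` over
    negatives; the balanced score is their sum, in [0, 2] and robust to
    class imbalance. Raises when a class is empty (the stratified term is
    undefined).
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced Brier requires both classes to be non-empty")
    brier_pos = float(np.mean((y[pos] - p[pos]) ** 2))
    brier_neg = float(np.mean((y[neg] - p[neg]) ** 2))
    return brier_pos, brier_neg, brier_pos + brier_neg


def expected_calibration_error(y_true, probabilities, n_bins: int = 10) -> float:
    """ECE over equal-width probability bins.

    Partitions [0, 1] into ``n_bins`` bins of width ``1/n_bins`` and returns
    the bin-weighted absolute difference between the mean predicted
    probability and the observed positive fraction; empty bins contribute 0.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    bins = np.clip((p * n_bins).astype(int), 0, n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        ece += (mask.sum() / y.size) * abs(p[mask].mean() - y[mask].mean())
    return float(ece)


def fairness_differences(
    metric_values: dict[str, dict[str, float | None]], privileged: str
) -> dict[str, dict[str, float | None]]:
    """Signed unprivileged-minus-privileged differences per metric.

    ``metric_values`` maps metric name → {group: value}. A metric missing
    (``None``/NaN) for either side records a missing difference.
    """
    diffs: dict[str, dict[str, float | None]] = {}
    for metric, per_group in metric_values.items():
        if privileged not in per_group:
            raise KeyError(f"privileged group {privileged!r} missing for metric {metric!r}")
        ref = per_group[privileged]
        diffs[metric] = {}
        for g, value in per_group.items():
            if g == privileged:
                continue
            if value is None or ref is None or not np.isfinite(value) or not np.isfinite(ref):
                diffs[metric][g] = None
            else:
                diffs[metric][g] = float(value - ref)
    return diffs


@dataclass
class ParityLossReport:
    per_metric: dict[str, float]
    cumulative: float
    incomplete_metrics: list[str] = field(default_factory=list)


def parity_losses(differences: dict[str, dict[str, float | None]]) -> ParityLossReport:
    """Per-metric parity loss (sum of absolute differences over unprivileged
    groups) and the cumulative parity loss (sum over metrics).

    Missing differences are excluded with a warning and the affected metric
    is flagged in the report.
    """
    per_metric: dict[str, float] = {}
    incomplete: list[str] = []
    for metric, diffs in differences.items():
        values = [v for v in diffs.values() if v is not None]
        if len(values) < len(diffs):
            warnings.warn(f"parity loss for {metric!r} excludes missing group differences")
            incomplete.append(metric)
        per_metric[metric] = float(sum(abs(v) for v in values))
    return ParityLossReport(
        per_metric=per_metric,
        cumulative=float(sum(per_metric.values())),
        incomplete_metrics=incomplete,
    )


def group_metric_report(
    y_true,
    y_pred,
    probabilities,
    groups: pd.Series | None = None,
    lp_counts: dict[str, int] | None = None,
    proxy_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-group (and overall) metric table over validated unlabeled patients.

    When per-group labeled-positive and proxy-validated counts are supplied,
    the GBE achieved by the predictions is included.
    """
    y = pd.Series(np.asarray(y_true, dtype=bool))
    pred = pd.Series(np.asarray(y_pred, dtype=bool))
    probs = pd.Series(np.asarray(probabilities, dtype=float))
    if groups is None:
        keys = {"overall": np.ones(len(y), dtype=bool)}
    else:
        gvals = pd.Series(np.asarray(groups, dtype=object))
        keys = {g: (gvals == g).to_numpy() for g in sorted(gvals.unique())}
        keys["overall"] = np.ones(len(y), dtype=bool)
    rows = []
    for g, mask in keys.items():
        row = {"group": g, "n": int(mask.sum())}
        row.update(discrimination_metrics(y[mask], pred[mask], probs[mask]))
        if y[mask].any() and not y[mask].all():
            bp, bn, bb = balanced_brier(y[mask], probs[mask])
            row.update(brier_pos=bp, brier_neg=bn, balanced_brier=bb)
            row["ece"] = expected_calibration_error(y[mask], probs[mask])
        if lp_counts is not None and proxy_counts is not None and g != "overall":
            from .thresholds import group_benefit_equality

            row["gbe"] = group_benefit_equality(
                int(pred[mask].sum()), lp_counts.get(g, 0), proxy_counts.get(g, 0), int(mask.sum())
            )
        rows.append(row)
    return pd.DataFrame(rows)
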