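"""End-to-end split runner: preparation → steps 1–4 → evaluation.

Glues the preparation, PU-learning, thresholding and metric modules into a
single replayable experiment: prepare a cohort once (filters, phecode
mapping, labels, proxy validation), then run any number of seeded
stratified splits through feature building, the enrichment screen, the
pseudo-labeling pipeline, per-group cutoff optimization on validation, and
test-set evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import prep as _prep
from .metrics import ProxyDefinition, group_metric_report, proxy_validate
from .phecodes import in_exclusion_range
from .pul import (
    ClassifierSpec,
    FittedPipeline,
    default_step_specs,
    predict_proba,
    run_baseline,
    run_sspul,
)
from .tables import CohortTables
from .thresholds import CutoffSet, apply_cutoffs, mcc_cutoff, optimize_gbe_cutoffs

__all__ = [
    "DEFAULT_PREVALENCE",
    "PreparedCohort",
    "prepare_cohort",
    "run_split",
    "evaluate_over_splits",
    "false_omission_rate",
    "SplitResult",
]

#: Population prevalence targets per group: census-adjusted cohort-study
#: estimates (NH-white, NH-AfAm, HL) and a meta-analysis estimate (EA).
DEFAULT_PREVALENCE: dict[str, float] = {
    "NH-white": 0.100,
    "NH-AfAm": 0.186,
    "HL": 0.140,
    "EA": 0.074,
}


@dataclass
class PreparedCohort:
    """Split-independent preparation products for one cohort."""

    tables: CohortTables
    eligible_ids: pd.Index
    labels: pd.Series
    events: pd.DataFrame
    n_unmapped: int
    exclusion_flags: pd.Series
    proxy_labels: pd.Series
    phecode_prevalence: pd.Series
    proxies: ProxyDefinition


def prepare_cohort(
    tables: CohortTables,
    phecode_map: pd.DataFrame,
    proxies: ProxyDefinition | None = None,
) -> PreparedCohort:
    """Run every split-independent preparation step.

    Applies patient eligibility filtering, initial LP/U labeling from raw
    disease codes, diagnosis-code hygiene, phecode mapping with
    first-encounter retention, the dementia exclusion-range flag, and
    proxy validation of unlabeled patients (against the raw diagnosis and
    medication tables).
    """
    proxies = proxies or ProxyDefinition()
    eligible = _prep.filter_patients(tables)
    dx_eligible = tables.diagnoses[tables.diagnoses["patient_id"].isin(eligible)]
    labels = _prep.assign_initial_labels(dx_eligible, eligible)
    dx_clean = _prep.filter_diagnoses(dx_eligible)
    events, n_unmapped = _prep.map_to_phecodes(dx_clean, phecode_map)

    flagged = set(
        events.loc[events["phecode"].map(in_exclusion_range), "patient_id"]
    )
    exclusion_flags = pd.Series(
        pd.Index(eligible).isin(list(flagged)), index=pd.Index(eligible, name="patient_id"),
        name="exclusion_flag",
    )
    unlabeled = labels.index[labels == "U"]
    proxy_labels = proxy_validate(
        tables.diagnoses, tables.medications, unlabeled, proxies
    )
    prevalence = _prep.phecode_prevalence(events, eligible)
    return PreparedCohort(
        tables=tables,
        eligible_ids=eligible,
        labels=labels,
        events=events,
        n_unmapped=n_unmapped,
        exclusion_flags=exclusion_flags,
        proxy_labels=proxy_labels,
        phecode_prevalence=prevalence,
        proxies=proxies,
    )


@dataclass
class SplitResult:
    """Artifacts and metrics of one split run."""

    split_seed: int
    selected_phecodes: list[str]
    pipeline: FittedPipeline
    cutoffs: CutoffSet
    val_probs: pd.Series
    test_probs: pd.Series
    test_predictions: pd.Series
    test_report: pd.DataFrame
    split: pd.Series
    baselines: dict[str, dict] = field(default_factory=dict)
    feature_matrix: _prep.FeatureMatrix | None = None
    shift_inputs: dict = field(default_factory=dict)


def _model_columns(fm: _prep.FeatureMatrix, selected: list[str]) -> list[str]:
    demo = fm.covariate_columns + ["sex_female"] + sorted(fm.group_columns.values())
    return list(selected) + demo


def _group_counts(
    labels: pd.Series, proxy: pd.Series, groups: pd.Series, ids: pd.Index
) -> tuple[dict[str, int], dict[str, int]]:
    lab = labels.loc[ids]
    grp = groups.loc[ids]
    lp_counts = {
        g: int(((lab == "LP") & (grp == g)).sum()) for g in sorted(grp.unique())
    }
    unl = ids[lab == "U"]
    proxy_u = proxy.reindex(unl).fillna(False)
    grp_u = grp.loc[unl]
    proxy_counts = {
        g: int(proxy_u[grp_u == g].sum()) for g in sorted(grp.unique())
    }
    return lp_counts, proxy_counts


def run_split(
    prepared: PreparedCohort,
    seed: int,
    prevalence: Mapping[str, float] | None = None,
    specs: dict[str, ClassifierSpec] | None = None,
    baselines: tuple[str, ...] = (),
    feature_selection: bool = True,
) -> SplitResult:
    """One seeded 80/10/10 split through the full pipeline.

    Stratified split → feature matrix (bounds fit on train) → enrichment
    screen on train → steps 1–3 → per-group GBE cutoff optimization on the
    validation set → cutoff application and per-group evaluation on the
    test set against proxy-validated labels. Optional ``baselines`` (any of
    ``"full"``, ``"risk_factors"``, ``"vanilla_pul"``) are fit on the same
    split and thresholded with the MCC cutoff.
    """
    prevalence = dict(prevalence or DEFAULT_PREVALENCE)
    specs = specs or default_step_specs()
    ss = np.random.SeedSequence(seed)
    s_split, s_pipe, s_base = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    )

    split = _prep.stratified_split(prepared.labels, seed=s_split)
    fm = _prep.build_feature_matrix(
        prepared.tables.patients[prepared.tables.patients["patient_id"].isin(prepared.eligible_ids)],
        prepared.events,
        split,
    )
    if feature_selection:
        selected = _prep.select_features(fm, prepared.labels, prepared.phecode_prevalence)
    else:
        selected = list(fm.phecode_columns)
    columns = _model_columns(fm, selected)

    pipe = run_sspul(
        fm,
        prepared.labels,
        prevalence,
        prepared.exclusion_flags,
        specs=specs,
        seed=s_pipe,
        feature_columns=columns,
    )

    val_ids = fm.partition_index("validation")
    test_ids = fm.partition_index("test")
    val_unl = val_ids[prepared.labels.loc[val_ids] == "U"]
    test_unl = test_ids[prepared.labels.loc[test_ids] == "U"]
    val_probs = predict_proba(pipe.step3, fm.X.loc[val_unl, columns])
    test_probs = predict_proba(pipe.step3, fm.X.loc[test_unl, columns])

    cutoffs = optimize_gbe_cutoffs(
        val_probs, fm.groups.loc[val_ids], prepared.labels.loc[val_ids],
        prepared.proxy_labels,
    )
    test_pred = apply_cutoffs(
        test_probs, fm.groups, prepared.labels, cutoffs
    )
    lp_counts, proxy_counts = _group_counts(
        prepared.labels, prepared.proxy_labels, fm.groups, test_ids
    )
    y_test = prepared.proxy_labels.reindex(test_unl).fillna(False).astype(bool)
    report = group_metric_report(
        y_test,
        test_pred.loc[test_unl],
        test_probs,
        groups=fm.groups.loc[test_unl],
        lp_counts=lp_counts,
        proxy_counts=proxy_counts,
    )

    result = SplitResult(
        split_seed=seed,
        selected_phecodes=selected,
        pipeline=pipe,
        cutoffs=cutoffs,
        val_probs=val_probs,
        test_probs=test_probs,
        test_predictions=test_pred,
        test_report=report,
        split=split,
    )

    for mode in baselines:
        base = run_baseline(
            mode,
            fm,
            prepared.labels,
            seed=s_base,
            feature_columns=columns,
            exclusion_flags=prepared.exclusion_flags,
            specs=specs,
        )
        bval = predict_proba(base.model, fm.X.loc[val_unl, base.feature_columns])
        btest = predict_proba(base.model, fm.X.loc[test_unl, base.feature_columns])
        cut = mcc_cutoff(bval, prepared.proxy_labels.reindex(val_unl).fillna(False))
        bpred = btest >= cut
        breport = group_metric_report(
            y_test,
            bpred,
            btest,
            groups=fm.groups.loc[test_unl],
            lp_counts=lp_counts,
            proxy_counts=proxy_counts,
        )
        result.baselines[mode] = {
            "model": base,
            "mcc_cutoff": cut,
            "test_probs": btest,
            "test_predictions": bpred,
            "test_report": breport,
        }
    # expose the data needed by the proxy-shift analysis
    result.shift_inputs = {
        "split": seed,
        "val_probs": val_probs,
        "test_probs": test_probs,
        "val_groups": fm.groups.loc[val_ids],
        "test_groups": fm.groups.loc[test_ids],
        "val_labels": prepared.labels.loc[val_ids],
        "test_labels": prepared.labels.loc[test_ids],
    }
    result.feature_matrix = fm
    return result


def evaluate_over_splits(
    prepared: PreparedCohort,
    n_splits: int,
    master_seed: int,
    prevalence: Mapping[str, float] | None = None,
    specs: dict[str, ClassifierSpec] | None = None,
    baselines: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-split, per-group test metrics over repeated random splits.

    Split seeds derive from ``master_seed`` through a seed sequence, so the
    whole experiment is replayable from one integer. Returns a long table
    with one row per (split, model, group).
    """
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(master_seed).spawn(n_splits)]
    rows = []
    for i, seed in enumerate(seeds):
        res = run_split(prepared, seed, prevalence=prevalence, specs=specs, baselines=baselines)
        frame = res.test_report.assign(split=i, model="sspul_gbe")
        rows.append(frame)
        for mode, art in res.baselines.items():
            rows.append(art["test_report"].assign(split=i, model=f"{mode}_mcc"))
    return pd.concat(rows, ignore_index=True)


def false_omission_rate(
    final_labels: pd.Series,
    truth: pd.DataFrame,
    negative_labels: tuple[str, ...] = ("RN", "AN"),
) -> float:
    """Fraction of pseudo-labeled negatives that are true cases.

    Ground truth is only available for synthetic cohorts; ``truth`` is the
    generator's truth table.
    """
    truth_map = truth.set_index("patient_id")["true_case"].astype(bool)
    neg_ids = final_labels.index[final_labels.isin(negative_labels)]
    if len(neg_ids) == 0:
        raise ValueError("no pseudo-labeled negatives")
    return float(truth_map.reindex(neg_ids).fillna(False).mean())
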