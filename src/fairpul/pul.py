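"""Steps 1–3 of the semi-supervised positive-unlabeled pipeline.

The pipeline pseudo-labels unlabeled training patients in three stages:

1. a linear-logistic classifier separates labeled positives (LP) from all
   unlabeled patients (U); unlabeled patients whose probabilistic gap
   ``2p - 1`` falls below a robustified minimum LP gap — and who are at
   least 70 at last visit and carry no phecode in the dementia exclusion
   range — become reliable negatives (RN);
2. a random forest separates LP from RN; per group, unlabeled patients with
   gaps above the group's robustified smallest LP gap become additional
   positives (AP) — added in decreasing-gap order until the group's positive
   prevalence reaches its population target — and remaining unlabeled
   patients with gaps below the group's largest RN gap become additional
   negatives (AN);
3. a gradient-boosted-tree classifier is trained on LP∪AP vs RN∪AN and is
   the final scorer.

Baselines share the same classifier contract: two supervised models that
treat every unlabeled patient as negative, and the vanilla two-step PU
learner whose scorer is the step-2 classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

from .prep import FeatureMatrix
from .synthetic import ConfigurationError

__all__ = [
    "ClassifierSpec",
    "GapStats",
    "FittedPipeline",
    "BaselineModel",
    "PipelineError",
    "probabilistic_gap",
    "robust_min_gap",
    "identify_reliable_negatives",
    "assign_pseudo_labels",
    "fit_step_classifier",
    "run_sspul",
    "run_baseline",
    "default_step_specs",
    "DEFAULT_RISK_FACTOR_PHECODES",
]

#: Manually curated disease risk-factor phecodes used by the restricted
#: supervised baseline (diabetes family, hyperlipidemia, hypertension).
DEFAULT_RISK_FACTOR_PHECODES = (
    "249",
    "250.2",
    "250.22",
    "250.24",
    "250.25",
    "272.1",
    "401",
    "401.1",
)

#: Minimum age at last visit for reliable-negative eligibility.
RN_MIN_AGE = 70.0


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot proceed (e.g. no reliable negatives)."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Pluggable probabilistic-classifier specification.

    ``family`` selects the estimator; ``hyperparameters`` override the fixed
    documented defaults; ``oversample_minority`` duplicates the minority
    class by seeded sampling with replacement before fitting. Fit/predict is
    deterministic given ``seed``.
    """

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    oversample_minority: bool = True
    seed: int = 0


_FAMILY_DEFAULTS: dict[str, dict[str, object]] = {
    "linear-logistic": {"C": 1.0, "solver": "lbfgs", "max_iter": 2000},
    "random-forest": {
        "n_estimators": 100,
        "max_depth": 12,
        "min_samples_leaf": 5,
        "max_features": "sqrt",
        "n_jobs": 1,
    },
    "gradient-boosted-trees": {
        "n_estimators": 150,
        "max_depth": 4,
        "learning_rate": 0.1,
        "tree_method": "hist",
        "n_jobs": 1,
        "eval_metric": "logloss",
        "verbosity": 0,
    },
}


def default_step_specs(oversample: bool = True) -> dict[str, ClassifierSpec]:
    """Default classifier families per stage: linear-logistic (step 1),
    random forest (step 2), gradient-boosted trees (step 3)."""
    return {
        "step1": ClassifierSpec("linear-logistic", oversample_minority=oversample),
        "step2": ClassifierSpec("random-forest", oversample_minority=oversample),
        "step3": ClassifierSpec("gradient-boosted-trees", oversample_minority=oversample),
    }


def make_classifier(spec: ClassifierSpec):
    """Instantiate the estimator for ``spec`` with its seed applied."""
    if spec.family not in _FAMILY_DEFAULTS:
        raise ConfigurationError(f"unknown classifier family {spec.family!r}")
    params = {**_FAMILY_DEFAULTS[spec.family], **dict(spec.hyperparameters)}
    params["random_state"] = spec.seed
    if spec.family == "linear-logistic":
        return LogisticRegression(**params)
    if spec.family == "random-forest":
        return RandomForestClassifier(**params)
    return XGBClassifier(**params)


def probabilistic_gap(p):
    """Probabilistic gap ``ΔPr = Pr(y=1|x) − Pr(y=0|x) = 2p − 1``."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0) | ~np.isfinite(arr)):
        raise ValueError("probabilities must lie in [0, 1]")
    gap = 2.0 * arr - 1.0
    return float(gap) if np.isscalar(p) or arr.ndim == 0 else gap


def robust_min_gap(
    gaps,
    subsample_size: int = 500,
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Robustified minimum gap: mean of per-subsample minima.

    Draws ``n_reps`` subsamples of ``min(subsample_size, len(gaps))`` gaps
    without replacement and averages the minima, damping the influence of a
    single outlying smallest gap. When the subsample covers every gap the
    result is the plain minimum.
    """
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size == 0:
        raise ValueError("empty gap vector")
    k = min(subsample_size, gaps.size)
    if k == gaps.size:
        return float(gaps.min())
    rng = np.random.default_rng(seed)
    mins = np.empty(n_reps)
    for i in range(n_reps):
        mins[i] = gaps[rng.choice(gaps.size, size=k, replace=False)].min()
    return float(mins.mean())


def identify_reliable_negatives(
    gaps: pd.Series,
    ages: pd.Series,
    exclusion_flags: pd.Series,
    threshold: float,
) -> pd.Index:
    """Unlabeled patients qualifying as reliable negatives.

    Requires a probabilistic gap strictly below ``threshold``, age at last
    visit of at least 70 years, and no phecode in the dementia exclusion
    range (290–292.99).
    """
    keep = (
        (gaps < threshold)
        & (ages.loc[gaps.index] >= RN_MIN_AGE)
        & ~exclusion_flags.loc[gaps.index].astype(bool)
    )
    return gaps.index[keep]


@dataclass
class GapStats:
    """Gap thresholds driving pseudo-label assignment."""

    global_min_lp_gap: float
    robust_min_lp_gap: dict[str, float]
    max_rn_gap: dict[str, float]


def assign_pseudo_labels(
    step2_probs: pd.Series,
    groups: pd.Series,
    labels: pd.Series,
    prevalence: Mapping[str, float],
    gap_stats: GapStats,
    seed: int = 0,
) -> pd.Series:
    """Per-group AP/AN assignment with prevalence matching.

    Within each group, remaining unlabeled patients with gaps above the
    group's robustified smallest LP gap are AP candidates; they are taken in
    decreasing-gap order (ties broken by a seeded random order) until the
    group's positive-label prevalence ``(|LP| + |AP|) / N`` reaches the
    population target, never overshooting by more than one patient. Zero APs
    are added when the LP prevalence already meets the target. Every
    remaining unlabeled patient with a gap below the group's largest RN gap
    becomes an AN; unlabeled patients matching neither criterion are marked
    ``excluded`` and dropped from step-3 training.
    """
    labels = labels.copy()
    rng = np.random.default_rng(seed)
    gaps = 2.0 * step2_probs - 1.0
    for g in sorted(groups.unique()):
        if g not in prevalence:
            raise ConfigurationError(f"group {g!r} missing from prevalence map")
        in_group = groups == g
        n_group = int(in_group.sum())
        n_lp = int(((labels == "LP") & in_group).sum())
        target = max(0, int(round(prevalence[g] * n_group)) - n_lp)

        remaining = in_group & (labels == "U")
        cand_gaps = gaps[remaining & (gaps > gap_stats.robust_min_lp_gap[g])]
        if target > 0 and len(cand_gaps) > 0:
            tiebreak = rng.random(len(cand_gaps))
            order = np.lexsort((tiebreak, -cand_gaps.to_numpy()))
            ap_ids = cand_gaps.index[order[:target]]
            labels.loc[ap_ids] = "AP"

        remaining = in_group & (labels == "U")
        an_ids = gaps.index[remaining & (gaps < gap_stats.max_rn_gap[g])]
        labels.loc[an_ids] = "AN"
        labels.loc[in_group & (labels == "U")] = "excluded"
    return labels


def fit_step_classifier(X: pd.DataFrame, y, spec: ClassifierSpec):
    """Fit one stage classifier, optionally oversampling the minority class.

    The minority class is duplicated by seeded sampling with replacement
    until both classes match the majority count; equal class sizes leave the
    training set unchanged.
    """
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise PipelineError("both classes must be non-empty to fit a stage classifier")
    Xv = X.to_numpy(dtype=np.float32)
    if spec.oversample_minority and n_pos != n_neg:
        rng = np.random.default_rng(spec.seed)
        minority = y if n_pos < n_neg else ~y
        extra = rng.choice(np.flatnonzero(minority), size=abs(n_neg - n_pos), replace=True)
        Xv = np.concatenate([Xv, Xv[extra]])
        y = np.concatenate([y, y[extra]])
    model = make_classifier(spec)
    model.fit(Xv, y.astype(int))
    return model


def predict_proba(model, X: pd.DataFrame) -> pd.Series:
    """Positive-class probability for every row of ``X``."""
    return pd.Series(model.predict_proba(X.to_numpy(dtype=np.float32))[:, 1], index=X.index)


@dataclass
class FittedPipeline:
    """Artifacts of a full steps-1–3 run on one training partition."""

    step1: object
    step2: object
    step3: object
    gap_stats: GapStats
    labels: pd.Series
    provenance: pd.Series
    composition: dict[str, dict[str, int]]
    feature_columns: list[str]
    step1_threshold: float


@dataclass
class BaselineModel:
    """A fitted baseline scorer and the feature columns it consumes."""

    mode: str
    model: object
    feature_columns: list[str]


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Replayable per-stage integer seeds derived from the master seed."""
    return [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n)]


def _composition(labels: pd.Series, groups: pd.Series) -> dict[str, dict[str, int]]:
    table = pd.crosstab(groups.loc[labels.index], labels)
    comp = {g: {k: int(v) for k, v in row.items()} for g, row in table.iterrows()}
    comp["overall"] = {k: int(v) for k, v in labels.value_counts().items()}
    return comp


def _fit_steps_1_2(
    fm: FeatureMatrix,
    labels: pd.Series,
    exclusion_flags: pd.Series,
    specs: dict[str, ClassifierSpec],
    seed: int,
    feature_columns: list[str],
    subsample_size: int = 500,
    n_reps: int = 1000,
):
    """Shared steps 1–2 used by both the full pipeline and the vanilla
    two-step PU baseline (which guarantees both see identical classifiers
    for identical seeds)."""
    seeds = _derive_seeds(seed, 6)
    train_ids = fm.partition_index("train")
    X = fm.X.loc[train_ids, feature_columns]
    lab = labels.loc[train_ids].copy()
    is_lp = lab == "LP"

    step1 = fit_step_classifier(X, is_lp, replace(specs["step1"], seed=seeds[0]))
    p1 = predict_proba(step1, X)
    gaps1 = 2.0 * p1 - 1.0
    threshold = robust_min_gap(
        gaps1[is_lp], subsample_size=subsample_size, n_reps=n_reps, seed=seeds[1]
    )
    u_gaps = gaps1[lab == "U"]
    rn_ids = identify_reliable_negatives(u_gaps, fm.age_last_visit, exclusion_flags, threshold)
    if len(rn_ids) == 0:
        raise PipelineError(
            "no reliable negatives: threshold "
            f"{threshold:.4f}, unlabeled gaps min {u_gaps.min():.4f} / "
            f"median {u_gaps.median():.4f} / max {u_gaps.max():.4f}"
        )
    lab.loc[rn_ids] = "RN"

    mask = is_lp | (lab == "RN")
    step2 = fit_step_classifier(X[mask], is_lp[mask], replace(specs["step2"], seed=seeds[2]))
    p2 = predict_proba(step2, X)
    gaps2 = 2.0 * p2 - 1.0

    groups = fm.groups.loc[train_ids]
    group_seeds = _derive_seeds(seeds[3], len(groups.unique()))
    robust_lp: dict[str, float] = {}
    max_rn: dict[str, float] = {}
    for i, g in enumerate(sorted(groups.unique())):
        lp_g = gaps2[is_lp & (groups == g)]
        rn_g = gaps2[(lab == "RN") & (groups == g)]
        if lp_g.empty or rn_g.empty:
            raise PipelineError(f"group {g!r} lacks LPs or RNs after step 1")
        robust_lp[g] = robust_min_gap(
            lp_g, subsample_size=min(subsample_size, len(lp_g)), n_reps=n_reps, seed=group_seeds[i]
        )
        max_rn[g] = float(rn_g.max())
    gap_stats = GapStats(
        global_min_lp_gap=threshold, robust_min_lp_gap=robust_lp, max_rn_gap=max_rn
    )
    return X, lab, p2, gap_stats, step1, step2, seeds


def run_sspul(
    fm: FeatureMatrix,
    labels: pd.Series,
    prevalence: Mapping[str, float],
    exclusion_flags: pd.Series,
    specs: dict[str, ClassifierSpec] | None = None,
    seed: int = 0,
    feature_columns: list[str] | None = None,
) -> FittedPipeline:
    """Execute steps 1–3 on the training partition of ``fm``.

    Returns the fitted stage classifiers, gap statistics, the final label
    state of every training patient (LP/RN/AP/AN/excluded) with provenance,
    and a per-group composition summary. All classifier and sampling seeds
    derive from the master ``seed`` through a fixed spawn order, so the run
    is replayable.
    """
    specs = specs or default_step_specs()
    feature_columns = list(feature_columns or fm.X.columns)
    X, lab, p2, gap_stats, step1, step2, seeds = _fit_steps_1_2(
        fm, labels, exclusion_flags, specs, seed, feature_columns
    )
    train_ids = X.index
    groups = fm.groups.loc[train_ids]

    provenance = pd.Series("initial", index=train_ids, name="provenance")
    provenance[lab == "RN"] = "step1"

    final = assign_pseudo_labels(p2, groups, lab, prevalence, gap_stats, seed=seeds[4])
    provenance[final.isin(["AP", "AN", "excluded"])] = "step2"

    pos = final.isin(["LP", "AP"])
    neg = final.isin(["RN", "AN"])
    used = pos | neg
    step3 = fit_step_classifier(X[used], pos[used], replace(specs["step3"], seed=seeds[5]))

    return FittedPipeline(
        step1=step1,
        step2=step2,
        step3=step3,
        gap_stats=gap_stats,
        labels=final,
        provenance=provenance,
        composition=_composition(final, groups),
        feature_columns=feature_columns,
        step1_threshold=gap_stats.global_min_lp_gap,
    )


def run_baseline(
    mode: str,
    fm: FeatureMatrix,
    labels: pd.Series,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    exclusion_flags: pd.Series | None = None,
    specs: dict[str, ClassifierSpec] | None = None,
    risk_factor_phecodes=DEFAULT_RISK_FACTOR_PHECODES,
) -> BaselineModel:
    """Fit a comparator model on the training partition.

    ``risk_factors``: supervised fit on demographics plus the curated
    risk-factor phecodes only; ``full``: supervised fit on all supplied
    feature columns; both treat every unlabeled patient as negative (noisy
    negatives). ``vanilla_pul``: steps 1–2 of the PU pipeline with the
    step-2 classifier as scorer (identical to the pipeline's step 2 for the
    same seed).
    """
    feature_columns = list(feature_columns or fm.X.columns)
    if mode == "vanilla_pul":
        if exclusion_flags is None:
            raise ConfigurationError("vanilla_pul requires exclusion_flags")
        specs = specs or default_step_specs()
        _, _, _, _, _, step2, _ = _fit_steps_1_2(
            fm, labels, exclusion_flags, specs, seed, feature_columns
        )
        return BaselineModel(mode=mode, model=step2, feature_columns=feature_columns)
    if mode not in ("risk_factors", "full"):
        raise ConfigurationError(f"unknown baseline mode {mode!r}")

    spec = spec or ClassifierSpec("linear-logistic")
    train_ids = fm.partition_index("train")
    if mode == "risk_factors":
        demo = fm.covariate_columns + ["sex_female"] + sorted(fm.group_columns.values())
        phe = [p for p in risk_factor_phecodes if p in fm.X.columns]
        cols = phe + demo
    else:
        cols = feature_columns
    X = fm.X.loc[train_ids, cols]
    y = (labels.loc[train_ids] == "LP").to_numpy()
    seeds = _derive_seeds(seed, 1)
    model = fit_step_classifier(X, y, replace(spec, seed=seeds[0]))
    return BaselineModel(mode=mode, model=model, feature_columns=cols)
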