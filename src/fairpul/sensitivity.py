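"""Robustness procedures: group-recoding counterfactuals, proxy-definition
shift analysis, and attribution-based group comparisons.

These analyses probe whether the fitted pipeline's behavior depends on the
group variable in unintended ways: re-scoring patients after recoding their
group indicators, re-validating under reduced proxy definitions, and testing
whether per-feature attribution–value correlations differ between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .metrics import ProxyDefinition, proxy_validate
from .thresholds import CutoffSet, apply_cutoffs, optimize_gbe_cutoffs

__all__ = [
    "ProxySubsetSpec",
    "enumerate_proxy_subsets",
    "race_recoding_analysis",
    "proxy_shift_analysis",
    "attribution_permutation_test",
    "absolute_attribution_comparison",
    "PermutationResult",
]


def _score(model, X: pd.DataFrame) -> np.ndarray:
    return model.predict_proba(X.to_numpy(dtype=np.float32))[:, 1]


def race_recoding_analysis(
    model,
    feature_columns: list[str],
    cutoffs: CutoffSet,
    fm,
    labels: pd.Series,
    proxy_labels: pd.Series,
    partition: str = "test",
) -> pd.DataFrame:
    """Counterfactual group-recoding sensitivity of the final classifier.

    For every ordered pair (g_from, g_to): rewrite the group indicator
    columns of unlabeled g_from patients to g_to while holding every other
    feature fixed, re-score with ``model``, apply g_from's *original*
    cutoff, and recompute sensitivity against proxy-validated labels. The
    report carries the sensitivity before and after recoding and their
    difference; pairs with no g_from patients (or no proxy positives) are
    marked missing. Non-recoded patients' scores are untouched by
    construction — each pair is scored on its own feature copy.
    """
    ids = fm.partition_index(partition)
    unl = ids[labels.loc[ids] == "U"]
    X = fm.X.loc[unl, feature_columns]
    groups = fm.groups.loc[unl]
    y = proxy_labels.reindex(unl).fillna(False).astype(bool)
    base_probs = pd.Series(_score(model, X), index=unl)

    group_names = sorted(fm.groups.unique())
    rows = []
    for g_from in group_names:
        mask = groups == g_from
        cut = cutoffs.cutoffs[g_from]
        if not mask.any() or not y[mask].any():
            for g_to in group_names:
                rows.append(
                    {"group_from": g_from, "group_to": g_to, "sensitivity_before": np.nan,
                     "sensitivity_after": np.nan, "delta_sensitivity": np.nan}
                )
            continue
        pred_before = base_probs[mask] >= cut
        sens_before = float((pred_before & y[mask]).sum() / y[mask].sum())
        for g_to in group_names:
            X_mod = X.loc[mask].copy()
            for g, col in fm.group_columns.items():
                if col in X_mod.columns:
                    X_mod[col] = np.uint8(g == g_to)
            probs_after = _score(model, X_mod)
            pred_after = probs_after >= cut
            sens_after = float((pred_after & y[mask].to_numpy()).sum() / y[mask].sum())
            rows.append(
                {
                    "group_from": g_from,
                    "group_to": g_to,
                    "sensitivity_before": sens_before,
                    "sensitivity_after": sens_after,
                    "delta_sensitivity": sens_after - sens_before,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProxySubsetSpec:
    """One reduced proxy definition for the distribution-shift analysis."""

    kind: str  # drop_one_icd | drop_one_phecode_group | drop_random5 | drop_all_meds
    dropped_icds: frozenset[str] = frozenset()
    drop_meds: bool = False
    seed: int | None = None
    name: str = ""

    def reduce(self, proxies: ProxyDefinition) -> ProxyDefinition:
        if not self.dropped_icds <= proxies.proxy_icds:
            raise ValueError("dropped codes must be a subset of the full proxy definition")
        reduced = proxies.drop_icds(self.dropped_icds)
        return reduced.drop_all_meds() if self.drop_meds else reduced


def enumerate_proxy_subsets(
    kind: str,
    proxies: ProxyDefinition | None = None,
    phecode_map: pd.DataFrame | None = None,
    seed: int = 0,
    n_random: int = 5,
) -> list[ProxySubsetSpec]:
    """Build the subset list for one shift-analysis family.

    ``drop_one_icd`` removes each proxy ICD in turn; ``drop_one_phecode_group``
    groups proxy ICDs by mapped phecode and removes one phecode's codes at a
    time (unmapped codes form their own group); ``drop_random5`` removes
    ``n_random`` seeded random ICDs; ``drop_all_meds`` removes every proxy
    medication.
    """
    proxies = proxies or ProxyDefinition()
    icds = sorted(proxies.proxy_icds)
    if kind == "drop_one_icd":
        return [
            ProxySubsetSpec(kind, frozenset({c}), name=f"drop_{c}") for c in icds
        ]
    if kind == "drop_one_phecode_group":
        if phecode_map is None:
            raise ValueError("drop_one_phecode_group requires a phecode map")
        lookup = dict(zip(phecode_map["icd10cm"].astype(str), phecode_map["phecode"].astype(str)))

        def _phe(code: str) -> str:
            probe = code
            while probe:
                if probe in lookup:
                    return lookup[probe]
                probe = probe[:-1].rstrip(".")
            return "unmapped"

        by_phecode: dict[str, set[str]] = {}
        for c in icds:
            by_phecode.setdefault(_phe(c), set()).add(c)
        return [
            ProxySubsetSpec(kind, frozenset(codes), name=f"drop_phecode_{phe}")
            for phe, codes in sorted(by_phecode.items())
        ]
    if kind == "drop_random5":
        rng = np.random.default_rng(seed)
        chosen = rng.choice(icds, size=min(n_random, len(icds)), replace=False)
        return [
            ProxySubsetSpec(kind, frozenset(chosen), seed=seed, name=f"drop_random{n_random}_seed{seed}")
        ]
    if kind == "drop_all_meds":
        return [ProxySubsetSpec(kind, frozenset(), drop_meds=True, name="drop_all_meds")]
    raise ValueError(f"unknown proxy subset kind {kind!r}")


def proxy_shift_analysis(
    split_results: list[dict],
    subsets: list[ProxySubsetSpec],
    diagnoses: pd.DataFrame,
    medications: pd.DataFrame,
    proxies: ProxyDefinition | None = None,
) -> pd.DataFrame:
    """Re-validate, re-threshold and re-evaluate under reduced proxy sets.

    Each element of ``split_results`` holds one split's stored artifacts:
    ``val_probs``/``test_probs`` (Series over unlabeled patients),
    ``val_groups``/``test_groups``, ``val_labels``/``test_labels`` and a
    ``split`` identifier. For each subset the proxy labels are rebuilt under
    the reduced definition, group cutoffs are re-optimized on validation and
    sensitivity/precision are re-evaluated per group on the test set. One
    row per (subset, split, group); subsets under which GBE is undefined for
    a group are flagged (NaN metrics).
    """
    proxies = proxies or ProxyDefinition()
    rows = []
    for subset in subsets:
        reduced = subset.reduce(proxies)
        for res in split_results:
            val_ids = res["val_probs"].index
            test_ids = res["test_probs"].index
            val_proxy = proxy_validate(diagnoses, medications, val_ids, reduced)
            test_proxy = proxy_validate(diagnoses, medications, test_ids, reduced)
            cutoffs = optimize_gbe_cutoffs(
                res["val_probs"], res["val_groups"], res["val_labels"], val_proxy
            )
            pred = apply_cutoffs(res["test_probs"], res["test_groups"], res["test_labels"], cutoffs)
            groups_t = res["test_groups"].loc[test_ids]
            for g in sorted(groups_t.unique()):
                mask = (groups_t == g).to_numpy()
                y = test_proxy.loc[test_ids].to_numpy()[mask]
                p = pred.to_numpy()[mask]
                sens = float((p & y).sum() / y.sum()) if y.any() else np.nan
                prec = float((p & y).sum() / p.sum()) if p.any() else np.nan
                rows.append(
                    {
                        "subset": subset.name or subset.kind,
                        "kind": subset.kind,
                        "split": res.get("split", 0),
                        "group": g,
                        "n_validated_pos": int(y.sum()),
                        "sensitivity": sens,
                        "precision": prec,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PermutationResult:
    """Outcome of the attribution-correlation permutation test.

    ``p_value`` is the plain proportion of permuted statistics at least as
    extreme as the observed one (it can be exactly 0); ``p_value_add_one``
    is the add-one-corrected variant ``(b + 1) / (n_perm + 1)``.
    """

    observed: float
    p_value: float
    p_value_add_one: float
    n_perm: int
    null_statistics: np.ndarray = field(repr=False, default=None)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def attribution_permutation_test(
    table: pd.DataFrame,
    feature: str,
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for a group difference in the feature-value /
    attribution correlation.

    The observed statistic is the absolute difference between the two
    groups' Pearson correlations of raw feature value with attribution.
    The null is built by shuffling group membership between the two compared
    groups ``n_perm`` times; the p-value is the proportion of permuted
    statistics greater than or equal to the observed one. Symmetric in the
    two groups.
    """
    sub = table[(table["feature"] == feature) & table["group"].isin([group_a, group_b])]
    parts = {}
    for g in (group_a, group_b):
        block = sub[sub["group"] == g]
        v = block["value"].to_numpy(dtype=float)
        s = block["attribution"].to_numpy(dtype=float)
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 patients for feature {feature!r}")
        if np.ptp(v) == 0 or np.ptp(s) == 0:
            raise ValueError(f"constant feature or attribution in group {g!r}")
        parts[g] = (v, s)
    va, sa = parts[group_a]
    vb, sb = parts[group_b]
    observed = abs(_corr(va, sa) - _corr(vb, sb))

    values = np.concatenate([va, vb])
    attrs = np.concatenate([sa, sb])
    n_a = va.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(values.size)
        ia, ib = perm[:n_a], perm[n_a:]
        null[i] = abs(_corr(values[ia], attrs[ia]) - _corr(values[ib], attrs[ib]))
    hits = int((null >= observed).sum())
    return PermutationResult(
        observed=observed,
        p_value=hits / n_perm,
        p_value_add_one=(hits + 1) / (n_perm + 1),
        n_perm=n_perm,
        null_statistics=null,
    )


def absolute_attribution_comparison(
    table: pd.DataFrame, feature: str, group_a: str, group_b: str, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test on absolute attribution magnitudes.

    Returns ``(U statistic, p-value)``. ``method`` is passed through to the
    rank test ("exact" enumerates the null distribution at small n). Any
    Bonferroni factor over the number of features tested is applied by the
    caller.
    """
    sub = table[table["feature"] == feature]
    a = sub.loc[sub["group"] == group_a, "attribution"].abs().to_numpy(dtype=float)
    b = sub.loc[sub["group"] == group_b, "attribution"].abs().to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
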