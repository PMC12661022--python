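"""Per-group probability-cutoff selection.

Post-processing bias mitigation: for each group, the classification cutoff
is chosen on the validation set so that the group benefit equality (GBE) —
the ratio of the predicted-positive prevalence to the observed (labeled plus
proxy-validated) positive prevalence — is as close to 1 as possible. The
comparator is a single MCC-maximizing cutoff shared by all groups. The
decision rule is always ``probability >= cutoff``, and labeled positives are
never re-thresholded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "CutoffSet",
    "UndefinedGBEError",
    "group_benefit_equality",
    "optimize_gbe_cutoffs",
    "mcc_cutoff",
    "apply_cutoffs",
]


class UndefinedGBEError(ValueError):
    """GBE is undefined: the group has no labeled or proxy-validated positives."""


@dataclass
class CutoffSet:
    """Per-group cutoffs, the method that produced them, and the achieved
    objective (``|GBE − 1|`` for GBE, the MCC for MCC)."""

    cutoffs: dict[str, float]
    method: str
    objective: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.cutoffs),
                "cutoff": [self.cutoffs[g] for g in self.cutoffs],
                "method": self.method,
                "objective": [self.objective.get(g, np.nan) for g in self.cutoffs],
            }
        )


def group_benefit_equality(
    pred_pos_unlabeled: int, lp: int, proxy_validated_pos: int, n_group: int
) -> float:
    """GBE ratio for one group.

    Numerator: labeled positives plus predicted positives among unlabeled
    patients; denominator: labeled plus proxy-validated positives. Both are
    prevalences over the same group, so the group size cancels; 1 is ideal.
    """
    if n_group <= 0:
        raise ValueError("n_group must be positive")
    denom = lp + proxy_validated_pos
    if denom == 0:
        raise UndefinedGBEError("group has no labeled or proxy-validated positives")
    return (lp + pred_pos_unlabeled) / denom


def _gbe_objective(cutoff: float, probs: np.ndarray, lp: int, denom: int) -> float:
    pred_pos = int((probs >= cutoff).sum())
    return abs((lp + pred_pos) / denom - 1.0)


def optimize_gbe_cutoffs(
    val_probs: pd.Series,
    groups: pd.Series,
    labels: pd.Series,
    proxy_labels: pd.Series,
    unlabeled_only_prior: bool = False,
) -> CutoffSet:
    """Choose one cutoff per group minimizing ``|GBE − 1|`` on validation.

    Runs Nelder–Mead from 0.5, then refines deterministically over every
    observed probability (plus 0 and 1): GBE is a right-continuous step
    function of the cutoff, so the refinement attains the global optimum
    regardless of optimizer plateaus. Ties in the objective resolve to the
    largest (most conservative) cutoff. A group whose GBE is undefined falls
    back to the global MCC cutoff.

    With ``unlabeled_only_prior`` the LP anchor is dropped from both sides
    of the ratio (the pure predicted-vs-proxy prevalence form).
    """
    cutoffs: dict[str, float] = {}
    objectives: dict[str, float] = {}
    fallback: float | None = None
    for g in sorted(groups.unique()):
        in_group = groups == g
        unl = in_group & (labels == "U")
        probs = val_probs[val_probs.index.isin(groups.index[unl])].to_numpy()
        lp = 0 if unlabeled_only_prior else int((in_group & (labels == "LP")).sum())
        proxy_pos = int(proxy_labels.reindex(groups.index[unl]).fillna(False).sum())
        denom = lp + proxy_pos
        if denom == 0 or probs.size == 0:
            if fallback is None:
                pooled_unl = labels == "U"
                fallback = mcc_cutoff(
                    val_probs[val_probs.index.isin(labels.index[pooled_unl])],
                    proxy_labels.reindex(labels.index[pooled_unl]).fillna(False),
                )
            logger.warning("GBE undefined for group %r; falling back to global MCC cutoff", g)
            cutoffs[g] = fallback
            objectives[g] = np.nan
            continue

        candidates = np.unique(np.concatenate([probs, [0.0, 1.0]]))
        objs = np.array([_gbe_objective(c, probs, lp, denom) for c in candidates])
        nm = minimize(
            lambda c: _gbe_objective(float(np.clip(c[0], 0.0, 1.0)), probs, lp, denom),
            x0=[0.5],
            method="Nelder-Mead",
        )
        nm_cut = float(np.clip(nm.x[0], 0.0, 1.0))
        candidates = np.append(candidates, nm_cut)
        objs = np.append(objs, _gbe_objective(nm_cut, probs, lp, denom))
        best = objs.min()
        # largest cutoff among the minimizers
        cutoffs[g] = float(candidates[objs <= best + 1e-15].max())
        objectives[g] = float(best)
    return CutoffSet(cutoffs=cutoffs, method="gbe", objective=objectives)


def _mcc_from_counts(tp, fp, fn, tn):
    tp, fp, fn, tn = (np.asarray(v, dtype=float) for v in (tp, fp, fn, tn))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = (tp * tn - fp * fn) / denom
    return np.where(denom > 0, mcc, 0.0)


def mcc_cutoff(val_probs: pd.Series, proxy_labels: pd.Series) -> float:
    """Cutoff maximizing the Matthews correlation coefficient.

    Candidates are the midpoints between consecutive sorted unique
    probabilities plus 0 and 1; ties resolve to the smallest cutoff.
    """
    probs = np.asarray(val_probs, dtype=float)
    y = np.asarray(proxy_labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both proxy classes must be present to maximize MCC")
    uniq = np.unique(probs)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    candidates = np.unique(np.concatenate([[0.0, 1.0], mids]))
    # vectorized confusion counts: for cutoff c, predicted positive iff p >= c
    order = np.argsort(probs, kind="mergesort")
    sorted_probs = probs[order]
    pos_cum = np.concatenate([[0], np.cumsum(y[order])])
    n_pos = int(y.sum())
    n = y.size
    k = np.searchsorted(sorted_probs, candidates, side="left")  # count below cutoff
    tp = n_pos - pos_cum[k]
    fp = (n - k) - tp
    fn = pos_cum[k]
    tn = k - fn
    mcc = _mcc_from_counts(tp, fp, fn, tn)
    return float(candidates[int(np.argmax(mcc))])


def apply_cutoffs(
    test_probs: pd.Series,
    groups: pd.Series,
    labels: pd.Series,
    cutoffs: CutoffSet | Mapping[str, float],
    fallback: float | None = None,
) -> pd.Series:
    """Predicted labels: positive iff probability ≥ the group's cutoff.

    Labeled positives keep their positive label and are not re-thresholded.
    A group absent from the cutoff set uses ``fallback`` or raises.
    """
    table = cutoffs.cutoffs if isinstance(cutoffs, CutoffSet) else dict(cutoffs)
    pred = np.zeros(len(test_probs), dtype=bool)
    group_vec = groups.loc[test_probs.index].to_numpy()
    prob_vec = test_probs.to_numpy(dtype=float)
    for g in np.unique(group_vec):
        cut = table.get(g, fallback)
        if cut is None:
            raise KeyError(f"no cutoff for group {g!r} and no fallback")
        in_group = group_vec == g
        pred[in_group] = prob_vec[in_group] >= cut
    pred |= (labels.reindex(test_probs.index) == "LP").to_numpy()
    return pd.Series(pred, index=test_probs.index, name="predicted_positive")
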