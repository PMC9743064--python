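"""Model evaluation (AUC, Kappa, TSS) and variable-importance analyses.

Presence-only data has no true absences, so background points stand in as
pseudo-absences for both the rank AUC and the binarized confusion metrics.
The binarization threshold defaults to the value maximizing TSS on the
training data, a common SDM convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid_io import EnvStack, OccurrenceSet
from .maxent import (
    MaxentModel,
    ReplicateConfig,
    ReplicateResult,
    build_features,
    fit_maxent,
    sample_background,
)
from .occurrences import PresenceTable, extract_presence_values

__all__ = [
    "MetricSet",
    "ImportanceReport",
    "ResponseCurve",
    "auc_presence_background",
    "kappa_tss",
    "max_tss_threshold",
    "evaluate_replicates",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
]


@dataclass
class MetricSet:
    auc: float
    kappa: float
    tss: float
    threshold_used: float
    confusion: tuple[int, int, int, int]  # TP, FN, FP, TN


@dataclass
class ImportanceReport:
    percent_contribution: pd.Series
    permutation_importance: pd.Series
    jackknife: pd.DataFrame | None = None  # columns: gain_with_only, gain_without
    gain_all: float | None = None


@dataclass
class ResponseCurve:
    variable: str
    grid: np.ndarray
    probability: np.ndarray

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.probability))])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def auc_presence_background(presence_scores, background_scores) -> float:
    """Probability a random presence outscores a random background point.

    Midrank (Mann-Whitney) handling of ties: ties count one half.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    return float((r_p - p.size * (p.size + 1) / 2) / (p.size * b.size))


def kappa_tss(confusion: tuple[int, int, int, int]) -> tuple[float, float]:
    """Cohen's kappa and the true skill statistic from (TP, FN, FP, TN).

    kappa = (Po - Pe) / (1 - Pe) with Pe the chance agreement from the
    margins; tss = sensitivity + specificity - 1. Degenerate margins
    (Pe = 1) make kappa undefined; NaN is returned for it.
    """
    tp, fn, fp, tn = confusion
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("empty confusion table")
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    kappa = float("nan") if pe >= 1.0 else (po - pe) / (1.0 - pe)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return float(kappa), float(sens + spec - 1.0)


def max_tss_threshold(presence_scores, background_scores) -> float:
    """Score threshold maximizing TSS; first maximizer, for determinism."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    candidates = np.unique(np.concatenate([p, b]))
    best_t, best_tss = candidates[0], -np.inf
    for t in candidates:
        sens = np.mean(p >= t)
        spec = np.mean(b < t)
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_t, best_tss = t, tss
    return float(best_t)


def _confusion(p_scores, b_scores, threshold) -> tuple[int, int, int, int]:
    tp = int(np.sum(p_scores >= threshold))
    fn = int(p_scores.size - tp)
    fp = int(np.sum(b_scores >= threshold))
    tn = int(b_scores.size - fp)
    return tp, fn, fp, tn


def evaluate_replicates(
    replicates: list[ReplicateResult],
    threshold_rule: str = "max_tss",
    fixed_threshold: float | None = None,
) -> tuple[pd.DataFrame, list[MetricSet]]:
    """Per-replicate test metrics plus the mean/SD summary table.

    Each replicate is scored on its held-out presences against the training
    background: rank AUC, then Kappa and TSS after binarizing at the
    threshold chosen on the *training* data (max-TSS by default; 'max_kappa'
    and 'fixed' with ``fixed_threshold`` are alternatives). The summary has
    one row per metric in Average/SD layout (sample SD; 0 for a single
    replicate).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    per_rep: list[MetricSet] = []
    for res in replicates:
        model = res.model
        train_scores = model.logistic(model.presence_env)
        bg_scores = model.logistic(model.background_env)
        test_scores = model.logistic(res.test_env)
        if threshold_rule == "fixed":
            if fixed_threshold is None:
                raise ValueError("fixed threshold rule needs fixed_threshold")
            thr = float(fixed_threshold)
        elif threshold_rule == "max_kappa":
            thr = _max_kappa_threshold(train_scores, bg_scores)
        else:
            thr = max_tss_threshold(train_scores, bg_scores)
        conf = _confusion(test_scores, bg_scores, thr)
        kappa, tss = kappa_tss(conf)
        auc = auc_presence_background(test_scores, bg_scores)
        per_rep.append(MetricSet(auc=auc, kappa=kappa, tss=tss, threshold_used=thr, confusion=conf))
    summary = pd.DataFrame(
        {
            "AUC": [np.mean([m.auc for m in per_rep]),
                    np.std([m.auc for m in per_rep], ddof=1) if len(per_rep) > 1 else 0.0],
            "Kappa": [np.mean([m.kappa for m in per_rep]),
                      np.std([m.kappa for m in per_rep], ddof=1) if len(per_rep) > 1 else 0.0],
            "TSS": [np.mean([m.tss for m in per_rep]),
                    np.std([m.tss for m in per_rep], ddof=1) if len(per_rep) > 1 else 0.0],
        },
        index=["Average", "SD"],
    ).T
    return summary, per_rep


def _max_kappa_threshold(p_scores, b_scores) -> float:
    candidates = np.unique(np.concatenate([p_scores, b_scores]))
    best_t, best_k = candidates[0], -np.inf
    for t in candidates:
        k, _ = kappa_tss(_confusion(p_scores, b_scores, t))
        if np.isfinite(k) and k > best_k + 1e-12:
            best_t, best_k = t, k
    return float(best_t)


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------


def percent_contribution(model: MaxentModel) -> pd.Series:
    """Share of fitting-gain credit per source variable, summing to 100.

    Each accepted coordinate-descent step's gain increase was credited to
    the stepped feature's source variable during fitting (products split
    50/50); negative residual credit is floored at zero before normalizing.
    """
    credit = pd.Series(model.contributions, dtype=float).clip(lower=0.0)
    credit = credit.reindex(model.variables).fillna(0.0)
    total = credit.sum()
    if total <= 0:
        return pd.Series(100.0 / len(credit), index=credit.index)
    return 100.0 * credit / total


def permutation_importance(
    model: MaxentModel,
    seed: int = 0,
    n_repeats: int = 1,
) -> pd.Series:
    """Normalized training-AUC drop when each variable is permuted.

    The variable's values are permuted jointly across presences and
    background (so its marginal distribution is preserved but its link to
    location is broken), the fixed model is re-applied, and the drop in
    training AUC — floored at zero — is normalized over variables to sum
    to 100.
    """
    rng = np.random.default_rng(seed)
    n_p = len(model.presence_env)
    combined = pd.concat([model.presence_env, model.background_env], ignore_index=True)
    base_p = model.logistic(model.presence_env)
    base_b = model.logistic(model.background_env)
    base_auc = auc_presence_background(base_p, base_b)
    drops = {}
    for v in model.variables:
        acc = 0.0
        for _ in range(n_repeats):
            perm = combined.copy()
            perm[v] = rng.permutation(perm[v].to_numpy())
            scores = model.logistic(perm)
            auc = auc_presence_background(scores[:n_p], scores[n_p:])
            acc += base_auc - auc
        drops[v] = max(acc / n_repeats, 0.0)
    s = pd.Series(drops, dtype=float).reindex(model.variables)
    total = s.sum()
    if total <= 0:
        return pd.Series(100.0 / len(s), index=s.index)
    return 100.0 * s / total


def jackknife_gains(
    occ: OccurrenceSet | PresenceTable,
    stack: EnvStack,
    variables: list[str] | None = None,
    config: ReplicateConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Regularized training gain with each variable alone and left out.

    Refits the model once per variable on just that variable, once on all
    the others, and once on the full set; the final regularized training
    gain of each fit is the importance measure.
    """
    config = config or ReplicateConfig()
    table = occ if isinstance(occ, PresenceTable) else extract_presence_values(occ, stack)
    if variables is None:
        variables = table.variables
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    rng = np.random.default_rng(config.seed)
    background = sample_background(stack, config.background_size, rng)

    def _gain(subset: list[str]) -> float:
        env = table.data[subset]
        sub_table = PresenceTable(data=table.data[["lon", "lat"] + subset],
                                  variables=subset, n_effective=len(table))
        fs = build_features(sub_table, background[subset], config, variables=subset)
        model = fit_maxent(env, background[subset], fs, config, variables=subset)
        return model.gain

    gain_all = _gain(list(variables))
    rows = {}
    for v in variables:
        rows[v] = {
            "gain_with_only": _gain([v]),
            "gain_without": _gain([u for u in variables if u != v]),
        }
    return pd.DataFrame(rows).T, gain_all


def response_curve(
    occ: OccurrenceSet | PresenceTable,
    stack: EnvStack,
    variable: str,
    sweep: np.ndarray | int = 100,
    config: ReplicateConfig | None = None,
) -> ResponseCurve:
    """Single-variable response: a model fit with only this variable,
    evaluated along a sweep of its background range."""
    config = config or ReplicateConfig()
    table = occ if isinstance(occ, PresenceTable) else extract_presence_values(occ, stack)
    if variable not in table.variables:
        raise ValueError(f"variable {variable!r} not in presence table")
    rng = np.random.default_rng(config.seed)
    background = sample_background(stack, config.background_size, rng)
    sub_table = PresenceTable(data=table.data[["lon", "lat", variable]],
                              variables=[variable], n_effective=len(table))
    fs = build_features(sub_table, background[[variable]], config, variables=[variable])
    model = fit_maxent(table.data[[variable]], background[[variable]], fs, config,
                       variables=[variable])
    bg_vals = background[variable].to_numpy(dtype=float)
    if np.isscalar(sweep):
        sweep = np.linspace(bg_vals.min(), bg_vals.max(), int(sweep))
    sweep = np.asarray(sweep, dtype=float)
    probs = model.logistic(pd.DataFrame({variable: sweep}))
    return ResponseCurve(variable=variable, grid=sweep, probability=probs)
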