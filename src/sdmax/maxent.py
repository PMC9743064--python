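"""Presence-background maximum-entropy model.

The model estimates a Gibbs distribution q(x) = exp(lambda . f(x)) / Z over
background cells whose feature expectations are pulled toward the presence
sample means, subject to an L1 penalty — the standard presence-background
maximum-entropy formulation. Fitting minimizes the convex objective

    L(lambda) = -(1/m) sum_i lambda . f(x_i) + log Z(lambda) + sum_j beta_j |lambda_j|

by cyclic coordinate descent with a soft-thresholded Newton step per
coordinate and backtracking, so the objective is non-increasing at every
accepted step. The regularized training gain is log(N_background) - L,
zero for the uninformative model.

Logistic output uses the standard transform c q / (1 + c q) with
c = exp(H), H the entropy of the fitted distribution over the training
background; an uninformative model therefore scores exactly 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grid_io import EnvStack, OccurrenceSet, RasterGrid
from .occurrences import PresenceTable, extract_presence_values

__all__ = [
    "Feature",
    "FeatureSet",
    "MaxentModel",
    "ReplicateConfig",
    "SuitabilityMap",
    "ReplicateResult",
    "build_features",
    "sample_background",
    "fit_maxent",
    "predict_raw",
    "predict_logistic",
    "run_replicates",
]


@dataclass(frozen=True)
class Feature:
    """One derived feature: class, source variable(s), optional hinge knot."""

    name: str
    kind: str                 # linear | quadratic | product | hinge_fwd | hinge_rev
    variables: tuple[str, ...]
    knot: float | None = None

    def raw(self, env: pd.DataFrame) -> np.ndarray:
        x = env[self.variables[0]].to_numpy(dtype=float)
        if self.kind == "linear":
            return x
        if self.kind == "quadratic":
            return x * x
        if self.kind == "product":
            return x * env[self.variables[1]].to_numpy(dtype=float)
        if self.kind == "hinge_fwd":
            return np.maximum(0.0, x - self.knot)
        if self.kind == "hinge_rev":
            return np.maximum(0.0, self.knot - x)
        raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class FeatureSet:
    """Ordered features plus the background min/max used to scale each to [0,1]."""

    features: list[Feature]
    scaling: np.ndarray  # (n_features, 2): min, max over training background

    def evaluate(self, env: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """(n_rows, n_features) scaled feature matrix."""
        out = np.empty((len(env), len(self.features)))
        for j, feat in enumerate(self.features):
            lo, hi = self.scaling[j]
            v = (feat.raw(env) - lo) / (hi - lo)
            out[:, j] = v
        if clamp:
            np.clip(out, 0.0, 1.0, out=out)
        return out

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def source_variables(self, j: int) -> tuple[str, ...]:
        return self.features[j].variables


@dataclass
class ReplicateConfig:
    """Replicated-fit settings: subsample splits, background, optimizer."""

    n_replicates: int = 10
    train_fraction: float = 0.75
    split_method: str = "subsample"
    seed: int = 0
    background_size: int = 10_000
    max_iterations: int = 500
    tolerance: float = 1e-5
    beta_multiplier: float = 1.0
    hinge_knots: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class MaxentModel:
    """Fitted model state, kept rich enough for importance analyses."""

    feature_set: FeatureSet
    lambdas: np.ndarray
    betas: np.ndarray
    log_partition: float            # log Z over the training background
    entropy: float                  # H of the fitted distribution over background
    gain_trace: list[float]
    objective_trace: list[float]
    contributions: dict[str, float]  # per-variable gain credit from fitting steps
    presence_env: pd.DataFrame
    background_env: pd.DataFrame
    variables: list[str]

    @property
    def gain(self) -> float:
        return self.gain_trace[-1] if self.gain_trace else 0.0

    def scores(self, env: pd.DataFrame) -> np.ndarray:
        """lambda . f(x) per row, features scaled/clamped with training scaling."""
        return self.feature_set.evaluate(env) @ self.lambdas

    def raw(self, env: pd.DataFrame) -> np.ndarray:
        """Raw score exp(lambda.f - log Z), normalized over training background."""
        return np.exp(self.scores(env) - self.log_partition)

    def logistic(self, env: pd.DataFrame) -> np.ndarray:
        # c*q = exp(H + lambda.f - log Z), one exponential for exactness at 0
        cq = np.exp(self.entropy + self.scores(env) - self.log_partition)
        return cq / (1.0 + cq)


@dataclass
class SuitabilityMap:
    grid: RasterGrid
    model_id: str = ""
    scenario_label: str = ""

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.valid_mask()]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("logistic suitability must lie in [0, 1]")


@dataclass
class ReplicateResult:
    model: MaxentModel
    train_index: np.ndarray
    test_index: np.ndarray
    suitability: SuitabilityMap
    test_env: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def build_features(
    table: PresenceTable,
    background_env: pd.DataFrame,
    config: ReplicateConfig | None = None,
    variables: list[str] | None = None,
) -> FeatureSet:
    """Auto-select feature classes from the presence count (MaxEnt-style).

    Linear features always; quadratic from 10 presences; hinge (both
    orientations, knots at evenly spaced background quantiles) from 15;
    pairwise products from 80. Every feature is min-max scaled on the
    background; features constant over the background are dropped.
    """
    config = config or ReplicateConfig()
    if variables is None:
        variables = table.variables
    m = len(table)
    if m < 2:
        raise ValueError(f"need at least 2 presences to build features, got {m}")
    feats: list[Feature] = [Feature(f"{v}", "linear", (v,)) for v in variables]
    if m >= 10:
        feats += [Feature(f"{v}^2", "quadratic", (v,)) for v in variables]
    if m >= 80:
        for i, u in enumerate(variables):
            for v in variables[i + 1:]:
                feats.append(Feature(f"{u}*{v}", "product", (u, v)))
    if m >= 15:
        qs = np.linspace(0.0, 1.0, config.hinge_knots + 2)[1:-1]
        for v in variables:
            knots = np.quantile(background_env[v].to_numpy(dtype=float), qs)
            for t, knot in enumerate(knots):
                feats.append(Feature(f"hinge({v})+@{t}", "hinge_fwd", (v,), float(knot)))
                feats.append(Feature(f"hinge({v})-@{t}", "hinge_rev", (v,), float(knot)))

    kept: list[Feature] = []
    scaling: list[tuple[float, float]] = []
    dropped = []
    for feat in feats:
        raw = feat.raw(background_env)
        lo, hi = float(raw.min()), float(raw.max())
        if hi - lo <= 0:
            dropped.append(feat.name)
            continue
        kept.append(feat)
        scaling.append((lo, hi))
    if dropped:
        warnings.warn(f"dropped constant features over background: {dropped[:5]}"
                      + ("..." if len(dropped) > 5 else ""), stacklevel=2)
    if not kept:
        raise ValueError("no non-constant features could be built")
    return FeatureSet(features=kept, scaling=np.array(scaling))


def sample_background(stack: EnvStack, size: int, rng: np.random.Generator) -> pd.DataFrame:
    """Seeded uniform sample of valid cells (capped at their number)."""
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    n = rows.size
    if n == 0:
        raise ValueError("stack has no valid cells")
    if size < n:
        pick = rng.choice(n, size=size, replace=False)
        rows, cols = rows[pick], cols[pick]
    return pd.DataFrame(stack.values_at(rows, cols), columns=stack.variables)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _objective(lambdas, pbar, s_bg, betas):
    return float(-(lambdas @ pbar) + logsumexp(s_bg) + betas @ np.abs(lambdas))


def fit_maxent(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    feature_set: FeatureSet,
    config: ReplicateConfig | None = None,
    variables: list[str] | None = None,
) -> MaxentModel:
    """Cyclic coordinate descent on the L1-penalized maxent objective.

    Per coordinate: a Newton step on the smooth part soft-thresholded by the
    penalty, halved until the full objective does not increase. Default
    penalties are beta_multiplier * max(sd_j, 0.05) / sqrt(m) with sd_j the
    presence standard deviation of feature j.
    """
    config = config or ReplicateConfig()
    if variables is None:
        variables = list(presence_env.columns)
    m = len(presence_env)
    if m < 2:
        raise ValueError("need at least 2 presences")
    F_p = feature_set.evaluate(presence_env)
    F_b = feature_set.evaluate(background_env)
    if not (np.all(np.isfinite(F_p)) and np.all(np.isfinite(F_b))):
        raise ValueError("non-finite feature values")
    n_bg, J = F_b.shape
    pbar = F_p.mean(axis=0)
    sd = F_p.std(axis=0)
    betas = config.beta_multiplier * np.maximum(sd, 0.05) / np.sqrt(m)

    lambdas = np.zeros(J)
    s_bg = np.zeros(n_bg)
    log_n = np.log(n_bg)
    obj = _objective(lambdas, pbar, s_bg, betas)
    objective_trace = [obj]
    gain_trace = [log_n - obj]
    contributions: dict[str, float] = {v: 0.0 for v in variables}

    for _ in range(config.max_iterations):
        obj_start = obj
        for j in range(J):
            lse = logsumexp(s_bg)
            w = np.exp(s_bg - lse)
            fj = F_b[:, j]
            e = float(w @ fj)
            var = float(w @ (fj - e) ** 2)
            if var <= 1e-12:
                continue
            g = -pbar[j] + e
            u = lambdas[j] - g / var
            new_l = np.sign(u) * max(abs(u) - betas[j] / var, 0.0)
            delta = new_l - lambdas[j]
            if delta == 0.0:
                continue
            # backtrack until the exact objective does not increase
            for _half in range(30):
                cand = lambdas.copy()
                cand[j] += delta
                s_cand = s_bg + delta * fj
                obj_cand = _objective(cand, pbar, s_cand, betas)
                if obj_cand <= obj + 1e-12:
                    break
                delta *= 0.5
            else:
                continue
            if obj_cand > obj:
                continue
            credit = obj - obj_cand
            srcs = feature_set.source_variables(j)
            for v in srcs:
                contributions[v] = contributions.get(v, 0.0) + credit / len(srcs)
            lambdas = cand
            s_bg = s_cand
            obj = obj_cand
        objective_trace.append(obj)
        gain_trace.append(log_n - obj)
        if obj_start - obj < config.tolerance:
            break

    lse = logsumexp(s_bg)
    w = np.exp(s_bg - lse)
    entropy = float(-(w @ np.log(np.maximum(w, 1e-300))))
    return MaxentModel(
        feature_set=feature_set,
        lambdas=lambdas,
        betas=betas,
        log_partition=float(lse),
        entropy=entropy,
        gain_trace=gain_trace,
        objective_trace=objective_trace,
        contributions=contributions,
        presence_env=presence_env.reset_index(drop=True),
        background_env=background_env.reset_index(drop=True),
        variables=list(variables),
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _env_frame(stack: EnvStack, model: MaxentModel) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    missing = [v for v in model.variables if v not in stack.variables]
    if missing:
        raise ValueError(f"stack is missing model variables: {missing}")
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    env = pd.DataFrame(
        np.column_stack([stack[v].values[rows, cols] for v in model.variables]),
        columns=model.variables,
    )
    return env, rows, cols


def predict_raw(model: MaxentModel, stack: EnvStack) -> RasterGrid:
    """Raw Gibbs score exp(lambda.f(x))/Z per valid cell."""
    env, rows, cols = _env_frame(stack, model)
    template = stack.template()
    out = np.full((template.nrows, template.ncols), template.nodata_value)
    out[rows, cols] = model.raw(env)
    return template.with_values(out, variable_name="raw_suitability")


def predict_logistic(model: MaxentModel, stack: EnvStack, model_id: str = "") -> SuitabilityMap:
    """Logistic suitability c q/(1+c q), c = exp(H) over training background."""
    env, rows, cols = _env_frame(stack, model)
    template = stack.template()
    out = np.full((template.nrows, template.ncols), template.nodata_value)
    out[rows, cols] = model.logistic(env)
    grid = template.with_values(out, variable_name="suitability")
    return SuitabilityMap(grid=grid, model_id=model_id, scenario_label=stack.scenario_label)


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------


def run_replicates(
    occ: OccurrenceSet,
    stack: EnvStack,
    config: ReplicateConfig | None = None,
    variables: list[str] | None = None,
) -> tuple[list[ReplicateResult], SuitabilityMap]:
    """Seeded subsample replicates and their cellwise-mean suitability map.

    Each replicate draws a fresh 75/25 train/test split of the presences
    (without replacement) and a fresh background sample, fits, and predicts.
    """
    config = config or ReplicateConfig()
    table = extract_presence_values(occ, stack)
    if variables is not None:
        table = PresenceTable(
            data=table.data[["lon", "lat"] + list(variables)],
            n_raw=table.n_raw,
            n_effective=table.n_effective,
            variables=list(variables),
        )
    n = len(table)
    n_train = int(round(config.train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"train fraction {config.train_fraction} leaves an empty split at n={n}")
    master = np.random.default_rng(config.seed)
    results: list[ReplicateResult] = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        perm = rng.permutation(n)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        background = sample_background(stack, config.background_size, rng)
        train_env = table.env.iloc[train_idx].reset_index(drop=True)
        train_table = PresenceTable(
            data=table.data.iloc[train_idx].reset_index(drop=True),
            variables=table.variables, n_raw=table.n_raw, n_effective=len(train_idx),
        )
        fs = build_features(train_table, background, config)
        model = fit_maxent(train_env, background, fs, config, variables=table.variables)
        smap = predict_logistic(model, stack, model_id=f"rep{rep}")
        results.append(ReplicateResult(
            model=model, train_index=train_idx, test_index=test_idx,
            suitability=smap, test_env=table.env.iloc[test_idx].reset_index(drop=True),
        ))
    template = stack.template()
    mask = stack.valid_mask()
    acc = np.zeros((template.nrows, template.ncols))
    for res in results:
        acc += np.where(mask, res.suitability.grid.values, 0.0)
    mean_vals = np.where(mask, acc / len(results), template.nodata_value)
    mean_map = SuitabilityMap(
        grid=template.with_values(mean_vals, variable_name="mean_suitability"),
        model_id="mean", scenario_label=stack.scenario_label,
    )
    return results, mean_map
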