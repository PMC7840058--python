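"""Permutation-allocated case-control mixed-logistic inference.

The engine behind the behavior-specific resource selection analysis.  For
each of many permutations, the control sites are partitioned region by
region among the behavior types in proportion to behavior frequency
(largest-remainder apportionment decides the sizes; membership is a uniform
random partition).  Each behavior's used locations are then contrasted
against its allocated controls with a random-intercept binomial model

    logit P(used) = beta0 + beta' x + u_region,   u_region ~ N(0, sigma^2),

fit by maximum likelihood with a Laplace approximation to the marginal
likelihood (the same approximation lme4's glmer uses).  One coefficient
vector is drawn from the multivariate normal described by each retained
fit; the pooled draws across permutations carry both estimation and
allocation uncertainty.  Significance is the empirical-CDF two-tailed
probability of the pooled draws with respect to zero; random effects are
summarized by their across-permutation distribution and the fraction of
permutations at the sigma^2 = 0 boundary; model quality is within-sample
classification accuracy averaged over retained permutations.

Because the ratio of used locations to controls is low, exp(coefficient)
approximates the resource selection function; the intercept does not
estimate overall use probability (used locations are not a random sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit  # noqa: F401  (logit used by callers/tests)

from rsfperm.dataset_io import AnalysisDataset

#: A fit whose random-intercept variance (on the z-scale) falls below this
#: is counted as a boundary ("zero-value" random effect) fit.
BOUNDARY_SIGMA2 = 1e-6

INTERCEPT = "intercept"


# ---------------------------------------------------------------------------
# Proportional allocation of control sites
# ---------------------------------------------------------------------------


def largest_remainder(total: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Floors of the exact quotas are topped up in order of largest fractional
    remainder (ties broken by input order), so the sizes sum exactly to
    ``total``.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    keys = list(weights)
    w = np.array([float(weights[k]) for k in keys])
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        if total > 0:
            raise ValueError("cannot apportion a positive total over all-zero weights")
        return {k: 0 for k in keys}
    quotas = total * w / w.sum()
    base = np.floor(quotas).astype(int)
    remainder = total - int(base.sum())
    order = sorted(range(len(keys)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return {k: int(b) for k, b in zip(keys, base)}


@dataclass(frozen=True)
class AllocationPlan:
    """One permutation's region-by-region assignment of controls to behaviors."""

    permutation_id: int
    assignment: dict          # region -> behavior -> tuple of control record_ids

    def sizes(self) -> dict[str, dict[str, int]]:
        return {r: {b: len(ids) for b, ids in bs.items()} for r, bs in self.assignment.items()}

    def controls_for(self, behavior: str) -> list:
        out: list = []
        for bs in self.assignment.values():
            out.extend(bs.get(behavior, ()))
        return out


def allocation_sizes(
    n_controls: int, behavior_counts: Mapping[str, int]
) -> dict[str, int]:
    """Within-region set sizes: controls apportioned by behavior frequency."""
    return largest_remainder(n_controls, behavior_counts)


def allocate_controls(
    control_ids: Mapping[str, Sequence],
    used_counts: Mapping[str, Mapping[str, int]],
    rng: np.random.Generator,
    permutation_id: int = 0,
) -> AllocationPlan:
    """Randomly partition each region's controls among behaviors.

    Set sizes follow :func:`allocation_sizes` (largest-remainder
    apportionment of the region's control count proportional to its
    behavior frequencies); membership is a uniform random partition.
    Regions with controls but no used locations leave their controls
    unassigned, with a warning.
    """
    assignment: dict = {}
    for region in control_ids:
        ids = list(control_ids[region])
        counts = {b: int(n) for b, n in used_counts.get(region, {}).items() if n > 0}
        if not counts:
            if ids:
                warnings.warn(
                    f"region {region!r} has {len(ids)} controls but no used locations; "
                    "its controls are unassigned",
                    stacklevel=2,
                )
            assignment[region] = {}
            continue
        sizes = allocation_sizes(len(ids), counts)
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        start = 0
        region_assign: dict = {}
        for b, size in sizes.items():
            region_assign[b] = tuple(shuffled[start:start + size])
            start += size
        assignment[region] = region_assign
    return AllocationPlan(permutation_id=permutation_id, assignment=assignment)


# ---------------------------------------------------------------------------
# Random-intercept logistic fit (Laplace marginal likelihood)
# ---------------------------------------------------------------------------


@dataclass
class PermutationFit:
    """One behavior model fit on one permutation's allocated controls."""

    behavior: str
    permutation_id: int
    converged: bool
    coef_names: list[str]
    fixed_effects: np.ndarray | None = None
    fixed_cov: np.ndarray | None = None
    random_intercepts: dict[str, float] = field(default_factory=dict)
    random_variance: float = 0.0
    boundary: bool = True
    accuracy: float | None = None
    drawn_params: np.ndarray | None = None
    n_used: int = 0
    n_controls: int = 0
    message: str = ""
    _design: tuple | None = field(default=None, repr=False)

    @property
    def regions(self) -> list[str]:
        return list(self.random_intercepts)


def _make_nll(y: np.ndarray, X: np.ndarray, group_idx: np.ndarray, n_groups: int):
    """Negative Laplace-approximated marginal log-likelihood of (beta, sigma^2).

    The random intercepts are profiled out: for each objective evaluation
    the per-region conditional modes are found by (damped) Newton steps,
    warm-started from the previous evaluation.
    """
    state = {"u": np.zeros(n_groups)}

    def nll(params: np.ndarray) -> float:
        beta, sigma2 = params[:-1], params[-1]
        eta0 = X @ beta
        if sigma2 < 1e-10:
            ll = float(y @ eta0 - np.logaddexp(0.0, eta0).sum())
            return -ll
        u = state["u"].copy()
        for _ in range(200):
            eta = eta0 + u[group_idx]
            mu = expit(eta)
            grad = np.bincount(group_idx, weights=y - mu, minlength=n_groups) - u / sigma2
            hess = np.bincount(group_idx, weights=mu * (1.0 - mu), minlength=n_groups) + 1.0 / sigma2
            step = grad / hess
            np.clip(step, -5.0, 5.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        state["u"] = u
        eta = eta0 + u[group_idx]
        mu = expit(eta)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        W = np.bincount(group_idx, weights=mu * (1.0 - mu), minlength=n_groups)
        penalty = float(u @ u) / (2.0 * sigma2) + 0.5 * float(np.sum(np.log1p(sigma2 * W)))
        return -(ll - penalty)

    return nll, state


def _fixed_cov(
    beta: np.ndarray, sigma2: float, u: np.ndarray,
    y: np.ndarray, X: np.ndarray, group_idx: np.ndarray, n_groups: int,
) -> np.ndarray:
    """Covariance of the fixed effects: inverse Schur complement of the
    joint (beta, u) Hessian of the penalized log-likelihood."""
    eta = X @ beta + (u[group_idx] if sigma2 >= 1e-10 else 0.0)
    w = expit(eta) * (1.0 - expit(eta))
    A = (X * w[:, None]).T @ X
    if sigma2 >= 1e-10:
        B = np.zeros((n_groups, X.shape[1]))
        np.add.at(B, group_idx, X * w[:, None])
        D = np.bincount(group_idx, weights=w, minlength=n_groups) + 1.0 / sigma2
        A = A - B.T @ (B / D[:, None])
    return np.linalg.inv(A)


def fit_behavior_model(
    used: pd.DataFrame,
    controls: pd.DataFrame,
    fixed_attrs: Sequence[str],
    group_col: str = "region",
    behavior: str = "",
    permutation_id: int = 0,
    max_sigma2: float = 25.0,
    start: np.ndarray | None = None,
) -> PermutationFit:
    """Fit ``logit P(used) = beta0 + beta'x + u_region`` by Laplace ML.

    ``used`` rows are the responses coded 1, ``controls`` 0; fixed
    attributes are expected on the z-scale (binary indicators such as
    disturbance presence enter as 0/1).  Boundary fits (sigma^2 = 0) are
    valid and flagged; non-convergence or a degenerate design yields
    ``converged=False`` so the permutation can be discarded.
    """
    fixed_attrs = list(fixed_attrs)
    coef_names = [INTERCEPT, *fixed_attrs]
    data = pd.concat([used, controls], ignore_index=True)
    y = np.concatenate([np.ones(len(used)), np.zeros(len(controls))])
    fit = PermutationFit(
        behavior=behavior, permutation_id=permutation_id, converged=False, coef_names=coef_names,
        n_used=len(used), n_controls=len(controls),
    )
    if len(used) == 0 or len(controls) == 0:
        fit.message = "need both used and control records"
        return fit
    if len(controls) < len(coef_names):
        fit.message = f"unreasonable split: {len(controls)} controls < {len(coef_names)} parameters"
        return fit

    Xattr = data[fixed_attrs].to_numpy(dtype=float)
    if np.isnan(Xattr).any():
        fit.message = "missing values in fixed attributes; drop incomplete records first"
        return fit
    X = np.column_stack([np.ones(len(data)), Xattr])
    regions = sorted(data[group_col].unique())
    region_index = {r: i for i, r in enumerate(regions)}
    group_idx = data[group_col].map(region_index).to_numpy(dtype=int)
    n_groups = len(regions)

    nll, state = _make_nll(y, X, group_idx, n_groups)
    p = X.shape[1]
    if start is not None and len(start) == p + 1:
        x0 = np.asarray(start, dtype=float).copy()
        x0[-1] = min(max(x0[-1], 0.0), max_sigma2)
    else:
        q = y.mean()
        x0 = np.zeros(p + 1)
        x0[0] = float(np.log(q / (1.0 - q)))
        x0[-1] = 0.25
    bounds = [(None, None)] * p + [(0.0, max_sigma2)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})

    beta, sigma2 = res.x[:-1], float(res.x[-1])
    ok = bool(res.success) and np.all(np.isfinite(res.x)) and np.isfinite(res.fun)
    if ok and np.max(np.abs(beta)) > 50.0:
        ok = False
        fit.message = "apparent complete separation (diverging coefficients)"
    cov = None
    if ok:
        # recompute modes at the optimum so u matches (beta, sigma2)
        nll(res.x)
        u = state["u"].copy() if sigma2 >= 1e-10 else np.zeros(n_groups)
        try:
            cov = _fixed_cov(beta, sigma2, u, y, X, group_idx, n_groups)
        except np.linalg.LinAlgError:
            ok = False
            fit.message = "singular information matrix"
        if cov is not None and not np.all(np.isfinite(cov)):
            ok = False
            fit.message = "non-finite coefficient covariance"

    fit.converged = ok
    if not ok:
        if not fit.message:
            fit.message = f"optimizer failure: {res.message}"
        return fit
    fit.fixed_effects = beta
    fit.fixed_cov = cov
    fit.random_variance = sigma2
    fit.boundary = sigma2 < BOUNDARY_SIGMA2
    fit.random_intercepts = {r: float(u[region_index[r]]) for r in regions}
    fit._design = (y, X, group_idx, np.array([u[region_index[r]] for r in regions]))
    fit.message = "ok"
    return fit


# ---------------------------------------------------------------------------
# Draws, p-values, accuracy
# ---------------------------------------------------------------------------


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def draw_parameters(fit: PermutationFit, rng: np.random.Generator) -> np.ndarray:
    """One draw from Normal(fixed_effects, fixed_cov) of a converged fit."""
    if not fit.converged:
        raise ValueError("cannot draw from a non-converged fit")
    cov = fit.fixed_cov
    min_eig = float(np.linalg.eigvalsh((cov + cov.T) / 2.0).min())
    if min_eig < -1e-8 * max(1.0, float(np.abs(cov).max())):
        warnings.warn("coefficient covariance not PSD; projecting to nearest PSD", stacklevel=2)
        cov = _nearest_psd(cov)
    return rng.multivariate_normal(fit.fixed_effects, cov, method="svd")


def ecdf_two_tailed_p(draws: np.ndarray) -> float:
    """Empirical two-tailed probability of ``draws`` with respect to zero.

    Twice the smaller of the fractions of draws <= 0 and >= 0, capped at 1.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one draw")
    lower = float(np.mean(draws <= 0.0))
    upper = float(np.mean(draws >= 0.0))
    return min(1.0, 2.0 * min(lower, upper))


def classification_accuracy(
    fit: PermutationFit,
    threshold: float = 0.5,
    include_random: bool = True,
) -> float:
    """Fraction of the fitting records classified on the correct side of
    ``threshold`` (ties count as incorrect).  Predicted probabilities
    include the estimated region intercepts unless ``include_random=False``.
    """
    if not fit.converged or fit._design is None:
        raise ValueError("accuracy requires a converged fit with stored design")
    y, X, group_idx, u = fit._design
    eta = X @ fit.fixed_effects
    if include_random:
        eta = eta + u[group_idx]
    phat = expit(eta)
    correct = ((phat > threshold) & (y == 1)) | ((phat < threshold) & (y == 0))
    return float(np.mean(correct))


# ---------------------------------------------------------------------------
# Permutation loop and pooling
# ---------------------------------------------------------------------------


@dataclass
class PooledInference:
    """Pooled permutation results for one behavior."""

    behavior: str
    n_permutations_run: int
    n_retained: int
    coef_names: list[str]
    pooled_draws: pd.DataFrame            # retained draws, one row per permutation
    fixed_summary: pd.DataFrame           # mean, se (sd of draws), two-tailed p
    random_summary: pd.DataFrame          # per-region mean, sd, prob_zero
    prob_zero_variance: float             # fraction of retained fits at sigma^2 = 0
    mean_accuracy: float
    seed: int

    @property
    def odds_ratios(self) -> pd.Series:
        """exp of pooled coefficient means; approximates the resource
        selection function for the covariates.  The intercept's value does
        not estimate overall use probability (used locations are not a
        random sample of habitat)."""
        return np.exp(self.fixed_summary["mean"]).rename("odds_ratio")


def _pool(
    behavior: str,
    coef_names: list[str],
    draws: list[np.ndarray],
    intercepts: list[dict[str, float]],
    boundary_flags: list[bool],
    accuracies: list[float],
    n_run: int,
    seed: int,
) -> PooledInference:
    if not draws:
        raise RuntimeError(
            f"no retained permutations for behavior {behavior!r}: "
            "every fit failed or was an unreasonable split"
        )
    pooled = pd.DataFrame(np.vstack(draws), columns=coef_names)
    fixed = pd.DataFrame(
        {
            "mean": pooled.mean(),
            "se": pooled.std(ddof=1) if len(pooled) > 1 else np.zeros(len(coef_names)),
            "p": [ecdf_two_tailed_p(pooled[c].to_numpy()) for c in coef_names],
        }
    )
    prob_zero = float(np.mean(boundary_flags))
    regions = sorted({r for d in intercepts for r in d})
    rows = {}
    for r in regions:
        vals = np.array([d[r] for d in intercepts if r in d])
        rows[r] = {
            "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "prob_zero": prob_zero,
        }
    random_summary = pd.DataFrame.from_dict(rows, orient="index")
    return PooledInference(
        behavior=behavior,
        n_permutations_run=n_run,
        n_retained=len(pooled),
        coef_names=coef_names,
        pooled_draws=pooled,
        fixed_summary=fixed,
        random_summary=random_summary,
        prob_zero_variance=prob_zero,
        mean_accuracy=float(np.mean(accuracies)),
        seed=seed,
    )


def run_study_analysis(
    dataset: AnalysisDataset,
    fixed_attrs: Sequence[str],
    behaviors: Sequence[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    accuracy_threshold: float = 0.5,
    include_random_in_accuracy: bool = True,
    fit_behaviors: Sequence[str] | None = None,
) -> dict[str, PooledInference]:
    """Run the full permutation analysis, all behaviors in one pass.

    Per permutation: controls are allocated jointly across all modeled
    behaviors, every behavior's model is fit on its allocated controls,
    converged fits are retained, and one parameter vector is drawn per
    retained fit.  The allocation stream and each behavior's draw stream
    are independent sub-streams of ``seed``, so results for one behavior do
    not depend on which other behaviors are modeled.

    ``behaviors`` defines the modeled set the allocation is apportioned
    over; ``fit_behaviors`` (default: all of them) restricts which models
    are actually fit — a pure speed switch that leaves the fitted
    behaviors' results bit-identical to a full run.
    """
    fixed_attrs = list(fixed_attrs)
    frame = dataset.frame.dropna(subset=fixed_attrs)
    n_dropped = len(dataset.frame) - len(frame)
    if n_dropped:
        dataset.log(f"inference: dropped {n_dropped} records with missing fixed attributes")

    used = frame[frame["role"] == "used"]
    if behaviors is None:
        behaviors = sorted(used["behavior"].unique())
    behaviors = [b for b in behaviors if (used["behavior"] == b).any()]
    if not behaviors:
        raise ValueError("no behavior with used locations to model")

    controls = frame[frame["role"] == "control"]
    control_ids = {r: list(g["record_id"]) for r, g in controls.groupby("region")}
    used_counts = {
        r: {b: int(((g["behavior"] == b)).sum()) for b in behaviors}
        for r, g in used.groupby("region")
    }
    used_by_behavior = {b: used[used["behavior"] == b] for b in behaviors}
    control_lookup = controls.set_index("record_id")

    if fit_behaviors is None:
        fit_behaviors = list(behaviors)
    else:
        unknown = set(fit_behaviors) - set(behaviors)
        if unknown:
            raise ValueError(f"fit_behaviors not among modeled behaviors: {sorted(unknown)}")
        fit_behaviors = [b for b in behaviors if b in set(fit_behaviors)]

    alloc_rng = np.random.default_rng([seed, 0])
    draw_rngs = {b: np.random.default_rng([seed, 1, i]) for i, b in enumerate(behaviors)}

    draws: dict[str, list[np.ndarray]] = {b: [] for b in behaviors}
    intercepts: dict[str, list[dict]] = {b: [] for b in behaviors}
    boundary: dict[str, list[bool]] = {b: [] for b in behaviors}
    accuracies: dict[str, list[float]] = {b: [] for b in behaviors}
    warm: dict[str, np.ndarray | None] = {b: None for b in behaviors}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for k in range(n_perm):
            plan = allocate_controls(control_ids, used_counts, alloc_rng, permutation_id=k)
            for b in fit_behaviors:
                ctrl_b = control_lookup.loc[plan.controls_for(b)].reset_index()
                fit = fit_behavior_model(
                    used_by_behavior[b], ctrl_b, fixed_attrs,
                    behavior=b, permutation_id=k, start=warm[b],
                )
                if not fit.converged:
                    continue
                warm[b] = np.append(fit.fixed_effects, fit.random_variance)
                fit.drawn_params = draw_parameters(fit, draw_rngs[b])
                fit.accuracy = classification_accuracy(
                    fit, threshold=accuracy_threshold, include_random=include_random_in_accuracy
                )
                draws[b].append(fit.drawn_params)
                intercepts[b].append(dict(fit.random_intercepts))
                boundary[b].append(fit.boundary)
                accuracies[b].append(fit.accuracy)

    coef_names = [INTERCEPT, *fixed_attrs]
    return {
        b: _pool(b, coef_names, draws[b], intercepts[b], boundary[b], accuracies[b], n_perm, seed)
        for b in fit_behaviors
    }


def run_permutation_analysis(
    dataset: AnalysisDataset,
    behavior: str,
    fixed_attrs: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    focal_only: bool = False,
    behaviors: Sequence[str] | None = None,
    **kwargs,
) -> PooledInference:
    """Permutation analysis for one focal behavior.

    By default every modeled behavior's fit is run each permutation
    (allocation is joint); ``focal_only=True`` skips the non-focal fits,
    which leaves the focal results unchanged (retention is per behavior and
    each behavior has its own draw sub-stream) but runs faster.
    """
    frame = dataset.frame
    if behaviors is None:
        behaviors = sorted(frame.loc[frame["role"] == "used", "behavior"].unique())
    if behavior not in behaviors:
        raise ValueError(f"behavior {behavior!r} has no used locations")
    results = run_study_analysis(
        dataset, fixed_attrs, behaviors=behaviors, n_perm=n_perm, seed=seed,
        fit_behaviors=[behavior] if focal_only else None, **kwargs,
    )
    return results[behavior]
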