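"""Multi-regime Ornstein–Uhlenbeck ("Simpsonian landscape") models and the
stepwise search for convergent adaptive peaks.

A *painting* assigns each branch to a selective regime: a shift on a branch
starts a new regime inherited by its descendants until overridden; the root
belongs to regime 0.  Each regime has its own optimum θ, while α and σ² are
shared.  The expected tip value is a weighted average of the regime optima,
with weights given by exponentially discounted occupancy of the root-to-tip
path (the Hansen model); the root state equals the root regime's optimum
(stationarity at the root), so the root weight is folded into regime 0.

The stepwise search greedily adds the AICc-best regime shift branch by
branch (forward phase), then greedily merges regime pairs to shared optima
(backward phase), which is what detects *convergent* peaks: distinct shifts
can land on the same optimum.  The AICc parameter count is 2 + the number of
distinct regimes (α, σ², and the θ's; shift locations are not charged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .tree import Phylogeny, shared_time_matrix
from .diversification import aicc
from .trait_models import _align

__all__ = ["RegimePainting", "hansen_design", "multipeak_loglik", "surface_search"]


@dataclass(frozen=True)
class RegimePainting:
    """Branch→regime assignment with fitted multi-peak OU parameters."""

    shift_nodes: tuple[int, ...]            # nodes whose subtending branch starts a new regime
    regime_of_node: tuple[int, ...]         # per-node regime id (root = regime 0)
    theta: tuple[float, ...]                # per-regime optimum, ln-mm
    alpha: float
    sigma2: float
    logL: float
    AICc: float
    trace: tuple[tuple[str, float], ...] = ()   # (step description, AICc)

    @property
    def k_shifts(self) -> int:
        return len(self.shift_nodes)

    @property
    def k_regimes(self) -> int:
        return len(self.theta)


def _paint(tree: Phylogeny, shift_nodes, regime_ids) -> np.ndarray:
    """Per-node regime id: regime 0 at the root, new regime on each shift
    branch, inherited until overridden."""
    shift_map = dict(zip(shift_nodes, regime_ids))
    regime = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.preorder():
        if v == tree.root:
            regime[v] = 0
        elif int(v) in shift_map:
            regime[v] = shift_map[int(v)]
        else:
            regime[v] = regime[tree.parent[v]]
    return regime


def hansen_design(
    tree: Phylogeny, regime_of_node: np.ndarray, n_regimes: int, alpha: float
) -> np.ndarray:
    """Tips × regimes weight matrix of the multi-optimum OU mean.

    A path segment in regime k spanning depths [d0, d1) on the root-to-tip
    path of a tip at depth T contributes e^{−α(T−d1)} − e^{−α(T−d0)} to
    W[i, k]; the root term e^{−αT} goes to the root regime (regime 0) because
    the root state is the root regime's optimum.  Rows sum to 1.
    """
    if alpha <= 0:
        raise ValueError("hansen weights require alpha > 0")
    n = tree.n_tips
    W = np.zeros((n, n_regimes))
    pos = {int(t): i for i, t in enumerate(tree.tips)}
    T = tree.root_height
    # accumulate per-edge contributions down the tree: for a tip at depth T_i,
    # contribution of edge ending at depth d1 (starting d0) is
    # e^{-alpha(T_i - d1)} - e^{-alpha(T_i - d0)}.  We push path segment lists.
    paths: dict[int, list[tuple[float, float, int]]] = {int(tree.root): []}
    for v in tree.preorder():
        v = int(v)
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        seg = (float(tree.depth[p]), float(tree.depth[v]), int(regime_of_node[v]))
        paths[v] = paths[p] + [seg]
    for t in tree.tips:
        t = int(t)
        i = pos[t]
        Ti = float(tree.depth[t])
        for d0, d1, k in paths[t]:
            W[i, k] += math.exp(-alpha * (Ti - d1)) - math.exp(-alpha * (Ti - d0))
        W[i, 0] += math.exp(-alpha * Ti)   # root state = root regime's optimum
    return W


def _ou_structure(S: np.ndarray, T: float, alpha: float) -> np.ndarray:
    """Unit-σ² non-stationary OU covariance: (1/2α)e^{−2α(T−s)}(1−e^{−2αs})."""
    return (1.0 / (2.0 * alpha)) * np.exp(-2.0 * alpha * (T - S)) * (-np.expm1(-2.0 * alpha * S))


def _fit_painting(
    tree: Phylogeny,
    z: np.ndarray,
    S: np.ndarray,
    regime_of_node: np.ndarray,
    n_regimes: int,
    theta_groups: list[list[int]] | None = None,
    alpha_bounds: tuple[float, float] | None = None,
):
    """Profile θ (GLS) and σ² analytically, optimize α on a bounded interval.

    ``theta_groups`` merges regimes onto shared optima (convergence): each
    group shares one θ column.  Returns (logL, alpha, sigma2, theta_full)
    where theta_full has one value per regime id.
    """
    T = tree.root_height
    n = len(z)
    if alpha_bounds is None:
        alpha_bounds = (1e-8, 50.0 / T)
    if theta_groups is None:
        theta_groups = [[k] for k in range(n_regimes)]

    def eval_alpha(alpha):
        alpha = max(alpha, 1e-10)
        W = hansen_design(tree, regime_of_node, n_regimes, alpha)
        if len(theta_groups) < n_regimes:
            Wg = np.column_stack([W[:, g].sum(axis=1) for g in theta_groups])
        else:
            Wg = W
        if np.any(Wg.sum(axis=0) <= 1e-12):
            empty = [gi for gi, g in enumerate(theta_groups) if Wg[:, gi].sum() <= 1e-12]
            raise ValueError(f"regime group(s) {empty} have no weight on any tip")
        V0 = _ou_structure(S, T, alpha)
        c, lowf = linalg.cho_factor(V0, lower=True)
        ViW = linalg.cho_solve((c, lowf), Wg)
        A = Wg.T @ ViW
        b = ViW.T @ z
        try:
            theta_g = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            # nearly collinear regime weights (e.g. a regime reduced to the
            # vanishing root term): minimum-norm optima keep logL well defined
            theta_g = np.linalg.lstsq(A, b, rcond=None)[0]
        resid = z - Wg @ theta_g
        quad = float(resid @ linalg.cho_solve((c, lowf), resid))
        sigma2 = quad / n
        if sigma2 <= 0:
            return -np.inf, sigma2, theta_g, 0.0
        logdet0 = 2.0 * float(np.sum(np.log(np.diag(c))))
        logL = -0.5 * (n * (math.log(2 * math.pi) + 1.0 + math.log(sigma2)) + logdet0)
        return logL, sigma2, theta_g, alpha

    res = optimize.minimize_scalar(
        lambda a: -eval_alpha(a)[0],
        bounds=alpha_bounds, method="bounded", options={"xatol": 1e-10},
    )
    best_alpha = res.x
    if -res.fun < eval_alpha(alpha_bounds[1])[0]:
        best_alpha = alpha_bounds[1]
    logL, sigma2, theta_g, alpha = eval_alpha(best_alpha)
    theta_full = np.empty(n_regimes)
    for gi, g in enumerate(theta_groups):
        theta_full[g] = theta_g[gi]
    return logL, alpha, sigma2, theta_full


def multipeak_loglik(
    tree: Phylogeny,
    trait: pd.Series,
    shift_nodes,
    *,
    theta_groups: list[list[int]] | None = None,
) -> RegimePainting:
    """Fit the multi-regime OU model for a given set of shift branches.

    Each shift node starts regime 1, 2, … in the given order; regime 0 is
    the root regime.  With no shifts this is exactly the single-optimum OU
    model.  θ is profiled by GLS, σ² analytically, α numerically.
    """
    sub, z = _align(tree, trait)
    S = shared_time_matrix(sub)
    shift_nodes = tuple(int(v) for v in shift_nodes)
    n_regimes = len(shift_nodes) + 1
    regime = _paint(sub, shift_nodes, range(1, n_regimes))
    logL, alpha, sigma2, theta = _fit_painting(sub, z, S, regime, n_regimes, theta_groups)
    groups = theta_groups if theta_groups is not None else [[k] for k in range(n_regimes)]
    k_par = 2 + len(groups)
    return RegimePainting(
        shift_nodes=shift_nodes,
        regime_of_node=tuple(int(r) for r in regime),
        theta=tuple(float(t) for t in theta),
        alpha=float(alpha), sigma2=float(sigma2), logL=float(logL),
        AICc=aicc(logL, k_par, len(z)),
    )


def _candidate_order(tree: Phylogeny) -> list[int]:
    """Non-root nodes ordered root-ward first, then by lexicographic minimum
    descendant tip label (the deterministic tie-breaking order)."""
    desc = tree.descendant_tips()
    key = {}
    for v in range(tree.n_nodes):
        if int(tree.parent[v]) < 0:
            continue
        min_lab = min(tree.labels[int(t)] for t in desc[v])
        key[v] = (float(tree.depth[v]), min_lab)
    return sorted(key, key=key.get)


def surface_search(
    tree: Phylogeny,
    trait: pd.Series,
    *,
    min_improvement: float | None = None,
) -> RegimePainting:
    """Stepwise AICc search for convergent adaptive peaks.

    Forward: from a single regime, repeatedly add the shift (on any branch)
    that most lowers AICc; a shift is retained only if it improves AICc by
    more than ``min_improvement``, which defaults to 2·ln(number of candidate
    branches) — a selection correction for picking the best of many branches
    (the expected maximum of C approximately-χ²₁ deviance gains under a
    shift-free model is about 2·ln C, so a bare AICc comparison would accept
    spurious shifts on almost every dataset).  Backward: repeatedly merge the
    pair of regimes onto a shared optimum that most lowers AICc (any strict
    improvement; merging only removes parameters).  α and σ² are re-optimized
    at every candidate; ties break toward the branch closest to the root,
    then by tip label.  Deterministic; the trace records every accepted
    step's AICc.
    """
    sub, z = _align(tree, trait)
    S = shared_time_matrix(sub)
    candidates = _candidate_order(sub)
    if min_improvement is None:
        min_improvement = 2.0 * math.log(len(candidates))

    shifts: list[int] = []
    trace: list[tuple[str, float]] = []

    def fit(shift_nodes, groups=None):
        regime = _paint(sub, shift_nodes, range(1, len(shift_nodes) + 1))
        n_regimes = len(shift_nodes) + 1
        try:
            logL, alpha, sigma2, theta = _fit_painting(sub, z, S, regime, n_regimes, groups)
        except (ValueError, np.linalg.LinAlgError, linalg.LinAlgError):
            return None
        k_par = 2 + (len(groups) if groups is not None else n_regimes)
        return logL, alpha, sigma2, theta, aicc(logL, k_par, len(z)), regime

    current = fit(shifts)
    trace.append(("start: single regime", current[4]))

    # ---- forward phase: add shifts ----
    while True:
        best = None
        for v in candidates:
            if v in shifts:
                continue
            trial = fit(shifts + [v])
            if trial is None:
                continue
            if trial[4] < current[4] - min_improvement and (
                best is None or trial[4] < best[1][4]
            ):
                best = (v, trial)
        if best is None:
            break
        shifts.append(best[0])
        current = best[1]
        trace.append((f"add shift at node {best[0]}", current[4]))

    # ---- backward phase: merge regimes into convergent peaks ----
    groups: list[list[int]] = [[k] for k in range(len(shifts) + 1)]
    while len(groups) > 1:
        best = None
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                merged = [g for i, g in enumerate(groups) if i not in (a, b)]
                merged.append(sorted(groups[a] + groups[b]))
                merged = sorted(merged)
                trial = fit(shifts, merged)
                if trial is None:
                    continue
                if trial[4] < current[4] and (best is None or trial[4] < best[1][4]):
                    best = (merged, trial)
        if best is None:
            break
        groups = best[0]
        current = best[1]
        trace.append((f"merge regimes -> {len(groups)} peaks", current[4]))

    logL, alpha, sigma2, theta, AICc_val, regime = (
        current[0], current[1], current[2], current[3], current[4], current[5],
    )
    # collapse θ to distinct regimes after merging
    return RegimePainting(
        shift_nodes=tuple(shifts),
        regime_of_node=tuple(int(r) for r in regime),
        theta=tuple(float(t) for t in theta),
        alpha=float(alpha), sigma2=float(sigma2), logL=float(logL),
        AICc=float(AICc_val), trace=tuple(trace),
    )
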