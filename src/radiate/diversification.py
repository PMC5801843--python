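"""Lineage-accumulation analysis: LTT, the γ statistic, the MCCR test, and
maximum-likelihood fitting of diversification models with missing-species
correction.

Four models of per-lineage speciation/extinction rates as functions of the
standing diversity ``N`` are supported:

* ``Yule``   — pure birth, λ_N = λ0, μ_N = 0;
* ``crBD``   — constant-rate birth–death, λ_N = λ0, μ_N = μ;
* ``DDL+E``  — diversity-dependent logistic with extinction,
  λ_N = max(0, λ0 − (λ0 − μ)·N/K), μ_N = μ;
* ``DDE+E``  — diversity-dependent exponential with extinction,
  λ_N = λ0·(μ/λ0)^(N/K) (declining to μ at N = K), μ_N = μ.

The likelihood of the branching times is computed with a hidden-species
master equation: the probability vector over the number of species alive but
not represented in the reconstructed tree is integrated through each
inter-node interval, multiplied by the speciation rate at each observed node,
and read out at the present in the state holding exactly the assumed number
of unsampled extant species.  The likelihood is conditioned on the crown age
and on survival of both crown lineages.  For constant rates and complete
sampling this agrees with the closed-form (Nee-type) crown-conditioned
likelihood, which is exposed separately as :func:`constant_rate_loglik` and
serves as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, special

from .tree import BranchingTimes, Phylogeny, branching_times

__all__ = [
    "LTTCurve",
    "MCCRResult",
    "DiversificationFit",
    "ltt",
    "gamma_stat",
    "mccr_test",
    "constant_rate_loglik",
    "dd_loglik",
    "aicc",
    "fit_diversification",
    "MODELS",
]

MODELS = ("Yule", "crBD", "DDL+E", "DDE+E")

_N_PARAMS = {"Yule": 1, "crBD": 2, "DDL+E": 3, "DDE+E": 3}


# ---------------------------------------------------------------------------
# LTT and the γ statistic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LTTCurve:
    """Lineage-through-time step curve: ages descending, counts non-decreasing."""

    times: np.ndarray
    counts: np.ndarray


def ltt(bt: BranchingTimes) -> LTTCurve:
    """Lineage-through-time curve; coincident nodes increment the count together."""
    times, mult = np.unique(np.round(bt.ages, 12), return_counts=True)
    times = times[::-1]
    mult = mult[::-1]
    counts = 1 + np.cumsum(mult)
    return LTTCurve(times=times, counts=counts)


def _gamma_from_age_matrix(ages: np.ndarray) -> np.ndarray:
    """γ for each row of a (reps × n−1) matrix of descending node ages."""
    ages = np.atleast_2d(ages)
    n = ages.shape[1] + 1
    if n < 3:
        raise ValueError("γ requires at least 3 tips")
    bounds = np.concatenate([ages, np.zeros((ages.shape[0], 1))], axis=1)
    g = bounds[:, :-1] - bounds[:, 1:]          # g_k, k = 2..n
    k = np.arange(2, n + 1, dtype=float)
    kg = k * g
    T = kg.sum(axis=1)
    inner_means = np.cumsum(kg, axis=1)[:, :-1].mean(axis=1)
    return (inner_means - T / 2.0) / (T * math.sqrt(1.0 / (12.0 * (n - 2))))


def gamma_stat(bt: BranchingTimes) -> float:
    """Pybus & Harvey's γ: standardized position of branching events in time.

    Negative values mean internode intervals near the root are short relative
    to those near the tips (an early burst); under constant-rate pure birth γ
    is asymptotically standard normal.
    """
    if bt.n_tips < 3:
        raise ValueError("γ is undefined for fewer than 3 tips")
    return float(_gamma_from_age_matrix(bt.ages[None, :])[0])


# ---------------------------------------------------------------------------
# MCCR test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCCRResult:
    gamma_obs: float
    null_gammas: np.ndarray
    p_value: float
    critical_value: float
    n_sampled: int
    n_total: int
    seed: int


def _pruned_yule_ages(
    n_total: int, n_sampled: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Branching times of ``n_sampled``-tip subtrees of ``n_total``-tip pure-birth trees.

    Node ages of the full tree are sums of independent Exp(kλ) internode
    durations (λ = 1; γ is rate-invariant).  The induced subtree on a uniform
    tip subset is obtained from the Yule topology law directly: merging
    backward in time, each coalescence joins a uniform pair of the extant
    lineages, and a node is retained in the subtree exactly when both merging
    lineages subtend sampled tips.  This is equivalent to simulating the full
    topology and deleting tips uniformly at random.
    """
    if n_sampled < 3:
        raise ValueError("need at least 3 sampled tips")
    n = n_total
    ks = np.arange(2, n + 1, dtype=float)
    g = rng.exponential(1.0, size=(reps, n - 1)) / ks          # g_k, k=2..n
    ages = np.cumsum(g[:, ::-1], axis=1)                        # x_n .. x_2 ascending

    out = np.empty((reps, n_sampled - 1))
    cnt = np.zeros(reps, dtype=np.int64)
    j = np.full(reps, n_sampled, dtype=np.int64)
    for col, k in enumerate(range(n, 1, -1)):                   # merge at age x_k
        u = rng.random(reps)
        p_both = j * (j - 1) / (k * (k - 1))
        hit = u < p_both
        rows = np.nonzero(hit)[0]
        out[rows, cnt[rows]] = ages[rows, col]
        cnt[rows] += 1
        j[hit] -= 1
    assert np.all(cnt == n_sampled - 1)
    return out[:, ::-1]                                         # descending


def mccr_test(
    tree: Phylogeny | BranchingTimes,
    n_total: int,
    reps: int = 10_000,
    seed: int = 0,
) -> MCCRResult:
    """Monte-Carlo constant-rate test of γ corrected for incomplete sampling.

    Simulates ``reps`` pure-birth trees of ``n_total`` tips, uniformly deletes
    tips down to the observed sample size, recomputes γ on each pruned tree,
    and reports the one-tailed probability that a null γ is at most the
    observed one (small p rejects constant rates toward an early burst).
    """
    bt = tree if isinstance(tree, BranchingTimes) else branching_times(tree)
    if n_total < bt.n_tips:
        raise ValueError(f"n_total ({n_total}) < sampled tips ({bt.n_tips})")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    nulls = _gamma_from_age_matrix(_pruned_yule_ages(n_total, bt.n_tips, reps, rng))
    obs = gamma_stat(bt)
    return MCCRResult(
        gamma_obs=obs,
        null_gammas=nulls,
        p_value=float(np.mean(nulls <= obs)),
        critical_value=float(np.quantile(nulls, 0.05)),
        n_sampled=bt.n_tips,
        n_total=n_total,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# constant-rate closed form (crown-conditioned)
# ---------------------------------------------------------------------------


def _log_p1(t: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """log p1(t): probability a lineage of age t has exactly one extant descendant."""
    r = lam - mu
    t = np.asarray(t, dtype=float)
    if abs(r) < 1e-12 * max(lam, 1.0):
        return -2.0 * np.log1p(lam * t)
    # p1 = r^2 e^{-rt} / (lam - mu e^{-rt})^2
    return 2.0 * math.log(abs(r)) - r * t - 2.0 * np.log(np.abs(lam - mu * np.exp(-r * t)))


def _log_survival(t: float, lam: float, mu: float) -> float:
    """log P(a lineage of age t has at least one extant descendant)."""
    if mu == 0:
        return 0.0
    r = lam - mu
    if abs(r) < 1e-12 * max(lam, 1.0):
        return -math.log1p(lam * t)
    return math.log(abs(r)) - math.log(abs(lam - mu * math.exp(-r * t)))


def constant_rate_loglik(bt: BranchingTimes, lam: float, mu: float) -> float:
    """Closed-form log-likelihood of completely sampled branching times under
    constant-rate birth–death, conditioned on the crown age and on survival of
    both crown lineages:

        log L = log (n−1)! + 2·log(1 − u(x₂)) + Σ_{i=3..n} [log λ + log p₁(x_i)]

    with u(t) = λ(1−e^{−rt})/(λ−μe^{−rt}) and p₁(t) = r²e^{−rt}/(λ−μe^{−rt})².
    """
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    n = bt.n_tips
    x2 = bt.root_age
    # log(1-u) = log(r e^{-rt}/(lam - mu e^{-rt})) = log P(t) - r t
    r = lam - mu
    if abs(r) < 1e-12 * max(lam, 1.0):
        log_1mu = -math.log1p(lam * x2)
    else:
        log_1mu = math.log(abs(r)) - r * x2 - math.log(abs(lam - mu * math.exp(-r * x2)))
    inner = bt.ages[1:]
    return float(
        special.gammaln(n) + 2.0 * log_1mu + np.sum(math.log(lam) + _log_p1(inner, lam, mu))
    )


# ---------------------------------------------------------------------------
# master-equation likelihood
# ---------------------------------------------------------------------------


def _rate_fn(model: str, lambda0: float, mu: float, K: float | None):
    """Per-lineage speciation/extinction rates as functions of total diversity N."""
    if model == "Yule":
        return (lambda N: np.full_like(N, lambda0, dtype=float), 0.0)
    if model == "crBD":
        return (lambda N: np.full_like(N, lambda0, dtype=float), mu)
    if K is None or K <= 0:
        raise ValueError(f"model {model} requires a positive carrying capacity K")
    if model == "DDL+E":
        return (lambda N: np.maximum(0.0, lambda0 - (lambda0 - mu) * N / K), mu)
    if model == "DDE+E":
        if mu <= 0:
            raise ValueError("DDE+E requires mu > 0 (λ_N = λ0·(μ/λ0)^(N/K))")
        return (lambda N: lambda0 * (mu / lambda0) ** (N / K), mu)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _propagate_interval(Q, k, dt, lam_of_N, mu):
    """Advance the hidden-species probability vector through an internode
    interval with ``k`` reconstructed lineages, via the symmetrized
    eigendecomposition of the tridiagonal birth–death generator (exact in dt,
    no stiffness limit).  Returns the new (unnormalized) vector."""
    lx = len(Q)
    n = np.arange(lx, dtype=float)
    N = n + k
    lamN = lam_of_N(N)
    diag = -(N) * (lamN + mu)
    # gain n-1 -> n: hidden splits (n-1)·λ plus observed splits 2k·λ — the
    # factor 2 sums over which daughter continues the observed lineage
    low = (n[1:] - 1 + 2 * k) * lam_of_N(N[1:] - 1)
    up = (n[:-1] + 1) * mu                          # gain n+1 -> n

    # restrict to the block reachable from n = 0 (zero birth rates decouple it)
    live = lx
    zero_low = np.nonzero(low <= 0)[0]
    if zero_low.size:
        live = int(zero_low[0]) + 1
    if mu <= 0 or live == 1:
        # lower-bidiagonal cascade: dense expm on the (small) live block
        live_b = min(live, lx)
        G = np.diag(diag[:live_b])
        if live_b > 1:
            G += np.diag(low[: live_b - 1], -1)
            if mu > 0:
                G += np.diag(up[: live_b - 1], 1)
        out = np.zeros_like(Q)
        out[:live_b] = linalg.expm(G * dt) @ Q[:live_b]
        return out

    low_b = low[: live - 1]
    up_b = up[: live - 1]
    # symmetrize: d[0]=0 (log), d[n]-d[n-1] = 0.5 log(low/up)
    logd = np.concatenate([[0.0], 0.5 * np.cumsum(np.log(low_b) - np.log(up_b))])
    if logd.max() - logd.min() > 600.0:
        # extreme λ/μ asymmetry: downward flow is negligible, treat as cascade
        G = np.diag(diag[:live]) + np.diag(low_b, -1) + np.diag(up_b, 1)
        out = np.zeros_like(Q)
        out[:live] = linalg.expm(G * dt) @ Q[:live]
        return out
    offdiag = np.sqrt(low_b * up_b)
    w, V = linalg.eigh_tridiagonal(diag[:live], offdiag)
    d = np.exp(logd - logd.mean())
    y = V @ ((np.exp(w * dt) * (V.T @ (Q[:live] / d))))
    out = np.zeros_like(Q)
    out[:live] = np.maximum(y * d, 0.0)
    return out


def dd_loglik(
    lambda0: float,
    mu: float,
    K: float | None,
    model: str,
    bt: BranchingTimes,
    n_total: int,
    *,
    lx: int | None = None,
) -> float:
    """Master-equation log-likelihood of the branching times under a
    (possibly diversity-dependent) birth–death model.

    ``n_total − n_tips`` missing extant species are carried as hidden-state
    mass; the likelihood is conditioned on the crown age and on survival of
    both crown lineages (closed form with rates (λ0, μ); exact for the
    constant-rate models, and the approximation used for the
    diversity-dependent models so that the K→∞ limit reproduces crBD exactly).
    """
    if lambda0 <= 0 or mu < 0:
        raise ValueError("need lambda0 > 0 and mu >= 0")
    n = bt.n_tips
    m = n_total - n
    if m < 0:
        raise ValueError(f"n_total ({n_total}) < n_tips ({n})")
    if model == "Yule" and mu != 0:
        raise ValueError("Yule model has mu = 0")
    lam_of_N, mu_eff = _rate_fn(model, lambda0, mu, K)

    if lx is None:
        lx = max(100, 4 * m + 40)
    lx = min(lx, max(10 * int(K), 1000) if (K is not None and model != "crBD") else 1000)
    lx = max(lx, m + 5)
    if mu == 0.0:
        # hidden species never die: states above m cannot return, truncation exact
        lx = m + 1
    elif mu < 1e-3 * lambda0:
        # near-pure-birth: downward flow negligible, keep the state space small
        lx = min(lx, m + 40)

    ages = np.append(bt.ages, 0.0)
    Q = np.zeros(lx)
    Q[0] = 1.0
    log_scale = 0.0
    for k in range(2, n + 1):
        dt = float(ages[k - 2] - ages[k - 1])
        if dt > 0:
            Q = _propagate_interval(Q, k, dt, lam_of_N, mu_eff)
            s = Q.sum()
            if not np.isfinite(s) or s <= 0:
                raise FloatingPointError(
                    f"master-equation underflow/overflow in interval k={k} "
                    f"(truncation lx={lx}); try a larger truncation"
                )
            log_scale += math.log(s)
            Q = Q / s
        if k < n:
            nodefac = k * lam_of_N(np.arange(lx, dtype=float) + k)
            Q = Q * nodefac
            s = Q.sum()
            if not np.isfinite(s) or s <= 0:
                return -np.inf
            log_scale += math.log(s)
            Q = Q / s
    if Q[m] <= 0:
        return -np.inf
    log_uncond = log_scale + math.log(Q[m])
    log_pc = 2.0 * _log_survival(bt.root_age, lambda0, mu)
    return float(log_uncond - log_pc)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample bias-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class DiversificationFit:
    model: str
    lambda0: float
    mu: float
    K: float | None
    logL: float
    k_params: int
    AICc: float
    dAICc: float
    n_total: int
    converged: bool
    message: str = ""


def _start_points(model: str, n_total: int, rng: np.random.Generator, n_starts: int):
    """Multi-start grid: λ0 log-spaced in [0.1, 50], μ/λ0 in [0, 0.95],
    K in (n_total, 20·n_total], with seeded jitter."""
    lam_grid = np.exp(
        np.linspace(math.log(0.1), math.log(50.0), n_starts)
        + rng.uniform(-0.2, 0.2, n_starts)
    )
    s_grid = np.linspace(0.05, 0.95, n_starts)
    rng.shuffle(s_grid)
    K_grid = n_total * np.linspace(1.5, 20.0, n_starts)
    rng.shuffle(K_grid)
    starts = []
    for i in range(n_starts):
        if model == "Yule":
            starts.append([math.log(lam_grid[i])])
        elif model == "crBD":
            starts.append([math.log(lam_grid[i]), s_grid[i]])
        else:
            starts.append([math.log(lam_grid[i]), s_grid[i], math.log(K_grid[i] - n_total)])
    return starts


def _unpack(model: str, x: np.ndarray, n_total: int):
    lam = math.exp(x[0])
    if model == "Yule":
        return lam, 0.0, None
    mu = lam * x[1]
    K = None
    if model in ("DDL+E", "DDE+E"):
        K = n_total + math.exp(x[2])
    return lam, mu, K


def fit_diversification(
    tree: Phylogeny | BranchingTimes,
    n_total: int,
    *,
    models: tuple[str, ...] = MODELS,
    seed: int = 0,
    n_starts: int = 5,
    lx: int | None = None,
) -> list[DiversificationFit]:
    """ML fits and AICc ranking of the diversification models.

    AICc uses the number of tips as the sample size.  Returns fits sorted by
    AICc (best first, ΔAICc = 0).  Non-convergence is flagged on the fit, not
    raised.
    """
    from scipy import optimize

    bt = tree if isinstance(tree, BranchingTimes) else branching_times(tree)
    n = bt.n_tips
    if n_total < n:
        raise ValueError("n_total must be at least the number of tips")
    rng = np.random.default_rng(seed)

    bounds_by_model = {
        "Yule": [(math.log(1e-4), math.log(1e4))],
        "crBD": [(math.log(1e-4), math.log(1e4)), (1e-8, 0.999)],
        "DDL+E": [(math.log(1e-4), math.log(1e4)), (1e-8, 0.999), (math.log(1e-3), math.log(1e8))],
        "DDE+E": [(math.log(1e-4), math.log(1e4)), (1e-6, 0.999), (math.log(1e-3), math.log(1e8))],
    }

    fits = []
    mle_by_model: dict[str, np.ndarray] = {}
    for model in models:
        bounds = bounds_by_model[model]

        def nll(x, model=model):
            lam, mu, K = _unpack(model, x, n_total)
            try:
                ll = dd_loglik(lam, mu, K, model, bt, n_total, lx=lx)
            except FloatingPointError:
                return 1e10
            if not np.isfinite(ll):
                return 1e10
            return -ll

        starts = _start_points(model, n_total, rng, n_starts)
        # warm starts at the nested simpler model's MLE guarantee the richer
        # model never scores below it (model nesting, up to local polish)
        if model == "crBD" and "Yule" in mle_by_model:
            starts.append([mle_by_model["Yule"][0], 1e-8])
        if model in ("DDL+E", "DDE+E") and "crBD" in mle_by_model:
            lam_c, s_c = mle_by_model["crBD"]
            starts.append([lam_c, max(s_c, 1e-6 if model == "DDE+E" else 1e-8),
                           math.log(5e7)])
        best = None
        any_ok = False
        message = ""
        for x0 in starts:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 60, "ftol": 1e-10},
            )
            any_ok = any_ok or res.success
            if best is None or res.fun < best.fun:
                best = res
        if not any_ok:
            message = f"optimizer did not report convergence: {best.message}"
        mle_by_model[model] = best.x
        lam, mu, K = _unpack(model, best.x, n_total)
        logL = -best.fun
        k = _N_PARAMS[model]
        fits.append(
            DiversificationFit(
                model=model, lambda0=lam, mu=mu, K=K, logL=logL, k_params=k,
                AICc=aicc(logL, k, n), dAICc=0.0, n_total=n_total,
                converged=any_ok, message=message,
            )
        )
    best_aicc = min(f.AICc for f in fits)
    fits = [replace(f, dAICc=f.AICc - best_aicc) for f in fits]
    return sorted(fits, key=lambda f: f.AICc)
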