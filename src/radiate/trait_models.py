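"""Gaussian models of continuous-trait evolution on ultrametric trees.

Fits and compares by AICc four classical models of ln body-size evolution:

* **BM** — Brownian motion, variance grows linearly with time at rate σ²;
* **OU** — Ornstein–Uhlenbeck with pull α toward an optimum, in the
  non-stationary parameterization (root state fixed, variance grows from 0);
* **EB** — early burst, Brownian rate decaying as σ²·e^{a·t} with a ≤ 0;
* **Delta** — Pagel's δ time-warp, node depths raised to the power δ with the
  total height preserved (δ > 1: late evolution, δ < 1: early).

All four are Gaussian, so the likelihood is a phylogenetic GLS: the root
state is profiled analytically and σ² is profiled analytically inside a 1-D
bounded optimization of the single shape parameter.  AICc uses the number of
species with trait data as the sample size.

The δ upper bound is 3, the conventional default of comparative-methods
fitting tools; data generated under strong late acceleration will pin δ̂
there, and a boundary estimate should be read as "at least this late-heavy".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .tree import Phylogeny, shared_time_matrix
from .diversification import aicc

__all__ = [
    "TraitModelFit",
    "species_svl",
    "read_trait_table",
    "model_vcv",
    "gls_loglik",
    "fit_trait_models",
    "ancestral_states",
    "TRAIT_MODELS",
]

TRAIT_MODELS = ("BM", "OU", "EB", "Delta")

#: Pagel δ search interval (upper bound 3 is the standard convention)
DELTA_BOUNDS = (1e-6, 3.0)


# ---------------------------------------------------------------------------
# body-size data preparation
# ---------------------------------------------------------------------------


def species_svl(raw: pd.DataFrame) -> pd.Series:
    """Species ln-SVL from specimen-level measurements.

    For each sex within each species, specimens in the upper two-thirds of
    the observed size range (SVL ≥ min + (max − min)/3) are averaged; the
    species value is the mean of the sex means, then ln-transformed.  Using
    an intermediate upper quantile rather than the maximum avoids
    overestimating asymptotic size from extreme individuals.

    ``raw`` needs columns ``species``, ``sex`` and ``svl_mm``.
    """
    required = {"species", "sex", "svl_mm"}
    if not required.issubset(raw.columns):
        raise ValueError(f"specimen table needs columns {sorted(required)}")

    def upper_two_thirds_mean(v: np.ndarray) -> float:
        v = np.asarray(v, dtype=float)
        cutoff = v.min() + (v.max() - v.min()) / 3.0
        return float(v[v >= cutoff].mean())

    out = {}
    for sp, grp in raw.groupby("species", sort=True):
        sex_means = [
            upper_two_thirds_mean(g["svl_mm"].to_numpy())
            for _, g in grp.groupby("sex")
            if len(g)
        ]
        if not sex_means:
            warnings.warn(f"species {sp!r} has no measurable specimens; excluded")
            continue
        if len(sex_means) == 1:
            warnings.warn(f"species {sp!r} has specimens of a single sex")
        out[sp] = math.log(float(np.mean(sex_means)))
    return pd.Series(out, name="ln_svl").rename_axis("species")


def read_trait_table(path) -> pd.Series:
    """Read a species trait table (CSV/TSV) into a ln-SVL Series.

    Accepts ``species, ln_svl`` (used as-is), ``species, svl_mm`` (species
    means, ln-transformed), or specimen-level ``species, sex, svl_mm``
    (aggregated via :func:`species_svl`).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "ln_svl" in df.columns:
        s = df.set_index("species")["ln_svl"].astype(float)
    elif "sex" in df.columns:
        s = species_svl(df)
    elif "svl_mm" in df.columns:
        s = np.log(df.set_index("species")["svl_mm"].astype(float))
    else:
        raise ValueError("trait table needs columns species + ln_svl | svl_mm | sex,svl_mm")
    s.index = s.index.astype(str).str.strip()
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("non-finite trait values")
    return s.rename("ln_svl")


# ---------------------------------------------------------------------------
# model covariance structures
# ---------------------------------------------------------------------------


def model_vcv(
    tree: Phylogeny,
    model: str,
    params: dict,
    *,
    S: np.ndarray | None = None,
) -> np.ndarray:
    """Among-tip trait covariance matrix implied by a model.

    With shared times ``s_ij`` (root to MRCA) and tree height T:

    * BM: σ²·s_ij
    * OU: (σ²/2α)·e^{−2α(T−s_ij)}·(1−e^{−2α·s_ij}); α = 0 falls back to BM
    * EB: σ²·(e^{a·s_ij}−1)/a; a = 0 falls back to BM
    * Delta: σ²·T·(s_ij/T)^δ (height-preserving time-warp)
    """
    if S is None:
        S = shared_time_matrix(tree)
    T = tree.root_height
    sigma2 = float(params.get("sigma2", 1.0))
    if model == "BM":
        return sigma2 * S
    if model == "OU":
        alpha = float(params["alpha"])
        if alpha == 0.0:
            return sigma2 * S
        return (sigma2 / (2.0 * alpha)) * np.exp(-2.0 * alpha * (T - S)) * (
            -np.expm1(-2.0 * alpha * S)
        )
    if model == "EB":
        a = float(params["a"])
        if a > 0:
            raise ValueError("EB exponent a must be <= 0")
        if a == 0.0:
            return sigma2 * S
        return sigma2 * np.expm1(a * S) / a
    if model == "Delta":
        delta = float(params["delta"])
        if delta <= 0:
            raise ValueError("delta must be > 0")
        return sigma2 * T * (S / T) ** delta
    raise ValueError(f"unknown trait model {model!r}; expected one of {TRAIT_MODELS}")


def gls_loglik(z: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """Phylogenetic GLS log-likelihood with the root state profiled out.

    Returns ``(logL, z0_hat)`` where ẑ0 = (1ᵀV⁻¹1)⁻¹·1ᵀV⁻¹z and
    logL = −½[n ln 2π + ln|V| + (z − ẑ0·1)ᵀV⁻¹(z − ẑ0·1)].
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        d = np.sqrt(np.diag(V))
        R = V / np.outer(d, d)
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
        raise linalg.LinAlgError(
            f"singular trait covariance (most correlated pair: tips {i} and {j}, "
            f"r = {R[i, j]:.6f}); near-duplicate tips?"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    ones = np.ones(n)
    Vi1 = linalg.cho_solve((c, low), ones)
    z0 = float(Vi1 @ z / (Vi1 @ ones))
    resid = z - z0
    quad = float(resid @ linalg.cho_solve((c, low), resid))
    logL = -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)
    return float(logL), z0


@dataclass(frozen=True)
class TraitModelFit:
    model: str
    sigma2: float
    z0: float
    logL: float
    k_params: int
    AICc: float
    dAICc: float
    alpha: float | None = None
    a: float | None = None
    delta: float | None = None
    at_bound: bool = False

    @property
    def shape_param(self) -> float | None:
        return {"BM": None, "OU": self.alpha, "EB": self.a, "Delta": self.delta}[self.model]


def _profiled_fit(z: np.ndarray, V0: np.ndarray) -> tuple[float, float, float]:
    """ML fit of (σ², z0) given the unit-rate structure V = σ²·V0.

    Returns (logL, sigma2_hat, z0_hat)."""
    n = len(z)
    c, low = linalg.cho_factor(V0, lower=True)
    logdet0 = 2.0 * np.sum(np.log(np.diag(c)))
    ones = np.ones(n)
    Vi1 = linalg.cho_solve((c, low), ones)
    z0 = float(Vi1 @ z / (Vi1 @ ones))
    resid = z - z0
    quad = float(resid @ linalg.cho_solve((c, low), resid))
    sigma2 = quad / n
    if sigma2 <= 0:
        return -np.inf, 0.0, z0
    logL = -0.5 * (n * (math.log(2.0 * math.pi) + 1.0 + math.log(sigma2)) + logdet0)
    return logL, sigma2, z0


def _align(tree: Phylogeny, trait: pd.Series) -> tuple[Phylogeny, np.ndarray]:
    """Prune the tree to the trait species and order values to the tip order."""
    trait = trait.dropna()
    labels = set(tree.tip_labels)
    have = [sp for sp in trait.index if sp in labels]
    missing = sorted(set(trait.index) - labels)
    if missing:
        raise ValueError(f"trait species not in tree: {missing}")
    sub = tree if len(have) == tree.n_tips else tree.prune(have)
    z = trait.loc[sub.tip_labels].to_numpy(dtype=float)
    return sub, z


def fit_trait_models(
    tree: Phylogeny,
    trait: pd.Series,
    *,
    models: tuple[str, ...] = TRAIT_MODELS,
) -> list[TraitModelFit]:
    """ML fits of BM/OU/EB/Delta with AICc ranking (best first, ΔAICc = 0).

    Shape-parameter bounds: α ∈ [1e-8, 50/T], a ∈ [−10/T, 0], δ ∈ (0, 3].
    σ² and the root state are profiled analytically, so each fit is a
    deterministic 1-D bounded optimization.  Boundary-pinned estimates are
    flagged via ``at_bound``, not raised.
    """
    sub, z = _align(tree, trait)
    S = shared_time_matrix(sub)
    T = sub.root_height
    n = len(z)

    shape_bounds = {
        "OU": (1e-8, 50.0 / T),
        "EB": (-10.0 / T, 0.0),
        "Delta": DELTA_BOUNDS,
    }
    shape_name = {"OU": "alpha", "EB": "a", "Delta": "delta"}

    fits: list[TraitModelFit] = []
    for model in models:
        k = 2 if model == "BM" else 3
        if model == "BM":
            logL, sigma2, z0 = _profiled_fit(z, S)
            fit = TraitModelFit(model, sigma2, z0, logL, k, aicc(logL, k, n), 0.0)
        else:
            lo, hi = shape_bounds[model]

            def nll(theta, model=model):
                V0 = model_vcv(sub, model, {shape_name[model]: theta}, S=S)
                try:
                    logL, _, _ = _profiled_fit(z, V0)
                except linalg.LinAlgError:
                    return 1e10
                return -logL

            res = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            # a bounded scalar search can miss a boundary optimum; check ends
            theta = res.x
            fval = res.fun
            for cand in (lo, hi):
                f = nll(cand)
                if f < fval:
                    theta, fval = cand, f
            V0 = model_vcv(sub, model, {shape_name[model]: theta}, S=S)
            logL, sigma2, z0 = _profiled_fit(z, V0)
            span = hi - lo
            at_bound = min(abs(theta - lo), abs(theta - hi)) < 1e-6 * span
            fit = TraitModelFit(
                model, sigma2, z0, logL, k, aicc(logL, k, n), 0.0,
                at_bound=at_bound, **{shape_name[model]: float(theta)},
            )
        fits.append(fit)
    best = min(f.AICc for f in fits)
    fits = [replace(f, dAICc=f.AICc - best) for f in fits]
    return sorted(fits, key=lambda f: f.AICc)


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------


def ancestral_states(tree: Phylogeny, trait: pd.Series) -> pd.DataFrame:
    """ML (GLS) ancestral states under Brownian motion.

    For each internal node v, ẑ_v = ẑ0 + c_vᵀ S⁻¹ (z − ẑ0·1) with
    c_v[i] the shared time between v and tip i; the root estimate equals the
    GLS root state.  Variances use the BM ML rate and account for root-state
    estimation.  Returns a DataFrame indexed by internal node id with columns
    ``age``, ``state`` and ``variance``.
    """
    sub, z = _align(tree, trait)
    S = shared_time_matrix(sub)
    n = len(z)
    c, low = linalg.cho_factor(S, lower=True)
    ones = np.ones(n)
    Si1 = linalg.cho_solve((c, low), ones)
    z0 = float(Si1 @ z / (Si1 @ ones))
    resid = z - z0
    Sir = linalg.cho_solve((c, low), resid)
    sigma2 = float(resid @ Sir) / n

    pos = {int(t): i for i, t in enumerate(sub.tips)}
    desc = sub.descendant_tips()
    rows = []
    for v in sub.internal_nodes:
        # shared time of node v with tip i: depth of MRCA(v, i) = depth of v
        # for descendants, else depth of MRCA of the clades
        cv = np.zeros(n)
        below = {pos[int(t)] for t in desc[v]}
        for i_tip in below:
            cv[i_tip] = sub.depth[v]
        # ancestors of v determine shared times with non-descendant tips
        u = v
        while sub.parent[u] >= 0:
            p = sub.parent[u]
            for cchild in sub.children[p]:
                if cchild != u:
                    for t in desc[cchild]:
                        cv[pos[int(t)]] = sub.depth[p]
            u = p
        state = z0 + float(cv @ Sir)
        Sicv = linalg.cho_solve((c, low), cv)
        h = 1.0 - float(cv @ Si1)
        var = sigma2 * (
            float(sub.depth[v]) - float(cv @ Sicv) + h * h / float(ones @ Si1)
        )
        rows.append((int(v), sub.node_age(int(v)), state, max(var, 0.0)))
    return pd.DataFrame(rows, columns=["node", "age", "state", "variance"]).set_index("node")
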