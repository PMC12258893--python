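"""Gamma log-link mixed models for silencing-memory half-lives.

The analysis model for comparing strains is

    Value ~ Strain + (1|Block) + (1|Block:Replicate),  family = Gamma(log)

and for environmental comparisons ``Value ~ Strain * Environment`` with the
same nested random intercepts. Both Gamma(log) and Gaussian(identity)
families are supported; Gamma(log) is the default throughout.

Estimation maximizes the Laplace-approximate marginal likelihood: an inner
Newton iteration finds the mode of the random effects given the outer
parameters, and an outer quasi-Newton optimizes the fixed effects, the two
variance components (on the log-SD scale) and the dispersion. With the
random terms removed the fit reduces exactly to a Gamma log-link GLM, solved
by iteratively reweighted least squares.

Inference uses the normal reference (Wald z / chi-square): there is no agreed
finite-sample degrees-of-freedom convention for this model class, and this is
documented as a limitation. Marginal means average predictions over the
levels of the other fixed factor with equal weights; pairwise contrasts are
adjusted by the single-step (Tukey-style) method — the adjusted p-value is
the probability that the maximum absolute standardized contrast in the family
exceeds the observed one, computed under the estimated contrast correlation
by scrambled-Sobol quasi-Monte-Carlo integration with a fixed internal seed.

Residual diagnostics follow the simulation approach: responses are simulated
from the fitted model (re-drawing random effects), each observation's scaled
residual is its rank position within its own simulated values, and the
resulting sample is tested for uniformity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.stats import qmc

from .errors import (
    AliasingError,
    EstimabilityError,
    ParameterError,
    ValidationError,
)

_ETA_CLIP = 500.0  # log-scale linear predictors beyond this overflow exp()


# ---------------------------------------------------------------------------
# Families


class _GammaLog:
    """Gamma family, log link: mean mu = exp(eta), Var = mu^2 / shape."""

    name = "gamma_log"
    disp_bounds = (-5.0, 15.0)  # bounds on log(shape)

    @staticmethod
    def check_response(y: np.ndarray) -> None:
        if np.any(y <= 0):
            raise ParameterError("gamma family requires strictly positive response values")

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray, theta: float) -> np.ndarray:
        alpha = math.exp(theta)
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return (
            alpha * (theta - eta)
            - special.gammaln(alpha)
            + (alpha - 1.0) * np.log(y)
            - alpha * y * np.exp(-eta)
        )

    @staticmethod
    def dldeta(y: np.ndarray, eta: np.ndarray, theta: float) -> np.ndarray:
        alpha = math.exp(theta)
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return alpha * (y * np.exp(-eta) - 1.0)

    @staticmethod
    def weight(y: np.ndarray, eta: np.ndarray, theta: float) -> np.ndarray:
        # -d2 loglik / d eta^2, strictly positive for y > 0
        alpha = math.exp(theta)
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return alpha * y * np.exp(-eta)

    @staticmethod
    def simulate(eta: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
        alpha = math.exp(theta)
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return rng.gamma(shape=alpha, scale=mu / alpha)

    @staticmethod
    def pearson(y: np.ndarray, eta: np.ndarray, theta: float) -> float:
        alpha = math.exp(theta)
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return float(np.sum((y - mu) ** 2 / (mu**2 / alpha)))

    @staticmethod
    def init(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
        beta0, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
        resid = y / np.exp(np.clip(X @ beta0, -_ETA_CLIP, _ETA_CLIP))
        cv2 = float(np.var(resid) / np.mean(resid) ** 2) if len(y) > 1 else 0.1
        alpha0 = min(max(1.0 / max(cv2, 1e-6), 0.1), 1e4)
        return beta0, math.log(alpha0)


class _GaussianIdentity:
    """Gaussian family, identity link: mean = eta, Var = sigma^2."""

    name = "gaussian_identity"
    disp_bounds = (-15.0, 10.0)  # bounds on log(sigma^2)

    @staticmethod
    def check_response(y: np.ndarray) -> None:
        pass

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray, theta: float) -> np.ndarray:
        s2 = math.exp(theta)
        return -0.5 * ((y - eta) ** 2 / s2 + theta + math.log(2.0 * math.pi))

    @staticmethod
    def dldeta(y: np.ndarray, eta: np.ndarray, theta: float) -> np.ndarray:
        return (y - eta) / math.exp(theta)

    @staticmethod
    def weight(y: np.ndarray, eta: np.ndarray, theta: float) -> np.ndarray:
        return np.full(len(y), 1.0 / math.exp(theta))

    @staticmethod
    def simulate(eta: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
        return eta + rng.normal(0.0, math.sqrt(math.exp(theta)), size=len(eta))

    @staticmethod
    def pearson(y: np.ndarray, eta: np.ndarray, theta: float) -> float:
        return float(np.sum((y - eta) ** 2 / math.exp(theta)))

    @staticmethod
    def init(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta0) ** 2))
        return beta0, math.log(max(rss / len(y), 1e-10))


_FAMILIES = {"gamma_log": _GammaLog, "gaussian_identity": _GaussianIdentity}


# ---------------------------------------------------------------------------
# Model specification and design matrices


@dataclass(frozen=True)
class GlmmSpec:
    """Specification of a half-life mixed model.

    ``factors`` are the fixed-effect factor columns (one factor, or two with
    ``interaction=True`` for the strain-by-environment model); ``random``
    selects nested random intercepts among ``"block"`` and
    ``"block_replicate"``. An empty ``random`` pins both variance components
    to zero (plain GLM).
    """

    response: str = "value"
    factors: tuple[str, ...] = ("strain",)
    interaction: bool = False
    random: tuple[str, ...] = ("block", "block_replicate")
    family: str = "gamma_log"

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "random", tuple(self.random))
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}; known: {sorted(_FAMILIES)}")
        # an empty factor tuple is the intercept-only model (used as the
        # reduced model in likelihood-ratio tests)
        if self.interaction and len(self.factors) != 2:
            raise ParameterError("interaction requires exactly two factors")
        for r in self.random:
            if r not in ("block", "block_replicate"):
                raise ParameterError(f"unknown random term {r!r}")


def _level_name(factor: str, level: str) -> str:
    return f"{factor}[{level}]"


def build_fixed_design(
    data: pd.DataFrame,
    factors: Sequence[str],
    interaction: bool,
    levels: Mapping[str, Sequence[str]] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Treatment-coded fixed design: intercept, factor dummies, products.

    The first level alphabetically is the reference. ``levels`` may be
    supplied (by a fitted model) to build prediction rows on the same coding.
    """
    if levels is None:
        levels = {f: sorted(map(str, pd.unique(data[f]))) for f in factors}
    else:
        levels = {f: list(levels[f]) for f in factors}
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["Intercept"]
    dummies: dict[tuple[str, str], np.ndarray] = {}
    for f in factors:
        observed = set(map(str, pd.unique(data[f])))
        unknown = observed - set(levels[f])
        if unknown:
            raise ValidationError(f"unknown levels for factor {f!r}: {sorted(unknown)}")
        vals = data[f].astype(str).to_numpy()
        for lvl in levels[f][1:]:
            d = (vals == lvl).astype(float)
            dummies[(f, lvl)] = d
            cols.append(d)
            names.append(_level_name(f, lvl))
    if interaction:
        f1, f2 = factors
        for l1 in levels[f1][1:]:
            for l2 in levels[f2][1:]:
                cols.append(dummies[(f1, l1)] * dummies[(f2, l2)])
                names.append(f"{_level_name(f1, l1)}:{_level_name(f2, l2)}")
    X = np.column_stack(cols)
    return X, names, {f: list(levels[f]) for f in factors}


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise AliasingError(f"fixed design is rank deficient; aliased columns: {bad}")


def build_random_design(
    data: pd.DataFrame, random: Sequence[str]
) -> tuple[np.ndarray, list[int], list[str], dict[str, list[str]]]:
    """Indicator matrices for the nested random intercepts.

    Returns ``(Z, sizes, term_names, group_levels)`` where ``sizes`` gives the
    number of columns per random term, in ``random`` order.
    """
    blocks = sorted(map(str, pd.unique(data["block"])))
    cols: list[np.ndarray] = []
    sizes: list[int] = []
    names: list[str] = []
    group_levels: dict[str, list[str]] = {}
    bvals = data["block"].astype(str).to_numpy()
    for term in random:
        if term == "block":
            group_levels[term] = blocks
            for b in blocks:
                cols.append((bvals == b).astype(float))
            sizes.append(len(blocks))
        else:  # block_replicate
            rvals = data["replicate"].astype(str).to_numpy()
            combos = sorted(set(zip(bvals, rvals)))
            group_levels[term] = [f"{b}:{r}" for b, r in combos]
            for b, r in combos:
                cols.append(((bvals == b) & (rvals == r)).astype(float))
            sizes.append(len(combos))
        names.append(term)
    Z = np.column_stack(cols) if cols else np.zeros((len(data), 0))
    return Z, sizes, names, group_levels


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class GlmmFit:
    """A fitted mixed model: link-scale fixed effects, variance components,
    dispersion, Laplace log-likelihood and everything needed for prediction,
    simulation and contrasts."""

    spec: GlmmSpec
    coef_names: list[str]
    beta: np.ndarray
    vcov_beta: np.ndarray
    var_block: float | None
    var_rep: float | None
    dispersion: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: dict[str, int]
    levels: dict[str, list[str]]
    notes: list[str] = field(default_factory=list)
    # internal state for simulation / refits
    _y: np.ndarray = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)
    _Z: np.ndarray = field(default=None, repr=False)
    _u: np.ndarray = field(default=None, repr=False)
    _z_sizes: list[int] = field(default_factory=list, repr=False)
    _z_terms: list[str] = field(default_factory=list, repr=False)
    _observed_cells: set = field(default_factory=set, repr=False)

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.coef_names)

    @property
    def shape(self) -> float:
        """Gamma shape (or 1/residual-variance analogue is not defined for
        gaussian; use ``dispersion`` there)."""
        if self.spec.family != "gamma_log":
            raise ParameterError("shape is defined for the gamma family only")
        return self.dispersion

    def summary_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "coefficients": {n: float(b) for n, b in zip(self.coef_names, self.beta)},
            "se": {
                n: float(s)
                for n, s in zip(self.coef_names, np.sqrt(np.diag(self.vcov_beta)))
            },
            "var_block": self.var_block,
            "var_replicate": self.var_rep,
            "dispersion": self.dispersion,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "notes": self.notes,
        }


def _joint_mode(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    dinv: np.ndarray,
    fam,
    theta: float,
    v0: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Newton mode of the joint (beta, u) penalized log-likelihood.

    The objective sum_i l_i(eta) - u' D^-1 u / 2 with eta = X beta + Z u is
    concave in (beta, u) for both families, so damped Newton converges; warm
    starts from the previous outer iteration make this a handful of steps.
    """
    p, q = X.shape[1], Z.shape[1]
    M = np.hstack([X, Z])
    pen = np.concatenate([np.zeros(p), dinv])
    v = v0.copy()

    def pll(v):
        eta = M @ v
        return float(np.sum(fam.loglik(y, eta, theta)) - 0.5 * np.sum(pen * v * v))

    f = pll(v)
    for _ in range(100):
        eta = M @ v
        grad = M.T @ fam.dldeta(y, eta, theta) - pen * v
        tol = 1e-9 * (1.0 + abs(f))
        if np.max(np.abs(grad)) < tol:
            break
        W = fam.weight(y, eta, theta)
        H = (M.T * W) @ M + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton; accept up to float noise, stop once progress stalls
        slack = 1e-11 * (1.0 + abs(f))
        t, accepted = 1.0, False
        for _ in range(30):
            f_new = pll(v + t * step)
            if f_new >= f - slack:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        v = v + t * step
        stalled = f_new - f < slack
        f = max(f, f_new)
        if stalled and t == 1.0:
            break
    return v, f


def _laplace_nll_factory(y, X, Z, z_sizes, fam, n_sd: int):
    """Negative Laplace marginal log-likelihood, profiled over (beta, u).

    The outer parameter vector is (log-SD per random term, dispersion); the
    fixed effects and random-effect modes are profiled out by the inner
    Newton solve, and the Laplace determinant is taken over the random-effect
    block. Returns (nll, details) where details(theta) recomputes the profiled
    state at an outer point.
    """
    p = X.shape[1]
    q = Z.shape[1]
    cache = {"v": np.concatenate([fam.init(y, X)[0], np.zeros(q)])}

    def state(theta_vec: np.ndarray):
        log_sds = theta_vec[:n_sd]
        disp = theta_vec[n_sd]
        sd2 = np.exp(2.0 * np.repeat(log_sds, z_sizes))
        dinv = 1.0 / sd2
        v, f = _joint_mode(y, X, Z, dinv, fam, disp, cache["v"])
        cache["v"] = v
        eta = X @ v[:p] + (Z @ v[p:] if q else 0.0)
        W = fam.weight(y, eta, disp)
        Huu = (Z.T * W) @ Z + np.diag(dinv)
        # log det(D Huu) = sum log sd2 + log det(Huu); -> 0 as sd -> 0
        sign, logdet = np.linalg.slogdet(Huu)
        ll = f - 0.5 * (logdet + float(np.sum(np.log(sd2)))) if sign > 0 else -1e10
        return v, W, dinv, ll

    def nll(theta_vec: np.ndarray) -> float:
        return -state(theta_vec)[3]

    return nll, state


def _central_gradient(fun, x: np.ndarray, h_rel: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = h_rel * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2.0 * h)
    return g


def _fit_glm_gamma(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """ML gamma log-link GLM by IRLS (unit working weights for this link),
    then ML shape given the mean fit."""
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    for _ in range(200):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        beta_new, *_ = np.linalg.lstsq(X, z, rcond=None)
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
    # d loglik / d alpha = 0  <=>  log(alpha) - psi(alpha) = c
    c = -1.0 - float(np.mean(np.log(y / mu) - y / mu))
    c = max(c, 1e-12)

    def f(a):
        return math.log(a) - special.digamma(a) - c

    lo, hi = 1e-8, 1e12
    alpha = optimize.brentq(f, lo, hi)
    return beta, math.log(alpha)


def fit_glmm(data: pd.DataFrame, spec: GlmmSpec) -> GlmmFit:
    """Fit the mixed model by maximizing the Laplace marginal likelihood.

    ``data`` must carry the response column plus every factor column and the
    ``block`` / ``replicate`` grouping columns. Censored (NaN) responses must
    be excluded beforehand. If only one block is present, the block random
    intercept is dropped automatically (and noted on the fit).
    """
    fam = _FAMILIES[spec.family]
    for col in (spec.response, "block", "replicate", *spec.factors):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from the model data")
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValidationError(
            "non-finite response values (censored estimates must be excluded "
            "before model fitting)"
        )
    fam.check_response(y)
    for f in spec.factors:
        if data[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} needs >= 2 levels to be tested")

    notes: list[str] = []
    random = list(spec.random)
    if "block" in random and data["block"].nunique() < 2:
        random.remove("block")
        notes.append("single block: (1|Block) random intercept dropped")

    X, names, levels = build_fixed_design(data, spec.factors, spec.interaction)
    _check_rank(X, names)
    Z, z_sizes, z_terms, group_levels = build_random_design(data, random)
    p, n_sd = X.shape[1], len(z_sizes)
    n_groups = {t: len(gl) for t, gl in group_levels.items()}
    observed_cells = (
        set(map(tuple, data[list(spec.factors)].astype(str).itertuples(index=False)))
        if len(spec.factors) > 1
        else set()
    )

    if n_sd == 0:
        # Exact GLM limit: no integral to approximate.
        if spec.family == "gamma_log":
            beta, disp = _fit_glm_gamma(y, X)
        else:
            beta, disp = fam.init(y, X)
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        loglik = float(np.sum(fam.loglik(y, eta, disp)))
        W = fam.weight(y, eta, disp)
        vcov_beta = np.linalg.inv((X.T * W) @ X)
        sds = np.array([])
        converged = True
    else:
        nll, state = _laplace_nll_factory(y, X, Z, z_sizes, fam, n_sd)
        _, disp0 = fam.init(y, X)
        x0 = np.concatenate([np.full(n_sd, math.log(0.2)), [disp0]])
        lo, hi = fam.disp_bounds
        bounds = [(-8.0, 3.0)] * n_sd + [(lo, hi)]
        res = optimize.minimize(
            nll,
            x0,
            jac=lambda x: _central_gradient(nll, x),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        v_hat, W, dinv, loglik = state(res.x)
        beta, disp = v_hat[:p], res.x[n_sd]
        converged = bool(res.success)
        # vcov(beta): beta block of the inverse joint (beta, u) Hessian at the
        # mode, variance parameters held at their estimates (Schur complement
        # of the u block) — positive definite by construction.
        Hbb = (X.T * W) @ X
        Hbu = (X.T * W) @ Z
        ZWZ = (Z.T * W) @ Z
        Huu = ZWZ + np.diag(dinv)
        vcov_beta = np.linalg.inv(Hbb - Hbu @ np.linalg.solve(Huu, Hbu.T))
        sds = np.exp(res.x[:n_sd])
        # Wald inference uses a Pearson-based dispersion with residual df
        # n - p - edf(u) (the gamma-GLM scale convention, extended with the
        # effective df of the shrunken random effects); the ML dispersion
        # underestimates residual variation in small samples because the
        # fitted means absorb part of it.
        eta_c = X @ beta + Z @ v_hat[p:]
        edf_u = float(np.trace(np.linalg.solve(Huu, ZWZ)))
        df_resid = len(y) - p - edf_u
        if df_resid > 1.0:
            pearson = fam.pearson(y, eta_c, disp)  # scaled by ML dispersion
            vcov_beta = vcov_beta * max(pearson / df_resid, 1e-12)

    vcov_beta = 0.5 * (vcov_beta + vcov_beta.T)
    var_by_term = dict(zip(z_terms, sds**2))
    dispersion = math.exp(disp)

    return GlmmFit(
        spec=spec,
        coef_names=names,
        beta=np.asarray(beta, dtype=float).copy(),
        vcov_beta=vcov_beta,
        var_block=float(var_by_term["block"]) if "block" in var_by_term else None,
        var_rep=(
            float(var_by_term["block_replicate"])
            if "block_replicate" in var_by_term
            else None
        ),
        dispersion=float(dispersion),
        loglik=float(loglik),
        converged=converged,
        n_obs=len(y),
        n_groups=n_groups,
        levels=levels,
        notes=notes,
        _y=y,
        _X=X,
        _Z=Z,
        _u=(v_hat[p:].copy() if n_sd else np.zeros(Z.shape[1])),
        _z_sizes=z_sizes,
        _z_terms=z_terms,
        _observed_cells=observed_cells,
    )


def filter_singleton_strains(
    data: pd.DataFrame, strain_col: str = "strain", block_col: str = "block"
) -> tuple[pd.DataFrame, list[str]]:
    """Drop strains tested in a single block (excluded from strain-effect
    fits by default). Returns the filtered frame and the dropped strains."""
    counts = data.groupby(strain_col)[block_col].nunique()
    dropped = sorted(counts.index[counts < 2])
    return data[~data[strain_col].isin(dropped)].copy(), [str(s) for s in dropped]


# ---------------------------------------------------------------------------
# Term tests


@dataclass(frozen=True)
class TermTest:
    term: str
    stat: float
    df: int
    p: float
    kind: str  # "wald" or "lr"


def _term_columns(fit: GlmmFit, term: str) -> list[int]:
    if ":" in term:
        f1, f2 = term.split(":")
        if not (f1 in fit.spec.factors and f2 in fit.spec.factors and fit.spec.interaction):
            raise ParameterError(f"unknown interaction term {term!r}")
        idx = [i for i, n in enumerate(fit.coef_names) if ":" in n]
    else:
        if term not in fit.spec.factors:
            raise ParameterError(f"unknown term {term!r}; factors: {fit.spec.factors}")
        idx = [
            i
            for i, n in enumerate(fit.coef_names)
            if n.startswith(f"{term}[") and ":" not in n
        ]
    if not idx:
        raise ParameterError(f"term {term!r} has no coefficients")
    return idx


def wald_test_term(fit: GlmmFit, term: str) -> TermTest:
    """Wald chi-square test of a whole factor (or interaction) term."""
    idx = _term_columns(fit, term)
    b = fit.beta[idx]
    V = fit.vcov_beta[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return TermTest(term=term, stat=stat, df=df, p=float(stats.chi2.sf(stat, df)), kind="wald")


def lr_test_term(data: pd.DataFrame, spec: GlmmSpec, term: str) -> TermTest:
    """Likelihood-ratio test of a term by refitting without it.

    Main effects cannot be dropped while their interaction is present.
    """
    if ":" in term:
        reduced = GlmmSpec(
            response=spec.response,
            factors=spec.factors,
            interaction=False,
            random=spec.random,
            family=spec.family,
        )
    else:
        if spec.interaction:
            raise ParameterError(
                "cannot drop a main effect while its interaction is in the model"
            )
        remaining = tuple(f for f in spec.factors if f != term)
        if len(remaining) == len(spec.factors):
            raise ParameterError(f"unknown term {term!r}")
        reduced = GlmmSpec(
            response=spec.response,
            factors=remaining,
            interaction=False,
            random=spec.random,
            family=spec.family,
        )
    full = fit_glmm(data, spec)
    red = fit_glmm(data, reduced)
    df = len(full.beta) - len(red.beta)
    stat = max(2.0 * (full.loglik - red.loglik), 0.0)
    return TermTest(term=term, stat=float(stat), df=df, p=float(stats.chi2.sf(stat, df)), kind="lr")


# ---------------------------------------------------------------------------
# Marginal means and Tukey contrasts


@dataclass
class MarginalMeans:
    """Link-scale marginal means with their covariance.

    ``labels`` pairs each row with its (level, stratum) where stratum is None
    for unconditioned means.
    """

    factor: str
    by: str | None
    labels: list[tuple[str, str | None]]
    estimates: np.ndarray
    cov: np.ndarray
    family: str

    def table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        df = pd.DataFrame(
            {
                self.factor: [l for l, _ in self.labels],
                "emmean": self.estimates,
                "se": se,
            }
        )
        if self.by is not None:
            df.insert(0, self.by, [s for _, s in self.labels])
        return df


def marginal_means(fit: GlmmFit, factor: str, by: str | None = None) -> MarginalMeans:
    """Equal-weight marginal means of a factor on the link (log) scale.

    Averages model predictions over the levels of the other fixed factor; with
    ``by`` the means are computed within each level of the stratifying factor
    (the reference grid cells). Requires every averaged-over design cell to be
    observed when the model carries an interaction.
    """
    if factor not in fit.spec.factors:
        raise ParameterError(f"factor {factor!r} not in the fixed specification")
    if by is not None and (by not in fit.spec.factors or by == factor):
        raise ParameterError(f"invalid conditioning factor {by!r}")
    factors = list(fit.spec.factors)
    grid = [dict(zip(factors, combo)) for combo in itertools.product(*(fit.levels[f] for f in factors))]
    if fit.spec.interaction and fit._observed_cells:
        for cell in grid:
            key = tuple(cell[f] for f in factors)
            if key not in fit._observed_cells:
                raise EstimabilityError(
                    f"design cell {key} has no observations; its marginal mean "
                    "is not estimable under the interaction model"
                )
    grid_df = pd.DataFrame(grid)
    X_grid, _, _ = build_fixed_design(grid_df, factors, fit.spec.interaction, levels=fit.levels)

    groups: list[tuple[str, str | None, np.ndarray]] = []
    if by is None:
        for lvl in fit.levels[factor]:
            mask = (grid_df[factor] == lvl).to_numpy()
            groups.append((lvl, None, mask))
    else:
        for stratum in fit.levels[by]:
            for lvl in fit.levels[factor]:
                mask = ((grid_df[factor] == lvl) & (grid_df[by] == stratum)).to_numpy()
                groups.append((lvl, stratum, mask))
    L = np.vstack([X_grid[mask].mean(axis=0) for _, _, mask in groups])
    est = L @ fit.beta
    cov = L @ fit.vcov_beta @ L.T
    return MarginalMeans(
        factor=factor,
        by=by,
        labels=[(l, s) for l, s, _ in groups],
        estimates=est,
        cov=0.5 * (cov + cov.T),
        family=fit.spec.family,
    )


def max_abs_tail_prob(
    t: float, corr: np.ndarray, n_points: int = 2**16, seed: int = 20260923
) -> float:
    """P(max_i |Z_i| >= t) for Z ~ N(0, corr), by scrambled-Sobol QMC.

    The correlation matrix may be singular (pairwise contrasts of k means span
    a (k-1)-dimensional space); integration runs in the reduced eigenspace.
    Fixed internal seed keeps reported p-values deterministic; accuracy is
    ~1e-4 at the default sample size.
    """
    m = corr.shape[0]
    if m == 1:
        return float(2.0 * stats.norm.sf(t))
    w, V = np.linalg.eigh(0.5 * (corr + corr.T))
    keep = w > 1e-10
    A = V[:, keep] * np.sqrt(w[keep])
    r = A.shape[1]
    sob = qmc.Sobol(d=r, scramble=True, seed=seed)
    u = sob.random(n_points)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    Zs = special.ndtri(u) @ A.T
    return float(np.mean(np.max(np.abs(Zs), axis=1) >= t))


@dataclass(frozen=True)
class ContrastResult:
    term: str
    stratum: str | None
    level_a: str
    level_b: str
    estimate: float  # difference of link-scale means = log ratio (gamma)
    se: float
    stat: float
    p_raw: float
    p_adj: float


def tukey_contrasts(means: MarginalMeans) -> list[ContrastResult]:
    """All pairwise contrasts of marginal means with single-step adjustment.

    ``estimate`` is mean(A) - mean(B) on the link scale (a log half-life
    ratio under the gamma family). The family of simultaneous inference is
    all pairs within a stratum when the means are conditioned (``by``),
    otherwise all pairs. The adjusted p-value is the tail probability of the
    family's maximum absolute standardized contrast under the estimated
    contrast correlation, so ``p_adj >= p_raw`` always, with equality for a
    family of one pair.
    """
    results: list[ContrastResult] = []
    strata = sorted({s for _, s in means.labels}, key=lambda s: (s is not None, s))
    for stratum in strata:
        idx = [i for i, (_, s) in enumerate(means.labels) if s == stratum]
        if len(idx) < 2:
            raise ParameterError("need >= 2 levels for pairwise contrasts")
        pairs = list(itertools.combinations(idx, 2))
        C = np.zeros((len(pairs), len(means.estimates)))
        for r, (i, j) in enumerate(pairs):
            C[r, i] = 1.0
            C[r, j] = -1.0
        est = C @ means.estimates
        cov = C @ means.cov @ C.T
        se = np.sqrt(np.diag(cov))
        if np.any(se <= 0):
            raise ParameterError("degenerate contrast covariance (zero standard error)")
        corr = cov / np.outer(se, se)
        z = est / se
        for r, (i, j) in enumerate(pairs):
            p_raw = float(2.0 * stats.norm.sf(abs(z[r])))
            p_adj = max_abs_tail_prob(abs(z[r]), corr)
            p_adj = min(1.0, max(p_adj, p_raw))
            results.append(
                ContrastResult(
                    term=means.factor,
                    stratum=stratum,
                    level_a=means.labels[i][0],
                    level_b=means.labels[j][0],
                    estimate=float(est[r]),
                    se=float(se[r]),
                    stat=float(z[r]),
                    p_raw=p_raw,
                    p_adj=float(p_adj),
                )
            )
    return results


def contrasts_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Canonical contrast table
    (``term,level_a,level_b,log_ratio,se,stat,p_raw,p_adj``)."""
    df = pd.DataFrame(
        {
            "term": [
                r.term if r.stratum is None else f"{r.term}|{r.stratum}" for r in results
            ],
            "level_a": [r.level_a for r in results],
            "level_b": [r.level_b for r in results],
            "log_ratio": [r.estimate for r in results],
            "se": [r.se for r in results],
            "stat": [r.stat for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )
    return df


# ---------------------------------------------------------------------------
# Simulation-based residual diagnostics


@dataclass
class ResidualDiagnostic:
    """Rank-based scaled residuals (uniform under a correct model), the KS
    uniformity test, and the dispersion ratio of observed vs simulated
    Pearson statistics."""

    residuals: np.ndarray
    ks_stat: float
    ks_p: float
    dispersion_ratio: float
    n_sim: int

    def summary_dict(self) -> dict:
        return {
            "ks_stat": float(self.ks_stat),
            "ks_p": float(self.ks_p),
            "dispersion_ratio": float(self.dispersion_ratio),
            "n_sim": int(self.n_sim),
        }


def simulate_response(
    fit: GlmmFit, rng: np.random.Generator, conditional: bool = False
) -> np.ndarray:
    """Draw one response vector from the fitted model.

    Unconditional draws (default) re-draw the random effects from their
    estimated distributions; conditional draws hold the fitted random-effect
    modes fixed and re-draw only the observation noise.
    """
    fam = _FAMILIES[fit.spec.family]
    eta = fit._X @ fit.beta
    if fit._Z.shape[1]:
        if conditional:
            eta = eta + fit._Z @ fit._u
        else:
            sds = []
            for term, size in zip(fit._z_terms, fit._z_sizes):
                var = fit.var_block if term == "block" else fit.var_rep
                sds.append(np.full(size, math.sqrt(var)))
            u = rng.normal(0.0, np.concatenate(sds))
            eta = eta + fit._Z @ u
    theta = math.log(fit.dispersion)
    return fam.simulate(eta, theta, rng)


def simulate_residual_check(
    fit: GlmmFit,
    y: np.ndarray | None = None,
    n_sim: int = 250,
    seed: int = 0,
    conditional: bool = True,
) -> ResidualDiagnostic:
    """Simulation-based residual diagnostic for a fitted model.

    Simulates ``n_sim`` response vectors from the fit; each observation's
    scaled residual is its (tie-randomized) rank position among its own
    simulated values, uniform on [0, 1] under a correctly specified model.
    Uniformity is tested by Kolmogorov-Smirnov; the dispersion ratio compares
    the observed Pearson statistic to the mean simulated one.

    By default the reference simulations condition on the fitted random
    effects (only observation noise is re-drawn): this makes the scaled
    residuals independent under a correct model, which the KS test requires.
    ``conditional=False`` re-draws the random effects instead, testing the
    marginal model at the cost of within-group residual dependence (the
    uniformity p-value is then anti-conservative).
    """
    if n_sim < 20:
        raise ParameterError("n_sim < 20 gives unstable residual ranks; refuse")
    fam = _FAMILIES[fit.spec.family]
    if y is None:
        y = fit._y
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    sims = np.vstack(
        [simulate_response(fit, rng, conditional=conditional) for _ in range(n_sim)]
    )
    below = (sims < y).sum(axis=0)
    ties = (sims == y).sum(axis=0)
    jitter = rng.uniform(size=len(y))
    residuals = (below + jitter * (ties + 1)) / (n_sim + 1)
    ks_stat, ks_p = stats.kstest(residuals, "uniform")
    eta_ref = fit._X @ fit.beta
    if conditional and fit._Z.shape[1]:
        eta_ref = eta_ref + fit._Z @ fit._u
    theta = math.log(fit.dispersion)
    pearson_obs = fam.pearson(y, eta_ref, theta)
    pearson_sim = np.array([fam.pearson(s, eta_ref, theta) for s in sims])
    return ResidualDiagnostic(
        residuals=residuals,
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
        dispersion_ratio=float(pearson_obs / np.mean(pearson_sim)),
        n_sim=n_sim,
    )
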