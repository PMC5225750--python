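"""REML estimation of variance components for clonally replicated field trials.

The engine maximizes the residual likelihood of a Gaussian linear mixed model

    y = X b + sum_j Z_j u_j,   u_j ~ N(0, theta_j G_j),

whose marginal covariance is linear in the parameters,
``V(theta) = sum_j theta_j M_j`` with ``M_j = Z_j G_j Z_j'`` (diagonal
indicator blocks for residual strata). Updates are average-information
Newton steps with step-halving and an expectation-maximization fallback;
components are kept above a small positive floor by projection.

Three trial-analysis layers sit on top of the engine:

* ``single_trial_analysis`` — replicate (fixed) + bed-within-replicate +
  subplot + additive (pedigree or genomic relationship) + family +
  clone-within-family + residual, with narrow-sense, broad-sense and
  clonal-mean ("ad hoc") heritabilities and delta-method standard errors.
* ``combined_trial_analysis`` — the paired-trial genotype-by-environment
  model with trial-specific bed/plot/residual variances and a trial-specific
  additive deviation; returns the Type-B additive correlation
  ``r_B = sigma_a^2 / (sigma_a^2 + sigma_ta^2)``.
* ``adjusted_means`` — genotype treated as fixed with design strata random;
  generalized-least-squares genotype means feed the whole-genome regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .relationships import RelationshipMatrix

__all__ = [
    "TrialData",
    "VarComponent",
    "REMLResult",
    "GeneticParams",
    "CombinedParams",
    "AdjustedMeans",
    "fit_reml",
    "heritability_stats",
    "single_trial_analysis",
    "combined_trial_analysis",
    "adjusted_means",
    "wald_covariate",
    "harmonic_mean_replicates",
]

# convergence thresholds for the REML iteration
LOGLIK_RTOL = 1e-8
PARAM_RTOL = 1e-6
VAR_FLOOR_FRAC = 1e-8   # lower bound on components, as a fraction of var(y)
MAX_ITER = 200


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, msg: str, trace: list[dict]):
        super().__init__(msg)
        self.trace = trace


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class TrialData:
    """Long-format plot-level phenotype records with design strata.

    ``df`` must contain columns ``trial, rep, bed, plot, genotype, family``
    plus one column per trait; ``weight`` (transplant-weight covariate) is
    optional and may be absent for advanced-selection trials. Beds are nested
    in replicates and subplots in beds; nesting labels need not be globally
    unique (they are combined with their parents internally).
    """

    df: pd.DataFrame

    REQUIRED = ("trial", "rep", "bed", "plot", "genotype", "family")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"TrialData missing columns: {missing}")
        fam_per_geno = self.df.groupby("genotype")["family"].nunique()
        if (fam_per_geno > 1).any():
            bad = fam_per_geno[fam_per_geno > 1].index[0]
            raise ValueError(f"genotype {bad!r} maps to more than one family")

    @property
    def trials(self) -> list[str]:
        return sorted(self.df["trial"].astype(str).unique())

    def trait_columns(self) -> list[str]:
        skip = set(self.REQUIRED) | {"weight"}
        return [c for c in self.df.columns if c not in skip]

    def subset_trial(self, trial: str) -> "TrialData":
        sub = self.df[self.df["trial"].astype(str) == str(trial)]
        return TrialData(sub.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialData":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class VarComponent:
    """One random term of the linear covariance structure."""

    name: str
    Z: np.ndarray                 # n x q incidence
    G: np.ndarray | None = None   # q x q covariance (None = identity)
    levels: list[str] | None = None

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def M(self) -> np.ndarray:
        if self.G is None:
            return self.Z @ self.Z.T
        return self.Z @ self.G @ self.Z.T


@dataclass
class REMLResult:
    """Converged REML fit: components, fixed-effect BLUEs, random-effect BLUPs."""

    varcomps: dict[str, float]
    varcomp_se: dict[str, float]
    varcomp_cov: pd.DataFrame
    boundary: dict[str, bool]
    loglik: float
    converged: bool
    n_iter: int
    beta: pd.Series
    beta_cov: pd.DataFrame
    blups: dict[str, pd.Series]
    trace: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def blue(self, term: str) -> float:
        return float(self.beta[term])


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def dummies(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Full indicator matrix for a factor, levels in sorted order."""
    s = labels.astype(str)
    levels = sorted(s.unique())
    index = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(s), len(levels)))
    Z[np.arange(len(s)), [index[v] for v in s]] = 1.0
    return Z, levels


def _drop_rank_deficient(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns (QR with pivoting)."""
    if X.shape[1] == 0:
        return X, names, []
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    return X[:, keep], [names[j] for j in keep], dropped


# ---------------------------------------------------------------------------
# core engine
# ---------------------------------------------------------------------------

def _loglik(theta: np.ndarray, Ms: list[np.ndarray], X: np.ndarray,
            y: np.ndarray) -> float:
    """Residual log-likelihood in the basis-invariant form (the
    ``log|X'X|`` normalization makes it independent of how the fixed
    effects are parameterized)."""
    n = len(y)
    V = np.zeros((n, n))
    for t, M in zip(theta, Ms):
        V += t * M
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ViX = linalg.cho_solve(cho, X, check_finite=False)
    Viy = linalg.cho_solve(cho, y, check_finite=False)
    W = X.T @ ViX
    try:
        Wc = linalg.cho_factor(W, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet_w = 2.0 * np.sum(np.log(np.diag(Wc[0])))
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    XtViy = X.T @ Viy
    yPy = float(y @ Viy - XtViy @ linalg.cho_solve(Wc, XtViy, check_finite=False))
    return -0.5 * (logdet_v + logdet_w - logdet_xx + yPy)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    components: list[VarComponent],
    fixed_names: list[str] | None = None,
    theta0: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    loglik_rtol: float = LOGLIK_RTOL,
    param_rtol: float = PARAM_RTOL,
) -> REMLResult:
    """Average-information REML with EM fallback.

    The last component is conventionally the residual but nothing in the
    algorithm requires it; ``V(theta)`` only needs to be positive definite at
    the floor, which holds whenever one component is full rank (e.g. the
    residual identity).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(X.shape[1])]
    X, fixed_names, dropped_fixed = _drop_rank_deficient(X, list(fixed_names))
    if X.shape[1] == 0:
        raise ValueError("no estimable fixed effects")

    Ms = [c.M() for c in components]
    names = [c.name for c in components]
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("response has zero variance")
    floor = VAR_FLOOR_FRAC * vary
    k = len(components)
    theta = (np.full(k, vary / k) if theta0 is None
             else np.maximum(np.asarray(theta0, dtype=float), floor))

    ll = _loglik(theta, Ms, X, y)
    trace: list[dict] = [{"iter": 0, "loglik": ll, "theta": theta.copy()}]
    converged = False
    AI = np.eye(k)
    it = 0
    for it in range(1, max_iter + 1):
        V = np.zeros((n, n))
        for t, M in zip(theta, Ms):
            V += t * M
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
        Vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)
        ViX = Vinv @ X
        W = X.T @ ViX
        C = np.linalg.inv(W)
        P = Vinv - ViX @ C @ ViX.T
        Py = P @ y

        w_vecs = [M @ Py for M in Ms]              # M_j P y
        quad = np.array([float(Py @ w) for w in w_vecs])   # y' P M_j P y
        tr_PM = np.array([float(np.sum(P * M.T)) for M in Ms])
        score = 0.5 * (quad - tr_PM)
        AI = 0.5 * np.array([[float(w_i @ P @ w_j) for w_j in w_vecs]
                             for w_i in w_vecs])

        # free set: components pinned at the floor with negative score stay put
        free = ~((theta <= floor * (1 + 1e-12)) & (score < 0))
        delta = np.zeros(k)
        if free.any():
            Af = AI[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(
                    Af + 1e-12 * np.eye(free.sum()), score[free])
            except np.linalg.LinAlgError:
                delta[free] = score[free] / np.maximum(np.diag(Af), 1e-12)

        new_ll = -np.inf
        new_theta = theta
        step = 1.0
        for _ in range(20):
            cand = np.maximum(theta + step * delta, floor)
            cand_ll = _loglik(cand, Ms, X, y)
            if cand_ll >= ll - 1e-12:
                new_theta, new_ll = cand, cand_ll
                break
            step *= 0.5
        else:
            # EM fallback: guaranteed ascent direction for this structure
            qs = np.array([c.q for c in components], dtype=float)
            cand = np.maximum(theta + (theta ** 2 / qs) * (quad - tr_PM), floor)
            cand_ll = _loglik(cand, Ms, X, y)
            if cand_ll >= ll - 1e-10:
                new_theta, new_ll = cand, cand_ll
            else:
                new_theta, new_ll = theta, ll   # stuck; report non-convergence

        rel_ll = abs(new_ll - ll) / max(1.0, abs(new_ll))
        rel_th = np.max(np.abs(new_theta - theta) / np.maximum(new_theta, floor))
        theta, ll = new_theta, new_ll
        trace.append({"iter": it, "loglik": ll, "theta": theta.copy()})
        if rel_ll < loglik_rtol and rel_th < param_rtol:
            converged = True
            break

    if not converged and it >= max_iter:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", trace)

    # final quantities at the converged estimate
    V = np.zeros((n, n))
    for t, M in zip(theta, Ms):
        V += t * M
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    Vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)
    ViX = Vinv @ X
    C = np.linalg.inv(X.T @ ViX)
    P = Vinv - ViX @ C @ ViX.T
    Py = P @ y
    beta = C @ (ViX.T @ y)

    w_vecs = [M @ Py for M in Ms]
    AI = 0.5 * np.array([[float(w_i @ P @ w_j) for w_j in w_vecs]
                         for w_i in w_vecs])
    boundary = {nm: bool(t <= floor * (1 + 1e-9)) for nm, t in zip(names, theta)}
    free_idx = [j for j in range(k) if not boundary[names[j]]]
    cov = np.zeros((k, k))
    if free_idx:
        sub = AI[np.ix_(free_idx, free_idx)]
        try:
            cov_sub = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            cov_sub = np.linalg.pinv(sub)
        for a, ja in enumerate(free_idx):
            for b, jb in enumerate(free_idx):
                cov[ja, jb] = cov_sub[a, b]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    blups: dict[str, pd.Series] = {}
    for c, t in zip(components, theta):
        GZt = c.Z.T if c.G is None else c.G @ c.Z.T
        u = t * (GZt @ Py)
        idx = c.levels if c.levels is not None else list(range(c.q))
        blups[c.name] = pd.Series(u, index=idx)

    reported = {nm: (0.0 if boundary[nm] else float(t))
                for nm, t in zip(names, theta)}
    return REMLResult(
        varcomps={nm: float(t) for nm, t in zip(names, theta)},
        varcomp_se={nm: float(s) for nm, s in zip(names, se)},
        varcomp_cov=pd.DataFrame(cov, index=names, columns=names),
        boundary=boundary,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        beta=pd.Series(beta, index=fixed_names),
        beta_cov=pd.DataFrame(C, index=fixed_names, columns=fixed_names),
        blups=blups,
        trace=trace,
        meta={"dropped_fixed": dropped_fixed, "reported_components": reported,
              "var_floor": floor},
    )


# ---------------------------------------------------------------------------
# trial-level fixed/random design construction
# ---------------------------------------------------------------------------

def _nested_label(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.Series:
    out = df[cols[0]].astype(str)
    for c in cols[1:]:
        out = out + ":" + df[c].astype(str)
    return out


def _fixed_design(df: pd.DataFrame, covariate: str | None,
                  extra_factors: list[tuple[str, pd.Series]] | None = None,
                  ) -> tuple[np.ndarray, list[str]]:
    """Intercept + (centered covariate) + reference-coded factor dummies."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if covariate is not None:
        w = df[covariate].to_numpy(dtype=float)
        cols.append(w - w.mean())
        names.append(covariate)
    for fname, series in (extra_factors or []):
        Z, levels = dummies(series)
        for j in range(1, len(levels)):      # drop first level
            cols.append(Z[:, j])
            names.append(f"{fname}[{levels[j]}]")
    return np.column_stack(cols), names


def harmonic_mean_replicates(df: pd.DataFrame) -> float:
    """Harmonic mean of the per-genotype replicate (plot) counts."""
    counts = df.groupby("genotype").size().to_numpy(dtype=float)
    return float(len(counts) / np.sum(1.0 / counts))


def wald_covariate(fit: REMLResult, term: str, alpha: float = 0.05) -> dict:
    """Wald test of a fixed effect: ``(beta / se)^2`` against chi-square(1).

    The covariate is kept when ``p <= alpha``.
    """
    if term not in fit.beta.index:
        raise KeyError(f"fixed term {term!r} not in the fit")
    b = float(fit.beta[term])
    se = float(np.sqrt(fit.beta_cov.loc[term, term]))
    if se == 0.0:
        raise ZeroDivisionError(f"zero standard error for {term!r}")
    stat = (b / se) ** 2
    p = float(stats.chi2.sf(stat, df=1))
    return {"term": term, "beta": b, "se": se, "wald": stat, "p": p,
            "keep": p <= alpha}


# ---------------------------------------------------------------------------
# single-trial genetic parameters
# ---------------------------------------------------------------------------

@dataclass
class GeneticParams:
    """Variance components plus heritabilities for one trial and trait."""

    trial: str
    trait: str
    fit: REMLResult
    h2: float
    h2_se: float
    H2: float
    H2_se: float
    hc2: float
    hc2_se: float
    r_harmonic: float
    hc2_mode: str
    covariate_wald: dict | None

    @property
    def varcomps(self) -> dict[str, float]:
        return self.fit.varcomps

    def to_dict(self) -> dict:
        return {
            "trial": self.trial, "trait": self.trait,
            "varcomps": self.fit.varcomps, "varcomp_se": self.fit.varcomp_se,
            "h2": self.h2, "h2_se": self.h2_se,
            "H2": self.H2, "H2_se": self.H2_se,
            "hc2": self.hc2, "hc2_se": self.hc2_se,
            "r_harmonic": self.r_harmonic, "hc2_mode": self.hc2_mode,
            "covariate_wald": self.covariate_wald,
            "loglik": self.fit.loglik,
        }


def _delta_se(grad: np.ndarray, cov: np.ndarray) -> float:
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def heritability_stats(components: dict[str, float], r: float,
                       hc2_mode: str = "literal") -> dict[str, float]:
    """h2, H2 and the ad-hoc clonal-mean hc2 from six variance components.

    ``components`` needs keys bed, plot, additive, family, clone, residual.
    ``sigma_t^2`` is their sum; ``h2 = additive / sigma_t^2``;
    ``H2 = (additive + family + clone) / sigma_t^2``. For hc2 the denominator
    divides the residual by the harmonic-mean replicate number ``r``
    (``literal`` mode) or divides bed, plot and residual all by ``r``
    (``clone_mean`` mode).
    """
    order = ("bed", "plot", "additive", "family", "clone", "residual")
    th = np.array([components[k] for k in order], dtype=float)
    st = th.sum()
    if st <= 0:
        raise ZeroDivisionError("total phenotypic variance is zero")
    sa = th[2]
    sg = th[2] + th[3] + th[4]
    if hc2_mode == "literal":
        w = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0 / r])
    elif hc2_mode == "clone_mean":
        w = np.array([1.0 / r, 1.0 / r, 1.0, 1.0, 1.0, 1.0 / r])
    else:
        raise ValueError("hc2_mode must be 'literal' or 'clone_mean'")
    return {"h2": float(sa / st), "H2": float(sg / st),
            "hc2": float(sa / (w @ th)), "sigma_t2": float(st)}


def _single_trial_components(df: pd.DataFrame, A_sub: RelationshipMatrix | None,
                             ) -> list[VarComponent]:
    comps = []
    Zb, lb = dummies(_nested_label(df, ("rep", "bed")))
    comps.append(VarComponent("bed", Zb, levels=lb))
    Zp, lp = dummies(_nested_label(df, ("rep", "bed", "plot")))
    comps.append(VarComponent("plot", Zp, levels=lp))
    Zg, lg = dummies(df["genotype"])
    if A_sub is not None:
        G = A_sub.subset(lg).values
        comps.append(VarComponent("additive", Zg, G=G, levels=lg))
    else:
        comps.append(VarComponent("additive", Zg, levels=lg))
    Zf, lf = dummies(df["family"])
    comps.append(VarComponent("family", Zf, levels=lf))
    comps.append(VarComponent("clone", Zg, levels=lg))
    comps.append(VarComponent("residual", np.eye(len(df)), levels=None))
    return comps


def single_trial_analysis(
    data: TrialData,
    trait: str,
    A: RelationshipMatrix | None = None,
    covariate: str | None = "weight",
    hc2_mode: str = "literal",
    wald_alpha: float = 0.05,
) -> GeneticParams:
    """Fit the single-trial clonal model and derive heritabilities.

    Terms: fixed intercept + replicate (+ transplant-weight covariate when it
    passes a 5% Wald test); random bed-within-replicate, subplot, additive
    genotype (covariance ``A``), family, clone-within-family, residual.

    Heritabilities with ``sigma_t^2`` the sum of all six components:

    * narrow-sense ``h2 = sigma_a^2 / sigma_t^2``
    * broad-sense ``H2 = (sigma_a^2 + sigma_f^2 + sigma_c^2) / sigma_t^2``
    * ad-hoc clonal-mean ``hc2 = sigma_a^2 / sigma_cbar^2``, where in the
      default ``literal`` mode only the residual is divided by the harmonic
      mean replicate number r, and in ``clone_mean`` mode bed, plot and
      residual are all divided by r.

    Standard errors of all three ratios are by the delta method from the
    average-information covariance of the components.
    """
    if hc2_mode not in ("literal", "clone_mean"):
        raise ValueError("hc2_mode must be 'literal' or 'clone_mean'")
    df = data.df
    trials = df["trial"].astype(str).unique()
    if len(trials) != 1:
        raise ValueError("single_trial_analysis expects exactly one trial")
    y = df[trait].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in trait {trait!r}")
    comps = _single_trial_components(df, A)

    use_cov = covariate if (covariate is not None and covariate in df.columns
                            and df[covariate].notna().all()) else None
    X, names = _fixed_design(df, use_cov, [("rep", df["rep"])])
    fit = fit_reml(y, X, comps, fixed_names=names)
    wald = None
    if use_cov is not None:
        wald = wald_covariate(fit, use_cov, alpha=wald_alpha)
        if not wald["keep"]:
            X, names = _fixed_design(df, None, [("rep", df["rep"])])
            fit = fit_reml(y, X, comps, fixed_names=names,
                           theta0=np.array([fit.varcomps[c.name] for c in comps]))

    order = ["bed", "plot", "additive", "family", "clone", "residual"]
    th = np.array([fit.varcomps[nm] for nm in order])
    cov = fit.varcomp_cov.loc[order, order].to_numpy()
    sa = th[2]
    st = th.sum()
    r = harmonic_mean_replicates(df)
    stats_ = heritability_stats(dict(zip(order, th)), r, hc2_mode)

    g_h2 = np.array([-sa, -sa, st - sa, -sa, -sa, -sa]) / st ** 2
    sg = th[2] + th[3] + th[4]
    g_H2 = np.array([-sg, -sg, st - sg, -sg, st - sg, -sg]) / st ** 2
    denom_w = (np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0 / r])
               if hc2_mode == "literal"
               else np.array([1.0 / r, 1.0 / r, 1.0, 1.0, 1.0, 1.0 / r]))
    scbar = float(denom_w @ th)
    g_hc2 = (np.eye(6)[2] * scbar - sa * denom_w) / scbar ** 2

    return GeneticParams(
        trial=str(trials[0]), trait=trait, fit=fit,
        h2=stats_["h2"], h2_se=_delta_se(g_h2, cov),
        H2=stats_["H2"], H2_se=_delta_se(g_H2, cov),
        hc2=stats_["hc2"], hc2_se=_delta_se(g_hc2, cov),
        r_harmonic=r, hc2_mode=hc2_mode, covariate_wald=wald,
    )


# ---------------------------------------------------------------------------
# combined (paired-trial) analysis and Type-B correlation
# ---------------------------------------------------------------------------

@dataclass
class CombinedParams:
    trials: tuple[str, str]
    trait: str
    fit: REMLResult
    type_b: float
    type_b_se: float
    connected: bool

    def to_dict(self) -> dict:
        return {"trials": list(self.trials), "trait": self.trait,
                "type_b": self.type_b, "type_b_se": self.type_b_se,
                "connected": self.connected, "varcomps": self.fit.varcomps}


def combined_trial_analysis(
    data: TrialData,
    trait: str,
    A: RelationshipMatrix | None = None,
    covariate: str | None = "weight",
    include_nonadditive_gxe: bool = True,
) -> CombinedParams:
    """Paired-trial model with trial-heterogeneous design/residual variances.

    The additive-by-trial deviation carries the same relationship structure
    as the main additive term, block-diagonal within trial (uncorrelated
    across trials); this keeps it identified against the identity
    clone-by-trial term. Returns the Type-B additive correlation
    ``r_B = sigma_a^2 / (sigma_a^2 + sigma_ta^2)`` with a delta-method SE.
    """
    df = data.df.copy()
    trial_ids = sorted(df["trial"].astype(str).unique())
    if len(trial_ids) != 2:
        raise ValueError("combined_trial_analysis expects exactly two trials")
    y = df[trait].to_numpy(dtype=float)
    trial_s = df["trial"].astype(str)

    shared = (set(df.loc[trial_s == trial_ids[0], "genotype"].astype(str))
              & set(df.loc[trial_s == trial_ids[1], "genotype"].astype(str)))
    connected = len(shared) > 0 or A is not None
    if not connected:
        import warnings
        warnings.warn("trials share no genotypes and no pedigree links; the "
                      "Type-B estimate is unreliable", stacklevel=2)

    comps: list[VarComponent] = []
    for t in trial_ids:
        mask = (trial_s == t).to_numpy()
        sub = df[mask]
        Zb, lb = dummies(_nested_label(sub, ("rep", "bed")))
        Zb_full = np.zeros((len(df), Zb.shape[1]))
        Zb_full[mask] = Zb
        comps.append(VarComponent(f"bed[{t}]", Zb_full, levels=lb))
        Zp, lp = dummies(_nested_label(sub, ("rep", "bed", "plot")))
        Zp_full = np.zeros((len(df), Zp.shape[1]))
        Zp_full[mask] = Zp
        comps.append(VarComponent(f"plot[{t}]", Zp_full, levels=lp))

    Zg, lg = dummies(df["genotype"])
    G_add = A.subset(lg).values if A is not None else None
    comps.append(VarComponent("additive", Zg, G=G_add, levels=lg))

    # genotype-by-trial cells, additive structure within trial
    cell = df["genotype"].astype(str) + "@" + trial_s
    Zta, lta = dummies(cell)
    q = len(lta)
    Gta = np.zeros((q, q))
    cell_geno = [c.split("@")[0] for c in lta]
    cell_trial = [c.split("@")[1] for c in lta]
    if A is not None:
        A_lookup = A.subset(sorted(set(cell_geno)))
        gi = {g: i for i, g in enumerate(A_lookup.labels)}
        for a in range(q):
            for b in range(q):
                if cell_trial[a] == cell_trial[b]:
                    Gta[a, b] = A_lookup.values[gi[cell_geno[a]], gi[cell_geno[b]]]
    else:
        np.fill_diagonal(Gta, 1.0)
    comps.append(VarComponent("additive_x_trial", Zta, G=Gta, levels=lta))

    Zf, lf = dummies(df["family"])
    comps.append(VarComponent("family", Zf, levels=lf))
    comps.append(VarComponent("clone", Zg, levels=lg))
    if include_nonadditive_gxe:
        fcell = df["family"].astype(str) + "@" + trial_s
        Ztf, ltf = dummies(fcell)
        comps.append(VarComponent("family_x_trial", Ztf, levels=ltf))
        comps.append(VarComponent("clone_x_trial", Zta, levels=lta))
    for t in trial_ids:
        mask = (trial_s == t).to_numpy().astype(float)
        comps.append(VarComponent(f"residual[{t}]", np.diag(mask),
                                  levels=None))

    has_cov = (covariate is not None and covariate in df.columns
               and df[covariate].notna().all())
    extra = [("trial", trial_s), ("rep", trial_s + ":" + df["rep"].astype(str))]
    X, names = _fixed_design(df, covariate if has_cov else None, extra)
    fit = fit_reml(y, X, comps, fixed_names=names)

    sa = fit.varcomps["additive"]
    sta = fit.varcomps["additive_x_trial"]
    if fit.boundary["additive_x_trial"]:
        sta = 0.0
    denom = sa + sta
    rb = sa / denom if denom > 0 else np.nan
    idx = ["additive", "additive_x_trial"]
    cov = fit.varcomp_cov.loc[idx, idx].to_numpy()
    grad = np.array([sta, -sa]) / denom ** 2 if denom > 0 else np.zeros(2)
    return CombinedParams(trials=(trial_ids[0], trial_ids[1]), trait=trait,
                          fit=fit, type_b=float(rb),
                          type_b_se=_delta_se(grad, cov), connected=connected)


# ---------------------------------------------------------------------------
# adjusted genotype means (genotype fixed, design random)
# ---------------------------------------------------------------------------

@dataclass
class AdjustedMeans:
    trial: str
    trait: str
    values: pd.Series            # genotype -> adjusted value
    fit: REMLResult
    inestimable: list[str]

    def aligned(self, genotypes: list[str]) -> np.ndarray:
        return self.values.loc[[str(g) for g in genotypes]].to_numpy()


def adjusted_means(
    data: TrialData,
    trait: str,
    covariate: str | None = None,
    replicate_random: bool = True,
) -> AdjustedMeans:
    """Generalized-least-squares genotype means with design strata random.

    The genotype (total clonal value) is fixed; replicate, bed-within-
    replicate and subplot are random by default (``replicate_random=False``
    moves replicate to the fixed part). The returned value per genotype is
    its GLS mean at the average covariate level.
    """
    df = data.df
    trials = df["trial"].astype(str).unique()
    if len(trials) != 1:
        raise ValueError("adjusted_means expects one trial")
    y = df[trait].to_numpy(dtype=float)

    Zg, lg = dummies(df["genotype"])
    cols = [Zg]
    names = [f"g[{g}]" for g in lg]
    use_cov = covariate if (covariate is not None and covariate in df.columns
                            and df[covariate].notna().all()) else None
    if use_cov is not None:
        w = df[use_cov].to_numpy(dtype=float)
        cols.append((w - w.mean())[:, None])
        names.append(use_cov)
    X = np.hstack(cols)

    comps: list[VarComponent] = []
    if replicate_random:
        Zr, lr = dummies(df["rep"])
        comps.append(VarComponent("rep", Zr, levels=lr))
    Zb, lb = dummies(_nested_label(df, ("rep", "bed")))
    comps.append(VarComponent("bed", Zb, levels=lb))
    Zp, lp = dummies(_nested_label(df, ("rep", "bed", "plot")))
    comps.append(VarComponent("plot", Zp, levels=lp))
    comps.append(VarComponent("residual", np.eye(len(df)), levels=None))

    fit = fit_reml(y, X, comps, fixed_names=names)
    inestimable = [nm[2:-1] for nm in fit.meta["dropped_fixed"]
                   if nm.startswith("g[")]
    vals = {}
    for g in lg:
        key = f"g[{g}]"
        if key in fit.beta.index:
            vals[g] = float(fit.beta[key])
    return AdjustedMeans(trial=str(trials[0]), trait=trait,
                         values=pd.Series(vals), fit=fit,
                         inestimable=inestimable)
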