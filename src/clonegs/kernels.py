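"""Relationship- and kernel-based prediction: GBLUP, PBLUP and Gaussian RKHS.

All three fit the same individual model ``y = 1 mu + Z a + e`` with
``a ~ N(0, sigma_a^2 K)``; they differ only in the kernel: the genomic
relationship matrix (GBLUP), the pedigree numerator matrix (PBLUP), or a
Gaussian kernel of marker distances (RKHS). Individuals present in the
kernel but without phenotypes are predicted jointly through their kernel
covariances with the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import MarkerMatrix
from .mixed_models import VarComponent, fit_reml
from .relationships import RelationshipMatrix, bend_psd

__all__ = ["gaussian_kernel", "fit_kernel_blup", "KernelBLUPResult"]

#: default bandwidth on the normalized mean-distance scale
DEFAULT_BANDWIDTH = 0.5


def gaussian_kernel(m: MarkerMatrix, h: float = DEFAULT_BANDWIDTH
                    ) -> RelationshipMatrix:
    """Gaussian kernel ``K_jk = exp(-h d2_jk / mean(d2))`` of dosage rows.

    ``d2`` is the squared Euclidean distance between dosage vectors and the
    normalizing constant is the mean off-diagonal ``d2``, making ``h``
    unit-free. The diagonal is exactly 1.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    if m.n_individuals < 2:
        raise ValueError("need at least two individuals to normalize distances")
    if np.isnan(m.dosages).any():
        raise ValueError("missing dosages; impute before building the kernel")
    X = m.dosages
    sq = (X * X).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.clip(d2, 0.0, None, out=d2)
    n = m.n_individuals
    mean_d2 = d2.sum() / (n * (n - 1))      # off-diagonal mean (diagonal is 0)
    if mean_d2 <= 0:
        raise ValueError("all individuals have identical dosages")
    K = np.exp(-h * d2 / mean_d2)
    np.fill_diagonal(K, 1.0)
    K = 0.5 * (K + K.T)
    return RelationshipMatrix(list(m.individual_ids), K, kind="kernel",
                              psd=True, meta={"bandwidth": h,
                                              "mean_d2": float(mean_d2)})


@dataclass
class KernelBLUPResult:
    sigma2_a: float
    sigma2_e: float
    mu: float
    gebv: pd.Series           # predictions for every kernel individual
    loglik: float | None
    converged: bool
    kernel_kind: str

    def aligned(self, ids: list[str]) -> np.ndarray:
        return self.gebv.loc[[str(i) for i in ids]].to_numpy()


def fit_kernel_blup(
    y_adj: pd.Series,
    k: RelationshipMatrix,
    fixed_variances: tuple[float, float] | None = None,
    bend_eps: float = 1e-6,
) -> KernelBLUPResult:
    """BLUP of additive values under a relationship/kernel covariance.

    ``y_adj`` is indexed by individual id and may cover a subset of the
    kernel labels; unphenotyped individuals are predicted through the
    kernel. Variances come from the REML engine unless ``fixed_variances``
    (``(sigma_a^2, sigma_e^2)``) is given, in which case the mixed-model
    equations are solved directly at those values.
    """
    obs_ids = [str(i) for i in y_adj.index]
    missing = [i for i in obs_ids if i not in set(k.labels)]
    if missing:
        raise KeyError(f"phenotyped ids not in kernel: {missing[:5]}")
    k = bend_psd(k, eps=bend_eps)
    idx = {g: i for i, g in enumerate(k.labels)}
    obs = np.array([idx[i] for i in obs_ids])
    K_oo = k.values[np.ix_(obs, obs)]
    y = y_adj.to_numpy(dtype=float)
    n = len(y)

    if fixed_variances is None:
        comps = [VarComponent("additive", np.eye(n), G=K_oo, levels=obs_ids),
                 VarComponent("residual", np.eye(n), levels=None)]
        fit = fit_reml(y, np.ones((n, 1)), comps, fixed_names=["intercept"])
        s_a, s_e = fit.varcomps["additive"], fit.varcomps["residual"]
        mu = float(fit.beta["intercept"])
        loglik: float | None = fit.loglik
        converged = fit.converged
        Vc = s_a * K_oo + s_e * np.eye(n)
        cho = linalg.cho_factor(Vc, lower=True, check_finite=False)
        resid = y - mu
        Vi_r = linalg.cho_solve(cho, resid, check_finite=False)
    else:
        s_a, s_e = fixed_variances
        Vc = s_a * K_oo + s_e * np.eye(n)
        cho = linalg.cho_factor(Vc, lower=True, check_finite=False)
        ones = np.ones(n)
        Vi1 = linalg.cho_solve(cho, ones, check_finite=False)
        Viy = linalg.cho_solve(cho, y, check_finite=False)
        mu = float(ones @ Viy / (ones @ Vi1))
        Vi_r = Viy - mu * Vi1
        loglik, converged = None, True

    a_all = s_a * (k.values[:, obs] @ Vi_r)
    return KernelBLUPResult(
        sigma2_a=float(s_a), sigma2_e=float(s_e), mu=mu,
        gebv=pd.Series(a_all, index=k.labels),
        loglik=loglik, converged=converged, kernel_kind=k.kind)
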