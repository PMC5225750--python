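"""Model evaluation: cross-validation, true validation, predictive ability,
prediction accuracy, selection efficiency, and method-comparison summaries.

Predictive ability (PA) is the Pearson correlation between adjusted
phenotypic values and GEBVs. Prediction accuracy (PACC) rescales PA by the
ad-hoc clonal-mean heritability; by default ``PACC = PA / sqrt(hc2)`` —
the scaling that makes PACC an estimate of corr(true breeding value,
predicted breeding value) — with the literal ``PA / hc2`` available behind
a flag. Selection efficiency is the fraction of the complete-information
genetic gain realized by marker-only selection of the top 5/10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MarkerMatrix
from .kernels import fit_kernel_blup, gaussian_kernel
from .relationships import RelationshipMatrix, bend_psd, grm_yang
from .wgr import WGRConfig, fit_wgr, predict_gebv

__all__ = [
    "GS_METHODS",
    "ValidationResult",
    "make_folds",
    "predictive_ability",
    "prediction_accuracy",
    "cross_validate",
    "true_validate",
    "selection_efficiency",
    "methods_summary_table",
]

#: the six genomic-selection methods averaged in summary tables
GS_METHODS = ("GBLUP", "BayesB", "BayesC", "BRR", "BL", "RKHS")
KERNEL_METHODS = ("GBLUP", "PBLUP", "RKHS")
BAYES_METHODS = ("BayesB", "BayesC", "BRR", "BL")


@dataclass
class ValidationResult:
    trait: str
    method: str
    scheme: str                   # "cv" | "true"
    train_id: str
    test_id: str
    pa: float
    pacc: float | None
    hc2: float | None
    pacc_flagged: bool = False
    folds: dict[str, int] | None = None
    seed: int | None = None
    per_fold_pa: list[float] | None = None
    predictions: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"trait": self.trait, "method": self.method,
                "scheme": self.scheme, "train": self.train_id,
                "test": self.test_id, "pa": self.pa, "pacc": self.pacc,
                "hc2": self.hc2, "pacc_flagged": self.pacc_flagged,
                "seed": self.seed, "per_fold_pa": self.per_fold_pa}


def make_folds(ids: list[str], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Random partition of ids into ``k`` folds with sizes differing by <= 1."""
    ids = [str(i) for i in ids]
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need at least {k} ids for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {}
    for pos, idx in enumerate(perm):
        assignment[ids[idx]] = pos % k
    return assignment


def predictive_ability(y_adj: np.ndarray | pd.Series,
                       gebv: np.ndarray | pd.Series) -> float:
    """Pearson correlation between adjusted phenotypes and GEBVs."""
    if isinstance(y_adj, pd.Series) and isinstance(gebv, pd.Series):
        gebv = gebv.loc[y_adj.index]
    y = np.asarray(y_adj, dtype=float)
    g = np.asarray(gebv, dtype=float)
    if len(y) != len(g):
        raise ValueError("length mismatch")
    if len(y) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(y) == 0 or np.std(g) == 0:
        raise ValueError("constant vector has no correlation")
    return float(np.corrcoef(y, g)[0, 1])


def prediction_accuracy(pa: float, hc2: float,
                        sqrt_scaling: bool = True) -> tuple[float, bool]:
    """PACC from PA and the ad-hoc heritability; returns (pacc, flagged).

    ``flagged`` marks values above 1 (possible with estimated heritability).
    """
    if hc2 <= 0:
        raise ValueError("hc2 must be > 0")
    if hc2 > 1:
        raise ValueError("hc2 must be <= 1")
    pacc = pa / np.sqrt(hc2) if sqrt_scaling else pa / hc2
    return float(pacc), bool(abs(pacc) > 1.0)


def _fit_and_predict(method: str, y_train: pd.Series, markers: MarkerMatrix,
                     predict_ids: list[str],
                     pedigree_A: RelationshipMatrix | None = None,
                     wgr_opts: dict | None = None,
                     rkhs_bandwidth: float = 0.5,
                     seed: int = 0) -> pd.Series:
    """Train one method and return GEBVs for ``predict_ids``.

    ``markers`` must contain both training and prediction individuals.
    """
    if method in KERNEL_METHODS:
        if method == "GBLUP":
            kern = bend_psd(grm_yang(markers, complete_case=False))
        elif method == "RKHS":
            kern = gaussian_kernel(markers, h=rkhs_bandwidth)
        else:
            if pedigree_A is None:
                raise ValueError("PBLUP requires a pedigree relationship matrix")
            kern = bend_psd(pedigree_A.subset(markers.individual_ids))
        res = fit_kernel_blup(y_train, kern)
        return res.gebv.loc[predict_ids]
    if method in BAYES_METHODS:
        opts = dict(wgr_opts or {})
        opts.setdefault("n_iter", 6000)
        opts.setdefault("burn_in", 1000)
        cfg = WGRConfig(model=method, seed=seed, **opts)
        m_train = markers.subset_individuals(list(y_train.index))
        fit = fit_wgr(y_train, m_train, cfg)
        m_new = markers.subset_individuals(predict_ids)
        return predict_gebv(fit, m_new)
    raise ValueError(f"unknown method {method!r}")


def cross_validate(
    y_adj: pd.Series,
    markers: MarkerMatrix,
    method: str,
    trait: str = "trait",
    trial: str = "trial",
    k: int = 5,
    seed: int = 0,
    hc2: float | None = None,
    pedigree_A: RelationshipMatrix | None = None,
    wgr_opts: dict | None = None,
    sqrt_scaling: bool = True,
) -> ValidationResult:
    """k-fold cross-validation within one trial.

    Each fold is held out in turn, GEBVs are predicted from the remaining
    folds, out-of-fold predictions are pooled, and one PA is computed over
    all individuals (per-fold correlations are also reported).
    """
    ids = [str(i) for i in y_adj.index]
    y_adj = pd.Series(y_adj.to_numpy(dtype=float), index=ids)
    folds = make_folds(ids, k=k, seed=seed)
    pooled = pd.Series(np.nan, index=ids)
    per_fold = []
    for f in range(k):
        test_ids = [i for i in ids if folds[i] == f]
        train_ids = [i for i in ids if folds[i] != f]
        try:
            preds = _fit_and_predict(method, y_adj.loc[train_ids], markers,
                                     test_ids, pedigree_A=pedigree_A,
                                     wgr_opts=wgr_opts, seed=seed + f)
        except Exception as err:
            raise RuntimeError(f"method {method} failed on fold {f}") from err
        pooled.loc[test_ids] = preds.to_numpy()
        per_fold.append(predictive_ability(y_adj.loc[test_ids], preds))
    pa = predictive_ability(y_adj, pooled)
    pacc, flagged = (None, False)
    if hc2 is not None:
        pacc, flagged = prediction_accuracy(pa, hc2, sqrt_scaling)
    return ValidationResult(trait=trait, method=method, scheme="cv",
                            train_id=trial, test_id=trial, pa=pa, pacc=pacc,
                            hc2=hc2, pacc_flagged=flagged, folds=folds,
                            seed=seed, per_fold_pa=per_fold,
                            predictions=pooled)


def true_validate(
    y_train: pd.Series,
    y_test: pd.Series,
    markers: MarkerMatrix,
    method: str,
    trait: str = "trait",
    train_trial: str = "train",
    test_trial: str = "test",
    hc2_test: float | None = None,
    pedigree_A: RelationshipMatrix | None = None,
    wgr_opts: dict | None = None,
    seed: int = 0,
    sqrt_scaling: bool = True,
) -> ValidationResult:
    """Train on one trial, score marker-only predictions on another.

    ``markers`` must cover the union of training and test individuals. PACC
    uses the test trial's ad-hoc heritability by default.
    """
    test_ids = [str(i) for i in y_test.index]
    preds = _fit_and_predict(method, y_train, markers, test_ids,
                             pedigree_A=pedigree_A, wgr_opts=wgr_opts,
                             seed=seed)
    pa = predictive_ability(y_test, preds)
    pacc, flagged = (None, False)
    if hc2_test is not None:
        pacc, flagged = prediction_accuracy(pa, hc2_test, sqrt_scaling)
    return ValidationResult(trait=trait, method=method, scheme="true",
                            train_id=train_trial, test_id=test_trial,
                            pa=pa, pacc=pacc, hc2=hc2_test,
                            pacc_flagged=flagged, seed=seed,
                            predictions=preds)


def selection_efficiency(
    gebv_incomplete: pd.Series,
    gebv_complete: pd.Series,
    top_fraction: float = 0.10,
) -> float:
    """Percent of complete-information genetic gain realized by marker-only
    ranking when selecting the top fraction.

    Gain of a selected set is the mean complete-information GEBV of the set
    minus the candidate-population mean; efficiency is
    ``100 * gain(incomplete top set) / gain(complete top set)``. Ties break
    by id order (stable).
    """
    inc = gebv_incomplete.copy()
    comp = gebv_complete.loc[inc.index]
    n = len(inc)
    n_sel = int(np.floor(n * top_fraction + 1e-9))
    if n_sel < 1:
        raise ValueError("top_fraction selects no individuals")
    if n_sel >= n:
        return 100.0    # both sets are the whole population
    order_inc = inc.sort_values(ascending=False, kind="stable").index[:n_sel]
    order_comp = comp.sort_values(ascending=False, kind="stable").index[:n_sel]
    base = comp.mean()
    gain_comp = comp.loc[order_comp].mean() - base
    if gain_comp == 0:
        raise ZeroDivisionError("complete-information gain is zero")
    gain_inc = comp.loc[order_inc].mean() - base
    return float(100.0 * gain_inc / gain_comp)


def methods_summary_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean across the six GS methods plus overall averages.

    ``results`` has traits as rows and methods as columns; a ``PBLUP``
    column, if present, is excluded from the GS mean and averaged
    separately. The returned frame appends a ``Mean`` column and an
    ``Overall`` row of column averages. Missing method cells raise.
    """
    gs_cols = [c for c in results.columns if c in GS_METHODS]
    missing = [m for m in GS_METHODS if m not in results.columns]
    if missing and len(gs_cols) == 0:
        raise ValueError("no GS method columns present")
    if results[gs_cols].isna().any().any():
        bad = results[gs_cols].isna().any(axis=1)
        raise ValueError(f"missing method cells for traits: "
                         f"{list(results.index[bad])}")
    out = results.copy()
    out["Mean"] = results[gs_cols].mean(axis=1)
    out.loc["Overall"] = out.mean(axis=0)
    return out
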