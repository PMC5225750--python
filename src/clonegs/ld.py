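"""Intra-linkage-group linkage disequilibrium, relatedness-corrected LD,
and distance-binned decay profiles.

LD between two markers is the squared Pearson correlation of their dosage
vectors (composite LD; dosages are unphased). The relatedness correction
whitens dosage vectors by the Cholesky factor of a relationship matrix —
by default the GRM built from the markers of the same linkage group —
after generalized-least-squares centering, so that family structure no
longer inflates the correlation. With an identity relationship the
corrected statistic equals the ordinary one exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import MarkerMatrix
from .relationships import RelationshipMatrix, bend_psd, grm_yang

__all__ = ["GeneticMap", "pairwise_r2", "corrected_r2", "ld_decay_profile",
           "lg_grm"]

#: eigenvalue floor for the whitening relationship matrix. An LG-specific GRM
#: built from tens-to-hundreds of markers is rank deficient for larger panels;
#: whitening through near-null directions amplifies noise, so eigenvalues are
#: clipped on the scale of the unit GRM diagonal rather than at machine level.
LD_BEND_EPS = 0.05


@dataclass
class GeneticMap:
    """marker -> (linkage group, position in cM)."""

    df: pd.DataFrame    # columns: marker, lg, cm

    def __post_init__(self) -> None:
        need = {"marker", "lg", "cm"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"genetic map needs columns {sorted(need)}")
        if self.df["marker"].duplicated().any():
            raise ValueError("marker mapped to more than one position")
        if (self.df["cm"] < 0).any():
            raise ValueError("negative map positions")
        self.df = self.df.assign(marker=self.df["marker"].astype(str),
                                 lg=self.df["lg"].astype(str))

    @property
    def linkage_groups(self) -> list[str]:
        return sorted(self.df["lg"].unique())

    def markers_on(self, lg: str) -> pd.DataFrame:
        sub = self.df[self.df["lg"] == str(lg)]
        return sub.sort_values("cm").reset_index(drop=True)

    def total_length_cm(self) -> float:
        return float(self.df.groupby("lg")["cm"].agg(lambda s: s.max() - s.min())
                     .sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "GeneticMap":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _lg_panel(m: MarkerMatrix, gmap: GeneticMap, lg: str
              ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Dosage columns, ids and positions for polymorphic markers on one LG."""
    sub = gmap.markers_on(lg)
    present = [mk for mk in sub["marker"] if mk in set(m.marker_ids)]
    if len(present) < 2:
        raise ValueError(f"fewer than 2 mapped markers on LG {lg!r}")
    idx = {mk: j for j, mk in enumerate(m.marker_ids)}
    cols = [idx[mk] for mk in present]
    X = m.dosages[:, cols]
    if np.isnan(X).any():
        raise ValueError("missing dosages; impute before LD analysis")
    pos = sub.set_index("marker").loc[present, "cm"].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} monomorphic markers on "
                      f"LG {lg}", stacklevel=2)
        X, pos = X[:, keep], pos[keep]
        present = [mk for mk, k in zip(present, keep) if k]
    if X.shape[1] < 2:
        raise ValueError(f"fewer than 2 polymorphic markers on LG {lg!r}")
    return X, present, pos


def _pair_table(lg: str, ids: list[str], pos: np.ndarray,
                corr: np.ndarray, colname: str) -> pd.DataFrame:
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame({
        "lg": lg,
        "marker_i": [ids[a] for a in iu],
        "marker_j": [ids[b] for b in ju],
        "dist_cm": np.abs(pos[iu] - pos[ju]),
        colname: corr[iu, ju] ** 2,
    })


def pairwise_r2(m: MarkerMatrix, gmap: GeneticMap, lg: str) -> pd.DataFrame:
    """All within-LG pairs: distance (cM) and dosage-correlation r^2."""
    X, ids, pos = _lg_panel(m, gmap, lg)
    corr = np.corrcoef(X, rowvar=False)
    return _pair_table(str(lg), ids, pos, corr, "r2")


def lg_grm(m: MarkerMatrix, gmap: GeneticMap, lg: str,
           eps: float = LD_BEND_EPS) -> RelationshipMatrix:
    """GRM built only from the (polymorphic, mapped) markers of one LG."""
    _, ids, _ = _lg_panel(m, gmap, lg)
    return bend_psd(grm_yang(m.subset_markers(ids), complete_case=False),
                    eps=eps)


def corrected_r2(m: MarkerMatrix, gmap: GeneticMap, lg: str,
                 v: RelationshipMatrix | None = None,
                 eps: float = LD_BEND_EPS) -> pd.DataFrame:
    """Relatedness-corrected LD ``rv2`` for all within-LG pairs.

    Each dosage vector is GLS-centered with respect to ``v`` (subtracting
    the generalized mean) and whitened by the inverse Cholesky factor of
    ``v``; ``rv2`` is the squared Pearson correlation of the transformed
    vectors. ``v`` defaults to the LG-specific GRM (bent PSD).
    """
    X, ids, pos = _lg_panel(m, gmap, lg)
    if v is None:
        v = lg_grm(m, gmap, lg, eps=eps)
    else:
        v = bend_psd(v, eps=eps)
    V = v.subset(m.individual_ids).values
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "relationship matrix singular after bending") from err
    ones = np.ones(len(X))
    Vi1 = linalg.cho_solve((L, True), ones, check_finite=False)
    ViX = linalg.cho_solve((L, True), X, check_finite=False)
    gls_mean = (ones @ ViX) / (ones @ Vi1)
    Xc = X - gls_mean
    Xw = linalg.solve_triangular(L, Xc, lower=True, check_finite=False)
    corr = np.corrcoef(Xw, rowvar=False)
    out = _pair_table(str(lg), ids, pos, corr, "rv2")
    return out


def ld_decay_profile(ld: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    """Mean LD statistics in distance bins ``[0, w), [w, 2w), ...``.

    Returns one row per non-empty bin with pair counts; empty intermediate
    bins are kept with NaN means and flagged by ``n_pairs == 0``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = ld["dist_cm"].to_numpy(dtype=float)
    stat_cols = [c for c in ("r2", "rv2") if c in ld.columns]
    n_bins = int(np.floor(d.max() / bin_width)) + 1 if len(d) else 0
    rows = []
    which = np.floor(d / bin_width).astype(int)
    for b in range(n_bins):
        mask = which == b
        row = {"bin_lo": b * bin_width, "bin_hi": (b + 1) * bin_width,
               "n_pairs": int(mask.sum())}
        for c in stat_cols:
            row[f"mean_{c}"] = float(ld.loc[mask, c].mean()) if mask.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
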