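"""Relationship matrices: pedigree numerator A, marker-based GRM, and bending.

The pedigree numerator matrix follows the tabular method; the genomic
relationship matrix follows the Yang et al. estimator with per-pair
complete-case averaging (no imputation). Non-positive-definite matrices are
repaired by eigenvalue clipping ("bending") before any solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MarkerMatrix, compute_allele_freq

__all__ = [
    "PedigreeTable",
    "RelationshipMatrix",
    "pedigree_numerator_matrix",
    "grm_yang",
    "bend_psd",
]

#: eigenvalues above this (negative) floor count as non-negative in PSD checks
PSD_TOL = 1e-8


class PedigreeError(ValueError):
    pass


@dataclass
class PedigreeTable:
    """(id, sire, dam) records, topologically ordered parents-before-offspring.

    Unknown parents are ``None``. Every named parent must have its own record;
    records are validated for duplicate ids, forward references and cycles at
    construction.
    """

    records: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        norm = []
        for rid, sire, dam in self.records:
            rid = str(rid)
            sire = None if sire in (None, "", "NA", "0") else str(sire)
            dam = None if dam in (None, "", "NA", "0") else str(dam)
            norm.append((rid, sire, dam))
        self.records = norm
        seen: set[str] = set()
        for rid, sire, dam in self.records:
            if rid in seen:
                raise PedigreeError(f"duplicate pedigree id {rid!r}")
            for par in (sire, dam):
                if par is not None and par not in seen:
                    raise PedigreeError(
                        f"parent {par!r} of {rid!r} has no earlier record "
                        "(missing record or ordering/cycle violation)")
            if rid in (sire, dam):
                raise PedigreeError(f"{rid!r} is its own parent")
            seen.add(rid)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PedigreeTable":
        df = pd.read_csv(path, dtype=str, na_values=["NA", ""],
                         keep_default_na=False)
        recs = [(row["id"],
                 None if pd.isna(row["sire"]) else row["sire"],
                 None if pd.isna(row["dam"]) else row["dam"])
                for _, row in df.iterrows()]
        return cls(recs)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.records, columns=["id", "sire", "dam"]).to_csv(
            path, index=False, na_rep="NA")

    def families(self) -> dict[str, str]:
        """Map each individual to a family label 'sire x dam' (founders map to
        their own id)."""
        fam = {}
        for rid, sire, dam in self.records:
            if sire is None and dam is None:
                fam[rid] = rid
            else:
                fam[rid] = f"{sire or 'NA'}x{dam or 'NA'}"
        return fam


@dataclass
class RelationshipMatrix:
    """Labelled symmetric matrix: pedigree A, genomic A_g, or kernel K."""

    labels: list[str]
    values: np.ndarray
    kind: str = "genomic"  # pedigree | genomic | kernel
    psd: bool | None = None
    bend_applied: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimension does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix is not symmetric (tol 1e-10)")
        if self.kind not in ("pedigree", "genomic", "kernel"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def check_psd(self) -> bool:
        self.psd = self.min_eigenvalue() >= -PSD_TOL
        return self.psd

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        index = {g: i for i, g in enumerate(self.labels)}
        rows = [index[str(g)] for g in ids]
        return RelationshipMatrix([str(g) for g in ids],
                                  self.values[np.ix_(rows, rows)],
                                  kind=self.kind, psd=None,
                                  bend_applied=self.bend_applied,
                                  meta=dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels
                     ).to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "genomic") -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float), kind=kind)


def pedigree_numerator_matrix(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    Founders get diagonal 1 (non-inbred); unknown parents act as unique
    unrelated founders. ``A_ii = 1 + 0.5 A(sire, dam)``;
    ``A_ij = 0.5 (A(j, sire_i) + A(j, dam_i))`` for earlier j.
    """
    ids = ped.ids
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (rid, sire, dam) in enumerate(ped.records):
        s = index[sire] if sire is not None else -1
        d = index[dam] if dam is not None else -1
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(ids, A, kind="pedigree", psd=True)


def grm_yang(m: MarkerMatrix, complete_case: bool = True) -> RelationshipMatrix:
    """Genomic relationship matrix with allele-frequency-specific weights.

    Off-diagonal: ``A_jk = mean_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``.
    Diagonal: ``A_jj = 1 + mean_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i))``.

    With ``complete_case=True`` (default) each pair averages over the markers
    non-missing in both individuals — no imputation. Set it False for speed on
    imputed panels (all markers used as-is).

    Raises
    ------
    ValueError
        If any marker is fixed (p in {0, 1}); run QC first.
    """
    p, _ = compute_allele_freq(m)
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = m.marker_ids[int(np.argmax((p <= 0.0) | (p >= 1.0)))]
        raise ValueError(
            f"marker {bad!r} has allele frequency 0 or 1; apply qc_filter before "
            "building the GRM")
    X = m.dosages
    w = 2.0 * p * (1.0 - p)
    Z = (X - 2.0 * p) / np.sqrt(w)          # standardized, NaN where missing
    diag_num = (X * X - (1.0 + 2.0 * p) * X + 2.0 * p * p) / w
    if complete_case and np.isnan(X).any():
        obs = (~np.isnan(X)).astype(float)
        Z0 = np.where(np.isnan(Z), 0.0, Z)
        cross = Z0 @ Z0.T
        counts = obs @ obs.T
        with np.errstate(invalid="ignore", divide="ignore"):
            A = cross / counts
        A[counts == 0] = 0.0
        dvals = 1.0 + np.nanmean(diag_num, axis=1)
        np.fill_diagonal(A, dvals)
    else:
        if np.isnan(X).any():
            raise ValueError("missing dosages present; impute first or use "
                             "complete_case=True")
        pmarkers = m.n_markers
        A = (Z @ Z.T) / pmarkers
        np.fill_diagonal(A, 1.0 + diag_num.mean(axis=1))
    A = 0.5 * (A + A.T)
    out = RelationshipMatrix(list(m.individual_ids), A, kind="genomic",
                             meta={"estimator": "yang",
                                   "complete_case": bool(complete_case),
                                   "n_markers": m.n_markers})
    out.check_psd()
    return out


def bend_psd(k: RelationshipMatrix, eps: float = 1e-6) -> RelationshipMatrix:
    """Repair a non-PSD matrix by clipping eigenvalues below ``eps`` up to ``eps``.

    Returns the input unchanged (bend_applied False) when the smallest
    eigenvalue is already >= ``eps``. Idempotent.
    """
    vals, vecs = np.linalg.eigh(k.values)
    if vals[0] >= eps:
        out = RelationshipMatrix(list(k.labels), k.values, kind=k.kind,
                                 psd=True, bend_applied=k.bend_applied,
                                 meta=dict(k.meta))
        return out
    clipped = np.maximum(vals, eps)
    V = (vecs * clipped) @ vecs.T
    V = 0.5 * (V + V.T)
    meta = dict(k.meta)
    meta.update({"bend_method": "eigenvalue_clip", "bend_eps": eps})
    return RelationshipMatrix(list(k.labels), V, kind=k.kind, psd=True,
                              bend_applied=True, meta=meta)
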