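"""Marker dosage handling: I/O, allele frequencies, QC filtering and imputation.

Dosages are biallelic SNP calls coded 0/1/2 (copies of the alternate allele)
with missing entries stored as NaN. Octoploid crops genotyped on SNP arrays
deliver disomic dosage calls, so everything downstream treats markers as
diploid dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "QCReport",
    "compute_allele_freq",
    "qc_filter",
    "impute_mean",
    "read_genotype_csv",
    "read_plink_text",
]


class AlleleFrequencyError(ValueError):
    """A marker has no non-missing calls, so its frequency is undefined."""


class EmptyPanelError(ValueError):
    """QC removed every marker."""


@dataclass
class MarkerMatrix:
    """Individuals x markers dosage table.

    Parameters
    ----------
    individual_ids
        Unique labels for the rows.
    marker_ids
        Unique labels for the columns.
    dosages
        Float array of shape ``(n_individuals, n_markers)``; entries are
        0, 1, 2 or NaN (missing). Imputed matrices may hold real-valued
        expected dosages.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValueError("row count does not match individual_ids")
        if p != len(self.marker_ids):
            raise ValueError("column count does not match marker_ids")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Per-marker alternate-allele frequency on non-missing calls."""
        return compute_allele_freq(self)[0]

    def subset_individuals(self, ids: list[str]) -> "MarkerMatrix":
        index = {g: i for i, g in enumerate(self.individual_ids)}
        rows = [index[str(g)] for g in ids]
        return MarkerMatrix([str(g) for g in ids], list(self.marker_ids),
                            self.dosages[rows])

    def subset_markers(self, marker_ids: list[str]) -> "MarkerMatrix":
        index = {m: j for j, m in enumerate(self.marker_ids)}
        cols = [index[str(m)] for m in marker_ids]
        return MarkerMatrix(list(self.individual_ids), [str(m) for m in marker_ids],
                            self.dosages[:, cols])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.dosages, index=self.individual_ids,
                          columns=self.marker_ids)
        df.to_csv(path, index_label="id")


@dataclass
class QCReport:
    """Per-rule and joint marker counts from :func:`qc_filter`."""

    n_input: int
    n_kept: int
    n_fail_maf: int
    n_fail_missing: int
    n_fail_both: int
    maf_min: float
    miss_max: float
    imputed_fraction: float | None = None
    dropped_markers: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_fail_maf": self.n_fail_maf,
            "n_fail_missing": self.n_fail_missing,
            "n_fail_both": self.n_fail_both,
            "maf_min": self.maf_min,
            "miss_max": self.miss_max,
            "imputed_fraction": self.imputed_fraction,
        }


def compute_allele_freq(m: MarkerMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency ``p`` and minor-allele frequency per marker.

    ``p_i`` is computed on non-missing calls only:
    ``p_i = sum(dosages) / (2 * n_non_missing)``; ``MAF_i = min(p_i, 1 - p_i)``.

    Raises
    ------
    AlleleFrequencyError
        If any marker has no non-missing calls (names the first such marker).
    """
    miss = np.isnan(m.dosages)
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = m.marker_ids[int(np.argmax(n_obs == 0))]
        raise AlleleFrequencyError(
            f"marker {bad!r} has no non-missing calls; frequency undefined")
    p = np.nansum(m.dosages, axis=0) / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    return p, maf


def missing_rate(m: MarkerMatrix) -> np.ndarray:
    """Per-marker fraction of missing calls."""
    return np.isnan(m.dosages).mean(axis=0)


def qc_filter(
    m: MarkerMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
) -> tuple[MarkerMatrix, QCReport]:
    """Drop markers with MAF below ``maf_min`` or missing rate above ``miss_max``.

    Markers exactly at a threshold are kept (elimination is strict:
    MAF < ``maf_min`` or missing rate > ``miss_max``). Individuals are never
    dropped.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= miss_max <= 1.0:
        raise ValueError("miss_max must be in [0, 1]")
    _, maf = compute_allele_freq(m)
    miss = missing_rate(m)
    fail_maf = maf < maf_min
    fail_miss = miss > miss_max
    keep = ~(fail_maf | fail_miss)
    if not keep.any():
        raise EmptyPanelError("no markers survive QC")
    kept_ids = [mid for mid, k in zip(m.marker_ids, keep) if k]
    report = QCReport(
        n_input=m.n_markers,
        n_kept=int(keep.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_missing=int(fail_miss.sum()),
        n_fail_both=int((fail_maf & fail_miss).sum()),
        maf_min=maf_min,
        miss_max=miss_max,
        dropped_markers=[mid for mid, k in zip(m.marker_ids, keep) if not k],
    )
    out = MarkerMatrix(list(m.individual_ids), kept_ids, m.dosages[:, keep])
    return out, report


def impute_mean(m: MarkerMatrix, round_to_int: bool = False) -> tuple[MarkerMatrix, float]:
    """Replace missing dosages by the expected dosage ``2 p_i``.

    Imputation at the per-marker mean leaves column means unchanged.
    Returns the imputed matrix and the fraction of cells that were missing.

    Parameters
    ----------
    round_to_int
        If True, round imputed values to the nearest integer dosage
        (off by default: samplers and relationship matrices use real dosages).
    """
    p, _ = compute_allele_freq(m)
    miss = np.isnan(m.dosages)
    frac = float(miss.mean())
    filled = m.dosages.copy()
    expected = 2.0 * p
    if round_to_int:
        expected = np.clip(np.round(expected), 0, 2)
    filled[miss] = np.broadcast_to(expected, filled.shape)[miss]
    return MarkerMatrix(list(m.individual_ids), list(m.marker_ids), filled), frac


def read_genotype_csv(path: str | Path) -> MarkerMatrix:
    """Read a wide genotype CSV: header = marker ids, first column = individual id.

    Missing dosages are empty cells or ``NA``.
    """
    df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    return MarkerMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
    )


def read_plink_text(ped_path: str | Path, map_path: str | Path,
                    missing_code: str = "0") -> MarkerMatrix:
    """Read text PLINK .ped/.map files into dosages of the minor allele.

    Each .ped row: family, individual, sire, dam, sex, phenotype, then two
    allele columns per marker. The dosage counts the lexicographically later
    allele; a call containing ``missing_code`` is treated as missing.
    """
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chrom", "marker", "cm", "bp"])
    marker_ids = [str(x) for x in map_df["marker"]]
    rows, ids = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(marker_ids):
                raise ValueError("ped/map marker count mismatch")
            rows.append(alleles)
    allele_arr = np.array(rows, dtype=object).reshape(len(ids), len(marker_ids), 2)
    dosages = np.full((len(ids), len(marker_ids)), np.nan)
    for j in range(len(marker_ids)):
        calls = allele_arr[:, j, :]
        ok = ~np.any(calls == missing_code, axis=1)
        observed = np.unique(calls[ok])
        if observed.size == 0:
            continue
        alt = sorted(observed)[-1]
        dosages[ok, j] = (calls[ok] == alt).sum(axis=1)
    return MarkerMatrix(ids, marker_ids, dosages)
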