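"""Core in-memory containers shared across the pipeline.

The central object is :class:`DosageMatrix`, a samples x variants matrix of
effect-allele dosages in [0, 2] together with per-variant metadata. GWAS
summary statistics travel as plain :class:`pandas.DataFrame` objects indexed
by variant id with columns CHR, BP, A1, A2, BETA, SE, P, N (``A1`` is the
effect allele whose dosage is counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: mandatory columns of a summary-statistics table (the index carries SNP ids)
SUMSTAT_COLUMNS = ["CHR", "BP", "A1", "A2", "BETA", "P"]
#: optional summary-statistics columns
SUMSTAT_OPTIONAL = ["SE", "N"]

#: mandatory columns of the per-variant metadata table of a DosageMatrix
VARIANT_COLUMNS = ["CHR", "BP", "A1", "A2", "INFO"]


class DataError(ValueError):
    """Malformed input data (shape, bounds or schema violations)."""


def validate_sumstats(stats: pd.DataFrame) -> pd.DataFrame:
    """Validate a summary-statistics table, returning it unchanged.

    Raises :class:`DataError` on missing columns, duplicate variant ids or
    p-values outside (0, 1].
    """
    missing = [c for c in SUMSTAT_COLUMNS if c not in stats.columns]
    if missing:
        raise DataError(f"summary statistics missing columns: {missing}")
    if stats.index.has_duplicates:
        dups = stats.index[stats.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate SNP ids in summary statistics: {dups[:10]}")
    p = np.asarray(stats["P"], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = stats.index[(~np.isfinite(p)) | (p <= 0) | (p > 1)].tolist()
        raise DataError(
            f"p-values must lie in (0, 1]; offending SNPs: {bad[:10]} "
            "(p = 0 should be clamped upstream, e.g. to 1e-300)"
        )
    return stats


@dataclass
class DosageMatrix:
    """Samples x variants matrix of effect-allele dosages with metadata.

    Parameters
    ----------
    dosages
        Array of shape ``(n_samples, n_variants)``; values in [0, 2] or NaN
        for missing genotypes.
    samples
        Sample identifiers, one per row.
    variants
        Per-variant metadata indexed by variant id with columns
        CHR, BP, A1, A2, INFO. ``A1`` is the counted (dosage) allele.
    """

    dosages: np.ndarray
    samples: pd.Index
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = pd.Index(self.samples)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-d array (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise DataError("sample count does not match dosage rows")
        if self.dosages.shape[1] != len(self.variants):
            raise DataError("variant count does not match dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise DataError(f"variant metadata missing columns: {missing}")
        if self.samples.has_duplicates:
            raise DataError("duplicate sample ids")
        if self.variants.index.has_duplicates:
            raise DataError("duplicate variant ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < -1e-6) | (self.dosages > 2 + 1e-6)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise DataError("dosages outside [0, 2]")

    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele A1 per variant (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    # ------------------------------------------------------------------ #
    def take_samples(self, mask: np.ndarray) -> "DosageMatrix":
        mask = np.asarray(mask)
        return DosageMatrix(self.dosages[mask, :], self.samples[mask], self.variants)

    def take_variants(self, mask: np.ndarray) -> "DosageMatrix":
        mask = np.asarray(mask)
        return DosageMatrix(self.dosages[:, mask], self.samples, self.variants.loc[mask] if mask.dtype == bool else self.variants.iloc[mask])

    def select_variants(self, ids) -> "DosageMatrix":
        """Subset (and reorder) by variant id."""
        idx = self.variants.index.get_indexer(pd.Index(ids))
        if np.any(idx < 0):
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"variants not in panel: {missing[:10]}")
        return DosageMatrix(self.dosages[:, idx], self.samples, self.variants.iloc[idx])

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        j = self.variants.index.get_loc(variant_id)
        return self.dosages[:, j]

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing values replaced by the per-variant mean."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(d, axis=0)
            nan_r, nan_c = np.where(np.isnan(d))
            d[nan_r, nan_c] = col_mean[nan_c]
        return d
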