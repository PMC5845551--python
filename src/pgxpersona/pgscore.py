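"""p-value-informed LD clumping and threshold-series polygenic scoring.

Scores follow the classic discovery-weighted construction: candidate SNPs
are clumped greedily by ascending discovery p-value (removing neighbours
within a physical window whose in-cohort dosage correlation r2 reaches the
threshold), and each score is the average over included SNPs of effect-allele
dosage times discovery beta, one score column per p-value cutoff P_T. The
per-SNP average (division by M_T, the number of SNPs entering the cutoff)
is intentional — many scoring tools default to raw sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DataError, DosageMatrix, validate_sumstats

__all__ = [
    "ClumpParams",
    "ThresholdGrid",
    "DEFAULT_THRESHOLDS",
    "PgsProfile",
    "ld_r2",
    "clump",
    "compute_pgs",
    "harmonize_alleles",
    "HarmonizationWarning",
]

#: default discovery p-value cutoff series
DEFAULT_THRESHOLDS = (1e-2, 5e-2, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class HarmonizationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ClumpParams:
    """LD-clumping parameters: r2 cutoff and +/- physical window."""

    r2_threshold: float = 0.1
    window_bp: int = 250_000

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold <= 1):
            raise DataError("r2_threshold must lie in (0, 1]")
        if self.window_bp <= 0:
            raise DataError("window_bp must be positive")


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing p-value cutoffs in (0, 1]."""

    thresholds: tuple = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if len(t) == 0:
            raise DataError("empty threshold grid")
        if any(not (0 < x <= 1) for x in t):
            raise DataError("thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise DataError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self):
        return len(self.thresholds)


@dataclass
class PgsProfile:
    """Per-sample scores, one column per p-value cutoff.

    ``scores`` is indexed by sample id with one column per threshold
    (``SCORE_PT_0.01`` ...); ``m_t`` maps each threshold to the number of
    retained SNPs entering it (M_T); thresholds with M_T = 0 carry NaN
    columns and are listed in ``empty_thresholds``.
    """

    scores: pd.DataFrame
    m_t: dict
    trait: str = ""
    clump_params: ClumpParams | None = None
    grid: ThresholdGrid | None = None

    @property
    def empty_thresholds(self) -> list:
        return [t for t, m in self.m_t.items() if m == 0]

    def column(self, threshold: float) -> pd.Series:
        return self.scores[score_column(threshold)]


def score_column(threshold: float) -> str:
    return f"SCORE_PT_{threshold:g}"


# --------------------------------------------------------------------------- #
def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Missing entries are dropped pairwise; zero variance raises."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise DataError("dosage vectors must share length >= 2")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        raise DataError("LD undefined: zero variance or too few complete pairs")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def clump(
    stats: pd.DataFrame, genos: DosageMatrix, params: ClumpParams | None = None
) -> list:
    """Greedy p-value-informed LD clumping; returns retained (index) SNP ids.

    Repeatedly takes the unremoved variant with the smallest discovery p as
    an index SNP and removes every unremoved variant on the same chromosome
    within +/- ``window_bp`` whose in-cohort dosage r2 with the index reaches
    ``r2_threshold``. Ties in p break by smaller position, then id.
    """
    params = params or ClumpParams()
    validate_sumstats(stats)
    missing = stats.index.difference(genos.variants.index)
    if len(missing) > 0:
        raise DataError(f"variants absent from genotype panel: {list(missing[:10])}")

    panel = genos.select_variants(stats.index)
    d = panel.imputed_dosages()
    mu = d.mean(axis=0)
    sd = d.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, np.nan, sd)
    z = (d - mu) / sd_safe  # zero-variance columns become NaN -> r2 NaN -> kept apart

    chrom = np.asarray(stats["CHR"])
    bp = np.asarray(stats["BP"], dtype=np.int64)
    order = np.lexsort((stats.index.to_numpy(), bp, np.asarray(stats["P"], dtype=float)))

    n = genos.n_samples
    alive = np.ones(len(stats), dtype=bool)
    retained: list = []
    for i in order:
        if not alive[i]:
            continue
        retained.append(stats.index[i])
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= params.window_bp)
        if near.any():
            r = z[:, near].T @ z[:, i] / n
            kill = np.zeros(near.sum(), dtype=bool)
            with np.errstate(invalid="ignore"):
                kill = (r * r) >= params.r2_threshold
            idx = np.flatnonzero(near)[kill]
            alive[idx] = False
    return retained


def compute_pgs(
    genos: DosageMatrix,
    stats: pd.DataFrame,
    retained: list,
    grid: ThresholdGrid | None = None,
    trait: str = "",
    clump_params: ClumpParams | None = None,
) -> PgsProfile:
    """Average-per-SNP weighted scores across the threshold grid.

    ``score_i(T) = sum_{j in retained, p_j < T} beta_j * d_ij / M_T``.
    Missing dosages are mean-imputed per variant. Thresholds with no SNPs
    are flagged empty (NaN column) rather than evaluated as 0/0.
    """
    grid = grid or ThresholdGrid()
    retained = list(retained)
    ridx = pd.Index(retained)
    if not ridx.isin(stats.index).all():
        raise DataError("retained variants must be a subset of the summary statistics")
    sub = stats.loc[ridx]
    panel = genos.select_variants(ridx)
    d = panel.imputed_dosages()
    beta = np.asarray(sub["BETA"], dtype=float)
    p = np.asarray(sub["P"], dtype=float)

    cols = {}
    m_t = {}
    for t in grid:
        mask = p < t  # strict inequality per the P_T < T convention
        m = int(mask.sum())
        m_t[t] = m
        if m == 0:
            cols[score_column(t)] = np.full(genos.n_samples, np.nan)
        else:
            cols[score_column(t)] = d[:, mask] @ beta[mask] / m
    scores = pd.DataFrame(cols, index=panel.samples)
    if not np.isfinite(scores.to_numpy()[:, [m_t[t] > 0 for t in grid]]).all():
        raise DataError("non-finite scores")
    return PgsProfile(scores, m_t, trait=trait, clump_params=clump_params, grid=grid)


# --------------------------------------------------------------------------- #
def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        return None


def match_alleles(a1: str, a2: str, b1: str, b2: str) -> int | None:
    """Orientation of allele pair (a1, a2) against panel pair (b1, b2).

    Returns +1 if a1 is the counted allele (possibly after strand
    complement), -1 if a2 is (effect must be flipped), None if the pairs are
    irreconcilable. Assumes strand-ambiguous pairs were removed upstream.
    """
    a1, a2, b1, b2 = a1.upper(), a2.upper(), b1.upper(), b2.upper()
    if (a1, a2) == (b1, b2):
        return 1
    if (a1, a2) == (b2, b1):
        return -1
    c1, c2 = _complement(a1), _complement(a2)
    if c1 is not None and c2 is not None:
        if (c1, c2) == (b1, b2):
            return 1
        if (c1, c2) == (b2, b1):
            return -1
    return None


def harmonize_alleles(stats: pd.DataFrame, genos: DosageMatrix) -> pd.DataFrame:
    """Align summary-statistic effect alleles to the panel's counted allele.

    Betas are negated where the effect allele is the panel's other allele;
    strand complements are tried before declaring a mismatch. Irreconcilable
    variants are dropped with a warning; the returned table's A1/A2 are the
    panel's and the dropped ids are stored in ``attrs['dropped']``.
    """
    validate_sumstats(stats)
    shared = stats.index.intersection(genos.variants.index)
    sub = stats.loc[shared].copy()
    pv = genos.variants.loc[shared]

    flips = np.empty(len(shared))
    bad = []
    for k, snp in enumerate(shared):
        o = match_alleles(sub["A1"].iat[k], sub["A2"].iat[k],
                          pv["A1"].iat[k], pv["A2"].iat[k])
        if o is None:
            bad.append(snp)
            flips[k] = np.nan
        else:
            flips[k] = o
    if bad:
        warnings.warn(
            f"dropped {len(bad)} variants with irreconcilable alleles: {bad[:10]}",
            HarmonizationWarning,
            stacklevel=2,
        )
        keep = ~np.isnan(flips)
        sub, pv, flips = sub.loc[keep], pv.loc[keep], flips[keep]
    out = sub.copy()
    out["BETA"] = np.asarray(sub["BETA"], dtype=float) * flips
    out["A1"] = pv["A1"].to_numpy()
    out["A2"] = pv["A2"].to_numpy()
    out.attrs["dropped"] = bad
    return out
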