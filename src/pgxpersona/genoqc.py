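"""Sample and variant quality control for dosage panels.

Implements the standard pharmacogenomic GWAS filter stack: sample call rate,
variant call rate, strand-ambiguous SNPs (A/T, C/G), indels, genotyping-era
MAF (exclude at MAF <= 1%), an exact Hardy-Weinberg test (exclude at
p < 1e-6), and the post-imputation inclusion filters (exclude MAF < 10% and
imputation INFO < 0.9). Boundary semantics are deliberately asymmetric —
the MAF QC bound excludes *at* equality while the post-imputation MAF and
INFO bounds exclude strictly below — mirroring the conventions of the
genotyping and imputation stages they come from.

The Hardy-Weinberg test is the exact conditional test: given the minor
allele count, the probability of each heterozygote count is computed and the
two-sided p-value sums all configurations no more likely than the observed
one. Dosages are rounded to hard genotype calls for the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DataError, DosageMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "QcEmptyError",
    "hwe_exact_test",
    "hwe_het_distribution",
    "is_ambiguous",
    "apply_qc",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class QcEmptyError(ValueError):
    """All samples or all variants were removed by QC."""


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults match the published pipeline."""

    sample_call_rate_min: float = 0.95
    variant_call_rate_min: float = 0.95
    maf_min_qc: float = 0.01          # exclude MAF <= this (equality excluded)
    hwe_p_min: float = 1e-6           # exclude HWE p < this
    maf_min_postimpute: float = 0.10  # exclude MAF < this
    info_min: float = 0.9             # exclude INFO < this
    drop_ambiguous: bool = True
    drop_indels: bool = True

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "variant_call_rate_min",
                     "maf_min_qc", "hwe_p_min", "maf_min_postimpute", "info_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QcReport:
    """Per-filter removal bookkeeping for one QC run."""

    n_samples_in: int
    n_variants_in: int
    steps: list = field(default_factory=list)  # (filter name, kind, n removed)
    retained_samples: list = field(default_factory=list)
    retained_variants: list = field(default_factory=list)

    def record(self, name: str, kind: str, n_removed: int) -> None:
        self.steps.append((name, kind, int(n_removed)))

    @property
    def n_samples_out(self) -> int:
        return len(self.retained_samples)

    @property
    def n_variants_out(self) -> int:
        return len(self.retained_variants)

    def validate(self) -> None:
        rm_s = sum(n for _, k, n in self.steps if k == "sample")
        rm_v = sum(n for _, k, n in self.steps if k == "variant")
        if self.n_samples_in - rm_s != self.n_samples_out:
            raise DataError("sample removal counts inconsistent with output")
        if self.n_variants_in - rm_v != self.n_variants_out:
            raise DataError("variant removal counts inconsistent with output")

    def to_dict(self) -> dict:
        return {
            "n_samples_in": self.n_samples_in,
            "n_variants_in": self.n_variants_in,
            "n_samples_out": self.n_samples_out,
            "n_variants_out": self.n_variants_out,
            "steps": [
                {"filter": n, "kind": k, "removed": r} for n, k, r in self.steps
            ],
            "retained_samples": list(map(str, self.retained_samples)),
            "retained_variants": list(map(str, self.retained_variants)),
        }


# --------------------------------------------------------------------------- #
def hwe_het_distribution(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` diploid genotypes carrying ``n_minor`` minor alleles, returns
    ``(het_counts, probabilities)`` for every attainable heterozygote count
    under Hardy-Weinberg equilibrium, via the stable upward recurrence
    ``P(h+2)/P(h) = 4 * hom_minor * hom_major / ((h+1)(h+2))``.
    """
    if n < 1 or n_minor < 0 or n_minor > 2 * n:
        raise DataError("invalid genotype totals")
    n_major = 2 * n - n_minor
    h_max = min(n_minor, n_major)
    h_min = n_minor % 2
    hets = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(len(hets), dtype=float)
    probs[0] = 1.0
    for i in range(len(hets) - 1):
        h = hets[i]
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        probs[i + 1] = probs[i] * 4.0 * hom_minor * hom_major / ((h + 1.0) * (h + 2.0))
        # renormalise on the fly to avoid overflow at large n
        if probs[i + 1] > 1e250:
            probs[: i + 2] /= probs[i + 1]
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value from genotype counts.

    Sums the conditional probabilities of all heterozygote counts no more
    likely than the observed one, given the allele counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise DataError("at least one genotype required")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    hets, probs = hwe_het_distribution(n, n_minor)
    p_obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def is_ambiguous(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    if not a1 or not a2:
        raise DataError("empty allele string")
    pair = {a1.upper(), a2.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _is_indel(a1: str, a2: str) -> bool:
    return len(a1) != 1 or len(a2) != 1 or a1.upper() not in _COMPLEMENT or a2.upper() not in _COMPLEMENT


# --------------------------------------------------------------------------- #
def apply_qc(genos: DosageMatrix, thr: QcThresholds | None = None) -> tuple[DosageMatrix, QcReport]:
    """Apply the full filter stack in a fixed order and return the surviving
    matrix plus a per-stage removal report.

    Order: sample call rate, variant call rate, ambiguity, indels, MAF (QC
    bound, computed on surviving samples), HWE on rounded genotype calls,
    post-imputation MAF, INFO. The surviving set is order-invariant but the
    per-stage counts are not, hence the fixed order.
    """
    thr = thr or QcThresholds()
    if genos.n_samples == 0 or genos.n_variants == 0:
        raise QcEmptyError("empty input matrix")

    report = QcReport(genos.n_samples, genos.n_variants)

    # 1. sample call rate
    keep_s = genos.sample_call_rate() >= thr.sample_call_rate_min
    report.record("sample_call_rate", "sample", (~keep_s).sum())
    if not keep_s.any():
        raise QcEmptyError("all samples removed by call-rate filter")
    genos = genos.take_samples(keep_s)

    def drop(name: str, remove: np.ndarray, g: DosageMatrix) -> DosageMatrix:
        report.record(name, "variant", remove.sum())
        g2 = g.take_variants(~remove)
        if g2.n_variants == 0:
            raise QcEmptyError(f"all variants removed at filter {name!r}")
        return g2

    # 2. variant call rate
    genos = drop("variant_call_rate", genos.variant_call_rate() < thr.variant_call_rate_min, genos)

    # 3. strand-ambiguous SNPs
    v = genos.variants
    if thr.drop_ambiguous:
        amb = np.array([
            not _is_indel(a1, a2) and is_ambiguous(a1, a2)
            for a1, a2 in zip(v["A1"], v["A2"])
        ])
        genos = drop("ambiguous", amb, genos)
        v = genos.variants

    # 4. indels
    if thr.drop_indels:
        ind = np.array([_is_indel(a1, a2) for a1, a2 in zip(v["A1"], v["A2"])])
        genos = drop("indels", ind, genos)

    # 5. MAF (genotyping-era bound, equality excluded)
    genos = drop("maf_qc", genos.maf() <= thr.maf_min_qc, genos)

    # 6. HWE on hard calls (dosages rounded; missing genotypes excluded)
    hwe_p = np.empty(genos.n_variants)
    for j, g in enumerate(genos.dosages.T):
        hard = np.rint(g[~np.isnan(g)]).astype(int)
        hwe_p[j] = hwe_exact_test(
            int((hard == 0).sum()), int((hard == 1).sum()), int((hard == 2).sum())
        )
    genos = drop("hwe", hwe_p < thr.hwe_p_min, genos)

    # 7. post-imputation MAF (strictly-below excluded)
    genos = drop("maf_postimpute", genos.maf() < thr.maf_min_postimpute, genos)

    # 8. imputation quality
    info = np.asarray(genos.variants["INFO"], dtype=float)
    genos = drop("info", info < thr.info_min, genos)

    report.retained_samples = list(genos.samples)
    report.retained_variants = list(genos.variants.index)
    report.validate()
    return genos, report
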