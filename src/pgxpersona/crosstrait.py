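"""Cross-trait combination of two GWAS summary-statistic sets.

Per shared variant the two signed Z-scores (recovered from the two-sided
p-values and effect directions) are combined by

* the O'Brien statistic ``T_OB = (w' S^-1 z) / sqrt(w' S^-1 w)`` with equal
  weights, which is powerful for concordant effects, and
* the direct linear combination ``T_w = (w' z) / sqrt(w' S w)`` maximized
  over a weight set (default the two sign patterns ``{(1,1),(1,-1)}/sqrt2``),
  which also captures opposite-direction effects.

Significance uses the smaller of the two p-values; taking the minimum of two
statistics without further correction is anti-conservative, and the package's
calibration tests quantify that inflation rather than hide it. A hit must
also be at least nominally significant (p < 0.05) in both univariate scans.
Significant variants are collapsed to LD-independent lead loci (r2 > 0.1
within a window shares a locus) and annotated with the nearest gene.

The correlation matrix S between the two Z fields defaults to the identity
— appropriate when the two GWASs have disjoint samples — and can be
estimated from the genome-wide null variants when samples overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import DataError, DosageMatrix, validate_sumstats
from .pgscore import match_alleles

__all__ = [
    "GENOME_WIDE_P",
    "NOMINAL_P",
    "DEFAULT_WEIGHT_SET",
    "p_to_z",
    "ob_statistic",
    "dlc_statistic",
    "combine_traits",
    "estimate_sigma",
    "lead_loci",
    "nearest_gene",
    "annotate_genes",
    "CrossTraitMeta",
    "CrossTraitResults",
]

GENOME_WIDE_P = 5e-8
NOMINAL_P = 0.05
_P_FLOOR = 1e-300

_SQ2 = 1.0 / np.sqrt(2.0)
DEFAULT_WEIGHT_SET = (np.array([_SQ2, _SQ2]), np.array([_SQ2, -_SQ2]))


def p_to_z(p: float, direction: int) -> float:
    """Signed Z from a two-sided p-value and an effect direction (+1/-1).

    ``z = direction * Phi^-1(1 - p/2)``; p is clamped to [1e-300, 1].
    """
    p = float(p)
    if not (0 < p <= 1):
        if p == 0:
            raise DataError("p = 0: clamp upstream (floor 1e-300) before inversion")
        raise DataError(f"p-value outside (0, 1]: {p}")
    if direction not in (1, -1, +1):
        raise DataError("direction must be +1 or -1")
    return float(direction * norm.isf(max(p, _P_FLOOR) / 2.0))


def _check_sigma(sigma: np.ndarray, k: int) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (k, k):
        raise DataError(f"sigma must be {k}x{k}")
    if not np.allclose(sigma, sigma.T):
        raise DataError("sigma must be symmetric")
    if not np.allclose(np.diag(sigma), 1.0):
        raise DataError("sigma must have a unit diagonal")
    return sigma


def ob_statistic(z, sigma=None, weights=None) -> tuple[float, float]:
    """O'Brien combined statistic and its two-sided normal p-value."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = z.size
    sigma = np.eye(k) if sigma is None else _check_sigma(sigma, k)
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    try:
        siw = np.linalg.solve(sigma, w)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular sigma") from exc
    t = float(siw @ z / np.sqrt(siw @ w))
    return t, float(2.0 * norm.sf(abs(t)))


def dlc_statistic(z, sigma=None, weight_set=None) -> tuple[float, float, np.ndarray]:
    """Best direct linear combination over a weight set.

    Returns ``(T, p, w)`` for the weight vector maximizing ``|w'z /
    sqrt(w'Sw)|``; p is the two-sided normal tail of T.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = z.size
    sigma = np.eye(k) if sigma is None else _check_sigma(sigma, k)
    ws = DEFAULT_WEIGHT_SET if weight_set is None else [
        np.asarray(w, dtype=float) for w in weight_set
    ]
    if len(ws) == 0:
        raise DataError("empty weight set")
    best_t, best_w = 0.0, None
    for w in ws:
        if w.shape != (k,) or not np.any(w):
            raise DataError("weight vectors must be nonzero and match z length")
        t = float(w @ z / np.sqrt(w @ sigma @ w))
        if best_w is None or abs(t) > abs(best_t):
            best_t, best_w = t, w
    return best_t, float(2.0 * norm.sf(abs(best_t))), best_w


# --------------------------------------------------------------------------- #
def _signed_z_table(stats: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    p = np.clip(np.asarray(stats["P"], dtype=float), _P_FLOOR, 1.0)
    sign = np.where(np.asarray(stats["BETA"], dtype=float) < 0, -1.0, 1.0)
    return sign * norm.isf(p / 2.0), sign


def combine_traits(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    sigma: np.ndarray | None = None,
    weight_set=None,
    gw_threshold: float = GENOME_WIDE_P,
    nominal: float = NOMINAL_P,
) -> pd.DataFrame:
    """Per-variant min(OB, dLC) combination of two summary-statistic sets.

    Alleles of the second set are harmonized to the first (strand complement
    allowed; irreconcilable variants dropped with a warning). Returns one
    row per shared variant with the signed Zs, both statistics and p-values,
    the combined p (the smaller of the two) and the dual-significance flags.
    """
    validate_sumstats(stats1)
    validate_sumstats(stats2)
    shared = stats1.index.intersection(stats2.index)
    if len(shared) == 0:
        raise DataError("no shared variants between the two traits")
    s1 = stats1.loc[shared]
    s2 = stats2.loc[shared].copy()

    flips = np.empty(len(shared))
    bad = []
    for k in range(len(shared)):
        o = match_alleles(s2["A1"].iat[k], s2["A2"].iat[k],
                          s1["A1"].iat[k], s1["A2"].iat[k])
        if o is None:
            bad.append(shared[k])
            flips[k] = np.nan
        else:
            flips[k] = o
    if bad:
        warnings.warn(f"dropped {len(bad)} unharmonizable variants", stacklevel=2)
        keep = ~np.isnan(flips)
        s1, s2, flips = s1.loc[keep], s2.loc[keep], flips[keep]
        if len(s1) == 0:
            raise DataError("no harmonizable shared variants")
    s2["BETA"] = np.asarray(s2["BETA"], dtype=float) * flips

    z1, sg1 = _signed_z_table(s1)
    z2, sg2 = _signed_z_table(s2)
    k = 2
    sig = np.eye(k) if sigma is None else _check_sigma(np.asarray(sigma), k)
    ws = DEFAULT_WEIGHT_SET if weight_set is None else [
        np.asarray(w, dtype=float) for w in weight_set
    ]

    Z = np.vstack([z1, z2])  # 2 x m
    w_ob = np.ones(2)
    siw = np.linalg.solve(sig, w_ob)
    t_ob = siw @ Z / np.sqrt(siw @ w_ob)
    p_ob = 2.0 * norm.sf(np.abs(t_ob))

    t_best = np.zeros(Z.shape[1])
    w_idx = np.zeros(Z.shape[1], dtype=int)
    for i, w in enumerate(ws):
        t_w = w @ Z / np.sqrt(w @ sig @ w)
        better = np.abs(t_w) > np.abs(t_best)
        t_best = np.where(better, t_w, t_best)
        w_idx = np.where(better, i, w_idx)
    p_dlc = 2.0 * norm.sf(np.abs(t_best))

    p_comb = np.minimum(p_ob, p_dlc)
    p1 = np.asarray(s1["P"], dtype=float)
    p2 = np.asarray(s2["P"], dtype=float)
    dir_str = ["".join("+" if s > 0 else "-" for s in pair) for pair in zip(sg1, sg2)]

    hits = pd.DataFrame(
        {
            "CHR": s1["CHR"].to_numpy(),
            "BP": s1["BP"].to_numpy(),
            "A1": s1["A1"].to_numpy(),
            "A2": s1["A2"].to_numpy(),
            "p1": p1,
            "p2": p2,
            "z1": z1,
            "z2": z2,
            "direction": dir_str,
            "t_ob": t_ob,
            "p_ob": p_ob,
            "t_dlc": t_best,
            "p_dlc": p_dlc,
            "dlc_weight": [tuple(np.round(ws[i], 6)) for i in w_idx],
            "p_combined": p_comb,
            "genome_wide": p_comb < gw_threshold,
            "both_nominal": (p1 < nominal) & (p2 < nominal),
        },
        index=s1.index,
    )
    hits["pass_dual"] = hits["genome_wide"] & hits["both_nominal"]
    return hits


def estimate_sigma(z1, z2, null_cut: float = 0.05, min_null: int = 1000) -> np.ndarray:
    """Estimate the 2x2 Z-correlation from genome-wide null variants.

    Restricts to variants with both univariate p above ``null_cut`` and
    shrinks the correlation to 0 when |r| is below 2/sqrt(m) (sampling
    noise). Restricting both margins to |z| < c attenuates the correlation
    of a bivariate normal by roughly the truncated-margin variance factor
    ``v = 1 - 2c phi(c) / (2 Phi(c) - 1)``, so the raw estimate is divided
    by ``v`` (and clipped to [-1, 1]). Intended for overlapping-sample GWAS
    pairs.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise DataError("z vectors must be aligned")
    zcut = norm.isf(null_cut / 2.0)
    mask = (np.abs(z1) < zcut) & (np.abs(z2) < zcut)
    m = int(mask.sum())
    if m < min_null:
        raise DataError(f"too few null variants to estimate sigma ({m} < {min_null})")
    r = float(np.corrcoef(z1[mask], z2[mask])[0, 1])
    if abs(r) < 2.0 / np.sqrt(m):
        r = 0.0
    v = 1.0 - 2.0 * zcut * norm.pdf(zcut) / (2.0 * norm.cdf(zcut) - 1.0)
    r = float(np.clip(r / v, -1.0, 1.0))
    return np.array([[1.0, r], [r, 1.0]])


# --------------------------------------------------------------------------- #
def lead_loci(
    hits: pd.DataFrame,
    ld_panel: DosageMatrix,
    r2_link: float = 0.1,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Collapse hits to LD-independent lead loci.

    Greedy by ascending combined p: the best remaining hit becomes the lead
    of a new locus; every remaining hit on the same chromosome within
    ``window_bp`` with r2 > ``r2_link`` joins that locus. Hits whose
    variants are missing from the LD panel are excluded with a warning.
    Returns the hit table with ``locus`` and ``lead`` columns.
    """
    in_panel = hits.index.isin(ld_panel.variants.index)
    if not in_panel.all():
        warnings.warn(
            f"{(~in_panel).sum()} hits absent from the LD panel were excluded",
            stacklevel=2,
        )
    hits = hits.loc[in_panel].copy()
    if hits.empty:
        hits["locus"] = pd.Series(dtype=int)
        hits["lead"] = pd.Series(dtype=bool)
        return hits

    panel = ld_panel.select_variants(hits.index)
    d = panel.imputed_dosages()
    mu, sd = d.mean(axis=0), d.std(axis=0, ddof=0)
    z = (d - mu) / np.where(sd == 0, np.nan, sd)
    n = d.shape[0]

    order = np.lexsort((hits.index.to_numpy(), np.asarray(hits["BP"]),
                        np.asarray(hits["p_combined"], dtype=float)))
    chrom = np.asarray(hits["CHR"])
    bp = np.asarray(hits["BP"], dtype=np.int64)
    locus = np.full(len(hits), -1, dtype=int)
    lead = np.zeros(len(hits), dtype=bool)
    next_locus = 0
    for i in order:
        if locus[i] >= 0:
            continue
        locus[i] = next_locus
        lead[i] = True
        free = (locus < 0) & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window_bp)
        if free.any():
            r = z[:, free].T @ z[:, i] / n
            with np.errstate(invalid="ignore"):
                linked = (r * r) > r2_link
            locus[np.flatnonzero(free)[linked]] = next_locus
        next_locus += 1
    hits["locus"] = locus
    hits["lead"] = lead
    return hits


def nearest_gene(
    chrom, pos: int, genes: pd.DataFrame, max_distance: int = 1_000_000
) -> tuple[str, float]:
    """Nearest gene to a 1-based variant position among BED-style intervals.

    ``genes`` has columns chrom/start/end/name with 0-based half-open
    coordinates. Distance is 0 inside a gene body, negative upstream of the
    start, positive downstream of the end; ties break alphabetically. If no
    gene lies within ``max_distance`` the label is ``"intergenic"``.
    """
    g = genes.loc[genes["chrom"].astype(str) == str(chrom)]
    if ((genes["end"] <= genes["start"])).any():
        bad = genes.loc[genes["end"] <= genes["start"], "name"].tolist()
        raise DataError(f"malformed gene intervals (end <= start): {bad[:5]}")
    if g.empty:
        return "intergenic", float("nan")
    pos0 = int(pos) - 1
    start = g["start"].to_numpy(dtype=np.int64)
    end = g["end"].to_numpy(dtype=np.int64)
    dist = np.where(pos0 < start, pos0 - start,
                    np.where(pos0 >= end, pos0 - end + 1, 0))
    best = np.min(np.abs(dist))
    if best > max_distance:
        return "intergenic", float("nan")
    cand = np.flatnonzero(np.abs(dist) == best)
    names = g["name"].to_numpy()
    pick = cand[np.argsort(names[cand], kind="stable")[0]]
    return str(names[pick]), float(dist[pick])


def annotate_genes(hits: pd.DataFrame, genes: pd.DataFrame,
                   max_distance: int = 1_000_000) -> pd.DataFrame:
    """Add nearest-gene label and signed distance columns to a hit table."""
    out = hits.copy()
    labels, dists = [], []
    for _, row in hits.iterrows():
        lab, d = nearest_gene(row["CHR"], int(row["BP"]), genes, max_distance)
        labels.append(lab)
        dists.append(d)
    out["nearest_gene"] = labels
    out["gene_distance"] = dists
    return out


# --------------------------------------------------------------------------- #
class CrossTraitMeta:
    """Model object pairing two traits' GWAS summary statistics.

    ``sigma=None`` means an identity Z-correlation (disjoint GWAS samples);
    pass ``estimate_sigma(...)`` output for overlapping cohorts.
    """

    def __init__(self, stats1: pd.DataFrame, stats2: pd.DataFrame,
                 sigma: np.ndarray | None = None,
                 labels: tuple[str, str] = ("trait1", "trait2")):
        self.stats1 = stats1
        self.stats2 = stats2
        self.sigma = sigma
        self.labels = labels

    def fit(self, weight_set=None, gw_threshold: float = GENOME_WIDE_P,
            nominal: float = NOMINAL_P) -> "CrossTraitResults":
        hits = combine_traits(self.stats1, self.stats2, sigma=self.sigma,
                              weight_set=weight_set, gw_threshold=gw_threshold,
                              nominal=nominal)
        return CrossTraitResults(self, hits)


class CrossTraitResults:
    """Per-variant combined statistics plus locus/gene annotation helpers."""

    def __init__(self, model: CrossTraitMeta, hits: pd.DataFrame):
        self.model = model
        self.hits = hits

    def significant(self) -> pd.DataFrame:
        """Hits passing both the genome-wide and dual-nominal rules."""
        return self.hits.loc[self.hits["pass_dual"]]

    def assign_loci(self, ld_panel: DosageMatrix, r2_link: float = 0.1,
                    window_bp: int = 500_000) -> pd.DataFrame:
        """Collapse the significant hits to lead loci using an LD panel."""
        self.loci = lead_loci(self.significant(), ld_panel, r2_link, window_bp)
        return self.loci

    def annotate(self, genes: pd.DataFrame, max_distance: int = 1_000_000) -> pd.DataFrame:
        table = getattr(self, "loci", None)
        if table is None:
            table = self.significant()
        self.annotated = annotate_genes(table, genes, max_distance)
        return self.annotated

    def summary(self) -> str:
        h = self.hits
        lines = [
            f"Cross-trait combination: {self.model.labels[0]} x {self.model.labels[1]}",
            f"shared variants: {len(h)}",
            f"genome-wide significant (combined p < {GENOME_WIDE_P:g}): "
            f"{int(h['genome_wide'].sum())}",
            f"passing the dual rule (also both univariate p < {NOMINAL_P:g}): "
            f"{int(h['pass_dual'].sum())}",
        ]
        lead_table = getattr(self, "annotated", getattr(self, "loci", None))
        if lead_table is not None and "lead" in lead_table:
            leads = lead_table.loc[lead_table["lead"]]
            cols = [c for c in ("CHR", "BP", "p1", "p2", "p_combined",
                                "direction", "nearest_gene") if c in leads]
            lines += ["", "lead SNPs (one per locus):",
                      leads[cols].to_string(float_format=lambda v: f"{v:.3g}")]
        return "\n".join(lines)

    def plot_manhattan(self, ax=None):
        """Manhattan-style plot of -log10 combined p by genomic position."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        h = self.hits.sort_values(["CHR", "BP"])
        offset = 0.0
        ticks, labels = [], []
        for chrom, grp in h.groupby("CHR", sort=True):
            x = offset + grp["BP"].to_numpy(dtype=float)
            ax.scatter(x, -np.log10(grp["p_combined"]), s=6,
                       color="tab:blue" if int(chrom) % 2 else "tab:cyan")
            ticks.append(offset + grp["BP"].mean())
            labels.append(str(chrom))
            offset = x.max() + 1e6
        ax.axhline(-np.log10(GENOME_WIDE_P), color="red", ls=":")
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("$-\\log_{10}$ combined p")
        return ax
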