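"""Logistic association of polygenic scores with binary treatment outcomes.

For each p-value cutoff the (z-scored) score enters a covariate-adjusted
logistic model of response or remission; the incremental Nagelkerke pseudo-R2
of the score, the per-SD odds ratio and its Wald p are recorded, the cutoff
grid is corrected by Benjamini-Hochberg, and the score at the optimal cutoff
(smallest raw p, ties to the smaller cutoff) is profiled by quartile odds
ratios against the lowest-score quartile.

The user-facing entry point is the :class:`PgsAssociation` model object,
whose :meth:`~PgsAssociation.fit` returns a :class:`PgsAssociationResults`
carrying the threshold scan, the quartile table and plotting helpers. The
underlying primitives (``fit_logistic``, ``nagelkerke_r2``, ``delta_r2``,
``bh_adjust``, ``scan_thresholds``, ``quartile_ors``) are module functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import DataError
from .pgscore import PgsProfile, score_column

__all__ = [
    "LogisticFit",
    "AssocScan",
    "SeparationError",
    "fit_logistic",
    "nagelkerke_r2",
    "delta_r2",
    "delta_r2_from_designs",
    "bh_adjust",
    "scan_thresholds",
    "quartile_ors",
    "PgsAssociation",
    "PgsAssociationResults",
]


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfect or quasi separation)."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit summary."""

    params: pd.Series
    bse: pd.Series
    llf: float
    nobs: int
    converged: bool

    def __post_init__(self) -> None:
        if self.llf > 1e-9:
            raise DataError("log-likelihood of a Bernoulli model cannot be positive")


def fit_logistic(y, X) -> LogisticFit:
    """IRLS (Newton) maximum-likelihood logistic regression.

    ``X`` must include an intercept column. Perfect separation raises
    :class:`SeparationError` instead of returning runaway coefficients.
    """
    y = np.asarray(y, dtype=float)
    Xdf = pd.DataFrame(X).astype(float)
    if y.ndim != 1 or len(y) != len(Xdf):
        raise DataError("y and X must be aligned")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("y must be binary 0/1")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # diverging fits flagged below
            res = sm.Logit(y, Xdf).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"logistic fit failed (likely separation or collinearity): {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(
            "IRLS did not converge within 100 iterations "
            "(perfect or quasi separation, or collinear design)"
        )
    if np.max(np.abs(res.params)) > 1e3:
        raise SeparationError("runaway coefficients indicate quasi-separation")
    return LogisticFit(
        params=pd.Series(res.params, index=Xdf.columns),
        bse=pd.Series(res.bse, index=Xdf.columns),
        llf=float(res.llf),
        nobs=int(res.nobs),
        converged=True,
    )


def _null_llf(y: np.ndarray) -> float:
    """Closed-form intercept-only Bernoulli log-likelihood."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke's normalized likelihood-ratio pseudo-R2.

    ``R2 = (1 - exp((2/n)(ll_null - ll_model))) / (1 - exp((2/n) ll_null))``.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if ll_model < ll_null - 1e-8:
        raise DataError("ll_model < ll_null: models are not nested as assumed")
    ll_model = min(ll_model, 0.0)
    denom = 1.0 - np.exp((2.0 / n) * ll_null)
    if denom <= 0.0:
        return 0.0  # degenerate outcome (all 0 or all 1)
    num = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    return float(np.clip(num / denom, 0.0, 1.0))


def delta_r2(full: LogisticFit, covonly: LogisticFit, null: LogisticFit) -> float:
    """Incremental Nagelkerke R2 of the score term: R2(full) - R2(cov-only)."""
    if not (full.nobs == covonly.nobs == null.nobs):
        raise DataError("models compare different sample sizes")
    n = full.nobs
    r2_full = nagelkerke_r2(full.llf, null.llf, n)
    r2_cov = nagelkerke_r2(covonly.llf, null.llf, n)
    d = r2_full - r2_cov
    if d < -1e-10:
        raise DataError("negative delta-R2 beyond tolerance: models not nested")
    return max(d, 0.0)


def delta_r2_from_designs(y: np.ndarray, score: np.ndarray, covs: np.ndarray) -> float:
    """Convenience: incremental Nagelkerke R2 of ``score`` over ``covs``."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    const = np.ones((n, 1))
    covs = np.asarray(covs, dtype=float).reshape(n, -1)
    ll_null = _null_llf(y)
    X_cov = np.hstack([const, covs])
    ll_cov = fit_logistic(y, X_cov).llf if covs.shape[1] else ll_null
    X_full = np.hstack([X_cov, np.asarray(score, dtype=float).reshape(n, 1)])
    ll_full = fit_logistic(y, X_full).llf
    return nagelkerke_r2(ll_full, ll_null, n) - nagelkerke_r2(ll_cov, ll_null, n)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------- #
def build_design(pheno: pd.DataFrame, covariates: list) -> pd.DataFrame:
    """Covariate design matrix with intercept; categoricals become
    reference-coded indicator columns."""
    cols = [pd.Series(1.0, index=pheno.index, name="const")]
    for c in covariates:
        if c not in pheno.columns:
            raise DataError(f"unknown covariate: {c}")
        s = pheno[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            cols.extend(dummies[col] for col in dummies.columns)
        else:
            cols.append(s.astype(float))
    return pd.concat(cols, axis=1)


@dataclass
class AssocScan:
    """Per-threshold association results for one outcome x one trait."""

    table: pd.DataFrame  # P_T, n_snps, coef, or_, p, delta_r2, p_fdr
    optimal: float       # P_T attaining the minimum raw p
    outcome: str = ""
    trait: str = ""
    covariates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        if (t["delta_r2"] < -1e-12).any() or (t["delta_r2"] > 1).any():
            raise DataError("delta_r2 outside [0, 1]")
        if (t["p_fdr"] + 1e-12 < t["p"]).any():
            raise DataError("adjusted p below raw p")

    @property
    def optimal_row(self) -> pd.Series:
        return self.table.loc[self.table["P_T"] == self.optimal].iloc[0]


def scan_thresholds(
    profile: PgsProfile,
    pheno: pd.DataFrame,
    covariates: list,
    outcome: str,
    standardize: bool = True,
    trait: str = "",
) -> AssocScan:
    """Fit one covariate-adjusted logistic model per threshold column.

    The score is z-scored before entry (so coefficients are per SD) unless
    ``standardize=False``. Empty threshold columns are skipped with a
    warning. BH adjustment runs across the scanned thresholds of this one
    outcome-by-trait family. Optimal threshold: smallest raw p, ties to the
    smaller cutoff.
    """
    if outcome not in pheno.columns:
        raise DataError(f"outcome column {outcome!r} missing from phenotypes")
    common = profile.scores.index.intersection(pheno.index)
    if len(common) == 0:
        raise DataError("no shared samples between profile and phenotypes")
    scores = profile.scores.loc[common]
    ph = pheno.loc[common]
    y = np.asarray(ph[outcome], dtype=float)
    X_cov = build_design(ph, covariates)
    ll_null = _null_llf(y)
    n = len(y)
    cov_fit_llf = fit_logistic(y, X_cov).llf if len(covariates) else ll_null
    r2_cov = nagelkerke_r2(cov_fit_llf, ll_null, n)

    rows = []
    for t in (profile.grid or sorted(profile.m_t)):
        col = score_column(t)
        if profile.m_t.get(t, 0) == 0:
            warnings.warn(f"threshold {t:g} has no SNPs; skipped", stacklevel=2)
            continue
        s = np.asarray(scores[col], dtype=float)
        if standardize:
            sd = s.std(ddof=0)
            if sd == 0:
                warnings.warn(f"constant score at threshold {t:g}; skipped", stacklevel=2)
                continue
            s = (s - s.mean()) / sd
        X = X_cov.copy()
        X["PGS"] = s
        fit = fit_logistic(y, X)
        coef = float(fit.params["PGS"])
        se = float(fit.bse["PGS"])
        from scipy.stats import norm as _norm

        pval = float(2.0 * _norm.sf(abs(coef / se)))
        dr2 = max(nagelkerke_r2(fit.llf, ll_null, n) - r2_cov, 0.0)
        rows.append(
            {"P_T": t, "n_snps": profile.m_t[t], "coef": coef, "se": se,
             "or_": float(np.exp(coef)), "p": pval, "delta_r2": dr2}
        )
    if not rows:
        raise DataError("no usable threshold columns")
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_adjust(table["p"].to_numpy())
    # ties resolve to the smaller P_T because the table is in increasing order
    optimal = float(table.loc[table["p"].idxmin(), "P_T"])
    return AssocScan(table, optimal, outcome=outcome, trait=trait,
                     covariates=list(covariates))


def quartile_ors(
    score: pd.Series, pheno: pd.DataFrame, covariates: list, outcome: str
) -> pd.DataFrame:
    """Odds ratios of the outcome for score quartiles Q2-Q4 vs Q1.

    Samples are binned by the empirical quartile cut-points (boundary ties
    go to the lower quartile); a logistic model with Q2/Q3/Q4 indicators and
    covariates yields Wald ORs, 95% CIs and p-values. Quartiles whose
    outcomes are constant are flagged unstable.
    """
    common = score.index.intersection(pheno.index)
    if len(common) < 40:
        raise DataError("need at least 40 samples (~10 per quartile)")
    s = np.asarray(score.loc[common], dtype=float)
    ph = pheno.loc[common]
    y = np.asarray(ph[outcome], dtype=float)
    cuts = np.quantile(s, [0.25, 0.5, 0.75])
    quart = (s[:, None] > cuts[None, :]).sum(axis=1)  # 0..3; ties to lower

    X = build_design(ph, covariates)
    for q in (1, 2, 3):
        X[f"Q{q + 1}"] = (quart == q).astype(float)
    fit = fit_logistic(y, X)

    from scipy.stats import norm as _norm

    rows = [{"quartile": "Q1", "n": int((quart == 0).sum()), "or_": 1.0,
             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "unstable": False}]
    for q in (1, 2, 3):
        name = f"Q{q + 1}"
        b, se = float(fit.params[name]), float(fit.bse[name])
        yq = y[quart == q]
        rows.append(
            {
                "quartile": name,
                "n": int((quart == q).sum()),
                "or_": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.959963984540054 * se)),
                "ci_high": float(np.exp(b + 1.959963984540054 * se)),
                "p": float(2.0 * _norm.sf(abs(b / se))),
                "unstable": bool(yq.size == 0 or yq.min() == yq.max()),
            }
        )
    return pd.DataFrame(rows).set_index("quartile")


# --------------------------------------------------------------------------- #
class PgsAssociation:
    """Model object tying a threshold-series score profile to an outcome.

    Parameters
    ----------
    profile
        :class:`~pgxpersona.pgscore.PgsProfile` of per-sample scores.
    pheno
        Phenotype/covariate table indexed by sample id containing the
        outcome column and every requested covariate.
    outcome
        Name of the binary outcome column (e.g. ``"RESPONSE"``).
    covariates
        Covariate column names entered in every model.
    """

    def __init__(self, profile: PgsProfile, pheno: pd.DataFrame, outcome: str,
                 covariates: list, standardize: bool = True):
        self.profile = profile
        self.pheno = pheno
        self.outcome = outcome
        self.covariates = list(covariates)
        self.standardize = standardize

    @classmethod
    def from_files(cls, profile_path, pheno_path, outcome, covariates, **kw):
        from .cohortio import read_phenotypes, read_profile

        return cls(read_profile(profile_path), read_phenotypes(pheno_path),
                   outcome, covariates, **kw)

    def fit(self) -> "PgsAssociationResults":
        scan = scan_thresholds(self.profile, self.pheno, self.covariates,
                               self.outcome, standardize=self.standardize,
                               trait=self.profile.trait)
        opt_scores = self.profile.column(scan.optimal)
        qtable = quartile_ors(opt_scores, self.pheno, self.covariates, self.outcome)
        return PgsAssociationResults(self, scan, qtable)


class PgsAssociationResults:
    """Fitted threshold scan plus quartile profiling at the optimal cutoff."""

    def __init__(self, model: PgsAssociation, scan: AssocScan,
                 quartile_table: pd.DataFrame):
        self.model = model
        self.scan = scan
        self.quartile_table = quartile_table

    @property
    def optimal_threshold(self) -> float:
        return self.scan.optimal

    @property
    def table(self) -> pd.DataFrame:
        return self.scan.table

    def summary(self) -> str:
        t = self.scan.table
        lines = [
            f"PGS association scan — outcome: {self.scan.outcome}"
            + (f", trait: {self.scan.trait}" if self.scan.trait else ""),
            f"covariates: {', '.join(self.scan.covariates) or '(none)'}",
            "",
            t.assign(delta_r2_pct=t["delta_r2"] * 100).to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
            "",
            f"optimal P_T = {self.scan.optimal:g} "
            f"(raw p = {self.scan.optimal_row['p']:.3g}, "
            f"delta-R2 = {self.scan.optimal_row['delta_r2'] * 100:.2f}%)",
            "",
            "Quartile odds ratios at the optimal threshold (Q1 reference):",
            self.quartile_table.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def plot_delta_r2(self, ax=None):
        """Bar plot of per-threshold incremental Nagelkerke R2 (percent)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.scan.table
        ax.bar([f"{x:g}" for x in t["P_T"]], t["delta_r2"] * 100)
        ax.set_xlabel("discovery p-value threshold $P_T$")
        ax.set_ylabel("Nagelkerke $\\Delta R^2$ (%)")
        ax.set_title(f"{self.scan.trait} vs {self.scan.outcome}".strip(" vs"))
        return ax

    def plot_quartile_ors(self, ax=None):
        """Line plot of quartile ORs with 95% CI bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        q = self.quartile_table
        xs = np.arange(len(q))
        ax.errorbar(
            xs, q["or_"],
            yerr=[(q["or_"] - q["ci_low"]).fillna(0), (q["ci_high"] - q["or_"]).fillna(0)],
            marker="o",
        )
        ax.axhline(1.0, ls=":", color="grey")
        ax.set_xticks(xs, q.index)
        ax.set_ylabel("odds ratio vs Q1")
        return ax
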