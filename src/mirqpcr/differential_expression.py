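"""Two-group differential expression with empirical-Bayes variance moderation.

Each miRNA g is fitted with an ordinary two-sample model on the −ΔCt scale:
β̂_g = mean(test) − mean(reference) is the log2 fold change, s_g² the pooled
within-group variance on d_g = n₁+n₂−2 degrees of freedom, and
v_g = 1/n₁ + 1/n₂ the unscaled variance of β̂_g.

With only a handful of samples per group the per-miRNA variances are noisy.
The moderated t shrinks them toward a common prior: assuming
s_g² | σ_g² ~ σ_g² χ²_{d_g}/d_g and σ_g² ~ s₀² d₀/χ²_{d₀} (a scaled inverse
chi-square prior), the posterior variance is

    s̃_g² = (d₀ s₀² + d_g s_g²) / (d₀ + d_g)

and t̃_g = β̂_g / √(s̃_g² v_g) follows a t distribution on d₀ + d_g degrees
of freedom under the null.  The hyperparameters (d₀, s₀²) are estimated by
moment matching on log s_g²: under the model, e_g = log s_g² − ψ(d_g/2) +
log(d_g/2) has mean log s₀² − ψ(d₀/2) + log(d₀/2) and variance
ψ′(d_g/2) + ψ′(d₀/2), where ψ and ψ′ are the digamma and trigamma
functions.  Excess dispersion of e_g beyond its sampling variance determines
d₀; no excess dispersion gives d₀ = ∞ (all variances shrunk to s₀², t̃
referred to the normal distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .errors import DesignError
from .normalization import NormalizedMatrix
from .plate_io import SampleSheet


@dataclass
class DesignSpec:
    """Two-group contrast: ``contrast = (test_group, reference_group)``."""

    group_of: dict[str, str]
    contrast: tuple[str, str]
    alpha: float = 0.05

    def __post_init__(self):
        test, ref = self.contrast
        if test == ref:
            raise DesignError("contrast groups must differ")
        for g in (test, ref):
            n = sum(1 for v in self.group_of.values() if v == g)
            if n < 2:
                raise DesignError(
                    f"group {g!r} has {n} sample(s); >=2 required per group"
                )
        if not 0 < self.alpha < 1:
            raise DesignError("alpha must be in (0, 1)")

    @classmethod
    def from_sample_sheet(
        cls, sheet: SampleSheet, contrast: tuple[str, str] | None = None, alpha: float = 0.05
    ) -> "DesignSpec":
        groups = sheet.groups
        if contrast is None:
            if len(groups) != 2:
                raise DesignError(
                    f"sample sheet has groups {groups}; specify an explicit contrast"
                )
            contrast = (groups[1], groups[0])
        return cls(dict(sheet.group_of), tuple(contrast), alpha)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]


@dataclass
class FitResult:
    """Per-miRNA two-sample fit; ``table`` columns: beta, s2, df, v, n_test, n_ref."""

    table: pd.DataFrame
    dropped: list[str] = field(default_factory=list)


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: ``d0`` degrees of freedom (may be +inf), ``s02`` variance."""

    d0: float
    s02: float

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError("prior df d0 must be positive")
        if not self.s02 > 0:
            raise ValueError("prior variance s02 must be positive")


def fit_group_model(nm: NormalizedMatrix, design: DesignSpec) -> FitResult:
    """Complete-case per-miRNA two-sample fit.

    A miRNA needs at least two non-missing values in each group; others are
    dropped and listed in :attr:`FitResult.dropped`.
    """
    test_s = [s for s in design.samples_in(design.contrast[0]) if s in nm.values.columns]
    ref_s = [s for s in design.samples_in(design.contrast[1]) if s in nm.values.columns]
    if len(test_s) < 2 or len(ref_s) < 2:
        raise DesignError(
            f"need >=2 usable samples per group, got {len(test_s)} test / {len(ref_s)} reference"
        )
    tv = nm.values[test_s].to_numpy()
    rv = nm.values[ref_s].to_numpy()
    n1 = np.sum(~np.isnan(tv), axis=1)
    n2 = np.sum(~np.isnan(rv), axis=1)
    usable = (n1 >= 2) & (n2 >= 2)
    dropped = [m for m, u in zip(nm.mirna_ids, usable) if not u]
    if not usable.any():
        raise DesignError("no miRNA has >=2 non-missing values in both groups")

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # rows later dropped as unusable legitimately have <2 values per group
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_t = np.nanmean(tv, axis=1)
        mean_r = np.nanmean(rv, axis=1)
        var_t = np.nanvar(tv, axis=1, ddof=1)
        var_r = np.nanvar(rv, axis=1, ddof=1)
    beta = mean_t - mean_r
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n1 - 1) * var_t + (n2 - 1) * var_r) / df
        v = 1.0 / n1 + 1.0 / n2

    table = pd.DataFrame(
        {
            "beta": beta,
            "s2": s2,
            "df": df.astype(float),
            "v": v,
            "n_test": n1,
            "n_ref": n2,
        },
        index=pd.Index(nm.mirna_ids, name="mirna_id"),
    ).loc[usable]
    return FitResult(table=table, dropped=dropped)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_moderation(fit: FitResult, min_s2: float = 1e-12) -> ModerationParams:
    """Estimate the variance prior (d0, s02) by moment matching on log s².

    Rows with zero (or numerically zero) sample variance carry no usable
    log-variance information and are excluded from hyperparameter
    estimation; they are still moderated downstream.  When the empirical
    spread of log s² does not exceed its expected sampling variance, the
    data show no variance heterogeneity and d0 = +inf.
    """
    tbl = fit.table
    ok = (tbl["df"] > 0) & (tbl["s2"] > min_s2)
    s2 = tbl.loc[ok, "s2"].to_numpy()
    df = tbl.loc[ok, "df"].to_numpy()
    if len(s2) < 2:
        raise DesignError(
            "need >=2 miRNAs with positive residual variance to estimate moderation "
            "(data may have exact zero variance everywhere)"
        )
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return ModerationParams(d0=d0, s02=s02)


def posterior_variance(s2: np.ndarray, df: np.ndarray, params: ModerationParams) -> np.ndarray:
    """Shrink residual variances toward the prior: (d0*s02 + df*s2)/(d0 + df)."""
    if math.isinf(params.d0):
        return np.full_like(np.asarray(s2, dtype=float), params.s02)
    return (params.d0 * params.s02 + df * s2) / (params.d0 + df)


def moderated_t_table(
    fit: FitResult,
    params: ModerationParams,
    design: DesignSpec,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Moderated t statistics, p values and BH-adjusted significance calls.

    ``params.d0 = 0`` is accepted as the unmoderated limit (classic pooled
    two-sample t per row); ``d0 = inf`` refers every statistic to the normal
    distribution with variance ``s02``.  Output is sorted by p value.
    """
    tbl = fit.table
    s2 = tbl["s2"].to_numpy()
    df = tbl["df"].to_numpy()
    d0, s02 = params.d0, params.s02

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = tbl["beta"].to_numpy() / np.sqrt(s2_post * tbl["v"].to_numpy())
        p = 2.0 * stats.norm.sf(np.abs(t))
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df) if d0 > 0 else s2
        df_total = df + d0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = tbl["beta"].to_numpy() / np.sqrt(s2_post * tbl["v"].to_numpy())
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero posterior variance with zero effect: no evidence either way
    p = np.where(np.isnan(p), 1.0, p)

    adj = adjust_pvalues(p, method=adjust)
    out = pd.DataFrame(
        {
            "logFC": tbl["beta"].to_numpy(),
            "t": t,
            "p_value": p,
            "adj_p_value": adj,
            "significant": adj < design.alpha,
            "df_total": df_total,
            "s2_post": s2_post,
            "n_test": tbl["n_test"].to_numpy(),
            "n_ref": tbl["n_ref"].to_numpy(),
        },
        index=tbl.index,
    )
    return out.sort_values("p_value", kind="mergesort")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, order-preserving.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment; ``method`` in {"bh", "bonferroni"}."""
    if method == "bh":
        return benjamini_hochberg(pvalues)
    if method == "bonferroni":
        p = np.asarray(pvalues, dtype=float)
        if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
            raise ValueError("p values must lie in [0, 1]")
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def differential_expression(
    nm: NormalizedMatrix, design: DesignSpec, adjust: str = "bh"
) -> tuple[pd.DataFrame, FitResult, ModerationParams]:
    """Fit, moderate and test in one call; returns (DE table, fit, prior)."""
    fit = fit_group_model(nm, design)
    params = estimate_moderation(fit)
    table = moderated_t_table(fit, params, design, adjust=adjust)
    return table, fit, params


# ---------------------------------------------------------------------------
# hierarchical clustering of significant miRNAs


@dataclass
class ClusteringResult:
    """Row/column agglomeration of the z-scored significant-miRNA matrix."""

    matrix: pd.DataFrame          # z-scored rows, reordered
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row; constant rows map to all-zero."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return values.sub(mean, axis=0).div(sd, axis=0)


def hierarchical_clustering(values: pd.DataFrame) -> ClusteringResult | None:
    """Complete-linkage Euclidean agglomeration of z-scored rows and columns.

    ``values`` is the normalized matrix restricted to significant miRNAs.
    Returns ``None`` (heatmap skipped) when fewer than two rows or columns
    are available; deterministic given its input.
    """
    from scipy.cluster import hierarchy

    if values.shape[0] < 2 or values.shape[1] < 2:
        return None
    z = zscore_rows(values.astype(float)).fillna(0.0)
    row_link = hierarchy.linkage(z.to_numpy(), method="complete", metric="euclidean")
    col_link = hierarchy.linkage(z.to_numpy().T, method="complete", metric="euclidean")
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusteringResult(
        matrix=z.loc[row_order, col_order],
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=row_order,
        col_order=col_order,
    )
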