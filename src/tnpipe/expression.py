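"""RPKM quantification and negative-binomial differential expression.

The two-group test is an exact conditional NB test: per-sample counts are
modelled as NB with a common per-gene concentration scaled by sample size
factors (median-of-ratios normalization); group sums are moment-matched to
NB laws, and the two-sided p-value sums the probabilities of all splits of
the observed total that are no more probable than the observed split.
Per-gene dispersions are method-of-moments estimates shrunk toward a fitted
mean-dispersion trend a0 + a1/mu.

DEG selection applies asymmetric thresholds: upregulated means log2FC > 1 at
p < 0.05, downregulated means log2FC < -1 at p < 0.001, with an expression
floor requiring mean RPKM > 0.5 in the higher group.  Raw p-values drive the
selection (BH q-values are reported alongside for transparency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, norm, poisson
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEGThresholds",
    "NBTestParams",
    "compute_rpkm",
    "size_factors",
    "estimate_dispersions",
    "nb_test",
    "select_degs",
    "relative_expression",
    "UP",
    "DOWN",
    "NONE",
]

UP = "UP"
DOWN = "DOWN"
NONE = "NONE"

TUMOR = "tumor"
CONTROL = "control"

#: pseudocount (RPKM units and normalized-count units) guarding log ratios
EPSILON = 0.25


@dataclass
class CountMatrix:
    """Raw RNA counts (genes x samples) with gene lengths and group labels.

    ``total_mapped`` may be provided per sample (e.g. counting reads mapped
    outside the gene model); when None, column sums of ``counts`` are used.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    groups: pd.Series
    total_mapped: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(c.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        self.groups = self.groups.reindex(c.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.groups.unique()) - {TUMOR, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if self.total_mapped is not None:
            self.total_mapped = self.total_mapped.reindex(c.columns)
            if self.total_mapped.isna().any():
                raise ValueError("total_mapped missing for some samples")

    @property
    def mapped(self) -> pd.Series:
        if self.total_mapped is not None:
            return self.total_mapped.astype(float)
        return self.counts.sum(axis=0).astype(float)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def compute_rpkm(m: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm(g, s) = counts(g, s) * 1e9 / (length(g) * total_mapped(s)).
    """
    tm = m.mapped
    if (tm <= 0).any():
        raise ValueError("total mapped reads must be positive in every sample")
    return m.counts.div(m.gene_lengths, axis=0).div(tm, axis=1) * 1e9


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference sample)."""
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(x)
    usable = np.isfinite(logs).all(axis=1)
    if usable.sum() < 10:
        # degenerate matrix: fall back to library-size ratios
        tot = x.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
        return pd.Series(sf, index=counts.columns)
    ref = logs[usable].mean(axis=1)
    sf = np.exp(np.median(logs[usable] - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


@dataclass(frozen=True)
class NBTestParams:
    trend_weight: float = 0.7
    pseudocount: float = 0.5
    exact_cap: int = 200_000
    min_dispersion: float = 1e-8
    max_dispersion: float = 10.0


def estimate_dispersions(
    m: CountMatrix,
    sf: pd.Series,
    params: NBTestParams = NBTestParams(),
) -> pd.Series:
    """Per-gene NB dispersion: method of moments shrunk toward a trend.

    On the normalized scale q = K/sf with group mean q_bar, the expected
    within-group sample variance is q_bar * mean(1/sf) + alpha * q_bar^2,
    which is solved for alpha per gene and pooled across the two groups.
    A mean-dispersion trend alpha(mu) = a0 + a1/mu is fitted by trimmed
    least squares over well-expressed genes, and the gene estimate is the
    convex blend trend_weight * trend + (1 - trend_weight) * raw.
    """
    q = m.counts.div(sf, axis=1)
    inv_sf = float((1.0 / sf).mean())
    num = np.zeros(len(q))  # pooled within-group SS
    mu_sq = np.zeros(len(q))
    mu_all = np.zeros(len(q))
    df = 0
    for grp in (TUMOR, CONTROL):
        cols = m.samples_in(grp)
        mg = len(cols)
        sub = q[cols].to_numpy(dtype=float)
        mean = sub.mean(axis=1)
        ss = ((sub - mean[:, None]) ** 2).sum(axis=1)
        num += ss
        # E[mean^2] = mu^2 + Var(mean); subtract the plug-in Var(mean)
        mu_sq += (mg - 1) * np.maximum(mean**2 - ss / (mg * (mg - 1)), 0.0)
        mu_all += mg * mean
        df += mg - 1
    mu_all /= len(m.counts.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = num / max(df, 1)
        mean_sq = mu_sq / max(df, 1)
        alpha_raw = (v - mu_all * inv_sf) / mean_sq
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, 0.0)
    alpha_raw = np.clip(alpha_raw, 0.0, params.max_dispersion)

    # trend fit on well-expressed genes, one trimming pass
    mask = mu_all > 5
    if mask.sum() >= 20:
        a0, a1 = _fit_trend(mu_all[mask], alpha_raw[mask])
    else:
        a0, a1 = float(np.median(alpha_raw[alpha_raw > 0]) if (alpha_raw > 0).any() else 0.01), 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu_all, 1e-8)
    trend = np.clip(trend, params.min_dispersion, params.max_dispersion)

    w = params.trend_weight
    blended = w * trend + (1.0 - w) * np.clip(alpha_raw, 0.0, 5.0 * trend + 0.1)
    alpha = np.clip(blended, params.min_dispersion, params.max_dispersion)
    return pd.Series(alpha, index=m.counts.index)


def _fit_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    # plain OLS: the raw estimates are right-skewed, so residual trimming
    # would bias the trend downward; extreme values are tamed only by the
    # dispersion cap applied upstream
    x = 1.0 / mu
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, alpha, rcond=None)
    a0 = float(max(coef[0], 0.0))
    a1 = float(max(coef[1], 0.0))
    if a0 == 0.0 and a1 == 0.0:
        a0 = float(max(np.median(alpha), 1e-4))
    return a0, a1


def _group_sum_logpmf(k: np.ndarray, mean: float, var: float):
    """log pmf of a moment-matched NB (Poisson when var <= mean)."""
    if mean <= 0:
        out = np.full(np.shape(k), -np.inf)
        out[np.asarray(k) == 0] = 0.0
        return out
    if var <= mean * (1 + 1e-9):
        return poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return nbinom.logpmf(k, r, p)


def nb_test(
    m: CountMatrix,
    params: NBTestParams = NBTestParams(),
) -> pd.DataFrame:
    """Two-sided NB test of equal group means per gene.

    Returns a DataFrame indexed by gene with columns base_mean, log2fc
    (tumor vs control, pseudocount-stabilized normalized means), p, q
    (BH-adjusted), dispersion, all_zero.  Requires >= 2 samples per group.
    """
    t_cols = m.samples_in(TUMOR)
    c_cols = m.samples_in(CONTROL)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need at least 2 samples per group")

    sf = size_factors(m.counts)
    alpha = estimate_dispersions(m, sf, params)
    q = m.counts.div(sf, axis=1)

    s_t = float(sf[t_cols].sum())
    s_c = float(sf[c_cols].sum())
    ss_t = float((sf[t_cols] ** 2).sum())
    ss_c = float((sf[c_cols] ** 2).sum())

    k_t = m.counts[t_cols].sum(axis=1).to_numpy(dtype=np.int64)
    k_c = m.counts[c_cols].sum(axis=1).to_numpy(dtype=np.int64)
    qbar_t = q[t_cols].mean(axis=1).to_numpy(dtype=float)
    qbar_c = q[c_cols].mean(axis=1).to_numpy(dtype=float)

    n_genes = len(m.counts)
    pvals = np.ones(n_genes)
    c = params.pseudocount
    lfc = np.log2((qbar_t + c) / (qbar_c + c))
    all_zero = (k_t + k_c) == 0
    lfc[all_zero] = 0.0

    a = alpha.to_numpy(dtype=float)
    for i in range(n_genes):
        total = int(k_t[i] + k_c[i])
        if total == 0:
            continue
        q0 = total / (s_t + s_c)
        mu_t = q0 * s_t
        mu_c = q0 * s_c
        var_t = mu_t + a[i] * q0**2 * ss_t
        var_c = mu_c + a[i] * q0**2 * ss_c
        if total <= params.exact_cap:
            ks = np.arange(total + 1)
            logp = _group_sum_logpmf(ks, mu_t, var_t) + _group_sum_logpmf(
                total - ks, mu_c, var_c
            )
            log_denom = logsumexp(logp)
            obs = logp[k_t[i]]
            sel = logp <= obs + 1e-8
            pvals[i] = float(np.exp(logsumexp(logp[sel]) - log_denom))
        else:
            # normal approximation to the conditional law of the tumor sum
            w = var_t * var_c / (var_t + var_c)
            mean_cond = mu_t + (total - mu_t - mu_c) * var_t / (var_t + var_c)
            zstat = (k_t[i] - mean_cond) / np.sqrt(w)
            pvals[i] = float(min(1.0, 2.0 * norm.sf(abs(zstat))))
    pvals = np.clip(pvals, 0.0, 1.0)

    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "base_mean": (qbar_t * len(t_cols) + qbar_c * len(c_cols))
            / (len(t_cols) + len(c_cols)),
            "log2fc": lfc,
            "p": pvals,
            "q": qvals,
            "dispersion": a,
            "all_zero": all_zero,
        },
        index=m.counts.index,
    )


@dataclass(frozen=True)
class DEGThresholds:
    """Asymmetric DEG selection thresholds."""

    up_p: float = 0.05
    down_p: float = 0.001
    lfc: float = 1.0
    rpkm_floor: float = 0.5


def select_degs(
    results: pd.DataFrame,
    rpkm: pd.DataFrame,
    groups: pd.Series,
    thresholds: DEGThresholds = DEGThresholds(),
) -> pd.DataFrame:
    """Classify genes as UP / DOWN / NONE under the asymmetric thresholds.

    A gene passes the expression floor only if its mean RPKM in the
    higher-expressed group exceeds ``rpkm_floor``.  UP requires log2fc >
    ``lfc`` and p < ``up_p``; DOWN requires log2fc < -``lfc`` and p <
    ``down_p``.  Returns results joined with mean RPKMs and a ``direction``
    column; selection is idempotent and monotone in the p cut-offs.
    """
    t_cols = list(groups.index[groups == TUMOR])
    c_cols = list(groups.index[groups == CONTROL])
    mean_t = rpkm[t_cols].mean(axis=1).reindex(results.index)
    mean_c = rpkm[c_cols].mean(axis=1).reindex(results.index)
    floor_ok = np.maximum(mean_t, mean_c) > thresholds.rpkm_floor

    up = floor_ok & (results["log2fc"] > thresholds.lfc) & (results["p"] < thresholds.up_p)
    down = (
        floor_ok & (results["log2fc"] < -thresholds.lfc) & (results["p"] < thresholds.down_p)
    )
    direction = np.where(up, UP, np.where(down, DOWN, NONE))
    out = results.copy()
    out["mean_rpkm_tumor"] = mean_t
    out["mean_rpkm_control"] = mean_c
    out["direction"] = direction
    return out


def relative_expression(
    gene: str,
    rpkm: pd.DataFrame,
    sample: str,
    controls,
    eps: float = EPSILON,
) -> float:
    """Per-sample log2 fold change of RPKM against the control mean."""
    controls = list(controls)
    if not controls:
        raise ValueError("controls must be non-empty")
    if gene not in rpkm.index:
        raise KeyError(f"gene {gene!r} absent from the expression matrix")
    s = float(rpkm.at[gene, sample])
    cmean = float(rpkm.loc[gene, controls].mean())
    return float(np.log2((s + eps) / (cmean + eps)))
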