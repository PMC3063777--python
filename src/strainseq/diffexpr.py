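"""Differential expression for two-strain digital read counts.

The model: gene counts y_gj are negative binomial with a *common*
dispersion phi shared by all genes (variance = mu + phi*mu^2).  Library
composition differences are corrected with upper-quartile scaling: each
sample's factor derives from the 75th percentile of its nonzero gene
counts relative to its total unique reads, normalized so factors have
geometric mean 1, giving effective sizes M_j = f_j * N_j.

Inference follows the classic exact-test workflow: counts are mapped to
pseudocounts at a common library size M* by NB quantile matching, the
common dispersion is maximized under the conditional likelihood of each
group's pseudocounts given their sum (a negative-hypergeometric /
Dirichlet-multinomial form), and each gene is tested by conditioning the
two rounded group sums on their total and summing the probabilities of
all outcomes no more probable than the observed one.  A single-factor
Poisson likelihood-ratio test with the same offsets is provided as the
comparator (it is anti-conservative on overdispersed data).  Multiple
testing is handled with Storey q-values (pi0-adjusted FDR).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .align_count import CountMatrix
from .gene_models import GeneModelSet

Q_THRESHOLD = 0.01
LOW_COUNT_LOG2 = -20.0
_TIE_TOL = 1e-7  # outcomes with prob <= p_obs*(1+tol) count as "as extreme"


@dataclass
class NormalizationFactors:
    """Per-sample upper-quartile normalization: N_j, u_j, f_j, M_j = f_j*N_j."""

    lib_sizes: pd.Series
    upper_quartiles: pd.Series
    factors: pd.Series
    effective_sizes: pd.Series

    @property
    def m_star(self) -> float:
        """Common library size: geometric mean of the effective sizes."""
        return float(np.exp(np.log(self.effective_sizes.to_numpy(float)).mean()))


@dataclass
class DispersionEstimate:
    """Common NB dispersion phi (delta = phi/(1+phi)) with its profile."""

    phi: float
    delta: float
    profile: pd.DataFrame  # columns delta, loglik
    pseudocounts: pd.DataFrame | None = None
    m_star: float | None = None


def strain_groups(samples: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Sample ids per strain, B6 first (the fold-change numerator)."""
    b6 = list(samples.index[samples["strain"] == "B6"])
    d2 = list(samples.index[samples["strain"] == "D2"])
    return b6, d2


# ---------------------------------------------------------------------------
# normalization


def total_count_scale(cm: CountMatrix) -> pd.DataFrame:
    """Counts per total unique reads in megabases: y_gj / (N_j / 1e6).

    A diagnostic scaling only; testing uses upper-quartile factors.
    """
    n = cm.lib_sizes.astype(float)
    if (n <= 0).any():
        raise ValueError("total_count_scale requires N_j > 0 for every sample")
    return cm.counts / (n / 1e6)


def upper_quartile_factors(cm: CountMatrix) -> NormalizationFactors:
    """Upper-quartile scale factors, normalized to geometric mean 1.

    u_j is the 75th percentile (linear interpolation) of the counts of genes
    with y_gj > 0 in sample j.  Raises ``ValueError`` for an all-zero sample.
    """
    uq = {}
    for s in cm.sample_ids:
        col = cm.counts[s].to_numpy(float)
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {s} has no nonzero gene counts")
        uq[s] = float(np.percentile(nz, 75))
    u = pd.Series(uq)[cm.sample_ids]
    n = cm.lib_sizes.astype(float)[cm.sample_ids]
    raw = u / n
    f = raw / np.exp(np.log(raw).mean())
    return NormalizationFactors(
        lib_sizes=n, upper_quartiles=u, factors=f, effective_sizes=f * n
    )


# ---------------------------------------------------------------------------
# NB helpers


def _nb_cdf(k: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    k = np.asarray(k, float)
    mu = np.maximum(np.asarray(mu, float), 1e-300)
    if phi < 1e-12:
        return stats.poisson.cdf(k, mu)
    r = 1.0 / phi
    return stats.nbinom.cdf(k, r, r / (r + mu))


def _nb_ppf(u: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.maximum(np.asarray(mu, float), 1e-300)
    if phi < 1e-12:
        return stats.poisson.ppf(u, mu)
    r = 1.0 / phi
    return stats.nbinom.ppf(u, r, r / (r + mu))


def quantile_adjust(
    counts: pd.DataFrame,
    factors: NormalizationFactors,
    groups: tuple[list[str], list[str]],
    phi: float,
) -> tuple[pd.DataFrame, float]:
    """Map counts to pseudocounts at the common library size M*.

    For each gene and sample, the pseudocount is the real value whose NB
    cumulative probability at mean lambda_g*M* matches the observed count's
    cumulative probability at its own M_j (per-group abundance lambda_g;
    linear interpolation between adjacent integer quantiles; clamped >= 0).
    When all effective sizes are equal the counts are returned unchanged.
    """
    m = factors.effective_sizes.astype(float)
    m_star = factors.m_star
    if np.allclose(m, m_star, rtol=1e-12, atol=0.0):
        return counts.astype(float).copy(), m_star
    pseudo = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    for grp in groups:
        sub = counts[grp].to_numpy(float)
        mg = m[grp].to_numpy(float)
        lam = sub.sum(axis=1) / mg.sum()  # per-gene abundance within the group
        mu_in = lam[:, None] * mg[None, :]
        mu_out = np.repeat(lam[:, None] * m_star, len(grp), axis=1)
        pseudo[grp] = _quantile_match(sub, mu_in, mu_out, phi)
    return pseudo, m_star


def _quantile_match(y, mu_in, mu_out, phi):
    shape = y.shape
    y, mu_in, mu_out = (a.ravel() for a in (y, mu_in, mu_out))
    out = np.zeros_like(y, float)
    ok = mu_in > 0
    u = np.empty_like(y)
    u[ok] = _nb_cdf(y[ok], mu_in[ok], phi)
    # fall back to plain ratio scaling in the extreme upper tail where the
    # discrete CDF saturates and interpolation loses all resolution
    fallback = ok & (u > 1 - 1e-12)
    work = ok & ~fallback
    if work.any():
        k = _nb_ppf(u[work], mu_out[work], phi)
        k = np.where(np.isfinite(k), k, 0.0)
        # nudge the bracket so F(k-1) < u <= F(k)
        for _ in range(3):
            k = k + (_nb_cdf(k, mu_out[work], phi) < u[work])
            k = k - ((_nb_cdf(k - 1, mu_out[work], phi) >= u[work]) & (k >= 1))
        f_k = _nb_cdf(k, mu_out[work], phi)
        f_km1 = np.where(k >= 1, _nb_cdf(k - 1, mu_out[work], phi), 0.0)
        denom = f_k - f_km1
        frac = np.where(denom > 0, (u[work] - f_km1) / np.maximum(denom, 1e-300), 1.0)
        z = k - 1 + np.clip(frac, 0.0, 1.0)
        z = np.where(np.isfinite(z), z, y[work] * mu_out[work] / mu_in[work])
        out[work] = np.maximum(z, 0.0)
    if fallback.any():
        out[fallback] = y[fallback] * mu_out[fallback] / mu_in[fallback]
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# common dispersion (conditional maximum likelihood)


def conditional_loglik(
    pseudo: pd.DataFrame, groups: tuple[list[str], list[str]], phi: float
) -> float:
    """Summed log conditional likelihood of each group's pseudocounts given
    their sum, under NB with common dispersion phi (r = 1/phi)."""
    r = 1.0 / max(phi, 1e-12)
    total = 0.0
    for grp in groups:
        if not grp:
            continue
        z = pseudo[grp].to_numpy(float)
        n = z.shape[1]
        zdot = z.sum(axis=1)
        total += float(
            np.sum(
                gammaln(zdot + 1)
                - gammaln(z + 1).sum(axis=1)
                + gammaln(z + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(zdot + n * r)
            )
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame,
    factors: NormalizationFactors,
    groups: tuple[list[str], list[str]],
    iterations: int = 2,
    grid_size: int = 25,
) -> DispersionEstimate:
    """Maximize the conditional likelihood over delta = phi/(1+phi).

    The delta grid spans [0.001, 0.95]; an interior grid optimum is refined
    by golden-section search.  Quantile adjustment and estimation are
    iterated ``iterations`` times (the adjustment depends on phi).
    Requires >= 2 samples in each group.
    """
    for grp in groups:
        if len(grp) < 2:
            raise ValueError("each strain group needs >= 2 samples")
    deltas = np.linspace(0.001, 0.95, grid_size)
    phi = 0.0
    profile = None
    pseudo, m_star = counts.astype(float), factors.m_star
    for _ in range(iterations):
        pseudo, m_star = quantile_adjust(counts, factors, groups, phi)
        lls = np.array(
            [conditional_loglik(pseudo, groups, d / (1 - d)) for d in deltas]
        )
        i = int(np.argmax(lls))
        if 0 < i < len(deltas) - 1:
            neg = lambda d: -conditional_loglik(pseudo, groups, d / (1 - d))
            delta = float(
                optimize.golden(neg, brack=(deltas[i - 1], deltas[i], deltas[i + 1]))
            )
            delta = float(np.clip(delta, deltas[0], deltas[-1]))
        else:
            delta = float(deltas[i])
        phi = delta / (1 - delta)
        profile = pd.DataFrame({"delta": deltas, "loglik": lls})
    return DispersionEstimate(
        phi=phi, delta=phi / (1 + phi), profile=profile,
        pseudocounts=pseudo, m_star=m_star,
    )


# ---------------------------------------------------------------------------
# exact NB test


def nb_exact_test(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact test of two NB group sums conditional on their total.

    Pr(s | S) is proportional to NBpmf(s; mean n_a*mu, size n_a/phi) *
    NBpmf(S-s; mean n_b*mu, size n_b/phi) with mu = S/(n_a+n_b); the
    p-value sums Pr(s|S) over outcomes no more probable than the observed
    one (ties included).  phi -> 0 reduces to the conditional binomial
    test.  S = 0 returns p = 1 by convention.
    """
    s_a, s_b = int(s_a), int(s_b)
    S = s_a + s_b
    if S == 0:
        return 1.0
    s = np.arange(S + 1)
    if phi < 1e-12:
        pr = stats.binom.pmf(s, S, n_a / (n_a + n_b))
        pr = pr / pr.sum()
    else:
        mu = S / (n_a + n_b)
        r_a, r_b = n_a / phi, n_b / phi
        lp = stats.nbinom.logpmf(s, r_a, r_a / (r_a + n_a * mu)) + stats.nbinom.logpmf(
            S - s, r_b, r_b / (r_b + n_b * mu)
        )
        lp -= logsumexp(lp)
        pr = np.exp(lp)
    p_obs = pr[s_a]
    return float(min(1.0, pr[pr <= p_obs * (1 + _TIE_TOL)].sum()))


def exact_test_pvalues(
    pseudo: pd.DataFrame, groups: tuple[list[str], list[str]], phi: float
) -> pd.Series:
    """Per-gene exact-test p-values on rounded (half-to-even) pseudocount sums."""
    grp_a, grp_b = groups
    s_a = np.rint(pseudo[grp_a].sum(axis=1).to_numpy(float)).astype(np.int64)
    s_b = np.rint(pseudo[grp_b].sum(axis=1).to_numpy(float)).astype(np.int64)
    p = np.array(
        [nb_exact_test(a, b, len(grp_a), len(grp_b), phi) for a, b in zip(s_a, s_b)]
    )
    return pd.Series(p, index=pseudo.index, name="p_value")


# ---------------------------------------------------------------------------
# Poisson LRT comparator


def poisson_lrt_statistics(
    counts: pd.DataFrame,
    groups: tuple[list[str], list[str]],
    factors: NormalizationFactors,
) -> pd.Series:
    """Likelihood-ratio statistics of the single-factor Poisson model with
    M_j offsets: null y_gj ~ Poisson(M_j*lambda_g) vs strain-specific rates;
    MLEs are closed-form (sum y / sum M per stratum)."""
    m = factors.effective_sizes.astype(float)

    def loglik(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(np.maximum(mu, 1e-300)), 0.0)
        return (term - mu).sum(axis=1)

    y_all = counts.to_numpy(float)
    m_all = m[counts.columns].to_numpy(float)
    lam0 = y_all.sum(axis=1) / m_all.sum()
    ll0 = loglik(y_all, lam0[:, None] * m_all[None, :])
    ll1 = np.zeros_like(ll0)
    for grp in groups:
        y = counts[grp].to_numpy(float)
        mg = m[grp].to_numpy(float)
        lam = y.sum(axis=1) / mg.sum()
        ll1 += loglik(y, lam[:, None] * mg[None, :])
    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    return pd.Series(stat, index=counts.index, name="lrt_stat")


def poisson_lrt_pvalues(
    counts: pd.DataFrame,
    groups: tuple[list[str], list[str]],
    factors: NormalizationFactors,
) -> pd.Series:
    """Upper chi-square(1) tail of the Poisson LRT statistic per gene.

    All-zero genes get p = 1.
    """
    stat = poisson_lrt_statistics(counts, groups, factors)
    return pd.Series(stats.chi2.sf(stat, df=1), index=counts.index, name="p_value")


def poisson_lrt(
    gene_counts: pd.Series,
    groups: tuple[list[str], list[str]],
    factors: NormalizationFactors,
) -> float:
    """Poisson LRT p-value for a single gene (see :func:`poisson_lrt_pvalues`)."""
    df = pd.DataFrame([gene_counts])
    return float(poisson_lrt_pvalues(df, groups, factors).iloc[0])


# ---------------------------------------------------------------------------
# Storey q-values


def estimate_pi0(p_values: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 by cubic-smoother extrapolation.

    pi0(lambda) = #{p > lambda} / (m*(1-lambda)) on the grid 0.05..0.95;
    a cubic polynomial (residuals weighted by sqrt(1-lambda) to tame the
    extrapolation variance) is evaluated at lambda = 1 and clamped to (0, 1].
    """
    p = np.asarray(p_values, float)
    m = p.size
    if m == 0:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    if len(lambdas) < 4:
        return 1.0
    coef = np.polyfit(lambdas, pi0_lam, deg=3, w=np.sqrt(1 - lambdas))
    pi0 = float(np.polyval(coef, 1.0))
    if not np.isfinite(pi0) or pi0 > 1.0:
        return 1.0
    if pi0 <= 0.0:
        positive = pi0_lam[pi0_lam > 0]
        return float(max(positive.min() if positive.size else 1.0 / m, 1.0 / m))
    return pi0


def storey_qvalues(p_values, pi0: float | None = None):
    """FDR q-values: q_(i) = min_{j>=i} pi0*m*p_(j)/j, capped at 1; tied
    p-values share a q-value.  Returns the same container type it is given
    (Series in, Series out)."""
    is_series = isinstance(p_values, pd.Series)
    p = np.asarray(p_values, float)
    m = p.size
    if m == 0:
        return p_values.copy() if is_series else np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    # ties share the smallest q among equal p
    ps = p[order]
    for start in np.flatnonzero(np.r_[True, np.diff(ps) > 0]):
        stop = start
        while stop + 1 < m and ps[stop + 1] == ps[start]:
            stop += 1
        q_sorted[start : stop + 1] = q_sorted[start : stop + 1].min()
    q = np.empty(m)
    q[order] = q_sorted
    if is_series:
        return pd.Series(q, index=p_values.index, name="q_value")
    return q


# ---------------------------------------------------------------------------
# DE calls and summaries


def call_de(
    counts: pd.DataFrame,
    factors: NormalizationFactors,
    groups: tuple[list[str], list[str]],
    p_values: pd.Series,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Assemble per-gene results: log2FC (B6/D2), abundance, p, q, flag, direction.

    log2FC = log2((mean B6 proportion + c)/(mean D2 proportion + c)) with the
    zero-guard c = 0.5/M*; a direction is assigned only when q < threshold.
    """
    grp_b6, grp_d2 = groups
    m = factors.effective_sizes.astype(float)
    prop = counts / m[counts.columns]
    c = 0.5 / factors.m_star
    fc = np.log2((prop[grp_b6].mean(axis=1) + c) / (prop[grp_d2].mean(axis=1) + c))
    with np.errstate(divide="ignore"):
        abundance = np.log2(prop.mean(axis=1))
    q = storey_qvalues(p_values)
    res = pd.DataFrame(
        {
            "log2_fc": fc,
            "avg_log_abundance": abundance,
            "p_value": p_values,
            "q_value": q,
        },
        index=counts.index,
    )
    res["direction"] = np.where(
        res["q_value"] < q_threshold,
        np.where(res["log2_fc"] > 0, "B6>D2", "D2>B6"),
        "none",
    )
    return flag_low_count(res)


def flag_low_count(results: pd.DataFrame, threshold: float = LOW_COUNT_LOG2) -> pd.DataFrame:
    """Flag genes whose log2 mean normalized proportion is below the threshold
    (the default -20 is about one read per million)."""
    results = results.copy()
    results["low_count_flag"] = results["avg_log_abundance"] < threshold
    return results


def run_exact_de(
    cm: CountMatrix, q_threshold: float = Q_THRESHOLD
) -> tuple[pd.DataFrame, NormalizationFactors, DispersionEstimate]:
    """Upper-quartile normalize, estimate common dispersion, exact-test every
    gene, and assemble the results table."""
    factors = upper_quartile_factors(cm)
    groups = strain_groups(cm.samples)
    disp = estimate_common_dispersion(cm.counts, factors, groups)
    p = exact_test_pvalues(disp.pseudocounts, groups, disp.phi)
    return call_de(cm.counts, factors, groups, p, q_threshold), factors, disp


def run_poisson_de(
    cm: CountMatrix, q_threshold: float = Q_THRESHOLD
) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Poisson LRT analogue of :func:`run_exact_de` (the comparator model)."""
    factors = upper_quartile_factors(cm)
    groups = strain_groups(cm.samples)
    p = poisson_lrt_pvalues(cm.counts, groups, factors)
    return call_de(cm.counts, factors, groups, p, q_threshold), factors


def length_bias_summary(
    results: pd.DataFrame, models: GeneModelSet, q_threshold: float = Q_THRESHOLD
) -> tuple[pd.DataFrame, float]:
    """DE counts per quartile of union-exon gene length.

    Returns the per-quartile table (n_genes, n_de, median_q) and a
    chi-square goodness-of-fit p-value against DE calls falling uniformly
    across the four length quartiles.
    """
    if len(results) < 4:
        raise ValueError("length bias summary needs >= 4 genes")
    lengths = pd.Series(
        {g: models.union_exon_length(g) for g in results.index}, name="length"
    )
    quart = pd.qcut(lengths.rank(method="first"), 4, labels=["Q1", "Q2", "Q3", "Q4"])
    de = results["q_value"] < q_threshold
    table = pd.DataFrame(
        {
            "n_genes": results.groupby(quart, observed=False).size(),
            "n_de": de.groupby(quart, observed=False).sum(),
            "median_q": results["q_value"].groupby(quart, observed=False).median(),
        }
    )
    n_de = table["n_de"].to_numpy(float)
    if n_de.sum() == 0:
        return table, 1.0
    chi_p = float(stats.chisquare(n_de).pvalue)
    return table, chi_p


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index_label="gene_id")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["low_count_flag"] = df["low_count_flag"].astype(bool)
    return df
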