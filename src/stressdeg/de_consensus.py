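"""Per-contrast differential-expression testing and the consensus DEG rule.

A gene is a DEG for one comparison only when *every* caller reports
|log2 fold change| > 1.2 and BH FDR <= 0.01 with sign-concordant fold
changes — the intersection rule used when several DE programs are run on
the same contrast and only jointly significant genes are retained.

Two desk-scale callers are provided:

``nb_wald``
    Per-gene negative-binomial model: method-of-moments dispersion shrunk
    toward a fitted mean–dispersion trend, Wald test on the log2 ratio of
    group means (delta method standard error).
``lm_moderated``
    limma-style: log2(normalized count + 0.5) response, two-sample t with
    the residual variance moderated toward a fitted mean–variance trend.
    The moderation prior df is estimated from the spread of the log
    residual variances around the trend (moment matching on the scaled-F
    model of gene-wise variances); when estimation is impossible a
    conventional prior df of 3 is used, and a fixed value can be forced
    via ``prior_df``.

FDR is controlled per (caller x genotype x tissue x scheme x comparison)
stratum.  Genes whose normalized mean count over the compared samples is
below 1 are excluded from testing and from the enrichment background.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CountMatrix, ValidationError, expand_scheme

LFC_THRESHOLD_DEFAULT = 1.2
FDR_THRESHOLD_DEFAULT = 0.01
MIN_NORM_MEAN = 1.0  # low-expression pre-filter
_PSEUDO = 0.5  # pseudocount in the log-transform caller
_PRIOR_DF = 3.0  # variance-moderation prior df
CALLERS = ("nb_wald", "lm_moderated")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values.

    adj_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped
    at 1; monotone non-decreasing in the sorted order of the inputs.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def normalize_library_sizes(counts: CountMatrix | pd.DataFrame,
                            method: str = "median_of_ratios") -> pd.Series:
    """Per-sample scale factors (divide counts by these to normalize).

    median_of_ratios: DESeq-style — factor_j is the median over
    all-positive genes of count_gj / geometric-mean_g.  total_count:
    factor_j = column sum / mean column sum.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if method == "total_count":
        sums = df.sum(axis=0).astype(float)
        return sums / sums.mean()
    if method == "median_of_ratios":
        vals = df.to_numpy(dtype=float)
        pos = (vals > 0).all(axis=1)
        if not pos.any():
            raise ValidationError(
                "median_of_ratios undefined: no gene with all-positive counts"
            )
        logv = np.log(vals[pos])
        geo = np.exp(logv.mean(axis=1, keepdims=True))
        ratios = vals[pos] / geo
        return pd.Series(np.median(ratios, axis=0), index=df.columns)
    raise ValidationError(f"unknown normalization method {method!r}")


def _group_columns(cm: CountMatrix, genotype: str, tissue: str, ewc: int) -> list[str]:
    return [
        s.sample_id for s in cm.samples
        if s.genotype == genotype and s.tissue == tissue and s.ewc == ewc
    ]


def _dispersion_trend(mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mean on genes with a positive MoM estimate."""
    ok = (alpha_mom > 0) & (mean > 0)
    if ok.sum() < 10:
        fill = float(np.median(alpha_mom[ok])) if ok.any() else 0.01
        return np.full_like(mean, max(fill, 1e-8))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
    a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        tr = a0 + a1 / np.maximum(mean, 1e-8)
    return tr


def _nb_wald(norm_ref: np.ndarray, norm_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB Wald test on normalized counts; returns (lfc, pvalue)."""
    n_r, n_t = norm_ref.shape[1], norm_test.shape[1]
    m_r = norm_ref.mean(axis=1)
    m_t = norm_test.mean(axis=1)
    v_r = norm_ref.var(axis=1, ddof=1)
    v_t = norm_test.var(axis=1, ddof=1)

    # pooled method-of-moments dispersion, then shrink toward the trend
    mean_all = (n_r * m_r + n_t * m_t) / (n_r + n_t)
    v_pool = ((n_r - 1) * v_r + (n_t - 1) * v_t) / (n_r + n_t - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(mean_all > 0, (v_pool - mean_all) / mean_all**2, 0.0)
    alpha_mom = np.clip(alpha_mom, 0.0, 10.0)
    trend = _dispersion_trend(mean_all, alpha_mom)
    df_gene = n_r + n_t - 2
    alpha = np.clip((df_gene * alpha_mom + _PRIOR_DF * trend) / (df_gene + _PRIOR_DF),
                    1e-8, 10.0)

    lfc = np.log2((m_t + _PSEUDO / 2) / (m_r + _PSEUDO / 2))
    var_mean_r = (m_r + alpha * m_r**2) / n_r
    var_mean_t = (m_t + alpha * m_t**2) / n_t
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = (var_mean_r / np.maximum(m_r, 1e-12) ** 2
               + var_mean_t / np.maximum(m_t, 1e-12) ** 2) / ln2sq
    se = np.sqrt(se2)
    both_zero = (m_r == 0) & (m_t == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(both_zero | (se == 0), 1.0, p)
    lfc = np.where(both_zero, 0.0, lfc)
    return lfc, p


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    from scipy.special import polygamma

    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _estimate_prior_df(s2: np.ndarray, s2_prior: np.ndarray, df: int) -> float:
    """Moment-match the prior df of the scaled-F model for gene variances.

    Under s2 ~ s2_0 * F(df, d0), var(log s2/s2_0) = trigamma(df/2) +
    trigamma(d0/2); the excess spread of log(s2/trend) over trigamma(df/2)
    identifies d0.  No excess (variances fully consistent with the trend)
    gives an effectively infinite prior df.
    """
    from scipy.special import polygamma

    ok = (s2 > 0) & (s2_prior > 0)
    if ok.sum() < 30:
        return _PRIOR_DF
    z = np.log(s2[ok] / s2_prior[ok])
    excess = float(np.var(z, ddof=1)) - float(polygamma(1, df / 2.0))
    if excess <= 1e-6:
        return 1e6
    return max(2.0 * _trigamma_inverse(excess), 1.0)


def _lm_moderated(norm_ref: np.ndarray, norm_test: np.ndarray,
                  prior_df: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Moderated two-sample t on log2(normalized count + 0.5)."""
    y_r = np.log2(norm_ref + _PSEUDO)
    y_t = np.log2(norm_test + _PSEUDO)
    n_r, n_t = y_r.shape[1], y_t.shape[1]
    m_r, m_t = y_r.mean(axis=1), y_t.mean(axis=1)
    df = n_r + n_t - 2
    ss = ((y_r - m_r[:, None]) ** 2).sum(axis=1) + ((y_t - m_t[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    # mean-variance trend: binned median of s2 against average log-expression
    a_mean = (n_r * m_r + n_t * m_t) / (n_r + n_t)
    s2_prior = _variance_trend(a_mean, s2)
    d0 = _estimate_prior_df(s2, s2_prior, df) if prior_df is None else float(prior_df)
    d0 = min(d0, 1e6)
    s2_mod = (df * s2 + d0 * s2_prior) / (df + d0)

    lfc = m_t - m_r
    denom = np.sqrt(s2_mod * (1.0 / n_r + 1.0 / n_t))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, lfc / denom, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df + d0)
    p = np.where(denom == 0, 1.0, p)
    return lfc, p


def _variance_trend(a_mean: np.ndarray, s2: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Median residual variance per expression bin, interpolated."""
    if a_mean.size < 2 * n_bins:
        med = float(np.median(s2)) if s2.size else 0.0
        return np.full_like(s2, med)
    qs = np.quantile(a_mean, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1e-9
    idx = np.clip(np.searchsorted(qs, a_mean, side="right") - 1, 0, n_bins - 1)
    centers = np.empty(n_bins)
    meds = np.empty(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            centers[b] = a_mean[sel].mean()
            meds[b] = np.median(s2[sel])
        else:
            centers[b] = np.nan
            meds[b] = np.nan
    ok = ~np.isnan(centers)
    return np.interp(a_mean, centers[ok], meds[ok])


_CALLER_FUNCS = {"nb_wald": _nb_wald, "lm_moderated": _lm_moderated}


def call_de(cm: CountMatrix, genotype: str, tissue: str,
            comparison: tuple[int, int], caller: str = "nb_wald",
            scheme: str | None = None,
            norm_method: str = "median_of_ratios",
            prior_df: float | None = None) -> pd.DataFrame:
    """Test one comparison for one genotype x tissue with one caller.

    Returns a tidy frame (one row per tested gene) with columns gene_id,
    genotype, tissue, scheme, comparison, caller, lfc, pvalue, fdr.  The
    comparison is (reference_ewc, test_ewc); lfc is log2(test/reference).
    BH FDR is applied within this stratum.  Genes failing the normalized
    mean-count >= 1 pre-filter are dropped before testing.
    """
    if caller not in _CALLER_FUNCS:
        raise ValidationError(f"unknown caller {caller!r}")
    ref_ewc, test_ewc = comparison
    cols_r = _group_columns(cm, genotype, tissue, ref_ewc)
    cols_t = _group_columns(cm, genotype, tissue, test_ewc)
    if len(cols_r) < 2 or len(cols_t) < 2:
        raise ValidationError(
            f"comparison {ref_ewc}/{test_ewc} needs >=2 replicates per side"
        )
    sub = cm.counts[cols_r + cols_t]
    factors = normalize_library_sizes(sub, norm_method)
    norm = sub.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    keep = norm.mean(axis=1) >= MIN_NORM_MEAN
    genes = np.asarray(cm.gene_ids)[keep]
    norm_r = norm[keep][:, : len(cols_r)]
    norm_t = norm[keep][:, len(cols_r):]
    if caller == "lm_moderated":
        lfc, p = _lm_moderated(norm_r, norm_t, prior_df)
    else:
        lfc, p = _CALLER_FUNCS[caller](norm_r, norm_t)
    return pd.DataFrame({
        "gene_id": genes,
        "genotype": genotype,
        "tissue": tissue,
        "scheme": scheme if scheme is not None else "",
        "comparison": f"{ref_ewc}/{test_ewc}",
        "caller": caller,
        "lfc": lfc,
        "pvalue": p,
        "fdr": benjamini_hochberg(p),
    })


def consensus(tables: list[pd.DataFrame],
              lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
              fdr_threshold: float = FDR_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Intersect per-caller DE tables into one direction call per gene.

    direction = up iff every caller has lfc > +threshold and
    fdr <= fdr_threshold; down iff every caller has lfc < -threshold and
    fdr <= fdr_threshold; otherwise ns (including sign disagreement).
    All tables must cover the same (gene, genotype, tissue, scheme,
    comparison) grid.
    """
    if not tables:
        raise ValidationError("need at least one caller table")
    key = ["gene_id", "genotype", "tissue", "scheme", "comparison"]
    grids = [frozenset(map(tuple, t[key].itertuples(index=False))) for t in tables]
    if any(g != grids[0] for g in grids[1:]):
        raise ValidationError("caller tables cover different (gene, comparison) grids")
    merged = pd.concat(tables, ignore_index=True)
    sig = merged["fdr"] <= fdr_threshold
    merged["up_ok"] = sig & (merged["lfc"] > lfc_threshold)
    merged["down_ok"] = sig & (merged["lfc"] < -lfc_threshold)
    agg = merged.groupby(key, sort=True).agg(
        all_up=("up_ok", "all"), all_down=("down_ok", "all")
    ).reset_index()
    agg["direction"] = np.where(
        agg["all_up"], "up", np.where(agg["all_down"], "down", "ns")
    )
    return agg.drop(columns=["all_up", "all_down"])


def de_analysis(cm: CountMatrix,
                schemes: Iterable[str] = ("AR", "TC"),
                callers: Iterable[str] = CALLERS,
                genotypes: Iterable[str] | None = None,
                tissues: Iterable[str] | None = None,
                lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
                fdr_threshold: float = FDR_THRESHOLD_DEFAULT,
                norm_method: str = "median_of_ratios",
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every caller over every stratum and intersect into consensus calls.

    Returns (results, calls): the long DE result table and the consensus
    direction table.  Strata are every genotype x tissue x scheme x
    comparison present in the data.
    """
    callers = list(callers)
    if genotypes is None:
        genotypes = sorted({s.genotype for s in cm.samples})
    if tissues is None:
        tissues = sorted({s.tissue for s in cm.samples})
    results = []
    consensus_parts = []
    for g, t, scheme_name in itertools.product(genotypes, tissues, schemes):
        scheme = expand_scheme(scheme_name)
        for comp in scheme.comparisons:
            per_caller = [
                call_de(cm, g, t, comp, caller=c, scheme=scheme_name,
                        norm_method=norm_method)
                for c in callers
            ]
            results.extend(per_caller)
            consensus_parts.append(
                consensus(per_caller, lfc_threshold, fdr_threshold)
            )
    results_df = pd.concat(results, ignore_index=True)
    calls_df = pd.concat(consensus_parts, ignore_index=True)
    return results_df, calls_df
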