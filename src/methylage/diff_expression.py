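"""Two-group negative-binomial differential expression.

Counts are normalized with median-of-ratios size factors, per-transcript NB
dispersions are estimated by method of moments and shrunk toward a fitted
mean-dispersion trend, and the group effect (log2 fold change of the older
group S+3 over the younger S+1) is tested with a Wald statistic.  Both raw
p-values and Benjamini-Hochberg FDR are reported, mirroring the dual
p < 0.05 / FDR < 0.05 thresholds used downstream.

The estimator is a deliberately compact DESeq2-style approximation: no
Cox-Reid dispersion adjustment, no LFC shrinkage, no outlier refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

PSEUDOCOUNT = 0.5
MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    log2fc: float
    se: float
    wald_stat: float
    p_value: float
    fdr: float

    @property
    def direction(self) -> str:
        return "down" if self.log2fc < 0 else "up"


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    The reference is the per-feature geometric mean over features with no
    zero count; each sample's factor is the median of its count/reference
    ratios, rescaled so the factors have geometric mean 1.  If no feature is
    positive in every sample, falls back to total-count scaling with a
    warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        warnings.warn(
            "no feature with all-positive counts; falling back to "
            "total-count size factors",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        factors = totals
    else:
        sub = mat[all_positive]
        log_ref = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(means: np.ndarray, disps: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by non-negative LS on gene-wise estimates."""
    ok = (disps > MIN_DISPERSION) & (means > 0)
    if ok.sum() < 10:
        fallback = float(np.median(disps[disps > 0])) if (disps > 0).any() else 0.1
        return np.full_like(means, max(fallback, MIN_DISPERSION))
    design = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, _ = optimize.nnls(design, disps[ok])
    trend = coef[0] + coef[1] / np.maximum(means, 1e-8)
    return np.clip(trend, MIN_DISPERSION, MAX_DISPERSION)


def estimate_dispersions(
    norm_counts: np.ndarray, group_idx: list[np.ndarray]
) -> np.ndarray:
    """Method-of-moments dispersions shrunk toward the fitted trend.

    For normalized counts x = K/s with group mean q, Var(x) ~ q*E[1/s] + alpha*q^2,
    so the within-group excess variance over the Poisson term estimates
    alpha*q^2.  Gene-wise estimates are combined with the trend on the log
    scale with equal weight, which stabilises the small-sample estimates
    without flattening genuine dispersion differences.
    """
    n_genes = norm_counts.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    base_mean = norm_counts.mean(axis=1)
    for idx in group_idx:
        x = norm_counts[:, idx]
        q = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        # Poisson part of Var(K/s): q * mean(1/s); s is embedded in x, so
        # approximate E[1/s] by n/sum(s) ~ 1 after normalization.
        num += (len(idx) - 1) * (v - q)
        den += (len(idx) - 1) * q**2
    with np.errstate(divide="ignore", invalid="ignore"):
        genewise = np.where(den > 0, num / den, 0.0)
    genewise = np.clip(genewise, MIN_DISPERSION, MAX_DISPERSION)
    trend = _fit_dispersion_trend(base_mean, genewise)
    log_alpha = 0.5 * np.log(genewise) + 0.5 * np.log(trend)
    return np.clip(np.exp(log_alpha), MIN_DISPERSION, MAX_DISPERSION)


def wald_test_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    reference: str | None = None,
) -> pd.DataFrame:
    """NB Wald test of a two-group design, per transcript.

    Parameters
    ----------
    counts
        Features x samples non-negative integer counts.
    groups
        Sample -> group label; exactly two levels, each with n >= 2.  The
        fold change is reported for the non-reference level relative to
        ``reference`` (default: the lexicographically smaller level, so with
        S1/S3 labels the result is S+3 vs S+1).

    Returns a DataFrame with columns transcript_id, base_mean, log2fc, se,
    stat, pvalue, fdr, direction; all-zero transcripts are excluded from
    testing and returned with NaN statistics.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("sample sheet does not cover all count columns")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if reference is None:
        reference = levels[0]
    other = next(l for l in levels if l != reference)
    idx_ref = np.flatnonzero((groups == reference).to_numpy())
    idx_alt = np.flatnonzero((groups == other).to_numpy())
    if len(idx_ref) < 2 or len(idx_alt) < 2:
        raise ValueError("each group needs >= 2 samples")

    sf = size_factors(counts).to_numpy()
    mat = counts.to_numpy(dtype=float)
    norm = mat / sf
    nonzero = mat.sum(axis=1) > 0

    n_genes = mat.shape[0]
    log2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    zstat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)

    sub = norm[nonzero]
    alpha = estimate_dispersions(sub, [idx_ref, idx_alt])
    q_ref = sub[:, idx_ref].mean(axis=1)
    q_alt = sub[:, idx_alt].mean(axis=1)

    # pseudo-count keeps the fold change finite when one group mean is 0
    q_ref_r = np.where(q_ref == 0, PSEUDOCOUNT, q_ref)
    q_alt_r = np.where(q_alt == 0, PSEUDOCOUNT, q_alt)
    lfc = np.log2(q_alt_r) - np.log2(q_ref_r)

    inv_s = 1.0 / sf
    q_ref_e = np.maximum(q_ref, PSEUDOCOUNT)
    q_alt_e = np.maximum(q_alt, PSEUDOCOUNT)
    # delta method on ln(mean of K_j/s_j): Var = (1/n^2) sum_j (q/s_j + a q^2) / q^2
    var_ref = (
        q_ref_e * inv_s[idx_ref].sum() + alpha * q_ref_e**2 * len(idx_ref)
    ) / (len(idx_ref) ** 2 * q_ref_e**2)
    var_alt = (
        q_alt_e * inv_s[idx_alt].sum() + alpha * q_alt_e**2 * len(idx_alt)
    ) / (len(idx_alt) ** 2 * q_alt_e**2)
    se_ln = np.sqrt(var_ref + var_alt)
    se_l2 = se_ln / np.log(2)
    z = lfc / se_l2
    # t reference absorbs the extra spread from plugging in estimated
    # dispersions at small n; df = observations entering the mean and
    # variance estimates (2 per sample) minus the 4 fitted parameters
    df = 2 * (len(idx_ref) + len(idx_alt)) - 4
    p = 2.0 * stats.t.sf(np.abs(z), df)

    log2fc[nonzero] = lfc
    se[nonzero] = se_l2
    zstat[nonzero] = z
    pval[nonzero] = p

    fdr = np.full(n_genes, np.nan)
    fdr[nonzero] = bh_adjust(p)

    out = pd.DataFrame(
        {
            "transcript_id": counts.index,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "stat": zstat,
            "pvalue": pval,
            "fdr": fdr,
        }
    )
    out["direction"] = np.where(out["log2fc"] < 0, "down", "up")
    out.loc[~nonzero, "direction"] = "excluded"
    return out


def fpkm(counts: pd.DataFrame, transcript_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    ``fpkm_ij = count_ij / (length_i/1000 * libsize_j/1e6)`` with library
    size the column total.
    """
    lengths = transcript_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing transcript lengths")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be > 0")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def de_results_from_frame(df: pd.DataFrame) -> list[DEResult]:
    """Materialise DEResult records from the tested rows of a result frame."""
    out = []
    for r in df.itertuples():
        if np.isnan(r.pvalue):
            continue
        out.append(
            DEResult(r.transcript_id, r.log2fc, r.se, r.stat, r.pvalue, r.fdr)
        )
    return out
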