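"""Window-based differential methylation from MBD-seq-style coverage.

Methylated-read counts over 25 bp CpG windows are normalized to RPKM
(reads per kilobase per million mapped reads) and compared between the two
age groups with a per-window Welch t-test; direction is reported as hypo-
or hyper-methylated in the older group (S+3 vs S+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diff_expression import PSEUDOCOUNT, bh_adjust
from .genome_annotation import WINDOW_SIZE


@dataclass(frozen=True)
class DMResult:
    window_key: str
    mean_ref: float
    mean_alt: float
    log2fc: float
    t_stat: float
    p_value: float
    fdr: float

    @property
    def direction(self) -> str:
        return "hypo" if self.log2fc < 0 else "hyper"


def rpkm(
    window_counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    window_size: int = WINDOW_SIZE,
) -> pd.DataFrame:
    """RPKM over fixed-size windows: count / (size_kb * mapped_millions).

    ``library_sizes`` defaults to the column totals of the count matrix.
    """
    if library_sizes is None:
        library_sizes = window_counts.sum(axis=0)
    library_sizes = library_sizes.reindex(window_counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    per_kb = window_size / 1e3
    return window_counts.div(per_kb * library_sizes / 1e6, axis=1)


def t_test_dm(
    rpkm_matrix: pd.DataFrame,
    groups: pd.Series,
    reference: str | None = None,
) -> pd.DataFrame:
    """Welch two-sample t-test per window on RPKM values.

    Zero-variance windows with equal group means get p = 1 by convention
    (keeps the BH adjustment well-defined); log2 fold change uses a 0.5
    pseudo-count on the group mean RPKMs.  Returns a DataFrame with columns
    window, mean_<ref>, mean_<alt>, log2fc, stat, pvalue, fdr, direction.
    """
    groups = groups.reindex(rpkm_matrix.columns)
    if groups.isna().any():
        raise ValueError("sample sheet does not cover all matrix columns")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if reference is None:
        reference = levels[0]
    other = next(l for l in levels if l != reference)
    a = rpkm_matrix.loc[:, (groups == reference).to_numpy()].to_numpy(float)
    b = rpkm_matrix.loc[:, (groups == other).to_numpy()].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance windows are handled by the p = 1 convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, pval = stats.ttest_ind(b, a, axis=1, equal_var=False)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    degenerate = np.isnan(pval)
    equal_means = np.isclose(mean_a, mean_b)
    pval = np.where(degenerate & equal_means, 1.0, pval)
    # zero variance but different means: infinitely strong evidence
    pval = np.where(degenerate & ~equal_means, 0.0, pval)
    t_stat = np.where(degenerate, 0.0, t_stat)

    lfc = np.log2(mean_b + PSEUDOCOUNT) - np.log2(mean_a + PSEUDOCOUNT)
    out = pd.DataFrame(
        {
            "window": rpkm_matrix.index,
            f"mean_{reference}": mean_a,
            f"mean_{other}": mean_b,
            "log2fc": lfc,
            "stat": t_stat,
            "pvalue": pval,
            "fdr": bh_adjust(pval),
        }
    )
    out["direction"] = np.where(out["log2fc"] < 0, "hypo", "hyper")
    return out


def significant_windows_bed(dm: pd.DataFrame, path, p_threshold: float = 0.05) -> None:
    """Write significant windows ("chrom:start-end" keys) as BED."""
    from .genome_annotation import write_bed

    rows = []
    for r in dm[dm["pvalue"] < p_threshold].itertuples():
        chrom, span = str(r.window).rsplit(":", 1)
        start, end = span.split("-")
        rows.append((chrom, int(start), int(end), r.direction))
    write_bed(rows, path)
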