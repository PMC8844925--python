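"""Developmental expression profiling of a gene x sample count matrix.

Counts are normalized by median-of-ratios size factors (the classic
between-sample normalization for RNA-seq count matrices), log2 fold changes
are computed for each developmental time point against the 0 h reference,
p-values come from a two-sided Welch-style location test on log-transformed
normalized counts (a documented stand-in for a negative-binomial Wald test;
externally computed p-values can be supplied instead), are
Benjamini–Hochberg adjusted per time-point contrast, and each gene is
assigned to one of four developmental expression clusters:

* ``strong_up``  — >4-fold induced (log2FC >= 2, adjusted p <= alpha) at
  one or more time points;
* ``up``         — >2-fold induced (log2FC >= 1) at one or more time points;
* ``down``       — >2-fold downregulated (log2FC <= −1);
* ``unchanged``  — none of the above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STRONG_UP = "strong_up"
UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"

DEFAULT_TIME_POINTS = (0, 6, 12, 18, 24)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Reference genes are those with nonzero counts in every sample; for each
    sample the factor is the median of that sample's counts divided by the
    per-gene geometric mean across samples. No rescaling of the factors is
    applied (classic definition).
    """
    mat = counts.to_numpy(dtype=float)
    ref = (mat > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference set (consider a pseudocount mode)"
        )
    logs = np.log(mat[ref])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors


def _groups(metadata: pd.DataFrame, reference_time: int) -> tuple[list[str], dict[int, list[str]]]:
    md = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    ref_samples = md.index[md["time_h"] == reference_time].tolist()
    if not ref_samples:
        raise ValueError(f"reference time point {reference_time} h absent from metadata")
    others = {
        int(t): md.index[md["time_h"] == t].tolist()
        for t in sorted(md["time_h"].unique())
        if t != reference_time
    }
    return ref_samples, others


def log2fc_vs_reference(
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_time: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2((mean_t + pseudocount) / (mean_ref + pseudocount)) per gene and
    non-reference time point, using replicate means of normalized counts."""
    ref_samples, others = _groups(metadata, reference_time)
    ref_mean = normalized[ref_samples].mean(axis=1)
    out = {}
    for t, samples in others.items():
        t_mean = normalized[samples].mean(axis=1)
        out[t] = np.log2((t_mean + pseudocount) / (ref_mean + pseudocount))
    return pd.DataFrame(out, index=normalized.index)


def differential_test(
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_time: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-sided Welch t-test on log2(normalized + pseudocount) between each
    time point and the reference, per gene.

    This is a location test on log-scale normalized counts, NOT a
    negative-binomial Wald test; with fewer than 2 replicates in either
    group (no within-group variance estimate) p = 1 is returned. Degenerate
    zero-variance identical groups also give p = 1.
    """
    ref_samples, others = _groups(metadata, reference_time)
    logged = np.log2(normalized + pseudocount)
    out = {}
    for t, samples in others.items():
        if len(samples) < 2 or len(ref_samples) < 2:
            out[t] = np.ones(len(normalized))
            continue
        a = logged[samples].to_numpy()
        b = logged[ref_samples].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0
        out[t] = p
    return pd.DataFrame(out, index=normalized.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_pvalues(pvalues: pd.DataFrame, family: str = "per_contrast") -> pd.DataFrame:
    """BH-adjust a gene x time-point p-value table.

    ``family='per_contrast'`` adjusts each time-point column separately;
    ``family='global'`` adjusts the pooled set of all tests.
    """
    if family == "per_contrast":
        return pd.DataFrame(
            {t: bh_adjust(pvalues[t].to_numpy()) for t in pvalues.columns},
            index=pvalues.index,
        )
    if family == "global":
        flat = bh_adjust(pvalues.to_numpy().ravel())
        return pd.DataFrame(
            flat.reshape(pvalues.shape), index=pvalues.index, columns=pvalues.columns
        )
    raise ValueError(f"unknown adjustment family {family!r}")


@dataclass
class ClassificationThresholds:
    fc_up_strong: float = 2.0
    fc_up: float = 1.0
    fc_down: float = -1.0
    alpha: float = 0.05


def classify_expression(
    log2fc: pd.DataFrame,
    padj: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Assign each gene to one developmental expression cluster.

    Significant time points are those with adjusted p <= alpha. Precedence:
    ``strong_up`` (any significant log2FC >= 2) > ``up`` (>= 1) > ``down``
    (<= −1) > ``unchanged``. A gene significant in both directions is
    assigned by the larger \\|log2FC\\| (tie goes up) and flagged ``mixed``.
    Returns cluster, deciding time point, deciding log2FC, and mixed flag.
    """
    th = thresholds or ClassificationThresholds()
    sig = padj.to_numpy() <= th.alpha
    lfc = log2fc.to_numpy()
    times = np.asarray(log2fc.columns)

    rows = []
    for i, gene in enumerate(log2fc.index):
        s, f = sig[i], lfc[i]
        up_mask = s & (f >= th.fc_up)
        down_mask = s & (f <= th.fc_down)
        mixed = bool(up_mask.any() and down_mask.any())
        cluster, t_dec, f_dec = UNCHANGED, None, 0.0
        if up_mask.any() or down_mask.any():
            max_up = f[up_mask].max() if up_mask.any() else -np.inf
            max_down = f[down_mask].min() if down_mask.any() else np.inf
            if up_mask.any() and (not down_mask.any() or max_up >= abs(max_down)):
                cluster = STRONG_UP if max_up >= th.fc_up_strong else UP
                j = int(np.flatnonzero(up_mask & (f == max_up))[0])
            else:
                cluster = DOWN
                j = int(np.flatnonzero(down_mask & (f == max_down))[0])
            t_dec, f_dec = int(times[j]), float(f[j])
        rows.append(
            {
                "gene_id": gene,
                "cluster": cluster,
                "deciding_time_h": t_dec,
                "deciding_log2fc": f_dec,
                "mixed": mixed,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def profile_counts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_time: int = 0,
    pseudocount: float = 1.0,
    thresholds: ClassificationThresholds | None = None,
    pvalues: pd.DataFrame | None = None,
    adjust_family: str = "per_contrast",
) -> dict:
    """Full expression stage: normalize, fold changes, test, adjust, classify.

    ``pvalues`` lets callers substitute externally computed per-gene/time raw
    p-values (e.g. from a dedicated count-model package) for the built-in
    stand-in test. Returns a dict with ``factors``, ``normalized``,
    ``log2fc``, ``pvalues``, ``padj``, ``clusters``.
    """
    factors = size_factors(counts)
    normalized = normalize(counts, factors)
    lfc = log2fc_vs_reference(normalized, metadata, reference_time, pseudocount)
    p = pvalues if pvalues is not None else differential_test(
        normalized, metadata, reference_time, pseudocount
    )
    padj = adjust_pvalues(p, family=adjust_family)
    clusters = classify_expression(lfc, padj, thresholds)
    return {
        "factors": factors,
        "normalized": normalized,
        "log2fc": lfc,
        "pvalues": p,
        "padj": padj,
        "clusters": clusters,
    }
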