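"""Bulk RNA-seq analysis from a gene x sample count matrix.

The pipeline starts from raw counts (alignment and counting happen
upstream) and provides:

* median-of-ratios size factors against a geometric-mean pseudoreference,
* negative-binomial differential expression with a locally-regressed
  mean-dispersion trend and an exact conditional two-group test,
* Benjamini-Hochberg FDR adjustment and DE calling (q and fold-change
  thresholds),
* PCA of log-transformed centered expression, and
* projection of query samples onto the principal axes of a reference
  developmental time course ("pseudotime embedding"): eigenvectors and
  centering come from the reference alone, and each query sample is
  labelled with the nearest reference timepoint in the top-k eigenspace.

The exact conditional NB test conditions on each gene's total count: the
two group sums are modelled as moment-matched negative binomials (means
proportional to summed size factors; the dispersion of a group sum of
NB(s_j q, alpha) variables is alpha * sum(s_j^2) / (sum s_j)^2), and the
two-sided p-value is the total probability of all splits of the observed
total that are no more likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DispersionModel",
    "PCAModel",
    "EmbeddingResult",
    "size_factors",
    "normalize",
    "dispersion_trend",
    "nb_test",
    "bh_adjust",
    "de_table",
    "call_de",
    "log_center",
    "pca",
    "embed_on_reference",
]

FOLD_CHANGE_EPS = 0.5  # pseudo-count on normalized means, guards /0


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup}")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integers")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a pseudoreference.

    The pseudoreference for gene i is the geometric mean of its counts
    across samples, computed over genes with no zero count; the factor for
    sample j is the median over those genes of counts_ij / pseudoref_i.
    """
    _validate_counts(counts)
    vals = counts.to_numpy(dtype=float)
    all_positive = (vals > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter the matrix "
            "or use more samples before computing size factors"
        )
    logs = np.log(vals[all_positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    return counts / factors


@dataclass(frozen=True)
class DispersionModel:
    """Per-gene raw and trend dispersions with the fitted trend."""

    mu: pd.Series          # base mean of normalized counts
    alpha_raw: pd.Series   # method-of-moments, clipped at 0
    alpha_trend: pd.Series  # smooth trend evaluated per gene
    method: str            # "local_regression" or "parametric_fallback"
    trend_params: tuple = ()

    def alpha_test(self) -> pd.Series:
        """Dispersion used in testing: max(raw, trend), guards small-n underestimates."""
        return pd.concat([self.alpha_raw, self.alpha_trend], axis=1).max(axis=1)


def dispersion_trend(
    normalized: pd.DataFrame,
    groups: pd.Series,
    lowess_frac: float = 0.4,
    min_genes_for_lowess: int = 50,
) -> DispersionModel:
    """Estimate per-gene NB dispersions and a smooth mean-dispersion trend.

    Raw dispersions are method-of-moments on normalized counts with the
    variance pooled within groups: alpha_i = max(0, (s2_i - mu_i) / mu_i^2).
    The trend alpha(mu) is a local linear regression (lowess) of log alpha
    on log mu over genes with positive raw dispersion; with fewer than
    ``min_genes_for_lowess`` such genes a parametric trend
    alpha(mu) = a0 + a1/mu is fit instead and flagged via ``method``.
    """
    groups = groups.reindex(normalized.columns)
    if groups.isna().any():
        raise ValueError("groups must cover all samples")
    levels = groups.unique()
    if any((groups == g).sum() < 2 for g in levels):
        raise ValueError("need >= 2 samples per group")

    vals = normalized.to_numpy(dtype=float)
    mu = vals.mean(axis=1)

    # Pooled within-group variance (unbiased per group, df-weighted).
    ss = np.zeros(len(normalized))
    df = 0
    for g in levels:
        sub = vals[:, (groups == g).to_numpy()]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += sub.shape[1] - 1
    s2 = ss / df

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    alpha_raw = np.clip(np.nan_to_num(alpha_raw), 0.0, None)

    fit_mask = (alpha_raw > 0) & (mu > 0)
    if fit_mask.sum() >= min_genes_for_lowess:
        lx = np.log(mu[fit_mask])
        ly = np.log(alpha_raw[fit_mask])
        sm = lowess(ly, lx, frac=lowess_frac, return_sorted=True)
        # Evaluate by interpolation, flat extrapolation beyond the range.
        trend_log = np.interp(np.log(np.clip(mu, 1e-300, None)), sm[:, 0], sm[:, 1])
        alpha_trend = np.exp(trend_log)
        method = "local_regression"
        params: tuple = ()
    else:
        # Parametric family alpha(mu) = a0 + a1/mu by nonnegative LS.
        from scipy.optimize import nnls

        x = mu[fit_mask]
        y = alpha_raw[fit_mask]
        if len(x) == 0:
            a0, a1 = 0.0, 0.0
        else:
            design = np.column_stack([np.ones_like(x), 1.0 / x])
            (a0, a1), _ = nnls(design, y)
        with np.errstate(divide="ignore"):
            alpha_trend = a0 + a1 / np.clip(mu, 1e-300, None)
        method = "parametric_fallback"
        params = (float(a0), float(a1))

    alpha_trend = np.clip(np.where(mu > 0, alpha_trend, 0.0), 1e-8, None)
    idx = normalized.index
    return DispersionModel(
        mu=pd.Series(mu, index=idx, name="base_mean"),
        alpha_raw=pd.Series(alpha_raw, index=idx, name="alpha_raw"),
        alpha_trend=pd.Series(alpha_trend, index=idx, name="alpha_trend"),
        method=method,
        trend_params=params,
    )


def _group_sum_pmf(total: int, mean: float, alpha: float) -> np.ndarray:
    """PMF of a moment-matched NB group sum over counts 0..total."""
    k = np.arange(total + 1)
    if alpha < 1e-10:
        return stats.poisson.pmf(k, mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return stats.nbinom.pmf(k, r, p)


def exact_conditional_nb_pvalue(
    k_a: int,
    k_b: int,
    s_a: np.ndarray,
    s_b: np.ndarray,
    alpha: float,
) -> float:
    """Two-sided exact conditional NB p-value for one gene.

    Conditions on the total K = k_a + k_b.  Group sums are modelled as NB
    with means q*S_g (q = K / (S_a + S_b), S_g the summed size factors)
    and dispersions alpha * sum(s_j^2) / S_g^2 (the moment-matched
    dispersion of a sum of independent NB counts sharing alpha).  The
    p-value is the probability, conditional on K, of all splits no more
    likely than the observed one.
    """
    K = k_a + k_b
    if K == 0:
        return 1.0
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    S_a, S_b = s_a.sum(), s_b.sum()
    q = K / (S_a + S_b)
    alpha_a = alpha * (s_a**2).sum() / S_a**2
    alpha_b = alpha * (s_b**2).sum() / S_b**2

    pa = _group_sum_pmf(K, q * S_a, alpha_a)
    pb = _group_sum_pmf(K, q * S_b, alpha_b)
    joint = pa * pb[::-1]  # joint[a] = P(A=a) P(B=K-a)
    total = joint.sum()
    if total <= 0:
        return 1.0
    obs = joint[k_a]
    # Tolerance so ties with the observed probability are always included.
    return float(min(joint[joint <= obs * (1.0 + 1e-8)].sum() / total, 1.0))


def nb_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    model: DispersionModel,
    groups: pd.Series,
) -> pd.Series:
    """Per-gene two-sided exact conditional NB p-values for two groups.

    Uses the testing dispersion max(raw, trend) per gene.  Genes with zero
    total count get p = 1.
    """
    groups = groups.reindex(counts.columns)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("nb_test requires exactly 2 groups")
    a_cols = (groups == levels[0]).to_numpy()
    b_cols = (groups == levels[1]).to_numpy()

    vals = counts.to_numpy(dtype=np.int64)
    s = factors.reindex(counts.columns).to_numpy(dtype=float)
    k_a = vals[:, a_cols].sum(axis=1)
    k_b = vals[:, b_cols].sum(axis=1)
    alpha = model.alpha_test().reindex(counts.index).to_numpy()

    p = np.ones(len(counts))
    for i in range(len(counts)):
        p[i] = exact_conditional_nb_pvalue(
            int(k_a[i]), int(k_b[i]), s[a_cols], s[b_cols], float(alpha[i])
        )
    return pd.Series(p, index=counts.index, name="p")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    counts: pd.DataFrame,
    groups: pd.Series,
    fdr: float = 0.01,
    min_fold: float = 2.0,
    control_label: str | None = None,
) -> pd.DataFrame:
    """Full differential-expression pipeline on a two-group count matrix.

    Size factors, normalization, dispersion trend, exact conditional NB
    test, BH adjustment, and DE calling.  Genes with zero total count are
    excluded from the multiple-testing universe.  Fold change is
    (mean_test + eps) / (mean_control + eps) on normalized counts with
    eps = 0.5.  Returns a DataFrame indexed by gene with columns
    base_mean, fold_change, log2_fold_change, p, q, is_de.
    """
    groups = groups.reindex(counts.columns)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("need exactly 2 groups")
    if control_label is None:
        control_label = levels[0]
    test_label = [g for g in levels if g != control_label][0]

    factors = size_factors(counts)
    nonzero = counts.sum(axis=1) > 0
    counts_nz = counts.loc[nonzero]
    norm = normalize(counts_nz, factors)
    model = dispersion_trend(norm, groups)
    p = nb_test(counts_nz, factors, model, groups)
    q = pd.Series(bh_adjust(p.to_numpy()), index=p.index, name="q")

    mean_c = norm.loc[:, (groups == control_label).to_numpy()].mean(axis=1)
    mean_t = norm.loc[:, (groups == test_label).to_numpy()].mean(axis=1)
    fc = (mean_t + FOLD_CHANGE_EPS) / (mean_c + FOLD_CHANGE_EPS)

    out = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "p": p,
            "q": q,
        }
    )
    out["is_de"] = call_de(out, fdr=fdr, min_fold=min_fold)
    return out


def call_de(results: pd.DataFrame, fdr: float = 0.01, min_fold: float = 2.0) -> pd.Series:
    """DE calls: q below the FDR threshold and fold change beyond min_fold (either direction)."""
    fc = results["fold_change"]
    beyond = (fc > min_fold) | (fc < 1.0 / min_fold)
    return (results["q"] < fdr) & beyond


def log_center(normalized: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """log2(x + 1) then per-gene centering; returns (matrix, centering vector)."""
    if (normalized.to_numpy() < 0).any():
        raise ValueError("normalized values must be nonnegative")
    logged = np.log2(normalized + 1.0)
    center = logged.mean(axis=1)
    return logged.sub(center, axis=0), center.rename("center")


@dataclass(frozen=True)
class PCAModel:
    """Principal axes of gene expression across samples."""

    center: pd.Series                  # per-gene mean removed before SVD
    components: pd.DataFrame           # k x genes, orthonormal rows
    explained_variance_ratio: np.ndarray
    k: int
    truncated: bool = False

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Project samples (columns of a genes x samples matrix) onto the axes."""
        aligned = matrix.reindex(self.center.index)
        centered = aligned.sub(self.center, axis=0)
        scores = centered.T @ self.components.T
        scores.columns = [f"PC{i + 1}" for i in range(self.components.shape[0])]
        return scores


def pca(matrix: pd.DataFrame, k: int = 10) -> tuple[PCAModel, pd.DataFrame]:
    """PCA of a genes x samples matrix, samples as observations.

    Equivalent to the eigendecomposition of the gene-gene covariance of
    the per-gene-centered data, computed through the SVD of the centered
    matrix.  ``k`` beyond the rank is truncated and flagged.  Returns the
    model and the per-sample score matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    center = matrix.mean(axis=1)
    X = matrix.sub(center, axis=0).to_numpy(dtype=float).T  # samples x genes
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max() * max(X.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    truncated = k > rank
    k_eff = min(k, rank) if rank > 0 else 1

    var = S**2
    total = var.sum()
    ratio = var[:k_eff] / total if total > 0 else np.zeros(k_eff)

    components = pd.DataFrame(
        Vt[:k_eff], columns=matrix.index, index=[f"PC{i + 1}" for i in range(k_eff)]
    )
    model = PCAModel(
        center=center,
        components=components,
        explained_variance_ratio=ratio,
        k=k_eff,
        truncated=truncated,
    )
    scores = pd.DataFrame(
        (U[:, :k_eff] * S[:k_eff]),
        index=matrix.columns,
        columns=components.index,
    )
    return model, scores


@dataclass(frozen=True)
class EmbeddingResult:
    """Query samples placed in the reference eigenspace."""

    scores: pd.DataFrame            # query samples x k
    reference_scores: pd.DataFrame  # reference samples x k
    nearest_label: pd.Series        # per query sample
    distance: pd.Series             # Euclidean distance to nearest reference sample
    model: PCAModel = field(repr=False, default=None)


def embed_on_reference(
    query_matrix: pd.DataFrame,
    reference_matrix: pd.DataFrame,
    reference_labels: pd.Series,
    k: int = 10,
    log_transform: bool = True,
    center_with: str = "reference",
    min_genes: int = 100,
) -> EmbeddingResult:
    """Project query samples onto the principal axes of a reference time course.

    Both matrices are genes x samples on the normalized scale; the gene
    universes are intersected (at least ``min_genes`` genes must overlap).
    Eigenvectors and the centering vector are computed from the reference
    alone; the query is centered with the reference gene means by default
    (``center_with="query"`` centers by query means instead) and projected
    onto the top-k axes.  Each query sample is assigned the label of the
    nearest reference sample in the eigenspace ("pseudotime" staging).
    """
    shared = reference_matrix.index.intersection(query_matrix.index)
    if len(shared) < min_genes:
        raise ValueError(
            f"gene overlap too small: {len(shared)} < {min_genes}"
        )
    ref = reference_matrix.loc[shared]
    qry = query_matrix.loc[shared]
    if log_transform:
        ref = np.log2(ref + 1.0)
        qry = np.log2(qry + 1.0)

    model, ref_scores = pca(ref, k=k)
    if center_with == "reference":
        q_scores = model.transform(qry)
    elif center_with == "query":
        q_centered = qry.sub(qry.mean(axis=1), axis=0)
        q_scores = (q_centered.T @ model.components.T)
        q_scores.columns = ref_scores.columns
    else:
        raise ValueError("center_with must be 'reference' or 'query'")

    labels = reference_labels.reindex(ref_scores.index)
    d = np.linalg.norm(
        q_scores.to_numpy()[:, None, :] - ref_scores.to_numpy()[None, :, :], axis=2
    )
    nearest_idx = d.argmin(axis=1)
    nearest = pd.Series(
        labels.to_numpy()[nearest_idx], index=q_scores.index, name="nearest_timepoint"
    )
    dist = pd.Series(d.min(axis=1), index=q_scores.index, name="distance")
    return EmbeddingResult(
        scores=q_scores,
        reference_scores=ref_scores,
        nearest_label=nearest,
        distance=dist,
        model=model,
    )
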