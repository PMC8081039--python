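"""Lipidomics statistics on internal-standard-corrected abundance tables.

Input is a lipids x samples table of relative abundances (analyte AUC over
class internal-standard AUC), with a lipid class per row (LPC, LPE, PC,
PE, TG, ...) and group/timepoint labels per sample.  Zero encodes a
non-detect.  The pipeline:

1. remove lipids detected in fewer than floor(n/2)+1 samples
   (``all_samples`` rule available as an alternative),
2. normalize each sample by its total over retained lipids,
3. for PCA only: add a small offset (1e-6), log10, z-score per lipid,
4. two-sample pooled-variance t-tests on the total-normalized data with
   BH FDR control, and
5. consistency calling across comparisons (e.g. mutant at 50 h vs wild
   type at 50/53/56 h): a lipid is "consistent" only if significant in
   every comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome import PCAModel, bh_adjust, pca as _pca

__all__ = [
    "LipidTable",
    "LipidTestResult",
    "detection_filter",
    "total_normalize",
    "log_zscore",
    "lipid_pca",
    "lipid_ttests",
    "lipid_fdr",
    "consistent_hits",
]


@dataclass(frozen=True)
class LipidTable:
    """Lipids x samples abundances plus row/column annotations."""

    abundances: pd.DataFrame
    classes: pd.Series      # per lipid
    groups: pd.Series       # per sample
    timepoints: pd.Series   # per sample

    def __post_init__(self) -> None:
        ab = self.abundances
        if (ab.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative (0 = non-detect)")
        if ab.index.has_duplicates:
            raise ValueError("duplicate lipid ids")
        if not self.classes.index.equals(ab.index):
            raise ValueError("classes must align with lipid index")
        for s in (self.groups, self.timepoints):
            if not s.index.equals(ab.columns):
                raise ValueError("sample annotations must align with columns")

    def with_abundances(self, ab: pd.DataFrame) -> "LipidTable":
        return LipidTable(
            abundances=ab,
            classes=self.classes.reindex(ab.index),
            groups=self.groups.reindex(ab.columns),
            timepoints=self.timepoints.reindex(ab.columns),
        )


@dataclass(frozen=True)
class LipidTestResult:
    """Per-lipid test results across one or more group comparisons."""

    table: pd.DataFrame           # lipid x [t, p, q, significant] per comparison
    significant: pd.DataFrame     # lipid x comparison booleans
    consistent: pd.Series         # significant in every comparison
    union: pd.Series              # significant in at least one comparison
    class_tally: pd.DataFrame     # per-class counts of consistent / union hits


def detection_filter(
    table: LipidTable, rule: str = "half_plus_one"
) -> tuple[LipidTable, list[str]]:
    """Remove lipids not detected in enough samples.

    ``half_plus_one`` (default) keeps lipids detected (abundance > 0) in at
    least floor(n_samples / 2) + 1 samples; ``all_samples`` requires
    detection in every sample.  Returns the filtered table and the removal
    list.
    """
    ab = table.abundances
    n = ab.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples")
    detected = (ab > 0).sum(axis=1)
    if rule == "half_plus_one":
        keep = detected >= n // 2 + 1
    elif rule == "all_samples":
        keep = detected == n
    else:
        raise ValueError(f"unknown rule: {rule}")
    removed = list(ab.index[~keep])
    return table.with_abundances(ab.loc[keep]), removed


def total_normalize(table: LipidTable) -> LipidTable:
    """Divide each sample by its total abundance over retained lipids."""
    ab = table.abundances
    totals = ab.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return table.with_abundances(ab / totals)


def log_zscore(
    table: LipidTable, offset: float = 1e-6
) -> tuple[pd.DataFrame, list[str]]:
    """Per-lipid z-scores of log10(x + offset) across samples.

    Uses the sample standard deviation (ddof=1).  Lipids with zero
    variance get z = 0 and are returned in the flag list.
    """
    logged = np.log10(table.abundances + offset)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    flat = sd <= 0
    sd_safe = sd.mask(flat, 1.0)
    z = logged.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[flat] = 0.0
    return z, list(table.abundances.index[flat])


def lipid_pca(transformed: pd.DataFrame, k: int = 10) -> tuple[PCAModel, pd.DataFrame]:
    """PCA of the z-scored lipid matrix (lipids x samples), samples as observations."""
    return _pca(transformed, k=k)


def lipid_ttests(
    table: LipidTable,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Two-sided pooled-variance t-tests per lipid between two sample sets.

    Applied to total-normalized (not z-scored) abundances.  Degenerate
    lipids with zero pooled variance get p = 1 when the group means are
    equal and p = 0 (flagged) when they differ.  Returns a DataFrame with
    columns t, p, degenerate.
    """
    ab = table.abundances
    missing = [s for s in list(group_a) + list(group_b) if s not in ab.columns]
    if missing:
        raise ValueError(f"unknown sample(s): {missing}")
    a = ab[group_a].to_numpy(dtype=float)
    b = ab[group_b].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")

    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate & equal_means, 1.0, p)
        p = np.where(degenerate & ~equal_means, 0.0, p)
    return pd.DataFrame(
        {"t": t, "p": p, "degenerate": degenerate}, index=ab.index
    )


def lipid_fdr(p_values, method: str = "bh", qvalue_lambda: float = 0.5) -> np.ndarray:
    """FDR-adjusted values for the lipid tests.

    ``bh`` is the Benjamini-Hochberg step-up (default).  ``qvalue`` is a
    positive-FDR style estimator: BH values scaled by Storey's null
    proportion estimate pi0 = min(1, #{p > lambda} / ((1 - lambda) m)).
    """
    p = np.asarray(p_values, dtype=float)
    q = bh_adjust(p)
    if method == "bh":
        return q
    if method == "qvalue":
        m = len(p)
        if m == 0:
            return q
        pi0 = min(1.0, (p > qvalue_lambda).sum() / ((1.0 - qvalue_lambda) * m))
        pi0 = max(pi0, 1.0 / m)  # never exactly 0
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown method: {method}")


def consistent_hits(
    results: dict[str, pd.DataFrame],
    classes: pd.Series | None = None,
    fdr: float = 0.05,
) -> LipidTestResult:
    """Consistency calling across comparisons.

    ``results`` maps a comparison name (e.g. "mut50_vs_wt53") to a
    per-lipid DataFrame containing a ``q`` column.  A lipid is
    ``consistent`` if q < fdr in every comparison, and in the ``union`` if
    significant in at least one.  Per-class tallies are reported when
    ``classes`` is given.
    """
    if not results:
        raise ValueError("need >= 1 comparison")
    names = list(results)
    index = results[names[0]].index
    sig = pd.DataFrame(index=index)
    flat = []
    for name in names:
        df = results[name].reindex(index)
        sig[name] = df["q"] < fdr
        flat.append(df.add_suffix(f"_{name}"))
    table = pd.concat(flat, axis=1)

    consistent = sig.all(axis=1)
    union = sig.any(axis=1)
    if classes is not None:
        cls = classes.reindex(index)
        class_tally = pd.DataFrame(
            {
                "consistent": consistent.groupby(cls).sum(),
                "union": union.groupby(cls).sum(),
                "total": cls.value_counts().sort_index(),
            }
        ).fillna(0).astype(int)
    else:
        class_tally = pd.DataFrame(columns=["consistent", "union", "total"])
    return LipidTestResult(
        table=table,
        significant=sig,
        consistent=consistent.rename("consistent"),
        union=union.rename("union"),
        class_tally=class_tally,
    )
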