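"""Compositional transforms and correlation-based ordination.

Relative-abundance tables are compositional: a log-ratio style transform is
applied before PCA to mitigate the induced non-linearity.  The default
transform adds a single pseudocount — half the smallest non-zero proportion in
the whole matrix — to every cell and takes the natural log; a centered
log-ratio (CLR) variant is available.  PCA is correlation-based (taxa are
standardized), so it is invariant to per-taxon affine rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import CountMatrix, to_cpm, top_n_by_abundance

__all__ = [
    "PCAResult",
    "logratio_transform",
    "clr_transform",
    "correlation_pca",
    "spearman_matrix",
    "within_family_profiles",
]

logger = logging.getLogger(__name__)


def logratio_transform(rel_abundance: pd.DataFrame) -> pd.DataFrame:
    """Log of proportions after adding one global pseudocount to every cell.

    The pseudocount is half the smallest non-zero proportion over the whole
    matrix (a single constant, not per-sample); rows are not renormalized
    afterwards.  Monotone per taxon, so sample orderings are preserved.
    """
    arr = rel_abundance.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero matrix cannot be log-ratio transformed")
    pseudo = 0.5 * nonzero.min()
    return pd.DataFrame(
        np.log(arr + pseudo), index=rel_abundance.index, columns=rel_abundance.columns
    )


def clr_transform(rel_abundance: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio: log(x + pseudocount) minus each row's mean log."""
    logged = logratio_transform(rel_abundance)
    return logged.sub(logged.mean(axis=1), axis=0)


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x axes
    loadings: pd.DataFrame     # taxa x axes
    variance_explained: np.ndarray  # percent per axis, sums to 100
    dropped_taxa: list[str]


def correlation_pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA on the taxon-taxon correlation matrix of a transformed table.

    Columns are standardized (mean 0, sd 1); constant columns are dropped with
    a warning.  Axes are ordered by decreasing eigenvalue and carry a
    deterministic sign convention: each loading vector's largest-magnitude
    element is positive.
    """
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    dropped = list(matrix.columns[constant])
    if dropped:
        logger.warning("dropping %d constant taxa from PCA: %s", len(dropped), dropped[:5])
    cols = matrix.columns[~constant]
    x = x[:, ~constant]
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 non-constant taxa")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| element of each axis is positive
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    scores = z @ eigvec
    axes = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    var_pct = 100.0 * eigval / eigval.sum()
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=axes),
        loadings=pd.DataFrame(eigvec, index=cols, columns=axes),
        variance_explained=var_pct,
        dropped_taxa=dropped,
    )


def pca_top_taxa(
    matrix: CountMatrix, top_n_taxa: int = 50, transform: str = "logratio"
) -> PCAResult:
    """Convenience: restrict to the top taxa by library-normalized abundance,
    convert to proportions, apply ``logratio`` or ``clr``, and run PCA."""
    top = top_n_by_abundance(matrix, top_n_taxa)
    props = to_cpm(top) / 1e6
    if transform == "logratio":
        tx = logratio_transform(props)
    elif transform == "clr":
        tx = clr_transform(props)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return correlation_pca(tx)


def spearman_matrix(cpm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between taxa over samples
    (mid-rank ties); constant taxa yield NaN entries."""
    if cpm.shape[0] < 3:
        raise ValueError("Spearman matrix needs >= 3 samples")
    import warnings

    with warnings.catch_warnings():
        # constant taxa are flagged NaN below; scipy's warning is redundant
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(cpm.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=cpm.columns, columns=cpm.columns)
    sd = cpm.std(axis=0)
    const = sd.index[sd == 0]
    out.loc[const, :] = np.nan
    out.loc[:, const] = np.nan
    np.fill_diagonal(out.values, 1.0)
    return out


def within_family_profiles(
    otu_counts: pd.DataFrame, top_k: int | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Unit-scaled per-sample OTU composition within one family.

    Rows (samples) are scaled to sum to 1 over the family's OTUs; samples with
    zero family counts are excluded and reported.  ``top_k`` restricts to the
    most abundant OTUs by total count before scaling.
    """
    if otu_counts.shape[1] < 1:
        raise ValueError("family must contain at least one OTU")
    counts = otu_counts
    if top_k is not None and top_k < counts.shape[1]:
        totals = counts.sum(axis=0)
        keep = sorted(counts.columns, key=lambda c: (-totals[c], c))[:top_k]
        counts = counts[keep]
    row_sums = counts.sum(axis=1)
    excluded = list(row_sums.index[row_sums == 0])
    kept = counts.loc[row_sums > 0]
    profile = kept.div(row_sums[row_sums > 0], axis=0)
    return profile, excluded
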