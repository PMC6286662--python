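"""Community comparison statistics for the composite-vs-grab design.

Implements the quantities used to compare sampling methods:

* Morisita dissimilarity (1 - Morisita's overlap index), a count-based measure
  chosen because it is little influenced by sample size — sequencing effort
  differs systematically between methods (grab events are triplicate).
* Individual-based rarefaction: expected richness in a random subsample of n
  reads (hypergeometric form) with the classical variance of rarefied richness
  (Heck, van Belle & Simberloff 1975), and accumulation curves.
* Dispersion to group centroid in a principal-coordinates embedding of a
  dissimilarity matrix, with negative eigenvalues handled by the imaginary-axis
  convention, tested by a seeded permutation t test and a Mann-Whitney U test.
* Grab-replicate pooling, time-matched pairing of composite samples with grab
  events, and per-taxon detection rates under parity trimming (both methods
  compared at equal sample numbers and maximal temporal overlap).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .filtering import CountMatrix

__all__ = [
    "RarefactionResult",
    "DissimilarityMatrix",
    "DispersionResult",
    "morisita_dissimilarity",
    "morisita_matrix",
    "rarefy_richness",
    "accumulation_curve",
    "pool_grab_replicates",
    "time_match_pairs",
    "detection_rates",
    "dispersion_to_centroid",
]

logger = logging.getLogger(__name__)


def _as_int_counts(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{name} must hold integral counts")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError(f"{name} must be non-negative")
    return arr.astype(np.int64)


def morisita_dissimilarity(x, y) -> float:
    """1 - Morisita's overlap index for two integer count vectors.

    C = 2 sum(x_i y_i) / ((lam_x + lam_y) N_x N_y) with
    lam = sum n_i (n_i - 1) / (N (N - 1)).  The index can exceed 1 at small
    counts, so the dissimilarity can be slightly negative; disjoint supports
    give exactly 1.
    """
    xa, ya = _as_int_counts(x, "x"), _as_int_counts(y, "y")
    if xa.shape != ya.shape:
        raise ValueError("count vectors must cover the same taxa")
    nx, ny = int(xa.sum()), int(ya.sum())
    if nx < 2 or ny < 2:
        raise ValueError("Morisita requires totals >= 2 in both samples")
    lam_x = (xa * (xa - 1)).sum() / (nx * (nx - 1))
    lam_y = (ya * (ya - 1)).sum() / (ny * (ny - 1))
    denom = (lam_x + lam_y) * nx * ny
    if denom == 0:
        return 1.0  # both samples are all-singletons with no repeats
    c = 2.0 * float((xa * ya).sum()) / denom
    return 1.0 - c


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise sample dissimilarities with optional group labels."""

    labels: list[str]
    values: np.ndarray
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("dissimilarity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("dissimilarity matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def morisita_matrix(counts: pd.DataFrame, groups: pd.Series | None = None) -> DissimilarityMatrix:
    """Pairwise Morisita dissimilarities over the rows of a count table."""
    labels = list(counts.index)
    n = len(labels)
    out = np.zeros((n, n))
    arr = _as_int_counts(counts.to_numpy(), "counts")
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = morisita_dissimilarity(arr[i], arr[j])
    return DissimilarityMatrix(labels, out, groups)


@dataclass(frozen=True)
class RarefactionResult:
    n_subsampled: int
    expected_richness: float
    standard_error: float


def _log_choose(n, k):
    n, k = np.asarray(n, dtype=float), np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_richness(counts, n: int) -> RarefactionResult:
    """Expected richness (and its SE) in a random subsample of ``n`` reads.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] computed via log-gamma; the
    variance is the exact hypergeometric form of Heck et al. (1975), which is
    zero at full depth (n = N).
    """
    arr = _as_int_counts(counts, "counts")
    arr = arr[arr > 0]
    total = int(arr.sum())
    if n <= 0:
        raise ValueError("subsample size must be positive")
    if n > total:
        raise ValueError(f"subsample size {n} exceeds total count {total}")
    log_cn = _log_choose(total, n)

    def q(m):  # P(taxon with m reads absent from the subsample)
        m = np.asarray(m, dtype=float)
        out = np.where(
            total - m >= n, np.exp(_log_choose(total - m, n) - log_cn), 0.0
        )
        return out

    qi = q(arr)
    expected = float(np.sum(1.0 - qi))
    var = float(np.sum(qi * (1.0 - qi)))
    # pairwise covariance term: 2 * sum_{i<j} [C(N-Ni-Nj, n)/C(N,n) - qi qj]
    if len(arr) > 1:
        pair_sum = 0.0
        for i in range(len(arr) - 1):
            mj = arr[i + 1:]
            pair_sum += float(np.sum(q(arr[i] + mj) - qi[i] * qi[i + 1:]))
        var += 2.0 * pair_sum
    var = max(var, 0.0)
    return RarefactionResult(n, expected, math.sqrt(var))


def accumulation_curve(counts, step: int = 10) -> list[RarefactionResult]:
    """Rarefaction at n = step, 2*step, ..., up to the full count total."""
    if step < 1:
        raise ValueError("step must be >= 1")
    arr = _as_int_counts(counts, "counts")
    total = int(arr.sum())
    points = list(range(step, total + 1, step))
    if not points or points[-1] != total:
        points.append(total)
    return [rarefy_richness(arr, n) for n in points]


def pool_grab_replicates(matrix: CountMatrix) -> CountMatrix:
    """Sum grab-replicate rows into one row per grab event.

    Grab samples sharing (sampler, initiation time) are summed; composite
    samples pass through unchanged.  Unequal replicate-set sizes are pooled
    with a warning rather than dropped.
    """
    meta = matrix.meta_for()
    grab = meta.index[meta["method"] == "grab"]
    other = [s for s in matrix.samples if s not in set(grab)]
    if len(grab) == 0:
        return matrix
    key = meta.loc[grab, ["sampler", "initiation_time_min"]]
    sizes = key.groupby(["sampler", "initiation_time_min"]).size()
    if sizes.nunique() > 1:
        logger.warning(
            "grab replicate sets of unequal size (%s); pooling anyway",
            sorted(sizes.unique()),
        )
    pooled_rows, pooled_meta = [], []
    for (sampler, t), members in key.groupby(["sampler", "initiation_time_min"]).groups.items():
        name = f"{sampler}_{int(t)}"
        pooled_rows.append(matrix.counts.loc[list(members)].sum(axis=0).rename(name))
        m = meta.loc[list(members)[0]].copy()
        m["replicate"] = None
        m.name = name
        pooled_meta.append(m)
    counts = pd.concat(
        [matrix.counts.loc[other]] + [r.to_frame().T for r in pooled_rows]
    ).astype(np.int64)
    new_meta = pd.concat([meta.loc[other]] + [m.to_frame().T for m in pooled_meta])
    return CountMatrix(counts, new_meta, matrix.taxon_meta)


def time_match_pairs(
    matrix: CountMatrix, tolerance_min: int = 1
) -> tuple[list[tuple[str, str]], list[str]]:
    """Pair each composite sample with the grab event initiated at
    approximately the same time (within ``tolerance_min`` minutes), per site.

    Expects grab replicates already pooled (one row per event).  Returns
    (pairs, unpaired sample names); multiple grab events within tolerance of
    one composite raise, demanding a tighter tolerance.
    """
    meta = matrix.meta_for()
    pairs: list[tuple[str, str]] = []
    unpaired: list[str] = []
    for site, site_meta in meta.groupby("site"):
        comps = site_meta[site_meta["method"] == "composite"]
        grabs = site_meta[site_meta["method"] == "grab"]
        matched_grabs: set[str] = set()
        for cname, crow in comps.iterrows():
            dt = (grabs["initiation_time_min"] - crow["initiation_time_min"]).abs()
            hits = list(grabs.index[dt <= tolerance_min])
            if len(hits) > 1:
                raise ValueError(
                    f"composite {cname} matches {len(hits)} grab events within "
                    f"{tolerance_min} min; tighten the tolerance"
                )
            if hits:
                pairs.append((cname, hits[0]))
                matched_grabs.add(hits[0])
            else:
                unpaired.append(cname)
        unpaired.extend(g for g in grabs.index if g not in matched_grabs)
    return pairs, unpaired


def _parity_trim(sorted_names: list[str], target: int) -> list[str]:
    """Trim a time-ordered sample list to ``target`` members: floor(excess/2)
    dropped from the start, ceil(excess/2) from the end (22 -> 15 drops the
    first 3 and last 4; 22 -> 18 drops 2 and 2)."""
    excess = len(sorted_names) - target
    if excess < 0:
        raise ValueError("cannot trim a set below its own size")
    head = excess // 2
    tail = excess - head
    return sorted_names[head: len(sorted_names) - tail]


def detection_rates(
    matrix: CountMatrix, parity_trim: bool = True, combine_sites: bool = True
) -> pd.DataFrame:
    """Per-taxon detection rate (non-zero samples / samples considered) per
    sampling method, on raw (unpooled) sample bottles.

    With ``parity_trim``, at each site the larger method's time-ordered sample
    set is trimmed from both ends to the size of the smaller, maximizing
    temporal overlap.  Rates are combined across sites by summing detections
    and denominators unless ``combine_sites`` is False.
    """
    meta = matrix.meta_for()
    frames = []
    for site, site_meta in meta.groupby("site"):
        sets: dict[str, list[str]] = {}
        for method, mm in site_meta.groupby("method"):
            order = mm.sort_values(["initiation_time_min", "replicate"], na_position="first")
            sets[method] = list(order.index)
        if parity_trim and len(sets) == 2:
            sizes = {m: len(v) for m, v in sets.items()}
            small = min(sizes.values())
            # trim by event for composites so trimming is contiguous in time
            for m in sets:
                if sizes[m] > small:
                    sets[m] = _parity_trim(sets[m], small)
        for method, names in sets.items():
            sub = matrix.counts.loc[names]
            frames.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "method": method,
                        "detections": (sub > 0).sum(axis=0),
                        "n_samples": len(names),
                    }
                )
            )
    long = pd.concat(frames)
    if combine_sites:
        agg = long.groupby([long.index, "method"])[["detections", "n_samples"]].sum()
        agg["rate"] = agg["detections"] / agg["n_samples"]
        return agg.reset_index(names=["taxon", "method"])
    long["rate"] = long["detections"] / long["n_samples"]
    return long.reset_index(names="taxon")


@dataclass
class DispersionResult:
    """Distances to group centroids and the associated two-sample tests."""

    distances: pd.Series
    groups: pd.Series
    group_means: pd.Series
    t_statistic: float
    permutation_p: float
    mannwhitney_u: float
    mannwhitney_p: float
    n_permutations: int
    seed: int
    eigenvalues: np.ndarray = field(repr=False, default=None)


def dispersion_to_centroid(
    D: DissimilarityMatrix,
    groups: pd.Series | dict | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
) -> DispersionResult:
    """Multivariate dispersion: distance of each sample to its group centroid
    in the principal-coordinates embedding of ``D``, plus two-group tests.

    The dissimilarity matrix is double-centered and eigendecomposed; axes with
    negative eigenvalues contribute *negatively* to squared distances (the
    imaginary-axis convention), clamped at zero.  Group centroids are the
    arithmetic means of member coordinates.  Two-sided tests: a seeded
    permutation t test on the distances (group labels permuted) and a
    Mann-Whitney U test.
    """
    if groups is None:
        groups = D.groups
    if groups is None:
        raise ValueError("group labels are required")
    groups = pd.Series(groups).reindex(D.labels)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("at least two groups are required")
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")

    d = D.values
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    pos = eigval > 1e-10
    neg = eigval < -1e-10
    x_pos = eigvec[:, pos] * np.sqrt(eigval[pos])
    x_neg = eigvec[:, neg] * np.sqrt(-eigval[neg])

    sq = np.zeros(n)
    for g in counts.index:
        members = np.asarray(groups == g)
        c_pos = x_pos[members].mean(axis=0) if x_pos.size else np.zeros(0)
        c_neg = x_neg[members].mean(axis=0) if x_neg.size else np.zeros(0)
        d_pos = ((x_pos[members] - c_pos) ** 2).sum(axis=1) if x_pos.size else 0.0
        d_neg = ((x_neg[members] - c_neg) ** 2).sum(axis=1) if x_neg.size else 0.0
        sq[members] = np.maximum(d_pos - d_neg, 0.0)
    dist = pd.Series(np.sqrt(sq), index=D.labels, name="distance_to_centroid")

    g_names = list(counts.index[:2]) if len(counts) == 2 else list(counts.index)
    if len(counts) != 2:
        logger.warning("permutation t test defined for 2 groups; using first two")
    a_vals = dist[groups == g_names[0]].to_numpy()
    b_vals = dist[groups == g_names[1]].to_numpy()
    t_obs = stats.ttest_ind(a_vals, b_vals, equal_var=True).statistic
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a_vals, b_vals])
    na, nb = len(a_vals), len(b_vals)

    def _t(av: np.ndarray, bv: np.ndarray) -> np.ndarray:
        # pooled-variance two-sample t along the last axis
        ma, mb = av.mean(axis=-1), bv.mean(axis=-1)
        va = av.var(axis=-1, ddof=1)
        vb = bv.var(axis=-1, ddof=1)
        sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        return (ma - mb) / np.sqrt(sp * (1.0 / na + 1.0 / nb))

    perm_idx = np.argsort(rng.random((n_permutations, na + nb)), axis=1)
    shuffled = pooled[perm_idx]
    t_perm = _t(shuffled[:, :na], shuffled[:, na:])
    hits = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    perm_p = (hits + 1) / (n_permutations + 1)
    u_stat, u_p = stats.mannwhitneyu(a_vals, b_vals, alternative="two-sided")

    return DispersionResult(
        distances=dist,
        groups=groups,
        group_means=dist.groupby(groups).mean(),
        t_statistic=float(t_obs),
        permutation_p=float(perm_p),
        mannwhitney_u=float(u_stat),
        mannwhitney_p=float(u_p),
        n_permutations=n_permutations,
        seed=seed,
        eigenvalues=eigval[::-1],
    )
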