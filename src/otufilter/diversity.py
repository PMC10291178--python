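"""Alpha diversity, Bray-Curtis beta diversity, PCoA and PERMANOVA.

Alpha metrics follow their textbook definitions on raw counts (no
rarefaction): observed richness, the bias-corrected Chao1 estimator,
Shannon entropy in natural-log units, and the inverse Simpson index.
Beta diversity is the Bray-Curtis dissimilarity, embedded by classical
principal-coordinates analysis, with group structure tested by a
permutation PERMANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import OtuTable, OtuTableError, ReplicateDesign, TaxonomyTable

__all__ = [
    "AlphaDiversityResult",
    "DistanceMatrix",
    "PcoaResult",
    "PermanovaResult",
    "observed_otus",
    "chao1",
    "shannon",
    "inverse_simpson",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "phylum_relative_abundance",
    "rank_relative_abundance",
]

ALPHA_METRICS = ("observed_otus", "chao1", "shannon", "inverse_simpson")


# -- alpha diversity -------------------------------------------------------

def observed_otus(counts) -> int:
    """Number of OTUs with count >= 1."""
    counts = np.asarray(counts)
    _check_counts(counts)
    return int((counts >= 1).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate.

    The bias-corrected form (default) is
    ``S_obs + f1 * (f1 - 1) / (2 * (f2 + 1))`` with ``f1`` the number of
    singletons and ``f2`` the number of doubletons; it is defined even
    when there are no doubletons.  ``bias_corrected=False`` selects the
    classic ``S_obs + f1**2 / (2 * f2)`` form, which requires f2 > 0
    whenever f1 > 0.
    """
    counts = np.asarray(counts)
    _check_counts(counts)
    s_obs = int((counts >= 1).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 and not f2:
        raise OtuTableError("classic Chao1 undefined with singletons but no "
                            "doubletons; use the bias-corrected form")
    return s_obs + (f1 ** 2 / (2.0 * f2) if f2 else 0.0)


def shannon(counts, base: float = math.e) -> float:
    """Shannon diversity, -sum(p * log p), natural log by default."""
    counts = np.asarray(counts, dtype=float)
    _check_counts(counts)
    total = counts.sum()
    if total <= 0:
        raise OtuTableError("Shannon index requires a positive total count")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


def inverse_simpson(counts) -> float:
    """Inverse Simpson index, 1 / sum(p**2): the effective number of
    dominant OTUs."""
    counts = np.asarray(counts, dtype=float)
    _check_counts(counts)
    total = counts.sum()
    if total <= 0:
        raise OtuTableError("inverse Simpson requires a positive total count")
    p = counts / total
    return float(1.0 / (p ** 2).sum())


def _check_counts(counts: np.ndarray) -> None:
    if counts.ndim != 1:
        raise OtuTableError("expected a 1-D count vector")
    if counts.size and (counts < 0).any():
        raise OtuTableError("counts must be non-negative")


@dataclass
class AlphaDiversityResult:
    """Per-sample alpha-diversity values with mean and SE per metric."""

    per_sample: pd.DataFrame  # samples x metrics
    mean: dict[str, float]
    se: dict[str, float]

    def values(self, metric: str) -> np.ndarray:
        return self.per_sample[metric].to_numpy()


def alpha_diversity(table: OtuTable) -> AlphaDiversityResult:
    """Observed OTUs, Chao1, Shannon and inverse Simpson for every sample."""
    rows = []
    for s in table.sample_ids:
        col = table.sample(s)
        rows.append((observed_otus(col), chao1(col), shannon(col),
                     inverse_simpson(col)))
    df = pd.DataFrame(rows, index=table.sample_ids, columns=list(ALPHA_METRICS))
    df.index.name = "sample_id"
    n = len(df)
    mean = {m: float(df[m].mean()) for m in ALPHA_METRICS}
    se = {
        m: (float(df[m].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0)
        for m in ALPHA_METRICS
    }
    return AlphaDiversityResult(per_sample=df, mean=mean, se=se)


# -- beta diversity --------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise OtuTableError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T):
            raise OtuTableError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise OtuTableError("distance matrix diagonal must be zero")
        if not np.isfinite(v).all():
            raise OtuTableError("distance matrix entries must be finite")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(table: OtuTable, relative: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    ``d(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik)`` on raw
    counts; with ``relative=True`` the counts are first converted to
    within-sample relative abundances.
    """
    if table.n_samples < 2:
        raise OtuTableError("Bray-Curtis needs at least two samples")
    data = table.counts.astype(float)
    if relative:
        totals = data.sum(axis=0)
        if (totals == 0).any():
            raise OtuTableError("cannot normalise a sample with zero total")
        data = data / totals
    cols = data.T  # samples x otus
    sums = cols.sum(axis=1)
    pair_tot = sums[:, None] + sums[None, :]
    both_zero = (pair_tot == 0) & ~np.eye(len(sums), dtype=bool)
    if both_zero.any():
        i, j = np.argwhere(both_zero)[0]
        raise OtuTableError(
            f"Bray-Curtis undefined for all-zero sample pair "
            f"({table.sample_ids[i]!r}, {table.sample_ids[j]!r})"
        )
    dm = squareform(pdist(cols, metric="braycurtis"))
    return DistanceMatrix(sample_ids=table.sample_ids, values=dm)


@dataclass
class PcoaResult:
    """Classical PCoA embedding.

    ``coordinates`` holds samples x axes, axes ordered by decreasing
    eigenvalue and scaled by the square root of the (positive)
    eigenvalue.  All eigenvalues, including negative ones, are reported
    in ``eigenvalues`` so distortion can be assessed; no Cailliez or
    Lingoes correction is applied.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def proportion_explained(self) -> np.ndarray:
        pos = np.clip(self.eigenvalues, 0.0, None)
        total = pos.sum()
        return pos / total if total > 0 else pos

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal-coordinates decomposition of a dissimilarity matrix.

    Double-centers ``-0.5 * D**2``, eigendecomposes, and returns
    coordinates on the axes with positive eigenvalues.
    """
    d2 = dm.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0) if n else 0.0
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    return PcoaResult(sample_ids=list(dm.sample_ids), coordinates=coords,
                      eigenvalues=eigvals)


# -- PERMANOVA -------------------------------------------------------------

@dataclass
class PermanovaResult:
    """One-way PERMANOVA outcome."""

    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool = False

    def __str__(self) -> str:
        kind = "exact" if self.exact else f"{self.n_permutations} permutations"
        return (f"PERMANOVA: R2 = {self.r_squared:.4f}, "
                f"pseudo-F = {self.pseudo_f:.4f}, p = {self.p_value:.4g} ({kind})")


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        ix = np.nonzero(codes == g)[0]
        if len(ix) > 1:
            sub = d2[np.ix_(ix, ix)]
            ss_within += sub[np.triu_indices(len(ix), k=1)].sum() / len(ix)
    return ss_total, ss_within


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Partitions the sum of squared dissimilarities by the grouping
    factor: ``SS_total = (1/n) * sum_{i<j} d_ij**2``, ``SS_within``
    summed per group with its own ``1/n_g`` scaling, and
    ``R**2 = SS_between / SS_total``.  The pseudo-F statistic is
    ``(SS_between / (a - 1)) / (SS_within / (n - a))`` and its p-value
    comes from unrestricted permutation of the group labels with the
    ``+1`` correction: ``p = (1 + #{F_perm >= F_obs}) / (1 + B)``.

    ``grouping`` is a sequence of labels aligned with ``dm.sample_ids``
    (or a mapping sample_id -> label).  ``n_permutations="exact"``
    enumerates every distinct relabelling instead of sampling; the exact
    p-value is the fraction of relabellings (including the identity)
    with ``F >= F_obs``.
    """
    n = len(dm.sample_ids)
    if hasattr(grouping, "get") and not isinstance(grouping, (list, tuple, np.ndarray, pd.Series)):
        labels = [grouping[s] for s in dm.sample_ids]
    else:
        labels = list(grouping)
    if len(labels) != n:
        raise OtuTableError("grouping length does not match the distance matrix")
    uniq = sorted(set(map(str, labels)))
    codes = np.array([uniq.index(str(g)) for g in labels])
    a = len(uniq)
    if a < 2:
        raise OtuTableError("PERMANOVA needs at least two groups")
    if a >= n:
        raise OtuTableError("no residual degrees of freedom (as many groups "
                            "as samples)")
    d2 = dm.values ** 2

    def f_stat(perm_codes: np.ndarray) -> tuple[float, float]:
        ss_total, ss_within = _permanova_ss(d2, perm_codes, a)
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            f = math.inf if ss_between > 0 else 0.0
        else:
            f = (ss_between / (a - 1)) / (ss_within / (n - a))
        r2 = ss_between / ss_total if ss_total > 0 else 0.0
        return f, r2

    f_obs, r2 = f_stat(codes)

    if n_permutations == "exact":
        hits = 0
        total = 0
        for perm in _distinct_relabelings(codes):
            f_p, _ = f_stat(perm)
            total += 1
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = hits / total
        return PermanovaResult(r_squared=r2, pseudo_f=f_obs, p_value=p,
                               n_permutations=total, seed=seed, exact=True)

    if not isinstance(n_permutations, (int, np.integer)) or n_permutations < 1:
        raise OtuTableError("n_permutations must be a positive integer or 'exact'")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(codes)
        f_p, _ = f_stat(perm)
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + int(n_permutations))
    return PermanovaResult(r_squared=r2, pseudo_f=f_obs, p_value=p,
                           n_permutations=int(n_permutations), seed=seed)


def _distinct_relabelings(codes: np.ndarray):
    """All distinct assignments of the multiset of labels to positions."""
    seen_positions = set()
    for perm in itertools.permutations(range(len(codes))):
        relabeled = tuple(codes[list(perm)])
        if relabeled not in seen_positions:
            seen_positions.add(relabeled)
            yield np.array(relabeled)


# -- taxonomic composition -------------------------------------------------

def phylum_relative_abundance(table: OtuTable, taxonomy: TaxonomyTable
                              ) -> pd.DataFrame:
    """Per-sample phylum shares (%) with mean and SE over samples.

    Shares use post-filter sample totals, so they always sum to 100%
    per sample.  Returns phyla x (per-sample columns + ``mean`` +
    ``se``), ordered by decreasing mean share.
    """
    return rank_relative_abundance(table, taxonomy, rank="phylum")


def rank_relative_abundance(table: OtuTable, taxonomy: TaxonomyTable,
                            rank: str = "phylum") -> pd.DataFrame:
    """Relative sequence abundance aggregated at a taxonomic rank."""
    df = table.to_dataframe()
    labels = [taxonomy.rank(otu, rank) for otu in table.otu_ids]
    grouped = df.groupby(pd.Index(labels, name=rank)).sum()
    totals = grouped.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise OtuTableError(f"samples with zero total reads: {empty}")
    shares = 100.0 * grouped / totals
    n = shares.shape[1]
    shares["mean"] = shares.mean(axis=1)
    if n > 1:
        shares["se"] = shares.iloc[:, :n].std(axis=1, ddof=1) / math.sqrt(n)
    else:
        shares["se"] = 0.0
    return shares.sort_values("mean", ascending=False)
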