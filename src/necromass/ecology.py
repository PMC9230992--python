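"""Community-composition statistics on OTU tables.

Implements the distance-based toolkit used for factorial microbiome
experiments: rarefaction (subsampling without replacement), taxonomic
aggregation, Bray-Curtis dissimilarity, principal coordinates analysis
(PCoA), PERMANOVA with sequential sums of squares and free label
permutation, pairwise PERMANOVA with Benjamini-Hochberg correction and
compact letters, the multivariate homogeneity-of-dispersions test,
variance partitioning over groups of explanatory variables via
distance-based redundancy analysis with Ezekiel-adjusted R-squared, and
single-variable db-RDA.

All permutation tests report p = (#{permuted statistic >= observed} + 1) /
(n_perm + 1) and are fully determined by an integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .residues import _compact_letters

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """OTU x sample table of non-negative integer read counts."""

    counts: pd.DataFrame
    marker: str = ""

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dup}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"all-zero samples: {empty}")
        return self.counts / totals


def _as_frame(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    return table.counts if isinstance(table, CountTable) else table


def rarefy(
    table: CountTable | pd.DataFrame, depth: int, seed: int
) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning;
    raises if no sample reaches the depth.  Draws are multivariate
    hypergeometric, so rarefied counts never exceed the originals and each
    kept sample sums exactly to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = _as_frame(table)
    marker = table.marker if isinstance(table, CountTable) else ""
    rng = np.random.default_rng(seed)
    kept: dict[str, np.ndarray] = {}
    dropped = []
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            kept[sample] = col.copy()
        else:
            kept[sample] = rng.multivariate_hypergeometric(col.astype(np.int64), depth)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    if not kept:
        raise ValueError(f"all samples have fewer than {depth} reads")
    out = pd.DataFrame(kept, index=counts.index)
    return CountTable(out, marker=marker)


def aggregate_taxa(
    table: CountTable | pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str,
    other_threshold: float = 1.0,
) -> pd.DataFrame:
    """Relative abundances (percent) aggregated at a taxonomic rank.

    Taxa whose mean relative abundance is strictly below ``other_threshold``
    percent are pooled into ``"others"``; a taxon exactly at the threshold
    is kept.  Columns sum to 100.
    """
    counts = _as_frame(table)
    if rank not in taxonomy.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy columns {list(taxonomy.columns)}")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError(f"all-zero samples: {totals.index[totals == 0].tolist()}")
    labels = taxonomy.reindex(counts.index)[rank].fillna("unclassified")
    rel = 100.0 * counts / totals
    grouped = rel.groupby(labels.to_numpy()).sum()
    small = grouped.mean(axis=1) < other_threshold
    if small.any():
        others = grouped.loc[small].sum(axis=0)
        grouped = grouped.loc[~small]
        grouped.loc["others"] = others
    return grouped


def bray_curtis(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between samples.

    d(i,j) = 1 - 2*sum_k min(x_ik, x_jk) / (sum_k x_ik + sum_k x_jk),
    returned as a square symmetric DataFrame with zero diagonal and
    ``attrs['metric'] = 'braycurtis'``.
    """
    counts = _as_frame(table)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError(f"all-zero samples: {totals.index[totals == 0].tolist()}")
    x = counts.to_numpy(float).T  # samples x OTUs
    d = squareform(pdist(x, metric="braycurtis"))
    out = pd.DataFrame(d, index=counts.columns, columns=counts.columns)
    out.attrs["metric"] = "braycurtis"
    return out


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=1e-10):
        raise ValueError("distance matrix diagonal must be zero")
    return a


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower double-centering of -d^2/2; the workhorse of PCoA and PERMANOVA."""
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


@dataclass
class OrdinationResult:
    """PCoA output: coordinates, eigenvalues, proportion explained."""

    coordinates: pd.DataFrame  # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    negative_eigenvalues: np.ndarray


def pcoa(d: pd.DataFrame) -> OrdinationResult:
    """Principal coordinates analysis via eigendecomposition of the
    Gower-centered matrix.

    Coordinates are eigenvector * sqrt(eigenvalue) for positive eigenvalues;
    negative eigenvalues (non-Euclidean distances) are reported unchanged,
    not corrected.  Axis signs are fixed by making the largest-magnitude
    coordinate on each axis positive, so downstream axis scores (BPC1/BPC2,
    FPC1/FPC2) are reproducible.
    """
    a = _check_distance(d)
    g = gower_center(a)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.index, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
        negative_eigenvalues=evals[evals < -tol],
    )


def _design_matrix(metadata: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Centered dummy/numeric design for the given metadata columns."""
    parts = []
    for col in columns:
        s = metadata[col]
        if s.dtype.kind in "biufc" and s.nunique() > 2:
            parts.append(s.to_numpy(float)[:, None])
        else:
            dummies = pd.get_dummies(s.astype(str), drop_first=True)
            parts.append(dummies.to_numpy(float))
    x = np.hstack(parts) if parts else np.empty((len(metadata), 0))
    return x - x.mean(axis=0, keepdims=True)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x and its rank."""
    if x.shape[1] == 0:
        n = x.shape[0]
        return np.zeros((n, n)), 0
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    u = u[:, :rank]
    return u @ u.T, rank


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table (one row per term plus Residual/Total)."""

    table: pd.DataFrame  # index: terms + Residual + Total; columns df, SS, F, R2, p
    n_permutations: int


def permanova(
    d: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Sequential (Type-I) partitioning of the total sum of squared distances
    following the McArdle-Anderson trace formulation: the Gower-centered
    matrix G has tr(G) = SST = sum_{i<j} d_ij^2 / N, and the SS explained by
    a design X is tr(H_X G).  Pseudo-F per term uses the residual mean
    square of the full model; p-values permute raw sample labels freely
    (no strata).  ``exhaustive=True`` enumerates all N! label orders
    (N <= 8) and returns exact p = #{F_perm >= F_obs}/N!, the identity
    permutation included.
    """
    a = _check_distance(d)
    n = a.shape[0]
    metadata = metadata.loc[d.index]
    for t in terms:
        if metadata[t].nunique() < 2:
            raise ValueError(f"factor {t!r} has a single level")
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    g = gower_center(a)
    sst = np.trace(g)

    hats, dfs = [], []
    prev_hat, prev_rank = np.zeros((n, n)), 0
    cum_cols: list[str] = []
    for t in terms:
        cum_cols.append(t)
        h, rank = _hat(_design_matrix(metadata, cum_cols))
        hats.append(h - prev_hat)
        dfs.append(rank - prev_rank)
        prev_hat, prev_rank = h, rank
    resid_proj = np.eye(n) - prev_hat
    df_res = n - 1 - prev_rank

    def stats_for(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(h * gm)) for h in hats])
        ss_res = float(np.sum(resid_proj * gm))
        return ss_terms, ss_res

    ss_terms, ss_res = stats_for(g)
    ms_res = ss_res / df_res
    f_obs = np.array(
        [(ss / df) / ms_res if df > 0 else np.nan for ss, df in zip(ss_terms, dfs)]
    )

    def f_for(gm: np.ndarray) -> np.ndarray:
        st, sr = stats_for(gm)
        mr = sr / df_res
        return np.array([(s / df) / mr if df > 0 else np.nan for s, df in zip(st, dfs)])

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = np.zeros(len(terms))
        total = 0
        for perm in iter_permutations(range(n)):
            idx = np.array(perm)
            fp = f_for(g[np.ix_(idx, idx)])
            count += fp >= f_obs - 1e-12
            total += 1
        pvals = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            fp = f_for(g[np.ix_(idx, idx)])
            count += fp >= f_obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)
        n_used = n_perm

    rows = []
    for t, df_t, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append({"term": t, "df": df_t, "SS": ss, "pseudo_F": f, "R2": ss / sst, "p": p})
    rows.append(
        {"term": "Residual", "df": df_res, "SS": ss_res, "pseudo_F": np.nan,
         "R2": ss_res / sst, "p": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": sst, "pseudo_F": np.nan, "R2": 1.0, "p": np.nan}
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_used)


def pairwise_permanova(
    d: pd.DataFrame,
    metadata: pd.DataFrame,
    factor: str,
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All level pairs tested by two-group PERMANOVA with BH correction.

    Returns a pairwise table (F, R2, raw and adjusted p) with a compact
    letter per level in ``attrs['letters']``: levels sharing a letter are
    not significantly different at ``alpha`` after FDR adjustment.
    """
    groups = metadata.loc[d.index, factor].astype(str)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    for lvl in levels:
        if (groups == lvl).sum() < 2:
            raise ValueError(f"level {lvl!r} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(levels, 2):
        mask = groups.isin([a, b]).to_numpy()
        sub = d.loc[mask, mask]
        res = permanova(
            sub, metadata.loc[sub.index], [factor],
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        )
        row = res.table.loc[factor]
        rows.append(
            {"group1": a, "group2": b, "pseudo_F": row["pseudo_F"],
             "R2": row["R2"], "p": row["p"]}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
    nonsig = {
        frozenset((r.group1, r.group2))
        for r in out.itertuples()
        if r.p_adj >= alpha
    }
    out.attrs["letters"] = _compact_letters(levels, nonsig)
    return out


@dataclass
class DispersionResult:
    """Multivariate homogeneity-of-dispersions test output."""

    distances: pd.Series  # sample -> distance to its group centroid
    group_means: pd.Series
    f: float
    p: float
    n_permutations: int


def beta_dispersion(
    d: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Test equality of group dispersions around multivariate centroids.

    Samples are embedded by PCoA keeping real axes (positive eigenvalues)
    and imaginary axes (negative eigenvalues).  The distance of a sample to
    its group centroid is sqrt(max(0, d_real^2 - d_imag^2)).  A one-way
    ANOVA F on these distances is tested by permuting group labels and
    recomputing centroids and distances.
    """
    a = _check_distance(d)
    groups = groups.loc[d.index].astype(str)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for lvl in levels:
        if (groups == lvl).sum() < 2:
            raise ValueError(f"group {lvl!r} has a single sample")
    g = gower_center(a)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-10
    real = evecs[:, evals > tol] * np.sqrt(evals[evals > tol])
    imag = evecs[:, evals < -tol] * np.sqrt(-evals[evals < -tol])
    lab = np.asarray(groups)

    def centroid_distances(lab_arr: np.ndarray) -> np.ndarray:
        dist = np.empty(len(lab_arr))
        for lvl in np.unique(lab_arr):
            m = lab_arr == lvl
            cr = real[m].mean(axis=0) if real.size else np.zeros(0)
            ci = imag[m].mean(axis=0) if imag.size else np.zeros(0)
            d2 = np.zeros(m.sum())
            if real.size:
                d2 += ((real[m] - cr) ** 2).sum(axis=1)
            if imag.size:
                d2 -= ((imag[m] - ci) ** 2).sum(axis=1)
            dist[m] = np.sqrt(np.maximum(d2, 0.0))
        return dist

    def anova_f(dist: np.ndarray, lab_arr: np.ndarray) -> float:
        grand = dist.mean()
        ssb = ssw = 0.0
        for lvl in np.unique(lab_arr):
            sub = dist[lab_arr == lvl]
            ssb += len(sub) * (sub.mean() - grand) ** 2
            ssw += ((sub - sub.mean()) ** 2).sum()
        df_b, df_w = len(np.unique(lab_arr)) - 1, len(dist) - len(np.unique(lab_arr))
        if ssw <= 0:
            return 0.0 if ssb <= 1e-12 else np.inf
        return (ssb / df_b) / (ssw / df_w)

    dist_obs = centroid_distances(lab)
    f_obs = anova_f(dist_obs, lab)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        lab_p = lab[rng.permutation(len(lab))]
        if anova_f(centroid_distances(lab_p), lab_p) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    dist_series = pd.Series(dist_obs, index=d.index)
    means = dist_series.groupby(groups.to_numpy()).mean()
    return DispersionResult(
        distances=dist_series, group_means=means, f=float(f_obs), p=p,
        n_permutations=n_perm,
    )


def _adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment; m = rank of the (centered) explanatory design."""
    if n - 1 - m <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)


@dataclass
class VariancePartition:
    """db-RDA variance partitioning across groups of explanatory variables."""

    unique: dict[str, float]
    shared: float
    residual: float
    adj_r2: dict[frozenset, float] = field(repr=False)

    def fractions(self) -> pd.Series:
        s = dict(self.unique)
        s["shared"] = self.shared
        s["residual"] = self.residual
        return pd.Series(s)


def variance_partition(
    d: pd.DataFrame,
    metadata: pd.DataFrame,
    groups: dict[str, list[str]],
) -> VariancePartition:
    """Partition distance-matrix variation among 2-4 explanatory groups.

    For every non-empty subset of groups the adjusted R-squared of the
    corresponding db-RDA is computed; the unique fraction of group g is
    adjR2(all) - adjR2(all without g), the pooled shared fraction is
    adjR2(all) - sum of uniques, and the residual is 1 - adjR2(all), so the
    fractions sum to one by construction (individual fractions may be
    slightly negative, as adjusted R-squared allows).
    """
    if not 2 <= len(groups) <= 4:
        raise ValueError("variance partitioning supports 2-4 explanatory groups")
    a = _check_distance(d)
    n = a.shape[0]
    metadata = metadata.loc[d.index]
    for name, cols in groups.items():
        x = _design_matrix(metadata, cols)
        if x.shape[1] == 0 or np.allclose(x, 0):
            raise ValueError(f"explanatory group {name!r} has zero variance")
    g = gower_center(a)
    sst = np.trace(g)
    names = list(groups)
    adj: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            cols = [c for s in subset for c in groups[s]]
            h, rank = _hat(_design_matrix(metadata, cols))
            r2 = float(np.sum(h * g)) / sst
            adj[frozenset(subset)] = _adjusted_r2(r2, n, rank)
    full = adj[frozenset(names)]
    unique = {
        name: full - adj[frozenset(set(names) - {name})] for name in names
    }
    shared = full - sum(unique.values())
    return VariancePartition(
        unique=unique, shared=shared, residual=1.0 - full, adj_r2=adj
    )


@dataclass
class DbRdaResult:
    """Single-constraint distance-based redundancy analysis."""

    f: float
    r2: float
    p: float
    n_permutations: int


def dbrda_single(
    d: pd.DataFrame,
    variable: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> DbRdaResult:
    """db-RDA of a distance matrix on one numeric explanatory variable.

    R2 = constrained SS / total SS of the Gower-centered matrix; pseudo-F
    uses (1, N-2) degrees of freedom; the p-value permutes the variable.
    """
    a = _check_distance(d)
    x = variable.loc[d.index].to_numpy(float)
    xc = x - x.mean()
    if np.allclose(xc, 0):
        raise ValueError("explanatory variable is constant")
    n = a.shape[0]
    g = gower_center(a)
    sst = np.trace(g)

    def r2_for(xv: np.ndarray) -> float:
        u = xv / np.linalg.norm(xv)
        return float(u @ g @ u) / sst

    r2 = r2_for(xc)
    f = r2 / ((1.0 - r2) / (n - 2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = xc[rng.permutation(n)]
        r2p = r2_for(xp)
        fp = r2p / ((1.0 - r2p) / (n - 2))
        if fp >= f - 1e-12:
            count += 1
    return DbRdaResult(
        f=float(f), r2=float(r2), p=(count + 1) / (n_perm + 1), n_permutations=n_perm
    )
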