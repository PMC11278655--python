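"""Alpha diversity, Bray-Curtis ordination, and permutation statistics.

Conventions match the vegan defaults common in amplicon studies: Shannon in
nats, Simpson reported as Gini-Simpson (1 - sum p^2), Chao1 on raw integer
counts without rarefaction, Bray-Curtis on relative abundances, and
permutation p-values by the add-one rule p = (1 + #{perm >= obs}) / (1 + n).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, kruskal, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_tables import CountTable


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric (tol 1e-12)")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be exactly zero")
        if (v < 0).any():
            raise ValueError("negative dissimilarity")
        self.values = 0.5 * (v + v.T)  # exact symmetry

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(pos, pos)])


@dataclasses.dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # over positive eigenvalues only


@dataclasses.dataclass
class PermutationTestResult:
    statistic_name: str
    statistic_value: float
    effect_size: float | None
    p_value: float
    n_permutations: int
    seed: int | None


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _alpha_one(counts: np.ndarray) -> dict:
    counts = np.asarray(counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample with zero total counts")
    present = counts[counts > 0]
    s_obs = present.size
    p = present / total
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    if s_obs >= 2:
        pielou = shannon / math.log(s_obs)
    else:
        pielou = math.nan  # undefined for a single-taxon sample
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        chao1 = s_obs + f1 * f1 / (2.0 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / 2.0  # bias-corrected form
    return {
        "shannon": shannon,
        "chao1": float(chao1),
        "simpson": simpson,
        "pielou": pielou,
        "observed_otus": s_obs,
    }


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), Chao1, Gini-Simpson, Pielou and richness.

    Pielou is NaN (flagged undefined) for samples with fewer than two
    observed OTUs.  Chao1 uses singleton/doubleton counts on the raw
    integer counts.
    """
    rows = {sid: _alpha_one(row) for sid, row in zip(table.sample_ids, table.counts)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable, presence_absence: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances (or Jaccard on
    presence/absence when requested)."""
    if table.data.shape[0] < 2:
        raise ValueError("need at least two samples")
    if presence_absence:
        condensed = pdist((table.counts > 0).astype(float), metric="jaccard")
    else:
        rel = table.relative_abundance().to_numpy()
        condensed = pdist(rel, metric="braycurtis")
    return DistanceMatrix(table.sample_ids, squareform(condensed))


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Principal coordinate analysis of a dissimilarity matrix.

    Eigendecomposition of the Gower-centered matrix; axes are eigenvectors
    scaled by sqrt(eigenvalue) for eigenvalues > eps * max; negative
    eigenvalues stay in the eigenvalue list (no Lingoes/Cailliez
    correction) but contribute no coordinates, and proportion explained is
    taken over the positive eigenvalues only.
    """
    b = _gower_center(dm.values)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = eps * max(abs(evals[0]), 1.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _group_indices(groups: pd.Series, ids: Sequence[str]) -> np.ndarray:
    groups = pd.Series(groups)
    missing = [i for i in ids if i not in groups.index]
    if missing:
        raise KeyError(f"samples missing from grouping: {missing}")
    labels = groups.loc[list(ids)].astype(str).to_numpy()
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def _pseudo_f(d2: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    a = codes.max() + 1
    iu = np.triu_indices(n, k=1)
    ss_t = d2[iu].sum() / n
    ss_w = 0.0
    for g in range(a):
        members = np.flatnonzero(codes == g)
        if members.size < 2:
            continue
        sub = d2[np.ix_(members, members)]
        ss_w += sub[np.triu_indices(members.size, k=1)].sum() / members.size
    ss_a = ss_t - ss_w
    f = (ss_a / (a - 1)) / (ss_w / (n - a))
    r2 = ss_a / ss_t
    return f, r2


def permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
    permutations: str = "sampled",
) -> PermutationTestResult:
    """One-way PERMANOVA (distance-based pseudo-F) with label permutation.

    ``permutations="exact"`` enumerates every relabelling (feasible only for
    small n); the exact p is then #{F_perm >= F_obs} / n! including the
    identity.  Sampled permutations use the add-one rule.
    """
    codes = _group_indices(groups, dm.ids)
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    if permutations == "sampled" and n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    d2 = dm.values**2
    f_obs, r2 = _pseudo_f(d2, codes)
    if permutations == "exact":
        total = 0
        as_extreme = 0
        for perm in itertools.permutations(range(len(codes))):
            f_p, _ = _pseudo_f(d2, codes[list(perm)])
            total += 1
            if f_p >= f_obs - 1e-12:
                as_extreme += 1
        p = as_extreme / total
        n_done = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            f_p, _ = _pseudo_f(d2, rng.permutation(codes))
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        n_done = n_perm
    return PermutationTestResult("pseudo-F", float(f_obs), float(r2), float(p), n_done, seed)


# ---------------------------------------------------------------------------
# betadisper (homogeneity of multivariate dispersions)
# ---------------------------------------------------------------------------

def dispersion_homogeneity(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[PermutationTestResult, pd.Series]:
    """Distance-to-group-centroid dispersion test.

    Samples are embedded by PCoA keeping real and imaginary (negative
    eigenvalue) axes separately; the squared distance of a sample to its
    group centroid is the positive-axis part minus the negative-axis part,
    floored at zero before the square root.  A one-way F statistic on the
    distances is tested by permuting group labels over the fixed distances.
    """
    codes = _group_indices(groups, dm.ids)
    if (np.bincount(codes) < 2).any():
        raise ValueError("every group needs at least 2 samples")

    b = _gower_center(dm.values)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(abs(evals).max(), 1.0)
    pos, neg = evals > tol, evals < -tol
    y_pos = evecs[:, pos] * np.sqrt(evals[pos])
    y_neg = evecs[:, neg] * np.sqrt(-evals[neg])

    dist = np.empty(len(codes))
    for g in np.unique(codes):
        members = codes == g
        c_pos = y_pos[members].mean(axis=0)
        c_neg = y_neg[members].mean(axis=0)
        d2 = ((y_pos[members] - c_pos) ** 2).sum(axis=1)
        if y_neg.shape[1]:
            d2 = d2 - ((y_neg[members] - c_neg) ** 2).sum(axis=1)
        dist[members] = np.sqrt(np.maximum(d2, 0.0))

    def f_stat(codes_: np.ndarray) -> float:
        groups_vals = [dist[codes_ == g] for g in np.unique(codes_)]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = f_oneway(*groups_vals).statistic
        return 0.0 if not np.isfinite(f) else float(f)

    f_obs = f_stat(codes)
    rng = np.random.default_rng(seed)
    count = sum(f_stat(rng.permutation(codes)) >= f_obs - 1e-12 for _ in range(n_perm))
    p = (1 + count) / (1 + n_perm)
    result = PermutationTestResult("betadisper-F", f_obs, None, float(p), n_perm, seed)
    return result, pd.Series(dist, index=dm.ids, name="distance_to_centroid")


# ---------------------------------------------------------------------------
# group-difference tests (Kruskal-Wallis + pairwise Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def group_difference_tests(
    values: pd.DataFrame,
    groups: pd.Series,
    correction: str = "fdr_bh",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon Kruskal-Wallis across groups plus pairwise two-sided
    Wilcoxon rank-sum tests, BH-corrected across taxa.

    The rank-sum test is exact when both groups have n <= 8 and no ties,
    otherwise the normal approximation with tie and continuity correction
    is used.  Returns (kruskal table, long pairwise table).
    """
    groups = groups.loc[values.index].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")

    kw_rows = []
    pw_rows = []
    for taxon in values.columns:
        x = values[taxon].to_numpy(dtype=float)
        by_level = [x[(groups == lv).to_numpy()] for lv in levels]
        if np.ptp(x) == 0:  # all values identical: H defined as 0
            h, p = 0.0, 1.0
        else:
            h, p = kruskal(*by_level)
        kw_rows.append({"taxon": taxon, "H": float(h), "p_raw": float(p)})
        for a, b in itertools.combinations(range(len(levels)), 2):
            xa, xb = by_level[a], by_level[b]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                pp = 1.0
            else:
                pooled = np.concatenate([xa, xb])
                no_ties = np.unique(pooled).size == pooled.size
                method = "exact" if (len(xa) <= 8 and len(xb) <= 8 and no_ties) else "asymptotic"
                pp = float(
                    mannwhitneyu(xa, xb, alternative="two-sided", method=method,
                                 use_continuity=True).pvalue
                )
            pw_rows.append(
                {"taxon": taxon, "group_a": levels[a], "group_b": levels[b], "p_raw": pp}
            )

    kw = pd.DataFrame(kw_rows).set_index("taxon")
    kw["q"] = multipletests(kw["p_raw"], method=correction)[1]
    pw = pd.DataFrame(pw_rows)
    pw["q"] = np.nan
    for (_, _), idx in pw.groupby(["group_a", "group_b"]).groups.items():
        pw.loc[idx, "q"] = multipletests(pw.loc[idx, "p_raw"], method=correction)[1]
    return kw, pw


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimperResult:
    group_a: str
    group_b: str
    table: pd.DataFrame  # per taxon: average_contribution, percent, cumulative_percent

    @property
    def mean_dissimilarity(self) -> float:
        return float(self.table["average_contribution"].sum())


def simper(table: CountTable, groups: pd.Series) -> SimperResult:
    """Similarity-percentage decomposition of between-group Bray-Curtis.

    For each between-group sample pair the taxon contribution is
    |x_ik - x_jk| / sum_m (x_im + x_jm) on relative abundances; these sum
    over taxa to exactly the pair's Bray-Curtis dissimilarity.  Averaging
    over all between-group pairs and normalising gives percent
    contributions sorted descending with a cumulative column.
    """
    groups = groups.loc[table.data.index].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"simper compares exactly two groups, got {levels}")
    rel = table.relative_abundance()
    ra = rel[(groups == levels[0]).to_numpy()].to_numpy()
    rb = rel[(groups == levels[1]).to_numpy()].to_numpy()
    if ra.shape[0] == 0 or rb.shape[0] == 0:
        raise ValueError("a group has no samples")
    contrib = np.zeros(rel.shape[1])
    n_pairs = 0
    for i in range(ra.shape[0]):
        for j in range(rb.shape[0]):
            denom = (ra[i] + rb[j]).sum()
            contrib += np.abs(ra[i] - rb[j]) / denom
            n_pairs += 1
    contrib /= n_pairs
    out = pd.DataFrame(
        {"average_contribution": contrib}, index=pd.Index(rel.columns, name="taxon")
    )
    total = out["average_contribution"].sum()
    out["percent"] = 100.0 * out["average_contribution"] / total if total > 0 else 0.0
    out = out.sort_values("percent", ascending=False, kind="mergesort")
    out["cumulative_percent"] = out["percent"].cumsum()
    return SimperResult(levels[0], levels[1], out)


def pair_taxon_contributions(
    table: CountTable, sample_i: str, sample_j: str
) -> pd.Series:
    """Per-taxon Bray-Curtis contributions for one sample pair (they sum to
    the pair's dissimilarity; exposed for the decomposition identity)."""
    rel = table.relative_abundance()
    xi, xj = rel.loc[sample_i].to_numpy(), rel.loc[sample_j].to_numpy()
    return pd.Series(np.abs(xi - xj) / (xi + xj).sum(), index=rel.columns)
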