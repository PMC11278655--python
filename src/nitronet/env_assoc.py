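"""Taxon-environment association: Spearman preference profiles and Mantel tests.

Preference profiling correlates each taxon's relative abundance with each
soil property (Spearman), applies Benjamini-Hochberg across all
(taxon, property) pairs jointly, and tallies significant positive/negative
associations per taxon and per property.  Mantel tests correlate a
community dissimilarity matrix with an environmental distance matrix, with
significance from joint row/column permutation of one matrix.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .diversity import DistanceMatrix, bray_curtis
from .io_tables import CountTable, SampleMetadata, TaxonomyMap, aggregate_by_rank

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SpearmanResult:
    rho: float
    p: float
    defined: bool = True


def spearman_corr(x, y) -> SpearmanResult:
    """Spearman rank correlation with the t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties);
    the two-sided p comes from t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df,
    with p = 0 at rho = +/-1.  A constant input yields an undefined,
    flagged result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, defined=False)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p))


@dataclasses.dataclass
class PreferenceProfile:
    """Spearman association of every taxon with every soil property."""

    table: pd.DataFrame  # long: taxon, property, rho, p_raw, q_bh, sign
    q_threshold: float

    def counts_by_taxon(self) -> pd.DataFrame:
        return self._counts("taxon")

    def counts_by_property(self) -> pd.DataFrame:
        return self._counts("property")

    def _counts(self, key: str) -> pd.DataFrame:
        sig = self.table[self.table["sign"] != "none"]
        out = (
            sig.pivot_table(index=key, columns="sign", values="rho", aggfunc="count")
            .reindex(columns=["positive", "negative"], fill_value=0)
            .fillna(0)
            .astype(int)
        )
        out.columns.name = None
        return out


def preference_profile(
    table: CountTable,
    meta: SampleMetadata,
    q_threshold: float = 0.05,
    tax: TaxonomyMap | None = None,
    rank: str | None = "phylum",
) -> PreferenceProfile:
    """Ecological-preference profile of taxa against soil properties.

    By default OTUs are aggregated to phylum first (pass ``rank=None`` for
    OTU-level profiling).  Works on relative abundances; properties with a
    constant value are excluded with a warning.  BH correction pools all
    (taxon, property) pairs into a single decision family; the sign label
    is positive/negative only where q <= q_threshold.
    """
    if rank is not None:
        if tax is None:
            raise ValueError("rank aggregation requires a taxonomy")
        table = aggregate_by_rank(table, tax, rank)
    shared = [s for s in table.sample_ids if s in meta.treatment.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 samples shared between table and metadata")
    rel = table.subset_samples(shared).relative_abundance()
    props = meta.properties.loc[shared]

    usable = []
    for prop in props.columns:
        if np.ptp(props[prop].to_numpy()) == 0:
            logger.warning("property %r is constant; excluded from profiling", prop)
        else:
            usable.append(prop)

    rows = []
    for taxon in rel.columns:
        for prop in usable:
            res = spearman_corr(rel[taxon], props[prop])
            rows.append(
                {"taxon": taxon, "property": prop,
                 "rho": res.rho, "p_raw": res.p, "defined": res.defined}
            )
    long = pd.DataFrame(rows)
    long["q_bh"] = np.nan
    ok = long["defined"] & long["p_raw"].notna()
    if ok.any():
        long.loc[ok, "q_bh"] = multipletests(long.loc[ok, "p_raw"], method="fdr_bh")[1]
    sign = np.where(
        ok & (long["q_bh"] <= q_threshold),
        np.where(long["rho"] > 0, "positive", "negative"),
        "none",
    )
    long["sign"] = sign
    return PreferenceProfile(long.drop(columns="defined"), q_threshold)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str
    seed: int | None


def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = 0,
    permutations: str = "sampled",
) -> MantelResult:
    """Mantel correlation between two distance matrices over the same objects.

    r correlates the strictly-upper-triangle vectors; the null permutes the
    rows and columns of ``dm_b`` jointly (never triangle entries
    independently).  One-sided p for r >= observed by the add-one rule, or
    exact enumeration of all n! object permutations with
    ``permutations="exact"``.
    """
    if dm_a.ids != dm_b.ids:
        raise ValueError("distance matrices must share ids in the same order")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if permutations == "sampled" and n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    va = _tri(dm_a.values)
    b = dm_b.values
    if np.ptp(va) == 0 or np.ptp(_tri(b)) == 0:
        # degenerate (constant) distance structure: correlation undefined
        return MantelResult(math.nan, math.nan, 0, method, seed)

    def corr(vb: np.ndarray) -> float:
        if method == "pearson":
            return float(np.corrcoef(va, vb)[0, 1])
        return float(stats.spearmanr(va, vb).statistic)

    r_obs = corr(_tri(b))
    n = dm_a.n
    if permutations == "exact":
        total = as_extreme = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            r_p = corr(_tri(b[np.ix_(idx, idx)]))
            total += 1
            if r_p >= r_obs - 1e-12:
                as_extreme += 1
        return MantelResult(r_obs, as_extreme / total, total, method, seed)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if corr(_tri(b[np.ix_(idx, idx)])) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm, method, seed)


def property_distance(meta: SampleMetadata, properties: list[str] | None = None) -> DistanceMatrix:
    """Euclidean distance on z-standardized soil properties."""
    props = meta.properties if properties is None else meta.properties[list(properties)]
    z = (props - props.mean()) / props.std(ddof=1).replace(0, np.nan)
    z = z.dropna(axis=1, how="all").fillna(0.0)
    return DistanceMatrix(list(props.index), squareform(pdist(z.to_numpy())))


def phylum_mantel_tests(
    table: CountTable,
    tax: TaxonomyMap,
    meta: SampleMetadata,
    top_n: int = 10,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Mantel r/p between each major phylum's Bray-Curtis matrix (over the
    phylum's OTUs) and the Euclidean distance of each standardized soil
    property, for the ``top_n`` most abundant phyla."""
    phyla_tab = aggregate_by_rank(table, tax, "phylum")
    phyla = list(phyla_tab.data.columns[:top_n])
    rel = table.data
    rows = []
    for k, phylum in enumerate(phyla):
        otus = [o for o in table.otu_ids if tax.rank_of(o, "phylum") == phylum]
        if len(otus) < 2:  # single-OTU phylum: composition is degenerate
            continue
        sub = CountTable(rel[otus].copy()).drop_empty_samples()
        if sub.data.shape[0] < 4:
            continue
        dm_comm = bray_curtis(sub)
        for prop in meta.properties.columns:
            dm_env = property_distance(
                SampleMetadata(
                    treatment=meta.treatment.loc[sub.sample_ids],
                    properties=meta.properties.loc[sub.sample_ids],
                ),
                [prop],
            )
            res = mantel(dm_comm, dm_env, method=method, n_perm=n_perm,
                         seed=None if seed is None else seed + k)
            rows.append({"phylum": phylum, "property": prop, "r": res.r, "p": res.p})
    return pd.DataFrame(rows)
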