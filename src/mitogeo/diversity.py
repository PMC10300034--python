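"""Population summary statistics and structure.

Distances between mitogenomes are counts of differing unmasked sites under
pairwise deletion (sites missing in either sample are skipped). On top of
those distances the module provides haplotype and nucleotide diversity,
one-level AMOVA with a permutation test, pairwise Φst, and PCA of
haplogroup-frequency tables.

AMOVA follows the standard variance-component construction: with N samples
in k groups of sizes n_g and squared distances d²,

    SSD(T) = Σ_{i<j} d²_ij / N
    SSD(W) = Σ_g Σ_{i<j∈g} d²_ij / n_g
    SSD(A) = SSD(T) − SSD(W)

mean squares over df (k−1, N−k), σ²_w = MS(W), σ²_a = (MS(A) − MS(W)) / n'
with n' = (N − Σ n_g²/N) / (k−1), and Φst = σ²_a / (σ²_a + σ²_w). The
p-value is the proportion of whole-label permutations with Φst at least
the observed value, with the add-one correction (b+1)/(m+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .refio import EMPTY_MASK, RecurrentSiteMask, VariantProfile


class DiversityError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str = "pairwise_differences"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise DiversityError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise DiversityError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.values = v

    def submatrix(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep_ids]
        return DistanceMatrix(list(keep_ids), self.values[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _site_map(profile: VariantProfile, mask: RecurrentSiteMask) -> dict[tuple[int, int], str]:
    return {m.site: m.canonical() for m in profile.mutations if not mask.is_masked(m)}


def pairwise_difference(p1: VariantProfile, p2: VariantProfile,
                        mask: RecurrentSiteMask = EMPTY_MASK) -> int:
    """Number of unmasked sites at which two profiles differ (pairwise deletion)."""
    m1, m2 = _site_map(p1, mask), _site_map(p2, mask)
    skip = p1.missing | p2.missing
    d = 0
    for site in m1.keys() | m2.keys():
        if site[0] in skip:
            continue
        if m1.get(site) != m2.get(site):
            d += 1
    return d


def pairwise_distances(profiles: Sequence[VariantProfile],
                       mask: RecurrentSiteMask = EMPTY_MASK) -> DistanceMatrix:
    if len(profiles) < 2:
        raise DiversityError("need at least 2 profiles")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise DiversityError("duplicate sample ids")
    n = len(profiles)
    maps = [_site_map(p, mask) for p in profiles]
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            skip = profiles[i].missing | profiles[j].missing
            mi, mj = maps[i], maps[j]
            d = sum(
                1
                for site in mi.keys() | mj.keys()
                if site[0] not in skip and mi.get(site) != mj.get(site)
            )
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids, vals)


def haplotype_diversity(profiles: Sequence[VariantProfile],
                        mask: RecurrentSiteMask = EMPTY_MASK) -> tuple[float, float]:
    """Nei's haplotype (gene) diversity H with its standard error.

    H = n/(n−1) · (1 − Σ pᵢ²) over haplotype frequencies pᵢ; the variance
    is Nei's large-sample formula. Haplotypes are compared on unmasked
    canonical profiles.
    """
    n = len(profiles)
    if n < 2:
        raise DiversityError("need at least 2 samples")
    keys: dict[tuple, int] = {}
    for p in profiles:
        key = tuple(m.canonical() for m in p.mutations if not mask.is_masked(m))
        keys[key] = keys.get(key, 0) + 1
    p_i = np.array(list(keys.values())) / n
    sum2 = float(np.sum(p_i**2))
    sum3 = float(np.sum(p_i**3))
    h = n / (n - 1) * (1.0 - sum2)
    var = (2.0 / (n * (n - 1))) * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    return h, float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(profiles: Sequence[VariantProfile], genome_length: int,
                         mask: RecurrentSiteMask = EMPTY_MASK) -> float:
    """π: mean per-site pairwise difference, with pairwise deletion of missing sites."""
    n = len(profiles)
    if n < 2:
        raise DiversityError("need at least 2 samples")
    if genome_length <= 0:
        raise DiversityError("genome_length must be positive")
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_difference(profiles[i], profiles[j], mask)
            compared = genome_length - len(profiles[i].missing | profiles[j].missing)
            if compared <= 0:
                continue
            total += d / compared
            pairs += 1
    return total / pairs if pairs else 0.0


# ---------------------------------------------------------------------------
# AMOVA / Φst
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int
    group_sizes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("sigma2_among", self.sigma2_among),
                ("sigma2_within", self.sigma2_within),
                ("pct_among", self.pct_among),
                ("pct_within", self.pct_within),
                ("phi_st", self.phi_st),
                ("p_value", self.p_value),
                ("n_permutations", self.n_permutations),
                ("seed", self.seed),
            ],
            columns=["quantity", "value"],
        )


def _components(d2: np.ndarray, group_idx: list[np.ndarray]) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) from squared distances and group index arrays."""
    n_total = sum(len(g) for g in group_idx)
    k = len(group_idx)
    ssd_total = d2.sum() / (2.0 * n_total)
    ssd_within = sum(d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in group_idx)
    ssd_among = ssd_total - ssd_within
    ms_among = ssd_among / (k - 1)
    ms_within = ssd_within / (n_total - k)
    n_prime = (n_total - sum(len(g) ** 2 for g in group_idx) / n_total) / (k - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_prime
    return sigma_a, sigma_w


def _phi(sigma_a: float, sigma_w: float) -> float:
    tot = sigma_a + sigma_w
    return 0.0 if tot == 0 else sigma_a / tot


def amova(dist: DistanceMatrix, grouping: Mapping[str, str],
          n_permutations: int = 9999, seed: int = 0,
          clamp_negative: bool = False) -> AmovaResult:
    """One-level AMOVA with a whole-label permutation test.

    Negative variance components (possible by construction) are reported as
    computed unless ``clamp_negative``.
    """
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(dist.ids):
        if sid not in grouping:
            raise DiversityError(f"sample '{sid}' missing from grouping")
        groups.setdefault(grouping[sid], []).append(i)
    if len(groups) < 2:
        raise DiversityError("need at least 2 groups")
    for g, members in groups.items():
        if len(members) < 2:
            raise DiversityError(f"group '{g}' has fewer than 2 members")
    names = sorted(groups)
    group_idx = [np.array(groups[g]) for g in names]
    sizes = np.array([len(g) for g in group_idx])
    d2 = dist.values**2
    sigma_a, sigma_w = _components(d2, group_idx)
    if clamp_negative:
        sigma_a = max(sigma_a, 0.0)
    phi_obs = _phi(sigma_a, sigma_w)
    tot = sigma_a + sigma_w
    pct_among = 0.0 if tot == 0 else 100.0 * sigma_a / tot

    rng = np.random.default_rng(seed)
    n = len(dist.ids)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        start = 0
        pidx = []
        for s in sizes:
            pidx.append(perm[start : start + s])
            start += s
        pa, pw = _components(d2, pidx)
        if clamp_negative:
            pa = max(pa, 0.0)
        if _phi(pa, pw) >= phi_obs - 1e-12:
            b += 1
    p_value = (b + 1) / (n_permutations + 1)
    return AmovaResult(
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_st=phi_obs,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        group_sizes={g: len(groups[g]) for g in names},
    )


def pairwise_phist(dist: DistanceMatrix, grouping: Mapping[str, str],
                   n_permutations: int = 9999, seed: int = 0,
                   clamp_negative: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Φst (and permutation p) for every pair of groups; AMOVA on each subset."""
    names = sorted({grouping[i] for i in dist.ids})
    phi = pd.DataFrame(0.0, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            ga, gb = names[a_i], names[b_i]
            keep = [i for i in dist.ids if grouping[i] in (ga, gb)]
            res = amova(dist.submatrix(keep), grouping, n_permutations, seed, clamp_negative)
            phi.loc[ga, gb] = phi.loc[gb, ga] = res.phi_st
            pval.loc[ga, gb] = pval.loc[gb, ga] = res.p_value
    return phi, pval


# ---------------------------------------------------------------------------
# Haplogroup-frequency PCA and Euclidean distances
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # populations x components
    explained_variance: list[float]  # fractions, non-increasing
    loadings: pd.DataFrame  # categories x components


def frequency_pca(freq: pd.DataFrame, tol: float = 1e-12) -> PcaResult:
    """PCA of a populations x categories frequency table.

    Raw frequencies are column-centred (not scaled) and decomposed by SVD;
    coordinates are left singular vectors scaled by the singular values, so
    full-rank inter-population distances equal Euclidean distances between
    centred rows.
    """
    if freq.shape[0] < 2 or freq.shape[1] < 2:
        raise DiversityError("need at least 2 populations and 2 categories")
    x = freq.to_numpy(dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    keep = s > tol * max(1.0, s[0] if len(s) else 1.0)
    if not np.any(keep):
        cols: list[str] = []
        return PcaResult(
            coordinates=pd.DataFrame(np.zeros((freq.shape[0], 0)), index=freq.index, columns=cols),
            explained_variance=[],
            loadings=pd.DataFrame(np.zeros((freq.shape[1], 0)), index=freq.columns, columns=cols),
        )
    u, s, vt = u[:, keep], s[keep], vt[keep]
    cols = [f"PC{i + 1}" for i in range(len(s))]
    coords = pd.DataFrame(u * s, index=freq.index, columns=cols)
    ev = (s**2 / np.sum(s**2)).tolist()
    loadings = pd.DataFrame(vt.T, index=freq.columns, columns=cols)
    return PcaResult(coords, ev, loadings)


def frequency_distance(freq: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between population frequency rows."""
    from scipy.spatial.distance import pdist, squareform

    vals = squareform(pdist(freq.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(list(freq.index), vals, metric="euclidean")
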