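"""Univariate group statistics and voxelwise permutation inference.

* Mann-Whitney U for VS/UWS vs MCS differences: exact (conditional on the
  observed ranks, ties averaged) when n1 + n2 <= 12, otherwise a normal
  approximation with tie-corrected variance and continuity correction.
* Spearman rho for imaging-vs-clinical correlations: Pearson on average
  ranks, exact permutation p for n <= 8, t-approximation otherwise.
* Voxelwise nonparametric correlation between subject maps and a clinical
  score, with family-wise error control by the permutation distribution of
  the maximum |rho| over in-mask voxels (max-statistic method).  Subjects
  whose map rating is 0 or 0.5 are excluded before the analysis.
* Inter-rater agreement as quadratic-weighted kappa on the ordinal scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
from scipy import stats

# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

EXACT_MW_LIMIT = 12  # n1 + n2 at or below this uses exact enumeration


def mann_whitney(x_group, y_group) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, z, p)``.

    U counts pairs where an x observation exceeds a y observation (ties
    count one half), i.e. the U statistic of the first sample.  The exact
    branch enumerates all ways of assigning the observed (tie-averaged)
    ranks to the two groups; p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = np.asarray(x_group, dtype=float)
    y = np.asarray(y_group, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0

    if var == 0.0:  # all values identical across both groups
        return mu, 0.0, 1.0

    sd = np.sqrt(var)
    cc = min(0.5, abs(u - mu))  # continuity correction, never past the mean
    z = (u - mu - np.sign(u - mu) * cc) / sd

    if n <= EXACT_MW_LIMIT:
        u_all = _enumerate_u(ranks, n1)
        m = len(u_all)
        p_le = np.count_nonzero(u_all <= u) / m
        p_ge = np.count_nonzero(u_all >= u) / m
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u, float(z), float(p)


def _enumerate_u(ranks: np.ndarray, n1: int) -> np.ndarray:
    """U statistic of every C(n, n1) assignment of the observed ranks."""
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2
    out = np.empty(comb(n, n1))
    for i, idx in enumerate(combinations(range(n), n1)):
        out[i] = ranks[list(idx)].sum() - offset
    return out


# ---------------------------------------------------------------------------
# Spearman rho
# ---------------------------------------------------------------------------

EXACT_SPEARMAN_LIMIT = 8


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation; returns ``(rho, p_two_sided)``.

    rho is the Pearson correlation of average-ranked values.  For n <= 8 the
    p-value is exact over all n! permutations of one rank vector; otherwise
    it uses the t-approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_SPEARMAN_LIMIT:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(rx_c @ ry_c[list(perm)]) >= obs - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


# ---------------------------------------------------------------------------
# Voxelwise permutation correlation with max-statistic FWE
# ---------------------------------------------------------------------------


@dataclass
class VoxelwiseResult:
    rho: np.ndarray  # per-voxel observed Spearman rho
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    n_permutations: int
    included_subjects: np.ndarray  # indices into the input subject axis


def voxelwise_perm_correlation(
    maps: np.ndarray,
    scores,
    n_permutations: int = 999,
    rng_seed: int = 0,
    exclusion_ratings=None,
    score_name: str = "score",
) -> VoxelwiseResult:
    """Per-voxel Spearman correlation with a permutation null.

    ``maps`` is (n_subjects, n_voxels); ``scores`` one clinical value per
    subject.  Subjects with ``exclusion_ratings`` of 0 or 0.5 are dropped
    (zero/undefined maps would create spurious correlations).  p-values use
    add-one smoothing ((b + 1) / (m + 1)); the FWE-corrected p compares each
    observed |rho| against the permutation distribution of the maximum |rho|
    over voxels.  Deterministic given ``rng_seed``.
    """
    maps = np.asarray(maps, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if maps.ndim != 2 or maps.shape[0] != len(scores):
        raise ValueError("maps must be (n_subjects, n_voxels) aligned with scores")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if exclusion_ratings is not None:
        ratings = np.asarray(exclusion_ratings, dtype=float)
        keep = ratings > 0.5
    else:
        keep = np.ones(len(scores), dtype=bool)
    included = np.flatnonzero(keep)
    if len(included) < 5:
        raise ValueError("need at least 5 included subjects after the rating exclusion")
    sc = scores[included]
    if np.ptp(sc) == 0:
        raise ValueError(f"scores for {score_name!r} are constant after exclusion")
    m = maps[included]
    n = len(included)

    # rank over subjects, per voxel and for the scores
    rm = stats.rankdata(m, axis=0).astype(float)
    rm -= rm.mean(axis=0, keepdims=True)
    norms = np.sqrt((rm**2).sum(axis=0))
    norms[norms == 0] = 1.0  # constant voxels get rho = 0
    rm /= norms
    rs = stats.rankdata(sc).astype(float)
    rs -= rs.mean()
    rs /= np.sqrt((rs**2).sum())

    rho_obs = rm.T @ rs
    abs_obs = np.abs(rho_obs)

    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(maps.shape[1], dtype=int)
    exceed_max = np.zeros(maps.shape[1], dtype=int)
    for _ in range(n_permutations):
        perm_rho = np.abs(rm.T @ rs[rng.permutation(n)])
        exceed += perm_rho >= abs_obs
        exceed_max += perm_rho.max() >= abs_obs
    p_unc = (exceed + 1) / (n_permutations + 1)
    p_fwe = (exceed_max + 1) / (n_permutations + 1)
    return VoxelwiseResult(rho_obs, p_unc, p_fwe, n_permutations, included)


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------


def inter_rater_agreement(ratings_rater1, ratings_rater2, scale=None) -> float:
    """Quadratic-weighted kappa between two raters on an ordinal scale.

    ``scale`` optionally fixes the full ordered category ladder (unused
    levels then still shape the weights); by default the union of observed
    values is used.  Undefined (raises) when the expected disagreement is
    zero, e.g. when both raters use a single common category.
    """
    r1 = np.asarray(ratings_rater1, dtype=float)
    r2 = np.asarray(ratings_rater2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("ratings must be paired 1-D vectors")
    cats = np.asarray(sorted(set(r1) | set(r2)) if scale is None else sorted(scale), dtype=float)
    if len(cats) < 2:
        raise ValueError("agreement undefined: fewer than 2 distinct categories in use")
    idx = {v: i for i, v in enumerate(cats)}
    k = len(cats)
    obs = np.zeros((k, k))
    for a, b in zip(r1, r2):
        obs[idx[a], idx[b]] += 1
    obs /= obs.sum()
    marg1 = obs.sum(axis=1)
    marg2 = obs.sum(axis=0)
    expected = np.outer(marg1, marg2)
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = (i - j) ** 2 / (k - 1) ** 2
    exp_dis = float((w * expected).sum())
    if exp_dis == 0:
        raise ValueError("agreement undefined: expected disagreement is zero")
    return 1.0 - float((w * obs).sum()) / exp_dis
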