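"""Phylogenetic signal in a binary trait (local-extinction status).

Two complementary tests of whether a binary trait (here: locally extinct
vs. still present) is clumped on a phylogeny:

* The D statistic.  The raw quantity is the sister-clade difference sum
  ΣD: nodal trait values are estimated tips-to-root as the unweighted mean
  of the two daughters, and the absolute daughter differences are summed
  over internal nodes.  ΣD_obs is scaled between the means of two null
  distributions — tip-shuffling (no phylogenetic structure) and a Brownian
  threshold model (strong clumping):

      D = (ΣD_obs - mean ΣD_brownian) / (mean ΣD_random - mean ΣD_brownian)

  so D ~ 0 for Brownian-like clumping and D ~ 1 for phylogenetic
  randomness, with Monte-Carlo p-values for departure from either pole.

* SES-MPD.  The mean pairwise patristic distance among the focal tips is
  compared to draws of equally many random tips (tip-label randomization);
  negative standardized effect sizes mean the focal set is phylogenetically
  clumped, with a rank p-value for the clumping side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .trees import Phylogeny, PolytomyError

__all__ = [
    "BinaryTrait",
    "DResult",
    "MPDResult",
    "patristic_matrix",
    "sum_sister_differences",
    "d_statistic",
    "ses_mpd",
    "brownian_threshold_trait",
]


@dataclass
class BinaryTrait:
    """A 0/1 trait defined for every analysis tip."""

    values: dict[str, int]
    prevalence: float

    @classmethod
    def from_mapping(cls, values: Mapping[str, int]) -> "BinaryTrait":
        vals = {str(k): int(v) for k, v in values.items()}
        bad = {k: v for k, v in vals.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"trait values must be 0/1, got {bad}")
        return cls(values=vals, prevalence=sum(vals.values()) / len(vals))


def patristic_matrix(tree: Phylogeny) -> pd.DataFrame:
    """All-pairs tip distances (sum of branch lengths along each path)."""
    return tree.patristic_matrix()


def _trait_vector(tree: Phylogeny, trait) -> np.ndarray:
    values = trait.values if isinstance(trait, BinaryTrait) else dict(trait)
    labels = tree.arrays()["tip_labels"]
    missing = [t for t in labels if t not in values]
    if missing:
        raise KeyError(f"trait missing for tips: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    vec = np.array([values[t] for t in labels], dtype=float)
    if not np.isin(vec, (0.0, 1.0)).all():
        raise ValueError("trait must be binary 0/1")
    return vec


def _sumd_columns(tree: Phylogeny, tip_values: np.ndarray) -> np.ndarray:
    """ΣD for each column of a (n_tips, m) tip-value matrix."""
    arr = tree.arrays()
    post = tree.postorder_internal()  # raises PolytomyError on polytomies
    m = tip_values.shape[1]
    vals = np.zeros((arr["n_nodes"], m))
    vals[: arr["n_tips"]] = tip_values
    sumd = np.zeros(m)
    for node, left, right in post:
        diff = vals[left] - vals[right]
        sumd += np.abs(diff)
        vals[node] = 0.5 * (vals[left] + vals[right])
    return sumd


def sum_sister_differences(tree: Phylogeny, trait) -> float:
    """Observed sister-clade difference sum ΣD for a binary trait.

    Requires a strictly bifurcating tree; resolve polytomies first.
    """
    vec = _trait_vector(tree, trait)
    return float(_sumd_columns(tree, vec[:, None])[0])


def _simulate_brownian_tips(tree: Phylogeny, m: int, rng: np.random.Generator) -> np.ndarray:
    """Brownian values at the tips, one replicate per column (rate 1)."""
    arr = tree.arrays()
    n_nodes, n_tips = arr["n_nodes"], arr["n_tips"]
    vals = np.zeros((n_nodes, m))
    sd = np.sqrt(arr["edge_length"])
    noise = rng.standard_normal((n_nodes, m))
    parent = arr["parent"]
    for node in arr["preorder"]:
        p = parent[node]
        if p >= 0:
            vals[node] = vals[p] + sd[node] * noise[node]
    return vals[:n_tips]


def _threshold_at_prevalence(values: np.ndarray, k: int) -> np.ndarray:
    """Per column, mark the k largest values as 1 (ties broken by order)."""
    n, m = values.shape
    out = np.zeros((n, m))
    if k > 0:
        top = np.argpartition(-values, k - 1, axis=0)[:k]
        np.put_along_axis(out, top, 1.0, axis=0)
    return out


@dataclass
class DResult:
    sum_d_obs: float
    d: float
    p_d_gt_0: float
    p_d_lt_1: float
    n_perm: int
    null_random_mean: float
    null_brownian_mean: float
    null_random: np.ndarray
    null_brownian: np.ndarray


def d_statistic(
    tree: Phylogeny, trait, n_perm: int = 10000, seed: int | None = None
) -> DResult:
    """The D statistic with tip-shuffling and Brownian-threshold nulls."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    vec = _trait_vector(tree, trait)
    k = int(vec.sum())
    if k == 0 or k == vec.size:
        raise ValueError("trait is constant; both null models are degenerate")
    rng = np.random.default_rng(seed)
    sum_d_obs = float(_sumd_columns(tree, vec[:, None])[0])

    # no-structure null: shuffle trait values over tips
    perms = np.empty((vec.size, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(vec)
    null_random = _sumd_columns(tree, perms)

    # Brownian null: continuous simulation thresholded at observed prevalence
    brown = _simulate_brownian_tips(tree, n_perm, rng)
    null_brownian = _sumd_columns(tree, _threshold_at_prevalence(brown, k))

    mean_r, mean_b = float(null_random.mean()), float(null_brownian.mean())
    if np.isclose(mean_r, mean_b):
        raise ValueError("null means coincide; D undefined on this tree/trait")
    d = (sum_d_obs - mean_b) / (mean_r - mean_b)
    # add-one rule keeps Monte-Carlo p-values off exact zero
    p_gt0 = (float((null_brownian >= sum_d_obs).sum()) + 1) / (n_perm + 1)
    p_lt1 = (float((null_random <= sum_d_obs).sum()) + 1) / (n_perm + 1)
    return DResult(
        sum_d_obs=sum_d_obs, d=float(d), p_d_gt_0=p_gt0, p_d_lt_1=p_lt1,
        n_perm=n_perm, null_random_mean=mean_r, null_brownian_mean=mean_b,
        null_random=null_random, null_brownian=null_brownian,
    )


@dataclass
class MPDResult:
    mpd_obs: float
    null_mean: float
    null_sd: float
    ses: float
    p: float
    n_runs: int
    focal_size: int


def _mpd(dist: np.ndarray, idx: np.ndarray) -> float:
    sub = dist[np.ix_(idx, idx)]
    k = idx.size
    return float(sub.sum() / (k * (k - 1)))


def ses_mpd(
    tree: Phylogeny,
    focal_set: Iterable[str],
    n_runs: int = 999,
    seed: int | None = None,
) -> MPDResult:
    """Standardized effect size of mean pairwise distance for a tip set.

    Null: random tip sets of the same size (equivalent to tip-label
    randomization).  ``p`` is the one-sided clumping rank p-value,
    ``(count(null <= obs) + 1) / (n_runs + 1)``.
    """
    labels = tree.arrays()["tip_labels"]
    pos = {t: i for i, t in enumerate(labels)}
    focal = [str(t) for t in focal_set]
    missing = [t for t in focal if t not in pos]
    if missing:
        raise KeyError(f"focal tips not in tree: {missing}")
    if len(set(focal)) != len(focal):
        raise ValueError("focal set contains duplicates")
    k = len(focal)
    if k < 2:
        raise ValueError("focal set needs at least 2 tips")
    if k >= len(labels):
        raise ValueError("focal set must be a proper subset of the tips")
    dist = tree.patristic_matrix().to_numpy()
    obs = _mpd(dist, np.array([pos[t] for t in focal]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_runs)
    for r in range(n_runs):
        null[r] = _mpd(dist, rng.choice(len(labels), size=k, replace=False))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    ses = (obs - null_mean) / null_sd if null_sd > 0 else float("nan")
    p = (float((null <= obs).sum()) + 1) / (n_runs + 1)
    return MPDResult(
        mpd_obs=obs, null_mean=null_mean, null_sd=null_sd, ses=float(ses),
        p=float(p), n_runs=n_runs, focal_size=k,
    )


def brownian_threshold_trait(
    tree: Phylogeny, prevalence: float, seed: int | None = None
) -> BinaryTrait:
    """Binary trait from thresholded Brownian evolution on the tree.

    Tips whose simulated continuous value falls above the (1 - prevalence)
    empirical quantile are scored 1; the realized prevalence is within one
    tip of the target.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    if tree.total_length <= 0:
        raise ValueError("tree has zero total branch length")
    rng = np.random.default_rng(seed)
    values = _simulate_brownian_tips(tree, 1, rng)[:, 0]
    k = max(1, min(values.size - 1, int(round(prevalence * values.size))))
    flags = _threshold_at_prevalence(values[:, None], k)[:, 0].astype(int)
    labels = tree.arrays()["tip_labels"]
    return BinaryTrait(values=dict(zip(labels, (int(f) for f in flags))),
                       prevalence=float(flags.mean()))
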