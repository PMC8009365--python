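"""Phylogenetic signal for binary traits: the D statistic.

D measures how dispersed a binary trait is across the tips of a phylogeny.
The observed sum of sister-clade differences, d_obs, is computed by a
branch-length-weighted down-pass estimating nodal trait values (the same
averaging used for phylogenetically independent contrasts) and summing the
absolute difference between the two daughters of every internal node.  d_obs
is then scaled between two reference expectations obtained by simulation on
the same tree:

* random — the trait shuffled across tips (D = 1 on average), and
* Brownian threshold — a unit-rate Brownian trait thresholded to the
  observed prevalence (D = 0 on average).

D < 0 or near 0 indicates phylogenetic clumping (conservatism); D > 1
indicates overdispersion.  A trait present in all tips or absent from all
tips carries no information and yields an undefined (NA) result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import Phylogeny

__all__ = ["DStatResult", "d_statistic", "sister_clade_difference_sum"]


@dataclass
class DStatResult:
    d_obs: float | None
    mean_d_random: float | None
    mean_d_brownian: float | None
    p_random: float | None   # fraction of permutation d values <= d_obs
    p_brownian: float | None  # fraction of Brownian d values >= d_obs
    undefined: bool = False

    @property
    def D(self) -> float | None:
        if self.undefined:
            return None
        return (self.d_obs - self.mean_d_brownian) / (
            self.mean_d_random - self.mean_d_brownian
        )

    @property
    def conservatism(self) -> bool | None:
        """Significantly clumped relative to the random reference (α=0.05)."""
        if self.undefined:
            return None
        return self.p_random < 0.05

    def display_d(self) -> str:
        return "NA" if self.undefined else f"{self.D:.2f}"


def _contrast_arrays(tree: Phylogeny):
    """Static per-node arrays for the vectorised down-pass."""
    left = np.array([tree.children[v][0] for v in tree.postorder])
    right = np.array([tree.children[v][1] for v in tree.postorder])
    return left, right


def sister_clade_difference_sum(tree: Phylogeny, traits: np.ndarray,
                                equal_weights: bool = False) -> np.ndarray:
    """Sum over internal nodes of |daughter nodal value difference|.

    ``traits`` is (n_tips,) or (n_tips, n_datasets); nodal values are the
    branch-length-weighted averages of daughter values with the usual
    independent-contrasts branch-length adjustment, or plain averages when
    ``equal_weights``.  Returns one d value per dataset.
    """
    x = np.atleast_2d(np.asarray(traits, dtype=float).T).T  # (n_tips, k)
    if x.shape[0] != tree.n_tips:
        raise ValueError("trait length does not match tip count")
    k = x.shape[1]
    vals = np.zeros((tree.n_nodes, k))
    vals[: tree.n_tips] = x
    vlen = tree.branch_lengths.astype(float).copy()
    # guard zero-length cherries: weights fall back to equal
    d_sum = np.zeros(k)
    for v, l, r in zip(tree.postorder, *_contrast_arrays(tree)):
        v1, v2 = vlen[l], vlen[r]
        if equal_weights or v1 + v2 <= 0:
            w1 = w2 = 0.5
            extra = 0.0
        else:
            if v1 == 0 or v2 == 0:
                v1, v2 = v1 + 1e-12, v2 + 1e-12
            w1, w2 = (1 / v1), (1 / v2)
            tot = w1 + w2
            w1, w2 = w1 / tot, w2 / tot
            extra = v1 * v2 / (v1 + v2)
        d_sum += np.abs(vals[l] - vals[r])
        vals[v] = w1 * vals[l] + w2 * vals[r]
        vlen[v] = vlen[v] + extra
    return d_sum


def _brownian_tips(tree: Phylogeny, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-rate Brownian tip values, (n_tips, n_sim)."""
    vals = np.zeros((tree.n_nodes, n_sim))
    order = tree.preorder()
    for v in order:
        p = tree.parent[v]
        if p < 0:
            continue
        sd = np.sqrt(max(tree.branch_lengths[v], 0.0))
        vals[v] = vals[p] + sd * rng.standard_normal(n_sim)
    return vals[: tree.n_tips]


def _threshold_to_prevalence(values: np.ndarray, n_ones: int) -> np.ndarray:
    """Binarise each column so exactly ``n_ones`` tips score 1 (top ranks)."""
    n_tips, k = values.shape
    order = np.argsort(values, axis=0)
    out = np.zeros_like(values)
    top = order[n_tips - n_ones:, :]
    np.put_along_axis(out, top, 1.0, axis=0)
    return out


def d_statistic(tree: Phylogeny, trait: np.ndarray, n_perm: int = 1000,
                n_sim: int = 1000, seed: int = 0,
                equal_weights: bool = False) -> DStatResult:
    """Compute D with permutation and Brownian-threshold references.

    ``trait`` holds one 0/1 value per tip, aligned to ``tree.tip_labels``.
    p_random is the fraction of permutation d values ≤ d_obs (small = more
    clumped than random); p_brownian the fraction of Brownian d values
    ≥ d_obs.  Raw proportions are reported, without +1 smoothing, mirroring
    the conventional implementation.
    """
    trait = np.asarray(trait)
    if trait.shape != (tree.n_tips,):
        raise ValueError("trait must hold one value per tip")
    if not np.isin(trait, (0, 1)).all():
        raise ValueError("trait must be binary")
    n_ones = int(trait.sum())
    if n_ones in (0, tree.n_tips):
        return DStatResult(None, None, None, None, None, undefined=True)
    if min(n_perm, n_sim) < 1:
        raise ValueError("n_perm and n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    d_obs = float(sister_clade_difference_sum(tree, trait, equal_weights)[0])
    perms = rng.permuted(
        np.tile(trait.astype(float), (n_perm, 1)), axis=1
    ).T  # (n_tips, n_perm)
    d_rand = sister_clade_difference_sum(tree, perms, equal_weights)
    bm = _threshold_to_prevalence(_brownian_tips(tree, n_sim, rng), n_ones)
    d_brown = sister_clade_difference_sum(tree, bm, equal_weights)
    return DStatResult(
        d_obs=d_obs,
        mean_d_random=float(d_rand.mean()),
        mean_d_brownian=float(d_brown.mean()),
        p_random=float((d_rand <= d_obs).mean()),
        p_brownian=float((d_brown >= d_obs).mean()),
    )
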