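"""Time-stratified CTMC over biome-occupancy sets (DEC family, ± jumps).

The state space is the power set of the biomes: each state is a bitmask over
biome indices, with the empty (null) range included as an anagenetically
absorbing state that is excluded from cladogenesis and from the root prior.
Anagenetic evolution gains one available biome at rate ``d`` per occupied
source biome and loses one occupied biome at rate ``e`` (a single-biome
range losing its biome enters the null state).  Cladogenesis follows the
classical model families:

* ``DEC`` — single-biome ancestors split sympatrically; widespread ancestors
  split by narrow vicariance (singleton vs complement) or subset sympatry
  (singleton vs full range).
* ``DIVALIKE`` — sympatry for single-biome ancestors, vicariance only for
  widespread ones.
* ``BAYAREALIKE`` — both daughters always inherit the full ancestral range.

``+J`` adds founder-event jumps: one daughter keeps the ancestral range, the
other starts in a single biome outside it (and available in the stratum),
each such ordered outcome carrying weight ``j`` against unit base weights.

Time stratification restricts each stratum's gains, jumps and allowed states
to the biomes already in existence; because biomes only ever appear, the
allowed set shrinks monotonically towards the past.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .occupancy import BiomeAvailability, OccupancyMatrix
from .phylo import Phylogeny

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "RangeStateSpace",
    "RangeProcess",
    "CladoTable",
    "build_process",
    "TreeModel",
    "loglik",
]

FAMILIES = ("DEC", "DIVALIKE", "BAYAREALIKE")
J_MAX = 3.0


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its anagenetic and cladogenetic parameters."""

    family: str = "DEC"
    jump: bool = False
    d: float = 0.1   # dispersal (biome gain) rate, events/Ma per source biome
    e: float = 0.01  # extirpation (biome loss) rate, events/Ma per biome
    j: float = 0.0   # founder-event weight against unit base weights

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.d < 0 or self.e < 0:
            raise ValueError("rates d, e must be >= 0")
        if not self.jump and self.j != 0:
            raise ValueError("j must be 0 when jump is False")
        if not 0 <= self.j <= J_MAX:
            raise ValueError(f"j must lie in [0, {J_MAX}]")

    @property
    def name(self) -> str:
        return self.family + ("+J" if self.jump else "")

    @property
    def k(self) -> int:
        """Number of free parameters (d, e and optionally j)."""
        return 3 if self.jump else 2

    def with_params(self, d=None, e=None, j=None) -> "ModelSpec":
        return ModelSpec(
            self.family,
            self.jump,
            self.d if d is None else float(d),
            self.e if e is None else float(e),
            self.j if j is None else float(j),
        )


class RangeStateSpace:
    """All subsets of the biome set, with per-stratum availability masks."""

    def __init__(self, avail: BiomeAvailability):
        self.avail = avail
        self.n_biomes = avail.n_biomes
        self.n_states = 1 << self.n_biomes  # includes the null state (mask 0)
        self.sizes = np.array([bin(s).count("1") for s in range(self.n_states)])
        # state s allowed in stratum iff every member biome is available there
        self.allowed = np.empty((avail.n_strata(), self.n_states), dtype=bool)
        for st in range(avail.n_strata()):
            ok = avail.available_in_stratum(st)
            biome_mask = int((ok * (1 << np.arange(self.n_biomes))).sum())
            self.allowed[st] = [
                (s & ~biome_mask) == 0 for s in range(self.n_states)
            ]

    def biomes_in(self, state: int) -> list[int]:
        return [b for b in range(self.n_biomes) if state >> b & 1]

    def label(self, state: int) -> str:
        if state == 0:
            return "null"
        return "+".join(self.avail.biomes[b] for b in self.biomes_in(state))


@dataclass
class CladoTable:
    """Normalised cladogenetic outcome distribution for one stratum.

    Flattened arrays over all (ancestor, left, right) outcomes with positive
    base weight; ``prob`` is normalised to sum to 1 within each ancestor.
    """

    anc: np.ndarray
    left: np.ndarray
    right: np.ndarray
    prob: np.ndarray
    kind: np.ndarray  # event class strings

    def rows_for(self, ancestor: int) -> np.ndarray:
        return np.where(self.anc == ancestor)[0]


@dataclass
class RangeProcess:
    """Per-stratum rate matrices and cladogenesis tables."""

    space: RangeStateSpace
    spec: ModelSpec
    Q: list[np.ndarray] = field(default_factory=list)
    clado: list[CladoTable] = field(default_factory=list)


def _clado_events(space: RangeStateSpace, spec: ModelSpec, stratum: int):
    """Yield (anc, left, right, weight, kind) for every allowed outcome."""
    ok = space.allowed[stratum]
    avail_biomes = [
        b for b in range(space.n_biomes) if ok[1 << b]
    ]
    for anc in range(1, space.n_states):
        if not ok[anc]:
            continue
        members = space.biomes_in(anc)
        outcomes: dict[tuple[int, int], str] = {}
        if spec.family == "BAYAREALIKE":
            outcomes[(anc, anc)] = "inheritance"
        elif len(members) == 1:
            outcomes[(anc, anc)] = "sympatry"
        else:
            for b in members:
                single, rest = 1 << b, anc & ~(1 << b)
                outcomes.setdefault((single, rest), "vicariance")
                outcomes.setdefault((rest, single), "vicariance")
                if spec.family == "DEC":
                    outcomes.setdefault((single, anc), "subset")
                    outcomes.setdefault((anc, single), "subset")
        for l_r, kind in sorted(outcomes.items()):
            yield anc, l_r[0], l_r[1], 1.0, kind
        if spec.jump:
            for b in avail_biomes:
                if not anc >> b & 1:
                    yield anc, anc, 1 << b, spec.j, "jump"
                    yield anc, 1 << b, anc, spec.j, "jump"


def build_process(space: RangeStateSpace, spec: ModelSpec,
                  avail: BiomeAvailability | None = None) -> RangeProcess:
    """Build per-stratum rate matrices and cladogenesis tables."""
    if avail is not None and avail is not space.avail:
        space = RangeStateSpace(avail)
    proc = RangeProcess(space, spec)
    S = space.n_states
    for st in range(space.avail.n_strata()):
        ok = space.allowed[st]
        Q = np.zeros((S, S))
        for s in range(1, S):
            if not ok[s]:
                continue
            size = space.sizes[s]
            for b in range(space.n_biomes):
                if s >> b & 1:  # loss of biome b (to null when singleton)
                    Q[s, s & ~(1 << b)] += spec.e
                elif ok[s | (1 << b)]:  # gain, one route per occupied source
                    Q[s, s | (1 << b)] += spec.d * size
            Q[s, s] = -Q[s].sum()
        # null state (row 0) is absorbing; disallowed rows stay zero
        proc.Q.append(Q)

        anc, left, right, w, kind = [], [], [], [], []
        for a, l, r, wt, k in _clado_events(space, spec, st):
            anc.append(a)
            left.append(l)
            right.append(r)
            w.append(wt)
            kind.append(k)
        anc = np.array(anc, dtype=int)
        left = np.array(left, dtype=int)
        right = np.array(right, dtype=int)
        w = np.array(w, dtype=float)
        prob = np.zeros_like(w)
        for a in np.unique(anc):
            rows = anc == a
            tot = w[rows].sum()
            if tot <= 0:
                raise RuntimeError(
                    f"no allowed cladogenetic outcome for ancestor state {a} "
                    f"in stratum {st}"
                )
            prob[rows] = w[rows] / tot
        keep = prob > 0
        proc.clado.append(
            CladoTable(anc[keep], left[keep], right[keep], prob[keep],
                       np.array(kind, dtype=object)[keep])
        )
    return proc


class TreeModel:
    """Pruning likelihood (and sampling support) for one tree + dataset.

    Branches are cut into segments at stratum boundaries; each segment is
    propagated with its stratum's matrix exponential, and conditional
    likelihoods are re-masked (states containing then-unavailable biomes set
    to zero, without renormalisation) whenever a segment crosses into an
    older stratum.  The root prior is uniform over the non-null states
    allowed at the root's age.
    """

    def __init__(self, tree: Phylogeny, occ: OccupancyMatrix,
                 avail: BiomeAvailability, spec: ModelSpec,
                 pmat_cache: dict | None = None):
        occ.check_against_tree(tree)
        if tuple(occ.biomes) != tuple(avail.biomes):
            raise ValueError("occupancy biome columns must match availability order")
        self.tree = tree
        self.avail = avail
        self.spec = spec
        self.space = RangeStateSpace(avail)
        self.process = build_process(self.space, spec)
        occ = occ.reordered(tree.tip_labels)
        self.tip_states = occ.state_masks()
        self.node_stratum = np.array([avail.stratum_of(a) for a in tree.ages])
        # per-node branch segmentation, youngest segment first:
        # (stratum, dt, age at the segment's older end)
        bounds = avail.boundaries()
        self.segments: list[list[tuple[int, float, float]]] = []
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                self.segments.append([])
                continue
            lo, hi = tree.ages[v], tree.ages[p]
            cuts = [lo] + [b for b in bounds if lo < b < hi] + [hi]
            segs = []
            for a, b in zip(cuts[:-1], cuts[1:]):
                segs.append((avail.stratum_of(0.5 * (a + b)), b - a, b))
            self.segments.append(segs)
        for v in range(tree.n_tips):
            st = self.node_stratum[v]
            if not self.space.allowed[st][self.tip_states[v]]:
                raise ValueError(
                    f"tip {tree.tip_labels[v]!r} occupies a biome unavailable "
                    f"at its age ({tree.ages[v]:g} Ma)"
                )
        # transition-matrix cache; shareable across models with identical
        # tree, availability and parameters (e.g. tip-shuffle replicates)
        self._pmats = pmat_cache if pmat_cache is not None else {}
        # filled by _upward():
        self.branch_top: list[np.ndarray | None] = []
        self.seg_vectors: list[list[np.ndarray]] = []
        self.node_cond: list[np.ndarray | None] = []
        self._log_scale = 0.0
        self._upward()

    # -- likelihood -------------------------------------------------------
    def pmat(self, stratum: int, dt: float) -> np.ndarray:
        key = (stratum, round(dt, 12))
        P = self._pmats.get(key)
        if P is None:
            P = expm(self.process.Q[stratum] * dt)
            self._pmats[key] = P
        return P

    def _tip_vector(self, v: int) -> np.ndarray:
        vec = np.zeros(self.space.n_states)
        vec[self.tip_states[v]] = 1.0
        return vec

    def _upward(self) -> None:
        """Tip-to-root pruning pass, storing per-segment vectors."""
        n = self.tree.n_nodes
        S = self.space.n_states
        self.branch_top = [None] * n
        self.seg_vectors = [[] for _ in range(n)]
        self.node_cond = [None] * n
        self._log_scale = 0.0
        cond = [None] * n
        for v in range(self.tree.n_tips):
            cond[v] = self._tip_vector(v)
        for v in self.tree.postorder:
            l, r = self.tree.children[v]
            ul = self._propagate_branch(l, cond[l])
            ur = self._propagate_branch(r, cond[r])
            tab = self.process.clado[self.node_stratum[v]]
            u = np.zeros(S)
            np.add.at(u, tab.anc, tab.prob * ul[tab.left] * ur[tab.right])
            u[~self.space.allowed[self.node_stratum[v]]] = 0.0
            scale = u.max()
            if scale > 0:
                u = u / scale
                self._log_scale += np.log(scale)
            cond[v] = u
            self.node_cond[v] = u
        self._root_cond = cond[self.tree.root]

    def _propagate_branch(self, v: int, vec: np.ndarray) -> np.ndarray:
        """Propagate child-side conditionals to the top (older end) of v."""
        segs = self.segments[v]
        stored = []
        for stratum, dt, _age_old in segs:
            stored.append(vec)
            vec = self.pmat(stratum, dt) @ vec
            vec = vec.copy()
            vec[~self.space.allowed[stratum]] = 0.0
        self.seg_vectors[v] = stored
        self.branch_top[v] = vec
        return vec

    def root_prior(self) -> np.ndarray:
        st = self.node_stratum[self.tree.root]
        ok = self.space.allowed[st].copy()
        ok[0] = False
        prior = ok.astype(float)
        return prior / prior.sum()

    def loglik(self) -> float:
        L = float(self.root_prior() @ self._root_cond)
        if L <= 0:
            return -np.inf
        return np.log(L) + self._log_scale


def loglik(tree: Phylogeny, occ: OccupancyMatrix, spec: ModelSpec,
           avail: BiomeAvailability) -> float:
    """Log-likelihood of tip biome occupancies under a range-evolution model."""
    return TreeModel(tree, occ, avail, spec).loglik()
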