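"""Protein distances, neighbor joining and bootstrap clade support.

Distance kinds
--------------
``p``             observed proportion of differing sites.
``poisson``       -ln(1-p), the Poisson correction.
``poisson_gamma`` a*((1-p)^(-1/a) - 1): Poisson correction with
                  gamma-distributed rate variation across sites, shape ``a``
                  (the study uses shape 5).
``jtt_ml``        one-parameter maximum-likelihood time under the empirical
                  JTT replacement model (Jones-Taylor-Thornton 1992).
``jtt_ml_gamma``  as above with rates integrated over a discrete gamma
                  (5 categories, mean rate per category).

Trees are dendropy objects; neighbor joining is the standard agglomerative
algorithm with the Q criterion, made fully deterministic by a lexicographic
tie-break on cluster labels.  Bootstrap support is the percentage of
column-resampled replicates whose NJ tree contains each internal bipartition
of the point-estimate tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .core_alignment import ColumnPolicy, apply_column_policy
from .seq_io import GAP, Alignment

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
X_CODE = 20
GAP_CODE = -1


class SaturationError(ValueError):
    """p-distance at or beyond the model's valid range (p >= 1)."""


# ---------------------------------------------------------------------------
# JTT model machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def jtt_model() -> tuple[np.ndarray, np.ndarray]:
    """Return (Q, pi): the JTT rate matrix normalised to one expected
    substitution per unit time, and its equilibrium frequencies."""
    with resources.as_file(resources.files("smydkit.data") / "jtt.json") as p:
        d = json.loads(Path(p).read_text())
    assert d["order"] == AA_ORDER
    pi = np.array(d["frequencies"], dtype=float)
    pi = pi / pi.sum()
    S = np.zeros((20, 20))
    vals = d["exchangeabilities_lower_triangle"]
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = vals[k]
            k += 1
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(pi * np.diag(Q)).sum()
    return Q, pi


@lru_cache(maxsize=1)
def _jtt_eigen() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition of the reversible JTT generator."""
    Q, pi = jtt_model()
    sp = np.sqrt(pi)
    A = (sp[:, None] * Q) / sp[None, :]
    lam, V = np.linalg.eigh((A + A.T) / 2)
    left = V.T * sp[None, :]          # V^T D
    right = V / sp[:, None]           # D^-1 V
    return lam, right, left


def jtt_transition_matrix(t: float, rates: np.ndarray | None = None) -> np.ndarray:
    """P(t) = expm(Q t), optionally averaged over a set of site rates."""
    lam, right, left = _jtt_eigen()
    if rates is None:
        P = (right * np.exp(lam * t)) @ left
    else:
        P = np.zeros((20, 20))
        for r in rates:
            P += (right * np.exp(lam * r * t)) @ left
        P /= len(rates)
    return np.clip(P, 1e-300, None)


def discrete_gamma_rates(shape: float, k: int = 5) -> np.ndarray:
    """Mean rates of ``k`` equal-probability gamma categories (mean 1)."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    cdf_hi = gamma_dist.cdf(edges[1:], a=shape + 1, scale=1.0 / shape)
    cdf_lo = gamma_dist.cdf(edges[:-1], a=shape + 1, scale=1.0 / shape)
    return k * (cdf_hi - cdf_lo)


# ---------------------------------------------------------------------------
# Distance models
# ---------------------------------------------------------------------------

DISTANCE_KINDS = ("p", "poisson", "poisson_gamma", "jtt_ml", "jtt_ml_gamma")


@dataclass(frozen=True)
class DistanceModel:
    kind: str = "poisson_gamma"
    gamma_shape: float = 5.0
    gamma_categories: int = 5

    def __post_init__(self) -> None:
        if self.kind not in DISTANCE_KINDS:
            raise ValueError(f"unknown distance kind {self.kind!r}")
        if "gamma" in self.kind and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")


def p_to_distance(p: float, model: DistanceModel) -> float:
    """Transform an observed proportion of differences to a distance."""
    if model.kind == "p":
        return float(p)
    if p >= 1.0:
        raise SaturationError(f"saturated: p = {p} >= 1")
    if model.kind == "poisson":
        return float(-np.log1p(-p))
    if model.kind == "poisson_gamma":
        a = model.gamma_shape
        return float(a * ((1.0 - p) ** (-1.0 / a) - 1.0))
    raise ValueError(f"{model.kind} has no closed form in p")


def encode_rows(rows: list[str]) -> np.ndarray:
    """Encode gapped rows as an (n, L) int8 matrix (gap=-1, X=20)."""
    lut = np.full(256, GAP_CODE, dtype=np.int8)
    for aa, i in _AA_INDEX.items():
        lut[ord(aa)] = i
    lut[ord("X")] = X_CODE
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    return lut[arr]


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(mismatches, usable sites) for encoded rows; X mismatches everything."""
    usable = (a != GAP_CODE) & (b != GAP_CODE)
    n = int(usable.sum())
    if n == 0:
        return 0, 0
    au, bu = a[usable], b[usable]
    mism = int(((au != bu) | (au == X_CODE) | (bu == X_CODE)).sum())
    return mism, n


def _jtt_pair_distance(a: np.ndarray, b: np.ndarray, model: DistanceModel) -> float:
    use = (a >= 0) & (a < 20) & (b >= 0) & (b < 20)
    if not use.any():
        raise ValueError("no usable sites for JTT distance")
    N = np.zeros((20, 20))
    np.add.at(N, (a[use], b[use]), 1.0)
    if np.trace(N) == N.sum():
        return 0.0
    rates = (
        discrete_gamma_rates(model.gamma_shape, model.gamma_categories)
        if model.kind == "jtt_ml_gamma" else None
    )
    nz = N > 0

    def neg_loglik(t: float) -> float:
        P = jtt_transition_matrix(t, rates)
        return -float((N[nz] * np.log(P[nz])).sum())

    res = minimize_scalar(neg_loglik, bounds=(1e-8, 50.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def pairwise_distance(
    a: str, b: str, model: DistanceModel, policy: ColumnPolicy | None = None
) -> float:
    """Distance between two gapped rows of equal length.

    The column policy is applied to the two-row alignment; for a single pair
    partial/complete deletion reduce to using the sites where both rows are
    non-gap, which is also what pairwise deletion prescribes.
    """
    if len(a) != len(b):
        raise ValueError("rows have unequal lengths")
    enc = encode_rows([a, b])
    if model.kind in ("jtt_ml", "jtt_ml_gamma"):
        return _jtt_pair_distance(enc[0], enc[1], model)
    mism, n = _pair_counts(enc[0], enc[1])
    if n == 0:
        raise ValueError("zero usable sites")
    return p_to_distance(mism / n, model)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if (m < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("nonzero diagonal")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def distance_matrix(
    al: Alignment,
    model: DistanceModel | None = None,
    policy: ColumnPolicy | None = None,
) -> DistanceMatrix:
    """All-pairs distances under a column policy.

    partial/complete deletion first drop low-coverage columns globally;
    residual gaps within kept columns are then excluded per pair (pairwise
    deletion simply keeps all columns at the first step).  Any pair that
    fails (saturation, no shared sites) aborts with an error naming it.
    """
    model = model or DistanceModel()
    policy = policy or ColumnPolicy()
    kept, _ = apply_column_policy(al, policy)
    enc = encode_rows([s for _, s in al.rows])[:, kept]
    ids = al.ids
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if model.kind in ("jtt_ml", "jtt_ml_gamma"):
                    d = _jtt_pair_distance(enc[i], enc[j], model)
                else:
                    mism, nn = _pair_counts(enc[i], enc[j])
                    if nn == 0:
                        raise ValueError("zero usable sites")
                    d = p_to_distance(mism / nn, model)
            except ValueError as exc:
                raise ValueError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            D[i, j] = D[j, i] = d
    return DistanceMatrix(taxa=list(ids), matrix=D)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Agglomerative NJ returning an unrooted tree (trifurcating seed node).

    Join selection minimises Q(i,j) = (m-2) d(i,j) - r(i) - r(j); exact ties
    are broken by the lexicographically smallest pair of cluster labels,
    where a cluster is labelled by its smallest member taxon.  Negative
    branch lengths are clamped to zero with the deficit moved to the sibling
    edge; the raw value is kept on the edge as ``raw_length``.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(D.taxa)
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: dict[int, dendropy.Node] = {}
    labels: dict[int, str] = {}
    for i, t in enumerate(D.taxa):
        nd = dendropy.Node(taxon=tns.get_taxon(t))
        nodes[i] = nd
        labels[i] = t
    d = {(i, j): D.matrix[i, j] for i in range(n) for j in range(n)}
    active = list(range(n))
    nxt = n

    def attach(parent: dendropy.Node, child: dendropy.Node, raw: float) -> None:
        parent.add_child(child)
        child.edge.length = max(raw, 0.0)
        child.edge.raw_length = raw

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[(i, k)] for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[(i, j)] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best_q is None or q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and key < best[0]
                ):
                    best_q = q
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[(i, j)] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[(i, j)] - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            li_c, lj_c = 0.0, d[(i, j)]
        elif lj < 0:
            li_c, lj_c = d[(i, j)], 0.0
        else:
            li_c, lj_c = li, lj
        new = dendropy.Node()
        new.add_child(nodes[i])
        nodes[i].edge.length = li_c
        nodes[i].edge.raw_length = li
        new.add_child(nodes[j])
        nodes[j].edge.length = lj_c
        nodes[j].edge.raw_length = lj
        nodes[nxt] = new
        labels[nxt] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            d[(nxt, k)] = d[(k, nxt)] = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
        d[(nxt, nxt)] = 0.0
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = sorted(active, key=lambda c: labels[c])
    a = 0.5 * (d[(i, j)] + d[(i, k)] - d[(j, k)])
    b = 0.5 * (d[(i, j)] + d[(j, k)] - d[(i, k)])
    c = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
    center = dendropy.Node()
    for node_idx, raw in ((i, a), (j, b), (k, c)):
        center.add_child(nodes[node_idx])
        nodes[node_idx].edge.length = max(raw, 0.0)
        nodes[node_idx].edge.raw_length = raw
    tree.seed_node = center
    tree.update_taxon_namespace()
    return tree


# ---------------------------------------------------------------------------
# Splits, Robinson-Foulds, patristic distances
# ---------------------------------------------------------------------------

def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree as canonical leaf-name sets.

    Each split is represented by the side that does not contain the
    lexicographically smallest leaf.
    """
    leaves = _leaf_labels(tree)
    anchor = min(leaves)
    n = len(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = leaves - below if anchor in below else below
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric-difference (RF) distance between two unrooted trees."""
    if _leaf_labels(t1) != _leaf_labels(t2):
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def _adjacency(tree: dendropy.Tree) -> dict:
    adj: dict = {}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            w = ch.edge.length or 0.0
            sup = getattr(ch, "support", None)
            adj.setdefault(node, []).append((ch, w, sup, not ch.is_leaf()))
            adj.setdefault(ch, []).append((node, w, sup, not ch.is_leaf()))
    return adj


def path_metrics(tree: dendropy.Tree, from_label: str) -> dict[str, tuple[float, float]]:
    """From one leaf to every other leaf: (patristic distance, minimum
    support over internal edges on the path; 100 when the path crosses no
    supported internal edge or supports are absent)."""
    start = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == from_label
    )
    adj = _adjacency(tree)
    out: dict[str, tuple[float, float]] = {}
    stack = [(start, 0.0, 100.0, None)]
    seen = {start}
    while stack:
        node, dist, minsup, _ = stack.pop()
        if node.is_leaf() and node is not start:
            out[node.taxon.label] = (dist, minsup)
        for nb, w, sup, internal in adj.get(node, []):
            if nb in seen:
                continue
            seen.add(nb)
            ms = minsup
            if internal and sup is not None:
                ms = min(ms, sup)
            stack.append((nb, dist + w, ms, None))
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates >= 1 required")


def _nj_from_encoded(enc: np.ndarray, ids: list[str], model: DistanceModel) -> dendropy.Tree:
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model.kind in ("jtt_ml", "jtt_ml_gamma"):
                d = _jtt_pair_distance(enc[i], enc[j], model)
            else:
                mism, nn = _pair_counts(enc[i], enc[j])
                if nn == 0:
                    raise ValueError(f"pair ({ids[i]}, {ids[j]}): zero usable sites")
                d = p_to_distance(mism / nn, model)
            D[i, j] = D[j, i] = d
    return neighbor_joining(DistanceMatrix(taxa=list(ids), matrix=D))


def bootstrap_support(
    al: Alignment,
    model: DistanceModel,
    policy: ColumnPolicy,
    tree: dendropy.Tree,
    cfg: BootstrapConfig,
) -> dendropy.Tree:
    """Annotate the point-estimate NJ tree with bootstrap percentages.

    Columns (after the global column policy) are resampled with replacement;
    each internal edge of ``tree`` receives the percentage of replicate NJ
    trees containing its bipartition, stored both as a numeric ``support``
    attribute and as the internal-node label.
    """
    if al.n_rows < 4:
        raise ValueError("bootstrap requires >= 4 rows")
    kept, _ = apply_column_policy(al, policy)
    enc = encode_rows([s for _, s in al.rows])[:, kept]
    ids = al.ids
    rng = np.random.default_rng(cfg.seed)
    L = enc.shape[1]
    counts: dict[frozenset[str], int] = {s: 0 for s in bipartitions(tree)}
    for _ in range(cfg.n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_tree = _nj_from_encoded(enc[:, cols], ids, model)
        for s in bipartitions(rep_tree):
            if s in counts:
                counts[s] += 1

    leaves = _leaf_labels(tree)
    anchor = min(leaves)
    n = len(leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = leaves - below if anchor in below else below
        if 2 <= len(side) <= n - 2:
            pct = 100.0 * counts[frozenset(side)] / cfg.n_replicates
            node.support = pct
            node.label = f"{pct:g}"
    return tree


def supports_from_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Parse internal-node labels as numeric supports (after read_newick)."""
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            node.support = float(node.label)
        except ValueError:
            pass
    return tree
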