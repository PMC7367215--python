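"""Population structure: PCA, supervised admixture, representatives, trees.

This module carries the sample-selection machinery for an admixed cohort:

* genotype PCA with out-of-sample projection — per-locus standardization by
  mean 2p and scale sqrt(2p(1-p)), eigen-decomposition of the standardized
  genotype covariance;
* supervised admixture: maximum-likelihood admixture proportions Q for a
  genotype vector under g_m ~ Binomial(2, Σ_k q_k f_km) with the ancestral
  AF matrix F held fixed (built from labeled reference panels), fitted by
  EM — the likelihood is concave in Q for fixed F, so the uniform start is
  only a tie-breaking convention;
* representative selection: within each group the sample closest (Euclidean)
  to the group centroid in PC space, reported with its admixture ratios;
* identity-by-state allele-sharing distances and a neighbor-joining tree
  with newick export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_af import MISSING, AFPanel, GenotypeMatrix, InputError
from .simulate import ParameterError

_F_CLIP = 1e-6


# ----------------------------------------------------------------- PCA

@dataclass
class PCAModel:
    locus_means: np.ndarray  # 2p over kept loci
    locus_scales: np.ndarray  # sqrt(2p(1-p))
    loadings: np.ndarray  # (M_kept, D), orthonormal columns
    reference_coords: np.ndarray  # (N_ref, D)
    eigenvalues: np.ndarray  # (D,) variances of the reference coords
    kept: np.ndarray  # bool mask over the input loci (monomorphic dropped)


def _standardize(geno: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    g = geno.astype(float)
    miss = geno == MISSING
    g[miss] = 0.0
    x = (g - means) / scales
    x[miss] = 0.0  # mean imputation: standardized zero
    return x


def fit_pca(reference: GenotypeMatrix, d: int = 2) -> PCAModel:
    """Fit the genotype PCA on a reference cohort.

    Monomorphic loci (zero scale) are dropped and recorded in the model's
    ``kept`` mask. Deterministic up to per-component sign, fixed by making
    the largest-magnitude loading of each component positive.
    """
    geno = reference.genotypes
    called = geno != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(geno == MISSING, 0, geno).sum(axis=0) / np.maximum(2 * n_called, 1)
    kept = (n_called > 0) & (p > 0) & (p < 1)
    means = 2.0 * p[kept]
    scales = np.sqrt(means * (1.0 - p[kept]))
    x = _standardize(geno[:, kept], means, scales)
    rank = min(x.shape)
    if not 1 <= d <= rank:
        raise ParameterError(f"d={d} exceeds rank {rank}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = vt[:d].T
    sign = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(d)])
    sign[sign == 0] = 1.0
    loadings *= sign
    coords = x @ loadings
    eig = s[:d] ** 2 / max(reference.n_samples - 1, 1)
    return PCAModel(locus_means=means, locus_scales=scales, loadings=loadings,
                    reference_coords=coords, eigenvalues=eig, kept=kept)


def project(model: PCAModel, g: np.ndarray) -> np.ndarray:
    """Project a genotype vector (over the model's input loci) into PC space.

    Missing entries contribute zero after standardization; an all-missing
    vector lands at the origin.
    """
    g = np.asarray(g)
    if g.ndim == 1:
        g = g[None, :]
    x = _standardize(g[:, model.kept], model.locus_means, model.locus_scales)
    out = x @ model.loadings
    return out[0] if out.shape[0] == 1 else out


# ------------------------------------------------------ supervised admixture

@dataclass
class AdmixtureModel:
    F: np.ndarray  # (K, M) fixed ancestral AFs
    Q: np.ndarray  # (K,) or (N, K) on the simplex
    loglik: float
    loglik_path: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def panel_F(panels: Sequence[AFPanel]) -> np.ndarray:
    """Stack reference panels into the ancestral AF matrix F (clipped away
    from {0,1}; unclipped vertices break the EM updates)."""
    f = np.vstack([p.records["af"].to_numpy(float) for p in panels])
    return np.clip(f, _F_CLIP, 1.0 - _F_CLIP)


def supervised_admixture(
    g: np.ndarray,
    F: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> AdmixtureModel:
    """Maximum-likelihood admixture proportions for one genotype vector.

    EM update (M' = number of non-missing loci, p_m = Σ_k q_k f_km):

        q_k <- q_k/(2M') · Σ_m [ g_m f_km / p_m + (2-g_m)(1-f_km)/(1-p_m) ]

    Convergence when the log-likelihood gain drops below ``tol`` or after
    ``max_iter`` sweeps; the log-likelihood is nondecreasing throughout.
    """
    F = np.clip(np.asarray(F, dtype=float), _F_CLIP, 1.0 - _F_CLIP)
    if F.ndim != 2 or F.shape[0] < 1:
        raise InputError("F must be a K x M matrix with K >= 1")
    k = F.shape[0]
    g = np.asarray(g)
    use = g != MISSING
    if not use.any():
        raise InputError("no usable loci (all genotypes missing)")
    gm = g[use].astype(float)
    fm = F[:, use]
    m_used = gm.size
    q = np.full(k, 1.0 / k)
    const = np.log(2.0) * float((gm == 1).sum())  # binomial coefficients

    def _loglik(p: np.ndarray) -> float:
        return const + float(gm @ np.log(p) + (2.0 - gm) @ np.log(1.0 - p))

    p = q @ fm
    ll = _loglik(p)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = (gm / p) @ fm.T + ((2.0 - gm) / (1.0 - p)) @ (1.0 - fm).T
        q = q * w / (2.0 * m_used)
        q = np.clip(q, 0.0, None)
        q /= q.sum()
        p = q @ fm
        ll_new = _loglik(p)
        path.append(ll_new)
        gain = ll_new - ll
        ll = ll_new
        if gain < tol:
            converged = True
            break
    return AdmixtureModel(F=F, Q=q, loglik=ll, loglik_path=path,
                          n_iter=it, converged=converged)


def supervised_admixture_batch(
    geno: np.ndarray,
    F: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Vectorized EM over many samples at once; returns Q (N, K).

    Same update as :func:`supervised_admixture`; convergence is judged on
    the total log-likelihood, which is adequate for descriptive Q estimates
    over a cohort.
    """
    F = np.clip(np.asarray(F, dtype=float), _F_CLIP, 1.0 - _F_CLIP)
    k, m = F.shape
    n = geno.shape[0]
    g = geno.astype(float)
    use = geno != MISSING
    g[~use] = 0.0  # missing loci contribute nothing to either term
    two = np.where(use, 2.0, 0.0)
    m_used = use.sum(axis=1).astype(float)  # (N,)
    q = np.full((n, k), 1.0 / k)
    ll_prev = -np.inf
    for _ in range(max_iter):
        p = q @ F  # (N, M)
        np.clip(p, _F_CLIP, 1.0 - _F_CLIP, out=p)
        w = (g / p) @ F.T + ((two - g) / (1.0 - p)) @ (1.0 - F).T
        q = q * w / (2.0 * m_used[:, None])
        q = np.clip(q, 0.0, None)
        q /= q.sum(axis=1, keepdims=True)
        p = q @ F
        np.clip(p, _F_CLIP, 1.0 - _F_CLIP, out=p)
        ll = float((g * np.log(p) + (two - g) * np.log(1.0 - p)).sum())
        if ll - ll_prev < tol * n:
            break
        ll_prev = ll
    return q


# ----------------------------------------------------- representative choice

@dataclass
class Representative:
    group: str
    sample_id: str
    score: float  # Euclidean distance to the group centroid in PC space
    q: np.ndarray

    def to_dict(self) -> dict:
        return {"group": self.group, "sample_id": self.sample_id,
                "score": self.score, "q": [float(x) for x in self.q]}


def select_representatives(
    coords: np.ndarray,
    Q: np.ndarray,
    grouping: Sequence[str],
    sample_ids: Sequence[str],
) -> dict[str, Representative]:
    """Pick each group's most central sample in PC space.

    Score = Euclidean distance to the group centroid; ties broken by higher
    dominant-ancestry Q, then lexicographic sample id.
    """
    coords = np.asarray(coords, dtype=float)
    Q = np.asarray(Q, dtype=float)
    groups = pd.Series(list(grouping))
    out: dict[str, Representative] = {}
    for grp in sorted(groups.unique()):
        idx = np.flatnonzero((groups == grp).to_numpy())
        centroid = coords[idx].mean(axis=0)
        dists = np.linalg.norm(coords[idx] - centroid, axis=1)
        ranked = sorted(
            range(len(idx)),
            key=lambda j: (dists[j], -float(Q[idx[j]].max()), str(sample_ids[idx[j]])),
        )
        best = idx[ranked[0]]
        out[str(grp)] = Representative(group=str(grp), sample_id=str(sample_ids[best]),
                                       score=float(dists[ranked[0]]), q=Q[best])
    return out


def representatives_json(reps: dict[str, Representative],
                         path: str | Path | None = None) -> str:
    payload = json.dumps({g: r.to_dict() for g, r in reps.items()}, indent=2)
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload


# ----------------------------------------------------------- IBS distances

def ibs_distance(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Identity-by-state distance matrix.

    d(i,j) = 1 - Σ_m (2 - |g_im - g_jm|) / (2 M_ij) over mutually
    non-missing loci; symmetric, zero diagonal, values in [0,1].
    """
    geno = g.genotypes if isinstance(g, GenotypeMatrix) else np.asarray(g)
    n = geno.shape[0]
    called = geno != MISSING
    gf = geno.astype(float)
    d = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called
        diff = np.abs(gf - gf[i])
        diff[~both] = 0.0
        m_ij = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(m_ij > 0, diff.sum(axis=1) / (2.0 * np.maximum(m_ij, 1)), 0.0)
        d[i] = row
    d[np.diag_indices(n)] = 0.0
    return (d + d.T) / 2.0


# -------------------------------------------------------- neighbor joining

@dataclass
class Tree:
    """Unrooted tree as an adjacency map with branch lengths."""

    adjacency: dict[str, dict[str, float]]
    leaves: list[str]

    def newick(self) -> str:
        # root at an internal node when one exists, else at the first leaf
        internal = [n for n in self.adjacency if n not in self.leaves]
        root = internal[0] if internal else self.leaves[0]

        def _sub(node: str, parent: str | None) -> str:
            children = [(nbr, ln) for nbr, ln in self.adjacency[node].items() if nbr != parent]
            if not children:
                return node
            parts = [f"{_sub(nbr, node)}:{ln:.10g}" for nbr, ln in children]
            label = node if node in self.leaves else ""
            return f"({','.join(parts)}){label}"

        return _sub(root, None) + ";"

    def to_newick_file(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")

    def leaf_distance_matrix(self) -> pd.DataFrame:
        """Path-length distances between all leaf pairs."""
        import heapq

        dm = pd.DataFrame(0.0, index=self.leaves, columns=self.leaves)
        for src in self.leaves:
            dist = {src: 0.0}
            heap = [(0.0, src)]
            while heap:
                d0, node = heapq.heappop(heap)
                if d0 > dist.get(node, np.inf):
                    continue
                for nbr, ln in self.adjacency[node].items():
                    nd = d0 + ln
                    if nd < dist.get(nbr, np.inf):
                        dist[nbr] = nd
                        heapq.heappush(heap, (nd, nbr))
            for dst in self.leaves:
                dm.loc[src, dst] = dist[dst]
        return dm

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial leaf bipartitions, each as the smaller/lexic side."""
        out: set[frozenset[str]] = set()

        def _collect(node: str, parent: str) -> set[str]:
            acc = {node} if node in self.leaves else set()
            for nbr in self.adjacency[node]:
                if nbr != parent:
                    acc |= _collect(nbr, node)
            return acc

        seen = set()
        for u in self.adjacency:
            for v in self.adjacency[u]:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                side = _collect(v, u)
                other = set(self.leaves) - side
                if len(side) >= 2 and len(other) >= 2:
                    out.add(frozenset(min(side, other, key=lambda s: (len(s), sorted(s)))))
        return out


def neighbor_joining(d: np.ndarray | pd.DataFrame, labels: Sequence[str] | None = None) -> Tree:
    """Saitou–Nei neighbor joining.

    Agglomerates the pair minimizing the Q-criterion, with limb lengths
    from the standard formulas; negative limbs are clamped to zero with the
    deficit moved to the sibling limb (the pair's total is preserved). Ties
    in Q are broken by node-index order for determinism. A 2-taxon input
    yields a single edge; 3 taxa resolve as a star.
    """
    if isinstance(d, pd.DataFrame):
        labels = labels or [str(c) for c in d.columns]
        d = d.to_numpy(dtype=float)
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if labels is None:
        labels = [f"L{i}" for i in range(n)]
    labels = [str(x) for x in labels]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-8):
        raise InputError("distance matrix must be square and symmetric")
    if np.diag(d).any():
        raise InputError("distance matrix diagonal must be zero")
    if (d < 0).any():
        raise InputError("distances must be nonnegative")
    if n < 2:
        raise InputError("need at least 2 taxa")

    adj: dict[str, dict[str, float]] = {lab: {} for lab in labels}

    def _connect(u: str, v: str, length: float) -> None:
        length = max(length, 0.0)
        adj.setdefault(u, {})[v] = length
        adj.setdefault(v, {})[u] = length

    if n == 2:
        _connect(labels[0], labels[1], d[0, 1])
        return Tree(adjacency=adj, leaves=labels)

    active = list(range(n))
    names = dict(enumerate(labels))
    dist = d.copy()
    next_internal = 0
    while len(active) > 3:
        r = len(active)
        sub = dist[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        qmat = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(qmat, np.inf)
        flat = np.argmin(qmat)
        ai, aj = np.unravel_index(flat, qmat.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (rowsum[ai] - rowsum[aj]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:  # clamp, preserving li + lj = dij
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_name = f"_nj{next_internal}"
        next_internal += 1
        _connect(names[i], new_name, li)
        _connect(names[j], new_name, lj)
        # distances from the new node to the remaining taxa
        new_row = np.zeros(dist.shape[0] + 1)
        for ak, kidx in enumerate(active):
            if kidx in (i, j):
                continue
            new_row[kidx] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : len(new_row) - 1] = new_row[: len(new_row) - 1]
        dist[: len(new_row) - 1, -1] = new_row[: len(new_row) - 1]
        new_idx = dist.shape[0] - 1
        names[new_idx] = new_name
        active = [x for x in active if x not in (i, j)] + [new_idx]

    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
        lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
        lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
        center = f"_nj{next_internal}"
        _connect(names[a], center, la)
        _connect(names[b], center, lb)
        _connect(names[c], center, lc)
    else:  # two subtrees left
        a, b = active
        _connect(names[a], names[b], dist[a, b])
    return Tree(adjacency=adj, leaves=labels)
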