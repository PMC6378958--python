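"""Group-level standardization and nonparametric inference.

Subject source maps (rectified by default) are projected to a template mesh
through a row-stochastic vertex-mapping matrix, smoothed on the cortical
graph with a Gaussian-equivalent diffusion kernel, and tested across
subjects with sign-flip permutation paired t-tests. Multiple comparisons
are handled either elementwise (Benjamini-Hochberg FDR over all sources ×
times jointly) or by cluster-based permutation: supra-threshold
spatio-temporal components scored by mass (summed |t|) against the
max-cluster null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay
from scipy.stats import t as t_dist

from .core_io import logger
from .head_model import SurfaceMesh


# ---------------------------------------------------------------------------
# template projection and smoothing
# ---------------------------------------------------------------------------

def check_vertex_mapping(mapping) -> None:
    """A vertex mapping must be row-stochastic with nonnegative entries."""
    m = sp.csr_matrix(mapping)
    if m.data.size and m.data.min() < 0:
        raise ValueError("vertex mapping has negative entries")
    rows = np.asarray(m.sum(axis=1)).ravel()
    if not np.allclose(rows, 1.0, atol=1e-9):
        raise ValueError("vertex mapping rows must sum to 1")


def project_to_template(values: np.ndarray, mapping, rectify: bool = False) -> np.ndarray:
    """Template values = mapping · subject values (optionally |values| first)."""
    m = sp.csr_matrix(mapping)
    values = np.asarray(values, float)
    if values.shape[0] != m.shape[1]:
        raise ValueError(f"mapping expects {m.shape[1]} subject vertices, "
                         f"got {values.shape[0]}")
    if rectify:
        values = np.abs(values)
    return m @ values


def mesh_adjacency(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Symmetric 0/1 vertex adjacency from the triangle edge set."""
    e = mesh.edges()
    n = mesh.n_vertices
    a = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    a = a + a.T
    a.data[:] = 1.0
    return a.tocsr()


def smooth_mesh(values: np.ndarray, mesh: SurfaceMesh, fwhm: float = 0.003,
                alpha: float = 0.15) -> np.ndarray:
    """Gaussian-equivalent smoothing by iterated neighbor diffusion.

    Each step applies an explicit graph-Laplacian diffusion
    v ← v + (alpha/deg_max)·(A v − deg·v), which exactly conserves the vertex
    sum (the Laplacian is symmetric with zero row sums) and preserves
    constants. On a roughly isotropic mesh one step adds per-axis variance
    ≈ alpha·mean(edge²)/2, so the step count is set to reach the requested
    Gaussian FWHM, with a fractional last step.
    """
    values = np.asarray(values, float)
    edge_len = mesh.mean_edge_length()
    if fwhm < edge_len:
        logger.warning("smoothing FWHM %.4g below mean edge length %.4g: no-op",
                       fwhm, edge_len)
        return values.copy()
    adj = mesh_adjacency(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    dmax = deg.max()
    e = mesh.edges()
    mean_sq_edge = float((np.linalg.norm(mesh.vertices[e[:, 0]]
                                         - mesh.vertices[e[:, 1]], axis=1) ** 2).mean())
    target_var = fwhm ** 2 / (8 * np.log(2))           # per-axis sigma²
    step_var = alpha * mean_sq_edge / 2.0
    n_full = int(target_var / step_var)
    frac = (target_var - n_full * step_var) / step_var  # fractional last step
    out = values.copy()
    degv = deg[:, None] if out.ndim > 1 else deg
    for step in range(n_full + 1):
        a = alpha if step < n_full else alpha * frac
        if a <= 0:
            break
        out = out + (a / dmax) * (adj @ out - degv * out)
    return out


# ---------------------------------------------------------------------------
# statistics containers
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    """t/p maps with correction metadata and (optionally) a cluster table."""

    t_map: np.ndarray
    p_map: np.ndarray
    correction: str               # none | fdr | cluster
    alpha: float
    n_randomizations: int
    significant: np.ndarray
    clusters: list = field(default_factory=list)   # dicts: id, mass, p, size

    def masked_t(self) -> np.ndarray:
        """t-values zeroed wherever not significant (display/export convention)."""
        return np.where(self.significant, self.t_map, 0.0)

    def to_tsv(self, path) -> None:
        lines = ["element\tt\tp\tsignificant"]
        flat_t = self.t_map.ravel()
        flat_p = self.p_map.ravel()
        flat_s = self.significant.ravel()
        for i in range(flat_t.size):
            lines.append(f"{i}\t{flat_t[i]:.6g}\t{flat_p[i]:.6g}\t{int(flat_s[i])}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _paired_t(diffs: np.ndarray):
    """Elementwise one-sample t on subject differences: (n, ...) → t map."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def permutation_paired_ttest(a: np.ndarray, b: np.ndarray, n_rand: int = 1000,
                             tail: str = "two", seed: int | np.random.Generator = 0,
                             alpha: float = 0.05) -> StatResult:
    """Sign-flip permutation paired t-test, elementwise.

    The null distribution flips the sign of whole subject difference maps;
    p = (1 + #{|t*| ≥ |t|})/(n_rand + 1). Zero-variance elements get p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("paired arrays with ≥2 subjects required")
    d = a - b
    n = d.shape[0]
    shape = d.shape[1:]
    dd = d.reshape(n, -1)
    t_obs = _paired_t(dd)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_rand, n))
    # sign flips leave Σd² unchanged: t* computable from flipped sums alone
    ss = (dd ** 2).sum(axis=0)
    sums = signs @ dd                                   # (n_rand, m)
    means = sums / n
    var = (ss[None, :] - n * means ** 2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_null = means / np.sqrt(var / n)
    t_null = np.nan_to_num(t_null)
    # tolerance so permutations tied with the observed statistic count as
    # exceedances despite round-off in the vectorized path
    tol = 1e-9 * np.maximum(1.0, np.abs(t_obs))
    if tail == "two":
        exceed = (np.abs(t_null) >= (np.abs(t_obs) - tol)[None, :]).sum(axis=0)
    elif tail == "pos":
        exceed = (t_null >= (t_obs - tol)[None, :]).sum(axis=0)
    elif tail == "neg":
        exceed = (t_null <= (t_obs + tol)[None, :]).sum(axis=0)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = (1.0 + exceed) / (n_rand + 1.0)
    zero_var = dd.std(axis=0) == 0
    if zero_var.any():
        logger.warning("%d zero-variance elements: p set to 1", int(zero_var.sum()))
        p[zero_var] = 1.0
    sig = p <= alpha
    return StatResult(t_obs.reshape(shape), p.reshape(shape), "none", alpha,
                      n_rand, sig.reshape(shape))


def fdr_correct(p_map: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over all elements jointly; discovery mask."""
    p = np.asarray(p_map, float).ravel()
    if p.size == 0:
        raise ValueError("empty p map")
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    mask = np.zeros(m, bool)
    if below.any():
        k = np.flatnonzero(below).max()
        mask[order[:k + 1]] = True
    return mask.reshape(np.shape(p_map))


# ---------------------------------------------------------------------------
# cluster-based permutation
# ---------------------------------------------------------------------------

def build_adjacency(positions: np.ndarray | None = None, mesh: SurfaceMesh | None = None,
                    rule: str = "delaunay", max_dist: float | None = None) -> sp.csr_matrix:
    """Spatial neighbor graph for sensors (Delaunay or distance rule) or sources
    (mesh edges). Symmetric, no self-loops."""
    if mesh is not None:
        return mesh_adjacency(mesh)
    pos = np.asarray(positions, float)
    n = len(pos)
    if rule == "distance":
        if max_dist is None:
            raise ValueError("distance rule needs max_dist")
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        a = (d > 0) & (d <= max_dist)
    elif rule == "delaunay":
        tri = Delaunay(pos)
        a = np.zeros((n, n), bool)
        for simplex in tri.simplices:
            for i in simplex:
                for j in simplex:
                    if i != j:
                        a[i, j] = True
    else:
        raise ValueError(f"unknown adjacency rule {rule!r}")
    isolated = np.flatnonzero(~a.any(axis=1))
    if isolated.size:
        logger.warning("adjacency has isolated nodes: %s", isolated[:5].tolist())
    return sp.csr_matrix(a.astype(float))


def _spatiotemporal_graph(spatial: sp.csr_matrix, n_times: int) -> sp.csr_matrix:
    """Kronecker-structured graph: spatial neighbors at equal time ± temporal
    neighbors (±1 sample) at equal element."""
    eye = sp.identity(n_times, format="csr")
    time_adj = sp.diags([np.ones(n_times - 1)] * 2, [-1, 1], format="csr")
    n_elem = spatial.shape[0]
    return (sp.kron(spatial, eye, format="csr")
            + sp.kron(sp.identity(n_elem, format="csr"), time_adj, format="csr"))


def _max_cluster_mass(t_flat: np.ndarray, graph: sp.csr_matrix, thresh: float):
    """Clusters of |t| > thresh on the spatio-temporal graph; (masses, labels)."""
    supra = np.flatnonzero(np.abs(t_flat) > thresh)
    if supra.size == 0:
        return np.array([]), None, supra
    sub = graph[supra][:, supra]
    n_comp, labels = connected_components(sub, directed=False)
    masses = np.zeros(n_comp)
    np.add.at(masses, labels, np.abs(t_flat[supra]))
    return masses, labels, supra


def cluster_permutation(a: np.ndarray, b: np.ndarray, adjacency: sp.csr_matrix,
                        cluster_alpha: float = 0.05, n_rand: int = 1000,
                        seed: int | np.random.Generator = 0,
                        alpha: float = 0.05) -> StatResult:
    """Cluster-mass permutation test on paired (subjects × elements × times) data.

    The cluster-forming threshold is the two-tailed t quantile at
    ``cluster_alpha``; clusters are connected components of supra-threshold
    |t| on the spatio-temporal graph, scored by summed |t|, and compared to
    the permutation distribution of the maximum cluster mass.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have identical shape")
    n = a.shape[0]
    shape = a.shape[1:]
    n_elem = shape[0]
    n_times = shape[1] if len(shape) > 1 else 1
    if adjacency.shape[0] != n_elem:
        raise ValueError("adjacency size does not match the element dimension")
    d = (a - b).reshape(n, -1)
    thresh = t_dist.ppf(1 - cluster_alpha / 2, df=n - 1)
    graph = _spatiotemporal_graph(sp.csr_matrix(adjacency), n_times)
    t_obs = _paired_t(d)
    masses, labels, supra = _max_cluster_mass(t_obs, graph, thresh)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_rand)
    ss = (d ** 2).sum(axis=0)
    for r in range(n_rand):
        signs = rng.choice([-1.0, 1.0], size=n)
        means = signs @ d / n
        var = (ss - n * means ** 2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_r = means / np.sqrt(var / n)
        t_r = np.nan_to_num(t_r)
        m_r, _, _ = _max_cluster_mass(t_r, graph, thresh)
        null[r] = m_r.max() if m_r.size else 0.0
    clusters = []
    sig = np.zeros(d.shape[1], bool)
    for cid in range(len(masses)):
        p = (1.0 + (null >= masses[cid] * (1 - 1e-9)).sum()) / (n_rand + 1.0)
        members = supra[labels == cid]
        clusters.append({"id": cid, "mass": float(masses[cid]), "p": float(p),
                         "size": int(members.size)})
        if p <= alpha:
            sig[members] = True
    p_map = np.ones(d.shape[1])
    for c in clusters:
        members = supra[labels == c["id"]]
        p_map[members] = c["p"]
    return StatResult(t_obs.reshape(shape), p_map.reshape(shape), "cluster", alpha,
                      n_rand, sig.reshape(shape), clusters)
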