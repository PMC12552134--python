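"""Representation geometry: PCA summaries, pairwise distances, MDS embedding.

Four summaries of a network's responses are compared across networks:

* population trajectories — the (N, T*K) response matrix projected onto its
  first 10 PCs along the unit axis, giving (10, T, K) reduced trajectories;
* single-unit selectivity — the same matrix projected onto 10 PCs along the
  time-by-trial axis, giving one 10-d point per unit;
* fixed-point configurations — all survey fixed points projected onto 7 PCs,
  each point keeping its (stability, input) tag;
* trajectory endpoints — the last state of every trial projected onto 10 PCs.

Each summary is normalized to unit total variance so scales are comparable
across networks.  Trajectory and endpoint summaries are compared with a
symmetric two-way linear-regression residual score; selectivity and
fixed-point summaries with an iterative-closest-point (ICP) registration
permitting one-to-many matching (tag-restricted for fixed points).  The
resulting pairwise distance matrices are embedded in 2-D with metric MDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

from .fixedpoints import FixedPoint
from .rnn import ResponseTensor

__all__ = [
    "TrajectorySummary",
    "SelectivitySummary",
    "FixedPointSummary",
    "EndpointSummary",
    "reduce_trajectories",
    "reduce_selectivity",
    "reduce_endpoints",
    "project_fixed_points",
    "trajectory_distance",
    "icp_distance",
    "distance_matrix",
    "embed_mds",
]


@dataclass
class TrajectorySummary:
    reduced: np.ndarray          # (n_pc, T, K)
    variance_captured: float
    normalized: bool = True

    @property
    def flat(self) -> np.ndarray:
        n_pc = self.reduced.shape[0]
        return self.reduced.reshape(n_pc, -1)


@dataclass
class SelectivitySummary:
    reduced: np.ndarray          # (N, n_pc)
    variance_captured: float
    normalized: bool = True


@dataclass
class FixedPointSummary:
    projected: np.ndarray        # (N_p, n_pc)
    tags: list[tuple] = field(default_factory=list)
    stable: np.ndarray | None = None
    variance_captured: float = 0.0


@dataclass
class EndpointSummary:
    projected: np.ndarray        # (K, n_pc)
    variance_captured: float
    normalized: bool = True


def _unit_total_variance(x: np.ndarray, axis_samples: int) -> np.ndarray:
    """Scale an array so the summed per-component variance equals 1."""
    total = np.sum(np.var(x, axis=axis_samples))
    if total <= 0:
        raise ValueError("degenerate summary: zero total variance")
    return x / np.sqrt(total)


def reduce_trajectories(z: ResponseTensor | np.ndarray,
                        n_pc: int = 10) -> TrajectorySummary:
    """Project population trajectories onto the first ``n_pc`` unit-axis PCs.

    The (N, T, K) activity tensor is reshaped to (N, T*K); samples are the
    T*K population states and features the N units.  The reduced tensor is
    rescaled to unit total variance.
    """
    act = z.activity if isinstance(z, ResponseTensor) else z
    N, T, K = act.shape
    if T * K < n_pc:
        raise ValueError("fewer samples than requested components")
    x = act.reshape(N, T * K)
    pca = PCA(n_components=min(n_pc, N))
    f = pca.fit_transform(x.T).T            # (n_pc, T*K)
    var = float(np.sum(pca.explained_variance_ratio_))
    f = _unit_total_variance(f, axis_samples=1)
    return TrajectorySummary(reduced=f.reshape(-1, T, K), variance_captured=var)


def reduce_selectivity(z: ResponseTensor | np.ndarray,
                       n_pc: int = 10) -> SelectivitySummary:
    """Project single-unit tuning profiles onto ``n_pc`` PCs of the T*K axis.

    Samples are the N units, features the T*K time-by-trial profile; the
    result is one ``n_pc``-dimensional point per unit, at unit total
    variance.
    """
    act = z.activity if isinstance(z, ResponseTensor) else z
    N, T, K = act.shape
    if N < n_pc:
        raise ValueError("fewer units than requested components")
    x = act.reshape(N, T * K)
    pca = PCA(n_components=n_pc)
    g = pca.fit_transform(x)                # (N, n_pc)
    var = float(np.sum(pca.explained_variance_ratio_))
    g = _unit_total_variance(g, axis_samples=0)
    return SelectivitySummary(reduced=g, variance_captured=var)


def reduce_endpoints(z: ResponseTensor | np.ndarray,
                     n_pc: int = 10) -> EndpointSummary:
    """Project per-trial final states onto ``n_pc`` PCs (one row per trial)."""
    act = z.activity if isinstance(z, ResponseTensor) else z
    s = act[:, -1, :].T                     # (K, N)
    if s.shape[0] < n_pc:
        raise ValueError("fewer trials than requested components")
    if np.allclose(np.var(s, axis=0).sum(), 0.0):
        raise ValueError("degenerate endpoints: all trials identical")
    pca = PCA(n_components=min(n_pc, s.shape[1]))
    proj = pca.fit_transform(s)
    var = float(np.sum(pca.explained_variance_ratio_))
    proj = _unit_total_variance(proj, axis_samples=0)
    return EndpointSummary(projected=proj, variance_captured=var)


def project_fixed_points(points: list[FixedPoint],
                         n_pc: int = 7) -> FixedPointSummary:
    """Project survey fixed points onto ``n_pc`` PCs, preserving tags."""
    if len(points) < n_pc:
        raise ValueError("fewer fixed points than requested components")
    p = np.stack([fp.coords for fp in points])       # (N_p, N)
    pca = PCA(n_components=min(n_pc, p.shape[1]))
    proj = pca.fit_transform(p)
    var = float(np.sum(pca.explained_variance_ratio_))
    proj = _unit_total_variance(proj, axis_samples=0)
    return FixedPointSummary(
        projected=proj,
        tags=[fp.input_tag + ("stable" if fp.stable else "unstable",)
              for fp in points],
        stable=np.array([fp.stable for fp in points]),
        variance_captured=var)


def trajectory_distance(f_i, f_j) -> float:
    """Symmetric two-way regression distance between reduced summaries.

    Each summary is an (n_pc, S) matrix over the same sample grid.  One
    summary is regressed onto the other by an intercept-free least-squares
    linear map of the component axis, in both directions; the distance is
    the mean of the two residual mean-squared errors.  It is exactly
    symmetric and vanishes whenever the two are related by an invertible
    linear map.
    """
    a = f_i.flat if isinstance(f_i, TrajectorySummary) else np.asarray(f_i)
    b = f_j.flat if isinstance(f_j, TrajectorySummary) else np.asarray(f_j)
    if isinstance(f_i, EndpointSummary):
        a = f_i.projected.T
    if isinstance(f_j, EndpointSummary):
        b = f_j.projected.T
    a = a.reshape(a.shape[0], -1)
    b = b.reshape(b.shape[0], -1)
    if a.shape[1] != b.shape[1]:
        raise ValueError("summaries sampled on different grids")

    def _score(src, tgt):
        m, *_ = np.linalg.lstsq(src.T, tgt.T, rcond=None)
        return float(np.mean((src.T @ m - tgt.T) ** 2))

    return 0.5 * (_score(a, b) + _score(b, a))


def _haar_orthogonal(d: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    return q * np.sign(np.diag(r))


def _moment_matched_init(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Coarse alignment: match principal axes, signs fixed by skewness."""
    d = src.shape[1]
    mats = []
    for cloud in (src, tgt):
        c = cloud - cloud.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(c.T))
        vecs = vecs[:, ::-1]
        proj = c @ vecs
        skew = np.mean(proj ** 3, axis=0)
        sign = np.where(skew >= 0, 1.0, -1.0)
        mats.append(vecs * sign)
    v_src, v_tgt = mats
    return v_src @ v_tgt.T if d else np.eye(d)


def _icp_one_direction(src, tgt, tags_src, tags_tgt, n_tries, rng,
                       max_iter, tol) -> float:
    """Best-over-restarts ICP score registering src onto tgt."""
    if tags_src is not None:
        tags_src = np.asarray(tags_src)
        tags_tgt = np.asarray(tags_tgt)
        covered = np.isin(tags_tgt, tags_src)
        if not covered.all():
            warnings.warn("target tags missing in source; excluded from match")
            tgt, tags_tgt = tgt[covered], tags_tgt[covered]
        groups = [(np.where(tags_tgt == t)[0], np.where(tags_src == t)[0])
                  for t in np.unique(tags_tgt)]
    best = np.inf
    inits = [_moment_matched_init(src, tgt)]
    inits += [_haar_orthogonal(src.shape[1], rng) for _ in range(n_tries - 1)]
    for a in inits:
        prev = np.inf
        for _ in range(max_iter):
            moved = src @ a
            if tags_src is None:
                idx = np.argmin(cdist(tgt, moved), axis=1)
            else:
                idx = np.empty(len(tgt), dtype=int)
                for tgt_rows, src_rows in groups:
                    sub = cdist(tgt[tgt_rows], moved[src_rows])
                    idx[tgt_rows] = src_rows[np.argmin(sub, axis=1)]
            matched = src[idx]
            a, _ = orthogonal_procrustes(matched, tgt)
            score = float(np.mean((matched @ a - tgt) ** 2))
            if prev - score < tol * max(prev, 1e-300):
                break
            prev = score
        best = min(best, score)
    return best


def icp_distance(
    p_src: np.ndarray,
    p_tgt: np.ndarray,
    tags_src=None,
    tags_tgt=None,
    n_tries: int = 60,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> float:
    """Symmetric ICP registration distance between two point clouds.

    Each direction runs ``n_tries`` registrations (one deterministic
    moment-matched start plus Haar-random orthogonal starts), keeping the
    minimal mean-squared mismatch; the distance is the mean of the two
    directional scores.  With tags given, matches are restricted to points
    carrying the same tag.
    """
    p_src = np.asarray(p_src, dtype=float)
    p_tgt = np.asarray(p_tgt, dtype=float)
    if p_src.size == 0 or p_tgt.size == 0:
        raise ValueError("empty point cloud")
    rng = np.random.default_rng(seed)
    s1 = _icp_one_direction(p_src, p_tgt, tags_src, tags_tgt,
                            n_tries, rng, max_iter, tol)
    s2 = _icp_one_direction(p_tgt, p_src, tags_tgt, tags_src,
                            n_tries, rng, max_iter, tol)
    return 0.5 * (s1 + s2)


def distance_matrix(summaries: list, metric: str,
                    n_tries: int = 60,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Pairwise distance matrix over network summaries for one metric."""
    rng = np.random.default_rng(seed)
    m = len(summaries)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if metric in ("trajectory", "endpoint"):
                d[i, j] = trajectory_distance(summaries[i], summaries[j])
            elif metric == "selectivity":
                d[i, j] = icp_distance(summaries[i].reduced,
                                       summaries[j].reduced,
                                       n_tries=n_tries, seed=rng)
            elif metric == "fixedpoint":
                d[i, j] = icp_distance(
                    summaries[i].projected, summaries[j].projected,
                    [str(t) for t in summaries[i].tags],
                    [str(t) for t in summaries[j].tags],
                    n_tries=n_tries, seed=rng)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[j, i] = d[i, j]
    return d


def embed_mds(
    d: np.ndarray,
    seed: int = 0,
    n_init: int = 8,
    max_iter: int = 500,
    eps: float = 1e-9,
) -> tuple[np.ndarray, float]:
    """2-D metric MDS of a precomputed dissimilarity matrix.

    Returns the embedding coordinates and the stress-1 value of the best of
    ``n_init`` restarts.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    import warnings as _warnings

    best_coords, best_stress = None, np.inf
    # one classical-scaling start (exact for realizable configurations)
    # plus the random restarts
    for init_kw in ({"init": "classical_mds", "n_init": 1},
                    {"n_init": n_init}):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            mds = MDS(n_components=2, dissimilarity="precomputed",
                      metric=True, max_iter=max_iter, eps=eps,
                      random_state=seed, normalized_stress=False, **init_kw)
            try:
                coords = mds.fit_transform(d)
            except (TypeError, ValueError):  # older API without string init
                continue
        if mds.stress_ < best_stress:
            best_coords, best_stress = coords, float(mds.stress_)
    denom = np.sum(d ** 2) / 2.0
    stress1 = float(np.sqrt(best_stress / denom)) if denom > 0 else 0.0
    return best_coords, stress1
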