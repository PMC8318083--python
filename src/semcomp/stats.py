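"""Shared statistical machinery.

Ordinary least squares, the one-sample t statistic, threshold-free cluster
enhancement (TFCE) on arbitrary graph x time grids, max-statistic permutation
inference by per-subject sign flipping, and partial correlation.

TFCE integrates cluster support under every threshold::

    TFCE(p) = integral_{h0}^{stat(p)}  e(h)^E * h^H  dh

where ``e(h)`` is the extent of the connected component containing ``p`` after
thresholding the map at ``h``.  The integral is discretized at step ``dh``
with midpoint evaluation and computed by an incremental union-find sweep over
descending thresholds (O(n_thresholds * n_active)), JIT-compiled with numba
when available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .io import savez_deterministic

logger = logging.getLogger("semcomp")

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


# ---------------------------------------------------------------------------
# OLS and t


def ols_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of ``y ~ X``.

    Raises on rank deficiency, naming the collinear columns.  ``y`` may be a
    vector or a (trials x k) matrix of stacked responses.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more trials ({n}) than predictors ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {collinear_columns(X)}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def collinear_columns(X: np.ndarray, names: Sequence[str] | None = None) -> list:
    """Columns involved in rank deficiency (via pivoted QR)."""
    import scipy.linalg as sla

    X = np.asarray(X, dtype=np.float64)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    _, _, piv = sla.qr(X, mode="economic", pivoting=True)
    bad = sorted(piv[rank:].tolist())
    if names is not None:
        return [names[i] for i in bad]
    return bad


def one_sample_t(values: np.ndarray, popmean: float = 0.0) -> float:
    """t = (mean - popmean) / (sd / sqrt(n)); zero variance -> signed inf."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = values.mean() - popmean
    sd = values.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero variance in one_sample_t; returning signed infinity")
        if m == 0.0:
            return 0.0
        return float(np.sign(m) * np.inf)
    return float(m / (sd / np.sqrt(n)))


def _t_map(centered: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t over grid points for weighted (sign-flip / zeroed) data.

    ``centered`` is (subjects x points) of values minus popmean; the permuted
    sample at point j is ``popmean + w_i * centered[i, j]``.
    """
    n = centered.shape[0]
    m = weights @ centered / n
    ss = (weights * weights) @ (centered * centered)
    var = (ss - n * m * m) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    # 0/0 (all-zero column) -> 0; x/0 -> signed inf is kept
    return np.where(np.isnan(t), 0.0, t)


# ---------------------------------------------------------------------------
# TFCE


@dataclass
class TFCEParams:
    """TFCE enhancement parameters.

    ``E``/``H`` are the extent and height exponents (defaults 0.5 / 2.0, the
    literature-standard pairing); ``dh`` the integration step (``None`` =
    per-map ``(max stat - h0) / n_steps``); ``h0`` the threshold origin.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    h0: float = 0.0
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be non-negative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def _neighbors_csr(n: int, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    und = np.concatenate([edges, edges[:, ::-1]]) if edges.size else edges
    counts = np.bincount(und[:, 0], minlength=n) if und.size else np.zeros(n, dtype=np.int64)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    if und.size:
        order = np.argsort(und[:, 0], kind="stable")
        indices = und[order, 1].astype(np.int64)
    else:
        indices = np.zeros(0, dtype=np.int64)
    return indptr, indices


@njit(cache=False)
def _tfce_positive_kernel(stat, indptr, indices, E, H, dh, h0, n_thresh):  # pragma: no cover
    n = stat.shape[0]
    out = np.zeros(n)
    order = np.argsort(stat)[::-1]
    parent = np.full(n, -1, np.int64)
    size = np.zeros(n, np.int64)
    ptr = 0
    for k in range(n_thresh, 0, -1):
        h = h0 + (k - 0.5) * dh  # midpoint rule for the threshold integral
        while ptr < n and stat[order[ptr]] >= h:
            v = order[ptr]
            parent[v] = v
            size[v] = 1
            for j in range(indptr[v], indptr[v + 1]):
                u = indices[j]
                if parent[u] >= 0:
                    ru = u
                    while parent[ru] != ru:
                        ru = parent[ru]
                    rv = v
                    while parent[rv] != rv:
                        rv = parent[rv]
                    if ru != rv:
                        if size[ru] < size[rv]:
                            tmp = ru
                            ru = rv
                            rv = tmp
                        parent[rv] = ru
                        size[ru] += size[rv]
            ptr += 1
        inc = (h ** H) * dh
        for i in range(ptr):
            v = order[i]
            r = v
            while parent[r] != r:
                r = parent[r]
            # path compression
            w = v
            while parent[w] != r:
                nxt = parent[w]
                parent[w] = r
                w = nxt
            out[v] += (size[r] ** E) * inc
    return out


def _tfce_positive_scipy(stat, edges, E, H, dh, h0, n_thresh):
    """Sparse connected-components fallback (no numba)."""
    n = stat.shape[0]
    out = np.zeros(n)
    if not edges.size:
        adj = sp.csr_matrix((n, n))
    else:
        u, v = edges[:, 0], edges[:, 1]
        adj = sp.coo_matrix(
            (np.ones(2 * len(u)), (np.r_[u, v], np.r_[v, u])), shape=(n, n)
        ).tocsr()
    for k in range(1, n_thresh + 1):
        h = h0 + (k - 0.5) * dh
        mask = stat >= h
        if not mask.any():
            break
        sub = adj[mask][:, mask]
        _, labels = connected_components(sub, directed=False)
        sizes = np.bincount(labels)
        out[mask] += (sizes[labels] ** E) * (h ** H) * dh
    return out


def _tfce_positive(stat: np.ndarray, edges: np.ndarray, params: TFCEParams) -> np.ndarray:
    smax = float(stat.max(initial=-np.inf))
    if not np.isfinite(stat).all():
        # clip infinities (degenerate t's) to the largest finite value so the
        # enhancement stays finite; they remain the map maximum
        finite = stat[np.isfinite(stat)]
        top = float(finite.max()) if finite.size else 0.0
        stat = np.clip(stat, None, max(top, params.h0))
        smax = float(stat.max(initial=-np.inf))
    if smax <= params.h0:
        return np.zeros_like(stat, dtype=np.float64)
    dh = params.dh if params.dh is not None else (smax - params.h0) / params.n_steps
    n_thresh = int(np.floor((smax - params.h0) / dh * (1 + 1e-12) + 0.5))
    if n_thresh < 1:
        return np.zeros_like(stat, dtype=np.float64)
    if _HAVE_NUMBA:
        indptr, indices = _neighbors_csr(stat.shape[0], edges)
        return _tfce_positive_kernel(
            np.ascontiguousarray(stat, dtype=np.float64),
            indptr,
            indices,
            float(params.E),
            float(params.H),
            float(dh),
            float(params.h0),
            n_thresh,
        )
    return _tfce_positive_scipy(
        np.asarray(stat, dtype=np.float64), np.asarray(edges, dtype=np.int64),
        params.E, params.H, dh, params.h0, n_thresh,
    )


def tfce_enhance(
    stat: np.ndarray,
    edges: np.ndarray,
    params: TFCEParams | None = None,
    tail: str = "two-sided",
) -> np.ndarray:
    """TFCE enhancement of a statistic map on a graph.

    ``stat`` is 1-D over grid points; ``edges`` the grid connectivity.  For the
    two-sided tail the negative lobe is enhanced on ``-stat`` and negated, so
    the output is signed.
    """
    stat = np.asarray(stat, dtype=np.float64)
    if stat.ndim != 1 or stat.size == 0:
        raise ValueError("stat must be a non-empty 1-D map over grid points")
    params = params or TFCEParams()
    pos = _tfce_positive(stat, edges, params)
    if tail == "one-sided-positive":
        return pos
    if tail == "two-sided":
        neg = _tfce_positive(-stat, edges, params)
        return pos - neg
    raise ValueError(f"unknown tail {tail!r}")


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class StatResult:
    """Statistic map + TFCE scores + permutation p-values on a grid.

    All maps are 1-D over the grid points; ``grid_shape`` (if set) allows
    re-inflating to (space x time) or (t x dt), with ``valid`` marking which
    cells of the full grid the points occupy.
    """

    stat: np.ndarray
    tfce: np.ndarray
    p: np.ndarray
    n_permutations: int
    tail: str
    null_max: np.ndarray | None = None
    grid_shape: tuple[int, int] | None = None
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.stat.shape == self.tfce.shape == self.p.shape):
            raise ValueError("stat/tfce/p grids must be congruent")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values outside [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("p computed from >= 1 permutation")

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p <= alpha

    def to_grid(self, values: np.ndarray | None = None, fill: float = np.nan) -> np.ndarray:
        """Re-inflate a 1-D point map onto the full 2-D grid."""
        if self.grid_shape is None:
            raise ValueError("no grid metadata attached")
        values = self.p if values is None else values
        out = np.full(int(np.prod(self.grid_shape)), fill)
        if self.valid is not None:
            out[np.flatnonzero(self.valid)] = values
        else:
            out[:] = values
        return out.reshape(self.grid_shape)

    def save(self, path: str | Path) -> None:
        import json

        path = Path(path)
        arrays = dict(stat=self.stat, tfce=self.tfce, p=self.p)
        if self.null_max is not None:
            arrays["null_max"] = self.null_max
        if self.valid is not None:
            arrays["valid"] = self.valid
        savez_deterministic(path.with_suffix(".npz"), **arrays)
        meta = {
            "kind": "stat_result",
            "n_permutations": self.n_permutations,
            "tail": self.tail,
            "grid_shape": list(self.grid_shape) if self.grid_shape else None,
            **{k: v for k, v in self.meta.items() if isinstance(v, (str, int, float, list, bool, type(None)))},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def permutation_test(
    per_subject_maps: np.ndarray,
    popmean: float,
    edges: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 10000,
    tail: str = "two-sided",
    seed: int | None = 0,
    null: str = "signflip",
    correction: str = "max",
    alpha: float = 0.05,
) -> StatResult:
    """Group-level TFCE permutation test of maps against ``popmean``.

    The observed map is the TFCE enhancement of the pointwise one-sample t.
    Null draws flip each subject's (map - popmean) sign independently
    (``null="signflip"``; ``null="zero"`` replaces a subject's deviation with 0
    instead, the literal reading of exchanging the coefficient with zero).
    Family-wise control uses the permutation distribution of the maximum TFCE
    score (``correction="max"``); ``correction="none"`` gives per-point
    uncorrected p-values.  Deterministic given ``seed``.
    """
    maps = np.asarray(per_subject_maps, dtype=np.float64)
    if maps.ndim != 2:
        raise ValueError("per_subject_maps must be (subjects x points)")
    n_sub = maps.shape[0]
    if n_sub < 4:
        raise ValueError("need at least 4 subjects for permutation inference")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if 1.0 / (1.0 + n_perm) > alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot reach alpha={alpha}: smallest attainable "
            f"p is {1.0 / (1.0 + n_perm):.3g}"
        )
    params = params or TFCEParams()
    one_sided = tail == "one-sided-positive"
    if tail not in ("two-sided", "one-sided-positive"):
        raise ValueError(f"unknown tail {tail!r}")
    if null not in ("signflip", "zero"):
        raise ValueError(f"unknown null scheme {null!r}")

    centered = maps - popmean
    ones = np.ones(n_sub)
    t_obs = _t_map(centered, ones)
    tfce_obs = tfce_enhance(t_obs, edges, params, tail)
    score_obs = tfce_obs if one_sided else np.abs(tfce_obs)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    exceed = np.zeros(maps.shape[1], dtype=np.int64)
    for i in range(n_perm):
        if null == "signflip":
            w = rng.integers(0, 2, n_sub) * 2.0 - 1.0
        else:
            w = rng.integers(0, 2, n_sub).astype(np.float64)
        t_p = _t_map(centered, w)
        tf = tfce_enhance(t_p, edges, params, tail)
        score = tf if one_sided else np.abs(tf)
        null_max[i] = score.max()
        if correction == "none":
            exceed += score >= score_obs

    if correction == "max":
        srt = np.sort(null_max)
        counts = n_perm - np.searchsorted(srt, score_obs, side="left")
        p = (1.0 + counts) / (1.0 + n_perm)
    elif correction == "none":
        p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    logger.info(
        "permutation_test: n_sub=%d points=%d n_perm=%d tail=%s null=%s correction=%s",
        n_sub, maps.shape[1], n_perm, tail, null, correction,
    )
    return StatResult(
        stat=t_obs,
        tfce=tfce_obs,
        p=p,
        n_permutations=n_perm,
        tail=tail,
        null_max=null_max,
        meta={"popmean": popmean, "null": null, "correction": correction, "seed": seed},
    )


# ---------------------------------------------------------------------------
# partial correlation


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial correlation r_xy.z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).  Any constant
    input (or a degenerate denominator) returns 0 with a logged warning rather
    than propagating missingness.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1 or x.size < 3:
        raise ValueError("x, y, z must be equal-length vectors of length >= 3")
    sx, sy, sz = x.std(), y.std(), z.std()
    if sx == 0 or sy == 0 or sz == 0:
        logger.warning("partial_correlation undefined for constant input; returning 0")
        return 0.0
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = (1.0 - rxz ** 2) * (1.0 - ryz ** 2)
    if denom <= 0:
        logger.warning("partial_correlation denominator degenerate; returning 0")
        return 0.0
    return float(np.clip((rxy - rxz * ryz) / np.sqrt(denom), -1.0, 1.0))
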