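"""RDM-based directed connectivity between two regions.

At each decimated time sample a region's representational dissimilarity
vector D(R, t) collects 1 - Pearson correlation between item source patterns
(items = the four two-word condition means by default, or individual
pseudo-trials).  Directed flow from region A to region B at lag dt is the
partial correlation between D(A, t-dt) and D(B, t), partialling out
D(B, t-dt) — a Granger-style statistic on pattern geometry.  The direction
contrast A->B minus B->A is tested across subjects with TFCE permutation
inference over the t x dt grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import TrialTensor
from .space import SourceSpace, lattice_edges, compact_edges
from .stats import StatResult, TFCEParams, permutation_test
from .decoding import make_pseudotrials, preprocess_for_patterns

logger = logging.getLogger("semcomp")

RDM_CONDITIONS = ("HA-comp", "LA-comp", "HA-list", "LA-list")


@dataclass
class RDMSeries:
    """Per-time condition-dissimilarity vectors for one region.

    ``rdm`` is (n_times x n_pairs) with entries 1 - r in [0, 2]; pair order is
    ``itertools.combinations(item_labels, 2)``.
    """

    region: str
    times_ms: np.ndarray
    rdm: np.ndarray
    item_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n_items = len(self.item_labels)
        if self.rdm.shape != (self.times_ms.size, n_items * (n_items - 1) // 2):
            raise ValueError("rdm shape does not match times x item pairs")
        if np.any((self.rdm < -1e-9) | (self.rdm > 2 + 1e-9)):
            raise ValueError("dissimilarities must lie in [0, 2]")

    @property
    def pair_labels(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.item_labels, 2))


@dataclass
class FlowGrid:
    """t x dt partial-correlation matrix for one direction (source -> target)."""

    source: str
    target: str
    t_axis_ms: np.ndarray
    dt_axis_ms: np.ndarray
    pc: np.ndarray  # (n_t, n_dt), NaN where t - dt precedes the series

    def __post_init__(self) -> None:
        if self.pc.shape != (self.t_axis_ms.size, self.dt_axis_ms.size):
            raise ValueError("pc shape does not match t x dt axes")
        finite = self.pc[np.isfinite(self.pc)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("partial correlations must lie in [-1, 1]")


def compute_rdm_series(
    trials: TrialTensor,
    region: np.ndarray,
    region_name: str = "",
    granularity: str = "condition",
    n_pseudo: int = 15,
    rng: np.random.Generator | int | None = 0,
) -> RDMSeries:
    """Time-resolved RDM of a region from one subject's (preprocessed) trials.

    ``granularity="condition"`` uses the four two-word condition-mean patterns
    (6 dissimilarity entries); ``"pseudo-trial"`` uses individual pseudo-trial
    patterns (4 * n_pseudo items).  Expects frequency regressed out and data
    decimated upstream.
    """
    region = np.asarray(region, dtype=np.int64)
    if region.size < 3:
        raise ValueError("region needs >= 3 sources for pattern correlations")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    patterns = []
    labels = []
    for cond in RDM_CONDITIONS:
        sel = trials.trials_of(cond)
        if sel.size == 0:
            raise ValueError(f"no trials for condition {cond!r}")
        block = trials.data[np.ix_(sel, region)]  # (trials, sources, time)
        if granularity == "condition":
            patterns.append(make_pseudotrials(block, min(n_pseudo, sel.size), rng).mean(axis=0))
            labels.append(cond)
        elif granularity == "pseudo-trial":
            pseudo = make_pseudotrials(block, n_pseudo, rng)
            for k in range(n_pseudo):
                patterns.append(pseudo[k])
                labels.append(f"{cond}#{k}")
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
    P = np.stack(patterns)  # (items, sources, time)
    n_items = P.shape[0]
    centered = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        logger.warning(
            "constant item patterns at %d (item, time) cells; dissimilarity set to 1",
            int(degenerate.sum()),
        )
    norms = np.where(degenerate, 1.0, norms)
    unit = centered / norms[:, None, :]
    pairs = list(itertools.combinations(range(n_items), 2))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    r = np.einsum("ist,ist->it", unit[ii], unit[jj])  # correlation per pair x time
    bad = degenerate[ii] | degenerate[jj]
    r[bad] = 0.0
    rdm = np.clip(1.0 - r, 0.0, 2.0).T  # (time, pairs)
    return RDMSeries(
        region=region_name,
        times_ms=trials.times_ms,
        rdm=rdm,
        item_labels=tuple(labels),
    )


def directed_flow(
    src: RDMSeries,
    dst: RDMSeries,
    t_window_ms: tuple[float, float] = (600.0, 1200.0),
    dt_max_ms: float = 600.0,
    dt_step_ms: float = 5.0,
) -> FlowGrid:
    """Partial correlation pc[t, dt] = r(D(src, t-dt), D(dst, t) | D(dst, t-dt)).

    Cells where ``t - dt`` precedes the series start are NaN.  Undefined
    correlations (constant dissimilarity vectors) contribute 0.
    """
    if src.times_ms.size != dst.times_ms.size or not np.allclose(src.times_ms, dst.times_ms):
        raise ValueError("source and target RDM series must share a time axis")
    if src.rdm.shape[1] != dst.rdm.shape[1]:
        raise ValueError("RDM vectors must have equal length")
    times = src.times_ms
    step = float(times[1] - times[0])
    dt_axis = np.arange(dt_step_ms, dt_max_ms + 1e-9, dt_step_ms)
    t_sel = np.flatnonzero((times >= t_window_ms[0]) & (times < t_window_ms[1]))
    t_axis = times[t_sel]

    def centered_unit(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = R - R.mean(axis=1, keepdims=True)
        n = np.linalg.norm(c, axis=1)
        ok = n > 0
        c = np.where(ok[:, None], c / np.where(ok, n, 1.0)[:, None], 0.0)
        return c, ok

    Su, Sok = centered_unit(src.rdm)
    Du, Dok = centered_unit(dst.rdm)

    dt_samples = np.round(dt_axis / step).astype(int)
    pc = np.full((t_sel.size, dt_axis.size), np.nan)
    for j, dts in enumerate(dt_samples):
        lag_idx = t_sel - dts
        ok = lag_idx >= 0
        if not ok.any():
            continue
        x = Su[lag_idx[ok]]  # D(src, t-dt)
        y = Du[t_sel[ok]]  # D(dst, t)
        z = Du[lag_idx[ok]]  # D(dst, t-dt)
        rxy = np.einsum("tm,tm->t", x, y)
        rxz = np.einsum("tm,tm->t", x, z)
        ryz = np.einsum("tm,tm->t", y, z)
        denom = (1.0 - rxz**2) * (1.0 - ryz**2)
        valid = (
            Sok[lag_idx[ok]] & Dok[t_sel[ok]] & Dok[lag_idx[ok]] & (denom > 1e-12)
        )
        vals = np.zeros(ok.sum())
        vals[valid] = np.clip(
            (rxy[valid] - rxz[valid] * ryz[valid]) / np.sqrt(denom[valid]), -1.0, 1.0
        )
        pc[ok, j] = vals
    return FlowGrid(
        source=src.region, target=dst.region, t_axis_ms=t_axis, dt_axis_ms=dt_axis, pc=pc
    )


def direction_contrast_test(
    ab: Sequence[FlowGrid],
    ba: Sequence[FlowGrid],
    tfce: TFCEParams | None = None,
    n_perm: int = 10000,
    seed: int | None = 0,
    tail: str = "two-sided",
) -> StatResult:
    """Group test of the per-subject direction contrast ab - ba on the t x dt grid.

    Grid connectivity is the 4-neighborhood of the matrix; cells missing in
    any subject are excluded.
    """
    if len(ab) != len(ba) or len(ab) < 4:
        raise ValueError("need matched FlowGrids for >= 4 subjects")
    shape = ab[0].pc.shape
    for g in list(ab) + list(ba):
        if g.pc.shape != shape:
            raise ValueError("incongruent flow grids")
    contrast = np.stack([a.pc - b.pc for a, b in zip(ab, ba)])  # (S, t, dt)
    valid = np.all(np.isfinite(contrast), axis=0).ravel()
    edges = compact_edges(lattice_edges(shape), valid)
    maps = contrast.reshape(len(ab), -1)[:, valid]
    result = permutation_test(
        maps, popmean=0.0, edges=edges, params=tfce, n_perm=n_perm, tail=tail, seed=seed
    )
    result.grid_shape = shape
    result.valid = valid
    result.meta.update(
        direction=f"{ab[0].source}->{ab[0].target} minus {ba[0].source}->{ba[0].target}",
        t_axis_ms=[float(ab[0].t_axis_ms[0]), float(ab[0].t_axis_ms[-1])],
        dt_axis_ms=[float(ab[0].dt_axis_ms[0]), float(ab[0].dt_axis_ms[-1])],
    )
    return result


def froi_union(results: Sequence[StatResult], masks: Sequence[np.ndarray], alpha: float = 0.05) -> np.ndarray:
    """Union of sources significant in any of several source x time StatResults.

    ``masks[i]`` gives the source indices of ``results[i]``'s spatial axis.
    """
    out: list[int] = []
    for res, mask in zip(results, masks):
        if res.grid_shape is None:
            raise ValueError("StatResult lacks grid metadata")
        sig = res.significant(alpha).reshape(res.grid_shape)
        out.extend(np.asarray(mask)[sig.any(axis=1)].tolist())
    return np.unique(np.asarray(out, dtype=np.int64))


class DirectedConnectivity:
    """RDM-based directed connectivity model between two named regions.

    Applies the shared pattern preprocessing (frequency regress-out +
    decimation) unless ``preprocess=False``.
    """

    def __init__(
        self,
        trials: Sequence[TrialTensor],
        space: SourceSpace,
        roi_a: str,
        roi_b: str,
        t_window_ms: tuple[float, float] = (600.0, 1200.0),
        dt_max_ms: float = 600.0,
        dt_step_ms: float = 5.0,
        granularity: str = "condition",
        n_pseudo: int = 15,
        preprocess: bool = True,
        decim: int = 5,
    ) -> None:
        self.space = space
        self.roi_a, self.roi_b = roi_a, roi_b
        self.mask_a, self.mask_b = space.mask(roi_a), space.mask(roi_b)
        self.t_window_ms = t_window_ms
        self.dt_max_ms, self.dt_step_ms = dt_max_ms, dt_step_ms
        self.granularity = granularity
        self.n_pseudo = n_pseudo
        if preprocess:
            trials = [preprocess_for_patterns(t, decim) for t in trials]
        self.trials = list(trials)

    def fit(self, seed: int | None = 0) -> "ConnectivityResults":
        """Per-subject RDM series and flow grids in both directions."""
        subj_seeds = np.random.SeedSequence(seed).spawn(len(self.trials))
        ab, ba = [], []
        for t, sseed in zip(self.trials, subj_seeds):
            rng = np.random.default_rng(sseed)
            rdm_a = compute_rdm_series(
                t, self.mask_a, self.roi_a, self.granularity, self.n_pseudo, rng
            )
            rdm_b = compute_rdm_series(
                t, self.mask_b, self.roi_b, self.granularity, self.n_pseudo, rng
            )
            ab.append(
                directed_flow(rdm_a, rdm_b, self.t_window_ms, self.dt_max_ms, self.dt_step_ms)
            )
            ba.append(
                directed_flow(rdm_b, rdm_a, self.t_window_ms, self.dt_max_ms, self.dt_step_ms)
            )
        logger.info(
            "directed_flow: %s<->%s, %d subjects, grid %s",
            self.roi_a, self.roi_b, len(self.trials), ab[0].pc.shape,
        )
        return ConnectivityResults(self, ab, ba, seed=seed)


class ConnectivityResults:
    """Per-subject flow grids plus the direction-contrast permutation test."""

    def __init__(self, model, ab: list[FlowGrid], ba: list[FlowGrid], seed) -> None:
        self.model = model
        self.ab = ab
        self.ba = ba
        self.seed = seed
        self.test: StatResult | None = None

    def mean_grid(self, direction: str = "ab") -> np.ndarray:
        grids = self.ab if direction == "ab" else self.ba
        return np.nanmean(np.stack([g.pc for g in grids]), axis=0)

    def direction_test(
        self, tfce: TFCEParams | None = None, n_perm: int = 10000, seed: int | None = 0,
        tail: str = "two-sided",
    ) -> StatResult:
        self.test = direction_contrast_test(self.ab, self.ba, tfce, n_perm, seed, tail)
        return self.test

    def summary(self, alpha: float = 0.05) -> str:
        m = self.model
        lines = [
            "RDM-based directed connectivity",
            f"  {m.roi_a} ({m.mask_a.size} sources) <-> {m.roi_b} ({m.mask_b.size} sources)"
            f"   subjects: {len(self.ab)}",
            f"  t window: {m.t_window_ms} ms   dt: {m.dt_step_ms}..{m.dt_max_ms} ms"
            f"   granularity: {m.granularity}",
            f"  mean pc {m.roi_a}->{m.roi_b}: {np.nanmean(self.mean_grid('ab')):.4f}"
            f"   {m.roi_b}->{m.roi_a}: {np.nanmean(self.mean_grid('ba')):.4f}",
        ]
        if self.test is not None:
            sig = self.test.significant(alpha)
            lines.append(
                f"  direction contrast: {int(sig.sum())} significant cells "
                f"(alpha={alpha}, n_perm={self.test.n_permutations}, min p={self.test.p.min():.4g})"
            )
            if sig.any():
                grid = self.test.to_grid(self.test.p, fill=1.0) <= alpha
                dt_ms = self.ab[0].dt_axis_ms[grid.any(axis=0)]
                t_ms = self.ab[0].t_axis_ms[grid.any(axis=1)]
                lines.append(
                    f"    t: {t_ms.min():.0f}-{t_ms.max():.0f} ms, "
                    f"dt: {dt_ms.min():.0f}-{dt_ms.max():.0f} ms"
                )
        return "\n".join(lines)
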