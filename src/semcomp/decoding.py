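"""Searchlight pairwise decoding with pseudo-trial averaging.

Condition pairs are classified with a linear maximum-margin classifier
(linear SVM, unit cost) on pseudo-trial source patterns inside sliding
searchlights (k graph-nearest sources x consecutive decimated samples), with
leave-one-stimulus-pair-out cross-validation re-partitioned on every
repetition.  Group inference compares accuracy to the 50% chance level with a
one-tailed t and TFCE max-statistic permutation correction.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .io import PAIRS, TrialTensor
from .regression import DesignMatrix, build_design
from .space import SourceSpace
from .stats import StatResult, TFCEParams, permutation_test

logger = logging.getLogger("semcomp")


# ---------------------------------------------------------------------------
# preprocessing


def regress_out_frequency(trials: TrialTensor, design: DesignMatrix | None = None) -> TrialTensor:
    """Remove the fitted word-frequency contribution at every source/time.

    The full design is fitted per (source, time) and only the two frequency
    columns' fitted contribution is subtracted, leaving condition structure
    untouched.
    """
    if design is None:
        for name in ("word1_logfreq", "word2_logfreq"):
            if np.ptp(getattr(trials, name)) == 0:
                raise ValueError(f"frequency covariate {name!r} is constant; nothing to regress")
        design = build_design(trials.condition, trials.word1_logfreq, trials.word2_logfreq)
    X = design.values
    f_idx = [design.columns.index("word1_logfreq"), design.columns.index("word2_logfreq")]
    for i in f_idx:
        if np.ptp(X[:, i]) == 0:
            raise ValueError(
                f"frequency column {design.columns[i]!r} is constant; nothing to regress"
            )
    Y = trials.data.reshape(trials.n_trials, -1)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted_freq = X[:, f_idx] @ beta[f_idx]
    out = trials.copy()
    out.data = (Y - fitted_freq).reshape(trials.data.shape)
    return out


def decimate(trials: TrialTensor, factor: int) -> TrialTensor:
    """Temporal downsampling: keep every ``factor``-th sample (data are
    low-pass filtered upstream).  ``mode="mean"`` averages blocks instead."""
    return _decimate(trials, factor, mode="subsample")


def _decimate(trials: TrialTensor, factor: int, mode: str = "subsample") -> TrialTensor:
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor > trials.n_time:
        raise ValueError(f"decimation factor {factor} exceeds {trials.n_time} samples")
    out = trials.copy()
    if mode == "subsample":
        out.data = np.ascontiguousarray(trials.data[:, :, ::factor])
    elif mode == "mean":
        n_keep = int(np.ceil(trials.n_time / factor))
        pad = n_keep * factor - trials.n_time
        d = trials.data
        if pad:
            d = np.concatenate([d, np.repeat(d[:, :, -1:], pad, axis=2)], axis=2)
        out.data = d.reshape(d.shape[0], d.shape[1], n_keep, factor).mean(axis=3)
    else:
        raise ValueError(f"unknown decimation mode {mode!r}")
    out.tstep_ms = trials.tstep_ms * factor
    return out


def preprocess_for_patterns(trials: TrialTensor, factor: int = 5) -> TrialTensor:
    """Shared pattern-analysis preprocessing: frequency regress-out, then
    decimation (used by both the decoder and the connectivity model)."""
    return decimate(regress_out_frequency(trials), factor)


# ---------------------------------------------------------------------------
# pseudo-trials


def make_pseudotrials(
    data: np.ndarray, n_pseudo: int = 15, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Average random disjoint partition blocks of one condition's trials.

    ``data`` is (trials x features...); returns (n_pseudo x features...).
    Remainder trials are assigned round-robin to the first blocks, so 60
    trials give 15 blocks of 4 and 45 trials give 15 blocks of 3.
    """
    n = data.shape[0]
    if n < n_pseudo:
        raise ValueError(f"need at least {n_pseudo} trials, got {n}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perm = rng.permutation(n)
    q, r = divmod(n, n_pseudo)
    sizes = np.full(n_pseudo, q)
    sizes[:r] += 1
    flat = data.reshape(n, -1)
    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    sums = np.add.reduceat(flat[perm], starts, axis=0)
    return (sums / sizes[:, None]).reshape((n_pseudo,) + data.shape[1:])


# ---------------------------------------------------------------------------
# searchlights


@dataclass
class SearchlightSpec:
    """Searchlight geometry: k graph-nearest sources x consecutive samples.

    ``n_sources_per_light`` is read as a count of breadth-first graph-nearest
    sources (ties broken by source index); ``n_timepoints_per_light``
    consecutive decimated samples are centered on the center sample (edges
    truncate).  ``time_stride`` subsamples center time points to thin the
    center grid.
    """

    n_sources_per_light: int = 100
    n_timepoints_per_light: int = 5
    time_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_sources_per_light < 1 or self.n_timepoints_per_light < 1:
            raise ValueError("neighborhood sizes must be positive")
        if self.time_stride < 1:
            raise ValueError("time_stride must be >= 1")


def source_neighborhoods(space: SourceSpace, mask: np.ndarray, k: int) -> list[np.ndarray]:
    """For each mask source, its k nearest mask sources by BFS hop distance.

    Deterministic: within a hop shell, sources are taken in index order.
    Returns neighborhoods as indices into ``mask`` (compact indexing).
    """
    mask = np.asarray(mask, dtype=np.int64)
    sub_edges = space.subgraph_edges(mask)
    n = mask.size
    k = min(k, n)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for u, v in sub_edges:
        neigh[u].append(v)
        neigh[v].append(u)
    neigh = [np.unique(x) for x in neigh]
    out = []
    for center in range(n):
        seen = np.zeros(n, dtype=bool)
        seen[center] = True
        order = [center]
        frontier = deque([center])
        while frontier and len(order) < k:
            shell = []
            for _ in range(len(frontier)):
                u = frontier.popleft()
                for v in neigh[u]:
                    if not seen[v]:
                        seen[v] = True
                        shell.append(v)
            for v in sorted(shell):
                if len(order) < k:
                    order.append(v)
                frontier.append(v)
        out.append(np.asarray(order, dtype=np.int64))
    return out


def time_neighborhood(center: int, n_time: int, width: int) -> np.ndarray:
    """``width`` consecutive samples centered on ``center``, truncated at edges."""
    half = (width - 1) // 2
    lo = max(0, center - half)
    hi = min(n_time, lo + width)
    lo = max(0, hi - width)
    return np.arange(lo, hi)


# ---------------------------------------------------------------------------
# pairwise decoding


def decode_pair(
    feats_a: np.ndarray,
    feats_b: np.ndarray,
    n_pseudo: int = 15,
    n_reps: int = 100,
    rng: np.random.Generator | int | None = None,
    standardize: bool = True,
    C: float = 1.0,
) -> float:
    """Mean leave-one-stimulus-pair-out linear-SVM accuracy over repetitions.

    Per repetition: both conditions are re-partitioned into ``n_pseudo``
    pseudo-trials, one random pseudo-trial per class is held out, the
    classifier is trained on the rest (features standardized by training-fold
    statistics) and scored on the held-out pair.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fa = feats_a.reshape(feats_a.shape[0], -1)
    fb = feats_b.reshape(feats_b.shape[0], -1)
    if np.ptp(fa) == 0 and np.ptp(fb) == 0:
        warnings.warn("degenerate (constant) features; returning chance accuracy")
        return 0.5
    labels = np.r_[np.zeros(n_pseudo - 1), np.ones(n_pseudo - 1)]
    correct = 0
    for _ in range(n_reps):
        pa = make_pseudotrials(fa, n_pseudo, rng)
        pb = make_pseudotrials(fb, n_pseudo, rng)
        hold = rng.integers(n_pseudo, size=2)
        train = np.vstack(
            [np.delete(pa, hold[0], axis=0), np.delete(pb, hold[1], axis=0)]
        )
        test = np.vstack([pa[hold[0]], pb[hold[1]]])
        if standardize:
            mu = train.mean(axis=0)
            sd = train.std(axis=0)
            sd[sd == 0] = 1.0
            train = (train - mu) / sd
            test = (test - mu) / sd
        clf = SVC(kernel="linear", C=C)
        clf.fit(train, labels)
        pred = clf.predict(test)
        correct += int(pred[0] == 0.0) + int(pred[1] == 1.0)
    return correct / (2.0 * n_reps)


# ---------------------------------------------------------------------------
# model / results


class SearchlightDecoder:
    """Searchlight pairwise decoder over a set of subjects.

    Expects preprocessed input (frequency regressed out, decimated); set
    ``preprocess=True`` to apply :func:`preprocess_for_patterns` internally.
    """

    def __init__(
        self,
        trials: Sequence[TrialTensor],
        space: SourceSpace,
        mask: str = "language",
        window_ms: tuple[float, float] = (600.0, 1200.0),
        spec: SearchlightSpec | None = None,
        pairs: tuple = PAIRS,
        n_pseudo: int = 15,
        preprocess: bool = False,
        decim: int = 5,
    ) -> None:
        self.space = space
        self.mask_name = mask
        self.mask = space.mask(mask)
        self.window_ms = window_ms
        self.spec = spec or SearchlightSpec()
        self.pairs = tuple(tuple(p) for p in pairs)
        self.n_pseudo = n_pseudo
        if preprocess:
            trials = [preprocess_for_patterns(t, decim) for t in trials]
        self.trials = list(trials)
        t0 = self.trials[0]
        wsl = t0.window_slice(window_ms)
        self.center_times = np.arange(wsl.start, wsl.stop, self.spec.time_stride)
        self.tstep_ms = t0.tstep_ms
        self._lights = source_neighborhoods(space, self.mask, self.spec.n_sources_per_light)

    @property
    def n_centers(self) -> int:
        return self.mask.size * self.center_times.size

    def fit(self, n_reps: int = 100, seed: int | None = 0) -> "DecodingResults":
        """Decode every pair at every searchlight center for every subject."""
        rng_root = np.random.SeedSequence(seed)
        subj_seeds = rng_root.spawn(len(self.trials))
        width = self.spec.n_timepoints_per_light
        acc = {
            pair: np.zeros((len(self.trials), self.mask.size, self.center_times.size))
            for pair in self.pairs
        }
        for s_i, (t, sseed) in enumerate(zip(self.trials, subj_seeds)):
            rng = np.random.default_rng(sseed)
            masked = t.data[:, self.mask, :]
            cond_idx = {c: t.trials_of(c) for c in set(sum(self.pairs, ()))}
            for pair in self.pairs:
                ia, ib = cond_idx[pair[0]], cond_idx[pair[1]]
                for c_s in range(self.mask.size):
                    srcs = self._lights[c_s]
                    for c_t, t_center in enumerate(self.center_times):
                        tsel = time_neighborhood(t_center, t.n_time, width)
                        fa = masked[np.ix_(ia, srcs, tsel)]
                        fb = masked[np.ix_(ib, srcs, tsel)]
                        acc[pair][s_i, c_s, c_t] = decode_pair(
                            fa, fb, self.n_pseudo, n_reps, rng
                        )
        logger.info(
            "searchlight_decode: %d subjects, %d centers, %d reps, pairs=%s",
            len(self.trials), self.n_centers, n_reps, self.pairs,
        )
        return DecodingResults(self, acc, n_reps=n_reps, seed=seed)


class DecodingResults:
    """Per-subject accuracy maps and group tests against chance."""

    chance = 0.5

    def __init__(self, model: SearchlightDecoder, accuracy: dict, n_reps: int, seed) -> None:
        self.model = model
        self.accuracy = accuracy  # pair -> (subjects, mask_sources, center_times)
        self.n_reps = n_reps
        self.seed = seed
        self.tests: dict[tuple, StatResult] = {}

    def _grid_edges(self) -> np.ndarray:
        from .space import spatiotemporal_edges

        spatial = self.model.space.subgraph_edges(self.model.mask)
        return spatiotemporal_edges(spatial, self.model.mask.size, self.model.center_times.size)

    def test_pair(
        self,
        pair: tuple[str, str],
        tfce: TFCEParams | None = None,
        n_perm: int = 10000,
        seed: int | None = 0,
    ) -> StatResult:
        """One-tailed group test of accuracy - 0.5 > 0 with TFCE correction."""
        pair = tuple(pair)
        maps = self.accuracy[pair]
        result = permutation_test(
            maps.reshape(maps.shape[0], -1),
            popmean=self.chance,
            edges=self._grid_edges(),
            params=tfce,
            n_perm=n_perm,
            tail="one-sided-positive",
            seed=seed,
        )
        result.grid_shape = (maps.shape[1], maps.shape[2])
        result.meta.update(
            pair=list(pair),
            window_ms=list(self.model.window_ms),
            tstep_ms=self.model.tstep_ms * self.model.spec.time_stride,
        )
        self.tests[pair] = result
        return result

    def grand_mean(self, pair: tuple[str, str]) -> float:
        return float(self.accuracy[tuple(pair)].mean())

    def summary(self, alpha: float = 0.05) -> str:
        m = self.model
        lines = [
            "Searchlight pairwise decoding",
            f"  subjects: {len(m.trials)}   mask: {m.mask_name} ({m.mask.size} sources)"
            f"   window: {m.window_ms} ms",
            f"  lights: {m.spec.n_sources_per_light} sources x "
            f"{m.spec.n_timepoints_per_light} samples   pseudo-trials: {m.n_pseudo}"
            f"   reps: {self.n_reps}",
        ]
        for pair in self.model.pairs:
            line = f"  {pair[0]} vs {pair[1]}: grand mean accuracy {self.grand_mean(pair):.3f}"
            if tuple(pair) in self.tests:
                res = self.tests[tuple(pair)]
                n_sig = int(res.significant(alpha).sum())
                line += f"; {n_sig} significant centers (alpha={alpha}, n_perm={res.n_permutations})"
            lines.append(line)
        return "\n".join(lines)
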