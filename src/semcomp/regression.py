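"""Two-stage mass-univariate regression with TFCE permutation inference.

Stage one fits an ordinary least-squares regression to each subject's
single-trial source estimates independently at every source (within a mask)
and time sample (within a window), with compositionality, association, their
interaction and number of words as predictors and the two word
log-frequencies as controls.  Stage two tests each predictor's coefficients
across subjects with a one-sample t and TFCE max-statistic permutation
correction over the source x time grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TrialTensor
from .space import SourceSpace, spatiotemporal_edges
from .stats import StatResult, TFCEParams, collinear_columns, permutation_test

logger = logging.getLogger("semcomp")

PREDICTORS = (
    "intercept",
    "association",
    "composition",
    "interaction",
    "n_words",
    "word1_logfreq",
    "word2_logfreq",
)


@dataclass
class DesignMatrix:
    """Trials x predictors matrix with a fixed column order."""

    values: np.ndarray
    columns: tuple[str, ...] = PREDICTORS
    coding: str = "dummy"

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("value columns do not match predictor names")
        rank = np.linalg.matrix_rank(self.values)
        if rank < len(self.columns):
            raise np.linalg.LinAlgError(
                "design matrix rank deficient; collinear columns: "
                f"{collinear_columns(self.values, self.columns)}"
            )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))


def build_design(
    condition: np.ndarray,
    word1_logfreq: np.ndarray,
    word2_logfreq: np.ndarray,
    coding: str = "dummy",
) -> DesignMatrix:
    """Design matrix from per-trial condition labels and covariates.

    Dummy coding (default) puts the single-word condition at the origin:
    association = 1 for HA-*, composition = 1 for *-comp, n_words = 1 for
    two-word trials, interaction = association x composition.  Effect coding
    (+-0.5) is available via ``coding="effect"``.  Frequency covariates are
    centered across trials.
    """
    condition = np.asarray(condition, dtype="U16")
    known = {"HA-comp", "LA-comp", "HA-list", "LA-list", "single"}
    unknown = set(condition.tolist()) - known
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    assoc = np.char.startswith(condition, "HA").astype(float)
    comp = np.char.endswith(condition, "comp").astype(float)
    n_words = (condition != "single").astype(float)
    if coding == "effect":
        assoc = np.where(n_words > 0, assoc - 0.5, 0.0)
        comp = np.where(n_words > 0, comp - 0.5, 0.0)
    elif coding != "dummy":
        raise ValueError(f"unknown coding {coding!r}")
    inter = assoc * comp
    w1 = np.asarray(word1_logfreq, dtype=float)
    w2 = np.asarray(word2_logfreq, dtype=float)
    values = np.column_stack(
        [
            np.ones(condition.size),
            assoc,
            comp,
            inter,
            n_words,
            w1 - w1.mean(),
            w2 - w2.mean(),
        ]
    )
    return DesignMatrix(values=values, coding=coding)


@dataclass
class BetaStack:
    """subject x predictor x source x time first-stage coefficients."""

    beta: np.ndarray
    predictors: tuple[str, ...]
    mask: np.ndarray  # source indices of axis 2
    window_ms: tuple[float, float]
    tstep_ms: float

    def __post_init__(self) -> None:
        if self.beta.shape[1] != len(self.predictors):
            raise ValueError("predictor axis does not match predictor names")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta stack contains non-finite values")

    def predictor_maps(self, name: str) -> np.ndarray:
        """(subjects x sources x time) maps for one predictor."""
        if name not in self.predictors:
            raise KeyError(f"predictor {name!r} not in {self.predictors}")
        return self.beta[:, self.predictors.index(name)]


def first_stage(
    trials: TrialTensor,
    design: DesignMatrix,
    mask: np.ndarray,
    window_ms: tuple[float, float],
) -> np.ndarray:
    """Per-(source, time) OLS within mask x window; returns (pred, src, time)."""
    mask = np.asarray(mask, dtype=np.int64)
    if mask.size == 0:
        raise ValueError("mask must be non-empty")
    wsl = trials.window_slice(window_ms)
    X = design.values
    if X.shape[0] != trials.n_trials:
        raise ValueError("design rows do not match trial count")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more trials than predictors")
    Y = trials.data[:, mask, wsl].reshape(trials.n_trials, -1)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return beta.reshape(len(design.columns), mask.size, wsl.stop - wsl.start)


class MassUnivariateRegression:
    """Two-stage regression model over a set of subjects.

    Parameters
    ----------
    trials : sequence of TrialTensor
        One tensor per subject.
    space : SourceSpace
    mask : str
        Name of the analysis mask (default ``"language"``).
    window_ms : (start, end)
        Analysis window, milliseconds from first-word onset, half-open.
    coding : {"dummy", "effect"}
    """

    def __init__(
        self,
        trials: Sequence[TrialTensor],
        space: SourceSpace,
        mask: str = "language",
        window_ms: tuple[float, float] = (0.0, 1200.0),
        coding: str = "dummy",
    ) -> None:
        if len(trials) < 1:
            raise ValueError("need at least one subject")
        self.trials = list(trials)
        self.space = space
        self.mask_name = mask
        self.mask = space.mask(mask)
        self.window_ms = window_ms
        self.coding = coding

    def fit(self) -> "MassRegressionResults":
        """Run the first-stage OLS for every subject."""
        betas = []
        for t in self.trials:
            design = build_design(t.condition, t.word1_logfreq, t.word2_logfreq, self.coding)
            betas.append(first_stage(t, design, self.mask, self.window_ms))
        stack = BetaStack(
            beta=np.stack(betas),
            predictors=PREDICTORS,
            mask=self.mask,
            window_ms=self.window_ms,
            tstep_ms=self.trials[0].tstep_ms,
        )
        return MassRegressionResults(self, stack)


class MassRegressionResults:
    """First-stage coefficients plus group-level TFCE permutation tests."""

    def __init__(self, model: MassUnivariateRegression, betas: BetaStack) -> None:
        self.model = model
        self.betas = betas
        self.tests: dict[str, StatResult] = {}

    @property
    def n_subjects(self) -> int:
        return self.betas.beta.shape[0]

    def _grid_edges(self, n_time: int) -> np.ndarray:
        spatial = self.model.space.subgraph_edges(self.betas.mask)
        return spatiotemporal_edges(spatial, self.betas.mask.size, n_time)

    def test_predictor(
        self,
        predictor: str,
        tfce: TFCEParams | None = None,
        n_perm: int = 10000,
        seed: int | None = 0,
        tail: str = "two-sided",
        window_ms: tuple[float, float] | None = None,
        null: str = "signflip",
    ) -> StatResult:
        """Second stage: one-sample t across subjects + TFCE permutation p.

        ``window_ms`` optionally restricts the test to a sub-window of the
        fitted window (e.g. the word-2 epoch).
        """
        maps = self.betas.predictor_maps(predictor)  # (S, src, time)
        t0 = self.betas.window_ms[0]
        step = self.betas.tstep_ms
        if window_ms is not None:
            i0 = int(np.ceil((window_ms[0] - t0) / step - 1e-9))
            i1 = int(np.ceil((window_ms[1] - t0) / step - 1e-9))
            if i0 < 0 or i1 > maps.shape[2] or i0 >= i1:
                raise ValueError("test window outside fitted window")
            maps = maps[:, :, i0:i1]
            t0 = t0 + i0 * step
        n_src, n_time = maps.shape[1], maps.shape[2]
        result = permutation_test(
            maps.reshape(maps.shape[0], -1),
            popmean=0.0,
            edges=self._grid_edges(n_time),
            params=tfce,
            n_perm=n_perm,
            tail=tail,
            seed=seed,
            null=null,
        )
        result.grid_shape = (n_src, n_time)
        result.meta.update(
            predictor=predictor,
            mask=self.model.mask_name,
            window_ms=[t0, t0 + n_time * step],
            tstep_ms=step,
        )
        logger.info("second_stage: predictor=%s window=%s tail=%s", predictor, result.meta["window_ms"], tail)
        self.tests[predictor] = result
        return result

    def clusters(self, predictor: str, alpha: float = 0.05) -> pd.DataFrame:
        """Connected significant clusters with extent, window and peak t."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        res = self.tests[predictor]
        sig = res.significant(alpha)
        rows = []
        if sig.any():
            n_src, n_time = res.grid_shape
            edges = self._grid_edges(n_time)
            idx = np.flatnonzero(sig)
            lookup = np.full(sig.size, -1)
            lookup[idx] = np.arange(idx.size)
            u, v = lookup[edges[:, 0]], lookup[edges[:, 1]]
            keep = (u >= 0) & (v >= 0)
            adj = coo_matrix(
                (np.ones(keep.sum()), (u[keep], v[keep])), shape=(idx.size, idx.size)
            )
            n_comp, labels = connected_components(adj, directed=False)
            t0, _ = res.meta["window_ms"]
            step = res.meta["tstep_ms"]
            for c in range(n_comp):
                pts = idx[labels == c]
                srcs = self.betas.mask[pts // n_time]
                times = t0 + (pts % n_time) * step
                peak = pts[np.argmax(np.abs(res.stat[pts]))]
                rows.append(
                    {
                        "predictor": predictor,
                        "n_points": pts.size,
                        "n_sources": np.unique(srcs).size,
                        "t_start_ms": times.min(),
                        "t_end_ms": times.max() + step,
                        "peak_t": res.stat[peak],
                        "min_p": res.p[pts].min(),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "predictor", "n_points", "n_sources",
                "t_start_ms", "t_end_ms", "peak_t", "min_p",
            ],
        )

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            "Mass univariate two-stage regression",
            f"  subjects: {self.n_subjects}   mask: {self.model.mask_name} "
            f"({self.betas.mask.size} sources)   window: {self.betas.window_ms} ms",
            f"  coding: {self.model.coding}   predictors: {', '.join(PREDICTORS)}",
        ]
        if not self.tests:
            lines.append("  (no second-stage tests run yet)")
        for name, res in self.tests.items():
            df = self.clusters(name, alpha)
            lines.append(
                f"  predictor {name!r}: n_perm={res.n_permutations} tail={res.tail} "
                f"min p={res.p.min():.4g}"
            )
            if df.empty:
                lines.append(f"    no significant clusters at alpha={alpha}")
            else:
                for _, r in df.iterrows():
                    lines.append(
                        f"    cluster: {int(r.n_sources)} sources, "
                        f"{r.t_start_ms:.0f}-{r.t_end_ms:.0f} ms, "
                        f"peak t={r.peak_t:.2f}, p={r.min_p:.4g}"
                    )
        return "\n".join(lines)
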