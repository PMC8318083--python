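"""Synthetic trial-level source estimates with plantable effects.

Emulates the inputs the pipeline assumes: per-subject trials x sources x time
tensors under a 2 x 2 (association low/high x compositionality list/comp) +
single-word design, with word log-frequency covariates mixed into the signal
with a negative slope, optional planted univariate or multivariate condition
effects, optional lagged inter-region coupling, and graph-structured noise.
Every planted feature is recorded in a :class:`GroundTruth` for recovery
tests.

Generative structure per trial::

    data = evoked (shared across conditions)
         + frequency contribution (slope * centered log-frequency * pattern)
         + planted effects (additive inside their region x window)
         + couplings (gain-scaled, lag-shifted projection of the source region)
         + noise (white -> graph-diffused -> temporally smoothed -> rescaled)
         + per-subject amplitude offset

Realized frequency covariates are centered within each condition cell before
entering the signal, so condition-mean contrasts of noiseless data reproduce
planted amplitudes exactly (the study matched frequency across conditions by
stimulus construction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import CONDITIONS, TrialTensor
from .space import SourceSpace

TWO_WORD = tuple(c for c in CONDITIONS if c != "single")


@dataclass
class DesignSpec:
    """Experimental design: subjects, trial counts, epoch timing.

    Defaults follow the two-cohort study design: 42 subjects, epoch
    [-100, 1200) ms at 1000 Hz, second word at 600 ms.
    """

    n_subjects: int = 42
    trials_per_condition: int = 60
    conditions: tuple[str, ...] = CONDITIONS
    epoch_start_ms: float = -100.0
    epoch_end_ms: float = 1200.0
    sample_rate_hz: float = 1000.0
    word2_onset_ms: float = 600.0

    def __post_init__(self) -> None:
        if not (self.epoch_start_ms < self.word2_onset_ms < self.epoch_end_ms):
            raise ValueError("require epoch_start < word2_onset < epoch_end")
        if self.trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")
        if set(self.conditions) != set(CONDITIONS):
            raise ValueError(f"conditions must be exactly {CONDITIONS}")

    @classmethod
    def experiment1(cls, **kw) -> "DesignSpec":
        """Cohort 1: 21 subjects, 60 trials per condition."""
        return cls(n_subjects=21, trials_per_condition=60, **kw)

    @classmethod
    def experiment2(cls, **kw) -> "DesignSpec":
        """Cohort 2: 21 subjects, 45 trials per condition."""
        return cls(n_subjects=21, trials_per_condition=45, **kw)

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    @property
    def n_time(self) -> int:
        return int(round((self.epoch_end_ms - self.epoch_start_ms) / self.step_ms))


@dataclass
class PlantedEffect:
    """An additive effect inside region_mask x window_ms.

    ``predictor_name`` is either a design-matrix predictor (``association``,
    ``composition``, ``interaction``, ``n_words``, ``word1_logfreq``,
    ``word2_logfreq``) for ``effect_form="univariate-amplitude"``, or a
    pairwise-pattern contrast ``"pattern:COND1|COND2"`` (+P to COND1, -P to
    COND2) / ``"pattern:per-condition"`` (independent pattern per two-word
    condition) for ``effect_form="multivariate-pattern"``.
    """

    predictor_name: str
    region_mask: np.ndarray
    window_ms: tuple[float, float]
    amplitude: float
    effect_form: str = "univariate-amplitude"
    pattern_seed: int = 0

    def __post_init__(self) -> None:
        self.region_mask = np.unique(np.asarray(self.region_mask, dtype=np.int64))
        if self.region_mask.size == 0:
            raise ValueError("region_mask must be non-empty")
        if self.effect_form not in ("univariate-amplitude", "multivariate-pattern"):
            raise ValueError(f"unknown effect_form {self.effect_form!r}")


@dataclass
class CouplingSpec:
    """Directed lagged coupling: target region receives a gain-scaled,
    lag-shifted random projection of the source region's signal."""

    source_region: str
    target_region: str
    lag_ms: float
    gain: float
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lag_ms <= 0:
            raise ValueError("lag_ms must be positive")
        if self.source_region == self.target_region:
            raise ValueError("source and target regions must differ")


@dataclass
class NoiseSpec:
    """Additive noise model: white sensor noise, optional graph-diffusion
    spatial correlation, per-subject amplitude offsets, temporal smoothing."""

    sensor_sd: float = 1.0
    spatial_corr_length: int = 0
    subject_sd: float = 0.0
    temporal_smoothing_ms: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sensor_sd, self.spatial_corr_length, self.subject_sd, self.temporal_smoothing_ms) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class GroundTruth:
    """Record of everything planted, for recovery tests."""

    design: dict
    effects: list = field(default_factory=list)
    couplings: list = field(default_factory=list)
    overlaps: list = field(default_factory=list)  # (effect_idx, coupling_idx) pairs
    generator: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return json.dumps(_clean(asdict(self)), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _coding_value(condition: np.ndarray, predictor: str, w1c: np.ndarray, w2c: np.ndarray) -> np.ndarray:
    """Per-trial regressor value under dummy coding (for planting effects)."""
    assoc = np.char.startswith(condition, "HA").astype(float)
    comp = np.char.endswith(condition, "comp").astype(float)
    if predictor == "association":
        return assoc
    if predictor == "composition":
        return comp
    if predictor == "interaction":
        return assoc * comp
    if predictor == "n_words":
        return (condition != "single").astype(float)
    if predictor == "word1_logfreq":
        return w1c
    if predictor == "word2_logfreq":
        return w2c
    raise ValueError(f"unknown predictor {predictor!r}")


def _bump(times_ms: np.ndarray, center_ms: float, sd_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - center_ms) / sd_ms) ** 2)


def _smooth_field(space: SourceSpace, raw: np.ndarray, steps: int = 2) -> np.ndarray:
    """Graph-diffusion smoothing of a per-source field."""
    adj = space.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel() + 1.0
    x = raw
    for _ in range(steps):
        x = (x + adj @ x) / deg if x.ndim == 1 else (x + adj @ x) / deg[:, None]
    return x


def _center_within_condition(values: np.ndarray, condition: np.ndarray) -> np.ndarray:
    out = values.copy()
    for c in np.unique(condition):
        sel = condition == c
        out[sel] -= out[sel].mean()
    return out


def simulate_dataset(
    design: DesignSpec,
    space: SourceSpace,
    effects: list[PlantedEffect] | tuple = (),
    couplings: list[CouplingSpec] | tuple = (),
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    evoked_amplitude: float = 1.0,
    freq_slope: float = -0.1,
    freq_mean: float = 3.0,
    freq_sd: float = 0.8,
    dropout: float = 0.0,
) -> tuple[list[TrialTensor], GroundTruth]:
    """Generate one TrialTensor per subject plus the ground-truth record.

    ``freq_slope`` is the (negative) amplitude change per log10-frequency unit
    — higher word frequency decreases activation.  ``dropout`` optionally
    removes each trial independently with that probability, emulating epoch
    rejection.
    """
    if seed is None:
        raise ValueError("simulate_dataset requires an explicit seed")
    if space.n_sources < 50:
        raise ValueError("source space must have at least 50 sources")
    noise = noise or NoiseSpec()
    step = design.step_ms
    n_time = design.n_time
    times = design.epoch_start_ms + step * np.arange(n_time)
    w2_on = design.word2_onset_ms

    for eff in effects:
        s, e = eff.window_ms
        if s < design.epoch_start_ms or e > design.epoch_end_ms or s >= e:
            raise ValueError(f"effect window {eff.window_ms} outside epoch")
        if eff.region_mask.max() >= space.n_sources:
            raise ValueError("effect region_mask outside source space")
    for cpl in couplings:
        if cpl.lag_ms >= design.epoch_end_ms - design.epoch_start_ms:
            raise ValueError(f"coupling lag {cpl.lag_ms} ms exceeds epoch length")
        if cpl.window_ms[0] - cpl.lag_ms < design.epoch_start_ms:
            raise ValueError("coupling lag reaches before epoch start for its window")

    ss = np.random.SeedSequence(seed)
    shared_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(design.n_subjects + 1)[1:]

    # fixed spatial structure shared across subjects
    evoked_pattern = 0.5 + 0.5 * _smooth_field(space, shared_rng.standard_normal(space.n_sources))
    freq_pattern = _smooth_field(space, shared_rng.standard_normal(space.n_sources))
    freq_pattern /= max(np.abs(freq_pattern).max(), 1e-12)
    coupling_mats = []
    for cpl in couplings:
        src_idx = space.mask(cpl.source_region)
        tgt_idx = space.mask(cpl.target_region)
        W = shared_rng.standard_normal((tgt_idx.size, src_idx.size)) / np.sqrt(src_idx.size)
        coupling_mats.append((src_idx, tgt_idx, W))

    w1_bump = _bump(times, 150.0, 50.0)  # word 1 evoked component
    w2_bump = _bump(times, w2_on + 150.0, 50.0)
    f1_bump = _bump(times, 250.0, 80.0)  # frequency effect ~200-350 ms post onset
    f2_bump = _bump(times, w2_on + 250.0, 80.0)

    n_per = design.trials_per_condition
    condition = np.repeat(np.array(CONDITIONS, dtype="U16"), n_per)
    is_single = condition == "single"
    two_word = ~is_single

    tensors: list[TrialTensor] = []
    truth = GroundTruth(
        design=asdict(design),
        generator={
            "evoked_amplitude": evoked_amplitude,
            "freq_slope": freq_slope,
            "freq_mean": freq_mean,
            "freq_sd": freq_sd,
            "dropout": dropout,
            "noise": asdict(noise),
            "seed": seed,
        },
    )
    for i, eff in enumerate(effects):
        truth.effects.append(
            {
                "predictor_name": eff.predictor_name,
                "region_mask": eff.region_mask,
                "window_ms": list(eff.window_ms),
                "amplitude": eff.amplitude,
                "effect_form": eff.effect_form,
                "pattern_seed": eff.pattern_seed,
            }
        )
    for j, cpl in enumerate(couplings):
        truth.couplings.append(asdict(cpl))
        for i, eff in enumerate(effects):
            w_overlap = eff.window_ms[0] < cpl.window_ms[1] and cpl.window_ms[0] < eff.window_ms[1]
            tgt_idx = space.mask(cpl.target_region)
            if w_overlap and np.intersect1d(eff.region_mask, tgt_idx).size:
                truth.overlaps.append([i, j])

    def idx_of(ms: float) -> int:
        return int(np.ceil((ms - design.epoch_start_ms) / step - 1e-9))

    for s_i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        n_trials = condition.size
        # realized log-frequencies are re-centered so every condition cell has
        # exactly the same mean (stimulus lists are frequency-matched across
        # conditions); covariates are then orthogonal to the condition factors
        w1c = _center_within_condition(rng.normal(freq_mean, freq_sd, n_trials), condition)
        w2c = _center_within_condition(rng.normal(freq_mean, freq_sd, n_trials), condition)
        w1 = freq_mean + w1c
        w2 = freq_mean + w2c

        sig = np.zeros((n_trials, space.n_sources, n_time))
        # evoked responses (identical across conditions; word-1 absent for single)
        sig += evoked_amplitude * np.einsum(
            "n,s,t->nst", two_word.astype(float), evoked_pattern, w1_bump
        )
        sig += evoked_amplitude * evoked_pattern[None, :, None] * w2_bump[None, None, :]
        # frequency contributions (word-1 only for two-word trials)
        sig += freq_slope * np.einsum("n,s,t->nst", w1c * two_word, freq_pattern, f1_bump)
        sig += freq_slope * np.einsum("n,s,t->nst", w2c, freq_pattern, f2_bump)

        for eff in effects:
            wsl = slice(idx_of(eff.window_ms[0]), idx_of(eff.window_ms[1]))
            n_win = wsl.stop - wsl.start
            if eff.effect_form == "univariate-amplitude":
                x = _coding_value(condition, eff.predictor_name, w1c, w2c)
                sig[:, eff.region_mask, wsl] += (
                    eff.amplitude * x[:, None, None] * np.ones((1, eff.region_mask.size, n_win))
                )
            else:
                # subject-specific (idiosyncratic) multivariate patterns:
                # decodable within subject, variable across subjects
                prng = np.random.default_rng([eff.pattern_seed, s_i])
                t_idx = np.arange(wsl.start, wsl.stop)
                if eff.predictor_name == "pattern:per-condition":
                    for c in TWO_WORD:
                        P = eff.amplitude * prng.standard_normal((eff.region_mask.size, n_win))
                        sel = np.flatnonzero(condition == c)
                        sig[np.ix_(sel, eff.region_mask, t_idx)] += P[None, :, :]
                elif eff.predictor_name.startswith("pattern:") and "|" in eff.predictor_name:
                    c1, c2 = eff.predictor_name[len("pattern:") :].split("|")
                    P = eff.amplitude * prng.standard_normal((eff.region_mask.size, n_win))
                    for c, sign in ((c1, 1.0), (c2, -1.0)):
                        sel = np.flatnonzero(condition == c)
                        sig[np.ix_(sel, eff.region_mask, t_idx)] += sign * P[None, :, :]
                else:
                    raise ValueError(
                        f"multivariate effect needs 'pattern:C1|C2' or "
                        f"'pattern:per-condition', got {eff.predictor_name!r}"
                    )

        for (src_idx, tgt_idx, W), cpl in zip(coupling_mats, couplings):
            lag = int(round(cpl.lag_ms / step))
            t0, t1 = idx_of(cpl.window_ms[0]), idx_of(cpl.window_ms[1])
            seg = sig[:, src_idx, t0 - lag : t1 - lag]
            sig[:, tgt_idx, t0:t1] += cpl.gain * np.einsum("ks,nst->nkt", W, seg)

        if noise.sensor_sd > 0:
            eps = rng.standard_normal(sig.shape)
            if noise.spatial_corr_length > 0:
                adj = space.adjacency()
                deg = np.asarray(adj.sum(axis=1)).ravel() + 1.0
                flat = eps.transpose(1, 0, 2).reshape(space.n_sources, -1)
                for _ in range(noise.spatial_corr_length):
                    flat = (flat + adj @ flat) / deg[:, None]
                eps = flat.reshape(space.n_sources, n_trials, n_time).transpose(1, 0, 2)
            if noise.temporal_smoothing_ms > 0:
                eps = gaussian_filter1d(eps, noise.temporal_smoothing_ms / step, axis=-1)
            # rescale so the realized trial noise SD matches sensor_sd
            eps *= noise.sensor_sd / max(eps.std(), 1e-12)
            sig += eps
        if noise.subject_sd > 0:
            sig += rng.normal(0.0, noise.subject_sd)

        keep = np.ones(n_trials, dtype=bool)
        if dropout > 0:
            keep = rng.random(n_trials) >= dropout
            for c in CONDITIONS:
                if (keep & (condition == c)).sum() < 2:
                    raise ValueError(f"dropout left fewer than 2 trials in condition {c!r}")

        tensors.append(
            TrialTensor(
                data=sig[keep],
                condition=condition[keep],
                word1_logfreq=w1[keep],
                word2_logfreq=w2[keep],
                subject_id=f"{s_i:02d}",
                tstart_ms=design.epoch_start_ms,
                tstep_ms=step,
            )
        )
    return tensors, truth
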