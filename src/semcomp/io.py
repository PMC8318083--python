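"""Array containers and on-disk formats.

A :class:`TrialTensor` holds one subject's single-trial source estimates
(trials x sources x time, dSPM-like units) together with condition labels,
word log-frequency covariates and the time axis.  Containers are written as a
deterministic ``.npz`` (zip of ``.npy`` members with frozen timestamps, so a
rerun under the same seed is bit-identical) plus a human-readable JSON
metadata sidecar.
"""

from __future__ import annotations

import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib import format as npformat

SCHEMA_VERSION = 1

#: The five conditions of the 2 x 2 (+ single-word control) design:
#: association low/high crossed with compositionality list/comp.
CONDITIONS = ("HA-comp", "LA-comp", "HA-list", "LA-list", "single")

#: The four pairwise classifications run by the decoder.
PAIRS = (
    ("HA-comp", "HA-list"),
    ("LA-comp", "LA-list"),
    ("HA-comp", "LA-comp"),
    ("HA-list", "LA-list"),
)


@dataclass
class TrialTensor:
    """One subject's trials x sources x time source estimates plus covariates."""

    data: np.ndarray  # (n_trials, n_sources, n_time) float64
    condition: np.ndarray  # (n_trials,) unicode labels
    word1_logfreq: np.ndarray  # (n_trials,) log10 word frequency, word 1
    word2_logfreq: np.ndarray  # (n_trials,) log10 word frequency, word 2
    subject_id: str
    tstart_ms: float = -100.0
    tstep_ms: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.condition = np.asarray(self.condition, dtype="U16")
        self.word1_logfreq = np.asarray(self.word1_logfreq, dtype=np.float64)
        self.word2_logfreq = np.asarray(self.word2_logfreq, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, sources, time)")
        n = self.data.shape[0]
        for name in ("condition", "word1_logfreq", "word2_logfreq"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length does not match n_trials={n}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        unknown = set(np.unique(self.condition)) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sources(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tstart_ms + self.tstep_ms * np.arange(self.n_time)

    def time_index(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms``."""
        i = int(np.ceil((t_ms - self.tstart_ms) / self.tstep_ms - 1e-9))
        if i < 0 or i > self.n_time:
            raise ValueError(f"time {t_ms} ms outside epoch")
        return i

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        """Half-open sample slice covering [start_ms, end_ms)."""
        start, end = window_ms
        if start >= end:
            raise ValueError("window start must precede end")
        return slice(self.time_index(start), self.time_index(end))

    def trials_of(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.condition == condition)

    def copy(self) -> "TrialTensor":
        return TrialTensor(
            self.data.copy(),
            self.condition.copy(),
            self.word1_logfreq.copy(),
            self.word2_logfreq.copy(),
            self.subject_id,
            self.tstart_ms,
            self.tstep_ms,
        )


# ---------------------------------------------------------------------------
# deterministic container writing


def savez_deterministic(path: str | Path, **arrays: np.ndarray) -> None:
    """Like np.savez but with frozen zip timestamps (bit-identical reruns)."""
    path = Path(path)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            npformat.write_array(buf, np.ascontiguousarray(arrays[name]))
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


_KNOWN_META = {
    "schema_version",
    "kind",
    "subject_id",
    "tstart_ms",
    "tstep_ms",
    "n_trials",
    "n_sources",
    "n_time",
    "config_hash",
}


def write_trials(tensor: TrialTensor, path: str | Path, config_hash: str | None = None) -> None:
    """Write a TrialTensor to ``<path>.npz`` + ``<path>.json`` sidecar."""
    path = Path(path)
    savez_deterministic(
        path.with_suffix(".npz"),
        data=tensor.data,
        condition=tensor.condition,
        word1_logfreq=tensor.word1_logfreq,
        word2_logfreq=tensor.word2_logfreq,
    )
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "trial_tensor",
        "subject_id": tensor.subject_id,
        "tstart_ms": tensor.tstart_ms,
        "tstep_ms": tensor.tstep_ms,
        "n_trials": tensor.n_trials,
        "n_sources": tensor.n_sources,
        "n_time": tensor.n_time,
    }
    if config_hash is not None:
        meta["config_hash"] = config_hash
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_trials(path: str | Path) -> TrialTensor:
    """Read a TrialTensor container; fails closed on truncation or mismatch."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise IOError(
            f"container schema version {meta.get('schema_version')!r} "
            f"does not match expected {SCHEMA_VERSION}"
        )
    extra = set(meta) - _KNOWN_META
    if extra:
        warnings.warn(f"container has unknown metadata fields {sorted(extra)}; ignored")
    try:
        with np.load(path.with_suffix(".npz")) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, ValueError, EOFError, KeyError) as exc:
        raise IOError(f"corrupt or truncated container {path}: {exc}") from exc
    for fieldname in ("data", "condition", "word1_logfreq", "word2_logfreq"):
        if fieldname not in arrays:
            raise IOError(f"container missing field {fieldname!r}")
    tensor = TrialTensor(
        arrays["data"],
        arrays["condition"],
        arrays["word1_logfreq"],
        arrays["word2_logfreq"],
        subject_id=str(meta["subject_id"]),
        tstart_ms=float(meta["tstart_ms"]),
        tstep_ms=float(meta["tstep_ms"]),
    )
    if tensor.data.shape != (meta["n_trials"], meta["n_sources"], meta["n_time"]):
        raise IOError("container field 'data' shape does not match sidecar metadata")
    return tensor


def write_dataset(tensors: list[TrialTensor], directory: str | Path, config_hash: str | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION, "kind": "dataset", "subjects": []}
    for t in tensors:
        write_trials(t, directory / f"sub-{t.subject_id}", config_hash)
        manifest["subjects"].append(t.subject_id)
    if config_hash is not None:
        manifest["config_hash"] = config_hash
    (directory / "dataset.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_dataset(directory: str | Path) -> list[TrialTensor]:
    directory = Path(directory)
    manifest = json.loads((directory / "dataset.json").read_text())
    return [read_trials(directory / f"sub-{sid}") for sid in manifest["subjects"]]
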