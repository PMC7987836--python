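"""Shared data containers, file I/O and configuration.

The pipeline passes three kinds of data between stages:

* :class:`MultiTimeSeries` — ROI-level (channel x time) signals, the input
  to the MVAR / Granger stage.  Stored as HDF5.
* :class:`VertexActivationMap` — vertex-level cortical activation maps
  (3-D coordinates in mm plus an activation time course per vertex), the
  input to ROI identification.  Stored as HDF5.
* :class:`TrialTable` — behavioral trial tables from the two-alternative
  phoneme categorization task.  Stored as CSV (comma-separated, UTF-8,
  header required).

:class:`AnalysisConfig` collects every analysis constant in one place;
YAML is the on-disk configuration dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("phonoflux")

GROUPS = ("sr-familiarization", "shl-familiarization")
CONDITIONS = ("Trained", "Naive")
CONTEXTS = ("_l", "_r")
RESPONSES = ("S", "SH")
STEPS = (1, 2, 3, 4, 5)

TRIAL_COLUMNS = ("subject_id", "group", "condition", "context", "step",
                 "response", "unrepaired")
_REQUIRED_TRIAL_COLUMNS = ("subject_id", "group", "context", "step", "response")


class SchemaError(ValueError):
    """A file is missing a required column, dataset, or attribute."""


class ValidationError(ValueError):
    """Data violate a container invariant or a category domain."""


class StabilityError(ValueError):
    """An autoregressive model is unstable (spectral radius >= 1)."""


# ---------------------------------------------------------------------------
# time axis helpers

def window_to_samples(window_ms: tuple[float, float], sampling_rate: float,
                      t0_ms: float, n_timepoints: int) -> tuple[int, int]:
    """Convert a closed window in ms to inclusive sample indices.

    Endpoints are rounded toward the interior of the window so that the
    returned samples all lie inside the closed interval.  At 1000 Hz with
    t0_ms = 0 the window [100, 500] maps to indices (100, 500): 401 samples.
    """
    dt_ms = 1000.0 / sampling_rate
    lo = int(np.ceil((window_ms[0] - t0_ms) / dt_ms - 1e-9))
    hi = int(np.floor((window_ms[1] - t0_ms) / dt_ms + 1e-9))
    if lo < 0 or hi >= n_timepoints or lo > hi:
        raise ValidationError(
            f"window {window_ms} ms falls outside the sampled span "
            f"(t0={t0_ms} ms, {n_timepoints} samples at {sampling_rate} Hz)")
    return lo, hi


# ---------------------------------------------------------------------------
# containers

@dataclass
class MultiTimeSeries:
    """Labeled multichannel time series (n_channels x n_timepoints).

    ``t0_ms`` is the time of the first sample relative to stimulus onset;
    acquisition in the experiments this models is at 1000 Hz.
    """

    labels: list[str]
    values: np.ndarray
    sampling_rate: float
    t0_ms: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (channels x time)")
        if self.values.shape[0] != len(self.labels):
            raise ValidationError(
                f"{len(self.labels)} labels for {self.values.shape[0]} channels")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("channel labels must be unique")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValidationError("need at least one channel and one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_timepoints) * 1000.0 / self.sampling_rate

    def window_indices(self, window_ms: tuple[float, float]) -> tuple[int, int]:
        return window_to_samples(window_ms, self.sampling_rate, self.t0_ms,
                                 self.n_timepoints)

    def channel(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown channel {label!r}") from None


@dataclass
class VertexActivationMap:
    """Vertex-level activation map: 3-D coordinates (mm) + time courses.

    Amplitudes are in arbitrary source-estimate units; only their relative
    magnitude and time-course shape enter the ROI algorithm.
    """

    vertex_ids: list[str]
    coords_mm: np.ndarray
    activation: np.ndarray
    sampling_rate: float
    t0_ms: float = 0.0

    def __post_init__(self):
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        self.activation = np.asarray(self.activation, dtype=float)
        self.vertex_ids = [str(v) for v in self.vertex_ids]
        n = len(self.vertex_ids)
        if len(set(self.vertex_ids)) != n:
            raise ValidationError("vertex_ids must be unique")
        if self.coords_mm.shape != (n, 3):
            raise ValidationError("coords_mm must be (n_vertices, 3)")
        if self.activation.ndim != 2 or self.activation.shape[0] != n:
            raise ValidationError("activation rows must match vertex count")
        if not (np.all(np.isfinite(self.coords_mm))
                and np.all(np.isfinite(self.activation))):
            raise ValidationError("coordinates and activation must be finite")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_timepoints(self) -> int:
        return self.activation.shape[1]

    def window_indices(self, window_ms: tuple[float, float]) -> tuple[int, int]:
        return window_to_samples(window_ms, self.sampling_rate, self.t0_ms,
                                 self.n_timepoints)


@dataclass
class AnalysisConfig:
    """All analysis constants.

    Defaults reproduce the published protocol: MVAR model order 5, 2000
    bootstrap replicates, alpha 0.05, the 100-500 ms analysis window,
    centroid selection at the 95th percentile with a 5 mm exclusion radius,
    ROI growth at 0.5 SDs and redundancy pruning at 0.9 SDs of the relevant
    similarity distributions, and continuum steps 2-5 entering analysis.
    """

    model_order: int = 5
    n_bootstrap: int = 2000
    alpha: float = 0.05
    window_ms: tuple[float, float] = (100.0, 500.0)
    centroid_percentile: float = 95.0
    exclusion_radius_mm: float = 5.0
    growth_sd_factor: float = 0.5
    redundancy_sd_factor: float = 0.9
    adjacency_radius_mm: float = 2.0
    steps_included: frozenset[int] = frozenset({2, 3, 4, 5})
    random_seed: int = 0

    def __post_init__(self):
        self.steps_included = frozenset(int(s) for s in self.steps_included)
        self.window_ms = (float(self.window_ms[0]), float(self.window_ms[1]))
        if self.model_order < 1:
            raise ValidationError("model_order must be >= 1")
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.window_ms[0] > self.window_ms[1]:
            raise ValidationError("window_ms must be a nonempty interval")
        for name in ("centroid_percentile", "exclusion_radius_mm",
                     "growth_sd_factor", "redundancy_sd_factor",
                     "adjacency_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not self.steps_included <= set(STEPS):
            raise ValidationError("steps_included must be a subset of 1..5")

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from ``random_seed``.

        Uses ``np.random.SeedSequence`` keyed on (random_seed, stage name),
        so stages are decorrelated but fully determined by the one seed.
        """
        key = [self.random_seed] + [ord(c) for c in stage]
        return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def load_config(path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML; unset keys take defaults.

    Unknown keys are logged as warnings and ignored; invalid values raise
    :class:`ValidationError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} must be a YAML mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    kwargs = {}
    for key, val in raw.items():
        if key not in known:
            logger.warning("config %s: ignoring unknown key %r", path, key)
            continue
        if key == "window_ms":
            val = tuple(val)
        elif key == "steps_included":
            val = frozenset(val)
        kwargs[key] = val
    return AnalysisConfig(**kwargs)


# ---------------------------------------------------------------------------
# trial tables

def assign_condition(group: str, context: str) -> str:
    """Map (training group, continuum context) to the Trained/Naive condition.

    The continuum sharing its potential onset cluster with the participant's
    training words is the Trained condition: the /sr/-group is Trained on the
    /_r/ continuum, the /shl/-group on the /_l/ continuum.
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    trained = (group == "sr-familiarization") == (context == "_r")
    return "Trained" if trained else "Naive"


def code_unrepaired(context: str, response: str) -> bool:
    """True when the response keeps the phonotactically illegal onset.

    On the /sr/-/ʃr/ continuum (context ``_r``) an "S" response yields the
    illegal /sr/ onset; on the /ʃl/-/sl/ continuum (context ``_l``) an "SH"
    response yields the illegal /ʃl/ onset.
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    if response not in RESPONSES:
        raise ValidationError(f"unknown response {response!r}")
    return (context == "_r" and response == "S") or \
           (context == "_l" and response == "SH")


@dataclass
class TrialTable:
    """Validated behavioral trial table.

    Wraps a DataFrame with columns subject_id, group, condition, context,
    step, response, unrepaired.  ``condition`` and ``unrepaired`` are
    deterministic recodings of the design columns and are recomputed on
    construction.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.df.copy()
        for col in _REQUIRED_TRIAL_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"trial table missing column {col!r}")
        df["step"] = pd.to_numeric(df["step"], errors="raise").astype(int)
        for col, domain in (("group", GROUPS), ("context", CONTEXTS),
                            ("response", RESPONSES), ("step", STEPS)):
            bad = ~df[col].isin(domain)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {row}: invalid {col} value {df[col].iloc[row]!r}")
        derived_cond = [assign_condition(g, c)
                        for g, c in zip(df["group"], df["context"])]
        derived_unrep = [code_unrepaired(c, r)
                         for c, r in zip(df["context"], df["response"])]
        for col, derived in (("condition", derived_cond),
                             ("unrepaired", derived_unrep)):
            if col in df.columns:
                provided = df[col]
                if col == "unrepaired" and provided.dtype == object:
                    provided = provided.astype(str).str.lower().isin(
                        ("true", "1", "yes"))
                mism = provided.to_numpy() != np.asarray(derived)
                if mism.any():
                    row = int(np.flatnonzero(mism)[0])
                    raise ValidationError(
                        f"row {row}: stored {col} disagrees with its "
                        f"derivation from the design columns")
        df["condition"] = derived_cond
        df["unrepaired"] = derived_unrep
        self.df = df.loc[:, list(TRIAL_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def read_trial_table(path) -> TrialTable:
    """Read a trial table from CSV (header required, comma-separated)."""
    df = pd.read_csv(path)
    return TrialTable(df)


def write_trial_table(table: TrialTable, path) -> None:
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HDF5 round-trip for time series and vertex maps

def _write_common(grp, labels_name, labels, values_name, values,
                  sampling_rate, t0_ms):
    grp.create_dataset(labels_name, data=np.array(labels, dtype=object),
                       dtype=h5py.string_dtype())
    grp.create_dataset(values_name, data=values)
    grp.attrs["sampling_rate"] = float(sampling_rate)
    grp.attrs["t0_ms"] = float(t0_ms)


def _read_attr(f, name):
    if name not in f.attrs:
        raise SchemaError(f"file lacks required attribute {name!r}")
    return float(f.attrs[name])


def _read_dataset(f, name):
    if name not in f:
        raise SchemaError(f"file lacks required dataset {name!r}")
    return f[name][()]


def write_timeseries(ts: MultiTimeSeries, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "MultiTimeSeries"
        _write_common(f, "labels", ts.labels, "values", ts.values,
                      ts.sampling_rate, ts.t0_ms)


def read_timeseries(path) -> MultiTimeSeries:
    with h5py.File(path, "r") as f:
        labels = [x.decode() if isinstance(x, bytes) else str(x)
                  for x in _read_dataset(f, "labels")]
        values = _read_dataset(f, "values")
        sr = _read_attr(f, "sampling_rate")
        t0 = _read_attr(f, "t0_ms")
    return MultiTimeSeries(labels=labels, values=values,
                           sampling_rate=sr, t0_ms=t0)


def write_vertex_map(vmap: VertexActivationMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "VertexActivationMap"
        _write_common(f, "vertex_ids", vmap.vertex_ids,
                      "activation", vmap.activation,
                      vmap.sampling_rate, vmap.t0_ms)
        f.create_dataset("coords_mm", data=vmap.coords_mm)


def read_vertex_map(path) -> VertexActivationMap:
    with h5py.File(path, "r") as f:
        ids = [x.decode() if isinstance(x, bytes) else str(x)
               for x in _read_dataset(f, "vertex_ids")]
        coords = _read_dataset(f, "coords_mm")
        act = _read_dataset(f, "activation")
        sr = _read_attr(f, "sampling_rate")
        t0 = _read_attr(f, "t0_ms")
    return VertexActivationMap(vertex_ids=ids, coords_mm=coords,
                               activation=act, sampling_rate=sr, t0_ms=t0)
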