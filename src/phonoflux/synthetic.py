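"""Synthetic inputs with known ground truth.

Three generators mirror the three kinds of data the pipeline consumes:

* :func:`simulate_mvar` — multichannel time series from a (possibly
  time-varying) stable MVAR process with specified directed couplings,
  standing in for trial-averaged cortical source time courses.
* :func:`simulate_vertex_map` — a planar patch of vertices carrying planted
  activation clusters over background noise, standing in for a group-level
  minimum-norm activation map.
* :func:`simulate_behavior` — two-condition categorization trial tables
  with logistic psychometric response curves and a planted word-learning
  effect on the unrepaired-response rate.

Each generator is deterministic given its seed, and each ground-truth
object can be serialized to a JSON sidecar for downstream recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (MultiTimeSeries, StabilityError, TrialTable,
                      ValidationError, VertexActivationMap, assign_condition,
                      CONTEXTS, GROUPS, STEPS)

BURN_IN = 200


# ---------------------------------------------------------------------------
# MVAR ground truth

@dataclass
class GroundTruthNetwork:
    """Directed MVAR network: coefficient tensor + innovation scales.

    ``coeffs`` has shape (p, n, n) for a static network or (n_timepoints,
    p, n, n) for a time-varying schedule; entry ``[k, i, j]`` (respectively
    ``[t, k, i, j]``) is the influence of channel j at lag k+1 on channel i.
    Stability (companion spectral radius < 1) is required at every timepoint.
    """

    n_channels: int
    order: int
    coeffs: np.ndarray
    innovation_sd: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.innovation_sd = np.broadcast_to(
            np.asarray(self.innovation_sd, dtype=float),
            (self.n_channels,)).copy()
        n, p = self.n_channels, self.order
        if self.coeffs.shape not in ((p, n, n),):
            if self.coeffs.ndim != 4 or self.coeffs.shape[1:] != (p, n, n):
                raise ValidationError(
                    f"coeffs must be (p, n, n) or (T, p, n, n); "
                    f"got {self.coeffs.shape}")
        if np.any(self.innovation_sd < 0):
            raise ValidationError("innovation_sd must be >= 0")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(n)]

    @property
    def time_varying(self) -> bool:
        return self.coeffs.ndim == 4

    def coeffs_at(self, t: int) -> np.ndarray:
        """(p, n, n) coefficient stack at output timepoint ``t``."""
        return self.coeffs[min(t, self.coeffs.shape[0] - 1)] \
            if self.time_varying else self.coeffs

    def spectral_radius(self, t: int = 0) -> float:
        """Spectral radius of the MVAR companion matrix at timepoint t."""
        A = self.coeffs_at(t)
        p, n = self.order, self.n_channels
        comp = np.zeros((n * p, n * p))
        comp[:n] = A.transpose(1, 0, 2).reshape(n, n * p)
        comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def check_stable(self, every: int = 100) -> float:
        """Raise :class:`StabilityError` if any checked timepoint is unstable.

        For time-varying schedules, checks every ``every``-th timepoint plus
        the last.  Returns the largest spectral radius checked.
        """
        if self.time_varying:
            idx = list(range(0, self.coeffs.shape[0], every))
            if idx[-1] != self.coeffs.shape[0] - 1:
                idx.append(self.coeffs.shape[0] - 1)
        else:
            idx = [0]
        worst = max(self.spectral_radius(t) for t in idx)
        if worst >= 1.0:
            raise StabilityError(
                f"MVAR network is unstable: companion spectral radius "
                f"{worst:.4f} >= 1")
        return worst

    def to_json(self) -> str:
        return json.dumps({
            "n_channels": self.n_channels, "order": self.order,
            "coeffs": self.coeffs.tolist(),
            "innovation_sd": self.innovation_sd.tolist(),
            "labels": self.labels,
        })

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthNetwork":
        d = json.loads(text)
        return cls(n_channels=d["n_channels"], order=d["order"],
                   coeffs=np.array(d["coeffs"]),
                   innovation_sd=np.array(d["innovation_sd"]),
                   labels=d["labels"])

    def true_edges(self, tol: float = 0.0) -> set[tuple[int, int]]:
        """Directed (source, target) pairs with any nonzero off-diagonal
        coefficient (absolute value > tol) at any lag or timepoint."""
        A = self.coeffs if self.time_varying else self.coeffs[None]
        mag = np.max(np.abs(A), axis=(0, 1))
        edges = set()
        for i in range(self.n_channels):
            for j in range(self.n_channels):
                if i != j and mag[i, j] > tol:
                    edges.add((j, i))
        return edges


def static_network(coupling: dict[tuple[int, int], float] | None,
                   n_channels: int, order: int = 5,
                   self_coeff: float = 0.3, innovation_sd: float = 1.0,
                   labels: list[str] | None = None) -> GroundTruthNetwork:
    """Convenience constructor: lag-1 self terms plus planted lag-1 edges.

    ``coupling`` maps (source, target) to a lag-1 coefficient.  Self terms
    of ``self_coeff`` at lag 1 give each channel realistic autocorrelation.
    """
    A = np.zeros((order, n_channels, n_channels))
    A[0] += np.eye(n_channels) * self_coeff
    for (src, tgt), c in (coupling or {}).items():
        if src == tgt:
            raise ValidationError("use self_coeff for diagonal terms")
        A[0, tgt, src] = c
    return GroundTruthNetwork(n_channels=n_channels, order=order, coeffs=A,
                              innovation_sd=np.full(n_channels, innovation_sd),
                              labels=labels or [])


def step_schedule(before: GroundTruthNetwork, after: GroundTruthNetwork,
                  n_timepoints: int, change_at: int) -> GroundTruthNetwork:
    """Piecewise-constant schedule switching coefficient sets at ``change_at``."""
    if before.coeffs.shape != after.coeffs.shape or before.time_varying:
        raise ValidationError("before/after must be static nets of equal shape")
    sched = np.empty((n_timepoints,) + before.coeffs.shape)
    sched[:change_at] = before.coeffs
    sched[change_at:] = after.coeffs
    return GroundTruthNetwork(n_channels=before.n_channels, order=before.order,
                              coeffs=sched, innovation_sd=before.innovation_sd,
                              labels=before.labels)


def ramp_schedule(start: GroundTruthNetwork, end: GroundTruthNetwork,
                  n_timepoints: int) -> GroundTruthNetwork:
    """Linear interpolation from ``start`` to ``end`` coefficients."""
    if start.coeffs.shape != end.coeffs.shape or start.time_varying:
        raise ValidationError("start/end must be static nets of equal shape")
    w = np.linspace(0.0, 1.0, n_timepoints)[:, None, None, None]
    sched = (1 - w) * start.coeffs[None] + w * end.coeffs[None]
    return GroundTruthNetwork(n_channels=start.n_channels, order=start.order,
                              coeffs=sched, innovation_sd=start.innovation_sd,
                              labels=start.labels)


def simulate_mvar(net: GroundTruthNetwork, n_timepoints: int, seed: int,
                  sampling_rate: float = 1000.0,
                  t0_ms: float = 0.0) -> MultiTimeSeries:
    """Simulate x(t) = sum_k A_k(t) x(t-k) + eps(t) with Gaussian innovations.

    The first ``order`` samples are drawn from the innovation distribution;
    a burn-in of ``BURN_IN`` samples (run under the t=0 coefficients) is
    generated and discarded so static networks start near stationarity.
    """
    net.check_stable()
    if n_timepoints <= net.order:
        raise ValidationError("n_timepoints must exceed the model order")
    rng = np.random.default_rng(seed)
    n, p = net.n_channels, net.order
    total = BURN_IN + n_timepoints
    eps = rng.standard_normal((total, n)) * net.innovation_sd
    x = np.zeros((total, n))
    x[:p] = eps[:p]
    A0 = net.coeffs_at(0)
    for t in range(p, total):
        A = A0 if t < BURN_IN else net.coeffs_at(t - BURN_IN)
        acc = eps[t].copy()
        for k in range(p):
            acc += A[k] @ x[t - k - 1]
        x[t] = acc
    out = x[BURN_IN:].T
    if np.any(np.abs(out) > 1e6):
        raise StabilityError("simulated series diverged (|x| > 1e6)")
    return MultiTimeSeries(labels=list(net.labels), values=out,
                           sampling_rate=sampling_rate, t0_ms=t0_ms)


# ---------------------------------------------------------------------------
# planted-cluster vertex maps

@dataclass
class PlantedCluster:
    center_mm: tuple[float, float]
    radius_mm: float
    amplitude: float
    n_vertices: int = 100


@dataclass
class RoiLayout:
    """Planted spatial activation clusters on a planar patch.

    Each cluster contributes ``n_vertices`` member vertices within
    ``radius_mm`` of its center; member activation is the cluster's latent
    time course scaled by a Gaussian spatial falloff (sigma = radius), plus
    i.i.d. vertex noise.  Background vertices carry noise only.  The
    signal-to-noise ratio at a cluster center is amplitude / noise_sd.
    """

    clusters: list[PlantedCluster]
    patch_size_mm: float = 100.0
    n_background: int = 1500
    noise_sd: float = 0.1

    def __post_init__(self):
        for c in self.clusters:
            if c.radius_mm <= 0:
                raise ValidationError("cluster radii must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def check_separation(self, min_separation_mm: float) -> None:
        centers = np.array([c.center_mm for c in self.clusters], dtype=float)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = float(np.linalg.norm(centers[i] - centers[j]))
                if d < min_separation_mm:
                    raise ValidationError(
                        f"clusters {i} and {j} are {d:.1f} mm apart; "
                        f"recovery testing requires >= {min_separation_mm} mm")

    def to_json(self, membership: dict[int, list[str]] | None = None) -> str:
        return json.dumps({
            "clusters": [{"center_mm": list(c.center_mm),
                          "radius_mm": c.radius_mm, "amplitude": c.amplitude,
                          "n_vertices": c.n_vertices} for c in self.clusters],
            "patch_size_mm": self.patch_size_mm,
            "n_background": self.n_background, "noise_sd": self.noise_sd,
            "membership": membership,
        })


def default_layout(n_clusters: int = 4, snr: float = 10.0,
                   separation_mm: float = 30.0,
                   radius_mm: float = 6.0) -> RoiLayout:
    """Well-separated clusters at the corners of a square grid."""
    noise_sd = 0.1
    offsets = [(25.0, 25.0), (25.0 + separation_mm, 25.0),
               (25.0, 25.0 + separation_mm),
               (25.0 + separation_mm, 25.0 + separation_mm),
               (25.0 + separation_mm / 2, 25.0 + separation_mm / 2)]
    clusters = [PlantedCluster(center_mm=offsets[i], radius_mm=radius_mm,
                               amplitude=snr * noise_sd)
                for i in range(n_clusters)]
    return RoiLayout(clusters=clusters,
                     patch_size_mm=max(50.0 + separation_mm, 80.0),
                     noise_sd=noise_sd)


def _latent_course(rng: np.random.Generator, n_t: int,
                   sampling_rate: float, smooth_ms: float = 5.0) -> np.ndarray:
    """Smooth random course: Gaussian-smoothed white noise, unit SD.

    Band-limited noise gives each cluster a rich, temporally smooth course
    whose correlation with any other cluster's course is small (the
    effective dimensionality is n_t / smoothing width), so planted
    clusters are genuinely distinct in time-course shape.
    """
    from scipy.ndimage import gaussian_filter1d
    sigma = smooth_ms * sampling_rate / 1000.0
    course = gaussian_filter1d(rng.standard_normal(n_t), sigma,
                               mode="nearest")
    return course / max(np.std(course), 1e-12)


def simulate_vertex_map(layout: RoiLayout, n_timepoints: int, seed: int,
                        sampling_rate: float = 1000.0, t0_ms: float = 0.0,
                        require_separated_by: float | None = None,
                        norm_window_ms: tuple[float, float] | None = (100.0,
                                                                      500.0),
                        ) -> tuple[VertexActivationMap, dict[int, list[str]]]:
    """Generate a vertex map with planted clusters; returns (map, membership).

    ``membership`` maps planted-cluster index to the vertex ids generated
    for it (the ground truth for recovery scoring).  When
    ``require_separated_by`` is set, overlapping clusters raise a
    configuration error before any data are generated.  Latent courses
    are normalized to unit SD within ``norm_window_ms`` (clipped to the
    sampled span) so every planted cluster carries equal in-window signal
    power; pass None to normalize over the full course.
    """
    if require_separated_by is not None:
        layout.check_separation(require_separated_by)
    rng = np.random.default_rng(seed)
    if norm_window_ms is not None:
        dt = 1000.0 / sampling_rate
        lo = min(max(int(round((norm_window_ms[0] - t0_ms) / dt)), 0),
                 n_timepoints - 2)
        hi = min(max(int(round((norm_window_ms[1] - t0_ms) / dt)), lo + 1),
                 n_timepoints - 1)
    else:
        lo, hi = 0, n_timepoints - 1
    ids, coords, courses = [], [], []
    membership: dict[int, list[str]] = {}
    for ci, cl in enumerate(layout.clusters):
        latent = _latent_course(rng, n_timepoints, sampling_rate)
        latent = latent / max(np.std(latent[lo:hi + 1]), 1e-12)
        members = []
        # uniform disk sample of member positions
        r = cl.radius_mm * np.sqrt(rng.uniform(0, 1, cl.n_vertices))
        th = rng.uniform(0, 2 * np.pi, cl.n_vertices)
        xy = np.column_stack([cl.center_mm[0] + r * np.cos(th),
                              cl.center_mm[1] + r * np.sin(th)])
        falloff = np.exp(-0.5 * (r / cl.radius_mm) ** 2)
        for vi in range(cl.n_vertices):
            vid = f"c{ci}_v{vi}"
            ids.append(vid)
            members.append(vid)
            coords.append([xy[vi, 0], xy[vi, 1], 0.0])
            courses.append(cl.amplitude * falloff[vi] * latent)
        membership[ci] = members
    bg_xy = rng.uniform(0, layout.patch_size_mm, (layout.n_background, 2))
    for bi in range(layout.n_background):
        ids.append(f"bg_v{bi}")
        coords.append([bg_xy[bi, 0], bg_xy[bi, 1], 0.0])
        courses.append(np.zeros(n_timepoints))
    activation = np.array(courses)
    activation += rng.standard_normal(activation.shape) * layout.noise_sd
    vmap = VertexActivationMap(vertex_ids=ids, coords_mm=np.array(coords),
                               activation=activation,
                               sampling_rate=sampling_rate, t0_ms=t0_ms)
    return vmap, membership


# ---------------------------------------------------------------------------
# behavioral trials

@dataclass
class BehaviorDesign:
    """Two-group categorization design with a planted learning effect.

    Per subject the design is 2 contexts x 5 steps x ``trials_per_cell``
    trials (27 by default, i.e. 270 trials).  The probability of an
    unrepaired response follows a logistic psychometric function of the
    continuum step, with a context-specific midpoint/slope and an additive
    ``learning_shift`` (log-odds) applied only in the Trained condition.
    """

    n_subjects: int = 12
    trials_per_cell: int = 27
    slope: dict[str, float] = field(
        default_factory=lambda: {"_l": 1.2, "_r": 1.2})
    midpoint: dict[str, float] = field(
        default_factory=lambda: {"_l": 3.5, "_r": 3.5})
    learning_shift: float = 1.0

    def __post_init__(self):
        if self.n_subjects < 1 or self.trials_per_cell < 1:
            raise ValidationError("n_subjects and trials_per_cell must be >= 1")
        for ctx in CONTEXTS:
            if ctx not in self.slope or ctx not in self.midpoint:
                raise ValidationError(f"psychometric parameters missing for "
                                      f"context {ctx!r}")

    @property
    def trials_per_subject(self) -> int:
        return self.trials_per_cell * len(CONTEXTS) * len(STEPS)

    def unrepaired_probability(self, context: str, step: int,
                               condition: str) -> float:
        """Analytic P(unrepaired response) for one stimulus cell."""
        logit = self.slope[context] * (step - self.midpoint[context])
        if condition == "Trained":
            logit += self.learning_shift
        return float(1.0 / (1.0 + np.exp(-logit)))

    def to_json(self) -> str:
        return json.dumps({
            "n_subjects": self.n_subjects,
            "trials_per_cell": self.trials_per_cell,
            "slope": self.slope, "midpoint": self.midpoint,
            "learning_shift": self.learning_shift,
        })


def simulate_behavior(design: BehaviorDesign, seed: int) -> TrialTable:
    """Draw a trial table from the design's psychometric model.

    Subjects alternate between the two familiarization groups; every
    subject contributes the full crossed design (contexts x steps x
    trials_per_cell).  Responses are recoded to S/SH according to which
    response is 'unrepaired' in each context.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(design.n_subjects):
        subject = f"s{si + 1:02d}"
        group = GROUPS[si % 2]
        for context in CONTEXTS:
            condition = assign_condition(group, context)
            for step in STEPS:
                p = design.unrepaired_probability(context, step, condition)
                unrep = rng.uniform(size=design.trials_per_cell) < p
                for u in unrep:
                    if context == "_r":
                        response = "S" if u else "SH"
                    else:
                        response = "SH" if u else "S"
                    rows.append((subject, group, context, step, response))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "context",
                                     "step", "response"])
    return TrialTable(df)
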