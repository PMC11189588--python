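"""Synthetic cohorts of ROI time series with known avalanche propagation.

The generator emulates the kind of data the avalanche pipeline consumes: a
directed probabilistic propagation graph drives a discrete branching
process on the ROIs; the resulting binary raster is rendered into a
continuous time series as signed activation pulses on a Gaussian noise
floor. Two groups share the graph topology up to a controlled fraction of
rewired edges, so the ground-truth group difference lives in the avalanche
*transition structure* rather than in spectra or amplitudes.

The process is parameterized by ``target_rho``, the expected number of
descendant activations produced by a single active ROI: rho < 1 is
subcritical (avalanches die quickly), rho = 1 critical (branching ratio
sigma ~ 1), rho > 1 supercritical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import BinaryRaster, RoiTimeSeries

__all__ = [
    "PropagationModel",
    "CohortSpec",
    "Cohort",
    "make_propagation_model",
    "perturb_model",
    "simulate_raster",
    "raster_to_timeseries",
    "make_cohort",
]

@dataclass
class PropagationModel:
    """Directed per-step activation probabilities plus drive and refractoriness.

    ``graph[i, j]`` is the probability that ROI ``j`` activates at bin
    ``t + 1`` given ROI ``i`` active at bin ``t`` (multiple active parents
    combine by noisy-OR). When the whole network is silent, each ROI seeds
    spontaneously with probability ``drive_rate`` per bin. A ROI that was
    active cannot reactivate for ``refractory_bins`` bins.
    """

    graph: np.ndarray
    drive_rate: float = 0.008
    target_rho: float = 1.0
    refractory_bins: int = 1

    def __post_init__(self) -> None:
        self.graph = np.asarray(self.graph, dtype=float)
        n = self.graph.shape[0]
        if self.graph.shape != (n, n):
            raise ValueError("graph must be square")
        if ((self.graph < 0) | (self.graph > 1)).any():
            raise ValueError("graph entries must lie in [0, 1]")
        if not 0 <= self.drive_rate <= 1:
            raise ValueError("drive_rate must lie in [0, 1]")
        if self.refractory_bins < 0:
            raise ValueError("refractory_bins must be >= 0")

    @property
    def n_rois(self) -> int:
        return self.graph.shape[0]


@dataclass
class CohortSpec:
    """Study-level parameters of a two-group synthetic cohort.

    Defaults follow the resting-state setting the pipeline targets:
    68 cortical ROIs sampled at 250 Hz, 5 minutes of usable signal per
    subject, and two balanced groups around 30 subjects each.
    ``effect_size`` is the fraction of propagation edges rewired between
    the two group graphs; ``burst_amplitude_z`` the z-score level that
    activation pulses reach after z-scoring; ``noise_sd`` the raw-scale
    standard deviation of the background noise.
    """

    n_per_group: int = 31
    n_rois: int = 68
    duration_s: float = 300.0
    fs: float = 250.0
    effect_size: float = 0.5
    burst_amplitude_z: float = 4.0
    noise_sd: float = 1.0
    density: float = 0.5
    target_rho: float = 1.0
    drive_rate: float = 0.008
    refractory_bins: int = 1
    group_names: tuple[str, str] = ("control", "patient")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [0, 1]")
        if not self.burst_amplitude_z > 0:
            raise ValueError("burst_amplitude_z must be positive")
        if self.n_per_group < 1 or self.n_rois < 2:
            raise ValueError("cohort needs >= 1 subject per group and >= 2 ROIs")


def make_propagation_model(
    n_rois: int,
    density: float,
    target_rho: float,
    seed: int | np.random.SeedSequence,
    *,
    drive_rate: float = 0.008,
    refractory_bins: int = 1,
) -> PropagationModel:
    """Random directed propagation graph with exact per-row branching.

    Off-diagonal edges are present independently with probability
    ``density`` (at least one per row), weights drawn uniformly and then
    rescaled so every row sums to ``target_rho`` — a single active ROI
    therefore produces ``target_rho`` descendants in expectation.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if not target_rho > 0:
        raise ValueError("target_rho must be positive")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_rois, n_rois)) < density
    np.fill_diagonal(mask, False)
    for i in range(n_rois):
        if not mask[i].any():
            j = int(rng.integers(n_rois - 1))
            mask[i, j + (j >= i)] = True
    weights = np.where(mask, rng.uniform(0.5, 1.5, size=(n_rois, n_rois)), 0.0)
    graph = weights * (target_rho / weights.sum(axis=1, keepdims=True))
    if (graph > 1).any():
        raise ValueError(
            "target_rho too large for this density: an edge probability exceeds 1"
        )
    return PropagationModel(
        graph=graph,
        drive_rate=drive_rate,
        target_rho=target_rho,
        refractory_bins=refractory_bins,
    )


def perturb_model(
    model: PropagationModel,
    effect_size: float,
    seed: int | np.random.SeedSequence,
) -> PropagationModel:
    """Rewire a fraction ``effect_size`` of edges to new random targets.

    Each selected edge (i, j) moves its weight to a uniformly chosen
    currently-empty target (i, j'); rows are rescaled back to the original
    row sums, so the branching regime is preserved while the propagation
    topology changes.
    """
    if not 0 <= effect_size <= 1:
        raise ValueError("effect_size must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    graph = model.graph.copy()
    n = graph.shape[0]
    row_sums = graph.sum(axis=1)
    edges = np.argwhere(graph > 0)
    k = int(round(effect_size * len(edges)))
    if k:
        chosen = edges[rng.choice(len(edges), size=k, replace=False)]
        for i, j in chosen:
            empty = np.flatnonzero((graph[i] == 0) & (np.arange(n) != i))
            if empty.size == 0:
                continue
            j_new = int(rng.choice(empty))
            graph[i, j_new] = graph[i, j]
            graph[i, j] = 0.0
        nonzero = graph.sum(axis=1) > 0
        graph[nonzero] *= (row_sums[nonzero] / graph.sum(axis=1)[nonzero])[:, None]
    return replace(model, graph=graph)


def simulate_raster(
    model: PropagationModel,
    n_bins: int,
    seed: int | np.random.SeedSequence,
    *,
    fs: float = 250.0,
) -> BinaryRaster:
    """Run the discrete branching process and return the binary raster.

    At each bin, active ROIs independently try to activate their graph
    targets (noisy-OR over parents); if the network is silent, every ROI
    seeds with ``drive_rate``. Refractory ROIs cannot reactivate.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n_rois
    bits = np.zeros((n, n_bins), dtype=np.uint8)
    log_miss = np.log1p(-np.minimum(model.graph, 1 - 1e-12))
    active = np.zeros(n, dtype=bool)
    cool = np.zeros(n, dtype=np.int32)
    drive = np.full(n, model.drive_rate)
    for t in range(n_bins):
        if active.any():
            idx = np.flatnonzero(active)
            p = -np.expm1(log_miss[idx].sum(axis=0))
        else:
            p = drive
        new = rng.random(n) < p
        if model.refractory_bins:
            new &= cool == 0
            cool -= cool > 0
            cool[new] = model.refractory_bins
        bits[:, t] = new
        active = new
    return BinaryRaster(bits=bits, fs=fs, bin_size=1, segment_bounds=[(0, n_bins)])


def raster_to_timeseries(
    raster: BinaryRaster,
    *,
    burst_amplitude_z: float = 4.0,
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    roi_labels: list[str] | None = None,
    subject_id: str = "",
    group: str | None = None,
) -> RoiTimeSeries:
    """Render a binary raster into a continuous ROI time series.

    Active samples take the value ``±A_r`` (random sign per activation),
    silent samples are Gaussian noise of standard deviation ``noise_sd``.
    The per-ROI amplitude ``A_r`` is calibrated from the ROI's active
    fraction so that, after the post-hoc z-scoring the analysis applies,
    pulse samples land at ``burst_amplitude_z`` z-units. With
    ``noise_sd = 0`` pulses have unit amplitude and any threshold below the
    pulse z-height recovers the raster exactly.

    Raises
    ------
    ValueError
        If a ROI is active so often that ``burst_amplitude_z`` is not
        attainable after z-scoring (requires ``z^2 * f < 1`` for active
        fraction ``f``).
    """
    if not burst_amplitude_z > 0:
        raise ValueError("burst_amplitude_z must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n, m = raster.bits.shape
    mask = raster.bits.astype(bool)
    f = mask.mean(axis=1)
    z = burst_amplitude_z
    infeasible = z * z * f >= 1
    if noise_sd > 0 and infeasible.any():
        r = int(np.flatnonzero(infeasible)[0])
        raise ValueError(
            f"ROI {r} is active {f[r]:.1%} of the time; burst_amplitude_z="
            f"{z} is unreachable after z-scoring (need z^2 * f < 1). "
            "Lower burst_amplitude_z or the drive."
        )
    if noise_sd > 0:
        # Solve A / sigma_total = z with sigma_total^2 = (1 - f) n^2 + f A^2.
        amp = z * noise_sd * np.sqrt(np.maximum(1 - f, 1e-12) / (1 - z * z * f))
    else:
        amp = np.ones(n)
    if noise_sd > 0:
        data = rng.normal(0.0, noise_sd, size=(n, m))
    else:
        data = np.zeros((n, m))
    signs = rng.integers(0, 2, size=(n, m)) * 2 - 1
    data = np.where(mask, signs * amp[:, None], data)
    if roi_labels is None:
        roi_labels = [f"roi{r:03d}" for r in range(n)]
    return RoiTimeSeries(
        data=data,
        fs=raster.fs,
        roi_labels=roi_labels,
        segment_bounds=[(a * raster.bin_size, b * raster.bin_size) for a, b in raster.segment_bounds]
        if raster.bin_size == 1
        else None,
        subject_id=subject_id,
        group=group,
    )


@dataclass
class Cohort:
    """Two-group cohort generated lazily, one subject at a time.

    Subjects are independent realizations of their group's propagation
    model; ``subject(k)`` regenerates subject ``k`` deterministically from
    the cohort seed, so the full set never needs to sit in memory at once.
    """

    spec: CohortSpec
    models: dict[str, PropagationModel]
    subject_ids: list[str]
    labels: list[str]

    def __len__(self) -> int:
        return len(self.subject_ids)

    def subject(self, k: int) -> RoiTimeSeries:
        spec = self.spec
        group = self.labels[k]
        ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, k))
        raster_seed, ts_seed = ss.spawn(2)
        n_bins = int(round(spec.duration_s * spec.fs))
        raster = simulate_raster(self.models[group], n_bins, raster_seed, fs=spec.fs)
        return raster_to_timeseries(
            raster,
            burst_amplitude_z=spec.burst_amplitude_z,
            noise_sd=spec.noise_sd,
            seed=ts_seed,
            roi_labels=[f"roi{r:03d}" for r in range(spec.n_rois)],
            subject_id=self.subject_ids[k],
            group=group,
        )

    def subject_raster(self, k: int) -> BinaryRaster:
        """Ground-truth raster of subject ``k`` (before rendering to a series)."""
        spec = self.spec
        ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, k))
        raster_seed, _ = ss.spawn(2)
        n_bins = int(round(spec.duration_s * spec.fs))
        return simulate_raster(self.models[self.labels[k]], n_bins, raster_seed, fs=spec.fs)

    def __iter__(self):
        return (self.subject(k) for k in range(len(self)))


def make_cohort(spec: CohortSpec) -> Cohort:
    """Build the two group models and the (lazy) subject roster.

    Group A uses a base random propagation graph; group B a copy with an
    ``effect_size`` fraction of edges rewired. All randomness derives from
    ``spec.seed``.
    """
    base_seed, perturb_seed = np.random.SeedSequence(entropy=spec.seed).spawn(2)
    base = make_propagation_model(
        spec.n_rois,
        spec.density,
        spec.target_rho,
        base_seed,
        drive_rate=spec.drive_rate,
        refractory_bins=spec.refractory_bins,
    )
    other = perturb_model(base, spec.effect_size, perturb_seed)
    g0, g1 = spec.group_names
    models = {g0: base, g1: other}
    subject_ids, labels = [], []
    for g in (g0, g1):
        for k in range(spec.n_per_group):
            subject_ids.append(f"{g}{k:03d}")
            labels.append(g)
    return Cohort(spec=spec, models=models, subject_ids=subject_ids, labels=labels)
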