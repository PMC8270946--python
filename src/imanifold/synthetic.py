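"""Synthetic multi-subject BOLD-like data with planted brain-state structure.

The generator emulates the statistical structure the pipeline is designed
to detect: N regional oscillators in the ultraslow band (0.04-0.07 Hz)
whose pairwise phase-locking pattern switches between a small number of
discrete coupling regimes ("stages") according to a hypnogram-like label
track with geometric (memoryless) dwell times. Dynamics are a
stage-switching Kuramoto model integrated with the Euler method,

    dtheta_i = 2 pi f_i dt + K sum_j A^{s(t)}_ij sin(theta_j - theta_i) dt
               + sigma_phase sqrt(dt) dW,

and the observed signal is cos(theta_i(t)) plus white observation noise.
Stage-specific adjacency templates A^{s} directly control the quantity
the pipeline measures — pairwise phase differences — so the planted
ground truth is exactly a stage-dependent coherence state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ParcellatedTimeseries, StageLabels

#: Frequency band the oscillators live in (Hz).
FREQ_BAND = (0.04, 0.07)

DEFAULT_TR_SECONDS = 2.08


@dataclass
class CouplingTemplate:
    """Stage-specific coupling structure: who phase-locks with whom."""

    stage_id: str
    adjacency: np.ndarray  # (N, N), symmetric, zero diagonal, >= 0
    global_gain: float = 1.0  # K, in rad/s

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(A < 0):
            raise ValueError("adjacency entries must be non-negative")
        if self.global_gain < 0:
            raise ValueError("global_gain must be >= 0")
        self.adjacency = A


@dataclass
class SimulationSpec:
    """Everything needed to simulate one subject, seeded end-to-end."""

    n_regions: int = 20
    tr_seconds: float = DEFAULT_TR_SECONDS
    templates: list[CouplingTemplate] = field(default_factory=list)
    natural_freqs: np.ndarray | None = None  # per-region Hz, drawn in band if None
    dwell_mean_trs: float = 100.0  # ~3.5 min at TR 2.08 s, a realistic NREM bout
    phase_noise_sd: float = 0.05  # rad / sqrt(s)
    obs_noise_sd: float = 0.1  # signal units
    substeps: int = 10  # Euler steps per TR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.dwell_mean_trs < 1:
            raise ValueError("dwell_mean_trs must be >= 1")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.natural_freqs is not None:
            f = np.asarray(self.natural_freqs, dtype=float)
            if f.shape != (self.n_regions,):
                raise ValueError("natural_freqs must have one entry per region")
            if np.any(f < FREQ_BAND[0]) or np.any(f > FREQ_BAND[1]):
                raise ValueError(f"natural_freqs must lie within {FREQ_BAND} Hz")
            self.natural_freqs = f

    @property
    def stage_ids(self) -> list[str]:
        return [t.stage_id for t in self.templates]


def generate_hypnogram(
    n_trs: int,
    stage_ids: list[str],
    dwell_mean_trs: float,
    seed: int,
    max_retries: int = 20,
) -> StageLabels:
    """Label track of contiguous stage runs with geometric dwell times.

    Runs have mean length ``dwell_mean_trs`` and successive stages always
    differ (when more than one stage is requested). The stage sequence
    cycles through seeded random permutations of the stage set — like a
    sleep cycle, every stage is visited once before any repeats — so all
    requested stages appear as soon as the track holds at least
    ``n_stages`` runs. If the track is long enough that every stage is
    expected to appear (``n_trs >= 4 * dwell_mean_trs * n_stages``) but
    some stage is still missing, the track is regenerated
    deterministically from ``seed + 1`` and so on, a bounded number of
    times.
    """
    if n_trs < 1:
        raise ValueError("n_trs must be >= 1")
    if not stage_ids:
        raise ValueError("need at least one stage id")
    if n_trs < len(stage_ids):
        raise ValueError(
            f"cannot cover {len(stage_ids)} stages with only {n_trs} TRs"
        )
    stage_ids = list(stage_ids)
    expect_all = n_trs >= 4 * dwell_mean_trs * len(stage_ids)
    p = 1.0 / dwell_mean_trs
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        labels: list[str] = []
        prev: str | None = None
        while len(labels) < n_trs:
            cycle = [stage_ids[k] for k in rng.permutation(len(stage_ids))]
            if len(cycle) > 1 and cycle[0] == prev:
                # avoid merging runs across cycle boundaries
                cycle.append(cycle.pop(0))
            for stage in cycle:
                run = int(rng.geometric(p))
                labels.extend([stage] * run)
                prev = stage
                if len(labels) >= n_trs:
                    break
        labels = labels[:n_trs]
        if not expect_all or set(labels) == set(stage_ids):
            return StageLabels(labels=np.asarray(labels, dtype=object))
    raise RuntimeError(
        f"failed to cover all stages in {max_retries} seeded attempts"
    )


def stage_coupling_templates(
    n_regions: int,
    stage_ids: list[str],
    n_blocks: int | list[int] | None = None,
    gain: float = 2.0,
    seed: int = 0,
) -> list[CouplingTemplate]:
    """One block-structured coupling template per stage.

    Each stage partitions the regions into blocks by an independent
    seeded permutation; regions couple (uniformly, row-normalised) only
    within their block, so the summed coupling on each region is ~``gain``
    regardless of block size. By default the block count *descends* with
    stage depth — the first stage is split into as many modules as there
    are stages, the last is one globally coupled block — mirroring the
    progressive increase of global BOLD synchrony from wakefulness to
    deep sleep. Pass an int for the same block count in every stage, or
    a list with one count per stage.
    """
    rng = np.random.default_rng(seed)
    n_stages = len(stage_ids)
    if n_blocks is None:
        blocks_per_stage = list(range(n_stages, 0, -1))
    elif isinstance(n_blocks, int):
        blocks_per_stage = [n_blocks] * n_stages
    else:
        if len(n_blocks) != n_stages:
            raise ValueError("need one block count per stage")
        blocks_per_stage = list(n_blocks)
    templates = []
    for stage, nb in zip(stage_ids, blocks_per_stage):
        if not 1 <= nb <= n_regions:
            raise ValueError(f"block count {nb} out of range for {n_regions} regions")
        perm = rng.permutation(n_regions)
        membership = np.empty(n_regions, dtype=int)
        for b, chunk in enumerate(np.array_split(perm, nb)):
            membership[chunk] = b
        A = (membership[:, None] == membership[None, :]).astype(float)
        np.fill_diagonal(A, 0.0)
        # row-normalise so the summed coupling on each region is ~gain
        deg = A.sum(axis=1, keepdims=True)
        deg[deg == 0] = 1.0
        A = A / deg
        A = (A + A.T) / 2.0
        templates.append(
            CouplingTemplate(stage_id=stage, adjacency=A, global_gain=gain)
        )
    return templates


def simulate_bold(
    spec: SimulationSpec,
    labels: StageLabels,
    return_phases: bool = False,
) -> ParcellatedTimeseries | tuple[ParcellatedTimeseries, np.ndarray]:
    """Simulate one subject's parcellated signal under a label track.

    Euler-integrates the stage-switching Kuramoto dynamics at step
    TR / ``substeps`` and observes cos(theta) + noise on the TR grid.
    With ``return_phases=True`` the (N, T) phase array at the TR grid is
    also returned (ground truth for oracle tests).

    Raises
    ------
    ValueError
        If a label in the track has no coupling template.
    """
    T = len(labels)
    template_of = {t.stage_id: t for t in spec.templates}
    for lab in dict.fromkeys(labels.labels):
        if lab not in template_of:
            raise ValueError(f"no coupling template for stage {lab!r}")

    rng = np.random.default_rng(spec.seed)
    N = spec.n_regions
    if spec.natural_freqs is None:
        freqs = rng.uniform(*FREQ_BAND, size=N)
    else:
        freqs = np.asarray(spec.natural_freqs, dtype=float)
    omega = 2.0 * np.pi * freqs  # rad/s
    dt = spec.tr_seconds / spec.substeps
    theta = rng.uniform(0.0, 2.0 * np.pi, size=N)

    KA = {
        sid: t.global_gain * t.adjacency for sid, t in template_of.items()
    }
    phases = np.empty((N, T))
    noise_scale = spec.phase_noise_sd * np.sqrt(dt)
    for t in range(T):
        A = KA[labels.labels[t]]
        for _ in range(spec.substeps):
            # sum_j A_ij sin(theta_j - theta_i)
            coupling = np.einsum(
                "ij,ij->i", A, np.sin(theta[None, :] - theta[:, None])
            )
            theta = theta + (omega + coupling) * dt
            if spec.phase_noise_sd > 0:
                theta = theta + noise_scale * rng.standard_normal(N)
        phases[:, t] = theta

    data = np.cos(phases)
    if spec.obs_noise_sd > 0:
        data = data + spec.obs_noise_sd * rng.standard_normal(data.shape)
    ts = ParcellatedTimeseries(data=data, tr_seconds=spec.tr_seconds)
    if return_phases:
        wrapped = np.angle(np.exp(1j * phases))
        return ts, wrapped
    return ts


def simulate_subject(
    n_trs: int,
    spec: SimulationSpec,
    seed: int | None = None,
    subject_id: str = "subject_0",
) -> tuple[ParcellatedTimeseries, StageLabels]:
    """Hypnogram + BOLD simulation for one subject in one call.

    ``seed`` overrides ``spec.seed`` for both the hypnogram and the
    dynamics so multi-subject cohorts can share one spec.
    """
    if seed is not None:
        spec = SimulationSpec(**{**spec.__dict__, "seed": seed})
    labels = generate_hypnogram(
        n_trs, spec.stage_ids, spec.dwell_mean_trs, seed=spec.seed
    )
    labels.subject_id = subject_id
    ts = simulate_bold(spec, labels)
    return ts, labels


def simulate_cohort(
    n_subjects: int,
    n_trs: int,
    spec: SimulationSpec,
    base_seed: int = 0,
) -> tuple[list[ParcellatedTimeseries], list[StageLabels]]:
    """Simulate a cohort sharing coupling templates, one seed per subject."""
    ts_list, labels_list = [], []
    for s in range(n_subjects):
        ts, labels = simulate_subject(
            n_trs, spec, seed=base_seed + 1000 * s + spec.seed,
            subject_id=f"subject_{s}",
        )
        ts_list.append(ts)
        labels_list.append(labels)
    return ts_list, labels_list
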