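"""Observation processes: search effort, encounters, harvest, telemetry.

Search effort (km of scent-dog search) is allocated across the 100 trapping
cells each occasion by a Dirichlet draw — flat for spatially uncorrelated
sampling, or weighted by 1 + (activity centers in the cell) to induce a
correlation between effort and animal density.  Given effort, three
Bernoulli/multinomial observation processes run off the same distance-decay
kernel with sex-specific scale:

* encounter:  cloglog(p_ijt) = b0 + b_eff*log(effort_jt) - d_ij/(2 sigma^2)
* harvest:    cloglog(h_ijt) = b0_harvest        - d_ij/(2 sigma^2)
* telemetry:  pi_ik ~ exp(-d_ik/(2 sigma^2)), multinomial with R fixes

Distances are in trap-spacing units (5 km).  Truth parameters follow the
mountain-lion system the simulator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import kernel
from .landscape import LandscapeGrid, Population, TrappingGrid, as_rng

__all__ = [
    "DetectionParameters",
    "EffortAllocation",
    "EncounterData",
    "HarvestData",
    "TelemetryData",
    "DatasetSummary",
    "allocate_effort",
    "effort_density_correlation",
    "encounter_probability",
    "simulate_encounters",
    "harvest_probability",
    "simulate_harvest",
    "telemetry_use_probs",
    "simulate_telemetry",
    "summarize_dataset",
]


@dataclass(frozen=True)
class DetectionParameters:
    """Generating parameters of the three observation processes.

    Defaults are the truth values of the emulated mountain-lion system;
    sigma is in 5-km trap-spacing units (log sigma_male = -0.65 is a male
    scale of about 2.6 km).
    """

    beta0_encounter: float = -5.0
    beta_eff: float = 1.0
    log_sigma_male: float = -0.65
    log_sigma_female: float = -0.85
    beta0_harvest: float = -2.25
    distance_unit_km: float = 5.0

    def __post_init__(self):
        if self.distance_unit_km <= 0:
            raise ValueError("distance_unit_km must be positive")

    def log_sigma(self, sex: str) -> float:
        if sex == "M":
            return self.log_sigma_male
        if sex == "F":
            return self.log_sigma_female
        raise ValueError(f"unknown sex code {sex!r}")

    def sigma(self, sex: str) -> float:
        return float(np.exp(self.log_sigma(sex)))


@dataclass(frozen=True)
class EffortAllocation:
    """Km of search per trapping cell and occasion; columns sum to total."""

    effort: np.ndarray  # (n_cells, n_occasions)
    total_per_occasion: float
    mode: str  # 'uncorrelated' | 'correlated'

    @property
    def n_occasions(self) -> int:
        return self.effort.shape[1]

    def per_cell_total(self) -> np.ndarray:
        return self.effort.sum(axis=1)


@dataclass(frozen=True)
class EncounterData:
    """Binary detections per (individual, trap cell, occasion)."""

    detections: np.ndarray  # (n_individuals, n_cells, n_occasions) uint8
    ids: np.ndarray
    sex: np.ndarray

    @property
    def n_occasions(self) -> int:
        return self.detections.shape[2]


@dataclass(frozen=True)
class HarvestData:
    """At most one harvest record per individual."""

    individual: np.ndarray  # (n_records,) population row index
    cell: np.ndarray  # (n_records,) trap-cell index
    occasion: np.ndarray  # (n_records,) 0-based occasion

    @property
    def n_records(self) -> int:
        return self.individual.shape[0]

    def availability(self, n_individuals: int, n_occasions: int) -> np.ndarray:
        """Occasion availability mask: False strictly after harvest."""
        avail = np.ones((n_individuals, n_occasions), dtype=bool)
        for i, t in zip(self.individual, self.occasion):
            avail[i, t + 1 :] = False
        return avail

    @staticmethod
    def empty() -> "HarvestData":
        z = np.empty(0, dtype=int)
        return HarvestData(individual=z, cell=z.copy(), occasion=z.copy())


@dataclass(frozen=True)
class TelemetryData:
    """Per-collar multinomial use counts over the landscape cells."""

    ids: np.ndarray  # (n_collars,) population row index
    sex: np.ndarray  # (n_collars,)
    counts: np.ndarray  # (n_collars, n_landscape_cells)
    n_fixes: int  # R

    @property
    def n_collars(self) -> int:
        return self.ids.shape[0]

    def subset(self, n_per_sex: int) -> "TelemetryData":
        """First n collars of each sex (collars were drawn at random)."""
        keep = []
        for s in ("M", "F"):
            rows = np.flatnonzero(self.sex == s)[:n_per_sex]
            if rows.shape[0] < n_per_sex:
                raise ValueError(f"not enough {s} collars to subset")
            keep.append(rows)
        rows = np.concatenate(keep)
        return TelemetryData(
            ids=self.ids[rows],
            sex=self.sex[rows],
            counts=self.counts[rows],
            n_fixes=self.n_fixes,
        )


@dataclass(frozen=True)
class DatasetSummary:
    """Table-2-style dataset summary."""

    n: int  # unique individuals detected
    recap: float  # mean detections per detected individual
    spatial_recap: float  # mean distinct trap cells per detected individual


def allocate_effort(
    total_per_occasion: float,
    n_occasions: int = 4,
    mode: str = "uncorrelated",
    trap_center_counts: Optional[np.ndarray] = None,
    n_cells: int = 100,
    seed=None,
) -> EffortAllocation:
    """Dirichlet allocation of total effort across trapping cells.

    One independent Dirichlet draw per occasion.  Uncorrelated mode uses a
    flat Dirichlet(1, ..., 1); correlated mode uses concentration 1 + c_j
    where c_j is the number of activity centers in trapping cell j.
    """
    if total_per_occasion <= 0:
        raise ValueError("total_per_occasion must be positive")
    if mode == "uncorrelated":
        alpha = np.ones(n_cells)
    elif mode == "correlated":
        if trap_center_counts is None:
            raise ValueError("correlated mode requires trap_center_counts")
        counts = np.asarray(trap_center_counts, dtype=float)
        alpha = 1.0 + counts
        n_cells = counts.shape[0]
    else:
        raise ValueError(f"unknown effort mode {mode!r}")
    rng = as_rng(seed)
    effort = np.empty((n_cells, n_occasions))
    for t in range(n_occasions):
        effort[:, t] = total_per_occasion * rng.dirichlet(alpha)
    return EffortAllocation(
        effort=effort, total_per_occasion=float(total_per_occasion), mode=mode
    )


def effort_density_correlation(
    effort: EffortAllocation, trap_center_counts: np.ndarray
) -> float:
    """Pearson correlation of per-cell total effort vs center counts.

    Effort is pooled over occasions (one value per dataset).  Returns NaN
    when either vector is constant (correlation undefined).
    """
    pooled = effort.per_cell_total()
    counts = np.asarray(trap_center_counts, dtype=float)
    if pooled.shape != counts.shape:
        raise ValueError(
            f"length mismatch: {pooled.shape[0]} effort cells vs "
            f"{counts.shape[0]} count cells"
        )
    if pooled.std() == 0 or counts.std() == 0:
        return float("nan")
    return float(np.corrcoef(pooled, counts)[0, 1])


def encounter_probability(
    params: DetectionParameters, sex: str, effort_km, distance_units
):
    """Per-occasion encounter probability on the cloglog scale.

    p = 1 - exp(-exp(b0 + b_eff*log(effort) - d/(2 sigma^2))); zero effort
    means zero encounter probability (no search, no encounter).
    """
    eff = np.asarray(effort_km, dtype=float)
    if np.any(eff < 0):
        raise ValueError("effort must be non-negative")
    decay = kernel.distance_decay_exponent(distance_units, params.log_sigma(sex))
    eff, decay = np.broadcast_arrays(eff, decay)
    p = np.zeros(eff.shape)
    pos = eff > 0
    eta = (
        params.beta0_encounter
        + params.beta_eff * np.log(eff[pos])
        - decay[pos]
    )
    p[pos] = -np.expm1(-np.exp(eta))
    if p.ndim == 0 or (np.isscalar(effort_km) and np.isscalar(distance_units)):
        return float(p.reshape(-1)[0])
    return p


def harvest_probability(params: DetectionParameters, sex: str, distance_units):
    """h = 1 - exp(-exp(b0_harvest - d/(2 sigma^2)))."""
    decay = kernel.distance_decay_exponent(distance_units, params.log_sigma(sex))
    h = -np.expm1(-np.exp(params.beta0_harvest - decay))
    return float(h) if np.ndim(h) == 0 else h


def _distance_units(
    pop: Population, centers: np.ndarray, unit_km: float
) -> np.ndarray:
    diff = pop.xy[:, None, :] - centers[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)) / unit_km


def _encounter_prob_matrix(
    pop: Population,
    traps: TrappingGrid,
    effort: EffortAllocation,
    params: DetectionParameters,
) -> np.ndarray:
    """p[i, j, t] for every individual, trap cell, occasion."""
    d = _distance_units(pop, traps.centers, params.distance_unit_km)
    n, J = d.shape
    T = effort.n_occasions
    p = np.zeros((n, J, T))
    for sex in ("M", "F"):
        rows = pop.sex == sex
        if not rows.any():
            continue
        p[rows] = encounter_probability(
            params,
            sex,
            effort.effort[None, :, :],
            d[rows][:, :, None],
        )
    return p


def simulate_encounters(
    pop: Population,
    traps: TrappingGrid,
    effort: EffortAllocation,
    params: DetectionParameters,
    harvest: Optional[HarvestData] = None,
    seed=None,
) -> EncounterData:
    """Independent Bernoulli encounters; harvested animals are removed.

    A harvest at occasion t* leaves the animal available through t* (both
    processes can fire the same occasion) and removes it afterwards.
    """
    rng = as_rng(seed)
    p = _encounter_prob_matrix(pop, traps, effort, params)
    det = (rng.random(p.shape) < p).astype(np.uint8)
    if harvest is not None and harvest.n_records:
        avail = harvest.availability(pop.size, p.shape[2])
        det *= avail[:, None, :].astype(np.uint8)
    return EncounterData(detections=det, ids=pop.ids.copy(), sex=pop.sex.copy())


def simulate_harvest(
    pop: Population,
    traps: TrappingGrid,
    params: DetectionParameters,
    n_occasions: int = 4,
    seed=None,
) -> HarvestData:
    """Sequential harvest over occasions with removal.

    Each occasion, every not-yet-harvested individual gets independent
    Bernoulli harvest draws across all trapping cells.  Simultaneous
    successes collapse to a single record in the highest-probability cell
    (lowest index on ties) — an animal is harvested once.
    """
    rng = as_rng(seed)
    d = _distance_units(pop, traps.centers, params.distance_unit_km)
    h = np.zeros_like(d)
    for sex in ("M", "F"):
        rows = pop.sex == sex
        if rows.any():
            h[rows] = harvest_probability(params, sex, d[rows])
    alive = np.ones(pop.size, dtype=bool)
    rec_i, rec_j, rec_t = [], [], []
    for t in range(n_occasions):
        draws = rng.random(h.shape) < h
        for i in np.flatnonzero(alive):
            hits = np.flatnonzero(draws[i])
            if hits.shape[0] == 0:
                continue
            j = hits[np.argmax(h[i, hits])]  # argmax keeps lowest index on ties
            rec_i.append(i)
            rec_j.append(int(j))
            rec_t.append(t)
            alive[i] = False
    return HarvestData(
        individual=np.asarray(rec_i, dtype=int),
        cell=np.asarray(rec_j, dtype=int),
        occasion=np.asarray(rec_t, dtype=int),
    )


def telemetry_use_probs(
    center_cell: int,
    sex: str,
    params: DetectionParameters,
    landscape: LandscapeGrid,
) -> np.ndarray:
    """Normalized space-use probabilities over all landscape cells."""
    diff = landscape.centers - landscape.centers[center_cell]
    d = np.sqrt((diff**2).sum(axis=1)) / params.distance_unit_km
    w = kernel.decay_weight(d, params.log_sigma(sex))
    return w / w.sum()


def simulate_telemetry(
    pop: Population,
    n_male_collars: int,
    n_female_collars: int,
    params: DetectionParameters,
    landscape: LandscapeGrid,
    traps: Optional[TrappingGrid] = None,
    n_fixes: int = 30,
    seed=None,
) -> TelemetryData:
    """Collar individuals and draw multinomial use counts (R fixes each).

    Collared individuals are sampled uniformly without replacement within
    sex; when ``traps`` is given, candidates are restricted to individuals
    whose activity centers lie inside the trapping grid (collars are
    deployed in the study area).
    """
    rng = as_rng(seed)
    if traps is not None:
        rel = pop.xy - traps.offset_km
        inside = np.all((rel >= 0) & (rel < traps.side_km), axis=1)
    else:
        inside = np.ones(pop.size, dtype=bool)
    chosen, sexes = [], []
    for sex, want in (("M", n_male_collars), ("F", n_female_collars)):
        cand = np.flatnonzero(inside & (pop.sex == sex))
        if cand.shape[0] < want:
            raise ValueError(
                f"requested {want} {sex} collars but only {cand.shape[0]} "
                "candidates available"
            )
        pick = rng.choice(cand, size=want, replace=False)
        chosen.append(pick)
        sexes.extend([sex] * want)
    rows = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    counts = np.zeros((rows.shape[0], landscape.n_cells), dtype=int)
    for r, i in enumerate(rows):
        pi = telemetry_use_probs(pop.center_cell[i], pop.sex[i], params, landscape)
        counts[r] = rng.multinomial(n_fixes, pi)
    return TelemetryData(
        ids=rows, sex=np.asarray(sexes), counts=counts, n_fixes=n_fixes
    )


def summarize_dataset(
    enc: EncounterData, harvest: Optional[HarvestData] = None
) -> DatasetSummary:
    """n / recap / spatial recap summary of one simulated dataset.

    Harvest records count as detections (in their cell) when supplied.
    recap and spatial_recap are means over detected individuals and include
    the first capture, so both have a floor of 1.
    """
    det = enc.detections.astype(int)
    per_ind = det.sum(axis=(1, 2))
    cells_used = (det.sum(axis=2) > 0).astype(int)
    if harvest is not None and harvest.n_records:
        per_ind = per_ind.copy()
        cells_used = cells_used.copy()
        for i, j in zip(harvest.individual, harvest.cell):
            per_ind[i] += 1
            cells_used[i, j] = 1
    detected = per_ind > 0
    n = int(detected.sum())
    if n == 0:
        return DatasetSummary(n=0, recap=float("nan"), spatial_recap=float("nan"))
    recap = float(per_ind[detected].mean())
    spatial = float(cells_used[detected].sum(axis=1).mean())
    return DatasetSummary(n=n, recap=recap, spatial_recap=spatial)
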