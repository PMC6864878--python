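"""Synthetic pest-management case generator.

Emulates the simulated study data: past cases and new query cases whose
attributes are drawn uniformly and independently from per-attribute
intervals (the spans observed in the study's printed test cases, plus the
agronomic 180-525 seeds/m² planting-density interval), split between the
two rice pests — the rice planthopper (RP) and the striped stem borer
*Chilo suppressalis* (CS) — on a single crop, rice.

Two query modes are provided.  ``independent`` queries are drawn exactly
like past cases and carry no ground truth.  ``perturbed`` queries start
from a uniformly chosen past case and jitter every numeric attribute by a
uniform offset of ±``perturbation_scale`` of that attribute's interval
width (ordinal stages unchanged); the source case id is recorded as the
query's ground truth, which makes top-1 retrieval accuracy measurable.

Each attribute draws from its own deterministic pseudo-random stream
derived from the master seed, so adding or re-configuring one attribute
leaves the other generated columns unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .case_model import (
    CaseBase,
    CaseRecord,
    GROWTH_STAGES,
    PEST_STAGES,
)

__all__ = ["GenerationConfig", "DEFAULT_INTERVALS", "generate_case_base", "generate_queries"]

#: Default per-attribute uniform generation intervals.
DEFAULT_INTERVALS: dict[str, tuple[float, float]] = {
    "pest_quantity": (309, 458),
    "infected_area": (56, 168),
    "planting_density": (180, 525),
    "temp_min": (15, 22),
    "temp_max": (24, 32),
    "humidity": (0.2573, 0.8706),
    "rainfall": (0.1250, 0.8290),
    "sunlight": (831, 4830),
    "wind_speed": (1, 8),
}

#: Attributes whose generated values are whole numbers (counts, lux, degrees).
_INTEGER_ATTRS = frozenset(
    {"pest_quantity", "infected_area", "planting_density", "temp_min",
     "temp_max", "sunlight", "wind_speed"}
)

# Fixed stream registry: every named stream owns one spawn key, so column
# draws stay stable when unrelated streams are added or re-configured.
_STREAMS = (
    "pest_quantity", "pest_stage", "infected_area", "growth_stage",
    "planting_density", "temp_min", "temp_max", "humidity", "rainfall",
    "sunlight", "wind_speed", "solution", "perturb_source", "perturb_jitter",
)

_CHEMICALS = {
    "RP": ("Buprofezin", "Imidacloprid", "Pymetrozine"),
    "CS": ("VIRTAKO", "Prevathon", "Chlorantraniliprole"),
}


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of one synthetic generation run."""

    n_past: int = 1000
    n_new: int = 300
    pest_split: Mapping[str, float] = field(
        default_factory=lambda: {"RP": 0.5, "CS": 0.5}
    )
    crop_name: str = "Rice"
    seed: int = 42
    intervals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTERVALS)
    )
    perturbation_scale: float = 0.05

    def __post_init__(self):
        if self.n_past < 0 or self.n_new < 0:
            raise ValueError("case counts must be non-negative")
        if not 0.0 <= self.perturbation_scale < 1.0:
            raise ValueError("perturbation_scale must lie in [0, 1)")
        total = sum(self.pest_split.values())
        if not np.isclose(total, 1.0) or any(v < 0 for v in self.pest_split.values()):
            raise ValueError("pest_split fractions must be non-negative and sum to 1")
        for name, (lo, hi) in self.intervals.items():
            if name not in DEFAULT_INTERVALS:
                raise ValueError(f"unknown attribute interval {name!r}")
            if not lo < hi:
                raise ValueError(f"{name}: require low < high, got [{lo}, {hi}]")

    def interval(self, name: str) -> tuple[float, float]:
        return tuple(self.intervals.get(name, DEFAULT_INTERVALS[name]))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _pest_counts(n: int, split: Mapping[str, float]) -> list[tuple[str, int]]:
    """Deterministic per-pest counts; remainders go to the earliest types."""
    items = list(split.items())
    counts = [int(np.floor(n * frac)) for _, frac in items]
    short = n - sum(counts)
    for i in range(short):
        counts[i % len(counts)] += 1
    return [(pest, cnt) for (pest, _), cnt in zip(items, counts)]


def _draw_numeric(rng: np.random.Generator, name: str,
                  interval: tuple[float, float], n: int) -> np.ndarray:
    lo, hi = interval
    if name in _INTEGER_ATTRS:
        return rng.integers(int(lo), int(hi) + 1, size=n).astype(float)
    # clip after rounding so 4-decimal presentation cannot leave the interval
    return np.clip(np.round(rng.uniform(lo, hi, size=n), 4), lo, hi)


def generate_case_base(config: GenerationConfig) -> CaseBase:
    """Draw ``config.n_past`` past cases with ids 1..n, grouped by pest type."""
    rng = _streams(config.seed)
    n = config.n_past
    cols = {
        name: _draw_numeric(rng[name], name, config.interval(name), n)
        for name in DEFAULT_INTERVALS
    }
    # disjoint default ranges already give min < max; sort to be safe
    tmin = np.minimum(cols["temp_min"], cols["temp_max"])
    tmax = np.maximum(cols["temp_min"], cols["temp_max"])
    pest_stage = rng["pest_stage"].choice(PEST_STAGES, size=n)
    growth_stage = rng["growth_stage"].choice(GROWTH_STAGES, size=n)

    pest_types: list[str] = []
    for pest, cnt in _pest_counts(n, config.pest_split):
        pest_types.extend([pest] * cnt)

    chem_idx = rng["solution"].integers(0, 3, size=n)
    dose = rng["solution"].integers(100, 400, size=n)

    cases = []
    for i in range(n):
        pest = pest_types[i]
        chems = _CHEMICALS.get(pest, _CHEMICALS["RP"])
        cases.append(
            CaseRecord(
                case_id=i + 1,
                pest_type=pest,
                crop_name=config.crop_name,
                pest_quantity=cols["pest_quantity"][i],
                pest_stage=str(pest_stage[i]),
                infected_area=cols["infected_area"][i],
                growth_stage=str(growth_stage[i]),
                planting_density=cols["planting_density"][i],
                temperature=(float(tmin[i]), float(tmax[i])),
                humidity=float(cols["humidity"][i]),
                rainfall=float(cols["rainfall"][i]),
                sunlight=cols["sunlight"][i],
                wind_speed=cols["wind_speed"][i],
                solution=f"Apply {chems[chem_idx[i]]} at {dose[i]} mL/ha",
            )
        )
    return CaseBase(cases=cases)


def _perturb(record: CaseRecord, query_id: int, config: GenerationConfig,
             rng: np.random.Generator) -> CaseRecord:
    """Jitter every numeric attribute by ±scale·range, clipped to its interval."""
    s = config.perturbation_scale

    def jitter(name: str, value: float) -> float:
        lo, hi = config.interval(name)
        out = value + rng.uniform(-s, s) * (hi - lo)
        out = float(np.clip(out, lo, hi))
        if name in _INTEGER_ATTRS:
            out = float(round(out))
        return out

    tmin = jitter("temp_min", record.temperature[0])
    tmax = jitter("temp_max", record.temperature[1])
    return replace(
        record,
        case_id=query_id,
        pest_quantity=jitter("pest_quantity", record.pest_quantity),
        infected_area=jitter("infected_area", record.infected_area),
        planting_density=jitter("planting_density", record.planting_density),
        temperature=(min(tmin, tmax), max(tmin, tmax)),
        humidity=float(np.clip(round(jitter("humidity", record.humidity), 4),
                               *config.interval("humidity"))),
        rainfall=float(np.clip(round(jitter("rainfall", record.rainfall), 4),
                               *config.interval("rainfall"))),
        sunlight=jitter("sunlight", record.sunlight),
        wind_speed=jitter("wind_speed", record.wind_speed),
        solution=None,
    )


def generate_queries(
    config: GenerationConfig,
    base: CaseBase | None = None,
    mode: str = "independent",
) -> tuple[list[CaseRecord], dict[int, int]]:
    """Draw ``config.n_new`` query cases, split over pest types like the base.

    Returns ``(queries, ground_truth)`` where ``ground_truth`` maps query
    id to the source past-case id (empty in ``independent`` mode).
    """
    if mode == "independent":
        qconfig = replace(config, n_past=config.n_new, seed=_query_seed(config.seed))
        queries = list(generate_case_base(qconfig).cases)
        queries = [replace(q, solution=None) for q in queries]
        return queries, {}
    if mode != "perturbed":
        raise ValueError(f"unknown query mode {mode!r}")
    if base is None or len(base) == 0:
        raise ValueError("perturbed mode requires a non-empty case base")

    rng = _streams(config.seed)
    source_rng, jitter_rng = rng["perturb_source"], rng["perturb_jitter"]
    by_pest: dict[str, list[CaseRecord]] = {}
    for c in base.cases:
        by_pest.setdefault(c.pest_type, []).append(c)

    queries: list[CaseRecord] = []
    ground_truth: dict[int, int] = {}
    qid = 0
    for pest, cnt in _pest_counts(config.n_new, config.pest_split):
        pool = by_pest.get(pest)
        if not pool:
            raise ValueError(f"case base has no cases of pest type {pest!r}")
        picks = source_rng.integers(0, len(pool), size=cnt)
        for k in picks:
            qid += 1
            source = pool[int(k)]
            queries.append(_perturb(source, qid, config, jitter_rng))
            ground_truth[qid] = source.case_id
    return queries, ground_truth


def _query_seed(seed: int) -> int:
    # independent queries use a distinct stream root, kept below 2**31
    return (seed * 2654435761 + 97) % (2**31 - 1)
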