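"""Filter -> compare -> rank case retrieval pipeline.

Retrieval of the most similar past case proceeds in three stages:

1. the *case filter* drops past cases whose identifiers (pest type and
   crop name) do not match the query, so only comparable incidents are
   scored;
2. the *case comparator* standardizes the query and every surviving
   candidate and computes a raw dissimilarity under a pluggable measure
   (triangular similarity by default), converted to a percent with the
   inverse exponential;
3. candidates are ranked by percent, descending, with ties broken by the
   smaller case id, and the top case's stored solution is attached to the
   result for reuse.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .case_model import CaseBase, CaseRecord, CaseSchema, Standardizer, StandardizedCase
from .measures import MEASURES, batch_dissimilarity, to_percent

__all__ = [
    "RetrievalResult",
    "Ranking",
    "NoCandidatesError",
    "filter_cases",
    "compare",
    "retrieve",
    "retrieve_best",
    "export_rankings_csv",
    "export_rankings_json",
]


class NoCandidatesError(ValueError):
    """The case filter left no past case to compare against."""


@dataclass(frozen=True)
class RetrievalResult:
    """One scored candidate: raw dissimilarity and percent similarity."""

    case_id: int
    raw: float
    percent: float
    solution: str | None = None


@dataclass
class Ranking:
    """All candidates for one query, ordered best-first."""

    query_id: int
    measure: str
    results: list[RetrievalResult] = field(default_factory=list)

    @property
    def best(self) -> RetrievalResult:
        return self.results[0]

    def to_rows(self) -> list[dict]:
        return [
            {
                "query_id": self.query_id,
                "rank": i + 1,
                "case_id": r.case_id,
                "raw": r.raw,
                "percent": r.percent,
            }
            for i, r in enumerate(self.results)
        ]


def filter_cases(base: CaseBase, pest_type: str, crop_name: str) -> CaseBase:
    """Past cases matching both identifiers, case-insensitively, in order."""
    pt, cn = pest_type.lower(), crop_name.lower()
    kept = [
        c
        for c in base.cases
        if c.pest_type.lower() == pt and c.crop_name.lower() == cn
    ]
    return CaseBase(cases=kept, schema=base.schema)


def compare(
    query: StandardizedCase,
    candidates: list[StandardizedCase],
    measure: str = "tsm",
    cosine_dialect: str = "shifted",
) -> Ranking:
    """Score every candidate against the query and rank them.

    Results are sorted by percent similarity descending; equal percents
    are broken by the smaller case id, making the ranking deterministic.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if not candidates:
        raise NoCandidatesError("no candidate cases to compare against")
    matrix = np.vstack([c.vector for c in candidates])
    raws = batch_dissimilarity(query.vector, matrix, measure, cosine_dialect)
    order = sorted(
        range(len(candidates)), key=lambda i: (raws[i], candidates[i].case_id)
    )
    results = [
        RetrievalResult(
            case_id=candidates[i].case_id,
            raw=float(raws[i]),
            percent=to_percent(float(raws[i])),
        )
        for i in order
    ]
    return Ranking(query_id=query.case_id, measure=measure, results=results)


def retrieve(
    query: CaseRecord,
    base: CaseBase,
    measure: str = "tsm",
    schema: CaseSchema | None = None,
    scheme: str = "minmax",
    cosine_dialect: str = "shifted",
) -> Ranking:
    """Full pipeline for one query: filter, standardize, compare, rank."""
    schema = schema or base.schema
    filtered = filter_cases(base, query.pest_type, query.crop_name)
    if len(filtered) == 0:
        raise NoCandidatesError(
            f"no past case matches identifiers ({query.pest_type}, {query.crop_name})"
        )
    std = Standardizer(schema, scheme)
    if scheme == "zscore":
        std.fit(base.cases)
    candidates = std.transform_all(filtered.cases)
    return compare(std.transform(query), candidates, measure, cosine_dialect)


def retrieve_best(
    query: CaseRecord,
    base: CaseBase,
    measure: str = "tsm",
    schema: CaseSchema | None = None,
    scheme: str = "minmax",
    cosine_dialect: str = "shifted",
) -> RetrievalResult:
    """The single most similar past case, with its solution attached.

    Solution *adaptation* is out of scope: the stored solution text is
    passed through unchanged for the user to revise.
    """
    ranking = retrieve(query, base, measure, schema, scheme, cosine_dialect)
    best = ranking.best
    try:
        solution = base[best.case_id].solution
    except KeyError:
        solution = None
    return RetrievalResult(
        case_id=best.case_id, raw=best.raw, percent=best.percent, solution=solution
    )


def export_rankings_csv(rankings: list[Ranking], target: str | Path) -> None:
    """Write rankings as flat CSV rows (query_id, rank, case_id, raw, percent)."""
    with Path(target).open("w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=("query_id", "rank", "case_id", "raw", "percent")
        )
        writer.writeheader()
        for ranking in rankings:
            writer.writerows(ranking.to_rows())


def export_rankings_json(rankings: list[Ranking], target: str | Path) -> None:
    doc = [
        {"query_id": r.query_id, "measure": r.measure, "results": r.to_rows()}
        for r in rankings
    ]
    Path(target).write_text(json.dumps(doc, indent=1) + "\n")
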