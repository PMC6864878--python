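"""Retrieval experiment harness.

Runs a batch of query cases through the retrieval pipeline under one or
several similarity measures and aggregates:

* top-1 percent-similarity statistics (mean / max / min) over the queries;
* top-1 retrieval accuracy against ground truth, reported as the average
  precision TP / (TP + FP), where a query counts as a true positive when
  the retrieved case id equals the known source case id.

Ground truth comes from the perturbed-query convention of
:mod:`tricase.synthetic_cases`: each query was jittered from a known past
case, and retrieval is correct when it recovers that source case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .case_model import CaseBase, CaseRecord, CaseSchema, Standardizer
from .retrieval import NoCandidatesError, Ranking, compare

__all__ = [
    "EvaluationSummary",
    "summarize",
    "average_precision",
    "run_queries",
    "compare_measures",
    "grid_to_frame",
    "plot_top1_percents",
]


@dataclass(frozen=True)
class EvaluationSummary:
    """Aggregate top-1 retrieval statistics for one measure."""

    measure: str
    n_queries: int
    mean_percent: float
    max_percent: float
    min_percent: float
    tp: int | None = None
    fp: int | None = None
    average_precision: float | None = None

    def to_dict(self) -> dict:
        d = {
            "measure": self.measure,
            "n_queries": self.n_queries,
            "mean_percent": self.mean_percent,
            "max_percent": self.max_percent,
            "min_percent": self.min_percent,
        }
        if self.average_precision is not None:
            d.update(tp=self.tp, fp=self.fp, average_precision=self.average_precision)
        return d


def summarize(
    rankings: Sequence[Ranking],
    ground_truth: Mapping[int, int] | None = None,
) -> EvaluationSummary:
    """Mean/max/min of the top-1 percents, plus precision if truth is given."""
    if not rankings:
        raise ValueError("no rankings to summarize")
    measures = {r.measure for r in rankings}
    if len(measures) != 1:
        raise ValueError(f"rankings mix measures: {sorted(measures)}")
    tops = [r.best.percent for r in rankings]
    tp = fp = None
    ap = None
    if ground_truth is not None:
        ap = average_precision(rankings, ground_truth)
        tp = sum(
            1 for r in rankings if r.best.case_id == ground_truth[r.query_id]
        )
        fp = len(rankings) - tp
    return EvaluationSummary(
        measure=measures.pop(),
        n_queries=len(rankings),
        mean_percent=math.fsum(tops) / len(tops),
        max_percent=max(tops),
        min_percent=min(tops),
        tp=tp,
        fp=fp,
        average_precision=ap,
    )


def average_precision(
    rankings: Sequence[Ranking], ground_truth: Mapping[int, int]
) -> float:
    """TP / (TP + FP): fraction of queries whose top-1 case is the true source."""
    if not rankings:
        raise ValueError("no rankings to evaluate")
    tp = 0
    for r in rankings:
        if r.query_id not in ground_truth:
            raise KeyError(f"no ground-truth entry for query {r.query_id}")
        if r.best.case_id == ground_truth[r.query_id]:
            tp += 1
    return tp / len(rankings)


def _standardized_pools(
    base: CaseBase, schema: CaseSchema | None, scheme: str
) -> tuple["Standardizer", dict[tuple[str, str], list]]:
    """Standardize the base once, grouped by (pest type, crop name)."""
    std = Standardizer(schema or base.schema, scheme)
    if scheme == "zscore":
        std.fit(base.cases)
    pools: dict[tuple[str, str], list] = {}
    for case in base.cases:
        key = (case.pest_type.lower(), case.crop_name.lower())
        pools.setdefault(key, []).append(std.transform(case))
    return std, pools


def run_queries(
    queries: Sequence[CaseRecord],
    base: CaseBase,
    measure: str = "tsm",
    schema: CaseSchema | None = None,
    scheme: str = "minmax",
    cosine_dialect: str = "shifted",
) -> list[Ranking]:
    """Retrieve against the base for every query, under one measure.

    Equivalent to calling :func:`tricase.retrieval.retrieve` per query,
    but standardizes the case base only once.
    """
    std, pools = _standardized_pools(base, schema, scheme)
    rankings = []
    for q in queries:
        key = (q.pest_type.lower(), q.crop_name.lower())
        candidates = pools.get(key)
        if not candidates:
            raise NoCandidatesError(
                f"no past case matches identifiers ({q.pest_type}, {q.crop_name})"
            )
        rankings.append(compare(std.transform(q), candidates, measure, cosine_dialect))
    return rankings


def compare_measures(
    queries: Sequence[CaseRecord],
    base: CaseBase,
    measures: Sequence[str] = ("tsm", "euclidean", "cosine"),
    schema: CaseSchema | None = None,
    scheme: str = "minmax",
    ground_truth: Mapping[int, int] | None = None,
    cosine_dialect: str = "shifted",
) -> tuple[list[EvaluationSummary], dict[str, list[Ranking]]]:
    """Side-by-side evaluation of several measures on the same queries.

    Returns per-measure summaries and the underlying rankings keyed by
    measure token.  Deterministic: identical inputs give identical output.
    """
    if not measures:
        raise ValueError("need at least one measure")
    std, pools = _standardized_pools(base, schema, scheme)
    std_queries = [
        (std.transform(q), (q.pest_type.lower(), q.crop_name.lower()))
        for q in queries
    ]
    rankings: dict[str, list[Ranking]] = {}
    for m in measures:
        per_measure = []
        for sq, key in std_queries:
            candidates = pools.get(key)
            if not candidates:
                raise NoCandidatesError(
                    f"no past case matches identifiers {key}"
                )
            per_measure.append(compare(sq, candidates, m, cosine_dialect))
        rankings[m] = per_measure
    summaries = [summarize(rankings[m], ground_truth) for m in measures]
    return summaries, rankings


def grid_to_frame(rankings_by_measure: Mapping[str, Sequence[Ranking]]) -> pd.DataFrame:
    """Per-query grid of (retrieved case id, percent) per measure.

    One row per query; columns ``<measure>_case_id`` and
    ``<measure>_percent`` — the layout of a measure-comparison table.
    """
    frames = {}
    for measure, rankings in rankings_by_measure.items():
        frames[f"{measure}_case_id"] = {
            r.query_id: r.best.case_id for r in rankings
        }
        frames[f"{measure}_percent"] = {
            r.query_id: r.best.percent for r in rankings
        }
    df = pd.DataFrame(frames)
    df.index.name = "query_id"
    return df.sort_index()


def plot_top1_percents(
    rankings_by_measure: Mapping[str, Sequence[Ranking]],
    target: str | Path,
) -> None:
    """Scatter of per-query top-1 percents per measure (one colour each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for measure, rankings in rankings_by_measure.items():
        xs = [r.query_id for r in rankings]
        ys = [100 * r.best.percent for r in rankings]
        ax.scatter(xs, ys, s=12, label=measure, alpha=0.7)
    ax.set_xlabel("query case id")
    ax.set_ylabel("top-1 similarity (%)")
    ax.set_ylim(0, 102)
    ax.legend()
    fig.tight_layout()
    fig.savefig(target, dpi=120)
    plt.close(fig)
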