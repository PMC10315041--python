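"""Per-resource reports, recommendations, and batch aggregation.

Batch assessment produces, per resource, a 12-bit metric vector; the
aggregate partitions resources by identical pass/fail vector (the exact
input an UpSet plot consumes), and summarises profile completeness as the
entry-wise fraction of recommended properties present.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from .errors import ContractError
from .harvest import make_resource
from .metrics import METRIC_IDS, EvaluationConfig, MetricResult, evaluate_all
from .profiles import ProfileSpec, ShapeReport, generate_shape, validate
from .recommendations import COOKBOOK_LINKS, recommendation_for  # noqa: F401

__all__ = [
    "BatchSummary", "summarize_combinations", "completeness",
    "recommendation_for", "export", "assess_batch", "membership_matrix_csv",
]


@dataclass
class BatchSummary:
    """Aggregated outcome of a batch assessment."""

    n_resources: int
    n_evaluations: int
    vectors: dict[str, tuple[bool, ...]]
    combination_counts: dict[tuple[str, ...], int]
    completeness: dict[str, float] = field(default_factory=dict)
    mean_completeness: float | None = None


def summarize_combinations(vectors: dict[str, tuple[bool, ...]]
                           ) -> dict[tuple[str, ...], int]:
    """Partition resources by identical metric vector.

    Keys are the tuples of passed metric ids (canonical order); counts sum
    to the number of resources.
    """
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) > 1:
        raise ContractError(f"ragged metric vectors: lengths {sorted(lengths)}")
    counts: dict[tuple[str, ...], int] = {}
    for vector in vectors.values():
        passed = tuple(mid for mid, ok in zip(METRIC_IDS, vector) if ok)
        counts[passed] = counts.get(passed, 0) + 1
    return counts


def completeness(report: ShapeReport, profile: ProfileSpec) -> float:
    """Fraction of the profile's recommended properties present.

    ``(|recommended| - warnings) / |recommended|`` per focus entity,
    averaged over foci (batch resources have exactly one). Profiles with no
    recommended properties are trivially complete (1.0).
    """
    r = len(profile.recommended_properties)
    if r == 0:
        return 1.0
    if not report.focus_results:
        return 0.0
    fractions = [(r - len(f.warnings)) / r for f in report.focus_results]
    return sum(fractions) / len(fractions)


# ---------------------------------------------------------------------------
# Batch assessment
# ---------------------------------------------------------------------------

def assess_batch(partition: dict, config: EvaluationConfig | None = None,
                 profile: ProfileSpec | None = None,
                 registry=None) -> BatchSummary:
    """Evaluate every resource of a partitioned dump.

    *partition* maps resource keys to their sub-graphs (see
    :func:`fairchecker.harvest.load_dump`). When a profile is supplied,
    resources carrying a focus entity of its target class also get a
    completeness fraction.
    """
    config = config or EvaluationConfig()
    vectors: dict[str, tuple[bool, ...]] = {}
    completeness_by_resource: dict[str, float] = {}
    shape = generate_shape(profile) if profile is not None else None
    for key in sorted(partition):
        graph = partition[key]
        resource = make_resource(key, graph, content_kind="rdf_serialization",
                                 syntaxes_found={"native-rdf"})
        results = evaluate_all(resource, config, registry=registry)
        vectors[key] = tuple(r.status == "pass" for r in results)
        if shape is not None:
            report = validate(graph, shape, profile=profile)
            if report.focus_results:
                completeness_by_resource[key] = completeness(report, profile)
    counts = summarize_combinations(vectors)
    mean = (sum(completeness_by_resource.values()) / len(completeness_by_resource)
            if completeness_by_resource else None)
    return BatchSummary(n_resources=len(vectors),
                        n_evaluations=len(METRIC_IDS) * len(vectors),
                        vectors=vectors,
                        combination_counts=counts,
                        completeness=completeness_by_resource,
                        mean_completeness=mean)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _combination_key(passed: tuple[str, ...]) -> str:
    return "+".join(passed) if passed else "(none)"


def _report_rows(resource_url: str, results: list[MetricResult]):
    for result in results:
        yield {"resource": resource_url, "metric_id": result.metric_id,
               "status": result.status,
               "evidence_count": len(result.evidence),
               "recommendation_key": "|".join(result.links)}


def export(report_or_summary, format: str, resource_url: str = "") -> str:
    """Serialize a single-resource report (list of metric results) or a
    batch summary to ``json``, ``csv`` or ``markdown`` with stable field
    order."""
    if format not in ("json", "csv", "markdown"):
        raise ContractError(f"unknown export format {format!r}")

    if isinstance(report_or_summary, BatchSummary):
        return _export_summary(report_or_summary, format)
    results = list(report_or_summary)
    if format == "json":
        payload = {
            "resource": resource_url,
            "metrics": [{"id": r.metric_id, "status": r.status,
                         "evidence_count": len(r.evidence),
                         "evidence": list(r.evidence),
                         "recommendation": r.recommendation,
                         "links": [COOKBOOK_LINKS.get(k, k) for k in r.links]}
                        for r in results],
            "n_pass": sum(1 for r in results if r.status == "pass"),
        }
        return json.dumps(payload, indent=2, sort_keys=False) + "\n"
    if format == "csv":
        buffer = io.StringIO()
        writer = csv.DictWriter(
            buffer, fieldnames=["resource", "metric_id", "status",
                                "evidence_count", "recommendation_key"],
            lineterminator="\n")
        writer.writeheader()
        for row in _report_rows(resource_url, results):
            writer.writerow(row)
        return buffer.getvalue()
    lines = [f"# FAIR assessment of {resource_url}", "",
             "| metric | status | evidence | recommendation |",
             "|--------|--------|----------|----------------|"]
    for r in results:
        lines.append(f"| {r.metric_id} | {r.status} | {len(r.evidence)} "
                     f"| {r.recommendation} |")
    n_pass = sum(1 for r in results if r.status == "pass")
    lines += ["", f"{n_pass} of {len(results)} metrics passed.", ""]
    return "\n".join(lines)


def _export_summary(summary: BatchSummary, format: str) -> str:
    if format == "json":
        payload = {
            "n_resources": summary.n_resources,
            "n_evaluations": summary.n_evaluations,
            "metric_ids": list(METRIC_IDS),
            "vectors": {k: [int(b) for b in v]
                        for k, v in sorted(summary.vectors.items())},
            "combination_counts": {
                _combination_key(k): c
                for k, c in sorted(summary.combination_counts.items())},
            "completeness": dict(sorted(summary.completeness.items())),
            "mean_completeness": summary.mean_completeness,
        }
        return json.dumps(payload, indent=2) + "\n"
    if format == "csv":
        buffer = io.StringIO()
        writer = csv.writer(buffer, lineterminator="\n")
        writer.writerow(["resource", "metric_id", "status"])
        for key in sorted(summary.vectors):
            for mid, ok in zip(METRIC_IDS, summary.vectors[key]):
                writer.writerow([key, mid, "pass" if ok else "fail"])
        return buffer.getvalue()
    lines = ["# Batch FAIR assessment", "",
             f"Resources assessed: {summary.n_resources} "
             f"({summary.n_evaluations} metric evaluations)", "",
             "| passed metrics | resources |", "|---|---|"]
    for key, count in sorted(summary.combination_counts.items(),
                             key=lambda kv: (-kv[1], kv[0])):
        lines.append(f"| {_combination_key(key)} | {count} |")
    if summary.mean_completeness is not None:
        lines += ["", f"Mean recommended-property completeness: "
                      f"{summary.mean_completeness:.1%}"]
    lines.append("")
    return "\n".join(lines)


def membership_matrix_csv(summary: BatchSummary) -> str:
    """UpSet-ready 0/1 matrix: one row per resource, one column per metric."""
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(["resource", *METRIC_IDS])
    for key in sorted(summary.vectors):
        writer.writerow([key, *[int(b) for b in summary.vectors[key]]])
    return buffer.getvalue()
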