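"""Union of prediction sets from multiple tools, evaluated as one.

Duplicate CDSs (identical contig/start/end/strand) are filtered out, but
alternative predictions for the same locus -- different coordinates -- are
all retained, ordered by start position. The same one-to-one comparison
then runs against the pooled set, so detection candidates can only grow
while spurious predictions accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compare import DETECTION_THRESHOLD, ComparisonReport, match_annotations
from .core import Annotation, CdsFeature, FeatureIdentity


@dataclass
class AggregateSet:
    member_labels: list[str]
    union_features: Annotation
    #: feature identity -> labels of every tool that proposed it
    provenance: dict[FeatureIdentity, set[str]] = field(default_factory=dict)


def union_predictions(sets: dict[str, Annotation]) -> AggregateSet:
    """Identity-level union of prediction sets, with provenance."""
    if not sets:
        raise ValueError("at least one prediction set required")
    union = Annotation()
    provenance: dict[FeatureIdentity, set[str]] = {}
    for label in sorted(sets):
        for f in sets[label]:
            if f.identity not in provenance:
                union.add(
                    CdsFeature(
                        f.contig, f.start, f.end, f.strand,
                        source="aggregate", attributes=dict(f.attributes),
                    )
                )
                provenance[f.identity] = set()
            provenance[f.identity].add(label)
    return AggregateSet(member_labels=sorted(sets), union_features=union, provenance=provenance)


def aggregate_compare(
    reference: Annotation,
    sets: dict[str, Annotation],
    threshold: float = DETECTION_THRESHOLD,
) -> tuple[ComparisonReport, AggregateSet]:
    """Compare the union of several tools' predictions against the reference.

    The returned report's ``contributors`` maps each detected gene to the
    sorted labels of the tools whose prediction won the assignment.
    """
    aggregate = union_predictions(sets)
    report = match_annotations(reference, aggregate.union_features, threshold)
    report.contributors = {
        o.gene: tuple(sorted(aggregate.provenance[o.prediction]))
        for o in report.gene_outcomes
        if o.prediction is not None
    }
    return report, aggregate
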