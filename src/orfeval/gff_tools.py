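"""Interval algebra on annotations: intersection and guarded addition.

``gff_intersect`` keeps the features of one annotation that are confirmed
by another (default: in-frame, >= 75% coverage). ``gff_add`` merges new
CDSs into an existing annotation while dropping any newcomer that overlaps
an existing CDS by more than an allowance (default 50 nt).
"""

from __future__ import annotations

from .compare import coverage_fraction, frame_compatible
from .core import Annotation, CdsFeature, overlap_length

OVERLAP_ALLOWANCE_NT = 50


def gff_intersect(
    a: Annotation,
    b: Annotation,
    min_coverage: float = 0.75,
    require_frame: bool = True,
    symmetric: bool = False,
) -> Annotation:
    """Features of ``a`` confirmed by at least one feature of ``b``.

    Confirmation means coverage of the a-feature >= ``min_coverage`` and,
    when ``require_frame``, same strand and reading frame. The a-side
    coordinates are kept (the first annotation is the frame of reference);
    ``symmetric=True`` additionally keeps b-features confirmed by a.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")

    def confirmed(feature: CdsFeature, against: Annotation) -> bool:
        for other in against.on_contig(feature.contig):
            if require_frame and not frame_compatible(feature, other):
                continue
            if coverage_fraction(feature, other) >= min_coverage:
                return True
        return False

    result = Annotation(f for f in a if confirmed(f, b))
    if symmetric:
        for f in b:
            if confirmed(f, a):
                result.add(f)
    return result


def gff_add(
    existing: Annotation,
    new: Annotation,
    overlap_allowance: int = OVERLAP_ALLOWANCE_NT,
    stranded: bool = False,
    footprint: bool = False,
) -> Annotation:
    """Existing annotation plus the new CDSs that do not collide with it.

    A new CDS is dropped when it overlaps an existing CDS by more than
    ``overlap_allowance`` nt (any strand unless ``stranded``). With
    ``footprint=True`` the overlap is measured against the merged coverage
    of all existing features rather than per feature (stricter for newcomers
    straddling several existing CDSs). Additions are flagged with
    ``added=true`` in their attributes; output always contains ``existing``.
    """
    if overlap_allowance < 0:
        raise ValueError("overlap_allowance must be >= 0")
    result = Annotation(existing)

    for n in new:
        if n.identity in result:
            continue
        neighbours = [
            e
            for e in existing.on_contig(n.contig)
            if (not stranded or e.strand == n.strand) and overlap_length(n, e) > 0
        ]
        if footprint:
            covered: set[int] = set()
            for e in neighbours:
                covered.update(range(max(e.start, n.start), min(e.end, n.end) + 1))
            worst = len(covered)
        else:
            worst = max((overlap_length(n, e) for e in neighbours), default=0)
        if worst <= overlap_allowance:
            result.add(
                CdsFeature(
                    n.contig, n.start, n.end, n.strand,
                    source=n.source, attributes={**n.attributes, "added": "true"},
                )
            )
    return result
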