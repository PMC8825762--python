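"""Classification of predicted CDSs against a reference gene set.

A reference gene counts as *detected* when some prediction on the same
strand, in the same reading frame (start coordinates congruent mod 3),
covers at least 75% of its nucleotides. A detected gene is a PERFECT match
when both ends agree exactly, otherwise a PARTIAL match (elongated and/or
truncated at the 5' and/or 3' end). Everything else is MISSED: no credit is
given for genes merely encompassed by a larger prediction in-frame, because
such a prediction's protein product is not the gene's product.

Matching is one-to-one: each prediction may detect at most one gene, and
each gene is matched to the candidate prediction deviating least from its
true locus. Contention between genes for the same prediction is resolved by
minimal deviation with a fully deterministic tie-break chain, and the losing
gene falls back to its next-best candidate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .core import Annotation, CdsFeature, FeatureIdentity, overlap_length

DETECTION_THRESHOLD = 0.75

PERFECT = "PERFECT"
PARTIAL = "PARTIAL"
MISSED = "MISSED"


@dataclass
class MatchOutcome:
    """Per reference gene: its category and the best-matching prediction, if any.

    Signed deviations are oriented 5'->3' in the gene's own reading
    direction; positive means the prediction is elongated beyond the gene
    end, negative means truncated.
    """

    gene: FeatureIdentity
    category: str
    prediction: Optional[FeatureIdentity] = None
    coverage: float = 0.0
    start_diff_nt: Optional[int] = None
    stop_diff_nt: Optional[int] = None

    @property
    def start_diff_codons(self) -> Optional[float]:
        return None if self.start_diff_nt is None else self.start_diff_nt / 3

    @property
    def stop_diff_codons(self) -> Optional[float]:
        return None if self.stop_diff_nt is None else self.stop_diff_nt / 3

    @property
    def detected(self) -> bool:
        return self.category in (PERFECT, PARTIAL)


@dataclass
class PredictionOutcome:
    prediction: FeatureIdentity
    matched_gene: Optional[FeatureIdentity] = None

    @property
    def is_detector(self) -> bool:
        return self.matched_gene is not None


@dataclass
class ComparisonReport:
    """All gene- and prediction-level outcomes of one comparison run."""

    gene_outcomes: list[MatchOutcome]
    prediction_outcomes: list[PredictionOutcome]
    detection_threshold: float = DETECTION_THRESHOLD
    #: for aggregate runs: winning-gene identity -> contributing tool labels
    contributors: dict[FeatureIdentity, tuple[str, ...]] = field(default_factory=dict)

    # -- convenience counts -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_outcomes)

    @property
    def n_predictions(self) -> int:
        return len(self.prediction_outcomes)

    def count(self, category: str) -> int:
        return sum(1 for o in self.gene_outcomes if o.category == category)

    @property
    def n_detected(self) -> int:
        return sum(1 for o in self.gene_outcomes if o.detected)

    @property
    def n_detectors(self) -> int:
        return sum(1 for p in self.prediction_outcomes if p.is_detector)

    # -- serialization ------------------------------------------------------
    TSV_COLUMNS = (
        "contig\tgene_start\tgene_end\tstrand\tcategory\tcoverage\t"
        "start_diff_nt\tstop_diff_nt\tprediction"
    )

    def to_tsv(self, path) -> None:
        def na(x):
            return "NA" if x is None else x

        with open(path, "w") as handle:
            handle.write(self.TSV_COLUMNS + "\n")
            for o in self.gene_outcomes:
                contig, start, end, strand = o.gene
                pred = "NA" if o.prediction is None else "{}:{}-{}({})".format(*o.prediction)
                handle.write(
                    f"{contig}\t{start}\t{end}\t{strand}\t{o.category}\t"
                    f"{o.coverage:.4f}\t{na(o.start_diff_nt)}\t{na(o.stop_diff_nt)}\t{pred}\n"
                )

    def to_dict(self) -> dict:
        return {
            "detection_threshold": self.detection_threshold,
            "genes": [
                {
                    "gene": list(o.gene),
                    "category": o.category,
                    "prediction": None if o.prediction is None else list(o.prediction),
                    "coverage": o.coverage,
                    "start_diff_nt": o.start_diff_nt,
                    "stop_diff_nt": o.stop_diff_nt,
                }
                for o in self.gene_outcomes
            ],
            "predictions": [
                {
                    "prediction": list(p.prediction),
                    "matched_gene": None if p.matched_gene is None else list(p.matched_gene),
                }
                for p in self.prediction_outcomes
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=1)
            handle.write("\n")


# ---------------------------------------------------------------------------
# the match rule


def frame_compatible(gene: CdsFeature, prediction: CdsFeature) -> bool:
    """Same strand and start coordinates congruent mod 3.

    For codon-multiple features this coordinate congruence is equivalent to
    sharing the reading frame anchored at either end.
    """
    if gene.contig != prediction.contig:
        return False
    return gene.strand == prediction.strand and (prediction.start - gene.start) % 3 == 0


def coverage_fraction(gene: CdsFeature, prediction: CdsFeature) -> float:
    """Fraction of the gene's nucleotides inside the prediction (frame-agnostic)."""
    return overlap_length(gene, prediction) / gene.length


def signed_diffs(gene: CdsFeature, prediction: CdsFeature) -> tuple[int, int]:
    """(start_diff_nt, stop_diff_nt) in gene orientation; positive = elongation."""
    if gene.contig != prediction.contig or gene.strand != prediction.strand:
        raise ValueError(f"signed_diffs requires same contig and strand: {gene!r} vs {prediction!r}")
    if gene.strand == "+":
        return gene.start - prediction.start, prediction.end - gene.end
    return prediction.end - gene.end, gene.start - prediction.start


def _deviation_key(gene: CdsFeature, prediction: CdsFeature) -> tuple:
    """Sort key of the spec'd tie-break chain: total deviation, then |start
    deviation|, then leftmost start, then shorter length."""
    sd, ed = signed_diffs(gene, prediction)
    return (abs(sd) + abs(ed), abs(sd), prediction.start, prediction.length)


def candidate_predictions(
    gene: CdsFeature, predictions: Annotation, threshold: float = DETECTION_THRESHOLD
) -> list[CdsFeature]:
    """Eligible detectors of ``gene``, best first (deterministic ordering)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    eligible = [
        p
        for p in predictions.on_contig(gene.contig)
        if frame_compatible(gene, p) and coverage_fraction(gene, p) >= threshold
    ]
    eligible.sort(key=lambda p: _deviation_key(gene, p))
    return eligible


def classify_gene(
    gene: CdsFeature, predictions: Annotation, threshold: float = DETECTION_THRESHOLD
) -> MatchOutcome:
    """Classify one gene against a prediction set, ignoring cross-gene contention."""
    candidates = candidate_predictions(gene, predictions, threshold)
    if not candidates:
        return MatchOutcome(gene=gene.identity, category=MISSED)
    return _outcome_for(gene, candidates[0])


def _outcome_for(gene: CdsFeature, prediction: CdsFeature) -> MatchOutcome:
    sd, ed = signed_diffs(gene, prediction)
    return MatchOutcome(
        gene=gene.identity,
        category=PERFECT if sd == 0 and ed == 0 else PARTIAL,
        prediction=prediction.identity,
        coverage=coverage_fraction(gene, prediction),
        start_diff_nt=sd,
        stop_diff_nt=ed,
    )


def match_annotations(
    reference: Annotation,
    predictions: Annotation,
    threshold: float = DETECTION_THRESHOLD,
    one_to_one: bool = True,
) -> ComparisonReport:
    """Gene-centric one-to-one matching of a prediction set to the reference.

    Genes propose to their candidate predictions in order of increasing
    deviation (deferred acceptance). A contested prediction keeps the gene
    it deviates least from -- ties broken by |start deviation|, then by gene
    coordinate order -- and the displaced gene falls back to its next-best
    candidate, or MISSED when none remain. The result is independent of
    processing order and byte-for-byte reproducible.

    ``one_to_one=False`` gives the permissive alternative for sensitivity
    analysis: every gene takes its best candidate independently, so one
    prediction may detect several genes (its outcome records the gene it
    deviates least from).
    """
    missing = predictions.contig_ids - reference.contig_ids
    if missing:
        warnings.warn(
            f"prediction contigs absent from reference (counted as non-detectors): "
            f"{sorted(missing)}",
            stacklevel=2,
        )

    genes = reference.features  # coordinate order
    candidates = [candidate_predictions(g, predictions, threshold) for g in genes]

    if not one_to_one:
        gene_outcomes = [classify_gene(g, predictions, threshold) for g in genes]
        best_gene: dict[FeatureIdentity, FeatureIdentity] = {}
        for gi, o in enumerate(gene_outcomes):
            if o.prediction is None:
                continue
            prev = best_gene.get(o.prediction)
            if prev is None or _deviation_key(genes[gi], predictions[o.prediction]) < (
                _deviation_key(reference[prev], predictions[o.prediction])
            ):
                best_gene[o.prediction] = o.gene
        prediction_outcomes = [
            PredictionOutcome(prediction=p.identity, matched_gene=best_gene.get(p.identity))
            for p in predictions
        ]
        return ComparisonReport(
            gene_outcomes=gene_outcomes,
            prediction_outcomes=prediction_outcomes,
            detection_threshold=threshold,
        )

    # deferred acceptance: assignment maps prediction identity -> gene index
    assigned: dict[FeatureIdentity, int] = {}
    next_choice = [0] * len(genes)
    queue = list(range(len(genes)))
    while queue:
        gi = queue.pop(0)
        gene = genes[gi]
        placed = False
        while next_choice[gi] < len(candidates[gi]):
            pred = candidates[gi][next_choice[gi]]
            next_choice[gi] += 1
            holder = assigned.get(pred.identity)
            if holder is None:
                assigned[pred.identity] = gi
                placed = True
                break
            # contention: smaller deviation wins; final tie-break is gene order
            chall_key = _deviation_key(gene, pred)[:2] + (gi,)
            holder_key = _deviation_key(genes[holder], pred)[:2] + (holder,)
            if chall_key < holder_key:
                assigned[pred.identity] = gi
                queue.append(holder)
                placed = True
                break
        if not placed:
            pass  # gene stays MISSED

    outcome_by_gene: dict[int, MatchOutcome] = {}
    for pred_id, gi in assigned.items():
        outcome_by_gene[gi] = _outcome_for(genes[gi], predictions[pred_id])
    gene_outcomes = [
        outcome_by_gene.get(gi, MatchOutcome(gene=genes[gi].identity, category=MISSED))
        for gi in range(len(genes))
    ]

    matched = {o.prediction: o.gene for o in gene_outcomes if o.prediction is not None}
    prediction_outcomes = [
        PredictionOutcome(prediction=p.identity, matched_gene=matched.get(p.identity))
        for p in predictions
    ]
    return ComparisonReport(
        gene_outcomes=gene_outcomes,
        prediction_outcomes=prediction_outcomes,
        detection_threshold=threshold,
    )
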