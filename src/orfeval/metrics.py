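"""Primary (M1-M12) and secondary evaluation metrics, and cross-genome ranking.

The twelve primary metrics:

==== =====================================================
M1   Percentage of genes detected
M2   Percentage of predicted CDSs that detected a gene
M3   Percentage difference of number of predicted CDSs
M4   Percentage difference of median predicted CDS length
M5   Percentage of perfect matches (of detected genes)
M6   Median start difference of matched predictions (codons)
M7   Median stop difference of matched predictions (codons)
M8   Percentage difference of matched overlapping predicted CDSs
M9   Percentage difference of matched short predicted CDSs
M10  Precision
M11  Recall
M12  False discovery rate
==== =====================================================

Percentage difference is ``100 * (predicted - reference) / reference``; its
ideal value is 0. Undefined values (zero denominators, empty sets) propagate
as explicit NA markers (``None``), never as zeros, and rank worst.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .compare import MISSED, PARTIAL, PERFECT, ComparisonReport
from .core import (
    Annotation,
    GenomeSequence,
    SHORT_ORF_NT,
    UndefinedValueError,
    gc_content,
    is_short,
    overlapping_features,
    start_codon_tally,
)

METRIC_NAMES = tuple(f"m{i}" for i in range(1, 13))

#: how each metric is ranked across tools
HIGHER_BETTER = ("m1", "m2", "m5", "m10", "m11")
CLOSER_TO_ZERO_BETTER = ("m3", "m4", "m8", "m9")
LOWER_BETTER = ("m6", "m7", "m12")


@dataclass
class MetricsBundle:
    """The twelve primary metrics for one tool on one genome; None marks NA."""

    m1: Optional[float] = None
    m2: Optional[float] = None
    m3: Optional[float] = None
    m4: Optional[float] = None
    m5: Optional[float] = None
    m6: Optional[float] = None
    m7: Optional[float] = None
    m8: Optional[float] = None
    m9: Optional[float] = None
    m10: Optional[float] = None
    m11: Optional[float] = None
    m12: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, ndigits: int = 2) -> dict[str, Optional[float]]:
        return {
            k: None if v is None else round(v, ndigits) for k, v in self.as_dict().items()
        }


@dataclass
class SecondaryMetrics:
    """Descriptive metric groups beyond M1-M12.

    Counts of overlapping and short CDSs on both sides of the comparison,
    per-category gene length and GC medians, start-codon usage of the
    reference genes and of the matched predictions, signed start/stop
    deviation medians, and the number of missed genes wholly encompassed by
    some prediction. GC and codon blocks require the genome and are None
    without it.
    """

    overlapping_pred_count: int = 0
    overlapping_ref_count: int = 0
    matched_overlapping_count: int = 0
    short_pred_count: int = 0
    short_ref_count: int = 0
    matched_short_count: int = 0
    length_by_category: dict[str, float] = field(default_factory=dict)
    gc_by_category: Optional[dict[str, float]] = None
    start_codon_usage_reference: Optional[dict[str, int]] = None
    start_codon_usage_matched: Optional[dict[str, int]] = None
    median_start_diff_signed_codons: Optional[float] = None
    median_stop_diff_signed_codons: Optional[float] = None
    count_genes_encompassed: int = 0

    def as_dict(self) -> dict:
        return {
            "overlapping_pred_count": self.overlapping_pred_count,
            "overlapping_ref_count": self.overlapping_ref_count,
            "matched_overlapping_count": self.matched_overlapping_count,
            "short_pred_count": self.short_pred_count,
            "short_ref_count": self.short_ref_count,
            "matched_short_count": self.matched_short_count,
            "length_by_category": dict(self.length_by_category),
            "gc_by_category": None if self.gc_by_category is None else dict(self.gc_by_category),
            "start_codon_usage_reference": self.start_codon_usage_reference,
            "start_codon_usage_matched": self.start_codon_usage_matched,
            "median_start_diff_signed_codons": self.median_start_diff_signed_codons,
            "median_stop_diff_signed_codons": self.median_stop_diff_signed_codons,
            "count_genes_encompassed": self.count_genes_encompassed,
        }


def percentage_difference(predicted_value: float, reference_value: float) -> float:
    """``100 * (predicted - reference) / reference``; 0 means no deviation."""
    if reference_value == 0:
        raise UndefinedValueError("percentage difference undefined for reference value 0")
    return 100.0 * (predicted_value - reference_value) / reference_value


def _pd_or_none(predicted: float, reference: float) -> Optional[float]:
    try:
        return percentage_difference(predicted, reference)
    except UndefinedValueError:
        return None


def compute_primary(
    report: ComparisonReport,
    reference: Annotation,
    predictions: Annotation,
    short_threshold_nt: int = SHORT_ORF_NT,
    property_side: str = "prediction",
    m5_denominator: str = "detected",
) -> MetricsBundle:
    """Compute M1-M12 from a comparison report.

    ``property_side`` controls whether M8/M9 count the matched *predictions*
    having the overlap/short property (default) or the detected reference
    *genes* having it. ``m5_denominator`` is ``"detected"`` (default) or
    ``"all"`` (perfect matches as a share of all reference genes).
    """
    if property_side not in ("prediction", "gene"):
        raise ValueError("property_side must be 'prediction' or 'gene'")
    if m5_denominator not in ("detected", "all"):
        raise ValueError("m5_denominator must be 'detected' or 'all'")

    n_genes = report.n_genes
    n_pred = report.n_predictions
    detected = report.n_detected
    perfect = report.count(PERFECT)
    detectors = report.n_detectors

    bundle = MetricsBundle()
    bundle.m1 = 100.0 * detected / n_genes if n_genes else None
    bundle.m2 = 100.0 * detectors / n_pred if n_pred else None
    bundle.m3 = _pd_or_none(n_pred, n_genes) if n_genes else None
    gene_lengths = [f.length for f in reference]
    pred_lengths = [f.length for f in predictions]
    if gene_lengths and pred_lengths:
        bundle.m4 = _pd_or_none(statistics.median(pred_lengths), statistics.median(gene_lengths))
    m5_div = detected if m5_denominator == "detected" else n_genes
    bundle.m5 = 100.0 * perfect / m5_div if m5_div else None

    start_devs = [
        abs(o.start_diff_nt) / 3
        for o in report.gene_outcomes
        if o.detected and o.start_diff_nt != 0
    ]
    stop_devs = [
        abs(o.stop_diff_nt) / 3
        for o in report.gene_outcomes
        if o.detected and o.stop_diff_nt != 0
    ]
    bundle.m6 = statistics.median(start_devs) if start_devs else 0.0
    bundle.m7 = statistics.median(stop_devs) if stop_devs else 0.0

    ref_overlapping = overlapping_features(reference)
    ref_short = {f.identity for f in reference if is_short(f, short_threshold_nt)}
    if property_side == "prediction":
        pred_overlapping = overlapping_features(predictions)
        matched_ids = [p.prediction for p in report.prediction_outcomes if p.is_detector]
        matched_overlap = sum(1 for pid in matched_ids if pid in pred_overlapping)
        matched_short = sum(
            1 for pid in matched_ids if is_short(predictions[pid], short_threshold_nt)
        )
    else:
        detected_ids = [o.gene for o in report.gene_outcomes if o.detected]
        matched_overlap = sum(1 for gid in detected_ids if gid in ref_overlapping)
        matched_short = sum(1 for gid in detected_ids if gid in ref_short)
    bundle.m8 = _pd_or_none(matched_overlap, len(ref_overlapping))
    bundle.m9 = _pd_or_none(matched_short, len(ref_short))

    # whole-feature confusion counts: TP = detector predictions,
    # FP = non-detector predictions, FN = missed genes
    tp = detectors
    fp = n_pred - detectors
    fn = report.count(MISSED)
    bundle.m10 = 100.0 * tp / (tp + fp) if (tp + fp) else None
    bundle.m11 = 100.0 * tp / (tp + fn) if (tp + fn) else None
    bundle.m12 = 100.0 * fp / (tp + fp) if (tp + fp) else None
    return bundle


def compute_secondary(
    report: ComparisonReport,
    reference: Annotation,
    predictions: Annotation,
    genome: Optional[GenomeSequence] = None,
    short_threshold_nt: int = SHORT_ORF_NT,
) -> SecondaryMetrics:
    """Descriptive metric groups; GC/codon blocks only when a genome is given.

    ``length_by_category`` and ``gc_by_category`` carry medians for PERFECT,
    PARTIAL and MISSED genes plus the joint "detected" (PERFECT+PARTIAL)
    group, for whichever categories are non-empty.
    """
    sec = SecondaryMetrics()
    pred_overlapping = overlapping_features(predictions) if len(predictions) else set()
    ref_overlapping = overlapping_features(reference) if len(reference) else set()
    sec.overlapping_pred_count = len(pred_overlapping)
    sec.overlapping_ref_count = len(ref_overlapping)
    sec.short_pred_count = sum(1 for f in predictions if is_short(f, short_threshold_nt))
    sec.short_ref_count = sum(1 for f in reference if is_short(f, short_threshold_nt))

    matched_ids = [p.prediction for p in report.prediction_outcomes if p.is_detector]
    sec.matched_overlapping_count = sum(1 for pid in matched_ids if pid in pred_overlapping)
    sec.matched_short_count = sum(
        1 for pid in matched_ids if is_short(predictions[pid], short_threshold_nt)
    )

    groups: dict[str, list] = {PERFECT: [], PARTIAL: [], MISSED: [], "detected": []}
    for o in report.gene_outcomes:
        gene = reference[o.gene]
        groups[o.category].append(gene)
        if o.detected:
            groups["detected"].append(gene)
    sec.length_by_category = {
        cat: float(statistics.median(f.length for f in feats))
        for cat, feats in groups.items()
        if feats
    }
    if genome is not None:
        sec.gc_by_category = {
            cat: float(statistics.median(gc_content(f.sequence(genome)) for f in feats))
            for cat, feats in groups.items()
            if feats
        }
        sec.start_codon_usage_reference = start_codon_tally(reference, genome)
        matched_ann = Annotation(predictions[pid] for pid in matched_ids)
        sec.start_codon_usage_matched = start_codon_tally(matched_ann, genome)

    signed_start = [o.start_diff_nt / 3 for o in report.gene_outcomes if o.detected]
    signed_stop = [o.stop_diff_nt / 3 for o in report.gene_outcomes if o.detected]
    if signed_start:
        sec.median_start_diff_signed_codons = float(statistics.median(signed_start))
        sec.median_stop_diff_signed_codons = float(statistics.median(signed_stop))

    # missed genes lying wholly inside some prediction interval (the
    # "encompassed by a larger predicted CDS" failure mode)
    missed_genes = [reference[o.gene] for o in report.gene_outcomes if o.category == MISSED]
    count = 0
    for gene in missed_genes:
        for p in predictions.on_contig(gene.contig):
            if p.start <= gene.start and p.end >= gene.end:
                count += 1
                break
    sec.count_genes_encompassed = count
    return sec


# ---------------------------------------------------------------------------
# ranking


@dataclass
class RankTable:
    """Per-metric, per-genome ranks and the summed rank ordering the tools."""

    tools: list[str]
    genomes: list[str]
    #: (genome, metric) -> {tool: rank}; ties carry the average rank
    ranks: dict[tuple[str, str], dict[str, float]]
    summed: dict[str, float]

    @property
    def ordering(self) -> list[str]:
        """Tools best-first by summed rank (ties broken alphabetically)."""
        return sorted(self.tools, key=lambda t: (self.summed[t], t))

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("tool\tsummed_rank\n")
            for tool in self.ordering:
                handle.write(f"{tool}\t{self.summed[tool]:g}\n")


def _rank_key(metric: str, value: Optional[float]) -> float:
    if value is None:
        return np.inf  # undefined ranks worst
    if metric in HIGHER_BETTER:
        return -value
    if metric in CLOSER_TO_ZERO_BETTER:
        return abs(value)
    return value


def rank_tools(bundles: dict[str, dict[str, MetricsBundle]]) -> RankTable:
    """Rank tools per metric per genome and total the ranks.

    ``bundles`` maps tool label -> genome label -> MetricsBundle. A tool
    missing a genome gets NA metrics there and ranks worst. Ties receive the
    average of the tied positions.
    """
    if not bundles:
        raise ValueError("no tools to rank")
    tools = sorted(bundles)
    genomes = sorted({g for per_tool in bundles.values() for g in per_tool})
    ranks: dict[tuple[str, str], dict[str, float]] = {}
    summed = {t: 0.0 for t in tools}
    empty = MetricsBundle()
    for genome in genomes:
        for metric in METRIC_NAMES:
            keys = [
                _rank_key(metric, getattr(bundles[t].get(genome, empty), metric))
                for t in tools
            ]
            r = rankdata(keys, method="average")
            ranks[(genome, metric)] = dict(zip(tools, r))
            for t, rv in zip(tools, r):
                summed[t] += float(rv)
    return RankTable(tools=tools, genomes=genomes, ranks=ranks, summed=summed)


def metrics_long_rows(
    tool: str, genome: str, bundle: MetricsBundle
) -> list[tuple[str, str, str, Optional[float]]]:
    """Long-form (tool, genome, metric, value) rows for TSV emission."""
    return [(tool, genome, name, value) for name, value in bundle.as_dict().items()]
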