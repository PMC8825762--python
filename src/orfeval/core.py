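"""Domain types and composition statistics for CDS annotations.

Coordinates are GFF3-style throughout: 1-based, inclusive on both ends.
A feature's identity -- the key used for deduplication and cross-module
bookkeeping -- is the tuple ``(contig, start, end, strand)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

#: Default upper bound (exclusive) below which a CDS counts as a short ORF.
SHORT_ORF_NT = 300

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FeatureIdentity = tuple[str, int, int, str]


class UndefinedValueError(ValueError):
    """A statistic has no defined value for the given input (e.g. empty set)."""


class BoundsError(ValueError):
    """A feature extends past the end of its contig."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CdsFeature:
    """One CDS interval on a contig.

    Parameters
    ----------
    contig : str
        Contig/chromosome identifier.
    start, end : int
        1-based inclusive coordinates, ``1 <= start <= end``.
    strand : str
        ``"+"`` or ``"-"``.
    source : str
        Label of the producing tool, or ``"reference"``.
    attributes : dict
        Free-form key/value annotations (GFF3 column 9 style).
    """

    contig: str
    start: int
    end: int
    strand: str
    source: str = "reference"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValueError(f"coordinates must be integers, got {self.start!r}/{self.end!r}")
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end}: require 1 <= start <= end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def identity(self) -> FeatureIdentity:
        return (self.contig, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sequence(self, genome: "GenomeSequence") -> str:
        """Nucleotide sequence in gene orientation (reverse-complemented on '-')."""
        raw = genome.slice(self.contig, self.start, self.end)
        return reverse_complement(raw) if self.strand == REVERSE else raw

    def __repr__(self) -> str:  # compact, used in error messages
        return f"CdsFeature({self.contig}:{self.start}-{self.end}{self.strand})"


class Annotation:
    """Ordered, deduplicated collection of :class:`CdsFeature`.

    Features are kept sorted by ``(contig, start, end)``; two features with
    the same identity tuple collapse to one (the first inserted wins).
    Used both for reference gene sets and for tool prediction sets.
    """

    def __init__(self, features: Iterable[CdsFeature] = ()) -> None:
        self._by_identity: dict[FeatureIdentity, CdsFeature] = {}
        self._sorted: Optional[list[CdsFeature]] = None
        for f in features:
            self.add(f)

    def add(self, feature: CdsFeature) -> bool:
        """Insert a feature; return False if its identity was already present."""
        key = feature.identity
        if key in self._by_identity:
            return False
        self._by_identity[key] = feature
        self._sorted = None
        return True

    @property
    def features(self) -> list[CdsFeature]:
        if self._sorted is None:
            self._sorted = sorted(
                self._by_identity.values(), key=lambda f: (f.contig, f.start, f.end, f.strand)
            )
        return self._sorted

    @property
    def contig_ids(self) -> set[str]:
        return {f.contig for f in self._by_identity.values()}

    def on_contig(self, contig: str) -> list[CdsFeature]:
        return [f for f in self.features if f.contig == contig]

    def __contains__(self, identity: FeatureIdentity) -> bool:
        return identity in self._by_identity

    def __getitem__(self, identity: FeatureIdentity) -> CdsFeature:
        return self._by_identity[identity]

    def __iter__(self) -> Iterator[CdsFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self._by_identity)

    def __repr__(self) -> str:
        return f"Annotation({len(self)} features on {len(self.contig_ids)} contig(s))"


class GenomeSequence:
    """Mapping of contig id to an uppercase A/C/G/T/N nucleotide string."""

    def __init__(self, sequences: dict[str, str]) -> None:
        self.sequences = dict(sequences)

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def slice(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive substring; raises BoundsError past the contig end."""
        seq = self.sequences[contig]
        if start < 1 or end > len(seq):
            raise BoundsError(f"{contig}:{start}-{end} outside contig of length {len(seq)}")
        return seq[start - 1 : end]

    def check_bounds(self, annotation: Annotation) -> None:
        for f in annotation:
            if f.contig not in self.sequences:
                raise BoundsError(f"{f!r}: contig {f.contig!r} not in genome")
            if f.end > self.length(f.contig):
                raise BoundsError(
                    f"{f!r} extends past end of contig {f.contig!r} "
                    f"(length {self.length(f.contig)})"
                )

    def __repr__(self) -> str:
        return f"GenomeSequence({len(self.sequences)} contig(s), {self.total_length} nt)"


@dataclass
class GenomeStats:
    """Table-style overview of a genome/annotation pair."""

    genome_size: int
    cds_count: int
    gene_density: float  # percent of genome covered by CDS intervals
    gc_content: float  # percent
    start_codon_tally: dict[str, int]
    stop_codon_tally: dict[str, int]
    longest_cds: int
    short_cds_count: int

    def as_dict(self) -> dict:
        return {
            "genome_size": self.genome_size,
            "cds_count": self.cds_count,
            "gene_density": round(self.gene_density, 2),
            "gc_content": round(self.gc_content, 2),
            "start_codon_tally": dict(self.start_codon_tally),
            "stop_codon_tally": dict(self.stop_codon_tally),
            "longest_cds": self.longest_cds,
            "short_cds_count": self.short_cds_count,
        }


# ---------------------------------------------------------------------------
# statistics


def gc_content(sequence: str) -> float:
    """GC percentage of a nucleotide string, N excluded from both sides of the ratio.

    Returns full precision; callers round for presentation.
    """
    counts = Counter(sequence.upper())
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if acgt == 0:
        raise UndefinedValueError("GC content undefined: no unambiguous nucleotides")
    return 100.0 * (counts["G"] + counts["C"]) / acgt


def gene_density(annotation: Annotation, genome: GenomeSequence) -> float:
    """Percent of the genome covered by the union of CDS intervals (strand-ignored)."""
    genome.check_bounds(annotation)
    total = genome.total_length
    if total == 0:
        raise UndefinedValueError("gene density undefined for an empty genome")
    covered = 0
    for contig in sorted(annotation.contig_ids):
        intervals = sorted((f.start, f.end) for f in annotation.on_contig(contig))
        cur_start, cur_end = None, None
        for s, e in intervals:
            if cur_end is None or s > cur_end + 1:
                if cur_end is not None:
                    covered += cur_end - cur_start + 1
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        if cur_end is not None:
            covered += cur_end - cur_start + 1
    return 100.0 * covered / total


def start_codon(feature: CdsFeature, genome: GenomeSequence) -> str:
    """First codon in gene orientation."""
    if feature.length < 3:
        raise ValueError(f"{feature!r}: shorter than one codon")
    return feature.sequence(genome)[:3]


def stop_codon(feature: CdsFeature, genome: GenomeSequence) -> str:
    """Last codon in gene orientation."""
    if feature.length < 3:
        raise ValueError(f"{feature!r}: shorter than one codon")
    return feature.sequence(genome)[-3:]


def start_codon_tally(annotation: Annotation, genome: GenomeSequence) -> dict[str, int]:
    """Counts of first codons over all features; counts sum to ``len(annotation)``."""
    return dict(Counter(start_codon(f, genome) for f in annotation))


def stop_codon_tally(annotation: Annotation, genome: GenomeSequence) -> dict[str, int]:
    return dict(Counter(stop_codon(f, genome) for f in annotation))


def is_short(feature: CdsFeature, threshold_nt: int = SHORT_ORF_NT) -> bool:
    """Short-ORF predicate: strictly below ``threshold_nt`` (default 300 nt)."""
    return feature.length < threshold_nt


def overlap_length(a: CdsFeature, b: CdsFeature) -> int:
    """Shared nucleotides between two features; 0 across contigs; strand ignored."""
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def overlapping_features(annotation: Annotation, min_overlap: int = 1) -> set[FeatureIdentity]:
    """Identities of features sharing >= ``min_overlap`` nt with another feature.

    Any-strand, same-contig. A sweep over the coordinate-sorted features keeps
    this near-linear for the non-pathological annotations seen in practice.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    result: set[FeatureIdentity] = set()
    for contig in annotation.contig_ids:
        feats = annotation.on_contig(contig)
        active: list[CdsFeature] = []
        for f in feats:
            # sorted by start, so a feature ending before f.start cannot
            # overlap f or anything after it
            still_active = [g for g in active if g.end >= f.start]
            for g in still_active:
                if overlap_length(f, g) >= min_overlap:
                    result.add(f.identity)
                    result.add(g.identity)
            active = still_active + [f]
    return result


def genome_stats(
    annotation: Annotation,
    genome: GenomeSequence,
    short_threshold_nt: int = SHORT_ORF_NT,
) -> GenomeStats:
    """Assemble the composition overview for one genome/annotation pair."""
    genome.check_bounds(annotation)
    lengths = [f.length for f in annotation]
    return GenomeStats(
        genome_size=genome.total_length,
        cds_count=len(annotation),
        gene_density=gene_density(annotation, genome) if len(annotation) else 0.0,
        gc_content=gc_content("".join(genome.sequences.values())),
        start_codon_tally=start_codon_tally(annotation, genome),
        stop_codon_tally=stop_codon_tally(annotation, genome),
        longest_cds=max(lengths) if lengths else 0,
        short_cds_count=sum(
            1 for f in annotation if is_short(f, short_threshold_nt)
        ),
    )
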