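"""Synthetic genomes, gold annotations and degraded prediction sets.

The generator emulates a bacterial genome/annotation pair at the
composition ranges seen in real model organisms -- GC content roughly
30-70%, ~80-90% of the genome covered by CDSs with a median length near
900 nt, ~10% short ORFs (< 300 nt), a minority of overlapping gene pairs,
mostly-ATG start codons, and translation table 11 or 4 stop-codon usage --
and then degrades the gold annotation into tool-like prediction sets with a
controlled error structure: missed genes, 5'/3' shifts in whole codons,
reading-frame breaks and spurious calls.

Every generated pair carries a machine-readable :class:`TruthLedger`
recording the intended outcome for each gene, so the comparison pipeline
can be validated against planted truth exactly. Shifts for genes intended
as PARTIAL are capped below the 25% truncation bound, and perturbed or
spurious features are rejection-sampled so that no prediction is an
eligible detector of any gene other than its own; ledger categories
therefore equal comparator categories by construction. All draws come from
a single seeded generator and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .compare import DETECTION_THRESHOLD, coverage_fraction, frame_compatible
from .core import (
    Annotation,
    CdsFeature,
    FeatureIdentity,
    GenomeSequence,
    reverse_complement,
)

STOPS_TABLE_11 = ("TAA", "TAG", "TGA")
STOPS_TABLE_4 = ("TAA", "TAG")  # TGA recoded to tryptophan

_BASES = np.array(["A", "C", "G", "T"])
_ALL_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
# bodies never draw any universal stop; table-4 internal TGAs are injected
# explicitly so their placement is controlled
_BODY_CODONS = tuple(c for c in _ALL_CODONS if c not in ("TAA", "TAG", "TGA"))

DEFAULT_START_PROFILE = {"ATG": 0.80, "GTG": 0.15, "TTG": 0.05}


class CapacityError(ValueError):
    """The requested genes do not fit on the genome at the requested density."""


def generate_genome(length: int, gc: float, seed: int) -> GenomeSequence:
    """Random single-contig genome with the requested GC percentage.

    I.i.d. bases, so the realized GC concentrates within ~1 percentage
    point of the target for lengths >= 100 kb.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000 nt")
    if not 0 < gc < 100:
        raise ValueError("gc must be strictly between 0 and 100")
    rng = np.random.default_rng(seed)
    p_gc = gc / 200.0
    p = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]  # A, C, G, T
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return GenomeSequence({"chr": seq})


def _quota_allocation(profile: dict[str, float], n: int, rng: np.random.Generator) -> list[str]:
    """Exactly-n draws honouring the profile by largest-remainder quotas."""
    keys = sorted(profile)
    total = sum(profile.values())
    shares = [n * profile[k] / total for k in keys]
    counts = [int(s) for s in shares]
    remainders = sorted(
        range(len(keys)), key=lambda i: (shares[i] - counts[i], keys[i]), reverse=True
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    out = [k for k, c in zip(keys, counts) for _ in range(c)]
    rng.shuffle(out)
    return out


def _default_length_sampler(rng: np.random.Generator) -> int:
    """Non-short CDS length: lognormal with median ~900 nt, clipped to [300, 3000]."""
    nt = int(np.clip(rng.lognormal(mean=np.log(900), sigma=0.5), 300, 3000))
    return max(300, (nt // 3) * 3)


def plant_annotation(
    genome: GenomeSequence,
    n_genes: int,
    length_dist: Optional[Callable[[np.random.Generator], int]] = None,
    frac_overlapping: float = 0.2,
    frac_short: float = 0.1,
    start_codon_profile: Optional[dict[str, float]] = None,
    translation_table: int = 11,
    seed: int = 0,
) -> tuple[GenomeSequence, Annotation]:
    """Write ``n_genes`` real CDSs into the genome and return gold coordinates.

    Genes are packed left to right with intergenic gaps of 50-150 nt, giving
    the high CDS density characteristic of bacterial genomes when the genome
    length is sized close to the packing requirement.
    Overlapping pairs (an exact, even count of ``round(frac_overlapping *
    n_genes)`` genes) are laid tail-to-tail on opposite strands with a
    10-50 nt overlap, so the partners can never share a reading frame.
    Exactly ``round(frac_short * n_genes)`` genes are short (102-297 nt);
    the rest draw from ``length_dist``. Start codons follow the profile by
    exact quota. Under translation table 4 roughly half the genes carry an
    internal in-frame TGA (read-through tryptophan), which a universal-code
    caller would interpret as a premature stop.
    """
    if translation_table not in (4, 11):
        raise ValueError("translation_table must be 4 or 11")
    if not 0 <= frac_overlapping <= 1 or not 0 <= frac_short <= 1:
        raise ValueError("fractions must be in [0, 1]")
    if start_codon_profile is None:
        start_codon_profile = DEFAULT_START_PROFILE
    if abs(sum(start_codon_profile.values()) - 1.0) > 1e-9:
        raise ValueError("start_codon_profile probabilities must sum to 1")
    if length_dist is None:
        length_dist = _default_length_sampler

    rng = np.random.default_rng(seed)
    contig = sorted(genome.sequences)[0]
    seq = list(genome.sequences[contig])
    contig_len = len(seq)

    n_short = int(round(frac_short * n_genes))
    n_overlap = int(round(frac_overlapping * n_genes))
    n_overlap -= n_overlap % 2  # overlaps come in pairs

    is_short_plan = [True] * n_short + [False] * (n_genes - n_short)
    rng.shuffle(is_short_plan)
    starts = _quota_allocation(start_codon_profile, n_genes, rng)
    stops_menu = STOPS_TABLE_4 if translation_table == 4 else STOPS_TABLE_11

    def gene_length(short: bool) -> int:
        if short:
            return 3 * int(rng.integers(34, 100))  # 102..297 nt
        return length_dist(rng)

    def cds_sequence(idx: int, nt: int) -> str:
        n_body = nt // 3 - 2
        body = [_BODY_CODONS[i] for i in rng.integers(0, len(_BODY_CODONS), n_body)]
        if translation_table == 4 and n_body >= 1 and (idx % 2 == 0 or rng.random() < 0.5):
            body[int(rng.integers(0, n_body))] = "TGA"
        stop = stops_menu[int(rng.integers(0, len(stops_menu)))]
        return starts[idx] + "".join(body) + stop

    protected: set[int] = set()  # 0-based positions of placed start/stop codons

    def write(start: int, end: int, strand: str, cds: str) -> None:
        genomic = reverse_complement(cds) if strand == "-" else cds
        for offset, base in enumerate(genomic):
            pos = start - 1 + offset
            if pos not in protected:
                seq[pos] = base
        if strand == "+":
            codon_pos = list(range(start - 1, start + 2)) + list(range(end - 3, end))
        else:
            codon_pos = list(range(end - 3, end)) + list(range(start - 1, start + 2))
        protected.update(codon_pos)

    annotation = Annotation()
    cursor = 1
    idx = 0
    pairs_left = n_overlap // 2
    while idx < n_genes:
        cursor += int(rng.integers(50, 151))
        if pairs_left > 0 and idx + 1 < n_genes:
            len_a = gene_length(is_short_plan[idx])
            len_b = gene_length(is_short_plan[idx + 1])
            o = int(rng.integers(10, 51))
            start_a, end_a = cursor, cursor + len_a - 1
            start_b = end_a - o + 1
            end_b = start_b + len_b - 1
            if end_b > contig_len:
                raise CapacityError(
                    f"gene pair {idx} does not fit: needs up to position {end_b} "
                    f"of a {contig_len} nt contig"
                )
            write(start_a, end_a, "+", cds_sequence(idx, len_a))
            write(start_b, end_b, "-", cds_sequence(idx + 1, len_b))
            annotation.add(CdsFeature(contig, start_a, end_a, "+", source="reference"))
            annotation.add(CdsFeature(contig, start_b, end_b, "-", source="reference"))
            cursor = end_b + 1
            idx += 2
            pairs_left -= 1
        else:
            nt = gene_length(is_short_plan[idx])
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = cursor, cursor + nt - 1
            if end > contig_len:
                raise CapacityError(
                    f"gene {idx} does not fit: needs up to position {end} "
                    f"of a {contig_len} nt contig"
                )
            write(start, end, strand, cds_sequence(idx, nt))
            annotation.add(CdsFeature(contig, start, end, strand, source="reference"))
            cursor = end + 1
            idx += 1

    new_genome = GenomeSequence({**genome.sequences, contig: "".join(seq)})
    return new_genome, annotation


# ---------------------------------------------------------------------------
# perturbation


@dataclass
class PerturbationProfile:
    """Error structure of an emulated prediction tool.

    ``start_shift``/``stop_shift`` are distributions over signed codon
    offsets (positive = elongation in gene orientation) with a point mass
    at 0; frame is preserved unless ``p_frameshift`` fires, which shifts a
    start by +1 or +2 nt and breaks the reading frame.
    """

    p_miss: float = 0.05
    p_spurious: float = 0.10  # expected spurious predictions per true gene
    start_shift: dict[int, float] = field(
        default_factory=lambda: {0: 0.70, 2: 0.10, -2: 0.10, 5: 0.05, -5: 0.05}
    )
    stop_shift: dict[int, float] = field(default_factory=lambda: {0: 0.95, -3: 0.05})
    p_frameshift: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_miss <= 1 or not 0 <= self.p_frameshift <= 1:
            raise ValueError("p_miss and p_frameshift must be in [0, 1]")
        if self.p_spurious < 0:
            raise ValueError("p_spurious must be >= 0")
        for dist in (self.start_shift, self.stop_shift):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("shift distributions must sum to 1")


@dataclass
class GeneRecord:
    gene: FeatureIdentity
    category: str  # intended comparator category
    prediction: Optional[FeatureIdentity] = None
    start_shift_nt: Optional[int] = None  # gene orientation, positive = elongation
    stop_shift_nt: Optional[int] = None
    note: str = ""


@dataclass
class TruthLedger:
    """What the generator did to every gene, plus the spurious markers."""

    gene_records: list[GeneRecord] = field(default_factory=list)
    spurious: list[FeatureIdentity] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(
                "kind\tcontig\tstart\tend\tstrand\tcategory\t"
                "start_shift_nt\tstop_shift_nt\tprediction\tnote\n"
            )
            for r in self.gene_records:
                pred = "NA" if r.prediction is None else "{}:{}-{}({})".format(*r.prediction)
                ss = "NA" if r.start_shift_nt is None else r.start_shift_nt
                es = "NA" if r.stop_shift_nt is None else r.stop_shift_nt
                handle.write(
                    f"gene\t{r.gene[0]}\t{r.gene[1]}\t{r.gene[2]}\t{r.gene[3]}\t"
                    f"{r.category}\t{ss}\t{es}\t{pred}\t{r.note}\n"
                )
            for s in self.spurious:
                handle.write(
                    f"spurious\t{s[0]}\t{s[1]}\t{s[2]}\t{s[3]}\tNA\tNA\tNA\tNA\t\n"
                )


def _draw_shift(dist: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    return int(rng.choice(keys, p=[dist[k] / sum(dist.values()) for k in keys]))


def _eligible_for_any(
    candidate: CdsFeature,
    genes: list[CdsFeature],
    threshold: float,
    exclude: Optional[FeatureIdentity] = None,
) -> bool:
    for g in genes:
        if g.identity == exclude:
            continue
        if frame_compatible(g, candidate) and coverage_fraction(g, candidate) >= threshold:
            return True
    return False


def perturb(
    annotation: Annotation,
    profile: PerturbationProfile,
    genome: Optional[GenomeSequence] = None,
    threshold: float = DETECTION_THRESHOLD,
) -> tuple[Annotation, TruthLedger]:
    """Degrade a gold annotation into a tool-like prediction set.

    Each gene is independently omitted (probability ``p_miss``),
    frame-shifted (``p_frameshift``, intended MISSED with a surviving
    non-detector prediction), or copied with codon shifts drawn from the
    profile. Truncating shifts are capped at 24% of the gene length so an
    intended PARTIAL can never fall under the 75% coverage gate; any shifted
    or spurious feature that would be an eligible detector of another gene
    is redrawn (after 50 failures the gene falls back to an exact copy,
    noted in the ledger). Spurious predictions are Poisson in number and
    placed uniformly at frame-free positions.
    """
    rng = np.random.default_rng(profile.seed)
    genes = annotation.features
    contig_len: dict[str, int] = {}
    for contig in annotation.contig_ids:
        if genome is not None and contig in genome.sequences:
            contig_len[contig] = genome.length(contig)
        else:
            contig_len[contig] = max(f.end for f in annotation.on_contig(contig)) + 1000

    predictions = Annotation()
    ledger = TruthLedger()

    for gene in genes:
        if rng.random() < profile.p_miss:
            ledger.gene_records.append(
                GeneRecord(gene=gene.identity, category="MISSED", note="omitted")
            )
            continue

        if rng.random() < profile.p_frameshift:
            placed = False
            for _ in range(50):
                bump = int(rng.integers(1, 3))
                start, end = gene.start + bump, gene.end
                cand = CdsFeature(gene.contig, start, end, gene.strand, source="sim")
                if not _eligible_for_any(cand, genes, threshold):
                    predictions.add(cand)
                    ledger.gene_records.append(
                        GeneRecord(
                            gene=gene.identity, category="MISSED",
                            prediction=cand.identity, note="frameshift",
                        )
                    )
                    placed = True
                    break
            if not placed:  # pragma: no cover - tiny dense-genome corner
                ledger.gene_records.append(
                    GeneRecord(gene=gene.identity, category="MISSED", note="omitted")
                )
            continue

        max_trunc_nt = int(0.24 * gene.length)
        note = ""
        for attempt in range(50):
            s = _draw_shift(profile.start_shift, rng)
            e = _draw_shift(profile.stop_shift, rng)
            if 3 * (max(0, -s) + max(0, -e)) > max_trunc_nt:
                continue
            if gene.strand == "+":
                start, end = gene.start - 3 * s, gene.end + 3 * e
            else:
                start, end = gene.start - 3 * e, gene.end + 3 * s
            if start < 1 or end > contig_len[gene.contig] or start > end:
                continue
            cand = CdsFeature(gene.contig, start, end, gene.strand, source="sim")
            if cand.identity != gene.identity and (
                cand.identity in predictions
                or _eligible_for_any(cand, genes, threshold, exclude=gene.identity)
            ):
                continue
            break
        else:
            s = e = 0
            cand = CdsFeature(gene.contig, gene.start, gene.end, gene.strand, source="sim")
            note = "fallback_zero_shift"
        predictions.add(cand)
        ledger.gene_records.append(
            GeneRecord(
                gene=gene.identity,
                category="PERFECT" if s == 0 and e == 0 else "PARTIAL",
                prediction=cand.identity,
                start_shift_nt=3 * s,
                stop_shift_nt=3 * e,
                note=note,
            )
        )

    # spurious calls, never eligible for any planted gene
    n_spurious = int(rng.poisson(profile.p_spurious * len(genes)))
    contigs = sorted(contig_len)
    weights = np.array([contig_len[c] for c in contigs], dtype=float)
    weights /= weights.sum()
    for _ in range(n_spurious):
        for _ in range(200):
            contig = contigs[int(rng.choice(len(contigs), p=weights))]
            nt = 3 * int(rng.integers(50, 301))  # 150..900 nt
            if nt >= contig_len[contig]:
                continue
            start = int(rng.integers(1, contig_len[contig] - nt + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            cand = CdsFeature(contig, start, start + nt - 1, strand, source="sim")
            if cand.identity in predictions:
                continue
            if _eligible_for_any(cand, genes, threshold):
                continue
            predictions.add(cand)
            ledger.spurious.append(cand.identity)
            break
    return predictions, ledger
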