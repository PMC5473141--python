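"""Per-sample count structures from spliced alignments.

Converts SAM records into the quantities the downstream statistics consume:
per-gene read counts, per-exon/per-intron average depths, per-junction read
counts (every observed alignment gap within a gene, annotated or not), and
reads contiguously spanning exon-intron boundaries.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .annotation import GeneModel, GeneModelSet

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: gaps shorter than this are treated as indels and merged into one block
MIN_INTRON_GAP = 20

#: default half-width of the window a read must cover contiguously to count
#: as spanning an exon-intron boundary
DEFAULT_ANCHOR = 8


@dataclass(frozen=True)
class AlignedRead:
    """One aligned segment, blocks in 1-based inclusive genomic coordinates."""

    query_id: str
    chrom: str
    blocks: tuple[Interval, ...]
    identity: float = 1.0
    is_unique: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        blocks = tuple(self.blocks)
        for (s, e) in blocks:
            if e < s:
                raise ValueError("block end < start")
        for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
            if s1 <= e0:
                raise ValueError("blocks overlap or out of order")
        object.__setattr__(self, "blocks", blocks)

    @property
    def gaps(self) -> tuple[Interval, ...]:
        """Skipped intervals between consecutive blocks (candidate introns)."""
        return tuple(
            (e0 + 1, s1 - 1) for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:])
        )

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def aligned_length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)


@dataclass
class SampleCounts:
    """All per-sample counts the event statistics and DEG analysis consume.

    Depth maps are keyed by (gene_id, transcription-order feature index);
    junction_reads by (gene_id, donor_end, acceptor_start) for every observed
    gap, annotated or not; boundary_reads by (gene_id, intron tx index,
    "5p"/"3p").
    """

    sample_id: str
    gene_reads: dict[str, int] = field(default_factory=dict)
    gene_unique_reads: dict[str, int] = field(default_factory=dict)
    exon_depth: dict[tuple[str, int], float] = field(default_factory=dict)
    intron_depth: dict[tuple[str, int], float] = field(default_factory=dict)
    junction_reads: dict[tuple[str, int, int], int] = field(default_factory=dict)
    boundary_reads: dict[tuple[str, int, str], int] = field(default_factory=dict)
    library_size: int = 0

    def junction(self, gene_id: str, donor_end: int, acceptor_start: int) -> int:
        return self.junction_reads.get((gene_id, donor_end, acceptor_start), 0)

    def boundary(self, gene_id: str, intron_tx: int, side: str) -> int:
        return self.boundary_reads.get((gene_id, intron_tx, side), 0)


def _merge_small_gaps(blocks: list[Interval], min_gap: int) -> tuple[Interval, ...]:
    if not blocks:
        return ()
    merged = [blocks[0]]
    for s, e in blocks[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 < min_gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return tuple(merged)


def _identity_from_record(rec: pysam.AlignedSegment, warned: list[bool]) -> float:
    aligned = sum(
        length for op, length in (rec.cigartuples or []) if op in (0, 7, 8)
    )
    if aligned == 0:
        return 0.0
    try:
        nm = rec.get_tag("NM")
    except KeyError:
        if not warned[0]:
            logger.warning("records without NM tag: identity assumed 1.0")
            warned[0] = True
        return 1.0
    return max(0.0, (aligned - int(nm)) / aligned)


def stream_alignments(
    path: str | Path,
    min_identity: float = 0.90,
    min_gap: int = MIN_INTRON_GAP,
) -> Iterator[AlignedRead]:
    """Yield unique reads passing the identity filter from a SAM/BAM file.

    Secondary/supplementary/unmapped records are dropped; records that fail to
    parse are skipped with a counter.  A missing header (no @SQ lines) is a
    hard error.  Identity comes from the NM tag when present, else 1.0 with a
    one-shot warning.
    """
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError("min_identity must lie in [0, 1]")
    warned = [False]
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=True) as sam:
        if sam.nreferences == 0:
            raise ValueError(f"{path}: SAM header has no reference sequences")
        for rec in sam:
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                identity = _identity_from_record(rec, warned)
                if identity < min_identity:
                    continue
                blocks0 = rec.get_blocks()  # 0-based half-open
                if not blocks0:
                    continue
                blocks = _merge_small_gaps(
                    [(s + 1, e) for s, e in blocks0], min_gap
                )
                yield AlignedRead(
                    query_id=rec.query_name or "",
                    chrom=rec.reference_name or "",
                    blocks=blocks,
                    identity=identity,
                    is_unique=rec.mapping_quality > 0,
                )
            except (ValueError, TypeError):
                n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d unparseable alignment records", n_skipped)


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def count_sample(
    reads: Iterable[AlignedRead],
    models: GeneModelSet,
    sample_id: str = "sample",
    anchor: int = DEFAULT_ANCHOR,
) -> SampleCounts:
    """Aggregate a read stream into SampleCounts.

    Fragments (reads sharing a query_id, e.g. mate pairs) count once toward
    gene_reads per overlapped gene; fragments overlapping more than one gene
    are excluded from gene_unique_reads.  Depths are aligned-base averages
    over the feature.  A read contributes to a junction count iff one of its
    gaps falls within the gene span; boundary counts require one block to
    cover [boundary-anchor+1, boundary+anchor] contiguously.
    """
    sc = SampleCounts(sample_id=sample_id)
    exon_bases: dict[tuple[str, int], float] = defaultdict(float)
    intron_bases: dict[tuple[str, int], float] = defaultdict(float)
    junctions: dict[tuple[str, int, int], int] = defaultdict(int)
    boundaries: dict[tuple[str, int, str], int] = defaultdict(int)
    frag_genes: dict[str, set[str]] = defaultdict(set)
    fragments: set[str] = set()

    for read in reads:
        if not read.is_unique:
            continue
        fragments.add(read.query_id)
        span = read.span
        for model in models.overlapping(read.chrom, span[0], span[1]):
            g = model.gene_id
            frag_genes[read.query_id].add(g)
            for gi, exon in enumerate(model.exons):
                ov = sum(_overlap(b, exon) for b in read.blocks)
                if ov:
                    exon_bases[(g, model.exon_tx_index(gi))] += ov
            for gi, intron in enumerate(model.introns):
                ov = sum(_overlap(b, intron) for b in read.blocks)
                if ov:
                    intron_bases[(g, model.intron_tx_index(gi))] += ov
                ti = model.intron_tx_index(gi)
                left, right = intron[0] - 1, intron[1] + 1  # exon edges
                for pos, genomic_side in ((left, "L"), (right, "R")):
                    window = (pos - anchor + 1, pos + anchor)
                    if any(
                        b[0] <= window[0] and b[1] >= window[1] for b in read.blocks
                    ):
                        if model.strand == "+":
                            side = "5p" if genomic_side == "L" else "3p"
                        else:
                            side = "3p" if genomic_side == "L" else "5p"
                        boundaries[(g, ti, side)] += 1
            gene_span = model.span
            for gs, ge in read.gaps:
                if gs >= gene_span[0] and ge <= gene_span[1]:
                    junctions[(g, gs - 1, ge + 1)] += 1

    for qid, genes in frag_genes.items():
        for g in genes:
            sc.gene_reads[g] = sc.gene_reads.get(g, 0) + 1
        if len(genes) == 1:
            (g,) = genes
            sc.gene_unique_reads[g] = sc.gene_unique_reads.get(g, 0) + 1

    for model in models:
        g = model.gene_id
        for gi, exon in enumerate(model.exons):
            ti = model.exon_tx_index(gi)
            if (g, ti) in exon_bases:
                sc.exon_depth[(g, ti)] = exon_bases[(g, ti)] / (
                    exon[1] - exon[0] + 1
                )
        for gi, intron in enumerate(model.introns):
            ti = model.intron_tx_index(gi)
            if (g, ti) in intron_bases:
                sc.intron_depth[(g, ti)] = intron_bases[(g, ti)] / (
                    intron[1] - intron[0] + 1
                )

    sc.junction_reads = dict(junctions)
    sc.boundary_reads = dict(boundaries)
    sc.library_size = len(fragments)
    return sc


# -- TSV round-trip -----------------------------------------------------------

_TABLES = (
    "genes.tsv",
    "exon_depth.tsv",
    "intron_depth.tsv",
    "junctions.tsv",
    "boundaries.tsv",
)


def write_counts(sc: SampleCounts, outdir: str | Path) -> None:
    """Write one sample's counts as the five TSV tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write(f"# sample_id={sc.sample_id}\tlibrary_size={sc.library_size}\n")
        fh.write("gene_id\treads\tunique_reads\n")
        for g in sorted(set(sc.gene_reads) | set(sc.gene_unique_reads)):
            fh.write(
                f"{g}\t{sc.gene_reads.get(g, 0)}\t{sc.gene_unique_reads.get(g, 0)}\n"
            )
    for name, data in (
        ("exon_depth.tsv", sc.exon_depth),
        ("intron_depth.tsv", sc.intron_depth),
    ):
        with open(outdir / name, "w") as fh:
            fh.write("gene_id\tindex\tdepth\n")
            for (g, i), d in sorted(data.items()):
                fh.write(f"{g}\t{i}\t{d!r}\n")
    with open(outdir / "junctions.tsv", "w") as fh:
        fh.write("gene_id\tdonor_end\tacceptor_start\treads\n")
        for (g, d, a), n in sorted(sc.junction_reads.items()):
            fh.write(f"{g}\t{d}\t{a}\t{n}\n")
    with open(outdir / "boundaries.tsv", "w") as fh:
        fh.write("gene_id\tintron_index\tside\treads\n")
        for (g, i, s), n in sorted(sc.boundary_reads.items()):
            fh.write(f"{g}\t{i}\t{s}\t{n}\n")


def read_counts(indir: str | Path, sample_id: str | None = None) -> SampleCounts:
    """Read the five TSV tables written by :func:`write_counts`."""
    indir = Path(indir)
    for name in _TABLES:
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing count table {indir / name}")
    with open(indir / "genes.tsv") as fh:
        header = fh.readline()
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").strip().split("\t")
        )
        sc = SampleCounts(
            sample_id=sample_id or meta.get("sample_id", indir.name),
            library_size=int(meta.get("library_size", 0)),
        )
        fh.readline()  # column header
        for line in fh:
            g, reads, uniq = line.rstrip("\n").split("\t")
            sc.gene_reads[g] = int(reads)
            sc.gene_unique_reads[g] = int(uniq)
    for name, target in (
        ("exon_depth.tsv", sc.exon_depth),
        ("intron_depth.tsv", sc.intron_depth),
    ):
        with open(indir / name) as fh:
            fh.readline()
            for line in fh:
                g, i, d = line.rstrip("\n").split("\t")
                target[(g, int(i))] = float(d)
    with open(indir / "junctions.tsv") as fh:
        fh.readline()
        for line in fh:
            g, d, a, n = line.rstrip("\n").split("\t")
            sc.junction_reads[(g, int(d), int(a))] = int(n)
    with open(indir / "boundaries.tsv") as fh:
        fh.readline()
        for line in fh:
            g, i, s, n = line.rstrip("\n").split("\t")
            sc.boundary_reads[(g, int(i), s)] = int(n)
    return sc
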