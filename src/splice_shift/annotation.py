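"""Gene models from GFF3: exon chains, derived introns, and splice junctions.

One model per gene: when a gene has several annotated transcripts, a single
representative exon chain is chosen (``first`` encountered or ``longest`` by
summed exon length).  All coordinates are 1-based inclusive, as in GFF3.
Exon and intron indices at reporting interfaces are in transcription order
(strand-aware); genomic order is used internally.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, TextIO

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class JunctionKey(NamedTuple):
    """A splice junction: last base of the upstream exon and first base of the
    downstream exon.  The excised interval is (donor_end+1, acceptor_start-1)."""

    gene_id: str
    donor_end: int
    acceptor_start: int

    def intron_interval(self) -> Interval:
        return (self.donor_end + 1, self.acceptor_start - 1)


@dataclass(frozen=True)
class GeneModel:
    """A single gene with an ordered, non-overlapping exon chain."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if e < s:
                raise ValueError(f"{self.gene_id}: exon end {e} < start {s}")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.gene_id}: overlapping or abutting exons")
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Intervals between consecutive exons, genomic order."""
        return tuple(
            (e0 + 1, s1 - 1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def length_nt(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    # -- transcription-order index conversion ---------------------------------

    def exon_tx_index(self, genomic_index: int) -> int:
        return genomic_index if self.strand == "+" else self.n_exons - 1 - genomic_index

    def intron_tx_index(self, genomic_index: int) -> int:
        return (
            genomic_index if self.strand == "+" else self.n_introns - 1 - genomic_index
        )

    def exon_genomic_index(self, tx_index: int) -> int:
        return self.exon_tx_index(tx_index)  # involution

    def intron_genomic_index(self, tx_index: int) -> int:
        return self.intron_tx_index(tx_index)  # involution


def derive_junctions(model: GeneModel) -> list[JunctionKey]:
    """One junction per annotated intron (genomic order)."""
    return [
        JunctionKey(model.gene_id, iv[0] - 1, iv[1] + 1) for iv in model.introns
    ]


def skip_junctions(model: GeneModel) -> list[JunctionKey]:
    """Junctions that would result from skipping one internal exon.

    Returned in genomic order of the skipped exon (indices 1..n_exons-2).
    """
    out = []
    for k in range(1, model.n_exons - 1):
        out.append(
            JunctionKey(model.gene_id, model.exons[k - 1][1], model.exons[k + 1][0])
        )
    return out


class GeneModelSet:
    """Gene models keyed by gene_id with per-chromosome interval lookup."""

    def __init__(self, models: Iterable[GeneModel] = ()):
        self._models: dict[str, GeneModel] = {}
        self._index_dirty = True
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._starts: dict[str, list[int]] = {}
        self._max_end_prefix: dict[str, list[int]] = {}
        for m in models:
            self.add(m)

    def add(self, model: GeneModel) -> None:
        if model.gene_id in self._models:
            raise ValueError(f"duplicate gene_id {model.gene_id}")
        self._models[model.gene_id] = model
        self._index_dirty = True

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._models.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._models[gene_id]

    def chroms(self) -> list[str]:
        return sorted({m.chrom for m in self})

    def _build_index(self) -> None:
        self._by_chrom = {}
        for m in self._models.values():
            self._by_chrom.setdefault(m.chrom, []).append(m)
        self._starts, self._max_end_prefix = {}, {}
        for chrom, ms in self._by_chrom.items():
            ms.sort(key=lambda m: m.span)
            self._starts[chrom] = [m.span[0] for m in ms]
            prefix, cur = [], 0
            for m in ms:
                cur = max(cur, m.span[1])
                prefix.append(cur)
            self._max_end_prefix[chrom] = prefix
        self._index_dirty = False

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """All models whose span intersects [start, end] (1-based inclusive)."""
        if self._index_dirty:
            self._build_index()
        ms = self._by_chrom.get(chrom)
        if not ms:
            return []
        hi = bisect_right(self._starts[chrom], end)
        out = []
        for i in range(hi - 1, -1, -1):
            if self._max_end_prefix[chrom][i] < start:
                break
            if ms[i].span[1] >= start:
                out.append(ms[i])
        out.reverse()
        return out


# -- GFF3 ---------------------------------------------------------------------


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, _, v = part.partition("=")
            attrs[k.strip()] = v.strip()
    return attrs


def parse_gene_models(
    stream: TextIO | Iterable[str], representative: str = "first"
) -> GeneModelSet:
    """Parse GFF3 gene/mRNA/exon features into one model per gene.

    Exons may be parented to mRNA features (which point at genes) or directly
    to genes.  ``representative`` selects the transcript used when a gene has
    several: ``first`` (order of appearance) or ``longest`` (summed exon
    length).  Genes whose chosen exon chain overlaps itself are rejected with
    a logged diagnostic; coordinates with end < start are a hard error.
    """
    if representative not in ("first", "longest"):
        raise ValueError(f"unknown representative policy {representative!r}")
    gene_meta: dict[str, tuple[str, str]] = {}  # gene -> (chrom, strand)
    mrna_parent: dict[str, str] = {}
    # (gene, transcript) -> set of exon intervals; transcript "" = direct parent
    chains: dict[tuple[str, str], set[Interval]] = {}
    tx_order: dict[str, list[str]] = {}
    n_orphan = 0

    for lineno, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9:
            continue
        chrom, _src, ftype, start_s, end_s, _score, strand, _phase, col9 = cols[:9]
        ftype = ftype.lower()
        if ftype not in ("gene", "mrna", "transcript", "exon"):
            continue
        start, end = int(start_s), int(end_s)
        if end < start:
            raise ValueError(f"GFF3 line {lineno}: end {end} < start {start}")
        attrs = _parse_attributes(col9)
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise ValueError(f"GFF3 line {lineno}: gene without ID")
            gene_meta[gid] = (chrom, strand)
        elif ftype in ("mrna", "transcript"):
            tid, parent = attrs.get("ID"), attrs.get("Parent")
            if tid and parent:
                mrna_parent[tid] = parent
                tx_order.setdefault(parent, []).append(tid)
        else:  # exon
            parent = attrs.get("Parent")
            if parent is None:
                n_orphan += 1
                logger.warning("GFF3 line %d: exon without Parent, skipped", lineno)
                continue
            for p in parent.split(","):
                if p in mrna_parent:
                    gene, tx = mrna_parent[p], p
                elif p in gene_meta:
                    gene, tx = p, ""
                else:
                    # Parent seen before definition is tolerated only for genes
                    # declared later; defer by treating p as transcript of itself.
                    gene, tx = p, ""
                chains.setdefault((gene, tx), set()).add((start, end))
                if tx and tx not in tx_order.setdefault(gene, []):
                    pass

    models = GeneModelSet()
    genes = set(gene_meta) | {g for g, _ in chains}
    for gid in sorted(genes):
        candidates = [(tx, chains[(g, tx)]) for (g, tx) in chains if g == gid]
        if not candidates:
            continue
        if gid in gene_meta:
            chrom, strand = gene_meta[gid]
        else:
            logger.warning("gene %s has exons but no gene record; skipped", gid)
            continue
        if representative == "longest":
            candidates.sort(
                key=lambda c: (-sum(e - s + 1 for s, e in c[1]), c[0])
            )
        else:
            order = {"": -1}
            order.update({t: i for i, t in enumerate(tx_order.get(gid, []))})
            candidates.sort(key=lambda c: order.get(c[0], len(order)))
        _, exon_set = candidates[0]
        try:
            models.add(GeneModel(gid, chrom, strand, tuple(sorted(exon_set))))
        except ValueError as exc:
            logger.warning("gene %s rejected: %s", gid, exc)
    return models


def write_gff3(models: GeneModelSet, stream: TextIO) -> None:
    """Write models as GFF3 (gene + exon records, exons parented to genes)."""
    stream.write("##gff-version 3\n")
    for m in sorted(models, key=lambda m: (m.chrom, m.span, m.gene_id)):
        s, e = m.span
        stream.write(
            f"{m.chrom}\t.\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
        )
        for es, ee in m.exons:
            stream.write(
                f"{m.chrom}\t.\texon\t{es}\t{ee}\t.\t{m.strand}\t.\t"
                f"Parent={m.gene_id}\n"
            )


def write_models_tsv(models: GeneModelSet, stream: TextIO) -> None:
    """Audit table: gene_id, chrom, strand, exon list, intron list."""
    stream.write("gene_id\tchrom\tstrand\texons\tintrons\tlength_nt\n")
    for m in sorted(models, key=lambda m: m.gene_id):
        exons = ",".join(f"{s}-{e}" for s, e in m.exons)
        introns = ",".join(f"{s}-{e}" for s, e in m.introns)
        stream.write(
            f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{exons}\t{introns}\t{m.length_nt}\n"
        )
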