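"""Quantification of a three-variant reporter locus.

The reporter carries a canonical GT-AG intron nested inside a noncanonical
AT-AC intron whose 3' splice sites lie 3 nt apart (AC on the outside).  Three
transcripts accumulate: unspliced, GT-AG-spliced, and AT-AC-spliced.  Because
the two junctions share neither end, a single junction read supports at most
one spliced variant; unspliced evidence comes from reads contiguously
spanning the shared 5' boundary of the outer intron.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import GeneModel
from .counting import SampleCounts

Interval = tuple[int, int]


@dataclass(frozen=True)
class ReporterModel:
    """Reporter locus geometry.  ``outer`` is the AT-AC intron, ``inner`` the
    nested GT-AG intron; plus strand."""

    gene_id: str
    chrom: str
    outer: Interval
    inner: Interval
    outer_intron_index: int = 0  # transcription-order index in the gene model

    def __post_init__(self) -> None:
        (os, oe), (ins, ine) = self.outer, self.inner
        if not (os < ins and ine < oe):
            raise ValueError("inner intron must lie strictly inside the outer")
        if oe - ine != 3:
            raise ValueError(
                "3' splice sites must be separated by exactly 3 nt with the "
                "outer acceptor outside"
            )

    @property
    def outer_junction(self) -> tuple[int, int]:
        return (self.outer[0] - 1, self.outer[1] + 1)

    @property
    def inner_junction(self) -> tuple[int, int]:
        return (self.inner[0] - 1, self.inner[1] + 1)

    def gene_model(self, flank: int = 200) -> GeneModel:
        """Two-exon gene model with the outer intron annotated, for counting."""
        (os, oe) = self.outer
        return GeneModel(
            self.gene_id,
            self.chrom,
            "+",
            ((max(1, os - flank), os - 1), (oe + 1, oe + flank)),
        )


@dataclass(frozen=True)
class ReporterQuant:
    """Counts and proportions of (unspliced, GT-AG, AT-AC) for one sample."""

    sample_id: str
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if sum(self.counts) <= 0:
            raise ValueError("reporter not covered")
        if min(self.counts) < 0:
            raise ValueError("negative variant count")

    @property
    def proportions(self) -> tuple[float, float, float]:
        total = sum(self.counts)
        return tuple(c / total for c in self.counts)  # type: ignore[return-value]


def quantify_reporter(
    counts: SampleCounts, model: ReporterModel, unspliced_rule: str = "5p"
) -> ReporterQuant:
    """Classify reporter reads into the three splice variants.

    AT-AC evidence: junction reads exactly matching the outer intron; GT-AG:
    junction reads exactly matching the inner intron; unspliced: reads
    spanning the outer intron's 5' boundary (``unspliced_rule='5p'``) or the
    mean of both boundaries (``'both'``).  Raises if the total is zero.
    """
    g = model.gene_id
    n_atac = counts.junction(g, *model.outer_junction)
    n_gtag = counts.junction(g, *model.inner_junction)
    five = counts.boundary(g, model.outer_intron_index, "5p")
    if unspliced_rule == "5p":
        n_unspliced = five
    elif unspliced_rule == "both":
        three = counts.boundary(g, model.outer_intron_index, "3p")
        n_unspliced = round((five + three) / 2)
    else:
        raise ValueError(f"unknown unspliced_rule {unspliced_rule!r}")
    return ReporterQuant(counts.sample_id, (n_unspliced, n_gtag, n_atac))
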