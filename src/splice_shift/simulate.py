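"""Synthetic gene models, replicate count data, and injected splicing events.

Counts are generated at the SampleCounts level: per-gene expression is
negative binomial (variance = mean + dispersion * mean^2), per-feature depth
values are Poisson around the gene's expected per-base depth, and junction
reads arise by binomial thinning of intron-spanning reads at the intron's
splicing efficiency.  Injected events perturb retention or junction-usage
odds by a stated fold so that detector recovery can be scored against known
truth.  Everything is deterministic under the design seed.

A small SAM emitter writes concrete spliced reads for end-to-end tests of
the alignment counting stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import GeneModel, GeneModelSet
from .counting import AlignedRead, SampleCounts
from .reporter import ReporterModel

logger = logging.getLogger(__name__)

READ_LENGTH = 100


# -- design -------------------------------------------------------------------


@dataclass(frozen=True)
class Injection:
    """One perturbation applied to the mutant genotype.

    ``fold`` multiplies the feature's odds (retention odds for IR, inverse
    for MES; skip-share odds for ES; variant-share odds for A5SS/A3SS).
    ``feature_index`` is in transcription order (intron for IR/MES/A5SS/A3SS,
    exon for ES)."""

    kind: str  # IR | MES | ES | A5SS | A3SS
    gene_id: str
    feature_index: int
    fold: float

    def expected_event_type(self) -> str:
        return {
            "IR": "IR",
            "MES": "MES",
            "ES": "ES_enhanced",
            "A5SS": "A5SS_enhanced",
            "A3SS": "A3SS_enhanced",
        }[self.kind]


@dataclass(frozen=True)
class AltVariantSpec:
    """An alternative junction attached to an annotated intron: which genomic
    end moves, by how many nt into the intron, and its baseline read share."""

    end: str  # "donor" | "acceptor"
    offset: int = 9
    share: float = 0.05


@dataclass
class SimulationDesign:
    """Full specification of a two-genotype replicated count simulation."""

    nb_mean: dict[str, float]
    dispersion: dict[str, float]
    efficiency: dict[tuple[str, int], float]
    n_replicates: int = 5
    seed: int = 0
    read_length: int = READ_LENGTH
    genotypes: tuple[str, ...] = ("wt", "mut")
    injections: list[Injection] = field(default_factory=list)
    alt_variants: dict[tuple[str, int], AltVariantSpec] = field(default_factory=dict)
    es_exons: dict[tuple[str, int], float] = field(default_factory=dict)
    boundary_rate: float = 0.5

    def __post_init__(self) -> None:
        for key, eff in self.efficiency.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"efficiency {eff} for {key} outside [0, 1]")
        for g, d in self.dispersion.items():
            if d < 0:
                raise ValueError(f"dispersion {d} for {g} negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class TruthSet:
    """Ground truth of a simulation run."""

    events: list[Injection] = field(default_factory=list)
    reporter_mixtures: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    clamped: list[str] = field(default_factory=list)


# -- gene model generation ----------------------------------------------------


def gen_models(
    n_genes: int,
    seed: int,
    exon_range: tuple[int, int] = (2, 8),
    exon_len_range: tuple[int, int] = (50, 500),
    intron_len_range: tuple[int, int] = (60, 1000),
    genes_per_chrom: int = 200,
    intergenic: int = 2000,
) -> GeneModelSet:
    """Random non-overlapping multi-exon gene models, deterministic in seed."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    models = GeneModelSet()
    pos, chrom_i = 1, 1
    for i in range(n_genes):
        if i and i % genes_per_chrom == 0:
            chrom_i += 1
            pos = 1
        n_exons = int(rng.integers(exon_range[0], exon_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        cur = pos + int(rng.integers(0, 500))
        for j in range(n_exons):
            elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append((cur, cur + elen - 1))
            cur += elen
            if j < n_exons - 1:
                cur += int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        models.add(GeneModel(f"G{i + 1:05d}", f"chr{chrom_i}", strand, tuple(exons)))
        pos = cur + intergenic
    return models


# -- count simulation ---------------------------------------------------------


def _odds_scale(p: float, fold: float) -> float:
    """Multiply the odds of p by fold."""
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    odds = p / (1.0 - p) * fold
    return odds / (1.0 + odds)


def _perturbations(design: SimulationDesign) -> tuple[dict, dict, dict]:
    """Injection lookup tables: retention / ES-share / alt-share odds folds."""
    retention: dict[tuple[str, int], float] = {}
    es: dict[tuple[str, int], float] = {}
    alt: dict[tuple[str, int], float] = {}
    for inj in design.injections:
        key = (inj.gene_id, inj.feature_index)
        if inj.kind == "IR":
            retention[key] = retention.get(key, 1.0) * inj.fold
        elif inj.kind == "MES":
            retention[key] = retention.get(key, 1.0) / inj.fold
        elif inj.kind == "ES":
            es[key] = es.get(key, 1.0) * inj.fold
        elif inj.kind in ("A5SS", "A3SS"):
            alt[key] = alt.get(key, 1.0) * inj.fold
        else:
            raise ValueError(f"unknown injection kind {inj.kind!r}")
    return retention, es, alt


def _variant_key(
    model: GeneModel, genomic_intron_index: int, spec: AltVariantSpec
) -> tuple[int, int]:
    s, e = model.introns[genomic_intron_index]
    donor_end, acceptor_start = s - 1, e + 1
    if spec.end == "donor":
        return (donor_end + spec.offset, acceptor_start)
    if spec.end == "acceptor":
        return (donor_end, acceptor_start - spec.offset)
    raise ValueError(f"unknown variant end {spec.end!r}")


def simulate_counts(
    models: GeneModelSet, design: SimulationDesign
) -> tuple[dict[str, list[SampleCounts]], TruthSet]:
    """Simulate replicate SampleCounts for every genotype plus ground truth.

    Per gene and replicate: reads X ~ NB(mean, dispersion); expected per-base
    depth d = X * read_length / gene length; each exon depth ~ Poisson(d);
    per intron, spanning reads ~ Poisson(d) split binomially into spliced
    (junction reads, possibly shared with an alternative junction) and
    retained (intron depth).  Injections act on the mutant genotype only.
    """
    truth = TruthSet(events=list(design.injections))
    ret_fold, es_fold, alt_fold = _perturbations(design)
    gene_order = sorted(m.gene_id for m in models)
    samples: dict[str, list[SampleCounts]] = {}

    for g_idx, genotype in enumerate(design.genotypes):
        perturbed = genotype != design.genotypes[0]
        reps = []
        for r in range(design.n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([design.seed, g_idx, r])
            )
            sc = SampleCounts(sample_id=f"{genotype}_{r + 1}")
            lib = 0
            for gid in gene_order:
                model = models[gid]
                mean = design.nb_mean[gid]
                disp = design.dispersion.get(gid, 0.0)
                if disp <= 1e-12:
                    x = int(rng.poisson(mean))
                else:
                    size = 1.0 / disp
                    x = int(rng.negative_binomial(size, size / (size + mean)))
                sc.gene_reads[gid] = x
                sc.gene_unique_reads[gid] = x
                lib += x
                d = x * design.read_length / model.length_nt
                for ti in range(model.n_exons):
                    sc.exon_depth[(gid, ti)] = float(rng.poisson(d))
                for ti in range(model.n_introns):
                    eff = design.efficiency.get((gid, ti), 1.0)
                    if perturbed and (gid, ti) in ret_fold:
                        retention = _odds_scale(1.0 - eff, ret_fold[(gid, ti)])
                        new_eff = 1.0 - retention
                        if not 0.0 <= new_eff <= 1.0:
                            new_eff = min(1.0, max(0.0, new_eff))
                            truth.clamped.append(f"{gid}:{ti}")
                        eff = new_eff
                    n_span = int(rng.poisson(d))
                    spliced = int(rng.binomial(n_span, eff)) if n_span else 0
                    retained = n_span - spliced
                    sc.intron_depth[(gid, ti)] = float(retained)
                    gi = model.intron_genomic_index(ti)
                    s, e = model.introns[gi]
                    ann_key = (gid, s - 1, e + 1)
                    spec = design.alt_variants.get((gid, ti))
                    if spec is not None and spliced:
                        share = spec.share
                        if perturbed and (gid, ti) in alt_fold:
                            share = _odds_scale(share, alt_fold[(gid, ti)])
                        n_var = int(rng.binomial(spliced, share))
                        vk = _variant_key(model, gi, spec)
                        if n_var:
                            sc.junction_reads[(gid, *vk)] = (
                                sc.junction_reads.get((gid, *vk), 0) + n_var
                            )
                        spliced -= n_var
                    if spliced:
                        sc.junction_reads[ann_key] = (
                            sc.junction_reads.get(ann_key, 0) + spliced
                        )
                    if retained:
                        for side in ("5p", "3p"):
                            nb = int(rng.binomial(retained, design.boundary_rate))
                            if nb:
                                sc.boundary_reads[(gid, ti, side)] = nb
                for ti, share in sorted(design.es_exons.items()):
                    e_gid, e_tx = ti
                    if e_gid != gid:
                        continue
                    if perturbed and (e_gid, e_tx) in es_fold:
                        share = _odds_scale(share, es_fold[(e_gid, e_tx)])
                    k = model.exon_genomic_index(e_tx)
                    if not 1 <= k <= model.n_exons - 2:
                        raise ValueError(
                            f"ES exon {e_gid}:{e_tx} is not internal"
                        )
                    n_skip = int(rng.poisson(d * share))
                    if n_skip:
                        key = (gid, model.exons[k - 1][1], model.exons[k + 1][0])
                        sc.junction_reads[key] = (
                            sc.junction_reads.get(key, 0) + n_skip
                        )
            sc.library_size = lib
            reps.append(sc)
        samples[genotype] = reps
    return samples, truth


def simulate_reporter(
    mixture: Sequence[float],
    depth: int,
    seed: int | np.random.Generator,
    model: ReporterModel,
    sample_id: str = "reporter",
) -> SampleCounts:
    """Multinomial draw of (unspliced, GT-AG, AT-AC) reporter reads.

    Returns a SampleCounts fragment holding only the reporter gene's junction
    and boundary counts, mergeable into a full sample via
    :func:`merge_reporter_counts`.
    """
    mixture = list(mixture)
    if any(m < 0 for m in mixture):
        raise ValueError("mixture fractions must be non-negative")
    if abs(sum(mixture) - 1.0) > 1e-9:
        raise ValueError("mixture must sum to 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([seed, 0xF16]))
    )
    n_unspliced, n_gtag, n_atac = (
        int(v) for v in rng.multinomial(depth, mixture)
    )
    sc = SampleCounts(sample_id=sample_id, library_size=depth)
    g = model.gene_id
    sc.gene_reads[g] = depth
    sc.gene_unique_reads[g] = depth
    if n_atac:
        sc.junction_reads[(g, *model.outer_junction)] = n_atac
    if n_gtag:
        sc.junction_reads[(g, *model.inner_junction)] = n_gtag
    if n_unspliced:
        sc.boundary_reads[(g, model.outer_intron_index, "5p")] = n_unspliced
    return sc


def merge_reporter_counts(sample: SampleCounts, fragment: SampleCounts) -> None:
    """Fold a reporter fragment into a full sample's counts in place."""
    for k, v in fragment.gene_reads.items():
        sample.gene_reads[k] = sample.gene_reads.get(k, 0) + v
    for k, v in fragment.gene_unique_reads.items():
        sample.gene_unique_reads[k] = sample.gene_unique_reads.get(k, 0) + v
    for k, v in fragment.junction_reads.items():
        sample.junction_reads[k] = sample.junction_reads.get(k, 0) + v
    for k, v in fragment.boundary_reads.items():
        sample.boundary_reads[k] = sample.boundary_reads.get(k, 0) + v
    sample.library_size += fragment.library_size


# -- scenario builder ---------------------------------------------------------


@dataclass
class Scenario:
    models: GeneModelSet
    design: SimulationDesign
    reporter: ReporterModel | None = None
    reporter_mixtures: dict[str, tuple[float, float, float]] | None = None
    reporter_depth: int = 2000


def build_scenario(
    n_genes: int = 400,
    n_replicates: int = 5,
    seed: int = 0,
    mean_depth: float = 400.0,
    dispersion: float = 0.05,
    efficiency: float = 0.8,
    n_ir: int = 0,
    ir_fold: float = 4.0,
    n_mes: int = 0,
    mes_fold: float = 6.0,
    n_es: int = 0,
    es_fold: float = 6.0,
    n_a5ss: int = 0,
    n_a3ss: int = 0,
    alt_fold: float = 6.0,
    alt_share: float = 0.05,
    es_share: float = 0.03,
    n_null_alt: int = 20,
    n_null_es: int = 20,
    with_reporter: bool = False,
    reporter_mixtures: dict[str, tuple[float, float, float]] | None = None,
    read_length: int = READ_LENGTH,
) -> Scenario:
    """Assemble models plus a design with randomly placed injections.

    ``mean_depth`` is the expected per-base exon depth of an average gene;
    expression means are set so NB counts produce it.  Null alt-variant
    introns and null skip-active exons (same rates in both genotypes) are
    included so the Fisher/ES code paths are exercised under the null.
    """
    models = gen_models(n_genes, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CE]))
    nb_mean, disp, eff = {}, {}, {}
    for m in models:
        nb_mean[m.gene_id] = mean_depth * m.length_nt / read_length
        disp[m.gene_id] = dispersion
        for ti in range(m.n_introns):
            eff[(m.gene_id, ti)] = efficiency

    introns = [
        (m.gene_id, ti) for m in models for ti in range(m.n_introns)
    ]
    internal_exons = [
        (m.gene_id, m.exon_tx_index(k))
        for m in models
        for k in range(1, m.n_exons - 1)
    ]
    introns.sort()
    internal_exons.sort()

    n_alt_total = n_a5ss + n_a3ss + n_null_alt
    n_es_total = n_es + n_null_es
    need = n_ir + n_mes + n_alt_total
    if need > len(introns) or n_es_total > len(internal_exons):
        raise ValueError("not enough features for requested injections")
    picked = [
        introns[i]
        for i in rng.choice(len(introns), size=need, replace=False)
    ]
    ir_introns = picked[:n_ir]
    mes_introns = picked[n_ir : n_ir + n_mes]
    alt_introns = picked[n_ir + n_mes :]
    picked_ex = [
        internal_exons[i]
        for i in rng.choice(len(internal_exons), size=n_es_total, replace=False)
    ]
    es_targets, es_null = picked_ex[:n_es], picked_ex[n_es:]

    injections: list[Injection] = []
    for g, ti in ir_introns:
        injections.append(Injection("IR", g, ti, ir_fold))
    for g, ti in mes_introns:
        injections.append(Injection("MES", g, ti, mes_fold))

    alt_variants: dict[tuple[str, int], AltVariantSpec] = {}
    kinds = ["A5SS"] * n_a5ss + ["A3SS"] * n_a3ss + [None] * n_null_alt
    for (g, ti), kind in zip(alt_introns, kinds):
        if kind is None:
            end = "donor" if rng.random() < 0.5 else "acceptor"
        else:
            strand = models[g].strand
            # 5' splice site is the genomic donor on + strand, acceptor on -
            if kind == "A5SS":
                end = "donor" if strand == "+" else "acceptor"
            else:
                end = "acceptor" if strand == "+" else "donor"
            injections.append(Injection(kind, g, ti, alt_fold))
        alt_variants[(g, ti)] = AltVariantSpec(end=end, share=alt_share)

    es_exons = {key: es_share for key in es_targets + es_null}
    for g, ti in es_targets:
        injections.append(Injection("ES", g, ti, es_fold))

    design = SimulationDesign(
        nb_mean=nb_mean,
        dispersion=disp,
        efficiency=eff,
        n_replicates=n_replicates,
        seed=seed,
        read_length=read_length,
        injections=injections,
        alt_variants=alt_variants,
        es_exons=es_exons,
    )
    scenario = Scenario(models=models, design=design)
    if with_reporter:
        chrom = "chrR"
        scenario.reporter = ReporterModel(
            gene_id="REPORTER", chrom=chrom, outer=(1201, 1500), inner=(1261, 1497)
        )
        scenario.reporter_mixtures = reporter_mixtures or {
            "wt": (0.45, 0.375, 0.175),
            "mut": (0.25, 0.20, 0.55),
        }
    return scenario


def run_scenario(
    scenario: Scenario,
) -> tuple[dict[str, list[SampleCounts]], TruthSet]:
    """Simulate counts for a scenario, including reporter reads if present."""
    samples, truth = simulate_counts(scenario.models, scenario.design)
    if scenario.reporter is not None and scenario.reporter_mixtures:
        truth.reporter_mixtures = dict(scenario.reporter_mixtures)
        for g_idx, (genotype, reps) in enumerate(samples.items()):
            mixture = scenario.reporter_mixtures.get(genotype)
            if mixture is None:
                continue
            for r, sc in enumerate(reps):
                frag = simulate_reporter(
                    mixture,
                    scenario.reporter_depth,
                    np.random.default_rng(
                        np.random.SeedSequence(
                            [scenario.design.seed, 0xF16, g_idx, r]
                        )
                    ),
                    scenario.reporter,
                    sample_id=sc.sample_id,
                )
                merge_reporter_counts(sc, frag)
    return samples, truth


def truth_tsv(truth: TruthSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tgene_id\tfeature_index\tfold\texpected_event_type\n")
        for ev in truth.events:
            fh.write(
                f"{ev.kind}\t{ev.gene_id}\t{ev.feature_index}\t{ev.fold}\t"
                f"{ev.expected_event_type()}\n"
            )


# -- SAM emission -------------------------------------------------------------


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{e - s + 1}M")
    return "".join(parts)


def write_sam(
    reads: Iterable[AlignedRead],
    references: dict[str, int],
    path: str | Path,
) -> None:
    """Write reads as a minimal text SAM file (SEQ omitted, NM:i:0)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rd in reads:
            fh.write(
                f"{rd.query_id}\t0\t{rd.chrom}\t{rd.blocks[0][0]}\t60\t"
                f"{_cigar(rd.blocks)}\t*\t0\t0\t*\t*\tNM:i:0\n"
            )


def gene_read_plan(
    model: GeneModel,
    junction_reads: int = 5,
    retained_reads: int = 3,
    exon_reads: int = 4,
    read_length: int = 60,
) -> list[AlignedRead]:
    """Deterministic reads for one gene: per-exon single-block reads, exact
    junction reads per intron, and intron-retaining reads spanning each
    intron's genomic-left boundary.  Supports exact-count integration tests
    of the counting stage."""
    half = read_length // 2
    reads: list[AlignedRead] = []
    n = 0
    for gi, (s, e) in enumerate(model.exons):
        length = min(read_length, e - s + 1)
        for _ in range(exon_reads):
            n += 1
            reads.append(
                AlignedRead(f"{model.gene_id}.e{gi}.{n}", model.chrom, ((s, s + length - 1),))
            )
    for gi, (s, e) in enumerate(model.introns):
        up = model.exons[gi]
        down = model.exons[gi + 1]
        left = (max(up[0], up[1] - half + 1), up[1])
        right = (down[0], min(down[1], down[0] + half - 1))
        for _ in range(junction_reads):
            n += 1
            reads.append(
                AlignedRead(f"{model.gene_id}.j{gi}.{n}", model.chrom, (left, right))
            )
        b = (s - half, s + half - 1)  # spans the left exon-intron boundary
        for _ in range(retained_reads):
            n += 1
            reads.append(
                AlignedRead(f"{model.gene_id}.r{gi}.{n}", model.chrom, (b,))
            )
    return reads
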