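"""Splicing-event detectors: intron retention / more-efficient splicing,
exon skipping, and alternative 5'/3' splice-site usage.

Each detector tests one feature per replicate pair on a 2x2 contingency table
(focal evidence vs background, mutant vs wild type) and reports an event only
if the test p-value is below alpha in *every* replicate pair and the
direction of the ratio shift agrees across all pairs.  Chi-square tables take
fractional depths as-is; Fisher tables are rounded half-up to integers.
No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .annotation import GeneModel, GeneModelSet, JunctionKey, derive_junctions, skip_junctions
from .counting import SampleCounts

logger = logging.getLogger(__name__)

EVENT_TYPES = (
    "IR",
    "MES",
    "ES_enhanced",
    "ES_reduced",
    "A5SS_enhanced",
    "A5SS_reduced",
    "A3SS_enhanced",
    "A3SS_reduced",
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Row 1 = focal evidence, row 2 = background; col 1 = mutant, col 2 = wt.

    Laid out as (a, b) = mutant (focal, background), (c, d) = wild type."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table entries must be non-negative")


def chi2_homogeneity(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 with df=1 and no continuity correction.

    Entries may be fractional.  Any zero margin carries no evidence either
    way: (statistic 0, p 1).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    statistic = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher2x2(t: ContingencyTable2x2, rounding: str = "half-up") -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities not
    exceeding that of the observed table (with a 1e-9 relative tie guard).

    Entries are rounded to integers first (``half-up`` or ``none`` for inputs
    already integral).  A zero margin gives p = 1.
    """
    if rounding == "half-up":
        a, b, c, d = (_round_half_up(x) for x in (t.a, t.b, t.c, t.d))
    elif rounding == "none":
        a, b, c, d = (int(x) for x in (t.a, t.b, t.c, t.d))
        if (a, b, c, d) != (t.a, t.b, t.c, t.d):
            raise ValueError("rounding='none' requires integer entries")
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(1.0, p)


@dataclass
class EventCall:
    """One candidate splicing event with per-replicate-pair evidence.

    ``feature_index`` is the intron (IR/MES/alt-SS) or exon (ES) index in
    transcription order.  ``per_replicate_p2`` holds the gene-level Fisher
    confirmation p-values for alt-SS events, else is empty.
    """

    event_type: str
    gene_id: str
    feature_index: int
    junction: tuple[int, int] | None
    per_replicate_p: list[float]
    per_replicate_ratio_mut: list[float]
    per_replicate_ratio_wt: list[float]
    significant: bool
    per_replicate_p2: list[float] = field(default_factory=list)


def _pairs(
    wt: Sequence[SampleCounts], mut: Sequence[SampleCounts], pairing: str
) -> list[tuple[list[SampleCounts], SampleCounts]]:
    """Replicate pairs as (wt side, mut replicate).

    ``index``: wt[i] vs mut[i]; ``pooled``: all wt vs each mut replicate."""
    if pairing == "index":
        if len(wt) != len(mut):
            raise ValueError("index pairing requires equal replicate numbers")
        return [([w], m) for w, m in zip(wt, mut)]
    if pairing == "pooled":
        return [(list(wt), m) for m in mut]
    raise ValueError(f"unknown pairing mode {pairing!r}")


def _mean(values: list[float]) -> float:
    return sum(values) / len(values) if values else 0.0


def _direction(ratios_mut: list[float], ratios_wt: list[float]) -> str | None:
    """'up' if mutant ratio exceeds wt in every pair, 'down' if below; else None."""
    if all(m > w for m, w in zip(ratios_mut, ratios_wt)):
        return "up"
    if all(m < w for m, w in zip(ratios_mut, ratios_wt)):
        return "down"
    return None


def scan_intron_retention(
    wt: Sequence[SampleCounts],
    mut: Sequence[SampleCounts],
    models: GeneModelSet,
    alpha: float = 0.01,
    pairing: str = "index",
    include_discordant: bool = False,
) -> list[EventCall]:
    """Per-intron chi-square test of intron depth against flanking-exon depth.

    Per replicate pair the table is (mut intron depth, mut background, wt
    intron depth, wt background), background = unweighted mean depth of the
    two flanking exons.  Direction: IR if intron/background is larger in the
    mutant in every pair, MES if smaller in every pair; discordant pairs yield
    no call.  Introns with zero background in any replicate are skipped.
    """
    pairs = _pairs(wt, mut, pairing)
    calls: list[EventCall] = []
    for model in models:
        g = model.gene_id
        for ti in range(model.n_introns):
            rows = []
            skip = False
            for wt_side, m in pairs:
                def bg(sc: SampleCounts) -> float:
                    return 0.5 * (
                        sc.exon_depth.get((g, ti), 0.0)
                        + sc.exon_depth.get((g, ti + 1), 0.0)
                    )

                mut_bg = bg(m)
                wt_bg = _mean([bg(w) for w in wt_side])
                mut_i = m.intron_depth.get((g, ti), 0.0)
                wt_i = _mean([w.intron_depth.get((g, ti), 0.0) for w in wt_side])
                if mut_bg == 0 or wt_bg == 0:
                    skip = True
                    break
                rows.append((mut_i, mut_bg, wt_i, wt_bg))
            if skip or not rows:
                if skip:
                    logger.debug("intron %s/%d skipped: zero background", g, ti)
                continue
            if all(r[0] == 0 and r[2] == 0 for r in rows):
                continue  # intron never covered: nothing to test
            ps, rm, rw = [], [], []
            for mut_i, mut_bg, wt_i, wt_bg in rows:
                _, p = chi2_homogeneity(
                    ContingencyTable2x2(mut_i, mut_bg, wt_i, wt_bg)
                )
                ps.append(p)
                rm.append(mut_i / mut_bg)
                rw.append(wt_i / wt_bg)
            direction = _direction(rm, rw)
            if direction is None and not include_discordant:
                continue
            calls.append(
                EventCall(
                    event_type=(
                        "discordant"
                        if direction is None
                        else ("IR" if direction == "up" else "MES")
                    ),
                    gene_id=g,
                    feature_index=ti,
                    junction=None,
                    per_replicate_p=ps,
                    per_replicate_ratio_mut=rm,
                    per_replicate_ratio_wt=rw,
                    significant=direction is not None
                    and all(p < alpha for p in ps),
                )
            )
    return calls


def scan_exon_skipping(
    wt: Sequence[SampleCounts],
    mut: Sequence[SampleCounts],
    models: GeneModelSet,
    alpha: float = 0.01,
    pairing: str = "index",
    include_discordant: bool = False,
) -> list[EventCall]:
    """Per-internal-exon chi-square test of skip-junction reads against the
    reads of the two inclusion junctions touching the exon.

    Exons whose skip junction is never observed in any sample are not tested.
    Direction: enhanced if skip/inclusion is larger in the mutant in every
    pair, reduced if smaller.
    """
    pairs = _pairs(wt, mut, pairing)
    all_samples = list(wt) + list(mut)
    calls: list[EventCall] = []
    for model in models:
        g = model.gene_id
        if model.n_exons < 3:
            continue
        for k in range(1, model.n_exons - 1):
            skip_key = (g, model.exons[k - 1][1], model.exons[k + 1][0])
            if not any(s.junction_reads.get(skip_key, 0) for s in all_samples):
                continue
            inc1 = (g, model.exons[k - 1][1], model.exons[k][0])
            inc2 = (g, model.exons[k][1], model.exons[k + 1][0])

            def skip_n(sc: SampleCounts) -> float:
                return float(sc.junction_reads.get(skip_key, 0))

            def incl_n(sc: SampleCounts) -> float:
                return float(
                    sc.junction_reads.get(inc1, 0) + sc.junction_reads.get(inc2, 0)
                )

            ps, rm, rw = [], [], []
            for wt_side, m in pairs:
                a, b = skip_n(m), incl_n(m)
                c = _mean([skip_n(w) for w in wt_side])
                d = _mean([incl_n(w) for w in wt_side])
                _, p = chi2_homogeneity(ContingencyTable2x2(a, b, c, d))
                ps.append(p)
                rm.append(a / b if b else math.inf)
                rw.append(c / d if d else math.inf)
            direction = _direction(rm, rw)
            if direction is None and not include_discordant:
                continue
            calls.append(
                EventCall(
                    event_type=(
                        "discordant"
                        if direction is None
                        else ("ES_enhanced" if direction == "up" else "ES_reduced")
                    ),
                    gene_id=g,
                    feature_index=model.exon_tx_index(k),
                    junction=(skip_key[1], skip_key[2]),
                    per_replicate_p=ps,
                    per_replicate_ratio_mut=rm,
                    per_replicate_ratio_wt=rw,
                    significant=direction is not None
                    and all(p < alpha for p in ps),
                )
            )
    return calls


def _variant_families(
    model: GeneModel, samples: Sequence[SampleCounts]
) -> list[tuple[int, JunctionKey, list[tuple[int, int]]]]:
    """Per intron: (genomic index, annotated key, observed variant junctions
    sharing exactly one end with it, excluding annotated and skip junctions)."""
    g = model.gene_id
    annotated = derive_junctions(model)
    annotated_set = {(j.donor_end, j.acceptor_start) for j in annotated}
    skips = {(j.donor_end, j.acceptor_start) for j in skip_junctions(model)}
    observed: set[tuple[int, int]] = set()
    for s in samples:
        for (gid, d, a), n in s.junction_reads.items():
            if gid == g and n > 0:
                observed.add((d, a))
    fams = []
    for gi, j in enumerate(annotated):
        variants = [
            (d, a)
            for (d, a) in sorted(observed)
            if ((d == j.donor_end) != (a == j.acceptor_start))
            and (d, a) not in annotated_set
            and (d, a) not in skips
        ]
        fams.append((gi, j, variants))
    return fams


def scan_alt_splice_sites(
    wt: Sequence[SampleCounts],
    mut: Sequence[SampleCounts],
    models: GeneModelSet,
    alpha: float = 0.01,
    pairing: str = "index",
    include_discordant: bool = False,
) -> list[EventCall]:
    """Per observed junction variant of an annotated intron, two Fisher tests
    per replicate pair: variant reads vs reads of the intron's other
    junctions, and variant reads vs the gene's unique read count.

    An event is significant only if both p-values are below alpha in every
    pair.  A5SS/A3SS labeling is strand-aware (which splice site differs from
    the annotated junction); enhanced/reduced follows the variant/gene-count
    ratio.  Variants of genes with a zero unique read count in any replicate
    are skipped.
    """
    pairs = _pairs(wt, mut, pairing)
    all_samples = list(wt) + list(mut)
    calls: list[EventCall] = []
    for model in models:
        g = model.gene_id
        if model.n_introns == 0:
            continue
        for gi, ann, variants in _variant_families(model, all_samples):
            if not variants:
                continue
            family = [(ann.donor_end, ann.acceptor_start)] + variants

            def jn(sc: SampleCounts, key: tuple[int, int]) -> float:
                return float(sc.junction_reads.get((g, key[0], key[1]), 0))

            for v in variants:
                others = [k for k in family if k != v]
                ps1, ps2, rm, rw = [], [], [], []
                skip = False
                for wt_side, m in pairs:
                    gm = float(m.gene_unique_reads.get(g, 0))
                    gw = _mean(
                        [float(w.gene_unique_reads.get(g, 0)) for w in wt_side]
                    )
                    if gm == 0 or gw == 0:
                        skip = True
                        break
                    vm, vw = jn(m, v), _mean([jn(w, v) for w in wt_side])
                    om = sum(jn(m, k) for k in others)
                    ow = _mean(
                        [sum(jn(w, k) for k in others) for w in wt_side]
                    )
                    ps1.append(fisher2x2(ContingencyTable2x2(vm, om, vw, ow)))
                    ps2.append(fisher2x2(ContingencyTable2x2(vm, gm, vw, gw)))
                    rm.append(vm / gm)
                    rw.append(vw / gw)
                if skip:
                    logger.debug(
                        "variant %s of %s skipped: zero gene count", v, g
                    )
                    continue
                direction = _direction(rm, rw)
                if direction is None and not include_discordant:
                    continue
                if v[0] != ann.donor_end:
                    site = "A5SS" if model.strand == "+" else "A3SS"
                else:
                    site = "A3SS" if model.strand == "+" else "A5SS"
                if direction is None:
                    event_type = "discordant"
                else:
                    label = "enhanced" if direction == "up" else "reduced"
                    event_type = f"{site}_{label}"
                calls.append(
                    EventCall(
                        event_type=event_type,
                        gene_id=g,
                        feature_index=model.intron_tx_index(gi),
                        junction=v,
                        per_replicate_p=ps1,
                        per_replicate_ratio_mut=rm,
                        per_replicate_ratio_wt=rw,
                        significant=direction is not None
                        and all(p < alpha for p in ps1)
                        and all(p < alpha for p in ps2),
                        per_replicate_p2=ps2,
                    )
                )
    return calls


def summarize_events(calls_by_contrast: dict[str, list[EventCall]]) -> dict:
    """Summary table material: per-contrast counts of significant events per
    type, genes with multiple significant retained introns, and cross-contrast
    shared (gene, feature, type) events."""
    summary: dict = {"contrasts": {}, "shared": {}}
    sig_keys: dict[str, set] = {}
    for name, calls in calls_by_contrast.items():
        sig = [c for c in calls if c.significant]
        per_type: dict[str, int] = defaultdict(int)
        ir_genes: dict[str, int] = defaultdict(int)
        for c in sig:
            per_type[c.event_type] += 1
            if c.event_type == "IR":
                ir_genes[c.gene_id] += 1
        multi = {g: n for g, n in ir_genes.items() if n > 1}
        summary["contrasts"][name] = {
            "events_per_type": dict(sorted(per_type.items())),
            "n_significant": len(sig),
            "multi_intron_ir_genes": len(multi),
            "multi_intron_ir_events": sum(multi.values()),
        }
        sig_keys[name] = {(c.event_type, c.gene_id, c.feature_index) for c in sig}
    names = sorted(sig_keys)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            summary["shared"][f"{n1}|{n2}"] = len(sig_keys[n1] & sig_keys[n2])
    return summary
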