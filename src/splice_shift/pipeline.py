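"""End-to-end orchestration: config parsing, stage execution, TSV outputs.

All stage outputs are pure functions of (inputs, config); timings and
versions go only into run_report.json so the tables are rerun-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import GeneModelSet, parse_gene_models, write_models_tsv
from .counting import (
    DEFAULT_ANCHOR,
    SampleCounts,
    count_sample,
    read_counts,
    stream_alignments,
)
from .events import (
    EventCall,
    scan_alt_splice_sites,
    scan_exon_skipping,
    scan_intron_retention,
    summarize_events,
)
from .normalize import CountMatrix, adjusted_rpkm, call_deg, deg_frame, logcpm, tmm_factors
from .reporter import ReporterModel, quantify_reporter

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    annotation: Path
    sample_sheet: Path
    out_dir: Path
    min_identity: float = 0.90
    alpha: float = 0.01
    min_abs_lfc: float = 0.6
    trim_m: float = 0.30
    trim_a: float = 0.05
    pairing: str = "index"
    anchor: int = DEFAULT_ANCHOR
    control_group: str = "wt"
    representative: str = "first"
    reporter: ReporterModel | None = None
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity outside [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha outside (0, 1)")
        if self.min_abs_lfc < 0:
            raise ValueError("min_abs_lfc negative")
        if self.pairing not in ("index", "pooled"):
            raise ValueError(f"unknown pairing {self.pairing!r}")
        for name in ("annotation", "sample_sheet"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        base = path.parent
        paths = cfg.get("paths", {})
        params = cfg.get("params", {})
        reporter = None
        if "reporter" in cfg:
            r = cfg["reporter"]
            reporter = ReporterModel(
                gene_id=r["gene_id"],
                chrom=r["chrom"],
                outer=tuple(r["outer"]),
                inner=tuple(r["inner"]),
                outer_intron_index=int(r.get("outer_intron_index", 0)),
            )
        return cls(
            annotation=base / paths["annotation"],
            sample_sheet=base / paths["sample_sheet"],
            out_dir=base / paths.get("out_dir", "out"),
            reporter=reporter,
            raw=cfg,
            **{
                k: params[k]
                for k in (
                    "min_identity",
                    "alpha",
                    "min_abs_lfc",
                    "trim_m",
                    "trim_a",
                    "pairing",
                    "anchor",
                    "control_group",
                    "representative",
                )
                if k in params
            },
        )

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "path"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return sheet


def load_sample(
    path: Path, sample_id: str, models: GeneModelSet, config: RunConfig
) -> SampleCounts:
    """Counts from a TSV directory, or from a SAM file via the counting stage."""
    if path.is_dir():
        return read_counts(path, sample_id=sample_id)
    return count_sample(
        stream_alignments(path, min_identity=config.min_identity),
        models,
        sample_id=sample_id,
        anchor=config.anchor,
    )


def events_frame(calls: list[EventCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "event_type": c.event_type,
                "gene_id": c.gene_id,
                "feature_index": c.feature_index,
                "junction": (
                    f"{c.junction[0]}-{c.junction[1]}" if c.junction else ""
                ),
                "p_values": ",".join(f"{p:.6g}" for p in c.per_replicate_p),
                "p2_values": ",".join(f"{p:.6g}" for p in c.per_replicate_p2),
                "ratios_mut": ",".join(
                    f"{r:.6g}" for r in c.per_replicate_ratio_mut
                ),
                "ratios_wt": ",".join(
                    f"{r:.6g}" for r in c.per_replicate_ratio_wt
                ),
                "significant": c.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_type",
            "gene_id",
            "feature_index",
            "junction",
            "p_values",
            "p2_values",
            "ratios_mut",
            "ratios_wt",
            "significant",
        ],
    )


def scan_all_events(
    wt: list[SampleCounts],
    mut: list[SampleCounts],
    models: GeneModelSet,
    alpha: float,
    pairing: str,
) -> list[EventCall]:
    calls = scan_intron_retention(wt, mut, models, alpha=alpha, pairing=pairing)
    calls += scan_exon_skipping(wt, mut, models, alpha=alpha, pairing=pairing)
    calls += scan_alt_splice_sites(wt, mut, models, alpha=alpha, pairing=pairing)
    return calls


def run_pipeline(config: RunConfig) -> dict:
    """count -> normalize/DEG -> event scans -> reporter quant, writing TSVs.

    Returns the run report (also written as run_report.json)."""
    t0 = time.time()
    timings: dict[str, float] = {}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def mark(start=time.time()):
            timings[name] = round(time.time() - start, 3)

        return mark

    try:
        mark = stage("annotation")
        with open(config.annotation) as fh:
            models = parse_gene_models(fh, representative=config.representative)
        with open(out / "models.tsv", "w") as fh:
            write_models_tsv(models, fh)
        mark()

        mark = stage("counting")
        sheet = read_sample_sheet(config.sample_sheet)
        base = Path(config.sample_sheet).parent
        samples: dict[str, SampleCounts] = {}
        groups: dict[str, list[str]] = {}
        for _, row in sheet.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            samples[row["sample_id"]] = load_sample(
                p, row["sample_id"], models, config
            )
            groups.setdefault(row["group"], []).append(row["sample_id"])
        if config.control_group not in groups:
            raise ValueError(
                f"control group {config.control_group!r} absent from sheet"
            )
        mark()

        mark = stage("normalization_deg")
        gene_ids = sorted(m.gene_id for m in models)
        counts = pd.DataFrame(
            {
                sid: [samples[sid].gene_reads.get(g, 0) for g in gene_ids]
                for sid in samples
            },
            index=gene_ids,
        )
        lengths = pd.Series(
            {g: models[g].length_nt for g in gene_ids}, name="length"
        )
        cm = CountMatrix(counts, gene_lengths=lengths)
        factors = tmm_factors(cm, trim_m=config.trim_m, trim_a=config.trim_a)
        rpkm = adjusted_rpkm(logcpm(cm, factors), lengths)
        deg_counts = {}
        control = groups[config.control_group]
        for group, members in sorted(groups.items()):
            if group == config.control_group:
                continue
            results = call_deg(
                rpkm[control],
                rpkm[members],
                alpha=config.alpha,
                min_abs_lfc=config.min_abs_lfc,
            )
            frame = deg_frame(results)
            frame.to_csv(out / f"deg_{group}.tsv", sep="\t")
            deg_counts[group] = int(frame["called"].sum())
        mark()

        mark = stage("events")
        wt_counts = [samples[s] for s in control]
        calls_by_contrast: dict[str, list[EventCall]] = {}
        deg_overlap = {}
        for group, members in sorted(groups.items()):
            if group == config.control_group:
                continue
            calls = scan_all_events(
                wt_counts,
                [samples[s] for s in members],
                models,
                alpha=config.alpha,
                pairing=config.pairing,
            )
            calls_by_contrast[group] = calls
            events_frame(calls).to_csv(
                out / f"events_{group}.tsv", sep="\t", index=False
            )
            deg_table = pd.read_csv(
                out / f"deg_{group}.tsv", sep="\t", index_col=0
            )
            deg_genes = set(deg_table.index[deg_table["called"]])
            event_genes = {c.gene_id for c in calls if c.significant}
            deg_overlap[group] = len(deg_genes & event_genes)
        summary = summarize_events(calls_by_contrast)
        summary["deg_called"] = deg_counts
        summary["deg_event_gene_overlap"] = deg_overlap
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        mark()

        mark = stage("reporter")
        if config.reporter is not None:
            rows = []
            for sid in samples:
                q = quantify_reporter(samples[sid], config.reporter)
                u, gtag, atac = q.counts
                pu, pg, pa = q.proportions
                rows.append(
                    {
                        "sample_id": sid,
                        "n_unspliced": u,
                        "n_gtag": gtag,
                        "n_atac": atac,
                        "p_unspliced": round(pu, 6),
                        "p_gtag": round(pg, 6),
                        "p_atac": round(pa, 6),
                    }
                )
            pd.DataFrame(rows).to_csv(
                out / "reporter.tsv", sep="\t", index=False
            )
        mark()
    except Exception as exc:
        failed = set(timings)
        all_stages = ["annotation", "counting", "normalization_deg", "events", "reporter"]
        current = next((s for s in all_stages if s not in failed), "unknown")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "timings_s": timings,
        "total_s": round(time.time() - t0, 3),
        "n_genes": len(models),
        "n_samples": len(samples),
        "summary": summary,
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
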