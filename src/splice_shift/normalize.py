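"""TMM normalization, logCPM, length-adjusted RPKM, and the t-test DEG rule.

The DEG rule is deliberately the raw one used upstream of this package's
event calls: two-sided t-test p < 0.01 and |log2 fold-change| >= 0.6, with no
multiple-testing correction.  Only the logCPM transform of voom is applied;
precision weights are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Genes x samples integer counts with library sizes and gene lengths."""

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise ValueError("library_sizes missing for some samples")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def genes(self) -> pd.Index:
        return self.counts.index


@dataclass(frozen=True)
class DEGResult:
    gene_id: str
    log_fc: float
    p_value: float
    called: bool


def _pick_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    # sample whose upper-quartile count fraction is closest to the mean
    uq = np.array(
        [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: int | str | None = None,
) -> pd.Series:
    """Trimmed mean of M-values normalization factors, geometric mean 1.

    For each sample, genes expressed in both it and the reference contribute a
    log-ratio M and abundance A (library-size-scaled); the extreme trim_m of
    M-values and trim_a of A-values are trimmed and the rest averaged with
    inverse asymptotic-variance weights.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes.to_numpy(dtype=float)
    n_genes, n_samples = counts.shape
    if n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    zero_cols = np.where(lib == 0)[0]
    if zero_cols.size:
        raise ValueError(
            f"all-zero sample(s): {list(cm.samples[zero_cols])}"
        )
    if ref is None:
        r = _pick_reference(counts, lib)
    elif isinstance(ref, str):
        r = int(cm.samples.get_loc(ref))
    else:
        r = int(ref)

    yr, nr = counts[:, r], lib[r]
    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == r:
            continue
        yj, nj = counts[:, j], lib[j]
        keep = (yj > 0) & (yr > 0)
        if not keep.any():
            raise ValueError(
                f"no genes co-expressed between {cm.samples[j]} and reference"
            )
        pj, pr = yj[keep] / nj, yr[keep] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # near-identical samples: trimmed mean of ~0 either way
        if np.allclose(m, m[0]):
            log_factors[j] = m[0]
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any():
            log_factors[j] = 0.0
            continue
        w = 1.0 / (
            (nj - yj[keep][sel]) / (nj * yj[keep][sel])
            + (nr - yr[keep][sel]) / (nr * yr[keep][sel])
        )
        log_factors[j] = float(np.sum(w * m[sel]) / np.sum(w))
    factors = 2.0 ** (log_factors - log_factors.mean())
    return pd.Series(factors, index=cm.samples, name="tmm_factor")


def logcpm(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """log2 counts per million with the voom offsets (count+0.5, lib*f+1)."""
    lib = cm.library_sizes.to_numpy(dtype=float)
    f = factors.reindex(cm.samples).to_numpy(dtype=float)
    eff = lib * f + 1.0
    return pd.DataFrame(
        np.log2((cm.counts.to_numpy(dtype=float) + 0.5) / eff * 1e6),
        index=cm.genes,
        columns=cm.samples,
    )


def adjusted_rpkm(
    logcpm_matrix: pd.DataFrame, gene_lengths_nt: pd.Series
) -> pd.DataFrame:
    """Length-adjusted logCPM: subtract log2(length/1000) per gene.

    Genes without a length are dropped with a diagnostic.
    """
    lengths = gene_lengths_nt.reindex(logcpm_matrix.index)
    missing = lengths.index[lengths.isna() | (lengths <= 0)]
    if len(missing):
        logger.warning(
            "dropping %d gene(s) without a valid length (e.g. %s)",
            len(missing),
            list(missing[:3]),
        )
    kept = logcpm_matrix.drop(index=missing)
    adj = np.log2(lengths.drop(index=missing).astype(float) / 1000.0)
    return kept.sub(adj, axis=0)


def call_deg(
    rpkm_group_a: pd.DataFrame,
    rpkm_group_b: pd.DataFrame,
    alpha: float = 0.01,
    min_abs_lfc: float = 0.6,
    equal_var: bool = False,
) -> list[DEGResult]:
    """Per-gene two-sided t-test on log-scale adjusted RPKM.

    log_fc = mean(group B) - mean(group A); called iff p < alpha and
    |log_fc| >= min_abs_lfc (boundary inclusive).  Welch's test by default.
    """
    if rpkm_group_a.shape[1] < 2 or rpkm_group_b.shape[1] < 2:
        raise ValueError("each group needs at least two replicates")
    genes = rpkm_group_a.index.intersection(rpkm_group_b.index)
    a = rpkm_group_a.loc[genes].to_numpy(dtype=float)
    b = rpkm_group_b.loc[genes].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    log_fc = b.mean(axis=1) - a.mean(axis=1)
    # degenerate zero-variance genes: equal means carry no evidence
    degenerate = np.isnan(p)
    p = np.where(degenerate & (log_fc == 0), 1.0, p)
    p = np.where(degenerate & (log_fc != 0), 0.0, p)
    results = [
        DEGResult(
            gene_id=str(g),
            log_fc=float(lfc),
            p_value=float(pv),
            called=bool(pv < alpha and abs(lfc) >= min_abs_lfc),
        )
        for g, lfc, pv in zip(genes, log_fc, p)
    ]
    return results


def deg_frame(results: list[DEGResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.log_fc, r.p_value, r.called) for r in results],
        columns=["gene_id", "log_fc", "p_value", "called"],
    ).set_index("gene_id")
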