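"""Growth-correlated gene-expression metrics and diversity summaries.

Two complementary metrics quantify how a gene's expression tracks growth
rate:

* the *subpopulation* metric — log2(FPKM in the fast-growing sorted bin)
  minus log2(FPKM in the slow bin) of one isogenic culture, capturing
  cell-to-cell heterogeneity;
* the *mean-population* metric — the difference between a gene's average
  log2 microarray ratio across fast chemostat conditions (dilution rate
  0.3 / h) and across slow conditions (0.05 / h), capturing the classical
  growth-rate response of whole cultures.

Comparing the two separates genes whose expression follows growth state per
cell from genes that only respond to environmentally imposed growth changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FAST_DILUTION_RATE = 0.3  # / h
SLOW_DILUTION_RATE = 0.05  # / h
DEFAULT_PSEUDOCOUNT = 0.1  # FPKM added before log2 to remove zeros
DEFAULT_FPKM_BANDS = (5.0, 30.0)  # low / medium / high expression bands


@dataclass
class ExpressionTable:
    """Gene x sample expression matrix with per-gene annotations.

    ``values`` is genes (index) x samples (columns); ``mode`` is "fpkm"
    (non-negative abundances) or "log2_ratio" (signed ratios to a common
    reference, chemostat style).  Annotations are optional: named gene sets,
    a gene -> replicon map and a gene -> conservation score map.
    """

    values: pd.DataFrame
    mode: str = "fpkm"
    gene_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    replicon: pd.Series | None = None
    conservation: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fpkm", "log2_ratio"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.mode == "fpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")
        for name, members in self.gene_sets.items():
            self.gene_sets[name] = frozenset(members)
            unknown = self.gene_sets[name] - set(self.values.index)
            if unknown:
                raise ValueError(
                    f"gene set {name!r} refers to unknown genes: {sorted(unknown)[:5]}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class GrowthExpressionMetric:
    """Per-gene log2 fast-over-slow expression change."""

    values: pd.Series  # index: gene ids
    source: str  # "subpopulation" | "mean_population"
    pseudocount: float = 0.0


@dataclass
class GeneSetShift:
    """Signed two-sample KS shift of a gene set against the remaining genes."""

    statistic: float  # KS D, signed by median(set) - median(rest)
    pvalue: float
    n_set: int
    n_rest: int
    median_difference: float
    low_power: bool = False


@dataclass
class MetricComparison:
    n_shared: int
    pearson_r: float
    pearson_p: float
    per_set_r: dict[str, float]
    per_set_shift: dict[str, tuple[GeneSetShift, GeneSetShift]]
    quadrants: pd.Series  # per-gene label
    quadrant_counts: dict[str, int]


def subpop_metric(
    table: ExpressionTable,
    fast_sample: str,
    slow_sample: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> GrowthExpressionMetric:
    """log2(FPKM_fast + c) - log2(FPKM_slow + c) per gene.

    The pseudocount ``c`` removes zeros; with c = 0 any zero FPKM is an
    error (named genes reported).  Antisymmetric under swapping the fast
    and slow samples.
    """
    if table.mode != "fpkm":
        raise ValueError("subpopulation metric requires an FPKM-mode table")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    fast = table.values[fast_sample].astype(float)
    slow = table.values[slow_sample].astype(float)
    if pseudocount == 0:
        zero = table.genes[(fast == 0) | (slow == 0)]
        if len(zero):
            raise ValueError(
                f"zero FPKM with pseudocount 0 for genes: {list(zero[:10])}"
            )
    vals = np.log2(fast + pseudocount) - np.log2(slow + pseudocount)
    return GrowthExpressionMetric(vals.rename("subpop_metric"), "subpopulation", pseudocount)


def meanpop_metric(
    ratios: pd.DataFrame,
    condition_rates: Mapping[str, float],
    fast_rate: float = FAST_DILUTION_RATE,
    slow_rate: float = SLOW_DILUTION_RATE,
) -> GrowthExpressionMetric:
    """Mean fast-condition log2 ratio minus mean slow-condition log2 ratio.

    ``ratios`` is a gene x condition table of log2(sample/reference)
    signals; ``condition_rates`` maps condition label -> chemostat dilution
    rate (/h).  Genes missing (NaN) in any required condition are excluded
    with a log entry, mirroring microarray missingness.
    """
    fast_conds = [c for c in ratios.columns if condition_rates.get(c) == fast_rate]
    slow_conds = [c for c in ratios.columns if condition_rates.get(c) == slow_rate]
    if not fast_conds or not slow_conds:
        raise ValueError(
            f"need at least one condition at each of {fast_rate}/h and {slow_rate}/h"
        )
    sub = ratios[fast_conds + slow_conds]
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        logger.info(
            "excluding %d genes with missing values in required conditions",
            int((~complete).sum()),
        )
    sub = sub[complete]
    vals = sub[fast_conds].mean(axis=1) - sub[slow_conds].mean(axis=1)
    return GrowthExpressionMetric(vals.rename("meanpop_metric"), "mean_population")


def gene_set_shift(
    metric: GrowthExpressionMetric | pd.Series, set_members: Iterable[str]
) -> GeneSetShift:
    """Distributional shift of a gene set's metric values vs all other genes.

    Two-sample Kolmogorov-Smirnov test of the set against the complement,
    with the D statistic signed by the sign of the median difference
    (positive = set shifted up).  Single-gene sets are computed but flagged
    low power.
    """
    values = metric.values if isinstance(metric, GrowthExpressionMetric) else metric
    members = frozenset(set_members)
    if not members:
        raise ValueError("empty gene set")
    in_set = values.index.isin(members)
    if in_set.all():
        raise ValueError("gene set equals the full gene universe; no background")
    if not in_set.any():
        raise ValueError("no gene-set members present in the metric")
    a = values[in_set].to_numpy(float)
    b = values[~in_set].to_numpy(float)
    ks = stats.ks_2samp(a, b, method="auto")
    med_diff = float(np.median(a) - np.median(b))
    sign = 1.0 if med_diff >= 0 else -1.0
    return GeneSetShift(
        statistic=sign * float(ks.statistic),
        pvalue=float(ks.pvalue),
        n_set=len(a),
        n_rest=len(b),
        median_difference=med_diff,
        low_power=len(a) < 3,
    )


def compare_metrics(
    m1: GrowthExpressionMetric,
    m2: GrowthExpressionMetric,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
) -> MetricComparison:
    """Scatter-style comparison of two growth-expression metrics.

    Pearson r over shared genes, per-gene-set restricted correlations, the
    signed KS shift of each set under both metrics, and per-gene quadrant
    labels (concordant/discordant up/down) for scatter exports.
    """
    shared = m1.values.index.intersection(m2.values.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    x = m1.values.loc[shared].astype(float)
    y = m2.values.loc[shared].astype(float)
    r, p = stats.pearsonr(x, y)

    quad = pd.Series("concordant_up", index=shared, name="quadrant")
    quad[(x < 0) & (y < 0)] = "concordant_down"
    quad[(x >= 0) & (y < 0)] = "discordant_x_up"
    quad[(x < 0) & (y >= 0)] = "discordant_y_up"

    per_set_r: dict[str, float] = {}
    per_set_shift: dict[str, tuple[GeneSetShift, GeneSetShift]] = {}
    for name, members in (gene_sets or {}).items():
        members = frozenset(members) & set(shared)
        if len(members) >= 3:
            idx = shared.isin(members)
            per_set_r[name] = float(stats.pearsonr(x[idx], y[idx])[0])
        if members and len(members) < len(shared):
            per_set_shift[name] = (
                gene_set_shift(pd.Series(x), members),
                gene_set_shift(pd.Series(y), members),
            )
    return MetricComparison(
        n_shared=len(shared),
        pearson_r=float(r),
        pearson_p=float(p),
        per_set_r=per_set_r,
        per_set_shift=per_set_shift,
        quadrants=quad,
        quadrant_counts=quad.value_counts().to_dict(),
    )


def expressed_gene_counts(
    table: ExpressionTable, band_edges: Sequence[float] = DEFAULT_FPKM_BANDS
) -> pd.DataFrame:
    """Number of genes per FPKM band per sample.

    Bands are half-open [lo, hi) over ``(-inf, *band_edges, inf)``; the
    defaults give low (<5), medium [5, 30) and high (>=30) FPKM bands.
    """
    if table.mode != "fpkm":
        raise ValueError("band counts require an FPKM-mode table")
    edges = list(band_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("band edges must be strictly increasing")
    full = [-np.inf, *edges, np.inf]
    labels = []
    for lo, hi in zip(full[:-1], full[1:]):
        if np.isinf(lo):
            labels.append(f"<{hi:g}")
        elif np.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"[{lo:g},{hi:g})")
    out = {}
    for sample in table.samples:
        v = table.values[sample].to_numpy(float)
        counts = [((v >= lo) & (v < hi)).sum() for lo, hi in zip(full[:-1], full[1:])]
        out[sample] = counts
    return pd.DataFrame(out, index=labels)


def concentration_curve(table: ExpressionTable, sample: str) -> pd.DataFrame:
    """Cumulative fraction of the transcriptome vs gene rank.

    Genes are sorted by descending FPKM; point k is
    (k/N, sum of top-k FPKM / total FPKM).  The curve is monotone, concave
    and ends at (1, 1); a steep initial rise means few genes dominate the
    transcriptome.
    """
    if table.mode != "fpkm":
        raise ValueError("concentration curve requires an FPKM-mode table")
    v = np.sort(table.values[sample].to_numpy(float))[::-1]
    total = v.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r} has zero total expression")
    n = len(v)
    return pd.DataFrame(
        {
            "rank_fraction": np.arange(1, n + 1) / n,
            "cumulative_fraction": np.cumsum(v) / total,
        }
    )


def classify_by_mean_expression(
    table: ExpressionTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Label genes high / mid / low by mean log expression across samples.

    A gene is "high" if its mean log2(FPKM + c) across all samples exceeds
    the across-genes mean by more than one s.d., "low" if it falls more
    than one s.d. below, else "mid".  Labels are invariant under a global
    rescaling of FPKM (a log-scale shift cancels in the z-score).  With
    zero spread (all genes equal) every gene is "mid".
    """
    if table.mode != "fpkm":
        raise ValueError("classification requires an FPKM-mode table")
    if len(table.genes) < 2:
        raise ValueError("need >= 2 genes for an s.d.")
    mean_log = np.log2(table.values.astype(float) + pseudocount).mean(axis=1)
    mu = mean_log.mean()
    sd = mean_log.std(ddof=1)
    labels = pd.Series("mid", index=table.genes, name="expression_class")
    if sd > 0:
        labels[mean_log > mu + sd] = "high"
        labels[mean_log < mu - sd] = "low"
    return labels


def replicon_fold_change(
    metric: GrowthExpressionMetric | pd.Series,
    replicon_map: Mapping[str, str] | pd.Series,
    core_replicons: Iterable[str],
) -> pd.DataFrame:
    """Median metric value per replicon, with z-scores vs the core set.

    Each gene belongs to one replicon (nuclear chromosome, mitochondrion,
    2-micron plasmid, virus).  The per-replicon median fold change is
    compared against the mean and s.d. of the medians of the
    ``core_replicons`` (normally the 16 nuclear chromosomes); selfish
    elements showing strong shifts stand out as large |z|.
    """
    values = metric.values if isinstance(metric, GrowthExpressionMetric) else metric
    rep = pd.Series(dict(replicon_map)) if not isinstance(replicon_map, pd.Series) else replicon_map
    rep = rep.reindex(values.index)
    missing = values.index[rep.isna()]
    if len(missing):
        logger.info("%d genes lack a replicon assignment; excluded", len(missing))
    df = pd.DataFrame({"value": values, "replicon": rep}).dropna(subset=["replicon"])
    med = df.groupby("replicon")["value"].agg(["median", "size"])
    med.columns = ["median", "n_genes"]
    core = [c for c in core_replicons if c in med.index]
    if not core:
        raise ValueError("no core replicon has any genes")
    core_medians = med.loc[core, "median"]
    mu = core_medians.mean()
    sd = core_medians.std(ddof=1) if len(core) > 1 else 0.0
    med["core"] = med.index.isin(core)
    if sd > 0:
        med["z"] = (med["median"] - mu) / sd
    else:
        med["z"] = np.where(med["median"] == mu, 0.0, np.inf * np.sign(med["median"] - mu))
    med.attrs["core_mean"] = float(mu)
    med.attrs["core_sd"] = float(sd)
    return med.reset_index()


def read_expression_table(
    path_or_buf,
    mode: str = "fpkm",
    annotation: pd.DataFrame | None = None,
) -> ExpressionTable:
    """Load a TSV gene x sample table (first column gene ids, header row).

    ``annotation``, if given, is a frame indexed by gene id with optional
    boolean gene-set columns (prefix ``set_``), a ``replicon`` column and a
    ``conservation`` column.
    """
    values = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    gene_sets: dict[str, frozenset[str]] = {}
    replicon = conservation = None
    if annotation is not None:
        for col in annotation.columns:
            if col.startswith("set_"):
                members = annotation.index[annotation[col].astype(bool)]
                gene_sets[col[4:]] = frozenset(members)
        if "replicon" in annotation.columns:
            replicon = annotation["replicon"]
        if "conservation" in annotation.columns:
            conservation = annotation["conservation"].astype(float)
    return ExpressionTable(values, mode, gene_sets, replicon, conservation)
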