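"""Transcriptome error-rate estimation from samtools-mpileup text.

Aligned RNA-seq reads are summarised per genomic position in pileup format;
the fraction of read bases disagreeing with the reference genome — after
discarding presumed genomic variants — estimates the combined
transcription/RT/PCR/sequencing error rate per sequenced base.  Because
per-position error counts are tiny relative to coverage, rates are only
meaningful pooled over many positions (whole transcriptome, one transcript,
one coverage bin, one conservation stratum).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence, TextIO

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# characters that, when absent, allow the fast counting path
_SPECIALS = set("^$+-*<>Nn")


class PileupParseError(ValueError):
    """Raised for malformed pileup lines in strict mode."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class PileupSite(NamedTuple):
    """One genomic position of a pileup.

    ``base_counts`` is (A, C, G, T) pooled over strands; ``depth`` is the
    declared read depth (includes deletion '*' and reference-skip symbols,
    which are excluded from both ``match_count`` and ``mismatch_count``).
    Sites whose reference base is N are flagged ``excluded`` and carry zero
    mismatches.
    """

    chrom: str
    pos: int
    ref_base: str
    depth: int
    match_count: int
    mismatch_count: int
    base_counts: tuple[int, int, int, int]
    excluded: bool = False

    @property
    def mismatch_fraction(self) -> float:
        return self.mismatch_count / self.depth if self.depth else 0.0


@dataclass
class ErrorRateEstimate:
    """Pooled mismatch rate over a set of retained sites."""

    total_bases: int
    total_mismatches: int
    rate: float
    n_sites_retained: int
    n_sites_discarded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate {self.rate} outside [0, 1]")


@dataclass
class CoverageBin:
    """Sites pooled over one or more adjacent exact-depth groups."""

    coverage_levels: tuple[int, ...]
    n_positions: int
    total_bases: int
    total_mismatches: int
    rate: float
    truncated: bool = False  # last bin absorbed a short remainder


@dataclass
class BatchBaseline:
    """Per-lab technical baseline and baseline-relative rates.

    Raw error rates are dominated by lab-specific technical error (library
    prep, sequencer chemistry), so cross-lab comparisons divide each
    experiment's rate by the mean rate of its lab.
    """

    batch_id: str
    member_rates: dict[str, float]
    baseline: float = field(init=False)
    relative_rates: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.member_rates:
            raise ValueError(f"batch {self.batch_id!r} has no experiments")
        self.baseline = float(np.mean(list(self.member_rates.values())))
        if self.baseline <= 0:
            raise ValueError(f"batch {self.batch_id!r} baseline is not positive")
        self.relative_rates = {
            k: v / self.baseline for k, v in self.member_rates.items()
        }


def _parse_base_string(bases: str, ref: str, line_number: int | None) -> tuple[int, int, list[int], int]:
    """Walk the pileup base-string grammar character by character.

    Returns (match, mismatch, [A,C,G,T] counts, n_read_symbols) where
    n_read_symbols additionally counts '*' '<' '>' placeholders.
    """
    match = 0
    counts = [0, 0, 0, 0]
    symbols = 0
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c in ".,":
            match += 1
            symbols += 1
            i += 1
        elif c == "^":
            if i + 1 >= n:
                raise PileupParseError("dangling '^' read-start marker", line_number)
            i += 2  # ^ plus mapping-quality char
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError("indel marker without length", line_number)
            length = int(bases[i + 1 : j])
            if j + length > n:
                raise PileupParseError("indel length exceeds base string", line_number)
            i = j + length
        elif c in "*<>":
            symbols += 1
            i += 1
        else:
            u = c.upper()
            if u in _BASE_INDEX:
                counts[_BASE_INDEX[u]] += 1
                symbols += 1
                i += 1
            elif u == "N":
                symbols += 1  # ambiguous read base: neither match nor mismatch
                i += 1
            else:
                raise PileupParseError(f"unknown pileup symbol {c!r}", line_number)
    ref_u = ref.upper()
    if ref_u in _BASE_INDEX:
        # '.'/',' already encode matches; explicit ref letters would be
        # non-standard but are folded in for robustness
        match += counts[_BASE_INDEX[ref_u]]
        counts[_BASE_INDEX[ref_u]] = 0
    mismatch = sum(counts)
    return match, mismatch, counts, symbols


def _fast_counts(bases: str, ref: str) -> tuple[int, int, list[int]]:
    match = bases.count(".") + bases.count(",")
    counts = [
        bases.count("A") + bases.count("a"),
        bases.count("C") + bases.count("c"),
        bases.count("G") + bases.count("g"),
        bases.count("T") + bases.count("t"),
    ]
    ref_u = ref.upper()
    if ref_u in _BASE_INDEX:
        match += counts[_BASE_INDEX[ref_u]]
        counts[_BASE_INDEX[ref_u]] = 0
    return match, sum(counts), counts


def parse_pileup(stream: TextIO | Iterable[str] | str, *, strict: bool = True) -> Iterator[PileupSite]:
    """Parse samtools-mpileup 6-column text into :class:`PileupSite` records.

    ``stream`` may be an open text handle, an iterable of lines, a path, or
    raw pileup text containing newlines.  In strict mode malformed lines
    (bad indel length, non-numeric position/depth, read-symbol count
    disagreeing with the declared depth) raise :class:`PileupParseError`;
    in tolerant mode they are skipped with a log entry (declared-depth
    disagreement keeps the parsed counts).
    """
    close = False
    if isinstance(stream, str):
        if "\n" in stream or "\t" in stream:
            stream = stream.splitlines()
        else:
            stream = (
                gzip.open(stream, "rt") if stream.endswith(".gz") else open(stream)
            )
            close = True
    try:
        for lineno, line in enumerate(stream, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                err = PileupParseError(
                    f"expected >=5 tab-separated fields, got {len(fields)}", lineno
                )
                if strict:
                    raise err
                logger.warning("skipping: %s", err)
                continue
            chrom, pos_s, ref, depth_s, bases = fields[:5]
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError:
                err = PileupParseError("non-numeric pos or depth", lineno)
                if strict:
                    raise err
                logger.warning("skipping: %s", err)
                continue
            ref = ref.upper()
            if ref == "N":
                yield PileupSite(chrom, pos, "N", depth, 0, 0, (0, 0, 0, 0), excluded=True)
                continue
            try:
                if _SPECIALS.isdisjoint(bases):
                    match, mismatch, counts = _fast_counts(bases, ref)
                    symbols = len(bases)
                else:
                    match, mismatch, counts, symbols = _parse_base_string(
                        bases, ref, lineno
                    )
            except PileupParseError as err:
                if strict:
                    raise
                logger.warning("skipping: %s", err)
                continue
            if symbols != depth:
                err = PileupParseError(
                    f"declared depth {depth} but {symbols} read symbols parsed", lineno
                )
                if strict:
                    raise err
                logger.warning("keeping parsed counts: %s", err)
                depth = symbols
            yield PileupSite(chrom, pos, ref, depth, match, mismatch, tuple(counts))
    finally:
        if close:
            stream.close()


def filter_genomic_variants(
    sites: Iterable[PileupSite], *, max_mismatch_fraction: float = 0.5
) -> tuple[list[PileupSite], list[PileupSite]]:
    """Split sites into (retained, discarded) by the genomic-variant rule.

    A site is discarded iff strictly more than ``max_mismatch_fraction`` of
    its reads mismatch the reference — such positions are presumed fixed
    genetic differences between the sequenced strain and the reference, not
    transcription errors.  Exactly-half sites are retained.
    """
    retained: list[PileupSite] = []
    discarded: list[PileupSite] = []
    for s in sites:
        if s.excluded or s.depth == 0:
            discarded.append(s)
        elif s.mismatch_count > max_mismatch_fraction * s.depth:
            discarded.append(s)
        else:
            retained.append(s)
    return retained, discarded


def iter_retained(
    sites: Iterable[PileupSite], *, max_mismatch_fraction: float = 0.5
) -> Iterator[PileupSite]:
    """Lazy counterpart of :func:`filter_genomic_variants` (retained only)."""
    for s in sites:
        if s.excluded or s.depth == 0:
            continue
        if s.mismatch_count > max_mismatch_fraction * s.depth:
            continue
        yield s


def transcriptome_error_rate(sites: Iterable[PileupSite]) -> ErrorRateEstimate:
    """Pooled error rate: total mismatches / total read depth over sites.

    Applied to all retained sites this is the transcriptome-wide rate;
    applied to the sites inside one annotated transcript it is that
    transcript's rate.
    """
    bases = 0
    mismatches = 0
    n = 0
    for s in sites:
        bases += s.depth
        mismatches += s.mismatch_count
        n += 1
    if n == 0 or bases == 0:
        raise ValueError("no sites with positive depth; error rate undefined")
    return ErrorRateEstimate(
        total_bases=bases,
        total_mismatches=mismatches,
        rate=mismatches / bases,
        n_sites_retained=n,
    )


def estimate_error_rate(
    stream: TextIO | Iterable[str] | str,
    *,
    strict: bool = False,
    apply_variant_filter: bool = True,
    max_mismatch_fraction: float = 0.5,
) -> ErrorRateEstimate:
    """Streaming parse -> variant filter -> pooled rate for large inputs.

    Memory-flat: sites are never materialised.  Equivalent to composing
    :func:`parse_pileup`, :func:`filter_genomic_variants` and
    :func:`transcriptome_error_rate`.
    """
    bases = mismatches = n_ret = n_disc = 0
    for s in parse_pileup(stream, strict=strict):
        is_variant = s.mismatch_count > max_mismatch_fraction * s.depth
        if s.excluded or s.depth == 0 or (apply_variant_filter and is_variant):
            n_disc += 1
            continue
        bases += s.depth
        mismatches += s.mismatch_count
        n_ret += 1
    if n_ret == 0 or bases == 0:
        raise ValueError("no usable sites in pileup stream")
    return ErrorRateEstimate(bases, mismatches, mismatches / bases, n_ret, n_disc)


def per_coverage_error_rate(
    sites: Iterable[PileupSite], min_positions: int = 100_000
) -> list[CoverageBin]:
    """Error rate stratified by read depth.

    Sites are grouped by exact depth; adjacent depth levels (increasing) are
    merged greedily until every bin holds at least ``min_positions``
    positions, with any short remainder attached to the last full bin
    (flagged ``truncated``).  A depth-independent error process yields a
    flat rate profile across bins.
    """
    groups: dict[int, list[int]] = {}
    for s in sites:
        g = groups.setdefault(s.depth, [0, 0, 0])
        g[0] += 1
        g[1] += s.depth
        g[2] += s.mismatch_count
    if not groups:
        raise ValueError("no sites supplied")
    total_positions = sum(g[0] for g in groups.values())
    if total_positions < min_positions:
        logger.warning(
            "only %d positions (< %d): returning a single coverage bin",
            total_positions,
            min_positions,
        )
    bins: list[CoverageBin] = []
    levels: list[int] = []
    npos = nbase = nmm = 0
    for depth in sorted(groups):
        g = groups[depth]
        levels.append(depth)
        npos += g[0]
        nbase += g[1]
        nmm += g[2]
        if npos >= min_positions:
            bins.append(CoverageBin(tuple(levels), npos, nbase, nmm, nmm / nbase))
            levels, npos, nbase, nmm = [], 0, 0, 0
    if levels:
        if bins:
            last = bins[-1]
            merged_levels = last.coverage_levels + tuple(levels)
            npos += last.n_positions
            nbase += last.total_bases
            nmm += last.total_mismatches
            bins[-1] = CoverageBin(
                merged_levels, npos, nbase, nmm, nmm / nbase, truncated=True
            )
        else:
            bins.append(
                CoverageBin(tuple(levels), npos, nbase, nmm, nmm / nbase, truncated=True)
            )
    return bins


def relative_error_rate(
    experiment_rates: Mapping[str, float], batches: Mapping[str, str]
) -> dict[str, BatchBaseline]:
    """Normalise per-experiment rates by their lab's mean rate.

    ``batches`` maps experiment id -> batch (lab) id; every experiment must
    be assigned.  Within each batch the mean of the relative rates is 1 by
    construction, making rates comparable across labs with different
    technical baselines.
    """
    unassigned = set(experiment_rates) - set(batches)
    if unassigned:
        raise ValueError(f"experiments without a batch: {sorted(unassigned)}")
    for exp, rate in experiment_rates.items():
        if rate <= 0:
            raise ValueError(f"experiment {exp!r} has non-positive rate {rate}")
    by_batch: dict[str, dict[str, float]] = {}
    for exp, rate in experiment_rates.items():
        by_batch.setdefault(batches[exp], {})[exp] = rate
    return {bid: BatchBaseline(bid, members) for bid, members in by_batch.items()}


# ---------------------------------------------------------------------------
# annotation-aware stratification


def read_gff_transcripts(
    path_or_buf, feature_types: Sequence[str] = ("gene", "transcript", "mRNA")
) -> pd.DataFrame:
    """Read transcript/gene intervals from GFF3 (1-based closed intervals).

    Returns a frame with columns chrom, start, end, strand, gene_id; the
    gene id is taken from the ID= or gene_id attribute.
    """
    df = pd.read_csv(
        path_or_buf,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chrom", "source", "type", "start", "end",
            "score", "strand", "frame", "attributes",
        ],
        dtype={"chrom": str},
    )
    df = df[df["type"].isin(feature_types)].copy()

    def _gene_id(attrs: str) -> str:
        for part in str(attrs).split(";"):
            part = part.strip()
            for key in ("ID=", "gene_id=", "Name="):
                if part.startswith(key):
                    return part[len(key):].strip('"')
            if part.startswith("gene_id "):
                return part.split(None, 1)[1].strip('"')
        return str(attrs)

    df["gene_id"] = df["attributes"].map(_gene_id)
    return df[["chrom", "start", "end", "strand", "gene_id"]].reset_index(drop=True)


def _interval_index(annotation: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples(index=False):
        # GFF intervals are closed; IntervalTree is half-open on the right
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end + 1, row.gene_id
        )
    return trees


def per_gene_error_rate(
    sites: Iterable[PileupSite], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Pooled rate per annotated gene (sites outside all genes dropped)."""
    trees = _interval_index(annotation)
    acc: dict[str, list[int]] = {}
    for s in sites:
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        for iv in tree.at(s.pos):
            g = acc.setdefault(iv.data, [0, 0, 0])
            g[0] += 1
            g[1] += s.depth
            g[2] += s.mismatch_count
    rows = [
        {
            "gene_id": gene,
            "n_sites": g[0],
            "total_bases": g[1],
            "total_mismatches": g[2],
            "rate": g[2] / g[1] if g[1] else float("nan"),
        }
        for gene, g in acc.items()
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "n_sites", "total_bases", "total_mismatches", "rate"]
    )


def stratified_error_rate(
    sites: Iterable[PileupSite],
    annotation: pd.DataFrame,
    gene_scores: Mapping[str, float],
    expression: Mapping[str, float] | None = None,
    n_bins: int = 4,
    top_expression_quantile: float | None = None,
) -> pd.DataFrame:
    """Error rate stratified by a per-gene score (e.g. conservation).

    Genes are placed in ``n_bins`` quantile bins of ``gene_scores``
    (optionally restricted first to genes above the ``top_expression_quantile``
    of ``expression``); each bin's rate pools mismatches and bases over all
    member genes' sites.  Genes with no covered sites are dropped with a log
    entry.
    """
    per_gene = per_gene_error_rate(sites, annotation)
    scored = per_gene[per_gene["gene_id"].isin(gene_scores)].copy()
    missing_sites = set(gene_scores) - set(per_gene["gene_id"])
    if missing_sites:
        logger.info("%d scored genes have no covered sites", len(missing_sites))
    if top_expression_quantile is not None:
        if expression is None:
            raise ValueError("expression required for quantile restriction")
        expr = scored["gene_id"].map(expression)
        cutoff = expr.quantile(1.0 - top_expression_quantile)
        scored = scored[expr >= cutoff]
    if scored.empty:
        raise ValueError("no genes left to stratify")
    scores = scored["gene_id"].map(gene_scores)
    scored["score"] = scores
    scored["bin"] = pd.qcut(scores.rank(method="first"), n_bins, labels=False)
    out = (
        scored.groupby("bin")
        .agg(
            n_genes=("gene_id", "size"),
            score_lo=("score", "min"),
            score_hi=("score", "max"),
            total_bases=("total_bases", "sum"),
            total_mismatches=("total_mismatches", "sum"),
        )
        .reset_index()
    )
    out["rate"] = out["total_mismatches"] / out["total_bases"]
    return out
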