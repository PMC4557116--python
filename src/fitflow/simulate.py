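"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding
analysis assumes — pileups with a planted per-base error rate and planted
genomic variants, FPKM tables with planted gene-set effects and a planted
cross-metric correlation, brightfield/GFP time-lapse stacks of
exponentially growing dark colonies, and Gaussian-mixture growth-rate
samples — and returns a truth table sufficient to score the downstream
estimates.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .imaging import ImageStack

_ALTS = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass
class TruthTable:
    """Planted parameters and per-entity ground truth of one generator run."""

    generator: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    records: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# pileup


def gen_pileup(
    genome_length: int,
    depth_model: tuple[float, float] = (30.0, 0.3),
    error_rate: float = 1e-4,
    n_variant_positions: int = 0,
    seed: int = 0,
    chrom: str = "chrS",
    dialect_marker_rate: float = 0.01,
    fixed_depth: int | None = None,
    out: TextIO | str | None = None,
) -> tuple[str | None, TruthTable]:
    """Synthetic samtools-mpileup text with a planted per-base error rate.

    Per position, depth is negative-binomial with the given (mean,
    dispersion) — dispersion is the NB ``alpha`` so variance = m + alpha*m^2
    — or ``fixed_depth`` when set.  Mismatching reads are binomial at
    ``error_rate`` with the substituted base uniform over the three
    alternatives; ``n_variant_positions`` random positions emit 100%
    mismatching reads (homozygous strain differences).  A small fraction of
    lines carries pileup dialect markers (read starts/ends, indels) to
    exercise parsers.  If ``out`` is a path or handle the text is streamed
    there and None is returned in its place.
    """
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    if n_variant_positions > genome_length:
        raise ValueError("more variant positions than genome positions")
    rng = np.random.default_rng(seed)
    if fixed_depth is not None:
        depths = np.full(genome_length, fixed_depth, dtype=np.int64)
    else:
        mean, alpha = depth_model
        if alpha > 0:
            r = 1.0 / alpha
            p = r / (r + mean)
            depths = rng.negative_binomial(r, p, size=genome_length)
        else:
            depths = rng.poisson(mean, size=genome_length)
        depths = np.maximum(depths, 1)
    refs = rng.choice(list("ACGT"), size=genome_length)
    mismatches = rng.binomial(depths, error_rate)
    variant_pos = rng.choice(genome_length, size=n_variant_positions, replace=False)
    is_variant = np.zeros(genome_length, dtype=bool)
    is_variant[variant_pos] = True
    mismatches[is_variant] = depths[is_variant]
    marked = rng.random(genome_length) < dialect_marker_rate
    # pre-draw alt bases for the (rare) mismatching sites
    close = False
    if isinstance(out, str):
        out = open(out, "w")
        close = True
    buf = out if out is not None else io.StringIO()
    try:
        write = buf.write
        for i in range(genome_length):
            d = int(depths[i])
            m = int(mismatches[i])
            ref = refs[i]
            k = (d - m + 1) // 2
            bases = "." * k + "," * (d - m - k)
            if m:
                alts = _ALTS[ref]
                picks = rng.integers(0, 3, size=m)
                bases += "".join(alts[p] for p in picks)
            if marked[i] and d >= 1:
                # read start on the first read, an insertion, and a read end
                bases = "^I" + bases[:1] + "+2AT" + bases[1:] + "$"
            write(f"{chrom}\t{i + 1}\t{ref}\t{d}\t{bases}\t{'I' * d}\n")
    finally:
        if close:
            buf.close()
    truth = TruthTable(
        "gen_pileup",
        seed,
        params={
            "genome_length": genome_length,
            "error_rate": error_rate,
            "depth_model": depth_model,
            "fixed_depth": fixed_depth,
            "n_variant_positions": n_variant_positions,
            "total_depth": int(depths.sum()),
            "total_planted_mismatches": int(mismatches[~is_variant].sum()),
            "variant_positions": sorted(int(p) + 1 for p in variant_pos),
        },
    )
    text = buf.getvalue() if isinstance(buf, io.StringIO) else None
    return text, truth


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    n_genes: int = 5000,
    set_specs: dict[str, tuple[int, float]] | None = None,
    noise_sd: float = 0.5,
    cross_metric_r: float = 0.3,
    seed: int = 0,
    baseline_log2_mean: float = 5.0,
    baseline_log2_sd: float = 2.0,
    n_conditions_per_rate: int = 6,
    condition_noise_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Synthetic FPKM bins and chemostat log2-ratio tables.

    ``set_specs`` maps gene-set name -> (size, effect in log2 units); the
    effect is added to the fast-vs-slow contrast of both metrics (positive
    = up in fast growth, e.g. ribosomal genes; negative = up in slow, e.g.
    stress genes).  Outside the planted effects the subpopulation and
    mean-population signals are bivariate normal with correlation
    ``cross_metric_r`` and s.d. ``noise_sd``.  Baseline log2 FPKM is normal
    (heavy-tailed on the linear scale) so concentration curves are
    realistically skewed.

    Returns (FPKM table with slow/mid/fast columns, chemostat log2-ratio
    table with ``rate0.05_*`` / ``rate0.3_*`` condition columns, truth).
    """
    set_specs = set_specs or {}
    if sum(size for size, _ in set_specs.values()) > n_genes:
        raise ValueError("gene-set sizes exceed n_genes")
    if not -1.0 <= cross_metric_r <= 1.0:
        raise ValueError("cross_metric_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)

    effects = np.zeros(n_genes)
    membership: dict[str, list[str]] = {}
    cursor = 0
    for name, (size, effect) in set_specs.items():
        idx = slice(cursor, cursor + size)
        effects[idx] = effect
        membership[name] = genes[cursor : cursor + size]
        cursor += size

    cov = np.array([[1.0, cross_metric_r], [cross_metric_r, 1.0]]) * noise_sd**2
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes)
    m_sub = effects + z[:, 0]  # subpopulation log2 fast/slow contrast
    m_mean = effects + z[:, 1]  # mean-population contrast

    fpkm = pd.DataFrame(
        {
            "slow": 2.0 ** (baseline - m_sub / 2),
            "mid": 2.0**baseline,
            "fast": 2.0 ** (baseline + m_sub / 2),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    chemo = {}
    for rate, sign in ((0.05, -1.0), (0.3, +1.0)):
        for rep in range(n_conditions_per_rate):
            col = f"rate{rate}_{rep}"
            chemo[col] = sign * m_mean / 2 + rng.normal(
                0.0, condition_noise_sd, size=n_genes
            )
    chemo = pd.DataFrame(chemo, index=fpkm.index)
    records = pd.DataFrame(
        {
            "gene_id": genes,
            "baseline_log2": baseline,
            "effect": effects,
            "true_subpop_metric": m_sub,
            "true_meanpop_metric": m_mean,
        }
    ).set_index("gene_id")
    truth = TruthTable(
        "gen_expression",
        seed,
        params={
            "n_genes": n_genes,
            "set_specs": dict(set_specs),
            "noise_sd": noise_sd,
            "cross_metric_r": cross_metric_r,
            "condition_rates": {c: (0.05 if c.startswith("rate0.05") else 0.3) for c in chemo.columns},
            "gene_sets": membership,
        },
        records=records,
    )
    return fpkm, chemo, truth


# ---------------------------------------------------------------------------
# time-lapse imaging


@dataclass
class ColonySpec:
    row: float
    col: float
    rate_per_hour: float
    initial_area_px: float


def _disk_coverage(shape, row, col, radius):
    r0 = max(int(np.floor(row - radius - 2)), 0)
    r1 = min(int(np.ceil(row + radius + 2)) + 1, shape[0])
    c0 = max(int(np.floor(col - radius - 2)), 0)
    c1 = min(int(np.ceil(col + radius + 2)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - row, cc - col)
    cov = np.clip(radius - dist + 0.5, 0.0, 1.0)  # anti-aliased edge
    return (slice(r0, r1), slice(c0, c1)), cov


def gen_timelapse(
    n_colonies: int = 15,
    rate_range: tuple[float, float] = (0.15, 0.40),
    frame_interval_minutes: float = 60.0,
    n_frames: int = 13,
    image_shape: tuple[int, int] = (1200, 1200),
    noise_sd: float = 4.0,
    collision_plan: Sequence[tuple[int, int, int]] | None = None,
    focus_plan: Sequence[int] | None = None,
    seed: int = 0,
    final_area_px: float = 6000.0,
    background: float = 200.0,
    colony_intensity: float = 60.0,
    gfp_background: float = 100.0,
    gfp_colony: float = 180.0,
    gfp_noise_sd: float = 3.0,
) -> tuple[ImageStack, ImageStack, TruthTable]:
    """Brightfield + GFP stacks of exponentially growing dark disk colonies.

    Colony areas follow A(t) = A0 * exp(rate * t) with rates drawn uniformly
    from ``rate_range``; initial areas are set per colony so that every
    colony reaches ``final_area_px`` at the last frame, keeping all colonies
    well-resolved at the frames that dominate the max-slope fit.  Colonies
    are rendered as anti-aliased dark disks on a brighter noisy background;
    the truth mask (coverage > 0.5) defines the planted per-frame areas.

    ``collision_plan`` entries (i, j, frame) place colonies i and j so their
    disks first overlap at that frame.  ``focus_plan`` lists colony indices
    that receive a single Rad52-style bright GFP pixel (set to frame mean +
    10 s.d.).  The GFP channel otherwise carries a uniform histone-like
    signal over each colony.
    """
    rng = np.random.default_rng(seed)
    lo, hi = rate_range
    rates = rng.uniform(lo, hi, size=n_colonies)
    total_h = (n_frames - 1) * frame_interval_minutes / 60.0
    a0 = final_area_px * np.exp(-rates * total_h)
    final_radius = np.sqrt(final_area_px / np.pi)

    # place colonies on a jittered grid with margins for their final size
    jig = 40.0  # max positional jitter, px
    margin = final_radius + jig + 5
    n_side = int(np.ceil(np.sqrt(n_colonies)))
    pitch_r = (image_shape[0] - 2 * margin) / max(n_side - 1, 1)
    pitch_c = (image_shape[1] - 2 * margin) / max(n_side - 1, 1)
    if n_colonies > 1 and min(pitch_r, pitch_c) - 2 * jig < 2 * final_radius + 6:
        raise ValueError("colonies do not fit in the frame at final size")
    positions = []
    for k in range(n_colonies):
        gr, gc = divmod(k, n_side)
        positions.append(
            (
                margin + gr * pitch_r + rng.uniform(-jig, jig),
                margin + gc * pitch_c + rng.uniform(-jig, jig),
            )
        )
    colonies = [
        ColonySpec(row=p[0], col=p[1], rate_per_hour=float(r), initial_area_px=float(a))
        for p, r, a in zip(positions, rates, a0)
    ]

    collision_plan = list(collision_plan or [])
    for i, j, frame in collision_plan:
        if not (0 < frame < n_frames):
            raise ValueError("collision frame outside the stack")
        # move colony j so that the two disks first overlap at `frame`;
        # size both so they are already large then (a clean >3 px gap one
        # frame earlier needs radii comparable to the final size)
        t_c = frame * frame_interval_minutes / 60.0
        t_p = (frame - 1) * frame_interval_minutes / 60.0
        for k in (i, j):
            colonies[k] = ColonySpec(
                row=colonies[k].row,
                col=colonies[k].col,
                rate_per_hour=colonies[k].rate_per_hour,
                initial_area_px=float(
                    final_area_px * np.exp(-colonies[k].rate_per_hour * t_c)
                ),
            )
        ri_c = np.sqrt(colonies[i].initial_area_px * np.exp(colonies[i].rate_per_hour * t_c) / np.pi)
        rj_c = np.sqrt(colonies[j].initial_area_px * np.exp(colonies[j].rate_per_hour * t_c) / np.pi)
        ri_p = np.sqrt(colonies[i].initial_area_px * np.exp(colonies[i].rate_per_hour * t_p) / np.pi)
        rj_p = np.sqrt(colonies[j].initial_area_px * np.exp(colonies[j].rate_per_hour * t_p) / np.pi)
        d = 0.5 * ((ri_c + rj_c) + (ri_p + rj_p))  # between the two touch radii
        if d <= ri_p + rj_p + 3:
            raise ValueError(
                "planned collision too abrupt: colonies already adjacent one frame earlier"
            )
        ang = np.arctan2(colonies[j].row - colonies[i].row, colonies[j].col - colonies[i].col)
        colonies[j] = ColonySpec(
            row=colonies[i].row + d * np.sin(ang),
            col=colonies[i].col + d * np.cos(ang),
            rate_per_hour=colonies[j].rate_per_hour,
            initial_area_px=colonies[j].initial_area_px,
        )

    focus_plan = list(focus_plan or [])
    timestamps = np.arange(n_frames) * frame_interval_minutes
    bf = np.empty((n_frames, *image_shape))
    gfp = np.empty((n_frames, *image_shape))
    truth_rows = []
    for f in range(n_frames):
        t_h = timestamps[f] / 60.0
        frame = background + rng.normal(0.0, noise_sd, size=image_shape)
        gframe = gfp_background + rng.normal(0.0, gfp_noise_sd, size=image_shape)
        for ci, spec in enumerate(colonies):
            area = spec.initial_area_px * np.exp(spec.rate_per_hour * t_h)
            radius = np.sqrt(area / np.pi)
            box, cov = _disk_coverage(image_shape, spec.row, spec.col, radius)
            frame[box] = frame[box] * (1 - cov) + colony_intensity * cov
            mask = cov > 0.5
            gframe[box][mask] = gfp_colony + rng.normal(
                0.0, gfp_noise_sd, size=int(mask.sum())
            )
            truth_rows.append(
                {
                    "colony": ci,
                    "frame": f,
                    "time_minutes": float(timestamps[f]),
                    "true_area_px": int(mask.sum()),
                    "analytic_area_px": float(area),
                    "row": spec.row,
                    "col": spec.col,
                }
            )
        for ci in focus_plan:
            spec = colonies[ci]
            mu, sd = gframe.mean(), gframe.std()
            gframe[int(round(spec.row)), int(round(spec.col))] = mu + 10 * sd
        bf[f] = frame
        gfp[f] = gframe
    records = pd.DataFrame(truth_rows)
    collision_times = {
        (i, j): frame * frame_interval_minutes for i, j, frame in collision_plan
    }
    truth = TruthTable(
        "gen_timelapse",
        seed,
        params={
            "n_colonies": n_colonies,
            "rates_per_hour": [c.rate_per_hour for c in colonies],
            "initial_areas_px": [c.initial_area_px for c in colonies],
            "positions": [(c.row, c.col) for c in colonies],
            "collision_times_minutes": collision_times,
            "focus_colonies": focus_plan,
            "frame_interval_minutes": frame_interval_minutes,
        },
        records=records,
    )
    return (
        ImageStack(bf, timestamps, "brightfield"),
        ImageStack(gfp, timestamps, "fluorescence"),
        truth,
    )


# ---------------------------------------------------------------------------
# growth-rate mixtures


def analytic_slow_fraction(mixture: Sequence[tuple[float, float, float]]) -> float:
    """Oracle slow fraction of a Gaussian mixture via the exact CDF tangent.

    Finds the mixture's density maximum x0 numerically, takes the true
    tangent t(x) = F(x0) + f(x0) (x - x0), and returns
    max(0, F(x_lo) - (1 - F(x_hi))) from the exact mixture CDF.
    """
    w = np.array([m[0] for m in mixture])
    mu = np.array([m[1] for m in mixture])
    sd = np.array([m[2] for m in mixture])
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture weights must be >= 0 and sum to 1")
    if np.any(sd <= 0):
        raise ValueError("degenerate mixture component (sd <= 0)")

    def pdf(x):
        return np.sum(w * stats.norm.pdf(x, mu, sd))

    def cdf(x):
        return float(np.sum(w * stats.norm.cdf(x, mu, sd)))

    # densest component's mean is a good bracket centre for the global mode
    k = int(np.argmax(w / sd))
    res = optimize.minimize_scalar(
        lambda x: -pdf(x),
        bounds=(mu[k] - 4 * sd[k], mu[k] + 4 * sd[k]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    x0 = float(res.x)
    s = pdf(x0)
    f0 = cdf(x0)
    x_lo = x0 - f0 / s
    x_hi = x0 + (1.0 - f0) / s
    return max(0.0, cdf(x_lo) - (1.0 - cdf(x_hi)))


def gen_growth_rates(
    mixture: Sequence[tuple[float, float, float]],
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, TruthTable]:
    """I.i.d. growth rates from a Gaussian mixture [(weight, mean, sd), ...].

    The truth table records the exact mixture and, for non-degenerate
    mixtures, the analytic slow fraction implied by the CDF-tangent
    definition.
    """
    w = np.array([m[0] for m in mixture], dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture weights must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(mixture), size=n, p=w / w.sum())
    mu = np.array([m[1] for m in mixture])
    sd = np.array([m[2] for m in mixture])
    rates = rng.normal(mu[comp], sd[comp])
    try:
        oracle = analytic_slow_fraction(mixture)
    except ValueError:
        oracle = None
    truth = TruthTable(
        "gen_growth_rates",
        seed,
        params={
            "mixture": [tuple(m) for m in mixture],
            "n": n,
            "oracle_slow_fraction": oracle,
        },
        records=pd.DataFrame({"rate": rates, "component": comp}),
    )
    return rates, truth
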