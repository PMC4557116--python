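"""Independent reference implementations used only to cross-check fitflow.

Each oracle is deliberately written with a different mechanism than the
implementation it scores: regex tokenisation vs manual scanning for the
pileup dialect, numpy.polyfit per window vs incremental sums for the
max-slope search, BFS flood fill vs scipy labelling for components.
"""

from __future__ import annotations

import re
from collections import deque

import numpy as np

_TOKEN = re.compile(r"\^.|\$|([+-])(\d+)|[.,*<>]|[ACGTNacgtn]")


def oracle_pileup_counts(bases: str, ref: str) -> tuple[int, int, dict[str, int], int]:
    """(match, mismatch, per-base counts, read symbols) via regex tokens."""
    match = 0
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    symbols = 0
    i = 0
    while i < len(bases):
        m = _TOKEN.match(bases, i)
        if m is None:
            raise ValueError(f"unparseable at {i}: {bases[i:]!r}")
        tok = m.group(0)
        i = m.end()
        if m.group(2):  # indel: skip the inserted/deleted sequence
            i += int(m.group(2))
            continue
        if tok.startswith("^") or tok == "$":
            continue
        if tok in ".,":
            match += 1
            symbols += 1
        elif tok in "*<>":
            symbols += 1
        elif tok.upper() == "N":
            symbols += 1
        else:
            counts[tok.upper()] += 1
            symbols += 1
    r = ref.upper()
    if r in counts:
        match += counts[r]
        counts[r] = 0
    return match, sum(counts.values()), counts, symbols


def random_pileup_line(rng: np.random.Generator, chrom: str = "chrO") -> str:
    """Random well-formed pileup line exercising the full dialect grammar."""
    ref = rng.choice(list("ACGT"))
    depth = int(rng.integers(1, 40))
    parts = []
    symbols = 0
    while symbols < depth:
        roll = rng.random()
        if roll < 0.55:
            tok = rng.choice([".", ","])
        elif roll < 0.85:
            tok = str(rng.choice(list("ACGTacgt")))
        elif roll < 0.92:
            tok = str(rng.choice(["*", "<", ">"]))
        else:
            tok = str(rng.choice(["N", "n"]))
        if rng.random() < 0.08:
            qual = chr(int(rng.integers(33, 90)))
            tok = "^" + qual + tok
        if rng.random() < 0.08:
            n_ins = int(rng.integers(1, 12))
            seq = "".join(rng.choice(list("ACGTacgt"), size=n_ins))
            tok = tok + str(rng.choice(["+", "-"])) + str(n_ins) + seq
        if rng.random() < 0.08:
            tok = tok + "$"
        parts.append(tok)
        symbols += 1
    pos = int(rng.integers(1, 10_000_000))
    return f"{chrom}\t{pos}\t{ref}\t{depth}\t{''.join(parts)}\t{'I' * depth}"


def oracle_max_slope_window(
    times_minutes: np.ndarray,
    areas: np.ndarray,
    min_points: int = 3,
    min_span_minutes: float = 180.0,
    min_r2: float = 0.95,
) -> tuple[float, tuple[float, float], float] | None:
    """Brute-force enumeration of every qualifying window with polyfit.

    Returns (slope per hour, window, r2) of the max-slope qualifying window
    or None.  Flat windows (zero variance of ln area) count as R^2 = 1.
    """
    t = np.asarray(times_minutes, dtype=float)
    y = np.log(np.asarray(areas, dtype=float))
    n = len(t)
    best = None
    for i in range(n):
        for j in range(i + min_points - 1, n):
            if j - i + 1 < min_points or t[j] - t[i] < min_span_minutes:
                continue
            tt, yy = t[i : j + 1], y[i : j + 1]
            slope, intercept = np.polyfit(tt, yy, 1)
            pred = slope * tt + intercept
            ss_res = float(np.sum((yy - pred) ** 2))
            ss_tot = float(np.sum((yy - yy.mean()) ** 2))
            r2 = 1.0 if ss_tot <= 0 else 1.0 - ss_res / ss_tot
            if r2 >= min_r2 and (best is None or slope > best[0]):
                best = (slope, (t[i], t[j]), r2)
    if best is None:
        return None
    return best[0] * 60.0, best[1], best[2]


def flood_fill_components(
    pixels: set[tuple[int, int]], min_area: int = 1
) -> list[frozenset[tuple[int, int]]]:
    """8-connected components of a pixel set by breadth-first flood fill."""
    remaining = set(pixels)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            r, c = queue.popleft()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in remaining:
                        remaining.remove(nb)
                        comp.add(nb)
                        queue.append(nb)
        if len(comp) >= min_area:
            comps.append(frozenset(comp))
    return comps
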