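"""Window-based structural-variant detection from mate-pair discordance.

The detection rule mirrors classic mate-pair SV screens: estimate the
insert-size model from concordant pairs, classify every pair against it,
tile the reference into 1.5 kb windows, and flag windows in which at least
25% of the pairs are discordant (mapping distance exceeding ten standard
deviations above the mean insert, or unexpected strand configuration) with
at least 25% of the window's pairs having partners clustered within 1 kb of
each other.  Discordant pairs from flagged windows are then clustered in
(left, right) coordinate space into typed calls: strand-discordant clusters
indicate an inversion, distance-only clusters a deletion or duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic_data import InsertSizeModel

__all__ = [
    "CONCORDANT",
    "DISTANCE_ANOMALY",
    "ORIENTATION_ANOMALY",
    "ONE_END_UNMAPPED",
    "InsertEstimationError",
    "SVCall",
    "estimate_insert_model",
    "classify_pair",
    "classify_pairs",
    "call_sv_windows",
    "refine_breakpoints",
]

CONCORDANT = "concordant"
DISTANCE_ANOMALY = "distance_anomaly"
ORIENTATION_ANOMALY = "orientation_anomaly"
ONE_END_UNMAPPED = "one_end_unmapped"


class InsertEstimationError(ValueError):
    """Too few usable pairs, or a degenerate span distribution."""


@dataclass(frozen=True)
class SVCall:
    """A typed rearrangement call with breakpoint intervals."""

    svtype: str  # "inversion" | "deletion_or_duplication"
    breakpoint_a: tuple[int, int]
    breakpoint_b: tuple[int, int]
    size: int
    support: int
    windows: tuple[int, ...]
    pair_index: tuple[int, ...] = ()
    refined: bool = False
    fallback: bool = False

    @staticmethod
    def _mid(iv: tuple[int, int]) -> float:
        return (iv[0] + iv[1]) / 2.0


def estimate_insert_model(
    records: pd.DataFrame,
    read_len: int = 50,
    expected_orientation: str = "same_strand",
    trim: tuple[float, float] = (0.01, 0.99),
    min_pairs: int = 1000,
) -> InsertSizeModel:
    """Fit the insert model from expected-orientation, both-mapped pairs.

    Mean and sd come from the span distribution trimmed at the given
    quantiles, which removes junction-spanning outliers without needing to
    know where the junctions are.
    """
    both = records[records["mapped1"] & records["mapped2"]]
    if expected_orientation == "same_strand":
        ok = both["strand1"] == both["strand2"]
    else:
        ok = both["strand1"] != both["strand2"]
    spans = both.loc[ok, "inferred_span"].to_numpy(dtype=float)
    if len(spans) < min_pairs:
        raise InsertEstimationError(
            f"need >= {min_pairs} expected-orientation pairs, got {len(spans)}"
        )
    lo, hi = np.quantile(spans, trim)
    kept = spans[(spans >= lo) & (spans <= hi)]
    mu, sd = float(np.mean(kept)), float(np.std(kept))
    if sd == 0.0:
        raise InsertEstimationError("degenerate span distribution (zero variance)")
    return InsertSizeModel(
        mean=mu, sd=sd, read_len=read_len, expected_orientation=expected_orientation
    )


def classify_pairs(
    records: pd.DataFrame,
    model: InsertSizeModel,
    sd_mult: float = 10.0,
    symmetric: bool = True,
) -> pd.Series:
    """Vectorised pair classification (see :func:`classify_pair`)."""
    both = records["mapped1"] & records["mapped2"]
    if model.expected_orientation == "same_strand":
        orient_ok = records["strand1"] == records["strand2"]
    else:
        orient_ok = records["strand1"] != records["strand2"]
    span = records["inferred_span"]
    upper = span > model.mean + sd_mult * model.sd  # strictly exceeding
    lower = span < model.mean - sd_mult * model.sd
    dist_bad = upper | (lower if symmetric else False)

    out = pd.Series(CONCORDANT, index=records.index)
    out[dist_bad] = DISTANCE_ANOMALY
    out[~orient_ok] = ORIENTATION_ANOMALY
    out[~both] = ONE_END_UNMAPPED
    return out


def classify_pair(
    record, model: InsertSizeModel, sd_mult: float = 10.0, symmetric: bool = True
) -> str:
    """Classify one mate pair against the insert model.

    Orientation anomalies take precedence over distance anomalies; a span of
    exactly mean + sd_mult*sd is still concordant (the threshold is strict).
    """
    if not (record.mapped1 and record.mapped2):
        return ONE_END_UNMAPPED
    same = record.strand1 == record.strand2
    expected_same = model.expected_orientation == "same_strand"
    if same != expected_same:
        return ORIENTATION_ANOMALY
    if record.inferred_span > model.mean + sd_mult * model.sd:
        return DISTANCE_ANOMALY
    if symmetric and record.inferred_span < model.mean - sd_mult * model.sd:
        return DISTANCE_ANOMALY
    return CONCORDANT


def _largest_cluster(values: np.ndarray, radius: float) -> tuple[int, float, float]:
    """Largest single-linkage 1-D cluster; returns (size, lo, hi)."""
    if len(values) == 0:
        return 0, np.nan, np.nan
    v = np.sort(values)
    breaks = np.where(np.diff(v) > radius)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(v)]))
    sizes = ends - starts
    i = int(np.argmax(sizes))
    return int(sizes[i]), float(v[starts[i]]), float(v[ends[i] - 1])


def _cluster_2d(left: np.ndarray, right: np.ndarray, radius: float) -> np.ndarray:
    """Single-linkage clustering with Chebyshev radius; returns labels."""
    n = len(left)
    order = np.argsort(left, kind="stable")
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    ol, orr = left[order], right[order]
    for i in range(n):
        j = i + 1
        while j < n and ol[j] - ol[i] <= radius:
            if abs(orr[j] - orr[i]) <= radius:
                union(order[i], order[j])
            j += 1
    return np.array([find(i) for i in range(n)])


def call_sv_windows(
    records: pd.DataFrame,
    model: InsertSizeModel,
    window: int = 1500,
    min_frac: float = 0.25,
    cluster_radius: int = 1000,
    min_pairs: int = 4,
    sd_mult: float = 10.0,
    symmetric: bool = True,
    frac_of: str = "all",
) -> tuple[list[SVCall], pd.DataFrame]:
    """Windowed discordance screen followed by 2-D pair clustering.

    A window (non-overlapping tile keyed by the pair's leftmost read) is a
    candidate iff its discordant fraction is >= ``min_frac`` *and* at least
    ``min_frac`` of its pairs (of all pairs, or of the discordant pairs when
    ``frac_of="discordant"``) have partners within ``cluster_radius`` of each
    other.  Discordant pairs from candidate windows are then single-linkage
    clustered on (left, right) positions; clusters with >= ``min_pairs``
    support become calls, typed by majority strand pattern (ties favour
    inversion, whose orientation evidence is stronger).

    Returns (calls, per-window statistics).
    """
    if frac_of not in ("all", "discordant"):
        raise ValueError("frac_of must be 'all' or 'discordant'")
    cols = ["pos1", "pos2", "mapped1", "mapped2", "strand1", "strand2", "inferred_span"]
    both = records.loc[records["mapped1"] & records["mapped2"], cols].copy()
    if both.empty:
        return [], pd.DataFrame(
            columns=["window", "start", "end", "n_pairs", "n_discordant",
                     "partner_cluster_fraction", "partner_lo", "partner_hi", "candidate"]
        )
    labels = classify_pairs(both, model, sd_mult=sd_mult, symmetric=symmetric)
    both["left"] = np.minimum(both["pos1"], both["pos2"])
    both["right"] = np.maximum(both["pos1"], both["pos2"])
    both["discordant"] = labels.isin([DISTANCE_ANOMALY, ORIENTATION_ANOMALY])
    both["orientation"] = labels == ORIENTATION_ANOMALY
    both["tile"] = both["left"] // window

    stats_rows = []
    candidate_tiles = []
    for tile, grp in both.groupby("tile", sort=True):
        n = len(grp)
        disc = grp[grp["discordant"]]
        n_disc = len(disc)
        cl_size, lo, hi = _largest_cluster(disc["right"].to_numpy(), cluster_radius)
        denom = n if frac_of == "all" else max(n_disc, 1)
        frac_clustered = cl_size / denom
        candidate = (
            n >= min_pairs
            and n_disc / n >= min_frac
            and frac_clustered >= min_frac
        )
        stats_rows.append(
            {
                "window": int(tile),
                "start": int(tile * window),
                "end": int((tile + 1) * window),
                "n_pairs": n,
                "n_discordant": n_disc,
                "partner_cluster_fraction": frac_clustered,
                "partner_lo": lo,
                "partner_hi": hi,
                "candidate": candidate,
            }
        )
        if candidate:
            candidate_tiles.append(tile)
    window_stats = pd.DataFrame(stats_rows)

    cand = both[both["tile"].isin(candidate_tiles) & both["discordant"]]
    calls: list[SVCall] = []
    if not cand.empty:
        left = cand["left"].to_numpy(dtype=float)
        right = cand["right"].to_numpy(dtype=float)
        labels2d = _cluster_2d(left, right, cluster_radius)
        rl = model.read_len
        for lab in np.unique(labels2d):
            mask = labels2d == lab
            if int(mask.sum()) < min_pairs:
                continue
            l, r = left[mask], right[mask]
            n_orient = int(cand["orientation"].to_numpy()[mask].sum())
            svtype = (
                "inversion"
                if n_orient * 2 >= int(mask.sum())
                else "deletion_or_duplication"
            )
            bp_a = (int(l.min()), int(l.max()) + rl)
            bp_b = (int(r.min()), int(r.max()) + rl)
            size = int(round(abs(SVCall._mid(bp_b) - SVCall._mid(bp_a))))
            calls.append(
                SVCall(
                    svtype=svtype,
                    breakpoint_a=bp_a,
                    breakpoint_b=bp_b,
                    size=size,
                    support=int(mask.sum()),
                    windows=tuple(sorted(set((l // window).astype(int)))),
                    pair_index=tuple(cand.index[mask]),
                )
            )
    calls.sort(key=lambda c: (c.breakpoint_a, c.breakpoint_b))
    return calls, window_stats


def _side_interval(
    starts: np.ndarray,
    gaps: np.ndarray,
    max_frag: float,
    read_len: int,
    clip_tol: int,
    at_right_edge: bool,
) -> tuple[float, float]:
    """Per-side junction interval from supporting reads.

    ``at_right_edge`` means the reads approach the junction from the left
    (junction at the right edge of the read cluster); gaps give each pair's
    fragment extent on the other side of the junction.
    """
    if at_right_edge:
        lo = float(np.max(starts + read_len)) - clip_tol
        hi = float(np.min(starts + max_frag - gaps))
    else:
        hi = float(np.min(starts)) + clip_tol
        lo = float(np.max(starts + read_len - max_frag + gaps))
    return lo, hi


def refine_breakpoints(
    call: SVCall,
    records: pd.DataFrame,
    model: InsertSizeModel,
    clip_tol: int = 5,
    sd_mult: float = 3.0,
) -> SVCall:
    """Geometrically narrow a call's breakpoint intervals.

    Each supporting read bounds the junction: it must end before the
    junction (within the clip tolerance), and its fragment -- at most
    mean + ``sd_mult``*sd long -- must still reach its mate on the far side.
    The per-side interval is the intersection of these constraints over all
    supporting pairs; which edge of each read cluster holds the junction is
    inferred from the reads' mate-ward facing (read 1 faces its 3'
    direction, read 2 its 5' direction under same-strand chemistry, both
    face 3' under opposite-strand chemistry), by majority vote.  An empty
    intersection falls back to the original interval, flagged.
    """
    if call.support < 3 or len(call.pair_index) < 3:
        raise ValueError("refinement needs >= 3 supporting pairs")
    sup = records.loc[list(call.pair_index)]
    pos1 = sup["pos1"].to_numpy(dtype=float)
    pos2 = sup["pos2"].to_numpy(dtype=float)
    left = np.minimum(pos1, pos2)
    right = np.maximum(pos1, pos2)
    rl = model.read_len
    max_frag = model.mean + sd_mult * model.sd

    left_is_1 = pos1 <= pos2
    s1 = (sup["strand1"] == "+").to_numpy()
    s2 = (sup["strand2"] == "+").to_numpy()
    left_plus = np.where(left_is_1, s1, s2)
    right_plus = np.where(left_is_1, s2, s1)
    left_is_read1 = left_is_1
    if model.expected_orientation == "same_strand":
        left_faces_right = np.where(left_is_read1, left_plus, ~left_plus)
        right_faces_right = np.where(~left_is_read1, right_plus, ~right_plus)
    else:
        left_faces_right = left_plus
        right_faces_right = right_plus
    # Junction at the right edge of a cluster iff its reads face right.
    a_right = bool(np.mean(left_faces_right) >= 0.5)
    b_right = bool(np.mean(right_faces_right) >= 0.5)

    def edge(xs: np.ndarray, right_edge: bool) -> float:
        return float(np.max(xs + rl)) if right_edge else float(np.min(xs))

    ja, jb = edge(left, a_right), edge(right, b_right)
    gaps_b = (jb - right) if b_right else (right + rl - jb)
    gaps_a = (ja - left) if a_right else (left + rl - ja)
    lo_a, hi_a = _side_interval(left, gaps_b, max_frag, rl, clip_tol, a_right)
    lo_b, hi_b = _side_interval(right, gaps_a, max_frag, rl, clip_tol, b_right)

    def narrowed(new: tuple[float, float], old: tuple[int, int]) -> tuple[tuple[int, int], bool]:
        lo = max(int(np.floor(new[0])), old[0])
        hi = min(int(np.ceil(new[1])), old[1])
        if lo >= hi:
            return old, True
        return (lo, hi), False

    iv_a, fb_a = narrowed((lo_a, hi_a), call.breakpoint_a)
    iv_b, fb_b = narrowed((lo_b, hi_b), call.breakpoint_b)
    size = int(round(abs(SVCall._mid(iv_b) - SVCall._mid(iv_a))))
    return replace(
        call,
        breakpoint_a=iv_a,
        breakpoint_b=iv_b,
        size=size,
        refined=True,
        fallback=fb_a or fb_b,
    )


def calls_to_bedpe(calls: list[SVCall], chrom: str) -> pd.DataFrame:
    """BEDPE-like table of calls."""
    return pd.DataFrame(
        [
            {
                "chrom1": chrom,
                "start1": c.breakpoint_a[0],
                "end1": c.breakpoint_a[1],
                "chrom2": chrom,
                "start2": c.breakpoint_b[0],
                "end2": c.breakpoint_b[1],
                "name": f"{c.svtype}_{i}",
                "size": c.size,
                "support": c.support,
                "refined": c.refined,
            }
            for i, c in enumerate(calls)
        ]
    )
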