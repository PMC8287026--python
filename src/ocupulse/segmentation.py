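"""RPE and choroidal-scleral-interface segmentation of B-scan sequences.

Per frame the stages are:

1. :func:`detect_rpe` — locate the posterior edge of the brightest band in
   each A-scan and smooth the profile across columns.
2. :func:`flatten_frame` — shift every A-scan so the posterior RPE sits on
   one reference row, removing curvature/tilt that would mislead the path
   search; each side of the optic-nerve gap is flattened independently.
3. :func:`find_inflection_nodes` — candidate CSI depths are inflection
   points of the Gaussian-smoothed axial intensity profile below the RPE
   where the transition is dark-to-bright (choroidal vessel into sclera).
4. :func:`build_graph_and_search` — a minimum-cost left-to-right path
   through one candidate per column.  Node cost is ``2 - g_hat`` where
   ``g_hat`` is the dark-to-bright gradient min-max normalised over the
   frame (strong edges are cheap); adjacent choices must satisfy
   ``|depth difference| <= max_jump_px`` per column of separation, and a
   column may be skipped at a fixed penalty (its depth is interpolated),
   which is how off-surface outlier candidates are rejected.
5. :func:`choroidal_thickness` — mean (CSI - RPE) over included columns,
   scaled to micrometres.

Frames are processed independently; temporal structure is handled later by
the waveform stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .datatypes import BScanSequence, SegmentationResult, ThicknessWaveform

__all__ = [
    "SegmentationConfig",
    "FrameUnusableError",
    "detect_rpe",
    "flatten_frame",
    "find_inflection_nodes",
    "build_graph_and_search",
    "choroidal_thickness",
    "segment_sequence",
]


class FrameUnusableError(RuntimeError):
    """Raised when a frame yields no trustworthy segmentation."""


@dataclass
class SegmentationConfig:
    smoothing_sigma: float = 2.0        # axial Gaussian sigma for node detection, px
    max_jump_px: float = 15.0           # max CSI depth step between adjacent columns
    rpe_median_window: int = 15         # cross-column median filter on the RPE profile
    rpe_edge_frac: float = 0.7          # posterior edge = last depth >= frac * band peak
    rpe_contrast_min: float = 2.0       # smoothed peak / column median to count as a band
    max_nodes_per_column: int = 6       # strongest candidates kept per A-scan
    skip_cost: float = 2.5              # penalty for skipping a column with candidates
    max_skip_run: int = 12              # DP lookback, columns
    min_gap_below_rpe_px: int = 6       # exclude the RPE edge itself from CSI candidates
    cost_eps: float = 1e-6


@dataclass
class _NodeSet:
    """Candidate CSI depths per column of one frame (flattened coords)."""

    columns: np.ndarray                      # included column indices with >= 1 node
    depths: list[np.ndarray] = field(default_factory=list)
    grads: list[np.ndarray] = field(default_factory=list)


def detect_rpe(
    frame: np.ndarray,
    on_region: tuple[int, int] = (0, 0),
    config: Optional[SegmentationConfig] = None,
) -> np.ndarray:
    """Posterior-RPE depth per A-scan.

    The RPE is the brightest axial band.  For each included column the
    axial profile is Gaussian-smoothed; the band containing the maximum is
    traced posteriorly until intensity falls below ``rpe_edge_frac`` of the
    band peak — that last row is the posterior edge.  The profile is then
    median-filtered across columns and interpolated through the excluded
    optic-nerve interval.  If more than half of the included columns show
    no sufficiently contrasted band the frame is unusable.
    """
    cfg = config or SegmentationConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    depth, width = frame.shape
    lo, hi = on_region
    included = np.concatenate([np.arange(0, lo), np.arange(hi, width)])
    if included.size == 0:
        raise ValueError("on_region excludes every column")

    smooth = ndimage.gaussian_filter1d(frame, sigma=cfg.smoothing_sigma, axis=0)
    sub = smooth[:, included]
    peaks = sub.max(axis=0)
    argpeaks = sub.argmax(axis=0)
    medians = np.median(sub, axis=0)
    ok = peaks >= cfg.rpe_contrast_min * np.maximum(medians, 1e-9)
    if ok.sum() <= 0.5 * included.size:
        raise FrameUnusableError(
            f"bright band undetectable in {included.size - ok.sum()} of "
            f"{included.size} included columns"
        )

    prof = np.full(width, np.nan)
    thresh = cfg.rpe_edge_frac * peaks
    # walk posteriorly from the band peak to the last row still above threshold
    below = sub < thresh[None, :]
    for j, col in enumerate(included):
        if not ok[j]:
            continue
        after = np.nonzero(below[argpeaks[j]:, j])[0]
        prof[col] = (argpeaks[j] + after[0] - 1) if after.size else (depth - 1)

    # median filter across included columns, then fill gaps by interpolation
    vals = prof[included]
    good = ~np.isnan(vals)
    vals[~good] = np.interp(included[~good], included[good], vals[good])
    vals = ndimage.median_filter(vals, size=cfg.rpe_median_window, mode="nearest")
    prof[included] = vals
    if lo < hi:  # bridge the optic-nerve gap for the flattening reference
        prof[lo:hi] = np.interp(
            np.arange(lo, hi),
            included,
            prof[included],
        )
    return prof


def flatten_frame(
    frame: np.ndarray,
    rpe_depth_px: np.ndarray,
    on_region: tuple[int, int] = (0, 0),
    reference_row: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Shift each included A-scan so its posterior RPE lies on one row.

    Each side of the optic-nerve gap uses the same reference row (the
    median RPE depth rounded), but shifts are computed per column, so the
    two sides are flattened independently of each other's tilt.  Columns
    are shifted with edge padding; the integer shift map is returned for
    inverse mapping (original depth = flattened depth - shift).
    """
    frame = np.asarray(frame, dtype=float)
    depth, width = frame.shape
    lo, hi = on_region
    included = np.concatenate([np.arange(0, lo), np.arange(hi, width)])
    rpe = np.asarray(rpe_depth_px, dtype=float)
    if np.any(np.isnan(rpe[included])):
        raise ValueError("RPE profile undefined on included columns")
    if reference_row is None:
        reference_row = int(round(np.nanmedian(rpe[included])))
    shifts = np.zeros(width, dtype=int)
    shifts[included] = reference_row - np.round(rpe[included]).astype(int)
    if np.any(np.abs(shifts) >= depth):
        raise ValueError("flattening shift exceeds frame depth")
    flat = frame.copy()
    for col in included:
        s = shifts[col]
        if s == 0:
            continue
        column = frame[:, col]
        if s > 0:
            flat[s:, col] = column[:-s]
            flat[:s, col] = column[0]
        else:
            flat[:s, col] = column[-s:]
            flat[s:, col] = column[-1]
    return flat, shifts, reference_row


def find_inflection_nodes(
    ascan: np.ndarray,
    rpe_depth_px: float,
    smoothing_sigma: float = 2.0,
    min_gap_px: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate CSI depths along one A-scan.

    Returns ``(depths, gradients)``: rows below the RPE where the second
    difference of the Gaussian-smoothed profile changes sign while the
    first difference is positive — a dark-to-bright inflection, the
    signature of crossing from choroidal vessel into sclera.  The gradient
    magnitude (first difference at the node) is the edge-strength attribute
    consumed by the path search.  May be empty.
    """
    x = ndimage.gaussian_filter1d(np.asarray(ascan, dtype=float), smoothing_sigma)
    if x.size <= 3:
        raise ValueError("profile too short")
    d1 = np.gradient(x)
    d2 = np.gradient(d1)
    sign_change = d2[:-1] * d2[1:] < 0
    cand = np.nonzero(sign_change)[0]
    start = int(np.floor(rpe_depth_px)) + min_gap_px
    cand = cand[(cand > start) & (cand < x.size - 1)]
    cand = cand[d1[cand] > 0]
    return cand.astype(int), d1[cand]


def _collect_nodes(
    flat: np.ndarray,
    reference_row: int,
    on_region: tuple[int, int],
    cfg: SegmentationConfig,
) -> _NodeSet:
    """Vectorised inflection-node detection over all included columns."""
    depth, width = flat.shape
    lo, hi = on_region
    included = np.concatenate([np.arange(0, lo), np.arange(hi, width)])
    smooth = ndimage.gaussian_filter1d(flat, sigma=cfg.smoothing_sigma, axis=0)
    d1 = np.gradient(smooth, axis=0)
    d2 = np.gradient(d1, axis=0)
    sign_change = d2[:-1, :] * d2[1:, :] < 0
    start = reference_row + cfg.min_gap_below_rpe_px
    mask = np.zeros_like(sign_change)
    if start < depth - 1:
        mask[start + 1:, :] = True
    valid = sign_change & mask & (d1[:-1, :] > 0)

    cols, depths_list, grads_list = [], [], []
    for col in included:
        rows = np.nonzero(valid[:, col])[0]
        if rows.size == 0:
            continue
        g = d1[rows, col]
        if rows.size > cfg.max_nodes_per_column:
            keep = np.argsort(g)[-cfg.max_nodes_per_column:]
            keep.sort()
            rows, g = rows[keep], g[keep]
        cols.append(col)
        depths_list.append(rows)
        grads_list.append(g)
    return _NodeSet(columns=np.array(cols, dtype=int), depths=depths_list, grads=grads_list)


def build_graph_and_search(
    nodes_per_column: list,
    grads_per_column: Optional[list] = None,
    max_jump_px: float = 15.0,
    skip_cost: float = 2.5,
    max_skip_run: int = 12,
    cost_eps: float = 1e-6,
    columns: Optional[np.ndarray] = None,
    return_cost: bool = False,
):
    """Minimum-cost surface through one candidate per column.

    ``nodes_per_column[i]`` are candidate depths for the i-th column with
    gradient attributes ``grads_per_column[i]``; ``columns`` gives the true
    column indices (defaults to 0..n-1) so gaps widen the allowed jump
    proportionally.  Node cost is ``2 - g_hat + eps`` with g_hat the
    min-max-normalised gradient over all candidates; skipping a column
    costs ``skip_cost`` and its depth is linearly interpolated afterwards.
    Transitions with ``|depth difference| > max_jump_px * column gap`` are
    forbidden.  Returns per-column depths (NaN where nothing could be
    assigned), and optionally the optimal path cost for oracle comparison.

    Raises :class:`FrameUnusableError` when no feasible path selects at
    least two nodes.
    """
    n = len(nodes_per_column)
    if columns is None:
        columns = np.arange(n)
    columns = np.asarray(columns)
    nodes = [np.asarray(d, dtype=float) for d in nodes_per_column]
    if grads_per_column is None:
        grads = [np.ones_like(d) for d in nodes]
    else:
        grads = [np.asarray(g, dtype=float) for g in grads_per_column]
    nonempty = [i for i in range(n) if nodes[i].size]
    if len(nonempty) < 2:
        raise FrameUnusableError("fewer than two columns with candidate nodes")

    allg = np.concatenate([grads[i] for i in nonempty])
    gmin, gmax = allg.min(), allg.max()
    span = gmax - gmin
    costs = [
        2.0 - ((grads[i] - gmin) / span if span > 0 else np.ones_like(grads[i]))
        + cost_eps
        for i in range(n)
    ]

    INF = np.inf
    # Two DP layers per (column, node): ``best_any`` is the cheapest path
    # ending there with any number of selected nodes (a bare start counts),
    # ``best_trans`` requires at least one transition, i.e. >= 2 nodes —
    # only those are acceptable surfaces.  Pointers: -1 marks a path start.
    best_any: list[np.ndarray] = []
    best_trans: list[np.ndarray] = []
    back_any: list[np.ndarray] = []
    back_trans: list[np.ndarray] = []
    for ii, i in enumerate(nonempty):
        ci = costs[i]
        start = ci + skip_cost * ii  # skip every nonempty column before
        bt = np.full(ci.size, INF)
        bkt = np.full((ci.size, 2), -1, dtype=int)
        for jj in range(max(0, ii - max_skip_run - 1), ii):
            j = nonempty[jj]
            gap = columns[i] - columns[j]
            reach = (
                np.abs(nodes[i][:, None] - nodes[j][None, :]) <= max_jump_px * gap
            )
            trans = np.where(reach, best_any[jj][None, :], INF)
            cand = ci[:, None] + trans + skip_cost * (ii - jj - 1)
            jbest = cand.argmin(axis=1)
            cbest = cand[np.arange(ci.size), jbest]
            better = cbest < bt
            bt = np.where(better, cbest, bt)
            bkt[better, 0] = jj
            bkt[better, 1] = jbest[better]
        ba = np.minimum(start, bt)
        bka = np.where((bt < start)[:, None], bkt, -1)
        best_any.append(ba)
        best_trans.append(bt)
        back_any.append(bka)
        back_trans.append(bkt)

    # terminal: >= 2 nodes required; pay skip cost for trailing columns
    totals = [
        best_trans[ii] + skip_cost * (len(nonempty) - 1 - ii)
        for ii in range(len(nonempty))
    ]
    end_ii = int(np.argmin([t.min() for t in totals]))
    end_a = int(totals[end_ii].argmin())
    total_cost = float(totals[end_ii][end_a])
    if not np.isfinite(total_cost):
        raise FrameUnusableError("no feasible CSI path")

    chosen: dict[int, float] = {}
    ii, a = end_ii, end_a
    chosen[nonempty[ii]] = nodes[nonempty[ii]][a]
    ii, a = back_trans[ii][a]  # the terminal step is necessarily a transition
    while ii >= 0:
        chosen[nonempty[ii]] = nodes[nonempty[ii]][a]
        ii, a = back_any[ii][a]

    path = np.full(n, np.nan)
    sel = np.array(sorted(chosen))
    path[sel] = [chosen[i] for i in sel]
    missing = np.isnan(path)
    path[missing] = np.interp(columns[missing], columns[sel], path[sel])

    if return_cost:
        return path, total_cost
    return path


def choroidal_thickness(
    csi_depth_px: np.ndarray,
    rpe_depth_px: np.ndarray,
    axial_spacing_um_per_px: float,
    included: Optional[np.ndarray] = None,
) -> float:
    """Mean choroidal thickness of a frame, micrometres.

    Average over included columns carrying both depths of
    ``(CSI - RPE) * spacing``; NaN columns are ignored.  Raises when no
    column has both depths.
    """
    csi = np.asarray(csi_depth_px, dtype=float)
    rpe = np.asarray(rpe_depth_px, dtype=float)
    if included is not None:
        csi, rpe = csi[included], rpe[included]
    ok = ~np.isnan(csi) & ~np.isnan(rpe)
    if not ok.any():
        raise FrameUnusableError("no column with both RPE and CSI depth")
    cht = float(np.mean(csi[ok] - rpe[ok]) * axial_spacing_um_per_px)
    return max(cht, 0.0)


def _segment_frame(
    frame: np.ndarray,
    on_region: tuple[int, int],
    spacing: float,
    cfg: SegmentationConfig,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One frame: RPE -> flatten -> nodes -> path per side -> thickness."""
    depth, width = frame.shape
    lo, hi = on_region
    rpe = detect_rpe(frame, on_region, cfg)
    flat, shifts, ref = flatten_frame(frame, rpe, on_region)
    nodeset = _collect_nodes(flat, ref, on_region, cfg)

    csi_flat = np.full(width, np.nan)
    # the optic-nerve gap is never crossed: solve each side separately
    sides = [nodeset.columns[nodeset.columns < lo], nodeset.columns[nodeset.columns >= hi]]
    any_side = False
    for side_cols in sides:
        if side_cols.size < 2:
            continue
        idx = [int(np.nonzero(nodeset.columns == c)[0][0]) for c in side_cols]
        try:
            path = build_graph_and_search(
                [nodeset.depths[i] for i in idx],
                [nodeset.grads[i] for i in idx],
                max_jump_px=cfg.max_jump_px,
                skip_cost=cfg.skip_cost,
                max_skip_run=cfg.max_skip_run,
                cost_eps=cfg.cost_eps,
                columns=side_cols,
            )
        except FrameUnusableError:
            continue
        csi_flat[side_cols] = path
        any_side = True
    if not any_side:
        raise FrameUnusableError("no side of the optic-nerve gap yielded a path")

    # back to original coordinates, then average
    csi = csi_flat - shifts
    included = np.concatenate([np.arange(0, lo), np.arange(hi, width)])
    rpe_masked = rpe.copy()
    if lo < hi:
        rpe_masked[lo:hi] = np.nan
        csi[lo:hi] = np.nan
    cht = choroidal_thickness(csi, rpe_masked, spacing, included=included)
    return rpe_masked, csi, cht


def segment_sequence(
    seq: BScanSequence,
    config: Optional[SegmentationConfig] = None,
) -> tuple[ThicknessWaveform, SegmentationResult]:
    """Segment every frame and compile the raw choroidal-thickness series.

    Unusable frames (no bright band, no feasible path) are dropped and the
    reason recorded; at least two usable frames are required.
    """
    cfg = config or SegmentationConfig()
    n, width = seq.n_frames, seq.width
    rpe_all = np.full((n, width), np.nan)
    csi_all = np.full((n, width), np.nan)
    cht = np.full(n, np.nan)
    usable = np.zeros(n, dtype=bool)
    reasons: dict[int, str] = {}
    for i in range(n):
        try:
            rpe_all[i], csi_all[i], cht[i] = _segment_frame(
                seq.frames[i], seq.on_region, seq.axial_spacing_um_per_px, cfg
            )
            usable[i] = True
        except (FrameUnusableError, ValueError) as e:
            reasons[i] = str(e)
    if usable.sum() < 2:
        raise FrameUnusableError(
            f"only {int(usable.sum())} usable frames; reasons: {reasons}"
        )
    wf = ThicknessWaveform(
        stage="raw",
        times_s=seq.timestamps_s[usable],
        cht_um=cht[usable],
        params={"n_frames_total": n, "n_frames_usable": int(usable.sum())},
    )
    result = SegmentationResult(
        rpe_depth_px=rpe_all,
        csi_depth_px=csi_all,
        cht_um=cht,
        usable=usable,
        drop_reasons=reasons,
    )
    return wf, result
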