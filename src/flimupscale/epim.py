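"""Three-step edge-preserving interpolation (EPIM) for FLIM matrices.

The 2x interpolation proceeds on a quincunx schedule:

* Step 1 copies every source pixel (i, j) to output (2i, 2j), so the
  original data survive bit-exactly.
* Step 2 fills the centers (2i+1, 2j+1).  For each center, the 4x4 block
  of surrounding source pixels is serialized along four candidate
  directions (horizontal, vertical, the two diagonals) in boustrophedon
  ("snake") order; the summed absolute difference of consecutive valid
  elements measures the variation along each direction.  Interpolation
  runs along the direction of MINIMUM variation — the edge direction —
  with a 4-point cubic stencil of weights (-1/16, 9/16, 9/16, -1/16)
  (the two diagonals), its two-row/two-column average (horizontal /
  vertical), or the full 16-pixel half-pixel cubic stencil when no
  direction wins (isotropic fallback).
* Step 3 fills the remaining axial positions from the already-filled
  checkerboard: a 5x5 window in the upscaled grid decides horizontal vs
  vertical, and the value comes from the 4 filled neighbors at offsets
  -3, -1, +1, +3 along the chosen axis with the same 4-point weights.

Pixels without a fitted lifetime are excluded from every variation and
every stencil; surviving weights are renormalized, and an output pixel
is invalid when too little stencil mass survives.  Each filled pixel
also records a direction-contrast value in [0, 1] — how anisotropic the
local variation is — which drives the wavelet detail gain downstream.

Factor-4 upscaling applies the 2x pipeline twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from functools import lru_cache

import numpy as np

from .flimio import FLIMFrame

__all__ = [
    "DirectionLabel",
    "EPIMParams",
    "EPIMResult",
    "snake_sequence",
    "directional_variation",
    "select_direction",
    "step1_embed",
    "step2_fill_diagonal_centers",
    "step3_fill_axial",
    "epim_upscale",
]

#: 4-point cubic stencil weights at half-pixel offsets (offsets -3,-1,+1,+3
#: in the 2x grid, i.e. distances 1.5, 0.5, 0.5, 1.5 on the source lattice).
W4 = np.array([-1.0, 9.0, 9.0, -1.0]) / 16.0

_CONTRAST_EPS = 1e-12


class DirectionLabel(IntEnum):
    HORIZONTAL = 0
    VERTICAL = 1
    DIAG_MAIN = 2  # top-left -> bottom-right diagonal
    DIAG_ANTI = 3  # top-right -> bottom-left diagonal
    ISOTROPIC = 4


@dataclass
class EPIMParams:
    """Tunables of the edge-preserving interpolator.

    min_support: minimum surviving absolute stencil weight mass below
        which an output lifetime is refused (marked invalid).
    tie_tol: relative tolerance within which directional variations are
        considered tied (isotropic fallback).
    kernel_a: shape parameter of the isotropic fallback's cubic kernel;
        -0.5 is the member whose half-pixel weights equal W4.
    """

    min_support: float = 0.5
    tie_tol: float = 1e-9
    kernel_a: float = -0.5


@dataclass
class EPIMResult:
    """2x (or 4x) grid with validity, per-pixel direction and contrast."""

    values: np.ndarray
    valid: np.ndarray
    gradient_contrast: np.ndarray
    direction: np.ndarray  # DirectionLabel codes, int8

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# snake serialization and directional variation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _snake_order(k: int, direction: DirectionLabel) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) index arrays serializing a k x k window along a direction.

    Lines parallel to the direction are concatenated in order of their
    offset; each line alternates traversal sense so consecutive sequence
    elements stay spatially close (boustrophedon).
    """
    if k not in (4, 5):
        raise ValueError(f"unsupported window size {k}; expected 4 or 5")
    lines: list[list[tuple[int, int]]] = []
    if direction == DirectionLabel.HORIZONTAL:
        lines = [[(r, c) for c in range(k)] for r in range(k)]
    elif direction == DirectionLabel.VERTICAL:
        lines = [[(r, c) for r in range(k)] for c in range(k)]
    elif direction == DirectionLabel.DIAG_MAIN:
        for off in range(-(k - 1), k):  # constant c - r
            lines.append([(r, r + off) for r in range(k) if 0 <= r + off < k])
    elif direction == DirectionLabel.DIAG_ANTI:
        for ssum in range(2 * k - 1):  # constant r + c
            lines.append([(r, ssum - r) for r in range(k) if 0 <= ssum - r < k])
    else:
        raise ValueError("ISOTROPIC has no serialization order")
    order: list[tuple[int, int]] = []
    for idx, line in enumerate(lines):
        order.extend(reversed(line) if idx % 2 else line)
    rr, cc = zip(*order)
    return np.array(rr), np.array(cc)


def snake_sequence(window: np.ndarray, direction: DirectionLabel) -> np.ndarray:
    """Serialize a k x k window (k in {4, 5}) into its k^2-element snake order."""
    window = np.asarray(window)
    k = window.shape[0]
    if window.shape != (k, k):
        raise ValueError("window must be square")
    rr, cc = _snake_order(k, DirectionLabel(direction))
    return window[rr, cc]


def _sequence_variation(seq: np.ndarray, seq_valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Summed |difference| between consecutive VALID elements of each sequence.

    Vectorized over leading axes; the sequence runs along the last axis.
    Invalid elements are dropped from the chain, so their stored values
    can never influence the result.  Returns (variation, pair_count).
    """
    seq = np.asarray(seq, dtype=float)
    seq_valid = np.asarray(seq_valid, dtype=bool)
    base = seq.shape[:-1]
    var = np.zeros(base)
    cnt = np.zeros(base, dtype=np.int64)
    last = np.zeros(base)
    has = np.zeros(base, dtype=bool)
    for k in range(seq.shape[-1]):
        v = seq[..., k]
        m = seq_valid[..., k]
        use = m & has
        var += np.where(use, np.abs(v - last), 0.0)
        cnt += use
        last = np.where(m, v, last)
        has |= m
    return var, cnt


def directional_variation(
    window: np.ndarray, window_valid: np.ndarray, direction: DirectionLabel
) -> tuple[float, int]:
    """Variation of a k x k window along one direction; see _sequence_variation."""
    seq = snake_sequence(np.asarray(window, dtype=float), direction)
    seqv = snake_sequence(np.asarray(window_valid, dtype=bool), direction)
    var, cnt = _sequence_variation(seq, seqv)
    return float(var), int(cnt)


def select_direction(
    stats: dict[DirectionLabel, tuple[float, int]], tie_tol: float = 1e-9
) -> DirectionLabel:
    """Pick the minimum-variation (edge) direction, or ISOTROPIC.

    ISOTROPIC is returned when the best candidates tie within the
    relative tolerance, or when any candidate's usable pair count drops
    below half the maximum (too few valid pixels to trust the
    comparison).
    """
    if not stats:
        raise ValueError("no candidate directions")
    labels = list(stats)
    variations = np.array([stats[d][0] for d in labels])
    counts = np.array([stats[d][1] for d in labels])
    if counts.max() == 0 or (counts < counts.max() / 2).any():
        return DirectionLabel.ISOTROPIC
    order = np.argsort(variations, kind="stable")
    vmin = variations[order[0]]
    if len(labels) > 1 and variations[order[1]] - vmin <= tie_tol * (1.0 + vmin):
        return DirectionLabel.ISOTROPIC
    return labels[order[0]]


# ---------------------------------------------------------------------------
# step 1: embed source on the even lattice
# ---------------------------------------------------------------------------


def step1_embed(
    source: np.ndarray, source_valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Copy source (i, j) to (2i, 2j); everything else is unfilled.

    Returns (grid, filled, valid): ``filled`` marks positions holding a
    value; ``valid`` marks positions holding a USABLE value (filled and
    not masked).
    """
    source = np.asarray(source, dtype=float)
    R, C = source.shape
    if source_valid is None:
        source_valid = np.ones((R, C), dtype=bool)
    grid = np.zeros((2 * R, 2 * C))
    filled = np.zeros((2 * R, 2 * C), dtype=bool)
    valid = np.zeros((2 * R, 2 * C), dtype=bool)
    grid[::2, ::2] = source
    filled[::2, ::2] = True
    valid[::2, ::2] = source_valid
    return grid, filled, valid


# ---------------------------------------------------------------------------
# step 2: fill the (2i+1, 2j+1) centers from 4x4 source blocks
# ---------------------------------------------------------------------------

# step-2 stencils in 4x4 window coordinates (row, col, weight)
_STEP2_STENCILS: dict[DirectionLabel, list[tuple[int, int, float]]] = {
    DirectionLabel.DIAG_MAIN: [(i, i, W4[i]) for i in range(4)],
    DirectionLabel.DIAG_ANTI: [(i, 3 - i, W4[i]) for i in range(4)],
    # two middle rows, each a 4-point cubic, averaged (printed 8 weights / 2)
    DirectionLabel.HORIZONTAL: [(r, c, W4[c] / 2.0) for r in (1, 2) for c in range(4)],
    DirectionLabel.VERTICAL: [(r, c, W4[r] / 2.0) for c in (1, 2) for r in range(4)],
}

_STEP2_DIRECTIONS = (
    DirectionLabel.HORIZONTAL,
    DirectionLabel.VERTICAL,
    DirectionLabel.DIAG_MAIN,
    DirectionLabel.DIAG_ANTI,
)


def _isotropic16_weights(a: float) -> np.ndarray:
    """Full 16-pixel separable cubic weights at the half-pixel center."""
    from .bicubic import kernel_weight

    w = kernel_weight(np.array([1.5, 0.5, 0.5, 1.5]), a)
    return np.outer(w, w)


def _windows_4x4(grid: np.ndarray) -> np.ndarray:
    """(R, C, 4, 4) view: window [i-1..i+2, j-1..j+2] per center, edge-padded."""
    padded = np.pad(grid, ((1, 2), (1, 2)), mode="edge")
    return np.lib.stride_tricks.sliding_window_view(padded, (4, 4))


def _masked_stencil_apply(
    win_v: np.ndarray,
    win_m: np.ndarray,
    stencil: list[tuple[int, int, float]] | np.ndarray,
    min_support: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Renormalized masked weighted sum over (..., k, k) windows.

    Returns (value, ok); ok is False where surviving |weight| mass is
    below min_support or the signed weight sum degenerates.
    """
    if isinstance(stencil, np.ndarray):
        items = [
            (r, c, stencil[r, c])
            for r in range(stencil.shape[0])
            for c in range(stencil.shape[1])
            if stencil[r, c] != 0.0
        ]
    else:
        items = stencil
    num = np.zeros(win_v.shape[:-2])
    den = np.zeros_like(num)
    absm = np.zeros_like(num)
    for r, c, w in items:
        m = win_m[..., r, c]
        num += w * np.where(m, win_v[..., r, c], 0.0)
        den += w * m
        absm += abs(w) * m
    ok = (absm >= min_support) & (np.abs(den) > 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    return val, ok


def _step2_core(
    source: np.ndarray, source_valid: np.ndarray, params: EPIMParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-center (value, ok, direction, contrast), each shaped like source."""
    win_v = _windows_4x4(source)
    win_m = _windows_4x4(source_valid.astype(float)) > 0.5

    variations = []
    counts = []
    for d in _STEP2_DIRECTIONS:
        rr, cc = _snake_order(4, d)
        var, cnt = _sequence_variation(win_v[..., rr, cc], win_m[..., rr, cc])
        variations.append(var)
        counts.append(cnt)
    var = np.stack(variations)
    cnt = np.stack(counts)

    vmax = var.max(axis=0)
    vmin = var.min(axis=0)
    contrast = (vmax - vmin) / (vmax + vmin + _CONTRAST_EPS)

    svar = np.sort(var, axis=0)
    iso = (
        (cnt.max(axis=0) == 0)
        | (cnt < cnt.max(axis=0) / 2).any(axis=0)
        | (svar[1] - svar[0] <= params.tie_tol * (1.0 + svar[0]))
    )
    direction = np.argmin(var, axis=0).astype(np.int8)
    direction[iso] = int(DirectionLabel.ISOTROPIC)

    value = np.zeros(source.shape)
    ok = np.zeros(source.shape, dtype=bool)
    for code, d in enumerate(_STEP2_DIRECTIONS):
        pick = direction == code
        if not pick.any():
            continue
        v, o = _masked_stencil_apply(win_v, win_m, _STEP2_STENCILS[d], params.min_support)
        value[pick] = v[pick]
        ok[pick] = o[pick]
    pick = direction == int(DirectionLabel.ISOTROPIC)
    if pick.any():
        v, o = _masked_stencil_apply(
            win_v, win_m, _isotropic16_weights(params.kernel_a), params.min_support
        )
        value[pick] = v[pick]
        ok[pick] = o[pick]
    return value, ok, direction, contrast


def step2_fill_diagonal_centers(
    partial: np.ndarray,
    filled: np.ndarray,
    valid: np.ndarray,
    params: EPIMParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fill every (2i+1, 2j+1) center of a step-1 grid.

    Returns (grid, filled, valid, direction, contrast); the last two are
    per-center (R, C) grids.
    """
    params = params or EPIMParams()
    source = partial[::2, ::2]
    source_valid = valid[::2, ::2]
    value, ok, direction, contrast = _step2_core(source, source_valid, params)
    grid = partial.copy()
    filled = filled.copy()
    valid = valid.copy()
    grid[1::2, 1::2] = value
    filled[1::2, 1::2] = True
    valid[1::2, 1::2] = ok
    return grid, filled, valid, direction, contrast


# ---------------------------------------------------------------------------
# step 3: fill the axial positions from the checkerboard
# ---------------------------------------------------------------------------


def _windows_5x5(grid: np.ndarray, r0: int, c0: int) -> np.ndarray:
    """(n, m, 5, 5) views of centered 5x5 windows at (r0::2, c0::2)."""
    padded = np.pad(grid, 2, mode="edge")
    sw = np.lib.stride_tricks.sliding_window_view(padded, (5, 5))
    return sw[r0::2, c0::2]


def _axial_estimate(
    lattice_v: np.ndarray,
    lattice_m: np.ndarray,
    idx: np.ndarray,
    axis: int,
    min_support: float,
) -> tuple[np.ndarray, np.ndarray]:
    """4-point W4 stencil along one axis of a (R, C) lattice.

    idx: (n, 4) clamped lattice indices along `axis` for each of n
    targets on that axis; broadcast against the other axis.
    """
    num = 0.0
    den = 0.0
    absm = 0.0
    for k in range(4):
        if axis == 1:
            v = lattice_v[:, idx[:, k]]
            m = lattice_m[:, idx[:, k]]
        else:
            v = lattice_v[idx[:, k], :]
            m = lattice_m[idx[:, k], :]
        w = W4[k]
        num = num + w * np.where(m, v, 0.0)
        den = den + w * m
        absm = absm + abs(w) * m
    ok = (absm >= min_support) & (np.abs(den) > 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    return val, ok


def _clamped_offsets(n: int, offsets: tuple[int, ...]) -> np.ndarray:
    base = np.arange(n)[:, None] + np.array(offsets)[None, :]
    return np.clip(base, 0, n - 1)


def _step3_class(
    grid: np.ndarray,
    avail: np.ndarray,
    r0: int,
    c0: int,
    params: EPIMParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fill one parity class of step-3 targets ((r0, c0) in {(0,1), (1,0)}).

    Returns per-target (value, ok, direction, contrast).
    """
    win_v = _windows_5x5(grid, r0, c0)
    win_m = _windows_5x5(avail.astype(float), r0, c0) > 0.5

    var = {}
    cnt = {}
    for d in (DirectionLabel.HORIZONTAL, DirectionLabel.VERTICAL):
        rr, cc = _snake_order(5, d)
        var[d], cnt[d] = _sequence_variation(win_v[..., rr, cc], win_m[..., rr, cc])
    vh, vv = var[DirectionLabel.HORIZONTAL], var[DirectionLabel.VERTICAL]
    ch, cv = cnt[DirectionLabel.HORIZONTAL], cnt[DirectionLabel.VERTICAL]
    vmax = np.maximum(vh, vv)
    vmin = np.minimum(vh, vv)
    contrast = (vmax - vmin) / (vmax + vmin + _CONTRAST_EPS)
    cmax = np.maximum(ch, cv)
    iso = (
        (cmax == 0)
        | (np.minimum(ch, cv) < cmax / 2)
        | (vmax - vmin <= params.tie_tol * (1.0 + vmin))
    )

    # filled sub-lattices: G_ee = step-1 pixels, G_oo = step-2 pixels
    G_ee, A_ee = grid[::2, ::2], avail[::2, ::2]
    G_oo, A_oo = grid[1::2, 1::2], avail[1::2, 1::2]
    R, C = G_ee.shape
    if (r0, c0) == (0, 1):
        # target (2i, 2j+1): horizontal neighbors on the step-1 row,
        # vertical neighbors on the step-2 column
        h_idx = _clamped_offsets(C, (-1, 0, 1, 2))
        v_idx = _clamped_offsets(R, (-2, -1, 0, 1))
        est_h, ok_h = _axial_estimate(G_ee, A_ee, h_idx, 1, params.min_support)
        est_v, ok_v = _axial_estimate(G_oo, A_oo, v_idx, 0, params.min_support)
    else:
        # target (2i+1, 2j): horizontal on the step-2 row, vertical on step-1
        h_idx = _clamped_offsets(C, (-2, -1, 0, 1))
        v_idx = _clamped_offsets(R, (-1, 0, 1, 2))
        est_h, ok_h = _axial_estimate(G_oo, A_oo, h_idx, 1, params.min_support)
        est_v, ok_v = _axial_estimate(G_ee, A_ee, v_idx, 0, params.min_support)

    pick_h = ~iso & (vh <= vv)
    pick_v = ~iso & (vv < vh)
    value = np.zeros_like(est_h)
    ok = np.zeros_like(ok_h)
    value[pick_h] = est_h[pick_h]
    ok[pick_h] = ok_h[pick_h]
    value[pick_v] = est_v[pick_v]
    ok[pick_v] = ok_v[pick_v]
    # isotropic: average the two directional estimates; fall back to
    # whichever survives masking
    both = iso & ok_h & ok_v
    only_h = iso & ok_h & ~ok_v
    only_v = iso & ~ok_h & ok_v
    value[both] = 0.5 * (est_h[both] + est_v[both])
    ok[both] = True
    value[only_h] = est_h[only_h]
    ok[only_h] = True
    value[only_v] = est_v[only_v]
    ok[only_v] = True

    direction = np.full(value.shape, int(DirectionLabel.ISOTROPIC), dtype=np.int8)
    direction[pick_h] = int(DirectionLabel.HORIZONTAL)
    direction[pick_v] = int(DirectionLabel.VERTICAL)
    return value, ok, direction, contrast


def step3_fill_axial(
    partial: np.ndarray,
    filled: np.ndarray,
    valid: np.ndarray,
    params: EPIMParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fill the (even, odd) and (odd, even) positions of a step-2 grid.

    Returns (grid, filled, valid, direction, contrast); direction and
    contrast are full-resolution grids populated at the step-3 targets.
    """
    params = params or EPIMParams()
    # only value-valid pixels may influence anything; unfilled are invalid
    avail = filled & valid
    grid = partial.copy()
    filled = filled.copy()
    valid = valid.copy()
    direction = np.full(grid.shape, int(DirectionLabel.ISOTROPIC), dtype=np.int8)
    contrast = np.zeros(grid.shape)
    for r0, c0 in ((0, 1), (1, 0)):
        value, ok, dcode, ctr = _step3_class(partial, avail, r0, c0, params)
        grid[r0::2, c0::2] = value
        filled[r0::2, c0::2] = True
        valid[r0::2, c0::2] = ok
        direction[r0::2, c0::2] = dcode
        contrast[r0::2, c0::2] = ctr
    return grid, filled, valid, direction, contrast


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _epim_2x(source: np.ndarray, source_valid: np.ndarray, params: EPIMParams) -> EPIMResult:
    source = np.asarray(source, dtype=float)
    source_valid = np.asarray(source_valid, dtype=bool)
    if source.ndim != 2 or min(source.shape) < 4:
        raise ValueError("EPIM needs a 2-D image at least 4x4")
    grid, filled, valid = step1_embed(source, source_valid)
    if not source_valid.any():
        # nothing usable anywhere: emit an all-invalid upscale
        return EPIMResult(
            values=grid,
            valid=valid,
            gradient_contrast=np.zeros(grid.shape),
            direction=np.full(grid.shape, int(DirectionLabel.ISOTROPIC), dtype=np.int8),
        )
    grid, filled, valid, dir2, ctr2 = step2_fill_diagonal_centers(grid, filled, valid, params)
    grid, filled, valid, dir3, ctr3 = step3_fill_axial(grid, filled, valid, params)

    direction = dir3
    direction[1::2, 1::2] = dir2
    direction[::2, ::2] = int(DirectionLabel.ISOTROPIC)
    contrast = ctr3
    contrast[1::2, 1::2] = ctr2
    # step-1 pixels inherit the mean contrast of their filled 4-neighbors
    cpad = np.pad(contrast, 1, constant_values=np.nan)
    cpad[1::2, 1::2] = np.nan  # step-1 positions are not contrast sources
    stacked = np.stack(
        [cpad[:-2, 1:-1], cpad[2:, 1:-1], cpad[1:-1, :-2], cpad[1:-1, 2:]]
    )
    with np.errstate(invalid="ignore"):
        neigh = np.nanmean(stacked, axis=0)
    contrast[::2, ::2] = np.nan_to_num(neigh[::2, ::2])
    return EPIMResult(values=grid, valid=valid, gradient_contrast=contrast, direction=direction)


def epim_upscale(
    frame: FLIMFrame, factor: int, params: EPIMParams | None = None
) -> tuple[EPIMResult, EPIMResult]:
    """Edge-preserving upscale of a FLIM frame's intensity and lifetime.

    Factor 2 runs steps 1-3 once; factor 4 applies the 2x pipeline
    twice.  Intensity is interpolated with an all-valid mask; the
    lifetime matrix uses its own validity mask so unfitted pixels never
    influence any output value.
    """
    if factor not in (2, 4):
        raise ValueError(f"unsupported upscale factor {factor}; expected 2 or 4")
    params = params or EPIMParams()
    n_passes = 1 if factor == 2 else 2

    ivals = frame.intensity.values
    ivalid = np.ones(ivals.shape, dtype=bool)
    lvals = np.where(frame.lifetime.valid, frame.lifetime.values, 0.0)
    lvalid = frame.lifetime.valid
    intensity_res = lifetime_res = None
    for _ in range(n_passes):
        intensity_res = _epim_2x(ivals, ivalid, params)
        lifetime_res = _epim_2x(lvals, lvalid, params)
        ivals, ivalid = intensity_res.values, intensity_res.valid
        lvals, lvalid = lifetime_res.values, lifetime_res.valid
    return intensity_res, lifetime_res
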