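"""Closed 2-D outlines of skeletal silhouettes and how to obtain them.

Outlines come from three sources: binary raster masks (traced with a
Moore-neighbour boundary walk on the largest connected component), Freeman
chain-code files in the style of classic outline-morphometrics software, or
plain CSV vertex lists.  All outlines are canonicalized counterclockwise in
a y-up frame so that dorsal/ventral have a consistent sign downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label

__all__ = [
    "Outline",
    "ChainCode",
    "extract_outline",
    "decode_chain_code",
    "encode_chain_code",
    "resample_outline",
]

# Freeman 8-direction convention: 0 = +x, counterclockwise through 7
FREEMAN_STEPS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
)


@dataclass(frozen=True)
class Outline:
    """An ordered closed contour (the last point connects to the first)."""

    points: np.ndarray  # (k, 2) float, columns x, y (y-up)
    specimen_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("an outline needs >= 3 (x, y) points")
        object.__setattr__(self, "points", pts)
        if self.perimeter() <= 0:
            raise ValueError("degenerate outline: zero perimeter")

    def segment_lengths(self) -> np.ndarray:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def perimeter(self) -> float:
        return float(self.segment_lengths().sum())

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return float(0.5 * np.sum(x * yn - xn * y))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def canonical(self) -> "Outline":
        """Counterclockwise orientation (positive signed area)."""
        if self.signed_area() < 0:
            return Outline(self.points[::-1].copy(), self.specimen_id)
        return self


@dataclass(frozen=True)
class ChainCode:
    """Freeman chain code: integer start pixel plus direction codes 0-7."""

    start: tuple[int, int]
    codes: tuple[int, ...]
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if len(self.codes) == 0:
            raise ValueError("empty chain code")
        if any(c not in range(8) for c in self.codes):
            bad = [c for c in self.codes if c not in range(8)]
            raise ValueError(f"chain codes must be 0-7, got {bad[:5]}")


def decode_chain_code(cc: ChainCode) -> Outline:
    """Accumulate Freeman steps into a closed vertex sequence.

    The decoded path must return to the start pixel; the final (repeated)
    vertex is dropped so the outline closes implicitly.
    """
    steps = FREEMAN_STEPS[list(cc.codes)]
    path = np.vstack([np.array(cc.start), np.array(cc.start) + np.cumsum(steps, axis=0)])
    if not np.array_equal(path[-1], path[0]):
        raise ValueError("chain code does not close back to its start pixel")
    return Outline(path[:-1].astype(float), cc.specimen_id).canonical()


def encode_chain_code(o: Outline, specimen_id: str = "") -> ChainCode:
    """Inverse of :func:`decode_chain_code` for 8-connected integer outlines."""
    pts = np.rint(o.points).astype(int)
    diffs = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    lookup = {tuple(s): i for i, s in enumerate(FREEMAN_STEPS)}
    try:
        codes = tuple(lookup[tuple(d)] for d in diffs)
    except KeyError:
        raise ValueError("outline is not an 8-connected unit-step path") from None
    return ChainCode(tuple(pts[0]), codes, specimen_id or o.specimen_id)


# Moore neighbourhood in (row, col) raster coordinates, clockwise from west
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of an 8-connected blob, ordered, as (row, col).

    Moore-neighbour tracing starting from the first foreground pixel in
    raster scan order, searching the neighbourhood clockwise from the
    backtrack pixel; stops on revisiting the start with the same entry move.
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))
    if len(rows) == 1:
        return np.array([start])
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    boundary = [start]
    cur = start
    back_dir = 0  # index into _MOORE of the backtrack pixel (initially west)
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    for _ in range(4 * h * w + 8):  # safety bound; valid masks stop earlier
        for k in range(1, 9):
            d = (back_dir + k) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(nr, nc):
                nxt = (nr, nc)
                # new backtrack = the neighbour checked just before d,
                # re-expressed relative to nxt (it is adjacent to both)
                pr = cur[0] + _MOORE[(d - 1) % 8][0]
                pc = cur[1] + _MOORE[(d - 1) % 8][1]
                back_dir = _MOORE.index((pr - nr, pc - nc))
                break
        else:  # no neighbour: isolated pixel already handled above
            return np.array(boundary)
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            # closed: cur == start was appended last iteration, drop the repeat
            return np.array(boundary[:-1]) if boundary[-1] == start else np.array(boundary)
        boundary.append(nxt)
        cur = nxt
    raise RuntimeError("boundary tracing failed to terminate")


def extract_outline(image: np.ndarray, min_area: int = 16,
                    specimen_id: str = "", mirror: bool = False) -> Outline:
    """Trace the boundary of the largest foreground component of a mask.

    The raster's y-axis points down; the returned outline lives in a y-up
    mathematical frame (y = height - 1 - row) and is counterclockwise.
    ``mirror`` flips x for right-facing specimens so all outlines share the
    same anatomical orientation before Fourier decomposition.
    """
    mask = np.asarray(image) > 0
    if not mask.any():
        raise ValueError("empty image: no foreground pixels")
    lab = _cc_label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    if sizes[biggest] < min_area:
        raise ValueError(
            f"largest component has {sizes[biggest]} px, below min_area={min_area}")
    blob = lab == biggest
    rc = _moore_trace(blob)
    if rc.shape[0] < 3:
        raise ValueError("component too small to form an outline")
    h = mask.shape[0]
    xy = np.column_stack([rc[:, 1].astype(float), (h - 1.0) - rc[:, 0]])
    if mirror:
        xy[:, 0] = -xy[:, 0]
    return Outline(xy, specimen_id).canonical()


def resample_outline(o: Outline, k: int) -> Outline:
    """Resample to k points equally spaced by arc length, keeping the start.

    Applying the operation twice with the same k is a fixed point.
    """
    if k < 8:
        raise ValueError("need k >= 8 resampled points")
    cur = o.points
    # one interpolation pass leaves the new vertices slightly unevenly
    # spaced in their own chord metric; iterate to the fixed point so the
    # operation is idempotent
    for _ in range(12):
        pts = np.vstack([cur, cur[:1]])
        seg = np.hypot(*np.diff(pts, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total <= 0:
            raise ValueError("degenerate outline: zero perimeter")
        targets = np.linspace(0.0, total, k, endpoint=False)
        x = np.interp(targets, s, pts[:, 0])
        y = np.interp(targets, s, pts[:, 1])
        nxt = np.column_stack([x, y])
        if cur.shape == nxt.shape and np.abs(cur - nxt).max() < 1e-12 * max(total, 1.0):
            cur = nxt
            break
        cur = nxt
    return Outline(cur, o.specimen_id)
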