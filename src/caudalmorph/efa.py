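"""Elliptical Fourier analysis of closed outlines.

A closed contour is decomposed into harmonically related ellipses: separate
Fourier series for the x and y coordinate increments under a piecewise-linear
arc-length parameterization (the classic Kuhl & Giardina formulation).  Each
harmonic n contributes four coefficients (a_n, b_n for x; c_n, d_n for y).

Size, position, rotation and starting point are removed by standardizing on
the first harmonic; the resulting normalized (NEF) descriptors satisfy
a1 = 1, b1 = c1 = 0 exactly, leaving 4N - 3 free shape variables per outline.
Harmonic count is chosen by the cumulative Fourier power criterion,
P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outlines import Outline

__all__ = [
    "HarmonicSet",
    "NEFDescriptors",
    "PowerSpectrum",
    "efa_decompose",
    "fourier_power",
    "select_harmonics",
    "efa_normalize",
    "efa_reconstruct",
    "average_by_species",
    "descriptors_to_frame",
    "frame_to_descriptors",
    "write_nef",
    "read_nef",
]

DEFAULT_N_MAX = 32  # decomposition order before power-based selection


@dataclass(frozen=True)
class HarmonicSet:
    """Raw elliptic Fourier coefficients plus the centroid terms A0/C0."""

    A0: float
    C0: float
    coeffs: np.ndarray  # (N, 4) rows (a_n, b_n, c_n, d_n)
    specimen_id: str = ""

    def __post_init__(self) -> None:
        co = np.asarray(self.coeffs, dtype=float)
        if co.ndim != 2 or co.shape[1] != 4 or co.shape[0] < 1:
            raise ValueError("coeffs must be (N, 4) with N >= 1")
        if not np.all(np.isfinite(co)):
            raise ValueError("non-finite Fourier coefficients")
        object.__setattr__(self, "coeffs", co)

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class NEFDescriptors:
    """First-harmonic-standardized coefficients: a1 = 1, b1 = c1 = 0."""

    coeffs: np.ndarray  # (N, 4)
    specimen_id: str = ""

    def __post_init__(self) -> None:
        co = np.asarray(self.coeffs, dtype=float)
        if not (co[0, 0] == 1.0 and co[0, 1] == 0.0 and co[0, 2] == 0.0):
            raise ValueError("not normalized: need a1 = 1, b1 = 0, c1 = 0")
        object.__setattr__(self, "coeffs", co)

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    @property
    def free_count(self) -> int:
        return 4 * self.n_harmonics - 3

    def free_vector(self) -> np.ndarray:
        """The 4N-3 free variables (a1, b1, c1 dropped)."""
        flat = self.coeffs.ravel()
        return np.concatenate([[flat[3]], flat[4:]])


@dataclass(frozen=True)
class PowerSpectrum:
    power: np.ndarray       # per-harmonic P_n >= 0
    cumulative: np.ndarray  # q_n, nondecreasing, q_N = 1

    def __post_init__(self) -> None:
        if self.power.size == 0:
            raise ValueError("empty power spectrum")


def _param(o: Outline, param: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    pts = np.vstack([o.points, o.points[:1]])
    dxy = np.diff(pts, axis=0)
    dt = np.hypot(dxy[:, 0], dxy[:, 1])
    keep = dt > 0  # collapse coincident vertices
    dxy, dt = dxy[keep], dt[keep]
    if dt.size < 3:
        raise ValueError("degenerate outline for Fourier decomposition")
    if param == "uniform":
        dt = np.full(dt.size, 1.0 / dt.size)
    elif param != "chord":
        raise ValueError("param must be 'chord' or 'uniform'")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return dxy[:, 0], dxy[:, 1], dt, t, float(t[-1])


def efa_decompose(o: Outline, N: int = DEFAULT_N_MAX, *,
                  param: str = "chord") -> HarmonicSet:
    """Elliptic Fourier coefficients of a closed outline, harmonics 1..N.

    ``param`` chooses the traversal parameterization: ``"chord"`` (default)
    is the classic cumulative chord-length approximation to arc length;
    ``"uniform"`` declares the vertices equally spaced in the curve
    parameter, which makes decomposition the exact (up to polygonal
    sampling) inverse of :func:`efa_reconstruct`.
    """
    if N < 1:
        raise ValueError("need at least one harmonic")
    dx, dy, dt, t, T = _param(o, param)
    n = np.arange(1, N + 1)[:, None]          # (N, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T    # (N, P+1)
    dcos = np.diff(np.cos(phi), axis=1)
    dsin = np.diff(np.sin(phi), axis=1)
    scale = T / (2.0 * np.pi**2 * n.ravel() ** 2)
    a = scale * ((dx / dt)[None, :] * dcos).sum(axis=1)
    b = scale * ((dx / dt)[None, :] * dsin).sum(axis=1)
    c = scale * ((dy / dt)[None, :] * dcos).sum(axis=1)
    d = scale * ((dy / dt)[None, :] * dsin).sum(axis=1)

    # centroid (bias) terms of the parameterized curve
    x0, y0 = o.points[0]
    xi = np.concatenate([[0.0], np.cumsum(dx)])[:-1] - (dx / dt) * t[:-1]
    delta = np.concatenate([[0.0], np.cumsum(dy)])[:-1] - (dy / dt) * t[:-1]
    t2 = np.diff(t**2)
    A0 = x0 + (1.0 / T) * np.sum((dx / (2.0 * dt)) * t2 + xi * dt)
    C0 = y0 + (1.0 / T) * np.sum((dy / (2.0 * dt)) * t2 + delta * dt)
    return HarmonicSet(float(A0), float(C0),
                       np.column_stack([a, b, c, d]), o.specimen_id)


def fourier_power(h: HarmonicSet | NEFDescriptors) -> PowerSpectrum:
    """Per-harmonic power P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2."""
    P = 0.5 * np.sum(h.coeffs**2, axis=1)
    total = P.sum()
    if total <= 0:
        raise ValueError("outline carries no Fourier power")
    return PowerSpectrum(P, np.cumsum(P) / total)


def select_harmonics(spec: PowerSpectrum, threshold: float = 0.99) -> int:
    """Smallest n whose cumulative power reaches the threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    hit = np.nonzero(spec.cumulative >= threshold - 1e-15)[0]
    return int(hit[0]) + 1 if hit.size else int(spec.power.size)


def _apply_frames(coeffs: np.ndarray, theta: float, psi: float) -> np.ndarray:
    """Rotate by -psi (spatial) and shift the starting phase by theta."""
    N = coeffs.shape[0]
    out = np.empty_like(coeffs)
    cps, sps = np.cos(psi), np.sin(psi)
    Rspace = np.array([[cps, sps], [-sps, cps]])
    for i in range(N):
        n = i + 1
        cn, sn = np.cos(n * theta), np.sin(n * theta)
        Rphase = np.array([[cn, -sn], [sn, cn]])
        M = coeffs[i].reshape(2, 2)
        out[i] = (Rspace @ M @ Rphase).ravel()
    return out


def pooled_harmonic_count(sets, threshold: float = 0.99) -> int:
    """Harmonics needed for the sample: smallest n whose mean cumulative
    power across specimens reaches the threshold."""
    sets = list(sets.values()) if isinstance(sets, dict) else list(sets)
    if not sets:
        raise ValueError("no harmonic sets supplied")
    qs = np.vstack([fourier_power(h).cumulative for h in sets])
    pooled = PowerSpectrum(np.ones(qs.shape[1]), qs.mean(axis=0))
    return select_harmonics(pooled, threshold)


def efa_normalize(h: HarmonicSet) -> NEFDescriptors:
    """Standardize by the first harmonic: remove size/position/rotation/start.

    The starting-point phase theta and spatial rotation psi are computed
    from the first-harmonic ellipse; every harmonic is re-expressed in that
    frame and divided by the semi-major axis length.  The pi-ambiguity of
    the normalized frame is resolved deterministically: a1 > 0 always, and
    between the two remaining candidate frames the one whose positive x-axis
    points toward the outline's longer extent (third moment of x; falling
    back to a lexicographic coefficient comparison for symmetric shapes).
    """
    a1, b1, c1, d1 = h.coeffs[0]
    denom = a1**2 + c1**2 - b1**2 - d1**2
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), denom)
    candidates = []
    for th in (theta, theta + np.pi):
        cth, sth = np.cos(th), np.sin(th)
        a1s = a1 * cth + b1 * sth
        c1s = c1 * cth + d1 * sth
        psi = np.arctan2(c1s, a1s)
        out = _apply_frames(h.coeffs, th, psi)
        E = out[0, 0]  # semi-major length, > 0 by construction of psi
        if E <= 0:
            continue
        out = out / E
        out[0, 0], out[0, 1], out[0, 2] = 1.0, 0.0, 0.0  # exact by construction
        candidates.append(out)
    if not candidates:
        raise ValueError("degenerate first harmonic: cannot normalize")
    if len(candidates) == 1:
        best = candidates[0]
    else:
        best = max(candidates, key=_frame_preference)
    return NEFDescriptors(best, h.specimen_id)


def _frame_preference(coeffs: np.ndarray) -> tuple:
    """Ranking key for the two candidate normalized frames."""
    k = max(64, 8 * coeffs.shape[0])
    xy = _evaluate(coeffs, 0.0, 0.0, coeffs.shape[0], k)
    skew = float(np.mean(xy[:, 0] ** 3))
    primary = 0.0 if abs(skew) < 1e-9 else np.sign(skew)
    return (primary, tuple(np.round(coeffs.ravel(), 9)))


def _evaluate(coeffs: np.ndarray, A0: float, C0: float,
              n_use: int, k: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    n = np.arange(1, n_use + 1)[:, None]
    cos_nt, sin_nt = np.cos(n * t), np.sin(n * t)
    a, b, c, d = (coeffs[:n_use, j][:, None] for j in range(4))
    x = A0 + (a * cos_nt + b * sin_nt).sum(axis=0)
    y = C0 + (c * cos_nt + d * sin_nt).sum(axis=0)
    return np.column_stack([x, y])


def efa_reconstruct(h: HarmonicSet | NEFDescriptors, n_use: int | None = None,
                    k: int = 256) -> Outline:
    """Truncated inverse Fourier sum at k equally spaced parameter values."""
    N = h.n_harmonics
    n_use = N if n_use is None else n_use
    if not 1 <= n_use <= N:
        raise ValueError(f"n_use must be in [1, {N}], got {n_use}")
    A0 = getattr(h, "A0", 0.0)
    C0 = getattr(h, "C0", 0.0)
    return Outline(_evaluate(h.coeffs, A0, C0, n_use, k), h.specimen_id)


# ---------------------------------------------------------------------------
# tables of descriptors

def descriptors_to_frame(descs: dict[str, NEFDescriptors] |
                         list[tuple[str, NEFDescriptors]]) -> pd.DataFrame:
    """Flatten per-specimen descriptors into a table of free variables.

    Columns are d1, then a2, b2, c2, d2, a3, ... (4N - 3 of them); the index
    holds specimen/species identifiers.
    """
    items = list(descs.items()) if isinstance(descs, dict) else list(descs)
    if not items:
        raise ValueError("no descriptors supplied")
    Ns = {d.n_harmonics for _, d in items}
    if len(Ns) > 1:
        raise ValueError(f"mixed harmonic counts: {sorted(Ns)}")
    N = Ns.pop()
    cols = ["d1"] + [f"{ch}{n}" for n in range(2, N + 1) for ch in "abcd"]
    rows = {sid: d.free_vector() for sid, d in items}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def frame_to_descriptors(df: pd.DataFrame) -> dict[str, NEFDescriptors]:
    out = {}
    N = (df.shape[1] + 3) // 4
    for sid, row in df.iterrows():
        co = np.concatenate([[1.0, 0.0, 0.0], row.to_numpy(float)]).reshape(N, 4)
        out[sid] = NEFDescriptors(co, str(sid))
    return out


def average_by_species(df: pd.DataFrame, species: pd.Series) -> pd.DataFrame:
    """Average normalized descriptors specimen-wise within species.

    ``df`` is a specimen x free-variable table (from
    :func:`descriptors_to_frame`); ``species`` maps specimen id -> species
    label.  Returns one row per species.
    """
    missing = df.index.difference(species.index)
    if len(missing):
        raise KeyError(f"specimens without species label: {list(missing)[:5]}")
    lab = species.loc[df.index]
    return df.groupby(lab).mean().sort_index()


# ---------------------------------------------------------------------------
# plain-text descriptor files (SHAPE-style .nef dialect)

def write_nef(path, sets: dict[str, HarmonicSet]) -> None:
    """One block per specimen: id, N, A0 C0, then N lines 'a b c d'."""
    with open(path, "w") as fh:
        for sid, h in sets.items():
            fh.write(f"{sid}\n{h.n_harmonics}\n{h.A0:.10g} {h.C0:.10g}\n")
            for row in h.coeffs:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_nef(path) -> dict[str, HarmonicSet]:
    out: dict[str, HarmonicSet] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        sid = lines[i]
        N = int(lines[i + 1])
        A0, C0 = (float(v) for v in lines[i + 2].split())
        co = np.array([[float(v) for v in lines[i + 3 + j].split()]
                       for j in range(N)])
        out[sid] = HarmonicSet(A0, C0, co, sid)
        i += 3 + N
    return out
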