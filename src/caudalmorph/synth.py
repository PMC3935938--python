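"""Synthetic study generator.

Everything the pipeline consumes can be simulated here: pure-birth (Yule)
phylogenies scaled to unit depth, ecological group labels with either
cladewise or convergent (multi-origin) structure, species trait matrices
under lambda-scaled Brownian motion with additive group mean shifts, and
parametric pygostyle-like closed outlines whose elongation / taper / dorsal
deflection / mid-constriction parameters map onto the five foraging classes
(underwater foragers elongate and straight, aerial/terrestrial short and
dorsally deflected, aerial with an hourglass mid-constriction).

All generators are deterministic per seed; a root seed fans out to
per-component sub-seeds with :func:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon

from .morphodata import SIZE_MEASUREMENTS, VERTEBRAL_METRICS, GroupFactor
from .outlines import Outline
from .phylo import Phylogeny, _from_dendropy, simulate_bm, tree_vcv, lambda_transform

__all__ = [
    "ShapeParams",
    "CLASS_SHAPE_PARAMS",
    "simulate_yule_tree",
    "assign_convergent_groups",
    "simulate_group_traits",
    "synth_pygostyle_outline",
    "rasterize_outline",
    "StudyBundle",
    "make_study_like_dataset",
    "write_bundle",
]


def _subseed(seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# trees and groups

def simulate_yule_tree(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth tree with ``n_tips``, rescaled to unit root-to-tip depth."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng)
    # the simulator stops at the n-th speciation, leaving two zero-length
    # pendant edges; sample the process one extra waiting time onward
    extra = rng.expovariate(n_tips)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    phy = _from_dendropy(tree)
    depth = phy.node_depths()[: phy.n_tips].max()
    return Phylogeny(phy.tips, phy.parent, phy.edge_length / depth)


def _clades(tree: Phylogeny) -> list[list[int]]:
    """Tip-index sets of every internal node, by node index order."""
    kids = tree.children()
    sets: dict[int, list[int]] = {i: [i] for i in range(tree.n_tips)}
    out = []
    for node in range(tree.n_tips, tree.n_nodes):
        # children always have smaller subtree-completion order; resolve
        # recursively
        def tips_of(j: int) -> list[int]:
            if j in sets:
                return sets[j]
            acc: list[int] = []
            for c in kids[j]:
                acc.extend(tips_of(c))
            sets[j] = acc
            return acc

        out.append(sorted(tips_of(node)))
    return out


def is_monophyletic(tree: Phylogeny, species: set[str]) -> bool:
    """True when the smallest clade containing ``species`` holds no others."""
    idx = {t: i for i, t in enumerate(tree.tips)}
    want = {idx[s] for s in species}
    best = None
    for clade in _clades(tree):
        if want <= set(clade) and (best is None or len(clade) < len(best)):
            best = clade
    return best is not None and set(best) == want


def assign_convergent_groups(tree: Phylogeny, n_groups: int,
                             origins_per_group: dict[str, int] | None,
                             seed: int, *, n_restarts: int = 40) -> GroupFactor:
    """Partition tips into labelled groups built from whole clades.

    Each group is the union of the requested number of independently chosen
    clades; k >= 2 origins makes the group non-monophyletic (verified).
    Unassigned tips fall into the last (background) group.

    Among ``n_restarts`` candidate labelings the one whose closest
    cross-class tip pair is most phylogenetically distant is kept: recently
    diverged sisters share ecology in real assemblages, and boundaries on
    near-zero branches would dominate any GLS-weighted analysis.
    """
    if origins_per_group is None:
        origins_per_group = {}
    names = list(origins_per_group) or [f"group{i + 1}" for i in range(n_groups)]
    while len(names) < n_groups:
        names.append(f"group{len(names) + 1}")
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    target = max(2, n // n_groups)
    # candidate origins: any proper clade, including single tips
    clades = [[i] for i in range(n)] + [c for c in _clades(tree) if len(c) < n]
    cv = tree_vcv(tree)
    depths = np.diag(cv.C)
    patristic = depths[:, None] + depths[None, :] - 2.0 * cv.C

    best_labels: np.ndarray | None = None
    best_score = -np.inf
    for _ in range(n_restarts):
        labels = _assign_once(tree, names, origins_per_group, clades, target, rng)
        if labels is None:
            continue
        cross = labels[:, None] != labels[None, :]
        score = float(patristic[cross].min()) if cross.any() else 0.0
        sizes = pd.Series(labels).value_counts()
        if sizes.min() < max(2, target // 3):
            score -= 1.0  # badly unbalanced placements lose
        if score > best_score:
            best_score, best_labels = score, labels
    if best_labels is None:
        raise ValueError("cannot place the requested group origins on this tree")
    mapping = pd.Series(best_labels, index=list(tree.tips), name="group")
    return _SyntheticGroups(mapping)


def _assign_once(tree: Phylogeny, names, origins_per_group, clades, target,
                 rng) -> np.ndarray | None:
    """One randomized clade-placement attempt; None when infeasible."""
    n = tree.n_tips
    labels = np.array([""] * n, dtype=object)
    for name in names[:-1]:
        k = origins_per_group.get(name, 1)
        best: tuple[float, list[int]] | None = None
        for _ in range(60):
            placed: list[int] = []
            used: set[int] = set(np.nonzero(labels != "")[0])
            order = rng.permutation(len(clades))
            for ci in order:
                c = clades[ci]
                if used & set(c):
                    continue
                if len(c) > max(1, int(1.8 * target / k)) + 1:
                    continue
                placed.append(ci)
                used |= set(c)
                if len(placed) == k:
                    break
            if len(placed) < k:
                continue
            members = {tree.tips[i] for ci in placed for i in clades[ci]}
            if k >= 2 and is_monophyletic(tree, members):
                continue
            score = abs(len(members) - target)
            if best is None or score < best[0]:
                best = (score, placed)
            if score == 0:
                break
        if best is None:
            return None
        for ci in best[1]:
            labels[clades[ci]] = name
    if not (labels == "").any():
        return None
    labels[labels == ""] = names[-1]
    return labels


class _SyntheticGroups(GroupFactor):
    """GroupFactor with free-form labels (synthetic schemes)."""

    def __init__(self, mapping: pd.Series, scheme: str = "synthetic"):
        object.__setattr__(self, "mapping", mapping)
        object.__setattr__(self, "scheme", scheme)

    def __post_init__(self) -> None:  # pragma: no cover - not dataclass-built
        pass


def _simplex_means(groups: list[str], p: int, effect_size: float) -> pd.DataFrame:
    """Group mean vectors mutually ``effect_size`` apart (regular simplex)."""
    G = len(groups)
    if p < G - 1 and effect_size > 0:
        raise ValueError(f"need p >= {G - 1} dimensions to separate {G} groups")
    M = np.zeros((G, p))
    if effect_size > 0 and G > 1:
        # regular simplex with unit edge: vertices of I_G centered, then
        # mapped to G-1 dims and scaled
        E = np.eye(G) - np.full((G, G), 1.0 / G)
        U, s, _ = np.linalg.svd(E)
        V = (U[:, : G - 1] * s[: G - 1])  # pairwise distance sqrt(2)
        M[:, : G - 1] = V / np.sqrt(2.0) * effect_size
    return pd.DataFrame(M, index=groups)


def simulate_group_traits(tree: Phylogeny, groups: GroupFactor,
                          effect_size: float, lam: float, p: int,
                          seed: int) -> pd.DataFrame:
    """Group mean shifts plus lambda-scaled Brownian residuals (unit rates).

    Group means sit at mutual Mahalanobis distance ``effect_size`` (the rate
    matrix is the identity, so Mahalanobis = Euclidean).
    """
    if p < 1:
        raise ValueError("need at least one trait dimension")
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    resid = simulate_bm(tree, np.eye(p), lam, _subseed(seed, 1))
    means = _simplex_means(sorted(groups.mapping.unique()), p, effect_size)
    shift = means.loc[groups.mapping.loc[resid.index]].to_numpy()
    X = resid.to_numpy() + shift
    return pd.DataFrame(X, index=resid.index,
                        columns=[f"trait{i + 1}" for i in range(p)])


# ---------------------------------------------------------------------------
# parametric pygostyle outlines

@dataclass(frozen=True)
class ShapeParams:
    """Parameters of the pygostyle-like outline family.

    elongation: length/height ratio (> 0); taper in [0, 1] (0 = blunt,
    1 = pointed caudal margin); deflection: signed dorsal bend of the
    midline in height units; constriction in [0, 1): depth of the
    mid-length hourglass notch; noise_sd: vertex noise as a fraction of the
    outline length.
    """

    elongation: float = 2.0
    taper: float = 0.3
    deflection: float = 0.0
    constriction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elongation <= 0:
            raise ValueError("elongation must be > 0")
        if not 0.0 <= self.taper <= 1.0:
            raise ValueError("taper must be in [0, 1]")
        if not 0.0 <= self.constriction < 1.0:
            raise ValueError("constriction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synth_pygostyle_outline(params: ShapeParams, k: int = 256,
                            specimen_id: str = "") -> Outline:
    """Closed smooth pygostyle-like outline (cranial at -x, caudal at +x,
    dorsal at +y).

    A superellipse base is stretched by elongation, linearly tapered toward
    the caudal end, notched at mid-length (Gaussian profile of depth
    ``constriction``), bent dorsally by ``deflection``, and optionally
    perturbed with seeded Gaussian vertex noise.
    """
    if k < 128:
        raise ValueError("need >= 128 outline points")
    m = 3.2  # superellipse exponent: near-rectangular cross-section
    a = params.elongation / 2.0
    b = 0.5
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    x = a * np.sign(ct) * np.abs(ct) ** (2.0 / m)
    y0 = b * np.sign(st) * np.abs(st) ** (2.0 / m)
    u = (x + a) / (2.0 * a)  # 0 cranial .. 1 caudal
    height = 1.0 - params.taper * u**2
    notch = 1.0 - params.constriction * np.exp(-0.5 * ((u - 0.5) / 0.05) ** 2)
    # fixed fine-scale anatomy shared by all classes, applied
    # multiplicatively so boundaries never cross the midline: a concave
    # ventral articulation facet for the last free vertebra at the cranial
    # end, and a convex dorsal lamina ridge at about a third of the length
    artic = 1.0 - 0.7 * np.exp(-0.5 * (u / 0.05) ** 2) * (y0 < 0)
    ridge = 1.0 + 0.3 * np.exp(-0.5 * ((u - 0.28) / 0.03) ** 2) * (y0 > 0)
    y = y0 * height * notch * artic * ridge + params.deflection * u**2
    pts = np.column_stack([x, y])
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        pts = pts + rng.normal(0.0, params.noise_sd * params.elongation, pts.shape)
    return Outline(pts, specimen_id).canonical()


def rasterize_outline(o: Outline, px_per_unit: float) -> np.ndarray:
    """Fill the outline polygon into a binary uint8 raster (y-down rows)."""
    if px_per_unit <= 0:
        raise ValueError("px_per_unit must be > 0")
    pts = o.points * px_per_unit
    span = max(float(np.ptp(pts[:, 0])), float(np.ptp(pts[:, 1])))
    if span < 32:
        raise ValueError(
            f"resolution too low: extent {span:.1f} px < 32; raise px_per_unit")
    margin = 4
    xs = pts[:, 0] - pts[:, 0].min() + margin
    ys = pts[:, 1] - pts[:, 1].min() + margin
    h = int(np.ceil(ys.max())) + margin + 1
    w = int(np.ceil(xs.max())) + margin + 1
    rows = (h - 1) - ys  # y-up -> raster rows
    img = np.zeros((h, w), dtype=np.uint8)
    rr, cc = _draw_polygon(rows, xs, shape=img.shape)
    img[rr, cc] = 1
    return img


# class-specific parameter distributions emulating the qualitative shape
# contrasts among foraging classes: divers elongate and straight, plunge
# divers elongate with gradual taper, foot-propelled divers tapering to a
# caudal point with dorsal bend, terrestrial short and deflected, aerial
# short, deflected, with the hourglass mid-constriction
CLASS_SHAPE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "Wing-Propelled Pursuit Dive": dict(elongation=(2.8, 0.15), taper=(0.05, 0.03),
                                        deflection=(0.02, 0.02), constriction=(0.0, 0.0)),
    "Plunge Dive": dict(elongation=(2.35, 0.12), taper=(0.55, 0.05),
                        deflection=(0.05, 0.02), constriction=(0.0, 0.0)),
    "Foot-Propelled Pursuit Dive": dict(elongation=(1.9, 0.1), taper=(0.9, 0.04),
                                        deflection=(0.3, 0.04), constriction=(0.0, 0.0)),
    "Terrestrial": dict(elongation=(1.45, 0.08), taper=(0.25, 0.05),
                        deflection=(0.6, 0.05), constriction=(0.0, 0.0)),
    "Aerial": dict(elongation=(1.45, 0.08), taper=(0.25, 0.05),
                   deflection=(0.6, 0.05), constriction=(0.6, 0.05)),
}


@dataclass
class StudyBundle:
    tree: Phylogeny
    groups: GroupFactor
    species_params: pd.DataFrame           # per-species mean ShapeParams values
    outlines: dict[str, Outline]           # specimen id -> outline
    specimen_species: pd.Series            # specimen id -> species
    measurements: pd.DataFrame             # specimen-level linear metrics
    seed: int
    images: dict[str, np.ndarray] = field(default_factory=dict)


def _clip_params(vals: dict[str, float]) -> ShapeParams:
    return ShapeParams(
        elongation=max(vals["elongation"], 0.6),
        taper=float(np.clip(vals["taper"], 0.0, 1.0)),
        deflection=vals["deflection"],
        constriction=float(np.clip(vals["constriction"], 0.0, 0.9)),
        noise_sd=vals.get("noise_sd", 0.0),
        seed=int(vals.get("seed", 0)),
    )


def make_study_like_dataset(n_species: int = 51, seed: int = 0, *,
                            specimens_per_species: tuple[int, int] = (2, 4),
                            diver_origins: int = 4,
                            noise_sd: float = 0.005,
                            rasterize: bool = False,
                            px_per_unit: float = 120.0) -> StudyBundle:
    """Generate a full study-like bundle: tree, labels, outlines, metrics.

    The default emulates the study design: 51 species, five foraging
    classes, wing-propelled pursuit divers arising in ``diver_origins``
    separate clades (convergent), 2-4 specimens per species.  Within-species
    outline variation (vertex noise + small parameter jitter) is much
    smaller than between-class differences.
    """
    tree = simulate_yule_tree(n_species, _subseed(seed, 0))
    classes = list(CLASS_SHAPE_PARAMS)
    groups = assign_convergent_groups(
        tree, len(classes),
        {c: (diver_origins if c == "Wing-Propelled Pursuit Dive" else 1)
         for c in classes},
        _subseed(seed, 1))
    groups = _SyntheticGroups(groups.mapping, "foraging")

    # within-class deviations evolve on the tree (Brownian with marginal sd
    # equal to the class sd at unit depth), so close relatives have similar
    # shapes; i.i.d. deviations would make near-zero branches carry large
    # shape jumps, which no heritable trait does
    rng = np.random.default_rng(_subseed(seed, 2))
    features = ["elongation", "taper", "deflection", "constriction"]
    dev = simulate_bm(tree, np.eye(len(features)), 1.0, _subseed(seed, 7))
    dev.columns = features
    sp_rows = {}
    for sp in tree.tips:
        spec = CLASS_SHAPE_PARAMS[groups.mapping[sp]]
        sp_rows[sp] = {key: mu + sd * dev.loc[sp, key]
                       for key, (mu, sd) in spec.items()}
    species_params = pd.DataFrame(sp_rows).T

    outlines: dict[str, Outline] = {}
    spec_species = {}
    measurements = []
    lo, hi = specimens_per_species
    cov = tree_vcv(tree)
    # species body size: lognormal with phylogenetic correlation
    size_bm = simulate_bm(tree, np.array([[0.04]]), 1.0, _subseed(seed, 3))
    sp_size = np.exp(size_bm[0])

    for si, sp in enumerate(tree.tips):
        n_spec = int(rng.integers(lo, hi + 1))
        base = species_params.loc[sp].to_dict()
        for j in range(n_spec):
            sid = f"{sp}_s{j + 1}"
            jitter = {key: base[key] * (1.0 + rng.normal(0, 0.02))
                      if key == "elongation" else base[key] + rng.normal(0, 0.01)
                      for key in base}
            jitter["noise_sd"] = noise_sd
            jitter["seed"] = _subseed(seed, 4, si, j)
            outlines[sid] = synth_pygostyle_outline(_clip_params(jitter),
                                                    specimen_id=sid)
            spec_species[sid] = sp
            size = sp_size.loc[sp] * (1.0 + rng.normal(0, 0.02))
            sizes = {sz: size * (2.0 + 0.4 * k) * (1.0 + rng.normal(0, 0.03))
                     for k, sz in enumerate(SIZE_MEASUREMENTS)}
            # vertebral metrics scale with size, shrink caudally, and carry
            # measurement noise
            for pos, posfac in (("first", 1.0), ("middle", 0.85), ("last", 0.7)):
                row = {"species": sp, "specimen": sid, "position": pos}
                for mi, metric in enumerate(VERTEBRAL_METRICS):
                    base_val = 1.0 + 0.25 * np.sin(mi + 1.0)
                    row[metric] = size * posfac * base_val * (1.0 + rng.normal(0, 0.05))
                row.update(sizes)
                measurements.append(row)
    meas = pd.DataFrame(measurements)

    bundle = StudyBundle(tree=tree, groups=groups,
                         species_params=species_params, outlines=outlines,
                         specimen_species=pd.Series(spec_species, name="species"),
                         measurements=meas, seed=seed)
    if rasterize:
        bundle.images = {sid: rasterize_outline(o, px_per_unit)
                         for sid, o in outlines.items()}
    return bundle


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Serialize a bundle as plain-text files plus PNG masks if present."""
    out = Path(outdir)
    (out / "outlines").mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(bundle.tree.to_newick() + "\n")
    groups = pd.DataFrame({"species": bundle.groups.mapping.index,
                           "foraging_style": bundle.groups.mapping.values})
    groups.to_csv(out / "groups.csv", index=False)
    bundle.measurements.to_csv(out / "measurements.csv", index=False)
    for sid, o in bundle.outlines.items():
        pd.DataFrame(o.points, columns=["x", "y"]).to_csv(
            out / "outlines" / f"{sid}.csv", index=False)
    bundle.specimen_species.rename_axis("specimen").reset_index().to_csv(
        out / "specimens.csv", index=False)
    if bundle.images:
        from PIL import Image

        (out / "images").mkdir(exist_ok=True)
        for sid, img in bundle.images.items():
            Image.fromarray((img * 255).astype(np.uint8)).save(
                out / "images" / f"{sid}.png")
    (out / "manifest.json").write_text(json.dumps(
        {"seed": bundle.seed, "n_species": bundle.tree.n_tips,
         "classes": sorted(bundle.groups.mapping.unique())}, indent=2) + "\n")
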