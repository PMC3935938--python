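"""Linear vertebral measurements, body-size proxy, and ecological groups.

The measurement schema follows the study design: for each specimen, 11
vertebral metrics (centrum, transverse-process, spinous-process and ventral-
process dimensions) at three serial positions along the free caudal series
(first, middle, last), plus five body-size measurements (sternum, synsacrum,
femur) whose geometric mean serves as the size proxy.  Size correction is a
per-trait phylogenetic (Brownian, lambda = 1) GLS regression on the proxy,
keeping the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, gls_fit, lambda_transform, tree_vcv

__all__ = [
    "VERTEBRAL_METRICS",
    "SIZE_MEASUREMENTS",
    "POSITIONS",
    "FLIGHT_STYLES",
    "FORAGING_STYLES",
    "DIVING_TYPES",
    "GroupFactor",
    "read_measurements",
    "aggregate_specimens",
    "geometric_mean_size",
    "pgls_size_correct",
    "merge_foraging_groups",
    "read_groups",
]

# centrum length/width/height; transverse-process length/width; spinous-
# process length/width/height; ventral-process length/width/height
VERTEBRAL_METRICS = ("CL", "CW", "CH", "TPL", "TPW",
                     "SPL", "SPW", "SPH", "VPL", "VPW", "VPH")
SIZE_MEASUREMENTS = ("sternum_length", "sternum_width", "keel_height",
                     "synsacrum_length", "femur_length")
POSITIONS = ("first", "middle", "last")

FLIGHT_STYLES = frozenset({"Flap", "Flap-Glide", "Dynamic Soar", "Static Soar",
                           "Wing-Propelled Flightless", "Foot-Propelled Flightless"})
FORAGING_STYLES = frozenset({"Aerial", "Terrestrial", "Plunge Dive",
                             "Foot-Propelled Pursuit Dive",
                             "Wing-Propelled Pursuit Dive"})
DIVING_TYPES = frozenset({"Non-diving", "Plunge Dive",
                          "Foot-Propelled Pursuit Dive",
                          "Wing-Propelled Pursuit Dive"})

_ALLOWED = {"flight": FLIGHT_STYLES, "foraging": FORAGING_STYLES,
            "diving": DIVING_TYPES}


@dataclass(frozen=True)
class GroupFactor:
    """Species -> ecological category under one classification scheme."""

    mapping: pd.Series  # index = species, values = category
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in _ALLOWED:
            raise ValueError(f"unknown scheme {self.scheme!r}; "
                             f"expected one of {sorted(_ALLOWED)}")
        bad = set(self.mapping) - _ALLOWED[self.scheme]
        if bad:
            raise ValueError(
                f"labels {sorted(bad)} are not valid {self.scheme} categories")

    @property
    def species(self) -> list[str]:
        return list(self.mapping.index)

    def categories(self) -> list[str]:
        return sorted(self.mapping.unique())

    def subset(self, species) -> "GroupFactor":
        return GroupFactor(self.mapping.loc[list(species)], self.scheme)

    def indicator(self, species=None) -> pd.DataFrame:
        """One-hot species x category matrix, columns in sorted order."""
        m = self.mapping if species is None else self.mapping.loc[list(species)]
        return pd.get_dummies(m).astype(float)[sorted(m.unique())]


def read_measurements(path) -> pd.DataFrame:
    """Read and validate the per-specimen measurement CSV.

    Required columns: species, specimen, position, the 11 vertebral metrics
    and the 5 size measurements.  All measurements must be positive.
    """
    df = pd.read_csv(path)
    required = ["species", "specimen", "position", *VERTEBRAL_METRICS, *SIZE_MEASUREMENTS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    bad_pos = set(df["position"]) - set(POSITIONS)
    if bad_pos:
        raise ValueError(f"invalid positions {sorted(bad_pos)}; expected {POSITIONS}")
    vals = df[list(VERTEBRAL_METRICS) + list(SIZE_MEASUREMENTS)]
    if (vals <= 0).any().any() or vals.isna().any().any():
        raise ValueError("all measurements must be present and > 0")
    return df


def aggregate_specimens(m: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Species-mean trait matrix for each serial position.

    Duplicate rows for the same specimen and position (the two measured
    middle vertebrae) are averaged within the specimen first, then specimen
    values are averaged within species.
    """
    out: dict[str, pd.DataFrame] = {}
    metrics = list(VERTEBRAL_METRICS)
    for pos in POSITIONS:
        sub = m[m["position"] == pos]
        if sub.empty:
            continue
        per_specimen = sub.groupby(["species", "specimen"])[metrics].mean()
        out[pos] = per_specimen.groupby("species").mean().sort_index()
    return out


def geometric_mean_size(m: pd.DataFrame) -> pd.Series:
    """Per-species geometric mean of the five body-size measurements.

    Size measurements are specimen-level (repeated across position rows);
    specimen values are arithmetically averaged to species means first, then
    combined as exp(mean(log)).
    """
    sizes = list(SIZE_MEASUREMENTS)
    vals = m[["species", "specimen"] + sizes].drop_duplicates(
        subset=["species", "specimen"])
    if (vals[sizes] <= 0).any().any():
        raise ValueError("size measurements must be > 0")
    sp_means = vals.groupby("species")[sizes].mean()
    gm = np.exp(np.log(sp_means).mean(axis=1))
    gm.name = "size"
    return gm.sort_index()


def pgls_size_correct(traits: pd.DataFrame, size: pd.Series,
                      tree: Phylogeny, *, lam: float = 1.0,
                      log10: bool = False) -> pd.DataFrame:
    """Residuals of each trait from a phylogenetic regression on body size.

    Each column is regressed on intercept + size under the Brownian
    covariance of ``tree`` (off-diagonals scaled by ``lam``); the returned
    table holds the (raw-scale) GLS residuals, same shape as the input.
    """
    common = traits.index.intersection(size.index)
    if len(common) < len(traits.index):
        raise KeyError(f"species without size value: "
                       f"{list(traits.index.difference(size.index))[:5]}")
    cov = lambda_transform(tree_vcv(tree), lam).reorder(list(traits.index))
    s = size.loc[traits.index].to_numpy(float)
    if log10:
        s = np.log10(s)
    if np.allclose(s, s[0]):
        raise ValueError("size proxy is constant: singular design")
    X = np.column_stack([np.ones_like(s), s])
    resid = {}
    for col in traits.columns:
        y = traits[col].to_numpy(float)
        if log10:
            y = np.log10(y)
        fit = gls_fit(y, X, cov)
        resid[col] = fit.residuals
    return pd.DataFrame(resid, index=traits.index)


def merge_foraging_groups(g: GroupFactor) -> GroupFactor:
    """Collapse Aerial and Terrestrial foragers into a Non-diving class."""
    if g.scheme == "diving":
        return g
    if g.scheme != "foraging":
        raise ValueError("merge_foraging_groups requires the foraging scheme")
    merged = g.mapping.replace({"Aerial": "Non-diving", "Terrestrial": "Non-diving"})
    return GroupFactor(merged, "diving")


def read_groups(path, scheme: str) -> GroupFactor:
    """Read the species->group CSV (columns species, flight_style,
    foraging_style) and return the factor for one scheme."""
    df = pd.read_csv(path).set_index("species")
    col = {"flight": "flight_style", "foraging": "foraging_style"}.get(scheme)
    if col is None:
        raise ValueError("scheme must be 'flight' or 'foraging' when reading")
    if col not in df.columns:
        raise ValueError(f"group table missing column {col!r}")
    return GroupFactor(df[col], scheme)
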