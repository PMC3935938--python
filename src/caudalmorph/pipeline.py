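"""One-shot analysis pipeline.

Mirrors the study's analysis graph on any compatible inputs:

* outlines -> elliptic Fourier decomposition -> cumulative-power harmonic
  selection -> first-harmonic normalization -> species averaging ->
  (phylogenetic signal, phylogenetic PCA -> MANOVA, pFDA);
* linear measurements -> species aggregation -> geometric-mean size proxy
  -> phylogenetic size correction -> (signal, MANOVA, pFDA).

`run_pipeline` is the file-in/file-out wrapper used by the command line;
the `analyze_*` functions are the in-memory API used by tests and scripts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import efa as _efa
from .morphodata import (GroupFactor, aggregate_specimens, geometric_mean_size,
                         merge_foraging_groups, pgls_size_correct,
                         read_groups, read_measurements)
from .multivar import phylo_manova, phylo_pca, select_components
from .outlines import Outline, extract_outline
from .pfda import pfda_fit_predict, pfda_optimal_lambda
from .phylo import Phylogeny, read_newick
from .signal import fit_pagel_lambda, permutation_signal_test

__all__ = ["PipelineConfig", "run_pipeline", "outline_descriptors",
           "species_shape_matrix", "analyze_trait_matrix"]


@dataclass
class PipelineConfig:
    tree: str = ""
    outlines: str = ""            # directory of outline CSVs (id,x,y) or images
    measurements: str = ""
    groups: str = ""
    specimens: str = ""           # specimen -> species table for outlines
    outdir: str = "results"
    scheme: str = "foraging"
    merge_diving: bool = False
    power_threshold: float = 0.99
    n_max_harmonics: int = 32
    pc_min_percent: float = 5.0
    n_sim: int = 1000
    n_perm: int = 999
    seed: int = 0
    lambda_override: float | None = None
    log10_size: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.power_threshold <= 1:
            raise ValueError("power_threshold must be in (0, 1]")
        if not 0 <= self.pc_min_percent <= 100:
            raise ValueError("pc_min_percent must be in [0, 100]")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def outline_descriptors(outlines: dict[str, Outline],
                        power_threshold: float = 0.99,
                        n_max: int = 32) -> tuple[pd.DataFrame, int]:
    """Decompose, select harmonics sample-wide, normalize.

    Returns the specimen x free-variable table and the retained harmonic
    count N (smallest count whose mean cumulative power over specimens
    reaches the threshold).
    """
    raw = {sid: _efa.efa_decompose(o, n_max) for sid, o in outlines.items()}
    N = _efa.pooled_harmonic_count(raw, power_threshold)
    descs = {
        sid: _efa.efa_normalize(
            _efa.HarmonicSet(h.A0, h.C0, h.coeffs[:N], sid))
        for sid, h in raw.items()
    }
    return _efa.descriptors_to_frame(descs), N


def species_shape_matrix(outlines: dict[str, Outline],
                         specimen_species: pd.Series,
                         power_threshold: float = 0.99,
                         n_max: int = 32) -> tuple[pd.DataFrame, int]:
    """Specimen descriptors averaged to a species x (4N-3) trait matrix."""
    df, N = outline_descriptors(outlines, power_threshold, n_max)
    return _efa.average_by_species(df, specimen_species), N


def analyze_trait_matrix(X: pd.DataFrame, groups: GroupFactor, tree: Phylogeny,
                         *, pc_min_percent: float | None = 5.0,
                         n_sim: int = 1000, n_perm: int = 999, seed: int = 0,
                         lambda_override: float | None = None) -> dict:
    """Signal + phylogenetic PCA/MANOVA + pFDA on one species trait matrix.

    When ``pc_min_percent`` is not None the MANOVA and pFDA run on the
    retained phylogenetic PC scores; otherwise on the raw columns.
    """
    g = groups.subset(X.index)
    lam_fit = fit_pagel_lambda(X, tree)
    perm = permutation_signal_test(X, tree, n_perm=n_perm, seed=seed)
    out: dict = {
        "lambda_hat": lam_fit.lambda_hat,
        "lambda_loglik": lam_fit.log_lik,
        "perm_L_obs": perm.L_obs,
        "perm_p": perm.p,
        "perm_index": perm.index,
    }
    Z = X
    if pc_min_percent is not None:
        ppca = phylo_pca(X, tree)
        keep = select_components(ppca, pc_min_percent)
        Z = ppca.scores.iloc[:, keep]
        out["ppca_percent_variance"] = ppca.percent_variance
        out["ppca_kept"] = len(keep)
        out["ppca_scores"] = Z
    man = phylo_manova(Z, g, tree, n_sim=n_sim, seed=seed + 1)
    out["manova"] = man
    lam_d = (lambda_override if lambda_override is not None
             else pfda_optimal_lambda(Z, g, tree))
    res = pfda_fit_predict(Z, g, tree, lam_d)
    out["pfda"] = res
    return out


def _load_outlines(path: Path) -> dict[str, Outline]:
    out: dict[str, Outline] = {}
    csvs = sorted(path.glob("*.csv"))
    if csvs:
        for f in csvs:
            df = pd.read_csv(f)
            out[f.stem] = Outline(df[["x", "y"]].to_numpy(float), f.stem).canonical()
        return out
    from PIL import Image

    for f in sorted(list(path.glob("*.png")) + list(path.glob("*.tif"))
                    + list(path.glob("*.tiff"))):
        img = np.asarray(Image.open(f))
        out[f.stem] = extract_outline(img, specimen_id=f.stem)
    if not out:
        raise FileNotFoundError(f"no outline CSVs or images under {path}")
    return out


def _manova_row(dataset: str, grouping: str, man) -> dict:
    return {"dataset": dataset, "grouping": grouping, "df": man.df1,
            "pillai": man.pillai, "approx_F": man.approx_F,
            "p_ahistorical": man.p_ahistorical,
            "p_phylogenetic": man.p_phylogenetic}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis graph and write result tables.

    Returns the output directory.  Raises KeyError naming offending species
    on label mismatches; stage names are attached to propagated errors.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = read_newick(Path(cfg.tree).read_text())
    groups = read_groups(cfg.groups, cfg.scheme)
    if cfg.merge_diving and cfg.scheme == "foraging":
        groups = merge_foraging_groups(groups)
    missing = set(groups.species) - set(tree.tips)
    if missing:
        raise KeyError(f"species not in tree: {sorted(missing)}")

    log: dict = {"config": dataclasses.asdict(cfg), "config_hash": cfg.digest(),
                 "seed": cfg.seed, "n_species": tree.n_tips}
    manova_rows = []
    summaries = {}

    if cfg.outlines:
        outlines = _load_outlines(Path(cfg.outlines))
        spec_map = pd.read_csv(cfg.specimens, index_col="specimen")["species"] \
            if cfg.specimens else pd.Series({k: k for k in outlines})
        shape, N = species_shape_matrix(outlines, spec_map,
                                        cfg.power_threshold, cfg.n_max_harmonics)
        log["harmonics_retained"] = N
        log["shape_variables"] = shape.shape[1]
        shape.to_csv(outdir / "shape_descriptors_species.csv")
        res = analyze_trait_matrix(
            shape, groups, tree, pc_min_percent=cfg.pc_min_percent,
            n_sim=cfg.n_sim, n_perm=cfg.n_perm, seed=cfg.seed,
            lambda_override=cfg.lambda_override)
        log["shape_pcs_retained"] = res.get("ppca_kept")
        manova_rows.append(_manova_row("Pygostyle Shape", cfg.scheme, res["manova"]))
        _write_pfda(outdir, "pygostyle", res, groups)
        summaries["pygostyle_shape"] = _summary(res)
        if "ppca_scores" in res:
            res["ppca_scores"].to_csv(outdir / "pygostyle_ppca_scores.csv")

    if cfg.measurements:
        meas = read_measurements(cfg.measurements)
        per_pos = aggregate_specimens(meas)
        size = geometric_mean_size(meas)
        for pos, traits in per_pos.items():
            resid = pgls_size_correct(traits, size, tree, log10=cfg.log10_size)
            resid.to_csv(outdir / f"vertebra_{pos}_size_corrected.csv")
            res = analyze_trait_matrix(
                resid, groups, tree, pc_min_percent=None,
                n_sim=cfg.n_sim, n_perm=cfg.n_perm, seed=cfg.seed,
                lambda_override=cfg.lambda_override)
            manova_rows.append(_manova_row(f"{pos.capitalize()} Vertebra",
                                           cfg.scheme, res["manova"]))
            _write_pfda(outdir, f"vertebra_{pos}", res, groups)
            summaries[f"vertebra_{pos}"] = _summary(res)

    pd.DataFrame(manova_rows).to_csv(outdir / "manova_results.csv", index=False)
    log["summaries"] = summaries
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    return outdir


def _summary(res: dict) -> dict:
    return {
        "lambda_hat": res["lambda_hat"],
        "lambda_loglik": res["lambda_loglik"],
        "perm_p": res["perm_p"],
        "perm_index": res["perm_index"],
        "pillai": res["manova"].pillai,
        "p_ahistorical": res["manova"].p_ahistorical,
        "p_phylogenetic": res["manova"].p_phylogenetic,
        "pfda_lambda": res["pfda"].lambda_used,
        "misclassification_rate": res["pfda"].misclassification_rate,
    }


def _write_pfda(outdir: Path, stem: str, res: dict, groups: GroupFactor) -> None:
    r = res["pfda"]
    scores = r.scores.copy()
    scores["true_class"] = groups.mapping.loc[scores.index]
    scores["predicted_class"] = r.predicted
    scores.to_csv(outdir / f"{stem}_pfda_scores.csv")
    r.confusion.to_csv(outdir / f"{stem}_pfda_confusion.csv")
    (outdir / f"{stem}_pfda_summary.json").write_text(json.dumps(
        {"lambda": r.lambda_used,
         "misclassification_rate": r.misclassification_rate}, indent=2) + "\n")
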