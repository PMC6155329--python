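"""Config-driven batteries: per-clade, per-response model comparisons.

A battery reproduces the shape of a full comparative analysis for one
(clade, response) pair: the single-equilibrium OU null, a Brownian-motion
model, one OU regression per continuous predictor and one OU ANOVA per
categorical predictor (parsimony-painted), all compared by AICc with
simple and global Akaike weights.  The battery also flags the predictor
that both attains the highest simple weight *and* reduces the half-life
relative to the null — the signature of adaptation rather than inertia.

Each clade is analysed on its own subtree, rescaled to unit height.
Species with missing values for a predictor are dropped for that model
only.  Fitting is deterministic; re-running a config reproduces outputs
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .phylo import parse_newick, prune_to_tips, scale_to_unit_height, time_matrices
from .traits import build_species_table, read_accessions
from .regimes import fitch_reconstruct
from .ou import GridConfig, ModelSpec, OUFitResult, fit_model
from .selection import ModelComparisonTable, battery_weights

__all__ = ["BatteryConfig", "BatteryResult", "run_battery", "fit_battery", "report"]

log = logging.getLogger(__name__)

DEFAULT_CONTINUOUS = (
    "mean_temperature",
    "temperature_seasonality",
    "temperature_continentality",
    "annual_precipitation",
    "precipitation_seasonality",
)
DEFAULT_CATEGORICAL = (
    "growth_form",
    "flower_size",
    "inflorescence",
    "habitat_light",
    "habitat_nutrient",
    "habitat_moisture",
)


@dataclass
class BatteryConfig:
    tree_path: str = ""
    accessions_path: str = ""
    clades: Optional[Sequence[str]] = None          # None = all clades present
    responses: Sequence[str] = ("2n", "x")
    continuous: Sequence[str] = ()
    categorical: Sequence[str] = ()
    grid: GridConfig = field(default_factory=GridConfig)
    outdir: str = "battery_out"
    min_species: int = 3
    me_for_x: bool = True
    include_ancova: bool = False

    @classmethod
    def from_mapping(cls, m: dict) -> "BatteryConfig":
        m = dict(m)
        gkeys = {k: m.pop(k) for k in list(m) if k.startswith("grid_")}
        grid = GridConfig(**{k[len("grid_"):]: v for k, v in gkeys.items()})
        return cls(grid=grid, **m)


@dataclass
class BatteryResult:
    table: ModelComparisonTable
    fits: dict                      # model name -> OUFitResult
    skipped: dict                   # model name -> reason
    best_predictor: Optional[str]
    half_life_reduced: bool


def _response_columns(response: str) -> tuple:
    if response not in ("2n", "x"):
        raise ValueError(f"unknown response {response!r} (expected '2n' or 'x')")
    return (f"y_{response}", f"me_{response}")


def fit_battery(
    tree,
    species: pd.DataFrame,
    response: str,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    grid: GridConfig = GridConfig(),
    clade: str = "",
) -> BatteryResult:
    """Fit one battery on an already-pruned, unit-height clade subtree.

    ``species`` must contain one row per tree tip with the response
    columns (``y_2n``/``me_2n`` or ``y_x``/``me_x``) plus any predictor
    columns named in ``continuous`` / ``categorical``.
    """
    ycol, mecol = _response_columns(response)
    for col in (ycol, mecol):
        if col not in species:
            raise KeyError(f"species table lacks column {col!r}")
    for p in tuple(continuous) + tuple(categorical):
        if p not in species.columns:
            raise KeyError(f"unknown predictor column {p!r}")
    sp = species.set_index("species")
    orphans = sorted(set(sp.index) - set(tree.tip_labels))
    orphans += sorted(set(tree.tip_labels) - set(sp.index))
    if orphans:
        raise ValueError(f"tree/table species mismatch: {', '.join(orphans[:8])}")
    order = list(tree.tip_labels)
    y = sp.loc[order, ycol].to_numpy(dtype=float)
    me = sp.loc[order, mecol].to_numpy(dtype=float)
    tm = time_matrices(tree)

    fits: dict = {}
    skipped: dict = {}
    null_spec = ModelSpec("intercept_ou", response=response)
    fits[null_spec.name] = fit_model(tree, y, me, null_spec, grid=grid, tm=tm)
    bm_spec = ModelSpec("brownian", response=response)
    fits[bm_spec.name] = fit_model(tree, y, me, bm_spec, grid=grid, tm=tm)

    for pname in continuous:
        spec = ModelSpec("continuous_ou", (pname,), response)
        vals = pd.to_numeric(sp.loc[order, pname], errors="coerce")
        keep = vals.notna().to_numpy()
        if keep.sum() < 3:
            skipped[spec.name] = "fewer than 3 species with predictor values"
            continue
        if np.ptp(vals[keep].to_numpy(dtype=float)) == 0:
            skipped[spec.name] = "predictor constant within clade"
            continue
        sub_tree, sub_y, sub_me, sub_order = _subset(tree, order, keep, y, me)
        fits[spec.name] = fit_model(
            sub_tree,
            sub_y,
            sub_me,
            spec,
            predictor=vals[keep].to_numpy(dtype=float),
            grid=grid,
            tm=time_matrices(sub_tree) if sub_tree is not tree else tm,
        )

    for pname in categorical:
        spec = ModelSpec("categorical_ou", (pname,), response)
        vals = sp.loc[order, pname]
        keep = vals.notna().to_numpy()
        if keep.sum() < 3:
            skipped[spec.name] = "fewer than 3 species with predictor values"
            continue
        states = set(map(str, vals[keep]))
        if len(states) < 2:
            skipped[spec.name] = "predictor constant within clade"
            continue
        sub_tree, sub_y, sub_me, sub_order = _subset(tree, order, keep, y, me)
        tip_states = {t: str(vals[t]) for t in sub_order}
        painting = fitch_reconstruct(sub_tree, tip_states)
        fits[spec.name] = fit_model(
            sub_tree,
            sub_y,
            sub_me,
            spec,
            painting=painting,
            grid=grid,
            tm=time_matrices(sub_tree) if sub_tree is not tree else tm,
        )

    rows = pd.DataFrame(
        [
            {
                "model": name,
                "loglik": f.loglik,
                "k_params": f.k_params,
                "n": f.n,
                "aicc": f.aicc,
                "t_half": f.t_half if f.t_half is not None else np.nan,
                "v_y": f.v_y if f.v_y is not None else np.nan,
                "R2": f.r2,
            }
            for name, f in fits.items()
        ]
    )
    for name, reason in skipped.items():
        log.info("skipped %s (%s, %s): %s", name, clade, response, reason)
    table = battery_weights(rows, response=response, clade=clade)
    best, reduced = table.best_predictor()
    return BatteryResult(
        table=table,
        fits=fits,
        skipped=skipped,
        best_predictor=best,
        half_life_reduced=reduced,
    )


def _subset(tree, order, keep, y, me):
    """Prune the clade tree to the species with predictor data."""
    if keep.all():
        return tree, y, me, order
    kept = [t for t, k in zip(order, keep) if k]
    sub = scale_to_unit_height(prune_to_tips(tree, kept))
    idx = {t: i for i, t in enumerate(order)}
    sel = [idx[t] for t in sub.tip_labels]
    return sub, y[sel], me[sel], list(sub.tip_labels)


def run_battery(config: BatteryConfig) -> dict:
    """Run all (clade, response) batteries described by a config.

    Returns ``{(clade, response): BatteryResult}`` and writes TSV/JSON
    reports plus a run log under ``config.outdir``.
    """
    tree_full = parse_newick(Path(config.tree_path).read_text())
    acc = read_accessions(config.accessions_path)
    species = build_species_table(acc, me_for_x=config.me_for_x)
    pred_cols = [
        c
        for c in acc.columns
        if c not in ("species", "clade", "count_2n", "count_x")
    ]
    for p in tuple(config.continuous) + tuple(config.categorical):
        if p not in pred_cols:
            raise KeyError(f"unknown predictor column {p!r} in accession table")
    if pred_cols:
        firsts = acc.groupby("species", sort=True)[pred_cols].first().reset_index()
        species = species.merge(firsts, on="species")
    clades = list(config.clades) if config.clades else sorted(species["clade"].unique())
    results = {}
    for clade in clades:
        members = species[species["clade"] == clade]
        if len(members) < config.min_species:
            raise ValueError(
                f"clade {clade!r} has {len(members)} species (< {config.min_species})"
            )
        missing = sorted(set(members["species"]) - set(tree_full.tip_labels))
        if missing:
            raise ValueError(
                f"species absent from tree: {', '.join(missing[:8])}"
            )
        sub = scale_to_unit_height(prune_to_tips(tree_full, members["species"]))
        for response in config.responses:
            results[(clade, response)] = fit_battery(
                sub,
                members,
                response,
                continuous=config.continuous,
                categorical=config.categorical,
                grid=config.grid,
                clade=clade,
            )
    report(results, config)
    return results


def report(results: dict, config: BatteryConfig) -> None:
    """Write one TSV + JSON per battery and a plain-text run log."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for (clade, response), res in results.items():
        stem = f"battery_{clade}_{response}"
        res.table.to_tsv(out / f"{stem}.tsv")
        payload = res.table.to_json()
        payload["fits"] = {k: f.to_dict() for k, f in res.fits.items()}
        payload["skipped"] = res.skipped
        payload["best_predictor"] = res.best_predictor
        payload["half_life_reduced"] = res.half_life_reduced
        (out / f"{stem}.json").write_text(json.dumps(payload, indent=1))
        manifest.append(stem)
    cfg_text = json.dumps(
        {**{k: v for k, v in asdict(config).items() if k != "grid"},
         "grid": asdict(config.grid)},
        sort_keys=True,
        default=str,
    )
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    lines = [
        f"chromou {__version__}",
        f"config_hash {cfg_hash}",
        f"grid {asdict(config.grid)}",
        "batteries " + ", ".join(manifest),
    ]
    (out / "run.log").write_text("\n".join(lines) + "\n")
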