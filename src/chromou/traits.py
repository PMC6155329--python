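"""Accession-level chromosome counts to per-species model inputs.

Chromosome counts arrive one row per accession (a counted individual or
population sample) with the diploid number ``2n``, the basic number ``x``,
and a clade label.  The response used by the evolutionary models is the
species mean of the *natural-log* counts; within-species replicate scatter
is pooled across species and converted into a per-species observation
variance ``me_i = s2_pooled / n_i`` that enters the model covariance as a
diagonal addition.  Clade-level descriptive statistics (mean, SD, CV) are
computed on the raw count scale.

Input format: delimited text (TSV/CSV) with headered columns ``species``,
``clade``, ``count_2n``, ``count_x`` plus one column per predictor; missing
predictor values are empty fields.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "species_means",
    "pooled_observation_variance",
    "clade_summary",
    "ellenberg_categorize",
    "build_species_table",
    "read_accessions",
    "CLADES",
]

log = logging.getLogger(__name__)

#: the fixed six-way clade partition used throughout
CLADES = ("Monocots", "Fabids", "Malvids", "Caryophyllales", "Lamiids", "Campanulids")

#: Ellenberg indicator groupings: axis -> ordered (lo, hi, category)
_ELLENBERG = {
    "moisture": ((1, 4, "dry"), (5, 8, "moist"), (9, 12, "wet")),
    # note the light axis is inverted: high indicator values mean open habitat
    "light": ((1, 4, "forest"), (5, 8, "semi-shaded"), (9, 12, "open")),
    "nutrient": ((1, 3, "oligotrophic"), (4, 6, "mesotrophic"), (7, 9, "eutrophic")),
}


def ellenberg_categorize(value: int, axis: str) -> str:
    """Map an Ellenberg indicator value onto its habitat category.

    moisture: dry [1-4], moist [5-8], wet [9-12]; light: forest [1-4],
    semi-shaded [5-8], open [9-12]; nutrient: oligo- [1-3], meso- [4-6],
    eutrophic [7-9].
    """
    if axis not in _ELLENBERG:
        raise KeyError(f"unknown Ellenberg axis: {axis!r}")
    v = int(value)
    for lo, hi, cat in _ELLENBERG[axis]:
        if lo <= v <= hi:
            return cat
    lo = _ELLENBERG[axis][0][0]
    hi = _ELLENBERG[axis][-1][1]
    raise ValueError(f"{axis} indicator {value} outside [{lo}, {hi}]")


def _check_counts(counts: pd.Series, name: str) -> None:
    bad = counts[(~np.isfinite(counts)) | (counts <= 0)]
    if len(bad):
        raise ValueError(f"non-positive {name} count(s): {bad.head().tolist()}")


def species_means(records: pd.DataFrame, count_col: str = "count_2n") -> pd.DataFrame:
    """Per-species mean and within-species variance of log counts.

    Returns one row per species with ``n`` (accessions), ``mean_raw``
    (arithmetic mean of counts), ``y`` (mean of ln counts), and ``s2``
    (sample variance of ln counts, NaN for singletons).  The observation
    variance column ``me`` is left unset; see
    :func:`pooled_observation_variance`.
    """
    if "species" not in records or count_col not in records:
        raise KeyError(f"records need 'species' and {count_col!r} columns")
    counts = pd.to_numeric(records[count_col])
    _check_counts(counts, count_col)
    df = records.assign(_count=counts, _log=np.log(counts))
    g = df.groupby("species", sort=True)
    out = pd.DataFrame(
        {
            "n": g["_count"].size(),
            "mean_raw": g["_count"].mean(),
            "y": g["_log"].mean(),
            "s2": g["_log"].var(ddof=1),  # NaN when n == 1
        }
    )
    if "clade" in records:
        out["clade"] = g["clade"].first()
    return out.reset_index()


def pooled_observation_variance(traits: pd.DataFrame) -> pd.DataFrame:
    """Attach ``me = s2_pooled / n`` to every species.

    The pooled within-species variance is
    ``sum((n_i - 1) * s2_i) / sum(n_i - 1)`` over species with replicates;
    singletons receive ``s2_pooled / 1``.
    """
    rep = traits[traits["n"] >= 2]
    if len(rep) == 0:
        raise ValueError(
            "no species has replicate accessions: supply observation "
            "variances externally or set me=0 explicitly"
        )
    dof = (rep["n"] - 1).to_numpy(dtype=float)
    s2_pooled = float(np.sum(dof * rep["s2"].to_numpy()) / np.sum(dof))
    out = traits.copy()
    out["me"] = s2_pooled / out["n"].to_numpy(dtype=float)
    out.attrs["s2_pooled"] = s2_pooled
    return out


def clade_summary(traits: pd.DataFrame, trait_name: str = "2n") -> pd.DataFrame:
    """Mean, SD and coefficient of variation of raw species means per clade.

    ``cv = sd / mean`` across species ``mean_raw`` values on the raw count
    scale (so a Monocots 2n mean of 33.7 with SD 25.1 gives CV 0.74).
    """
    if "clade" not in traits:
        raise KeyError("traits table has no 'clade' column")
    rows = []
    for clade, grp in traits.groupby("clade", sort=False):
        if len(grp) < 2:
            raise ValueError(f"clade {clade!r} has fewer than 2 species")
        m = float(grp["mean_raw"].mean())
        sd = float(grp["mean_raw"].std(ddof=1))
        rows.append(
            {"clade": clade, "trait": trait_name, "mean": m, "sd": sd, "cv": sd / m}
        )
    return pd.DataFrame(rows)


def _species_x(sub: pd.DataFrame) -> int:
    """Majority basic number; ties go to the lowest value, with a warning."""
    vals = pd.to_numeric(sub["count_x"]).astype(int)
    vc = vals.value_counts()
    top = vc[vc == vc.max()].index
    if vals.nunique() > 1:
        choice = int(min(top))
        log.warning(
            "species %r has conflicting basic numbers %s; using %d",
            getattr(sub, "name", "?"), sorted(vals.unique().tolist()), choice,
        )
        return choice
    return int(vals.iloc[0])


def build_species_table(
    records: pd.DataFrame, me_for_x: bool = True
) -> pd.DataFrame:
    """Full species table for both responses (2n and x).

    Columns: species, clade, n, mean_raw, y_2n, me_2n, x, y_x, me_x.  The
    basic number is treated as a species constant (majority rule on
    conflict); observation variances are attached to the x response too
    unless ``me_for_x`` is False, in which case ``me_x`` is 0.
    """
    t2n = pooled_observation_variance(species_means(records, "count_2n"))
    _check_counts(pd.to_numeric(records["count_x"]), "count_x")
    xval = (
        records.groupby("species", sort=True)
        .apply(_species_x, include_groups=False)
        .rename("x")
        .reset_index()
    )
    out = t2n.rename(columns={"y": "y_2n", "s2": "s2_2n", "me": "me_2n"})
    out = out.merge(xval, on="species")
    out["y_x"] = np.log(out["x"].astype(float))
    out["me_x"] = out["me_2n"] if me_for_x else 0.0
    out.attrs["s2_pooled"] = t2n.attrs["s2_pooled"]
    return out


def read_accessions(path, sep: str | None = None) -> pd.DataFrame:
    """Read an accession table from TSV/CSV (separator sniffed by default)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"species", "count_2n", "count_x"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"accession table missing column(s): {sorted(missing)}")
    return df
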