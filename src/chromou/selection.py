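"""Small-sample AIC and Akaike weights for model batteries.

A *battery* is the set of models fitted to one (clade, response) pair: the
single-equilibrium OU null, a Brownian-motion model, and one adaptation
model per predictor.  Two weight conventions are reported:

* **global** weights — Akaike weights over all models in the battery;
* **simple** weights — weights over all models *excluding* the
  single-equilibrium OU null (whose simple weight is left blank).

Parameter counts are fixed package-wide so AICc orderings are
reproducible: intercept-only OU = 3, BM = 2, continuous OU = 4,
categorical OU = 2 + K optima, ANCOVA = 3 + K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["aicc", "akaike_weights", "battery_weights", "ModelComparisonTable"]


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1); requires n > k + 1."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * float(loglik) + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """w_m = exp(-delta_m / 2) / sum(exp(-delta / 2)), delta vs. the minimum."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc sequence")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass
class ModelComparisonTable:
    """One battery of fitted models with both weight conventions."""

    df: pd.DataFrame
    response: str = ""
    clade: str = ""

    def best_predictor(self, null_t_half: Optional[float] = None):
        """Name of the model with the highest simple weight, plus whether it
        also reduced the half-life relative to the null (the flag that
        earns bold-facing in a report)."""
        cand = self.df[self.df["simple_aicw"].notna()]
        if cand.empty:
            return None, False
        row = cand.loc[cand["simple_aicw"].idxmax()]
        reduced = False
        if null_t_half is None:
            null_rows = self.df[self.df["is_null"]]
            if not null_rows.empty:
                null_t_half = null_rows["t_half"].iloc[0]
        t = row.get("t_half")
        if (
            null_t_half is not None
            and t is not None
            and np.isfinite(null_t_half)
            and not pd.isna(t)
        ):
            reduced = bool(t < null_t_half)
        return str(row["model"]), reduced

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_json(self) -> dict:
        return {
            "clade": self.clade,
            "response": self.response,
            "models": self.df.replace({np.nan: None}).to_dict(orient="records"),
        }


def battery_weights(
    rows: pd.DataFrame,
    null_name: str = "(single-equilibrium O-U)",
    response: str = "",
    clade: str = "",
    simple_pairwise: bool = False,
) -> ModelComparisonTable:
    """Attach global and simple Akaike weights to a battery.

    ``rows`` needs ``model`` and ``aicc`` columns; exactly one row must be
    the single-equilibrium OU null (matched by ``null_name``).  Simple
    weights are normalized over all models except the null, which gets a
    blank.  ``simple_pairwise=True`` switches to the literal pairwise
    reading (each model reweighted against the null alone); the default
    convention is the one that reproduces published weight columns.
    """
    df = rows.copy().reset_index(drop=True)
    if "model" not in df or "aicc" not in df:
        raise KeyError("battery rows need 'model' and 'aicc' columns")
    is_null = df["model"] == null_name
    if is_null.sum() != 1:
        raise ValueError(
            f"battery must contain exactly one null model named {null_name!r}"
        )
    df["is_null"] = is_null
    df["global_aicw"] = akaike_weights(df["aicc"].to_numpy())
    simple = np.full(len(df), np.nan)
    others = ~is_null.to_numpy()
    if others.sum() == 0:
        raise ValueError("battery has no models besides the null")
    if simple_pairwise:
        null_aicc = float(df.loc[is_null, "aicc"].iloc[0])
        for i in np.flatnonzero(others):
            simple[i] = akaike_weights([df.at[i, "aicc"], null_aicc])[0]
    else:
        simple[others] = akaike_weights(df.loc[others, "aicc"].to_numpy())
    df["simple_aicw"] = simple
    return ModelComparisonTable(df=df, response=response, clade=clade)
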