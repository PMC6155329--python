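"""Synthetic trees, regimes, predictors and accession-level count data.

The generator produces datasets with the statistical structure the
analysis assumes: a unit-height pure-birth (Yule) tree, branch-painted
categorical niches, species traits evolved forward under an OU (or BM)
process toward regime optima, Brownian continuous predictors with
species-level means and SDs, and integer diploid counts with replicate
accessions whose within-species scatter exercises the pooled-variance
estimator.  All randomness flows through an explicit integer seed; the
same (seed, config) is bit-reproducible.

Default condition ranges mirror the granularity of the real study system
(clades of 67-200 species, ~1.7 accessions per species, log-scale
chromosome numbers around e^3 ≈ 20-30 for 2n).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import dendropy
from dendropy.simulate import treesim

from .phylo import Phylogeny, scale_to_unit_height
from .regimes import RegimePainting

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_regimes",
    "simulate_ou_trait",
    "simulate_bm_trait",
    "simulate_bm_predictor",
    "emit_accessions",
    "make_dataset",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic clade dataset.

    Defaults are the generating conditions used throughout the test
    battery: a 132-species clade (the size of the largest-but-one real
    clade), moderate inertia (t_half = 0.25 tree heights), stationary
    variance 0.3 in squared log units, three habitat regimes with optima
    spanning roughly one log unit, and 1-3 accessions per species with
    log-scale within-species SD 0.05.
    """

    n_tips: int = 132
    seed: int = 0
    t_half: float = 0.25
    v_y: float = 0.3
    optima: dict = field(default_factory=lambda: {"open": 3.1, "semi-shaded": 3.6, "forest": 4.0})
    regime_shift_prob: float = 0.05
    predictor_sigma2: float = 1.0
    accessions_min: int = 1
    accessions_max: int = 3
    within_species_sd: float = 0.05
    clade_label: str = "Monocots"

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be at least 3")
        if self.within_species_sd < 0:
            raise ValueError("within_species_sd must be non-negative")
        for name in ("v_y", "predictor_sigma2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticDataset:
    """A complete synthetic clade: tree, regimes, traits, accessions."""

    tree: Phylogeny
    true_painting: RegimePainting
    species: pd.DataFrame      # species, clade, y_true, tip state, predictors
    accessions: pd.DataFrame   # species, clade, count_2n, count_x, predictors
    config: SimulationConfig

    def write(self, outdir) -> None:
        """Emit the same Newick + TSV formats the pipeline reads."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        self.species.to_csv(out / "species.tsv", sep="\t", index=False)
        self.accessions.to_csv(out / "accessions.tsv", sep="\t", index=False)
        cfg = {k: v for k, v in vars(self.config).items()}
        lines = [f"{k} = {v!r}" for k, v in cfg.items()]
        (out / "config.txt").write_text("\n".join(lines) + "\n")


def simulate_yule_tree(n_tips: int, seed: int) -> Phylogeny:
    """Unit-height pure-birth tree with labeled tips sp0001..spNNNN.

    Built with dendropy's birth-death sampler (death rate 0); every tip
    branch is extended by one further exponential waiting time so that no
    terminal branch has zero length, then the tree is scaled to height 1.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be at least 3")
    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng
    )
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    dtree.seed_node.edge.length = None
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:04d}"
    tree = Phylogeny.from_dendropy(dtree)
    return scale_to_unit_height(tree)


def simulate_regimes(
    tree: Phylogeny, states: Sequence[str], shift_prob: float, seed: int
) -> tuple:
    """Branch-wise Bernoulli regime shifts from a root in state 0.

    Each branch flips to a uniformly chosen *other* state with probability
    ``shift_prob``.  Returns ``(painting, tip_states)`` where
    ``painting.change_count`` is the realized number of shift events (not
    a parsimony minimum).  Simpler than a continuous-time Markov process
    but sufficient to exercise parsimony mapping and the weight matrix.
    """
    states = tuple(states)
    if len(states) == 0:
        raise ValueError("need at least one regime state")
    if not (0.0 <= shift_prob <= 1.0):
        raise ValueError("shift_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    K = len(states)
    node_state = np.zeros(tree.n_nodes, dtype=np.intp)
    n_shifts = 0
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            node_state[v] = 0
            continue
        s = node_state[p]
        if K > 1 and rng.random() < shift_prob:
            offset = rng.integers(1, K)
            s = (s + offset) % K
            n_shifts += 1
        node_state[v] = s
    painting = RegimePainting(
        states=states, node_state=node_state, root_regime=0, change_count=n_shifts
    )
    tips = {lbl: states[node_state[i]] for i, lbl in enumerate(tree.tip_labels)}
    return painting, tips


def simulate_ou_trait(
    tree: Phylogeny,
    painting: RegimePainting,
    t_half: float,
    v_y: float,
    optima: dict,
    seed: int,
    y0: Optional[float] = None,
) -> np.ndarray:
    """Forward OU simulation along branches; returns tip values.

    Branch transition: child = parent * e^{-a t} + theta * (1 - e^{-a t})
    + Normal(0, v_y * (1 - e^{-2 a t})) with a = ln2 / t_half and theta
    the optimum of the branch's regime.  The root starts at ``y0``
    (default: the root regime's optimum, matching how the root's
    influence is folded into that regime's design column).
    """
    missing = [s for s in painting.states if s not in optima]
    if missing:
        raise KeyError(f"no optimum for regime(s): {', '.join(map(str, missing))}")
    if not (np.isfinite(t_half) and t_half > 0):
        raise ValueError("t_half must be positive and finite (use simulate_bm_trait)")
    alpha = LN2 / t_half
    rng = np.random.default_rng(seed)
    vals = np.zeros(tree.n_nodes)
    theta_root = float(optima[painting.states[painting.root_regime]])
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            vals[v] = theta_root if y0 is None else float(y0)
            continue
        t = tree.branch_length[v]
        theta = float(optima[painting.states[painting.node_state[v]]])
        fade = np.exp(-alpha * t)
        sd = np.sqrt(v_y * -np.expm1(-2.0 * alpha * t))
        vals[v] = vals[p] * fade + theta * (1.0 - fade) + rng.normal(0.0, sd)
    return vals[: tree.n_tips].copy()


def simulate_bm_trait(
    tree: Phylogeny, sigma2: float, seed: int, y0: float = 0.0
) -> np.ndarray:
    """Forward Brownian simulation: child = parent + Normal(0, sigma2 * t)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    vals = np.zeros(tree.n_nodes)
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            vals[v] = y0
            continue
        vals[v] = vals[p] + rng.normal(0.0, np.sqrt(sigma2 * tree.branch_length[v]))
    return vals[: tree.n_tips].copy()


def simulate_bm_predictor(
    tree: Phylogeny,
    sigma2: float,
    seed: int,
    mean: float = 0.0,
    sd_scale: float = 0.1,
) -> pd.DataFrame:
    """Brownian per-species predictor means with positive species SDs.

    Tip values are a BM realization started at ``mean``; the species-level
    SD column (emulating within-range environmental spread) is drawn from
    a Gamma(2, sd_scale/2) distribution, always positive.
    """
    vals = simulate_bm_trait(tree, sigma2, seed, y0=mean)
    rng = np.random.default_rng(seed + 1)
    sds = rng.gamma(shape=2.0, scale=sd_scale / 2.0, size=tree.n_tips)
    return pd.DataFrame(
        {"species": list(tree.tip_labels), "mean": vals, "sd": sds}
    )


def emit_accessions(
    y_true: pd.Series | dict,
    config: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """Integer diploid counts per accession from true log-2n species values.

    Per species, ``n_i ~ Uniform{accessions_min..accessions_max}``
    accessions are drawn; each count is the nearest even integer >= 4 of
    ``exp(y_true + Normal(0, within_species_sd))`` (diploid counts are
    even by convention; the log-normal scatter stands in for miscounts and
    cytotype variation).  The basic number ``x`` is a species constant:
    the species' mean count divided by an assigned ploidy level (1 or 2),
    halved and clipped to >= 2.
    """
    if config.within_species_sd < 0:
        raise ValueError("within_species_sd must be non-negative")
    rng = np.random.default_rng(seed)
    items = list(y_true.items())
    rows = []
    for species, y in items:
        n_i = int(rng.integers(config.accessions_min, config.accessions_max + 1))
        ploidy = int(rng.integers(1, 3))  # 1 = diploid, 2 = tetraploid-derived
        mean_count = float(np.exp(y))
        x = max(2, round(mean_count / 2.0 / ploidy))
        for _ in range(n_i):
            val = float(np.exp(y + rng.normal(0.0, config.within_species_sd)))
            count = max(4, int(2 * round(val / 2.0)))
            rows.append(
                {
                    "species": species,
                    "clade": config.clade_label,
                    "count_2n": count,
                    "count_x": x,
                }
            )
    return pd.DataFrame(rows)


def make_dataset(config: SimulationConfig) -> SyntheticDataset:
    """End-to-end synthetic clade generation from one config + seed.

    Sub-seeds for the tree, regimes, trait, predictor and accession draws
    are derived deterministically from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)]
    tree = simulate_yule_tree(config.n_tips, sub[0])
    states = tuple(config.optima.keys())
    painting, tip_states = simulate_regimes(
        tree, states, config.regime_shift_prob, sub[1]
    )
    y = simulate_ou_trait(
        tree, painting, config.t_half, config.v_y, config.optima, sub[2]
    )
    pred = simulate_bm_predictor(tree, config.predictor_sigma2, sub[3])
    species = pd.DataFrame(
        {
            "species": list(tree.tip_labels),
            "clade": config.clade_label,
            "y_true": y,
            "habitat_light": [tip_states[t] for t in tree.tip_labels],
            "mean_temperature": pred["mean"].to_numpy(),
            "mean_temperature_sd": pred["sd"].to_numpy(),
        }
    )
    acc = emit_accessions(
        pd.Series(y, index=list(tree.tip_labels)), config, sub[4]
    )
    acc = acc.merge(
        species[["species", "habitat_light", "mean_temperature"]], on="species"
    )
    return SyntheticDataset(
        tree=tree,
        true_painting=painting,
        species=species,
        accessions=acc,
        config=config,
    )
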