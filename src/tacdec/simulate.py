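"""Synthetic phylogenies, traits and game fixtures.

The comparative stage needs a phylogeny and a species trait table with the
statistical structure that lambda = 1 PGLS assumes. This module generates
them: a Yule (pure-birth) tree, Brownian-motion (BM) trait evolution along
its branches, an integer cooperativeness score in {0..3} obtained by
thresholding a latent BM trait (so the score carries phylogenetic signal,
mirroring a sum of three present/absent cooperative behaviours), iid
log-normal research-effort counts, and deception counts whose
ln(count + 1) is linear in the predictors with BM-distributed residuals.

Everything is deterministic given the seed (NumPy's default PCG64
generator); the generating coefficients are returned alongside the data so
parameter-recovery experiments can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import dendropy
import numpy as np
import pandas as pd

from .game import (
    EquilibriumReport,
    GameParams,
    PopulationState,
    Trajectory,
    classify_regime,
    find_mixed_equilibrium,
    integrate,
    jacobian_stability,
)

__all__ = [
    "SyntheticSpec",
    "simulate_yule_tree",
    "simulate_bm",
    "simulate_comparative_dataset",
    "GameFixture",
    "generate_game_fixtures",
    "DEFAULT_GAME_PARAM_SETS",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating model for a synthetic comparative dataset.

    Defaults emulate a modest primate-scale collation: 24 species, effort
    counts centred around e^4 ≈ 55 publications, a cooperativeness effect of
    0.9 on the log response and a Brownian residual rate of 0.2 per unit of
    tree depth.
    """

    seed: int
    n_tips: int = 24
    birth_rate: float = 1.0
    beta: dict = field(
        default_factory=lambda: {
            "intercept": 1.0,
            "cooperativeness": 0.9,
            "log_research_effort": 0.5,
        }
    )
    sigma2: float = 0.2
    effort_log_mean: float = 4.0
    effort_log_sd: float = 1.0
    count_model: Literal["round", "poisson"] = "round"
    coop_quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        for name in ("birth_rate", "sigma2", "effort_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def simulate_yule_tree(
    n_tips: int | None = None,
    birth_rate: float = 1.0,
    seed: int = 0,
    max_time: float | None = None,
) -> dendropy.Tree:
    """Simulate a rooted, bifurcating, ultrametric pure-birth tree.

    Exactly one of ``n_tips`` (stop when that many lineages exist, then let
    the final inter-event time elapse so pendant edges are positive) or
    ``max_time`` (run the birth process for a fixed duration starting from a
    single lineage; tip number is then random with mean e^(rate * T)) must
    be given. Identical seeds give identical Newick strings.
    """
    if (n_tips is None) == (max_time is None):
        raise ValueError("specify exactly one of n_tips or max_time")
    if n_tips is not None and n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root._birth = 0.0
    active: list[dendropy.Node] = [root]
    t = 0.0
    while True:
        k = len(active)
        if n_tips is not None and k == n_tips:
            t_end = t + rng.exponential(1.0 / (k * birth_rate))
            break
        wait = rng.exponential(1.0 / (k * birth_rate))
        if max_time is not None and t + wait > max_time:
            t_end = max_time
            break
        t += wait
        node = active.pop(int(rng.integers(k)))
        node._split = t
        for _ in range(2):
            child = dendropy.Node()
            child._birth = t
            node.add_child(child)
            active.append(child)
    # positions: internal node = its split time, leaf = t_end
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        pos = getattr(node, "_split", t_end)
        if parent is not None:
            node.edge.length = pos - parent._split
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"sp{i + 1:03d}")
    tree.is_rooted = True
    return tree


def simulate_bm(
    tree: dendropy.Tree,
    sigma2: float,
    root_state: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Brownian motion along the tree; returns tip values by label.

    Each branch adds an independent Normal(0, sigma2 * branch length)
    increment, so tip covariance equals sigma2 times shared path length —
    exactly the error model of lambda = 1 PGLS — and standardized contrasts
    of the output are iid Normal(0, sigma2).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._bm = float(root_state)
        else:
            edge = node.edge.length or 0.0
            node._bm = node.parent_node._bm + rng.normal(0.0, np.sqrt(sigma2 * edge))
        if node.is_leaf():
            values[node.taxon.label] = node._bm
    return pd.Series(values, name="bm")


def simulate_comparative_dataset(
    spec: SyntheticSpec,
) -> tuple[dendropy.Tree, pd.DataFrame, dict]:
    """Generate a (tree, trait table, truth) triple per ``spec``.

    Cooperativeness is a latent BM trait cut at the quantiles in
    ``spec.coop_quantiles``; neocortex ratio and volume derive from a shared
    latent BM trait (they are correlated, as in real brains); research
    effort is iid log-normal; the latent log response is
    sum(beta * predictor) + BM(sigma2) noise and the deception count is
    round(e^latent - 1) floored at 0 (or Poisson with that mean when
    ``count_model='poisson'``).
    """
    rng = np.random.default_rng(spec.seed)
    sub = [int(x) for x in rng.integers(0, 2**31 - 1, size=5)]
    tree = simulate_yule_tree(spec.n_tips, spec.birth_rate, seed=sub[0])
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    latent_coop = simulate_bm(tree, 1.0, 0.0, seed=sub[1]).loc[species]
    cuts = np.quantile(latent_coop, spec.coop_quantiles)
    coop = np.sum(latent_coop.to_numpy()[:, None] > cuts[None, :], axis=1)

    brain = simulate_bm(tree, 0.25, 0.0, seed=sub[2]).loc[species].to_numpy()
    neocortex_volume = np.exp(3.0 + brain)
    neocortex_ratio = np.exp(0.8 + 0.4 * brain)

    effort_rng = np.random.default_rng(sub[3])
    research_effort = np.maximum(
        1,
        np.ceil(
            np.exp(effort_rng.normal(spec.effort_log_mean, spec.effort_log_sd, len(species)))
        ).astype(int),
    )

    noise = simulate_bm(tree, spec.sigma2, 0.0, seed=sub[4]).loc[species].to_numpy()
    beta = spec.beta
    latent = (
        beta.get("intercept", 0.0)
        + beta.get("cooperativeness", 0.0) * coop
        + beta.get("neocortex_ratio", 0.0) * neocortex_ratio
        + beta.get("log_neocortex_volume", 0.0) * np.log(neocortex_volume)
        + beta.get("log_research_effort", 0.0) * np.log(research_effort)
        + noise
    )
    mean_counts = np.maximum(np.expm1(latent), 0.0)
    if spec.count_model == "poisson":
        counts = np.random.default_rng(spec.seed + 1).poisson(mean_counts)
    else:
        counts = np.round(mean_counts).astype(int)
    table = pd.DataFrame(
        {
            "species": species,
            "deception_count": counts,
            "cooperativeness": coop,
            "neocortex_ratio": neocortex_ratio,
            "neocortex_volume": neocortex_volume,
            "research_effort": research_effort,
        }
    )
    truth = {
        "beta": dict(beta),
        "sigma2": spec.sigma2,
        "n_tips": spec.n_tips,
        "birth_rate": spec.birth_rate,
        "seed": spec.seed,
        "count_model": spec.count_model,
    }
    return tree, table, truth


#: reproduction parameter sets for the three qualitative dynamical outcomes;
#: the deception cost d is an admissible choice satisfying the constraint set
#: (d = 0.1 for the collapse and stable-mix regimes, d = 0.45 for the
#: bistable regime), not a published value.
DEFAULT_GAME_PARAM_SETS = {
    "collapse": GameParams(b=1.5, c=0.5, s=0.2, d=0.1, q_mode="constant", q=0.8),
    "bistable": GameParams(b=1.5, c=0.5, s=0.2, d=0.45, q_mode="constant", q=0.5),
    "stable_mix": GameParams(b=1.5, c=0.5, s=0.2, d=0.1, q_mode="freq_dependent"),
}


@dataclass(frozen=True)
class GameFixture:
    """A labelled dynamics fixture for regression testing."""

    name: str
    params: GameParams
    label: Literal["collapse", "bistable", "stable_mix"]
    trajectory: Trajectory
    equilibrium: EquilibriumReport


def generate_game_fixtures(
    param_sets: dict[str, GameParams] | None = None,
    t_end: float = 300.0,
) -> list[GameFixture]:
    """Trajectories plus the attracting equilibrium for each parameter set.

    Each set is labelled by regime (constant q) or as a stable mixture
    (frequency-dependent q); trajectories start from a nearly monomorphic
    CC population invaded by rare TDs and HDs.
    """
    if param_sets is None:
        param_sets = DEFAULT_GAME_PARAM_SETS
    start = PopulationState(0.98, 0.01, 0.01)
    fixtures = []
    for name, params in param_sets.items():
        traj = integrate(start, params, t_end=t_end)
        if params.q_mode == "freq_dependent":
            eq = find_mixed_equilibrium(params)
            if eq is None:
                raise ValueError(f"param set {name!r} has no stable mixture")
            label = "stable_mix"
        else:
            regime = classify_regime(params)
            if regime.label == "cooperation_collapse":
                label = "collapse"
                eq = jacobian_stability(PopulationState(0.0, 0.0, 1.0), params)
            else:
                label = "bistable"
                eq = jacobian_stability(PopulationState(1.0, 0.0, 0.0), params)
        fixtures.append(
            GameFixture(name=name, params=params, label=label, trajectory=traj, equilibrium=eq)
        )
    return fixtures
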