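"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of the empirical study: an ultrametric
dated phylogeny; species-level diet diversity x and venom diversity y evolving
as bivariate Brownian motion (y = b0 + b1*x + Brownian residual); a handful of
venomic records per species whose compositions are Dirichlet draws tuned so
each record's *expected* diversity index hits a noisy target around y_true;
and per-species multinomial prey-record counts whose category probabilities
are solved so the diet index matches x_true.

Diversity targets are imposed on the expected index of the Dirichlet draw by
a one-dimensional solve for the symmetric concentration parameter, using the
closed forms  E[1 - sum p_i^2] = (1 - 1/K) * K*alpha / (K*alpha + 1)  and
E[-sum p_i ln p_i] = psi(K*alpha + 1) - psi(alpha + 1).  Within-species
variance therefore arises from genuine compositional sampling rather than
additive Gaussian noise on the index scale.

Trait values live directly on the index scale (the regression is run on
indices); targets outside the attainable range [0, max index for the category
count] are clipped and counted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special

from .errors import ValidationError
from .phylo import Phylogeny, write_tree
import dendropy

logger = logging.getLogger(__name__)

_STAGE_TREE, _STAGE_TRAITS, _STAGE_RECORDS = 1, 2, 3


@dataclass
class SyntheticScenario:
    """A stated world: all knobs of the generative model with defaults chosen
    to mirror the empirical dataset's shape (tens of species, 1-4 venomic
    records each, toxin-family panels of ~15 families, Gini-Simpson scale).

    ``b0``/``b1`` are the true evolutionary regression intercept and slope on
    the index scale; ``sigma2_x`` and ``sigma2_y_resid`` are Brownian rates
    per unit branch length; ``within_sd_y`` scatters each record's target
    diversity around the species value.
    """

    n_species: int = 66
    tree_model: str = "yule"  # yule | star | fixed_newick
    birth_rate: float = 1.0
    newick: str | None = None
    index: str = "simpson"
    x_root: float = 0.55
    b0: float = 0.4
    b1: float = 0.15
    sigma2_x: float = 0.005
    sigma2_y_resid: float = 0.002
    within_sd_y: float = 0.03
    replicates_range: tuple[int, int] = (1, 4)
    n_toxin_families: int = 15
    n_prey_categories: int = 15
    dirichlet_concentration_range: tuple[float, float] = (1e-3, 1e6)
    diet_records_range: tuple[int, int] = (20, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValidationError("n_species must be >= 3")
        if self.sigma2_x <= 0 or self.sigma2_y_resid <= 0:
            raise ValidationError("Brownian rates must be positive")
        for rng_pair in (self.replicates_range, self.diet_records_range,
                         self.dirichlet_concentration_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValidationError(f"range {rng_pair} is not ordered")
        if self.tree_model not in {"yule", "star", "fixed_newick"}:
            raise ValidationError(f"unknown tree model {self.tree_model!r}")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage,))
        )


# ---------------------------------------------------------------------------
# index arithmetic on parametric compositions
# ---------------------------------------------------------------------------

def max_index(index: str, k: int) -> float:
    """Largest attainable value of an index over k categories."""
    return math.log(k) if index == "shannon" else 1.0 - 1.0 / k


def expected_index_dirichlet(index: str, alpha: float, k: int) -> float:
    """Expected diversity of a symmetric Dirichlet(alpha) composition."""
    if index == "simpson":
        return (1.0 - 1.0 / k) * k * alpha / (k * alpha + 1.0)
    return float(scipy.special.psi(k * alpha + 1.0) - scipy.special.psi(alpha + 1.0))


def concentration_for_index(
    index: str,
    target: float,
    k: int,
    bounds: tuple[float, float] = (1e-3, 1e6),
) -> float:
    """Symmetric Dirichlet concentration whose expected index equals target.

    Clamped to ``bounds``; targets at/above the attainable maximum saturate at
    the upper bound (near-uniform draws), targets at/below zero at the lower.
    """
    lo, hi = bounds
    if target <= expected_index_dirichlet(index, lo, k):
        return lo
    if target >= expected_index_dirichlet(index, hi, k):
        return hi
    if index == "simpson":
        u = target / (1.0 - 1.0 / k)
        return min(max(u / (1.0 - u) / k, lo), hi)
    f = lambda la: expected_index_dirichlet(index, math.exp(la), k) - target
    return math.exp(scipy.optimize.brentq(f, math.log(lo), math.log(hi), xtol=1e-12))


def _geometric_probs(r: float, k: int) -> np.ndarray:
    p = r ** np.arange(k, dtype=float)
    return p / p.sum()


def evenness_probs(index: str, target: float, k: int) -> np.ndarray:
    """Deterministic probability vector over k categories whose index equals
    ``target``: a geometric family p_i ~ r**i, with the decay r solved by
    bisection (r = 1 is uniform/maximal, r -> 0 is single-category/zero)."""
    from .compositions import diversity

    top = max_index(index, k)
    if target >= top:
        return np.full(k, 1.0 / k)
    if target <= 0:
        p = np.zeros(k)
        p[0] = 1.0
        return p
    f = lambda r: diversity(_geometric_probs(r, k), index) - target
    r = scipy.optimize.brentq(f, 1e-12, 1.0, xtol=1e-14)
    return _geometric_probs(r, k)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _yule_newick(n: int, birth_rate: float, rng: np.random.Generator) -> str:
    """Forward Yule simulation; all tips extended to the final time so the
    tree is exactly ultrametric."""
    children: dict[int, list[int]] = {}
    start = {0: 0.0}
    active = [0]
    t, next_id = 0.0, 1
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        kids = [next_id, next_id + 1]
        next_id += 2
        children[node] = kids
        for kid in kids:
            start[kid] = t
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / (birth_rate * n))

    labels = iter(f"sp{i + 1:03d}" for i in range(n))

    def fmt(node: int) -> str:
        if node in children:
            inner = ",".join(fmt(c) for c in children[node])
            end = start[children[node][0]]
            return f"({inner}):{end - start[node]:.12g}"
        return f"{next(labels)}:{t_end - start[node]:.12g}"

    return fmt(0) + ";"


def simulate_tree(scenario: SyntheticScenario) -> Phylogeny:
    """Simulate (or load) the scenario's ultrametric rooted phylogeny."""
    if scenario.tree_model == "fixed_newick":
        if not scenario.newick:
            raise ValidationError("tree_model fixed_newick requires scenario.newick")
        newick = scenario.newick
    elif scenario.tree_model == "star":
        tips = ",".join(f"sp{i + 1:03d}:1" for i in range(scenario.n_species))
        newick = f"({tips});"
    else:
        newick = _yule_newick(scenario.n_species, scenario.birth_rate,
                              scenario.rng(_STAGE_TREE))
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True
    )


# ---------------------------------------------------------------------------
# trait and record simulation
# ---------------------------------------------------------------------------

def simulate_bivariate_traits(
    tree: Phylogeny, scenario: SyntheticScenario
) -> dict[str, tuple[float, float]]:
    """Exact Brownian simulation of (x_true, y_true) per species.

    x accumulates N(0, sigma2_x * branch length) increments from the root
    value; the residual of y accumulates independently at rate
    sigma2_y_resid; y_true = b0 + b1 * x_true + residual.  The implied
    cross-species covariance of x is sigma2_x * C and the Brownian cross-rate
    is b1 * sigma2_x, exactly the structure the regression model assumes.
    """
    rng = scenario.rng(_STAGE_TRAITS)
    values: dict[int, tuple[float, float]] = {id(tree.seed_node): (scenario.x_root, 0.0)}
    out: dict[str, tuple[float, float]] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            px, pe = values[id(node.parent_node)]
            bl = node.edge.length or 0.0
            x = px + rng.normal(0.0, math.sqrt(scenario.sigma2_x * bl))
            e = pe + rng.normal(0.0, math.sqrt(scenario.sigma2_y_resid * bl))
            values[id(node)] = (x, e)
        if node.is_leaf():
            x, e = values[id(node)]
            out[node.taxon.label] = (x, scenario.b0 + scenario.b1 * x + e)
    return out


def simulate_records(
    species_values: dict[str, tuple[float, float]],
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Generate venom and diet input tables realizing the true trait values.

    Venom: per species, m ~ uniform(replicates_range) records, each a
    Dirichlet composition whose concentration is solved so the expected index
    equals y_true + N(0, within_sd_y) (clipped into the attainable range).
    Diet: a single multinomial draw of N ~ uniform(diet_records_range) prey
    records with category probabilities solved so the index equals x_true.
    Prey categories are nested two families per order.  Returns the two
    tables plus the count of clipped diversity targets.
    """
    rng = scenario.rng(_STAGE_RECORDS)
    index, kv, kd = scenario.index, scenario.n_toxin_families, scenario.n_prey_categories
    max_v, max_d = max_index(index, kv), max_index(index, kd)
    venom_rows, diet_rows = [], []
    n_clipped = 0

    for species in sorted(species_values):
        x_true, y_true = species_values[species]
        # venomic records
        m = int(rng.integers(scenario.replicates_range[0], scenario.replicates_range[1] + 1))
        for j in range(m):
            target = y_true + rng.normal(0.0, scenario.within_sd_y)
            if target < 0.0 or target > max_v:
                n_clipped += 1
                target = min(max(target, 0.0), max_v)
            if target <= 0.0:
                comp = np.zeros(kv)
                comp[int(rng.integers(kv))] = 1.0
            else:
                alpha = concentration_for_index(
                    index, target, kv, scenario.dirichlet_concentration_range
                )
                comp = rng.dirichlet(np.full(kv, alpha))
            record_id = f"{species}_r{j + 1}"
            method = "proteome" if rng.random() < 0.5 else "transcriptome"
            source = f"synthstudy_{record_id}"
            for fam, frac in enumerate(comp):
                venom_rows.append(
                    (species, record_id, source, method, f"Tox{fam + 1:02d}", 100.0 * frac)
                )
        # diet records
        x_target = x_true
        if x_target < 0.0 or x_target > max_d:
            n_clipped += 1
            x_target = min(max(x_target, 0.0), max_d)
        probs = evenness_probs(index, x_target, kd)
        n_items = int(rng.integers(scenario.diet_records_range[0],
                                   scenario.diet_records_range[1] + 1))
        counts = rng.multinomial(n_items, probs)
        for cat, count in enumerate(counts):
            if count > 0:
                diet_rows.append(
                    (species, f"Fam{cat + 1:02d}", f"Ord{cat // 2 + 1:02d}", int(count))
                )

    if n_clipped:
        logger.info("simulate_records: clipped %d unattainable diversity targets", n_clipped)
    venom = pd.DataFrame(
        venom_rows,
        columns=["species", "record_id", "source", "method", "toxin_family",
                 "percent_abundance"],
    )
    diet = pd.DataFrame(
        diet_rows, columns=["species", "prey_family", "prey_order", "n_records"]
    )
    return venom, diet, n_clipped


def scenario_dataset(
    scenario: SyntheticScenario,
    level: str = "family",
    with_x_sampling_variance: bool = False,
):
    """Simulate one scenario and run it through the compositional stages
    in memory (no files): per-record venom indices, filtered per-species diet
    indices, species summary and Brownian covariance.

    Returns ``(SpeciesSummary, PhyloCovariance, truth)`` where truth maps
    species to (x_true, y_true).  With ``with_x_sampling_variance`` the
    delta-method variance of the plug-in diet index is propagated into the
    summary (otherwise diet diversity is treated as exact, as in the
    empirical pipeline).
    """
    from . import compositions as comp
    from .phylo import bm_covariance
    from .regression import summarize_replicates

    tree = simulate_tree(scenario)
    truth = simulate_bivariate_traits(tree, scenario)
    venom, diet, _ = simulate_records(truth, scenario)
    tables, _ = comp.filter_diet(comp.aggregate_diet(diet, level))
    x_val = {t.species_id: comp.diversity(t.proportions, scenario.index) for t in tables}
    rows = [
        (sp, x_val[sp], comp.diversity(g["percent_abundance"].to_numpy(), scenario.index))
        for (sp, _), g in venom.groupby(["species", "record_id"], sort=False)
        if sp in x_val
    ]
    data = summarize_replicates(rows)
    if with_x_sampling_variance:
        x_var = {
            t.species_id: comp.index_sampling_variance(
                list(t.counts.values()), scenario.index
            )
            for t in tables
        }
        data.sampling_var_x = np.array([x_var[sp] for sp in data.taxa])
    C = bm_covariance(tree).reorder(data.taxa)
    return data, C, truth


def write_scenario_bundle(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Emit venom.csv, diet.csv, tree.nwk and truth.json for one scenario.

    The files are exactly the formats the pipeline reads; truth.json records
    the true regression line, per-species trait values and the seed.  Same
    scenario + seed => byte-identical bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(scenario)
    truth = simulate_bivariate_traits(tree, scenario)
    venom, diet, n_clipped = simulate_records(truth, scenario)

    paths = {
        "venom": outdir / "venom.csv",
        "diet": outdir / "diet.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    venom.to_csv(paths["venom"], index=False)
    diet.to_csv(paths["diet"], index=False)
    write_tree(tree, paths["tree"])
    payload = {
        "scenario": asdict(scenario),
        "b0": scenario.b0,
        "b1": scenario.b1,
        "seed": scenario.seed,
        "n_clipped_targets": n_clipped,
        "species": {
            sp: {"x_true": x, "y_true": y} for sp, (x, y) in sorted(truth.items())
        },
    }
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths
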