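"""Synthetic trees, communities and occurrence grids with known structure.

The tree simulator is ages-first: conditional on the root age t_1, the
remaining n - 2 node ages are i.i.d. draws from the birth-death node-age
density λ p1(t) / v_{t_1}, obtained by inverting the closed-form CDF
v_t / v_{t_1}; the topology is then built backward by merging uniformly
chosen lineage pairs at each successive age.  This matches the likelihood's
exchangeable-density form exactly, so the simulator and the likelihood are
mutually validating, and the uniform pairing reproduces the equiprobable
labeled histories of the reconstructed process.

Grid generation plants the latitudinal signal the analysis is meant to
detect: low-latitude ("tropical") cells draw their species with inclusion
probabilities concentrated on a few clades, high-latitude cells draw
uniformly, with a mixing weight ``skew_strength`` interpolating between the
two regimes.  A ground-truth sidecar records each cell's generating regime so
tests can score recovery.  All randomness flows from the scenario's single
mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .bd import BirthDeathParams, v
from .tree import TimeTree

__all__ = [
    "SimulationError",
    "GridScenario",
    "SyntheticGrid",
    "draw_node_ages",
    "simulate_tree",
    "sample_community_random",
    "sample_community_clade_biased",
    "find_clades",
    "generate_grid",
]


class SimulationError(RuntimeError):
    """A rejection loop failed to produce a valid draw."""


# -- node ages ----------------------------------------------------------------


def draw_node_ages(
    n: int, params: BirthDeathParams, t1: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. node ages from λ p1(t)/v_{t1} on (0, t1) by inverse CDF.

    The CDF is v_t / v_{t1}; writing E = e^{-(λ-μ)t} and a = λ(1-ρ) - μ,
    v_t = ρλ(1-E)/(ρλ + aE) inverts to E = ρλ(1-v)/(ρλ + v a).
    """
    if t1 <= 0:
        raise SimulationError(f"root age must be positive, got {t1!r}")
    lam, mu, rho = params.lam, params.mu, params.rho
    a = lam * (1.0 - rho) - mu
    v1 = float(v(t1, params))
    target = rng.uniform(size=n) * v1
    E = rho * lam * (1.0 - target) / (rho * lam + target * a)
    return -np.log(E) / (lam - mu)


def _draw_root_age(
    n_tips: int, params: BirthDeathParams, rng: np.random.Generator, max_tries: int = 1000
) -> float:
    """Root age from the forward process, by rejection.

    Runs a Gillespie birth-death forward from the two root lineages and
    returns the first-passage time to ceil(n_tips / ρ) extant lineages;
    realizations that go extinct first are rejected.
    """
    lam, mu, rho = params.lam, params.mu, params.rho
    target = max(int(math.ceil(n_tips / rho)), 2)
    for _ in range(max_tries):
        n_ext = 2
        t = 0.0
        while 0 < n_ext < target:
            t += rng.exponential(1.0 / (n_ext * (lam + mu)))
            if mu > 0 and rng.random() < mu / (lam + mu):
                n_ext -= 1
            else:
                n_ext += 1
        if n_ext >= target:
            return t
    raise SimulationError(
        f"forward process went extinct {max_tries} times before reaching {target} lineages"
    )


# -- trees --------------------------------------------------------------------


def simulate_tree(
    n_tips: int,
    bd: BirthDeathParams,
    seed: int,
    root_age: float | None = None,
) -> TimeTree:
    """Simulate an ultrametric birth-death time tree with known parameters.

    With ``root_age=None`` the root age is drawn from the forward process by
    rejection; passing a value (e.g. 1.0) fixes it, which is convenient for
    unit-scale calibration.  Output is deterministic in ``seed``: the same
    seed yields byte-identical Newick.
    """
    if n_tips < 3:
        raise SimulationError(f"need at least 3 tips, got {n_tips}")
    rng = np.random.default_rng(seed)
    t1 = float(root_age) if root_age is not None else _draw_root_age(n_tips, bd, rng)
    if t1 <= 0:
        raise SimulationError(f"root age must be positive, got {t1!r}")
    ages = np.sort(draw_node_ages(n_tips - 2, bd, t1, rng))

    width = max(4, len(str(n_tips)))
    tns = dendropy.TaxonNamespace()
    lineages = []
    for i in range(n_tips):
        taxon = tns.new_taxon(label=f"s{i + 1:0{width}d}")
        nd = dendropy.Node(taxon=taxon)
        nd.age = 0.0
        lineages.append(nd)

    def merge(age: float) -> None:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = dendropy.Node()
        parent.age = float(age)
        b = lineages.pop(j)
        a = lineages.pop(i)
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = parent.age - child.age
        lineages.append(parent)

    for age in ages:
        merge(age)
    merge(t1)  # root

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = lineages[0]
    return TimeTree(tree)


# -- communities --------------------------------------------------------------


def _bernoulli_community(
    tips: Sequence[str],
    probs: np.ndarray,
    rng: np.random.Generator,
    min_size: int | None,
    max_draws: int,
) -> frozenset[str]:
    for _ in range(max_draws):
        mask = rng.random(len(tips)) < probs
        if min_size is None or int(mask.sum()) >= min_size:
            return frozenset(t for t, keep in zip(tips, mask) if keep)
    raise SimulationError(
        f"could not draw a community of at least {min_size} species in {max_draws} tries"
    )


def sample_community_random(
    tree: TimeTree,
    rho0: float,
    seed: int | np.random.Generator,
    min_size: int | None = None,
    max_draws: int = 1000,
) -> frozenset[str]:
    """Include each tip independently with probability ``rho0``.

    This is the null regime of the skew index: a community drawn this way has
    effective sampling proportion ρ_E equal to ρ_0 in expectation, hence
    PS ≈ 1.  ``min_size`` turns on resampling until the community is at least
    that large (calibration mode).
    """
    if not (0 < rho0 <= 1):
        raise ValueError(f"rho0 must be in (0, 1], got {rho0!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tips = sorted(tree.tips)
    probs = np.full(len(tips), rho0)
    return _bernoulli_community(tips, probs, rng, min_size, max_draws)


def sample_community_clade_biased(
    tree: TimeTree,
    clades: Iterable[Iterable[str]],
    p_in: float,
    p_out: float,
    seed: int | np.random.Generator,
    min_size: int | None = None,
    max_draws: int = 1000,
) -> frozenset[str]:
    """Include clade members with probability ``p_in``, the rest with ``p_out``.

    ``clades`` is a collection of tip-label sets (see :func:`find_clades`).
    With ``p_in > p_out`` the community concentrates in the named clades, its
    divergence times are young, and PS exceeds 1.  ``p_in == p_out`` reduces
    to :func:`sample_community_random`.
    """
    if not (0 <= p_out <= 1 and 0 < p_in <= 1):
        raise ValueError("inclusion probabilities must be in [0, 1]")
    if p_in <= p_out:
        raise ValueError(f"need p_in > p_out, got p_in={p_in!r}, p_out={p_out!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    in_clades: set[str] = set()
    for clade in clades:
        clade = set(clade)
        unknown = clade - tree.tips
        if unknown:
            raise KeyError(f"clade contains unknown species: {sorted(unknown)}")
        in_clades |= clade
    tips = sorted(tree.tips)
    probs = np.array([p_in if t in in_clades else p_out for t in tips])
    return _bernoulli_community(tips, probs, rng, min_size, max_draws)


def find_clades(
    tree: TimeTree, target_fraction: float = 0.2, max_clades: int = 3
) -> list[frozenset[str]]:
    """Pick disjoint clades jointly covering about ``target_fraction`` of tips.

    Greedy: non-root internal-node tip sets are scanned from largest to
    smallest, keeping any clade that is disjoint from those already kept and
    no larger than ~1.3x the remaining deficit.  Used to choose the favored
    clades of the skewed grid regime.
    """
    if not (0 < target_fraction <= 1):
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction!r}")
    n = tree.n_tips
    target = max(2, round(target_fraction * n))
    candidates = sorted(tree.clades(), key=len, reverse=True)
    picked: list[frozenset[str]] = []
    covered: set[str] = set()
    remaining = target
    for clade in candidates:
        if len(picked) >= max_clades or remaining <= 0:
            break
        if len(clade) > 1.3 * remaining or clade & covered:
            continue
        picked.append(clade)
        covered |= clade
        remaining = target - len(covered)
    if not picked:
        # every clade overshoots: take the smallest one of at least target size
        fallback = min(
            (c for c in candidates if len(c) >= target), key=len, default=candidates[0]
        )
        picked = [fallback]
    return picked


# -- grids --------------------------------------------------------------------


@dataclass(frozen=True)
class GridScenario:
    """Study conditions for a synthetic occurrence grid.

    Defaults mirror the shark analysis scale: a 236-species meta-community on
    a unit-root-age tree with (λ, μ, ρ) = (17, 6, 1), 100 cells split evenly
    between tropical (|lat| ≤ 23.5°) and temperate bands, an expected per-cell
    sampling fraction of 0.15 (about 35 species per cell), and full clade
    concentration in the tropics at ``skew_strength = 1``.  The seed is
    mandatory; there is no implicit randomness.
    """

    seed: int
    n_species: int = 236
    bd: BirthDeathParams = field(default_factory=lambda: BirthDeathParams(17.0, 6.0, 1.0))
    n_cells: int = 100
    latitudes: tuple[int, ...] | None = None
    skew_clades: tuple[frozenset[str], ...] | None = None
    skew_strength: float = 1.0
    base_rho0: float = 0.15
    tropical_cutoff: float = 23.5
    p_out: float = 0.02
    root_age: float = 1.0
    min_cell_size: int = 11
    clade_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.skew_strength <= 1):
            raise ValueError("skew_strength must be in [0, 1]")
        if not (0 < self.base_rho0 <= 1):
            raise ValueError("base_rho0 must be in (0, 1]")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")


@dataclass(frozen=True)
class SyntheticGrid:
    """A generated grid: the meta-tree, occurrence records and ground truth."""

    tree: TimeTree
    occurrences: pd.DataFrame
    truth: pd.DataFrame
    clades: tuple[frozenset[str], ...]
    seed: int


def _default_latitudes(n_cells: int, cutoff: float) -> list[int]:
    """Half the cells inside the tropical band, half in temperate bands."""
    n_trop = n_cells // 2
    n_temp = n_cells - n_trop
    trop_span = int(cutoff)  # integer cells in [-cutoff, cutoff)
    lats = []
    for i in range(n_trop):
        lats.append(-trop_span + (i * 2 * trop_span) // max(n_trop, 1))
    for i in range(n_temp):
        band = 40 + (i * 20) // max(n_temp, 1)  # |lat| in [40, 60)
        lats.append(band if i % 2 == 0 else -band)
    return lats


def generate_grid(
    scenario: GridScenario, out_dir: str | Path | None = None
) -> SyntheticGrid:
    """Generate an occurrence grid with a planted latitudinal skew gradient.

    Tropical cells (|lat| ≤ ``tropical_cutoff``) draw species with inclusion
    probability ``skew_strength * p_biased + (1 - skew_strength) * base_rho0``
    where p_biased concentrates on the favored clades; temperate cells draw
    uniformly at ``base_rho0``.  The biased regime's p_in is calibrated so
    both regimes have the same expected community size, isolating the
    compositional (not richness) signal.

    When ``out_dir`` is given, writes ``occurrences.csv``, ``truth.csv`` and
    ``tree.nwk`` there; the CSVs carry the seed in a comment header and are
    byte-identical across runs with the same scenario.
    """
    rng = np.random.default_rng(scenario.seed)
    tree_seed = int(rng.integers(0, 2**31 - 1))
    tree = simulate_tree(
        scenario.n_species, scenario.bd, seed=tree_seed, root_age=scenario.root_age
    )

    clades = scenario.skew_clades or tuple(
        find_clades(tree, target_fraction=scenario.clade_fraction)
    )
    in_clades = set().union(*clades)
    n, m = scenario.n_species, len(in_clades)
    expect = scenario.base_rho0 * n
    p_out = scenario.p_out
    p_in = float(np.clip((expect - p_out * (n - m)) / m, p_out + 0.05, 0.95))

    lats = list(scenario.latitudes) if scenario.latitudes is not None else (
        _default_latitudes(scenario.n_cells, scenario.tropical_cutoff)
    )
    if len(lats) != scenario.n_cells:
        raise ValueError("latitudes must have one entry per cell")
    lons = [-180 + (i * 360) // scenario.n_cells for i in range(scenario.n_cells)]

    tips = sorted(tree.tips)
    base_probs = np.full(len(tips), scenario.base_rho0)
    biased_probs = np.array([p_in if t in in_clades else p_out for t in tips])

    occ_rows: list[tuple[str, float, float]] = []
    truth_rows: list[dict] = []
    for lat, lon in zip(lats, lons):
        tropical = abs(lat) <= scenario.tropical_cutoff
        if tropical and scenario.skew_strength > 0:
            probs = (
                scenario.skew_strength * biased_probs
                + (1.0 - scenario.skew_strength) * base_probs
            )
            regime = "clade_biased"
        else:
            probs = base_probs
            regime = "random"
        members = _bernoulli_community(
            tips, probs, rng, scenario.min_cell_size, max_draws=1000
        )
        for sp in sorted(members):
            occ_rows.append((sp, lat + 0.5, lon + 0.5))
        truth_rows.append(
            {
                "cell_lat": lat,
                "cell_lon": lon,
                "band": "tropical" if tropical else "temperate",
                "regime": regime,
                "n_species": len(members),
            }
        )

    occurrences = pd.DataFrame(occ_rows, columns=["species", "latitude", "longitude"])
    truth = pd.DataFrame(truth_rows)
    grid = SyntheticGrid(
        tree=tree,
        occurrences=occurrences,
        truth=truth,
        clades=tuple(clades),
        seed=scenario.seed,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = f"# phyloskew synthetic grid, seed={scenario.seed}\n"
        for name, df in (("occurrences.csv", occurrences), ("truth.csv", truth)):
            with open(out_dir / name, "w", newline="") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        tree.write(out_dir / "tree.nwk", schema="newick")
    return grid
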