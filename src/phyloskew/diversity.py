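"""Per-community diversity indices: SR, Faith's PD, AvTD, and the skew pair PS/PE.

Faith's PD is the sum of branch lengths on the minimum spanning path
connecting a community's species on the reference tree; the path is taken on
the unrooted tree, so the edge above the members' MRCA is never counted (the
rooted variant would differ for nested subsets).

AvTD (average taxonomic distinctness) is the mean patristic distance over all
unordered pairs of members; on an ultrametric tree this equals twice the mean
MRCA age.  It is computed on the same time tree as PD — "taxonomic" survives
in the name only for historical reasons.

Phylogenetic skew is PS = ρ̂_E / ρ_0, where ρ_0 = s / S_meta is the
community's actual sampling fraction of the meta-community and ρ̂_E is the
effective sampling proportion estimated by the birth-death model from the
community's own divergence times.  Communities concentrated in few clades
have young divergences, look "fully sampled" to the model (large ρ̂_E), and
get PS ≫ 1.  Phylogenetic-clade evenness is the reciprocal, PE = 1 / PS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .bd import BirthDeathParams, fit_sampling_proportion
from .tree import TimeTree, TreeError

__all__ = [
    "CommunityIndices",
    "faith_pd",
    "avtd",
    "phylogenetic_skew",
    "community_indices",
    "MIN_SR_FOR_SKEW",
]

#: skew indices are computed only for communities with more than 10 species,
#: because of the small-sample bias of the effective-sampling estimate
MIN_SR_FOR_SKEW = 11


def _check_members(tree: TimeTree, members: Iterable[str]) -> frozenset[str]:
    members = frozenset(members)
    unknown = members - tree.tips
    if unknown:
        raise TreeError(f"unknown species labels: {sorted(unknown)}")
    if len(members) < 2:
        raise ValueError("need at least two member species")
    return members


def faith_pd(tree: TimeTree, members: Iterable[str]) -> float:
    """Faith's phylogenetic diversity of ``members`` on ``tree``.

    Sum of the branch lengths of the unrooted minimum spanning path: an edge
    is counted exactly when member species occur on both of its sides.  With
    ``members`` equal to the full tip set this is the total branch length.
    """
    members = _check_members(tree, members)
    m = len(members)
    dtree = tree.dendropy_tree
    total = 0.0
    # postorder member counts below each node; an edge lies on the spanning
    # path iff 0 < count below < m
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            nd._pd_count = 1 if nd.taxon.label in members else 0
        else:
            nd._pd_count = sum(ch._pd_count for ch in nd.child_nodes())
        if nd is not dtree.seed_node and 0 < nd._pd_count < m:
            total += nd.edge.length
    return float(total)


def avtd(tree: TimeTree, members: Iterable[str]) -> float:
    """Average taxonomic distinctness: mean pairwise patristic distance.

    On an ultrametric tree the distance between two tips is twice their MRCA
    age, so the mean is accumulated per internal node as 2 * age * (number of
    member pairs whose MRCA is that node), divided by C(m, 2).
    """
    members = _check_members(tree, members)
    m = len(members)
    dtree = tree.dendropy_tree
    total = 0.0
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            nd._td_count = 1 if nd.taxon.label in members else 0
            continue
        counts = [ch._td_count for ch in nd.child_nodes()]
        below = sum(counts)
        cross = (below * below - sum(c * c for c in counts)) // 2
        if cross:
            total += 2.0 * nd.age * cross
        nd._td_count = below
    n_pairs = m * (m - 1) // 2
    return float(total / n_pairs)


def phylogenetic_skew(rhoE: float, rho0: float) -> float:
    """PS = ρ̂_E / ρ_0; values ≫ 1 mean clade-concentrated membership."""
    if not (0 < rho0 <= 1):
        raise ValueError(f"rho0 must be in (0, 1], got {rho0!r}")
    if not (0 < rhoE <= 1):
        raise ValueError(f"rhoE must be in (0, 1], got {rhoE!r}")
    return rhoE / rho0


@dataclass(frozen=True)
class CommunityIndices:
    """All per-community indices; PS/PE are NaN below the size filter.

    ``ps * pe == 1`` exactly whenever both are defined, and
    ``rho0 == sr / s_meta``.
    """

    sr: int
    pd: float
    avtd: float
    rho0: float
    rhoE: float
    ps: float
    pe: float
    flags: str = ""


def community_indices(
    tree: TimeTree,
    members: Iterable[str],
    meta_params: BirthDeathParams,
    s_meta: int | None = None,
    min_sr_skew: int = MIN_SR_FOR_SKEW,
    fit_seed: int = 0,
    n_starts: int = 10,
) -> CommunityIndices:
    """Assemble SR, PD, AvTD, ρ_0, ρ̂_E, PS and PE for one community.

    ``meta_params`` carries the step-one (λ̂, μ̂) estimated from the
    meta-community; ``s_meta`` is the meta-community size (defaults to the
    number of tree tips).  PS/PE require at least ``min_sr_skew`` members;
    PD/AvTD require at least 2.  Boundary hits of the ρ̂_E fit are recorded
    in ``flags``.
    """
    members = _check_members(tree, members)
    sr = len(members)
    s_meta = tree.n_tips if s_meta is None else int(s_meta)
    if sr > s_meta:
        raise ValueError(f"community size {sr} exceeds meta-community size {s_meta}")
    rho0 = sr / s_meta

    pd_val = faith_pd(tree, members)
    avtd_val = avtd(tree, members)

    flags: list[str] = []
    if sr >= min_sr_skew:
        sub = tree.induced_subtree(members)
        res = fit_sampling_proportion(
            sub.divergence_times(),
            meta_params.lam,
            meta_params.mu,
            seed=fit_seed,
            n_starts=n_starts,
        )
        rhoE = res.params.rho
        if not res.converged:
            flags.append("rhoE_not_converged")
        if res.boundary.get("rho"):
            flags.append(f"rhoE_boundary_{res.boundary['rho']}")
        ps = phylogenetic_skew(rhoE, rho0)
        pe = 1.0 / ps
    else:
        rhoE = ps = pe = math.nan
        flags.append("below_min_sr_for_skew")

    return CommunityIndices(
        sr=sr,
        pd=pd_val,
        avtd=avtd_val,
        rho0=rho0,
        rhoE=rhoE,
        ps=ps,
        pe=pe,
        flags=";".join(flags),
    )
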