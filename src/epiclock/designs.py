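"""Canonical pedigree topologies for simulation studies.

Two stylized designs cover the systems the estimator targets: replicated
mutation-accumulation lineages radiating from a single founder (sexual
or clonal propagation), and a two-stem tree whose branch points are
dated relative to the present (the intra-organismal somatic phylogeny of
a long-lived perennial).
"""

from __future__ import annotations

from typing import Sequence

from .pedigree import Pedigree, build_pedigree

__all__ = ["ma_pedigree", "two_stem_tree"]


def ma_pedigree(
    n_lineages: int,
    sampled_generations: Sequence[int],
    founder_sampled: bool = True,
) -> Pedigree:
    """Mutation-accumulation design: independent lineages from one founder.

    Each lineage is a chain from the founder (generation 0) with a
    sampled node at every generation in ``sampled_generations``
    (progenitor sampling: the sampled plant is the germline individual).
    Sample ids are ``S_F`` for the founder and ``S_<lineage>_<gen>``.
    """
    if n_lineages < 1:
        raise ValueError("need at least one lineage")
    gens = sorted(sampled_generations)
    if not gens or gens[0] <= 0:
        raise ValueError("sampled generations must be positive")
    nodes = [("F", 0.0, "S_F" if founder_sampled else None)]
    edges = []
    for lin in range(1, n_lineages + 1):
        prev = "F"
        for g in gens:
            nid = f"L{lin}_g{g}"
            nodes.append((nid, float(g), f"S_{lin}_{g}"))
            edges.append((prev, nid))
            prev = nid
    return build_pedigree(nodes, edges)


def two_stem_tree(
    total_age: float,
    branch_ages_stem1: Sequence[float],
    branch_ages_stem2: Sequence[float],
) -> Pedigree:
    """Two clonal stems diverging at the tree base, with dated branches.

    ``branch_ages_*`` are coring ages of the branch points in years
    before present; each branch carries one leaf sampled at the present
    (absolute time ``total_age``).  Sample ids are ``S_<stem>_<age>``.
    """
    for ages in (branch_ages_stem1, branch_ages_stem2):
        if not ages:
            raise ValueError("each stem needs at least one branch")
        if max(ages) > total_age:
            raise ValueError("branch ages cannot exceed the total tree age")
    nodes = [("base", 0.0, None)]
    edges = []
    for stem, ages in (("T1", branch_ages_stem1), ("T2", branch_ages_stem2)):
        prev = "base"
        for age in sorted(ages, reverse=True):
            junction = f"{stem}_j{age:g}"
            leaf = f"{stem}_leaf{age:g}"
            nodes.append((junction, float(total_age - age), None))
            nodes.append((leaf, float(total_age), f"S_{stem}_{age:g}"))
            edges.append((prev, junction))
            edges.append((junction, leaf))
            prev = junction
    return build_pedigree(nodes, edges)
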