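"""Peptide-map structure: redundancy, occupancy, subsections, bridges.

Redundancy counts how many peptides cover a residue.  A peptide's *density*
sums, over its exchange-competent residues, the number of peptides in which
that residue is exchange-competent; *occupancy* is density divided by the
number of competent residues.  Peptides with occupancy below a cut-off
(default 2.5) are weakly constrained and are filtered before optimisation.

Subsections are connected components of the peptide overlap graph (edge when
two spans share at least one residue); bridging peptides are those whose
removal splits a subsection in two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .hx_io import Dataset, Peptide

__all__ = [
    "CoverageProfile",
    "compute_occupancy",
    "filter_by_occupancy",
    "find_subsections",
    "find_bridging_peptides",
]

log = logging.getLogger(__name__)

OCCUPANCY_THRESHOLD = 2.5


@dataclass
class CoverageProfile:
    """Redundancy / density / occupancy of one peptide map."""

    redundancy: dict[int, int]            # residue -> peptides covering it (full span)
    competent_redundancy: dict[int, int]  # residue -> peptides where it is competent
    density: dict[int, int]               # peptide id -> sum of competent redundancies
    occupancy: dict[int, float | None]    # peptide id -> density / n (None if n == 0)
    flagged: list[int] = field(default_factory=list)  # peptides with no competent residues


def compute_occupancy(dataset: Dataset) -> CoverageProfile:
    """Per-residue redundancy and per-peptide occupancy for a peptide map."""
    if not dataset.peptides:
        raise ValueError("empty dataset")
    redundancy: dict[int, int] = {}
    competent: dict[int, int] = {}
    for p in dataset.peptides:
        for r in p.span:
            redundancy[r] = redundancy.get(r, 0) + 1
        for r in dataset.peptide_competent(p):
            competent[r] = competent.get(r, 0) + 1
    density: dict[int, int] = {}
    occupancy: dict[int, float | None] = {}
    flagged: list[int] = []
    for p in dataset.peptides:
        comp = dataset.peptide_competent(p)
        if not comp:
            density[p.id] = 0
            occupancy[p.id] = None
            flagged.append(p.id)
            continue
        d = sum(competent[r] for r in comp)
        density[p.id] = d
        occupancy[p.id] = d / len(comp)
    return CoverageProfile(redundancy, competent, density, occupancy, flagged)


def filter_by_occupancy(
    dataset: Dataset,
    threshold: float = OCCUPANCY_THRESHOLD,
    iterative: bool = False,
) -> tuple[Dataset, list[Peptide]]:
    """Remove peptides with occupancy below ``threshold``.

    Occupancies are computed once against the full map and peptides removed
    in a single pass; with ``iterative=True`` the computation is repeated on
    the surviving map until a fixed point.  Peptides with no
    exchange-competent residues (undefined occupancy) are always removed.
    Returns the filtered dataset and the removed peptides.
    """
    removed: list[Peptide] = []
    current = dataset
    while True:
        if not current.peptides:
            break
        prof = compute_occupancy(current)
        drop = [
            p for p in current.peptides
            if prof.occupancy[p.id] is None or prof.occupancy[p.id] < threshold
        ]
        if not drop:
            break
        removed.extend(drop)
        drop_ids = {p.id for p in drop}
        kept = [p for p in current.peptides if p.id not in drop_ids]
        current = Dataset(
            protein_id=current.protein_id,
            timepoints=current.timepoints,
            peptides=kept,
            n_term_exclusion=current.n_term_exclusion,
        )
        if not iterative:
            break
    if not current.peptides:
        log.warning(
            "occupancy filter at %.3g removed all %d peptides",
            threshold, len(removed),
        )
    for p in removed:
        log.info("filtered peptide %d (%d-%d)", p.id, p.start, p.end)
    return current, removed


def _overlap_graph(dataset: Dataset) -> nx.Graph:
    g = nx.Graph()
    peps = dataset.peptides
    g.add_nodes_from(range(len(peps)))
    for i in range(len(peps)):
        for j in range(i + 1, len(peps)):
            if peps[i].start <= peps[j].end and peps[j].start <= peps[i].end:
                g.add_edge(i, j)
    return g


def find_subsections(dataset: Dataset) -> list[Dataset]:
    """Split a dataset into independent subsections.

    Subsections are connected components of the peptide overlap graph, each
    returned as its own :class:`Dataset`, ordered by first residue.
    """
    if not dataset.peptides:
        return []
    g = _overlap_graph(dataset)
    components = [sorted(c) for c in nx.connected_components(g)]
    subsets = []
    for comp in components:
        peps = [dataset.peptides[i] for i in comp]
        subsets.append(
            Dataset(
                protein_id=dataset.protein_id,
                timepoints=dataset.timepoints,
                peptides=peps,
                n_term_exclusion=dataset.n_term_exclusion,
            )
        )
    subsets.sort(key=lambda d: min(p.start for p in d.peptides))
    return subsets


def find_bridging_peptides(dataset: Dataset) -> list[Peptide]:
    """Peptides whose individual removal increases the subsection count.

    These are the cut vertices (articulation points) of the peptide overlap
    graph; deleting one splits an otherwise connected subsection.
    """
    if len(dataset.peptides) < 3:
        return []
    g = _overlap_graph(dataset)
    cuts = sorted(nx.articulation_points(g))
    return [dataset.peptides[i] for i in cuts]
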