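"""High-level composition of the stages: structure → graph → scores → sites."""

from __future__ import annotations

import numpy as np

from . import nn
from .graph import GRAPH_CUTOFF, build_near_surface_graph, featurize
from .labeling import AtomTargets, compute_targets
from .sites import LINKAGE_CUTOFF, MIN_CLUSTER_SIZE, SCORE_THRESHOLD, BindingSite, predict_sites
from .surface import PROBE_RADIUS, SASA_CUTOFF, detect_surface_atoms
from .types import ProteinGraph, StructureModel

__all__ = ["prepare_graph", "predict_structure", "training_example"]


def prepare_graph(
    s: StructureModel,
    graph_cutoff: float = GRAPH_CUTOFF,
    probe_radius: float = PROBE_RADIUS,
    sasa_cutoff: float = SASA_CUTOFF,
) -> ProteinGraph:
    """Surface detection (if not yet done) + near-surface graph + features."""
    if not any(a.is_surface for a in s.protein_atoms):
        detect_surface_atoms(s, probe_radius=probe_radius, sasa_cutoff=sasa_cutoff)
    g = build_near_surface_graph(s, cutoff=graph_cutoff)
    return featurize(s, g)


def predict_structure(
    s: StructureModel,
    params: dict,
    config: nn.ModelConfig,
    graph_cutoff: float = GRAPH_CUTOFF,
    score_threshold: float = SCORE_THRESHOLD,
    linkage_cutoff: float = LINKAGE_CUTOFF,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> tuple[nn.ScoredAtoms, list[BindingSite]]:
    """Run the full prediction pipeline on a parsed structure."""
    g = prepare_graph(s, graph_cutoff=graph_cutoff)
    result = nn.forward(g, params, config, training=False)
    scored = result.scored
    coords = s.coords()[scored.atom_indices]
    sites = predict_sites(
        scored, coords, score_threshold, linkage_cutoff, min_cluster_size
    )
    return scored, sites


def training_example(
    s: StructureModel,
    graph_cutoff: float = GRAPH_CUTOFF,
    midpoint: float | None = None,
    steepness: float | None = None,
) -> tuple[ProteinGraph, AtomTargets]:
    """Graph + sigmoid targets for a labeled structure (ligands present)."""
    g = prepare_graph(s, graph_cutoff=graph_cutoff)
    kwargs = {}
    if midpoint is not None:
        kwargs["midpoint"] = midpoint
    if steepness is not None:
        kwargs["steepness"] = steepness
    targets = compute_targets(s, **kwargs)
    return g, targets
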