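"""End-to-end orchestration: fixes + roosts -> networks -> permutation report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import pandas as pd
from shapely.geometry import Polygon

from .errors import EmptyInputError
from .interactions import (
    Situation,
    assign_roosts,
    detect_coflight_events,
    detect_diurnal_ground_events,
    joint_sampling_counts,
    nocturnal_cooccurrences,
    together_counts,
)
from .networks import build_aggregate, build_layer, centrality_table
from .permutation import AnalysisConfig, PermutationReport, run_reference_model
from .trajectory import StudyConfig, bin_to_epochs, filter_individuals


@dataclass
class PipelineResult:
    """Everything one analysis run produces."""

    fixes: pd.DataFrame                      # retained, epoch-aligned
    exclusions: pd.DataFrame
    cohort: list[str]
    events: dict[str, pd.DataFrame]          # situation label -> event table
    assignments: pd.DataFrame                # nightly roost assignments
    layers: dict[str, nx.Graph]
    aggregate: nx.Graph
    centralities: pd.DataFrame
    report: PermutationReport | None

    @property
    def networks(self) -> dict[str, nx.Graph]:
        return {**self.layers, "aggregate": self.aggregate}


def build_networks(
    fixes: pd.DataFrame,
    roosts: Mapping[str, Polygon],
    cfg: StudyConfig,
) -> PipelineResult:
    """Filter the cohort, infer interactions in the three situations, and
    build the SRI layers and their aggregate (no permutation test)."""
    retained, exclusions = filter_individuals(fixes, cfg)
    if retained.empty:
        raise EmptyInputError(
            "no individuals pass the duration/range filters; nothing to analyse"
        )
    aligned = bin_to_epochs(retained, cfg)
    cohort = sorted(aligned["individual_id"].unique())

    coflight = detect_coflight_events(aligned, cfg)
    diurnal = detect_diurnal_ground_events(aligned, roosts, cfg)
    assignments = assign_roosts(aligned, roosts, cfg)
    nocturnal = nocturnal_cooccurrences(assignments)
    events = {
        Situation.COFLIGHT.value: coflight,
        Situation.NOCTURNAL_GROUND.value: nocturnal,
        Situation.DIURNAL_GROUND.value: diurnal,
    }

    layers: dict[str, nx.Graph] = {}
    for situation in Situation:
        label = situation.value
        source = assignments if situation is Situation.NOCTURNAL_GROUND else aligned
        denom = joint_sampling_counts(source, situation, cohort)
        numerator = "slots" if situation is Situation.NOCTURNAL_GROUND else cfg.sri_numerator
        together = together_counts(events[label], cohort, numerator=numerator)
        layers[label] = build_layer(together, denom, cohort, label)
    aggregate = build_aggregate(layers)

    return PipelineResult(
        fixes=aligned,
        exclusions=exclusions,
        cohort=cohort,
        events=events,
        assignments=assignments,
        layers=layers,
        aggregate=aggregate,
        centralities=pd.DataFrame(),
        report=None,
    )


def run_pipeline(
    fixes: pd.DataFrame,
    roosts: Mapping[str, Polygon],
    cfg: StudyConfig,
    analysis: AnalysisConfig | None = None,
) -> PipelineResult:
    """Full analysis: networks, centralities, and the node-permutation
    reference model for all nine (measure x situation) cells."""
    result = build_networks(fixes, roosts, cfg)
    analysis = analysis or AnalysisConfig()
    result.centralities = centrality_table(
        result.networks, damping=analysis.pagerank_damping
    )
    result.report = run_reference_model(result.layers, analysis)
    return result
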