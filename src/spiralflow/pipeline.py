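"""Per-site pipeline orchestration and cohort comparison.

Stage order: vessel-class union mask -> homotopic thinning -> segment
graph (class transfer) -> spurious-spur pruning -> small-subnetwork
removal -> resampling to the fixed node budget -> sub-voxel recentering
and calibrated radius estimation -> size-filtered morphometry -> terminal
classification and network-Poiseuille flow solve.  Every run is
deterministic given inputs, configuration and seed; the provenance block
of each report suffices to re-run the site bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from scipy import ndimage

from . import __version__
from .graph import build_graph, filter_subnetworks, prune_spurious, resample_nodes
from .hemodynamics import (
    DEFAULT_VISCOSITY,
    FlowProblem,
    FlowSolution,
    classify_terminals,
    solve_flow,
)
from .morphometry import MorphometrySummary, apply_size_filter, measure_segments, summarize_site
from .phantoms import CohortSpec, Phantom, make_cohort
from .radius import CalibrationModel, default_calibration, estimate_radii
from .skeleton import skeletonize
from .stats import compare_cohort
from .voxelio import SPIRAL, VESSEL_CLASSES, LabelVolume


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Every tunable parameter of the per-site pipeline."""

    mask_classes: tuple = VESSEL_CLASSES  # classes merged for thinning
    spur_factor: float = 2.0
    min_spur_len_um: float | None = None  # default: 2 voxels
    min_subnetwork_segments: int = 30
    total_nodes: int = 10000
    n_rays: int = 36
    recenter: bool = True
    max_radius_vox: float = 25.0
    calibration: CalibrationModel | None = None  # default: built-in tube suite
    min_radius_um: float = 10.0
    min_length_um: float = 10.0
    summary_classes: tuple = (SPIRAL,)
    delta_p: float = 1000.0
    viscosity: float = DEFAULT_VISCOSITY
    terminal_proximity_um: float | None = None  # default: 2 voxels
    require_flow: bool = True  # False: a morphometry-only run (no inlets/outlets)

    def to_provenance(self) -> dict:
        d = dataclasses.asdict(self)
        cal = self.calibration
        d["calibration"] = (
            None if cal is None else {"a": cal.a, "b": cal.b, "c": cal.c, "fit_range": list(cal.fit_range)}
        )
        return d


@dataclass
class SiteReport:
    site_id: str
    provenance: dict
    summary: MorphometrySummary
    flow: FlowSolution
    stage_timings_s: dict = field(default_factory=dict)

    def to_json(self, path=None):
        payload = {
            "site_id": self.site_id,
            "provenance": self.provenance,
            "summary": self.summary.to_dict(),
            "flow": json.loads(self.flow.to_json()),
        }
        text = json.dumps(payload, sort_keys=True, indent=2)
        if path is None:
            return text
        Path(path).write_text(text)
        return path


def run_site(inputs, config: PipelineConfig | None = None, site_id: str = "site") -> SiteReport:
    """Run the full pipeline on one implantation site.

    ``inputs`` is either a :class:`~spiralflow.phantoms.Phantom` or a
    :class:`~spiralflow.voxelio.LabelVolume` (the segmentation is the
    pipeline's real input; the intensity volume only feeds preprocessing
    upstream of segmentation).
    """
    config = config or PipelineConfig()
    if isinstance(inputs, Phantom):
        labels = inputs.labels
    elif isinstance(inputs, LabelVolume):
        labels = inputs
    else:
        raise TypeError(f"run_site expects a Phantom or LabelVolume, got {type(inputs)}")

    timings: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as e:  # noqa: BLE001 - wrapped with stage context
            raise StageError(name, e) from e
        timings[name] = time.perf_counter() - t0
        return out

    mask = stage("mask", lambda: labels.class_mask(config.mask_classes))
    skel = stage("skeletonize", lambda: skeletonize(mask))
    g = stage("build_graph", lambda: build_graph(skel, labels))

    def provisional_radii():
        # distance-transform radii give the pruning stage a local vessel
        # scale before the calibrated Rayburst estimates exist
        edt = ndimage.distance_transform_edt(mask) * labels.voxel_size_um
        for node in g.nodes.values():
            if node.voxel is not None:
                node.radius_um = float(edt[node.voxel])

    stage("provisional_radii", provisional_radii)
    g = stage(
        "prune_spurious",
        lambda: prune_spurious(g, config.spur_factor, config.min_spur_len_um),
    )
    g = stage(
        "filter_subnetworks",
        lambda: filter_subnetworks(g, config.min_subnetwork_segments),
    )

    def clear_radii():
        for node in g.nodes.values():
            node.radius_um = float("nan")

    stage("clear_provisional_radii", clear_radii)
    g = stage("resample_nodes", lambda: resample_nodes(g, config.total_nodes))
    calibration = config.calibration or default_calibration(n_rays=config.n_rays)
    stage(
        "estimate_radii",
        lambda: estimate_radii(
            g,
            mask,
            calibration=calibration,
            n_rays=config.n_rays,
            max_radius_vox=config.max_radius_vox,
            recenter=config.recenter,
        ),
    )
    stage("measure_segments", lambda: measure_segments(g))
    view = stage(
        "size_filter",
        lambda: apply_size_filter(g, config.min_radius_um, config.min_length_um),
    )
    summary = stage(
        "summarize", lambda: summarize_site(view, site_id, config.summary_classes)
    )
    try:
        inlets, outlets, _roles = stage(
            "classify_terminals",
            lambda: classify_terminals(g, labels, config.terminal_proximity_um),
        )
        flow = stage(
            "solve_flow",
            lambda: solve_flow(
                FlowProblem(
                    g.spiral_subgraph(config.summary_classes),
                    inlets,
                    outlets,
                    config.delta_p,
                    config.viscosity,
                )
            ),
        )
    except StageError as err:
        if config.require_flow or err.stage != "classify_terminals":
            raise
        flow = FlowSolution(
            node_pressures={}, segment_flows={}, total_outflow=0.0,
            resistance=float("inf"), conductance=0.0, delta_p=config.delta_p,
            viscosity=config.viscosity, inlets=[], outlets=[],
            diagnostic=f"flow skipped: {err.cause}",
        )
    provenance = {
        "spiralflow_version": __version__,
        "site_id": site_id,
        "voxel_size_um": labels.voxel_size_um,
        "config": config.to_provenance(),
        "stage_order": list(timings),
        "seed": getattr(inputs, "seed", None),
    }
    return SiteReport(site_id, provenance, summary, flow, timings)


def run_cohort(spec: CohortSpec, config: PipelineConfig | None = None):
    """Generate a two-group cohort, run every site, compare the groups.

    Returns ``(reports_a, reports_b, comparisons, table)``.
    """
    config = config or PipelineConfig()
    if config.calibration is None:
        config = dataclasses.replace(
            config, calibration=default_calibration(n_rays=config.n_rays)
        )
    pairs = make_cohort(spec)
    reports_a, reports_b = [], []
    for i, (ph_a, ph_b) in enumerate(pairs):
        reports_a.append(run_site(ph_a, config, site_id=f"A{i:02d}"))
        reports_b.append(run_site(ph_b, config, site_id=f"B{i:02d}"))
    comparisons, table = compare_cohort(reports_a, reports_b)
    return reports_a, reports_b, comparisons, table
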