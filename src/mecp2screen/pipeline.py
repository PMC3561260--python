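"""End-to-end orchestration of the integrated target screen.

Glues the stages together: windows from the annotation, chip/input
window quantification with top-decile calling, the detection-prefiltered
differential-expression screen, probe-to-gene collapse, and the
DE x binding intersection.  Works on in-memory objects (e.g. a
``SyntheticScreen``) or on the standard files the CLI consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import annotation, coverage, expression, integration
from .expression import ExpressionScreenResult
from .integration import TargetSet
from .synthetic import SyntheticScreen


@dataclass
class ScreenResult:
    """Everything one full run produces."""

    quant: pd.DataFrame
    de: ExpressionScreenResult
    targets: TargetSet
    direction_summary: pd.DataFrame


def run_screen(
    screen: SyntheticScreen,
    fraction: float = 0.10,
    fragment_extension_bp: int = 200,
    assignment: str = "midpoint",
    mode: str = "rawp",
    p_cutoff: float = 0.005,
    fc_cutoff: float = 1.2,
    normalization: str = "passthrough",
) -> ScreenResult:
    """Run quantify -> rank -> DE -> integrate on one synthetic screen.

    The synthetic matrix is already on log2 scale, hence the passthrough
    normalization default.
    """
    windows = annotation.derive_windows(screen.genes, screen.sizes, screen.config.flank_bp)
    quant = coverage.quantify_windows(
        screen.chip, screen.input, windows,
        fraction=fraction,
        fragment_extension_bp=fragment_extension_bp,
        assignment=assignment,
    )
    log2 = expression.normalize_log2(screen.matrix, normalization)
    ko_list = expression.detection_prefilter(screen.calls, screen.groups, "KO")
    wt_list = expression.detection_prefilter(screen.calls, screen.groups, "WT")
    de = expression.differential_expression(
        log2, screen.groups, mode=mode, p_cutoff=p_cutoff, fc_cutoff=fc_cutoff,
        ko_prefiltered=ko_list, wt_prefiltered=wt_list,
    )
    de = expression.collapse_probes_to_genes(de, screen.probe_map)
    targets = integration.intersect_targets(de.genes, quant)
    summary = integration.direction_by_region_summary(targets)
    return ScreenResult(quant=quant, de=de, targets=targets, direction_summary=summary)
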