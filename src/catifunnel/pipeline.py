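"""End-to-end orchestration of the three evidence arms.

The arms are independent — no arm's output gates another; the study view
treats expression screening, qPCR validation and the variant funnel as
parallel evidence and cross-references their gene lists at the end.
Any subset of arms may be supplied; missing arms are skipped and
recorded.  Serialization is canonical (sorted keys, sorted sets), so a
rerun on the same inputs produces byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import RunConfig
from .core import ExpressionMatrix, LocusInterval, VariantRecord
from .expression import ScreenReport, run_expression_screen
from .qpcr import TestResult, run_qpcr_validation
from .variants import FunnelReport, PanelManifest, run_variant_funnel

logger = logging.getLogger(__name__)

__all__ = ["StudySummary", "run_study"]


@dataclass
class StudySummary:
    screen: ScreenReport | None = None
    qpcr_results: list[TestResult] | None = None
    qpcr_labels: dict[str, str] | None = None
    funnel: FunnelReport | None = None
    #: genes in both the expression case-only set and the final funnel
    #: candidate list
    cross_reference: list[str] = field(default_factory=list)
    skipped_arms: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        out: dict = {"skipped_arms": sorted(self.skipped_arms)}
        out["expression_screen"] = (self.screen.to_json_dict()
                                    if self.screen else None)
        if self.qpcr_results is not None:
            out["qpcr_tests"] = [
                {"gene": r.gene, "strain": r.strain.value,
                 "contrast": f"{r.contrast[0]}to{r.contrast[1]}",
                 "test_used": r.test_used, "p_value": round(r.p_value, 10),
                 "direction": r.direction}
                for r in sorted(self.qpcr_results,
                                key=lambda r: (r.gene, r.strain.value,
                                               r.contrast))
            ]
            out["qpcr_classification"] = dict(sorted(
                (self.qpcr_labels or {}).items()))
        else:
            out["qpcr_tests"] = None
            out["qpcr_classification"] = None
        out["variant_funnel"] = (self.funnel.to_json_dict()
                                 if self.funnel else None)
        out["cross_reference"] = list(self.cross_reference)
        return out

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "study_summary.json"
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        if self.funnel is not None:
            from .variants import _variant_row
            pd.DataFrame(
                [_variant_row(v) for v in self.funnel.candidates]
            ).to_csv(out_dir / "variant_candidates.tsv", sep="\t",
                     index=False)
        logger.info("wrote study summary to %s", path)
        return path


def run_study(
    case_matrix: ExpressionMatrix | None = None,
    control_matrix: ExpressionMatrix | None = None,
    ct_table: pd.DataFrame | None = None,
    case_a: Sequence[VariantRecord] | None = None,
    case_b: Sequence[VariantRecord] | None = None,
    panel: PanelManifest | None = None,
    loci: Sequence[LocusInterval] | None = None,
    config: RunConfig | None = None,
) -> StudySummary:
    """Run every arm whose inputs are present and cross-reference genes.

    The cross-reference lists genes appearing both in the expression
    case-only sets (either direction) and among the final funnel
    candidates' gene names.  If the two arms share no gene namespace the
    list is empty and a warning is logged.
    """
    config = config or RunConfig()
    summary = StudySummary()

    if case_matrix is not None and control_matrix is not None:
        summary.screen = run_expression_screen(case_matrix, control_matrix,
                                               config)
    else:
        summary.skipped_arms.append("expression_screen")

    if ct_table is not None:
        summary.qpcr_results, summary.qpcr_labels = run_qpcr_validation(
            ct_table, config)
    else:
        summary.skipped_arms.append("qpcr_validation")

    if case_a is not None and case_b is not None:
        summary.funnel = run_variant_funnel(case_a, case_b, panel=panel,
                                            loci=loci, config=config)
    else:
        summary.skipped_arms.append("variant_funnel")

    if summary.screen is not None and summary.funnel is not None:
        screen_genes = set(summary.screen.case_only_up) \
            | set(summary.screen.case_only_down)
        funnel_genes = {v.gene for v in summary.funnel.candidates if v.gene}
        summary.cross_reference = sorted(screen_genes & funnel_genes)
        if screen_genes and funnel_genes and not summary.cross_reference:
            all_screen = set()
            for strain in summary.screen.up_total:
                all_screen |= set(summary.screen.up_total[strain])
                all_screen |= set(summary.screen.down_total[strain])
            if not (all_screen & funnel_genes):
                logger.warning(
                    "expression and variant arms share no gene ids; "
                    "cross-reference computed on an empty namespace"
                )
    return summary
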