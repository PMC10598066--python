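"""Two-strain fold-change expression screen with Venn exclusion.

The screen compares lenses before cortical opacity (4 weeks) with lenses
after onset (8 and 10 weeks), in the cataractous case strain and in a
wild-type control strain:

1. drop genes whose signal is below the floor in every sample;
2. average replicates within each (strain, timepoint) group;
3. per contrast (4->8, 4->10), call a gene *up* if the test/reference
   mean ratio strictly exceeds the up threshold (default 1.5) and *down*
   if the reference/test ratio strictly exceeds the down threshold
   (default 2.25) — the asymmetric thresholds are the study design;
4. take the union of the two contrasts per strain and direction;
5. exclude from the case-strain sets every gene also called in the
   control strain (Venn exclusion), leaving case-only changes.

Fold changes are ratios of group means on linear-scale signals, not
means of per-replicate ratios, so single-replicate control groups are
handled identically to replicated ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .core import ExpressionMatrix, Strain

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSets",
    "ScreenReport",
    "filter_low_signal",
    "group_means",
    "contrast_sets",
    "union_contrasts",
    "strain_exclusion",
    "run_expression_screen",
]


@dataclass(frozen=True)
class ContrastSets:
    """Up/down gene sets for one (reference, test) timepoint contrast."""

    contrast: tuple[int, int]
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"contrast {self.contrast}: genes in both up and down "
                f"sets: {sorted(overlap)[:5]}"
            )


@dataclass
class ScreenReport:
    """Per-strain contrast sets, unions, and the case-only Venn results."""

    contrasts: dict[Strain, dict[tuple[int, int], ContrastSets]]
    up_total: dict[Strain, frozenset[str]]
    down_total: dict[Strain, frozenset[str]]
    case_only_up: frozenset[str]
    case_only_down: frozenset[str]
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.case_only_up <= self.up_total.get(Strain.CASE, frozenset()):
            raise ValueError("case_only_up is not a subset of the case up union")
        if not self.case_only_down <= self.down_total.get(Strain.CASE,
                                                          frozenset()):
            raise ValueError(
                "case_only_down is not a subset of the case down union"
            )

    def to_json_dict(self) -> dict:
        out: dict = {"stage_counts": dict(sorted(self.stage_counts.items()))}
        for strain in self.contrasts:
            for contrast, cs in self.contrasts[strain].items():
                tag = f"{strain.value}_{contrast[0]}to{contrast[1]}"
                out[f"{tag}_up"] = sorted(cs.up)
                out[f"{tag}_down"] = sorted(cs.down)
        for strain in self.up_total:
            out[f"{strain.value}_up_total"] = sorted(self.up_total[strain])
            out[f"{strain.value}_down_total"] = sorted(self.down_total[strain])
        out["case_only_up"] = sorted(self.case_only_up)
        out["case_only_down"] = sorted(self.case_only_down)
        return out


def filter_low_signal(
    matrix: ExpressionMatrix, floor: float
) -> ExpressionMatrix:
    """Drop genes whose signal is strictly below ``floor`` in ALL samples.

    A gene with even one sample at or above the floor is retained.
    """
    if floor <= 0:
        raise ValueError(f"signal floor must be positive, got {floor}")
    keep = (matrix.signals >= floor).any(axis=1)
    out = ExpressionMatrix(matrix.signals.loc[keep], matrix.samples)
    logger.info("low-signal filter (floor %g): %d -> %d genes",
                floor, matrix.n_genes, out.n_genes)
    return out


def group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean signal per gene for each (strain, timepoint) group.

    Returns a genes x groups frame with MultiIndex columns
    (strain, timepoint).  Single-replicate groups pass through unchanged;
    an empty group raises.
    """
    groups: dict[tuple[Strain, int], list[str]] = {}
    for s in matrix.samples:
        groups.setdefault((s.strain, s.timepoint), []).append(s.sample_id)
    for (strain, tp), ids in groups.items():
        if not ids:  # pragma: no cover - unreachable via construction
            raise ValueError(f"empty group ({strain.value}, {tp} wk)")
    cols = {}
    for (strain, tp), ids in sorted(groups.items(),
                                    key=lambda kv: (kv[0][0].value, kv[0][1])):
        cols[(strain, tp)] = matrix.signals[ids].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["strain", "timepoint"])
    return out


def contrast_sets(
    means: pd.DataFrame,
    strain: Strain,
    reference_tp: int,
    test_tp: int,
    config: RunConfig,
) -> ContrastSets:
    """Fold-change gene sets for one timepoint contrast within one strain.

    up = {g : mean_test/mean_ref > up_threshold}, down = {g : mean_ref /
    mean_test > down_threshold}; both strictly.  Genes with a zero mean
    in the relevant denominator are excluded from that side and logged.
    """
    for tp in (reference_tp, test_tp):
        if (strain, tp) not in means.columns:
            raise ValueError(
                f"no ({strain.value}, {tp} wk) group in the means table"
            )
    ref = means[(strain, reference_tp)]
    test = means[(strain, test_tp)]

    zero_ref = ref.index[ref == 0]
    if len(zero_ref):
        logger.warning(
            "%s %d->%d: %d genes with zero reference mean excluded from "
            "the up side (e.g. %s)", strain.value, reference_tp, test_tp,
            len(zero_ref), list(zero_ref[:3]),
        )
    zero_test = test.index[test == 0]
    if len(zero_test):
        logger.warning(
            "%s %d->%d: %d genes with zero test mean excluded from the "
            "down side (e.g. %s)", strain.value, reference_tp, test_tp,
            len(zero_test), list(zero_test[:3]),
        )

    up_ok = ref > 0
    down_ok = test > 0
    up = frozenset(ref.index[up_ok & (test / ref.where(up_ok) >
                                      config.up_threshold)])
    down = frozenset(ref.index[down_ok & (ref / test.where(down_ok) >
                                          config.down_threshold)])
    cs = ContrastSets(contrast=(reference_tp, test_tp), up=up, down=down)
    logger.info("%s %d->%d wk: %d up (> %g-fold), %d down (> %g-fold)",
                strain.value, reference_tp, test_tp, len(up),
                config.up_threshold, len(down), config.down_threshold)
    return cs


def union_contrasts(
    a: ContrastSets, b: ContrastSets
) -> tuple[frozenset[str], frozenset[str]]:
    """Per-direction union of two contrasts sharing a reference timepoint."""
    if a.contrast[0] != b.contrast[0]:
        raise ValueError(
            f"contrasts have different reference timepoints: "
            f"{a.contrast} vs {b.contrast}"
        )
    return a.up | b.up, a.down | b.down


def strain_exclusion(
    case_set: frozenset[str] | set[str],
    control_set: frozenset[str] | set[str],
) -> frozenset[str]:
    """Venn exclusion: genes called in the case strain but not the control."""
    return frozenset(case_set) - frozenset(control_set)


def run_expression_screen(
    case_matrix: ExpressionMatrix,
    control_matrix: ExpressionMatrix,
    config: RunConfig | None = None,
    reference_tp: int = 4,
    test_tps: tuple[int, ...] = (8, 10),
) -> ScreenReport:
    """Run the full screen: floor filter, means, contrasts, unions, Venn.

    The low-signal filter is applied to each strain's matrix
    independently before its own contrasts.
    """
    config = config or RunConfig()
    counts: dict[str, int] = {}
    contrasts: dict[Strain, dict[tuple[int, int], ContrastSets]] = {}
    up_total: dict[Strain, frozenset[str]] = {}
    down_total: dict[Strain, frozenset[str]] = {}

    for strain, matrix in ((Strain.CASE, case_matrix),
                           (Strain.CONTROL, control_matrix)):
        counts[f"{strain.value}_genes_input"] = matrix.n_genes
        filtered = filter_low_signal(matrix, config.signal_floor)
        counts[f"{strain.value}_genes_above_floor"] = filtered.n_genes
        means = group_means(filtered)
        per = {}
        for tp in test_tps:
            cs = contrast_sets(means, strain, reference_tp, tp, config)
            per[(reference_tp, tp)] = cs
            counts[f"{strain.value}_{reference_tp}to{tp}_up"] = len(cs.up)
            counts[f"{strain.value}_{reference_tp}to{tp}_down"] = len(cs.down)
        contrasts[strain] = per
        cs_list = list(per.values())
        if len(cs_list) == 2:
            up_u, down_u = union_contrasts(cs_list[0], cs_list[1])
        else:
            up_u = frozenset().union(*(cs.up for cs in cs_list))
            down_u = frozenset().union(*(cs.down for cs in cs_list))
        up_total[strain], down_total[strain] = up_u, down_u
        counts[f"{strain.value}_up_total"] = len(up_u)
        counts[f"{strain.value}_down_total"] = len(down_u)

    case_only_up = strain_exclusion(up_total[Strain.CASE],
                                    up_total[Strain.CONTROL])
    case_only_down = strain_exclusion(down_total[Strain.CASE],
                                      down_total[Strain.CONTROL])
    counts["case_only_up"] = len(case_only_up)
    counts["case_only_down"] = len(case_only_down)
    logger.info("screen complete: %d case-only up, %d case-only down",
                len(case_only_up), len(case_only_down))
    return ScreenReport(
        contrasts=contrasts,
        up_total=up_total,
        down_total=down_total,
        case_only_up=case_only_up,
        case_only_down=case_only_down,
        stage_counts=counts,
    )
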