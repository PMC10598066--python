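"""qPCR validation: relative quantification and the adaptive two-sample test.

Expression is quantified relative to a reference gene (Gapdh in the
study) with the 2^-dCt model: relative quantity = 2^-(Ct_target -
Ct_reference), i.e. one cycle earlier doubles the estimate.  Amplification
efficiency is assumed to be exactly 2 per cycle.

Group differences (4-week baseline vs 8- or 10-week) are tested with a
two-tailed two-sample t-test whose flavour is chosen by a variance
pre-test: if a two-tailed F-test on the variance ratio does not reject
homoscedasticity, the pooled-variance Student test is used, otherwise
the Welch test with Satterthwaite degrees of freedom.  No
multiple-testing correction is applied: each gene is judged at the
per-test alpha, matching the validation design this mirrors.

A gene is classified *case_only_increased* when it rises significantly
(in either contrast) in the case strain but in neither contrast of the
control strain, and *both_increased* when both strains rise — the latter
pattern is read as lens maturation rather than disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .core import Strain

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "relative_expression",
    "homoscedasticity_check",
    "adaptive_t_test",
    "classify_validated",
    "run_qpcr_validation",
]


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest collectable despite the name

    gene: str
    contrast: tuple[int, int]
    strain: Strain
    test_used: str  # "student" | "welch"
    p_value: float
    direction: str  # "up" | "down" | "none"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.test_used not in ("student", "welch"):
            raise ValueError(f"unknown test flavour {self.test_used!r}")


def relative_expression(ct_target, ct_reference):
    """Relative quantity under the 2^-dCt model (efficiency exactly 2).

    Accepts scalars or arrays; equal cycles give 1.0 and each cycle of
    earlier target amplification doubles the result.
    """
    return 2.0 ** -(np.asarray(ct_target, dtype=float)
                    - np.asarray(ct_reference, dtype=float))


def homoscedasticity_check(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> bool:
    """Two-tailed F-test on the variance ratio; True = equal variances kept.

    Returns True iff the test fails to reject at ``alpha``.  Two
    degenerate all-equal samples have equal variances by construction and
    return True; a single zero-variance sample against a positive-variance
    one yields a variance ratio of 0 or infinity and returns False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        return True
    if vx == 0 or vy == 0:
        return False
    f = vx / vy
    dist = stats.f(len(x) - 1, len(y) - 1)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    p = min(p, 1.0)
    return bool(p >= alpha)


def adaptive_t_test(
    x: Sequence[float],
    y: Sequence[float],
    config: RunConfig | None = None,
    gene: str = "",
    contrast: tuple[int, int] = (0, 0),
    strain: Strain = Strain.CASE,
) -> TestResult:
    """Two-tailed Student-or-Welch test chosen by the variance pre-test.

    ``x`` is the reference (baseline) group and ``y`` the test group;
    direction is "up" when the test group mean is higher and the p-value
    falls below ``config.alpha_test``, "down" in the mirror case, "none"
    otherwise.  Two zero-variance samples with equal means give p = 1;
    with different means the difference is exact and p = 0.
    """
    config = config or RunConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    equal_var = homoscedasticity_check(x, y, config.alpha_homoscedasticity)
    test_used = "student" if equal_var else "welch"
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        p = 1.0 if x.mean() == y.mean() else 0.0
    else:
        p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
    if p < config.alpha_test and y.mean() > x.mean():
        direction = "up"
    elif p < config.alpha_test and y.mean() < x.mean():
        direction = "down"
    else:
        direction = "none"
    return TestResult(gene=gene, contrast=contrast, strain=strain,
                      test_used=test_used, p_value=p, direction=direction)


def classify_validated(
    case_results: Sequence[TestResult],
    control_results: Sequence[TestResult],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Classify each gene from its per-strain, per-contrast test results.

    *case_only_increased*: significant increase (p < alpha) in at least
    one case contrast and in no control contrast; *both_increased*:
    significant increase in at least one contrast of each strain;
    otherwise *not_validated*.  A significant decrease in the control
    does not block the case-only label — only control increases do.
    Every gene must carry results for both strains.
    """
    def sig_up(results: Sequence[TestResult]) -> dict[str, bool]:
        per_gene: dict[str, bool] = {}
        for r in results:
            hit = r.direction == "up" and r.p_value < alpha
            per_gene[r.gene] = per_gene.get(r.gene, False) or hit
        return per_gene

    case_up = sig_up(case_results)
    control_up = sig_up(control_results)
    genes = sorted(set(case_up) | set(control_up))
    labels: dict[str, str] = {}
    for gene in genes:
        if gene not in case_up or gene not in control_up:
            missing = "case" if gene not in case_up else "control"
            raise ValueError(
                f"gene {gene!r} has no {missing}-strain test results"
            )
        if case_up[gene] and control_up[gene]:
            labels[gene] = "both_increased"
        elif case_up[gene]:
            labels[gene] = "case_only_increased"
        else:
            labels[gene] = "not_validated"
    return labels


def run_qpcr_validation(
    ct_table: pd.DataFrame,
    config: RunConfig | None = None,
    reference_tp: int = 4,
    test_tps: tuple[int, ...] = (8, 10),
) -> tuple[list[TestResult], dict[str, str]]:
    """Per-gene adaptive tests on relative quantities, then classification.

    ``ct_table`` has columns gene, sample_id, strain, timepoint,
    ct_target, ct_reference (see ``io.read_ct_table``).
    """
    config = config or RunConfig()
    df = ct_table.copy()
    df["rel"] = relative_expression(df["ct_target"], df["ct_reference"])
    results: list[TestResult] = []
    for (gene, strain), sub in df.groupby(["gene", "strain"], sort=True):
        base = sub.loc[sub["timepoint"] == reference_tp, "rel"].to_numpy()
        if len(base) < 2:
            raise ValueError(
                f"gene {gene!r} ({strain.value}): fewer than 2 baseline "
                f"replicates at {reference_tp} wk"
            )
        for tp in test_tps:
            test = sub.loc[sub["timepoint"] == tp, "rel"].to_numpy()
            if len(test) < 2:
                raise ValueError(
                    f"gene {gene!r} ({strain.value}): fewer than 2 "
                    f"replicates at {tp} wk"
                )
            results.append(adaptive_t_test(
                base, test, config, gene=gene,
                contrast=(reference_tp, tp), strain=strain,
            ))
    case_results = [r for r in results if r.strain is Strain.CASE]
    control_results = [r for r in results if r.strain is Strain.CONTROL]
    labels = classify_validated(case_results, control_results,
                                config.alpha_test)
    n_case_only = sum(1 for v in labels.values()
                      if v == "case_only_increased")
    n_both = sum(1 for v in labels.values() if v == "both_increased")
    logger.info("qPCR validation: %d genes case-only increased, %d "
                "increased in both strains", n_case_only, n_both)
    return results, labels
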