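"""Detection filtering and differential-expression calling for one fraction.

A gene counts as detected when its mean FPKM reaches
``detection_min_mean_fpkm`` (default 0.5) in at least one diagnosis group.
Detected genes are tested with a two-sided pooled-variance Student's t
test on ``log2(FPKM + log_pseudocount)``; fold change is the ratio of the
linear-scale group means (MDD over control). A gene is called up when
p < alpha and fold change >= ``fc_threshold`` (default 1.3), down when
p < alpha and fold change <= 1/``fc_threshold``. Benjamini-Hochberg
q-values are reported over the detected genes but are not used for
selection — significance calls rest on the raw p, matching the selection
rule the thresholds were designed for. ``log2_fc`` and ``neg_log10_p``
columns give volcano-plot coordinates directly.

Note on thresholds: a 1.3-fold change corresponds to |log2 FC| ~ 0.379
(0.584 is the log2 of a 1.5-fold change); the operative threshold here is
the fold change itself.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import percent, vectorized_ttest
from .errors import ConfigurationError

log = logging.getLogger(__name__)

DE_COLUMNS = (
    "gene_id",
    "mean_control",
    "mean_case",
    "fold_change",
    "p_value",
    "q_value",
    "class",
    "log2_fc",
    "neg_log10_p",
)


@dataclass
class AnalysisConfig:
    """Thresholds of the detection / DE / ratio stages."""

    detection_min_mean_fpkm: float = 0.5
    fc_threshold: float = 1.3
    alpha: float = 0.05
    log_pseudocount: float = 1.0  # added before the log2 transform in the t test
    ratio_pseudocount: float = 0.0  # added to both fractions in subject ratios

    def validate(self) -> None:
        if self.fc_threshold <= 1:
            raise ConfigurationError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.detection_min_mean_fpkm < 0:
            raise ConfigurationError("detection_min_mean_fpkm must be >= 0")
        if self.log_pseudocount < 0 or self.ratio_pseudocount < 0:
            raise ConfigurationError("pseudocounts must be >= 0")


@dataclass
class DetectionSummary:
    """Counts and percentages over the detected genes of one fraction."""

    n_detected: int
    n_sig_up: int
    n_sig_down: int
    pct_sig_up: float
    pct_sig_down: float
    n_up_fc: int
    n_down_fc: int


def _group_columns(matrix: pd.DataFrame, samples: pd.DataFrame, min_per_group: int = 1):
    """Map matrix columns to the two diagnosis groups via the sample sheet."""
    sheet = samples.set_index("sample_id")
    present = [s for s in matrix.columns if s in sheet.index]
    ctrl = [s for s in present if sheet.at[s, "group"] == "control"]
    case = [s for s in present if sheet.at[s, "group"] == "MDD"]
    if len(ctrl) < min_per_group or len(case) < min_per_group:
        raise ConfigurationError(
            f"need at least {min_per_group} samples per group; "
            f"got {len(ctrl)} control, {len(case)} MDD"
        )
    return ctrl, case


def detect_genes(
    matrix: pd.DataFrame, samples: pd.DataFrame, config: AnalysisConfig | None = None
) -> set[str]:
    """Genes whose mean FPKM meets the threshold in at least one group."""
    config = config or AnalysisConfig()
    config.validate()
    ctrl, case = _group_columns(matrix, samples)
    mean_ctrl = matrix[ctrl].mean(axis=1)
    mean_case = matrix[case].mean(axis=1)
    keep = (mean_ctrl >= config.detection_min_mean_fpkm) | (
        mean_case >= config.detection_min_mean_fpkm
    )
    return set(matrix.index[keep])


def de_test(
    matrix: pd.DataFrame, samples: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-gene DE statistics for one fraction's (pre-filtered) matrix.

    Returns a DataFrame with one row per gene: group means, linear fold
    change (MDD/control), t-test p on log2(FPKM + pseudocount), BH q,
    significance class (``up``/``down``/``ns``; ``undefined`` when the
    control mean is 0 and the fold change does not exist), and volcano
    coordinates.
    """
    config = config or AnalysisConfig()
    config.validate()
    ctrl, case = _group_columns(matrix, samples, min_per_group=2)

    x_ctrl = matrix[ctrl].to_numpy(dtype=float)
    x_case = matrix[case].to_numpy(dtype=float)
    mean_ctrl = x_ctrl.mean(axis=1)
    mean_case = x_case.mean(axis=1)

    log_ctrl = np.log2(x_ctrl + config.log_pseudocount)
    log_case = np.log2(x_case + config.log_pseudocount)
    _, p = vectorized_ttest(log_case, log_ctrl)

    n_degenerate = int(np.sum(p == 1.0))
    if n_degenerate:
        log.info("%d genes with zero variance and equal means assigned p = 1", n_degenerate)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ctrl > 0, mean_case / mean_ctrl, np.nan)
        log2_fc = np.log2(fc)
        neg_log10_p = -np.log10(p)

    undefined = mean_ctrl == 0
    if undefined.any():
        log.warning(
            "%d genes with zero control mean: fold change undefined, excluded from classification",
            int(undefined.sum()),
        )

    q = bh_adjust(p)
    sig = p < config.alpha
    cls = np.full(len(matrix), "ns", dtype=object)
    cls[sig & (fc >= config.fc_threshold)] = "up"
    cls[sig & (fc <= 1.0 / config.fc_threshold)] = "down"
    cls[undefined] = "undefined"

    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "mean_control": mean_ctrl,
            "mean_case": mean_case,
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
            "class": cls,
            "log2_fc": log2_fc,
            "neg_log10_p": neg_log10_p,
        }
    ).set_index("gene_id")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_and_summarize(
    results: pd.DataFrame, config: AnalysisConfig | None = None
) -> DetectionSummary:
    """Summary counts over a fraction's DE results.

    ``n_sig_up``/``n_sig_down`` count direction at p < alpha alone (with
    their percentages of the detected total); ``n_up_fc``/``n_down_fc``
    additionally require the fold-change threshold.
    """
    config = config or AnalysisConfig()
    if results.empty:
        return DetectionSummary(0, 0, 0, 0.0, 0.0, 0, 0)
    ok = results["class"] != "undefined"
    p = results["p_value"]
    fc = results["fold_change"]
    sig = ok & (p < config.alpha)
    n_detected = len(results)
    n_sig_up = int((sig & (fc > 1)).sum())
    n_sig_down = int((sig & (fc < 1)).sum())
    return DetectionSummary(
        n_detected=n_detected,
        n_sig_up=n_sig_up,
        n_sig_down=n_sig_down,
        pct_sig_up=percent(n_sig_up, n_detected),
        pct_sig_down=percent(n_sig_down, n_detected),
        n_up_fc=int((results["class"] == "up").sum()),
        n_down_fc=int((results["class"] == "down").sum()),
    )
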