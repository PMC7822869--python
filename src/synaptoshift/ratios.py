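"""The synaptic/total enrichment-ratio statistic and its group-shift test.

For each gene and subject the enrichment ratio is

    ratio(g, s) = (FPKM_synaptic(g, s) + c) / (FPKM_total(g, s) + c)

with pseudocount ``c`` (default 0; with c = 0 a zero denominator excludes
that observation). Group means of the subject-level ratios give the
control and MDD columns of the ratio table; their quotient (MDD/control,
the "ratio of ratios") quantifies the shift of a gene's expression
between compartments in disease, and a two-sided pooled-variance
Student's t test on the subject-level ratios tests it.

The gene universe for ratio analysis is conventionally the intersection
of the genes passing detection in both fractions (see
``pipeline.ratio_universe``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import percent, vectorized_ttest
from .errors import PairingError

log = logging.getLogger(__name__)

RATIO_GROUP_COLUMN = {"control": "ct_ratio", "MDD": "mdd_ratio"}


@dataclass
class SubjectRatios:
    """Per-gene, per-subject enrichment ratios plus subject group labels."""

    ratios: pd.DataFrame  # genes x subjects; NaN where excluded
    groups: pd.Series  # subject_id -> {control, MDD}


@dataclass
class EnrichmentClassSummary:
    """Distributional summary of one group's mean enrichment ratios."""

    n_genes: int
    n_above_1: int
    n_below_1: int
    median_ratio: float
    pct_enriched_1p5: float
    pct_enriched_2: float
    pct_depleted_1p5: float
    pct_depleted_2: float


@dataclass
class ValidationReport:
    """Consistency check of a published-style ratio table."""

    n_rows: int
    n_pass: int
    n_fail: int
    max_discrepancy: float
    failures: pd.DataFrame  # offending rows with recomputed ratio and discrepancy

    @property
    def ok(self) -> bool:
        return self.n_fail == 0


def subject_ratios(
    matrix: pd.DataFrame, samples: pd.DataFrame, pseudocount: float = 0.0
) -> SubjectRatios:
    """Synaptic/total ratio per gene and subject.

    Every subject must contribute exactly one sample per fraction
    (:class:`PairingError` otherwise). With ``pseudocount`` 0, a zero
    total-fraction value makes that (gene, subject) observation NaN; the
    exclusion count is logged.
    """
    sheet = samples[samples["sample_id"].isin(matrix.columns)]
    pivot = sheet.pivot_table(
        index="subject_id", columns="fraction", values="sample_id", aggfunc="first"
    )
    for fraction in ("total", "synaptic"):
        if fraction not in pivot.columns:
            pivot[fraction] = np.nan
    incomplete = pivot.index[pivot[["total", "synaptic"]].isna().any(axis=1)]
    if len(incomplete):
        raise PairingError(
            "subjects missing a fraction profile: " + ", ".join(map(str, incomplete))
        )
    subjects = pivot.index.to_numpy()
    syn = matrix[pivot["synaptic"].to_numpy()].to_numpy(dtype=float) + pseudocount
    tot = matrix[pivot["total"].to_numpy()].to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tot > 0, syn / tot, np.nan)
    n_excluded = int(np.isnan(ratio).sum())
    if n_excluded:
        log.info("%d (gene, subject) ratios excluded for zero denominators", n_excluded)
    groups = sheet.drop_duplicates("subject_id").set_index("subject_id")["group"]
    return SubjectRatios(
        ratios=pd.DataFrame(ratio, index=matrix.index, columns=subjects),
        groups=groups.reindex(subjects),
    )


def shift_test(ratios: SubjectRatios, alpha: float = 0.05) -> pd.DataFrame:
    """Group means, ratio of ratios, and shift p-value per gene.

    Genes with fewer than two valid subject ratios in either group are
    skipped (count logged). Returns columns ``ct_ratio, mdd_ratio,
    mdd_over_ct, p_value, n_control, n_case, significant``.
    """
    ctrl_cols = ratios.groups.index[ratios.groups == "control"]
    case_cols = ratios.groups.index[ratios.groups == "MDD"]
    r_ctrl = ratios.ratios[ctrl_cols].to_numpy(dtype=float)
    r_case = ratios.ratios[case_cols].to_numpy(dtype=float)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ct_mean = np.nanmean(r_ctrl, axis=1)
        case_mean = np.nanmean(r_case, axis=1)
    _, p = vectorized_ttest(r_case, r_ctrl)

    n_ctrl = (~np.isnan(r_ctrl)).sum(axis=1)
    n_case = (~np.isnan(r_case)).sum(axis=1)
    valid = (n_ctrl >= 2) & (n_case >= 2)
    if (~valid).any():
        log.info("%d genes skipped (<2 valid ratios in a group)", int((~valid).sum()))

    with np.errstate(divide="ignore", invalid="ignore"):
        roc = case_mean / ct_mean
    out = pd.DataFrame(
        {
            "ct_ratio": ct_mean,
            "mdd_ratio": case_mean,
            "mdd_over_ct": roc,
            "p_value": p,
            "n_control": n_ctrl,
            "n_case": n_case,
        },
        index=ratios.ratios.index,
    )
    out = out[valid]
    out["significant"] = out["p_value"] < alpha
    return out


def validate_ratio_table(table: pd.DataFrame, tolerance: float = 1e-4) -> ValidationReport:
    """Check mdd_ratio / ct_ratio against the printed MDD/Ct column.

    Every row must satisfy ``|mdd_ratio/ct_ratio - mdd_over_ct| <=
    tolerance``; failures are collected, not raised.
    """
    recomputed = table["mdd_ratio"].astype(float) / table["ct_ratio"].astype(float)
    discrepancy = (recomputed - table["mdd_over_ct"].astype(float)).abs()
    failing = discrepancy > tolerance
    failures = table.loc[failing].copy()
    failures["recomputed"] = recomputed[failing]
    failures["discrepancy"] = discrepancy[failing]
    return ValidationReport(
        n_rows=len(table),
        n_pass=int((~failing).sum()),
        n_fail=int(failing.sum()),
        max_discrepancy=float(discrepancy.max()) if len(table) else 0.0,
        failures=failures,
    )


def _group_ratios(records: pd.DataFrame, group: str) -> pd.Series:
    try:
        column = RATIO_GROUP_COLUMN[group]
    except KeyError:
        raise ValueError(f"group must be one of {list(RATIO_GROUP_COLUMN)}, got {group!r}")
    return records[column].astype(float)


def classify_enrichment(records: pd.DataFrame, group: str = "control") -> EnrichmentClassSummary:
    """Distribution of one group's mean ratios: above/below 1, median, tails.

    Enrichment percentages count ratios strictly above 1.5 and 2.0;
    depletion counts ratios strictly below 1/1.5 and 1/2. Ratios exactly
    1.0 sit in neither the above-1 nor the below-1 bucket. Percentages are
    of the full gene universe, rounded half-up to two decimals.
    """
    if records.empty:
        raise ValueError("classify_enrichment requires a non-empty record table")
    r = _group_ratios(records, group)
    n = len(r)
    summary = EnrichmentClassSummary(
        n_genes=n,
        n_above_1=int((r > 1.0).sum()),
        n_below_1=int((r < 1.0).sum()),
        median_ratio=float(np.median(r)),
        pct_enriched_1p5=percent(int((r > 1.5).sum()), n),
        pct_enriched_2=percent(int((r > 2.0).sum()), n),
        pct_depleted_1p5=percent(int((r < 1 / 1.5).sum()), n),
        pct_depleted_2=percent(int((r < 0.5).sum()), n),
    )
    # tail nesting must hold on every run
    assert summary.pct_enriched_2 <= summary.pct_enriched_1p5
    assert summary.pct_depleted_2 <= summary.pct_depleted_1p5
    return summary


def top_bottom(records: pd.DataFrame, n: int, group: str = "control"):
    """Gene ids with the ``n`` highest and lowest group-mean ratios.

    Ties are broken by gene id (lexicographic). If fewer than ``n``
    records exist the lists are truncated with a warning.
    """
    r = _group_ratios(records, group)
    if n > len(r):
        log.warning("requested top/bottom %d of %d records; truncating", n, len(r))
        n = len(r)
    frame = pd.DataFrame(
        {"ratio": r.to_numpy(), "gene_id": records.index.astype(str)}
    ).reset_index(drop=True)
    top = frame.sort_values(["ratio", "gene_id"], ascending=[False, True])["gene_id"]
    bottom = frame.sort_values(["ratio", "gene_id"], ascending=[True, True])["gene_id"]
    return list(top.iloc[:n]), list(bottom.iloc[:n])
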