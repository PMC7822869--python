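"""qPCR cross-validation: Livak ddCt, platform correlation, covariate screens.

Relative quantification follows the Livak method. Per sample, technical
replicates are collapsed to their mean Ct per gene; the reference value is
the geometric mean of the housekeeping-gene Cts (GAPDH, ACTB and 18S rRNA
by default); dCt = Ct_target - reference. The group contrast is
ddCt = mean dCt(MDD) - mean dCt(control) and the reported fold change is
2^-ddCt, with a two-sided pooled-variance Student's t test on the
per-sample dCt values. Because dCt is a difference of cycles, adding a
constant to every Ct (target and housekeeping alike) leaves the result
unchanged, and swapping the group roles inverts the fold change exactly.

Also here: Pearson correlation of fold changes between RNA-seq and qPCR,
per-gene covariate screens (Pearson, with 0/1 coding of binary covariates,
i.e. the point-biserial correlation), and group comparisons of the
demographic table (Student's t for continuous variables, two-sided
Fisher's exact for 2x2 categorical ones).
"""
from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import equal_var_ttest
from .errors import ConfigurationError, FormatError, InsufficientDataError
from .io import covariate_columns

log = logging.getLogger(__name__)

HOUSEKEEPING_GENES = ("GAPDH", "ACTB", "18s_rRNA")
CT_TABLE_COLUMNS = ("sample_id", "gene", "ct", "replicate")

CONTINUOUS_COVARIATES = ("age", "pmi", "ph")
BINARY_COVARIATES = ("sex", "antidepressant", "alcohol")


def reference_value(cts) -> float:
    """Geometric mean of one sample's housekeeping Ct values."""
    cts = np.asarray(cts, dtype=float)
    if cts.size == 0:
        raise ValueError("at least one housekeeping Ct is required")
    if np.any(cts <= 0) or not np.all(np.isfinite(cts)):
        raise ValueError("housekeeping Ct values must be finite and > 0")
    return float(stats.gmean(cts))


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table TSV: sample_id, gene, ct, replicate."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    missing = [c for c in CT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"Ct table missing columns: {', '.join(missing)}")
    ct = table["ct"].astype(float)
    if np.any(ct <= 0) or not np.isfinite(ct).all():
        raise FormatError("Ct values must be finite and > 0")
    return table


def delta_ct(
    ct_table: pd.DataFrame, housekeeping: tuple[str, ...] = HOUSEKEEPING_GENES
) -> pd.DataFrame:
    """Per-sample dCt for every target gene (replicates collapsed to means)."""
    collapsed = ct_table.groupby(["sample_id", "gene"], sort=False)["ct"].mean().reset_index()
    wide = collapsed.pivot(index="sample_id", columns="gene", values="ct")
    hk_present = [g for g in housekeeping if g in wide.columns]
    if not hk_present:
        raise FormatError(f"no housekeeping gene among {housekeeping} in the Ct table")
    hk = wide[hk_present]
    no_ref = hk.isna().all(axis=1)
    if no_ref.any():
        raise FormatError(
            "samples without any housekeeping Ct: " + ", ".join(wide.index[no_ref])
        )
    reference = hk.apply(lambda row: reference_value(row.dropna()), axis=1)
    targets = [g for g in wide.columns if g not in housekeeping]
    return wide[targets].sub(reference, axis=0)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    samples: pd.DataFrame,
    housekeeping: tuple[str, ...] = HOUSEKEEPING_GENES,
) -> pd.DataFrame:
    """Livak relative quantification per target gene.

    Returns one row per target: ``fold_change`` (2^-ddCt, MDD vs control),
    ``p_value`` (t test on per-sample dCt), ``delta_delta_ct``,
    ``n_control``, ``n_case``.
    """
    dct = delta_ct(ct_table, housekeeping)
    groups = samples.drop_duplicates("sample_id").set_index("sample_id")["group"]
    groups = groups.reindex(dct.index)
    rows = []
    for gene in dct.columns:
        values = dct[gene].dropna()
        g = groups.reindex(values.index)
        ctrl = values[g == "control"].to_numpy()
        case = values[g == "MDD"].to_numpy()
        if len(ctrl) < 2 or len(case) < 2:
            raise ConfigurationError(
                f"gene {gene!r}: need >=2 samples per group, "
                f"got {len(ctrl)} control, {len(case)} MDD"
            )
        ddct = case.mean() - ctrl.mean()
        _, p = equal_var_ttest(case, ctrl)
        rows.append(
            dict(
                gene_id=gene,
                fold_change=float(2.0 ** (-ddct)),
                p_value=p,
                delta_delta_ct=float(ddct),
                n_control=len(ctrl),
                n_case=len(case),
            )
        )
    return pd.DataFrame(rows).set_index("gene_id")


def per_sample_relative_expression(
    ct_table: pd.DataFrame,
    samples: pd.DataFrame,
    housekeeping: tuple[str, ...] = HOUSEKEEPING_GENES,
) -> pd.DataFrame:
    """Per-sample 2^-(dCt - mean control dCt), for plotting distributions."""
    dct = delta_ct(ct_table, housekeeping)
    groups = samples.drop_duplicates("sample_id").set_index("sample_id")["group"]
    groups = groups.reindex(dct.index)
    ctrl_mean = dct[groups == "control"].mean(axis=0)
    return 2.0 ** (-(dct - ctrl_mean))


def cross_platform_correlation(fc_rnaseq, fc_qpcr) -> tuple[float, float, int]:
    """Pearson r (and two-sided p) between paired per-gene fold changes."""
    a = pd.Series(dict(fc_rnaseq) if isinstance(fc_rnaseq, Mapping) else fc_rnaseq, dtype=float)
    b = pd.Series(dict(fc_qpcr) if isinstance(fc_qpcr, Mapping) else fc_qpcr, dtype=float)
    shared = a.index.intersection(b.index)
    shared = [g for g in shared if np.isfinite(a[g]) and np.isfinite(b[g])]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"cross-platform correlation needs >=3 shared genes, got {len(shared)}"
        )
    r, p = stats.pearsonr(a[shared], b[shared])
    return float(r), float(p), len(shared)


def covariate_screen(expression: pd.Series, samples: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of one gene's expression with each covariate.

    Continuous covariates are used as-is; binary covariates are coded 0/1
    (equivalent to the point-biserial correlation). Constant covariates or
    fewer than 3 paired observations are reported as not assessable.
    """
    rows = []
    by_sample = samples.drop_duplicates("sample_id").set_index("sample_id")
    for cov in covariate_columns(samples):
        col = by_sample[cov].reindex(expression.index)
        paired = pd.DataFrame({"expr": expression, "cov": col}).dropna()
        n_missing = len(expression) - len(paired)
        if n_missing:
            log.info("covariate %s: %d samples without a value skipped", cov, n_missing)
        result = dict(covariate=cov, statistic=np.nan, p_value=np.nan,
                      n=len(paired), assessable=False)
        if len(paired) >= 3:
            values = paired["cov"]
            if not pd.api.types.is_numeric_dtype(values):
                levels = sorted(values.unique())
                if len(levels) == 2:
                    values = (values == levels[1]).astype(float)
                elif len(levels) < 2:
                    values = None  # constant
                else:
                    log.warning("covariate %s has >2 levels; not assessable", cov)
                    values = None
            if values is not None and values.nunique() > 1 and paired["expr"].nunique() > 1:
                r, p = stats.pearsonr(paired["expr"], values)
                result.update(statistic=float(r), p_value=float(p), assessable=True)
        rows.append(result)
    return pd.DataFrame(rows).set_index("covariate")


def demographics_compare(samples: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of subject-level demographics.

    Continuous variables (age, PMI, pH) use Student's t; binary variables
    (sex, antidepressant, alcohol) use a two-sided Fisher's exact test on
    the 2x2 subject-count table.
    """
    subjects = samples.drop_duplicates("subject_id")
    ctrl = subjects[subjects["group"] == "control"]
    case = subjects[subjects["group"] == "MDD"]
    if ctrl.empty or case.empty:
        raise ConfigurationError("demographics comparison needs both groups present")
    covs = covariate_columns(samples)
    rows = []
    for var in covs:
        if var in CONTINUOUS_COVARIATES or (
            var not in BINARY_COVARIATES and pd.api.types.is_numeric_dtype(subjects[var])
        ):
            a = ctrl[var].dropna().to_numpy(dtype=float)
            b = case[var].dropna().to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = equal_var_ttest(a, b)
            rows.append(dict(variable=var, test="student_t", statistic=t, p_value=p))
        else:
            table = pd.crosstab(subjects["group"], subjects[var])
            if table.shape != (2, 2):
                log.warning("variable %s is not 2x2; skipped", var)
                continue
            odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
            rows.append(dict(variable=var, test="fisher_exact", statistic=float(odds),
                             p_value=float(p)))
    return pd.DataFrame(rows).set_index("variable")
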