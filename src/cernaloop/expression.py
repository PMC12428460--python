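"""Expression-vs-clinical association battery and qPCR ΔCt operations.

Comparisons always filter to the requested stratum first (e.g. restrict
to WHO grade 2 before comparing recurrent vs not recurrent), then test.
Fold-changes are reported on the linear scale from log2-scale medians
(FC = 2^Δmedian).  Missing annotation values are never imputed: samples
drop per comparison with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .datatypes import CtTable, ExpressionDataset
from .errors import StratificationError, UndefinedResultError
from .stats import CorrelationResult, TestResult

logger = logging.getLogger("cernaloop")


def _apply_strata(annotation: pd.DataFrame, strata: dict | None) -> pd.DataFrame:
    """Restrict annotation rows to a stratum given as {field: value-or-list}."""
    if not strata:
        return annotation
    mask = pd.Series(True, index=annotation.index)
    for field_name, wanted in strata.items():
        if field_name not in annotation.columns:
            raise KeyError(f"unknown annotation field {field_name!r}")
        allowed = wanted if isinstance(wanted, (list, tuple, set)) else [wanted]
        mask &= annotation[field_name].isin(list(allowed))
    out = annotation.loc[mask]
    if out.empty:
        raise StratificationError(f"stratum filter {strata!r} leaves no samples")
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group expression comparison for one gene."""

    gene: str
    grouping: str
    case_label: str
    reference_label: str
    n_case: int
    n_reference: int
    median_case: float      # log2 scale
    median_reference: float  # log2 scale
    fc: float                # linear scale, case / reference
    test: TestResult


def compare_groups(
    ds: ExpressionDataset,
    gene: str,
    grouping: str,
    case: str,
    reference: str,
    strata: dict | None = None,
    alternative: str = "two_sided",
) -> ComparisonResult:
    """Mann–Whitney comparison of one gene between two annotation groups.

    ``strata`` filters the cohort first (e.g. ``{"who_grade": 2}``);
    ``case``/``reference`` are levels of the ``grouping`` field.  The
    fold-change is 2^(median(case) - median(reference)).
    """
    gene = gene.strip().upper()
    if gene not in ds.values.index:
        raise KeyError(f"gene {gene!r} absent from the expression matrix")
    ann = _apply_strata(ds.annotation, strata)
    labels = ann[grouping]
    case_ids = labels.index[labels == case]
    ref_ids = labels.index[labels == reference]
    if len(case_ids) == 0 or len(ref_ids) == 0:
        raise StratificationError(
            f"empty group for {grouping!r}={case if len(case_ids) == 0 else reference!r} "
            f"under stratum filter {strata!r}"
        )
    x = ds.values.loc[gene, case_ids].to_numpy()
    y = ds.values.loc[gene, ref_ids].to_numpy()
    test = stats.mann_whitney(x, y, alternative=alternative)
    return ComparisonResult(
        gene=gene,
        grouping=grouping,
        case_label=str(case),
        reference_label=str(reference),
        n_case=len(x),
        n_reference=len(y),
        median_case=float(np.median(x)),
        median_reference=float(np.median(y)),
        fc=stats.fc_between_medians(x, y),
        test=test,
    )


@dataclass(frozen=True)
class SubtypeComparison:
    """Global Kruskal–Wallis plus Dunn pairwise results across subtypes."""

    gene: str
    subtypes: tuple[str, ...]
    n_per_subtype: tuple[int, ...]
    medians: tuple[float, ...]
    global_test: TestResult
    pairwise: tuple[tuple[tuple[str, str], float, TestResult], ...]
    # each entry: ((subtype_i, subtype_j), fc_i_vs_j, dunn result)
    n_excluded: int


def compare_subtypes(
    ds: ExpressionDataset,
    gene: str,
    strata: dict | None = None,
    dunn_adjust: str = "bonferroni",
) -> SubtypeComparison:
    """Kruskal–Wallis + Dunn post hoc on one gene across molecular subtypes.

    Samples without a subtype call are excluded (count logged).
    """
    gene = gene.strip().upper()
    if gene not in ds.values.index:
        raise KeyError(f"gene {gene!r} absent from the expression matrix")
    ann = _apply_strata(ds.annotation, strata)
    subtyped = ann[ann["meng_subtype"].notna()]
    n_excluded = len(ann) - len(subtyped)
    if n_excluded:
        logger.info("compare_subtypes: %d unsubtyped sample(s) excluded", n_excluded)
    levels = tuple(sorted(subtyped["meng_subtype"].unique()))
    if len(levels) < 3:
        raise StratificationError(
            f"need >= 3 non-empty subtype groups, found {levels} under {strata!r}"
        )
    groups = [
        ds.values.loc[gene, subtyped.index[subtyped["meng_subtype"] == lv]].to_numpy()
        for lv in levels
    ]
    global_test = stats.kruskal_wallis(groups)
    dunn = stats.dunn_posthoc(groups, adjust=dunn_adjust)
    pairwise = tuple(
        (
            (levels[i], levels[j]),
            stats.fc_between_medians(groups[i], groups[j]),
            res,
        )
        for (i, j), res in dunn
    )
    return SubtypeComparison(
        gene=gene,
        subtypes=levels,
        n_per_subtype=tuple(len(g) for g in groups),
        medians=tuple(float(np.median(g)) for g in groups),
        global_test=global_test,
        pairwise=pairwise,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class PrevalenceResult:
    """Subtype prevalence per stratum with pairwise Fisher tests.

    ``counts``/``percentages`` are subtype × stratum tables; each Fisher
    test compares a subtype pair's counts across the two strata.
    """

    strata_labels: tuple[str, ...]
    counts: pd.DataFrame
    percentages: pd.DataFrame
    fisher: dict[tuple[str, str], TestResult]
    n_excluded: int


def subtype_prevalence(
    annotation: pd.DataFrame,
    strata_field: str = "recurrent",
    cohort: dict | None = None,
) -> PrevalenceResult:
    """Subtype prevalence (%) across the two levels of ``strata_field``.

    ``cohort`` optionally restricts the cohort first (e.g. grade 2 only).
    Unsubtyped samples are excluded with a logged count.  For every
    subtype pair a 2×2 Fisher test (subtype_i vs subtype_j × stratum)
    is run where the table is non-degenerate.
    """
    ann = _apply_strata(annotation, cohort)
    subtyped = ann[ann["meng_subtype"].notna()]
    n_excluded = len(ann) - len(subtyped)
    if n_excluded:
        logger.info("subtype_prevalence: %d unsubtyped sample(s) excluded", n_excluded)
    strata_levels = tuple(sorted(subtyped[strata_field].dropna().unique()))
    if len(strata_levels) != 2:
        raise StratificationError(
            f"{strata_field!r} must have exactly 2 levels in the cohort, found {strata_levels}"
        )
    subtypes = tuple(sorted(subtyped["meng_subtype"].unique()))
    counts = pd.DataFrame(
        0, index=list(subtypes), columns=list(strata_levels), dtype=int
    )
    for stratum in strata_levels:
        sub = subtyped[subtyped[strata_field] == stratum]
        if sub.empty:
            raise StratificationError(f"stratum {strata_field}={stratum!r} is empty")
        vc = sub["meng_subtype"].value_counts()
        for st in subtypes:
            counts.loc[st, stratum] = int(vc.get(st, 0))
    percentages = counts / counts.sum(axis=0) * 100.0

    fisher: dict[tuple[str, str], TestResult] = {}
    for i in range(len(subtypes)):
        for j in range(i + 1, len(subtypes)):
            table = [
                [counts.iloc[i, 0], counts.iloc[i, 1]],
                [counts.iloc[j, 0], counts.iloc[j, 1]],
            ]
            try:
                fisher[(subtypes[i], subtypes[j])] = stats.fisher_exact(table)
            except UndefinedResultError:
                logger.info(
                    "Fisher test skipped for degenerate pair %s vs %s",
                    subtypes[i], subtypes[j],
                )
    return PrevalenceResult(
        strata_labels=strata_levels,
        counts=counts,
        percentages=percentages,
        fisher=fisher,
        n_excluded=n_excluded,
    )


def correlate_features(
    ds: ExpressionDataset,
    gene_x: str,
    feature_y: str,
    strata: dict | None = None,
) -> CorrelationResult:
    """Spearman correlation between a gene and a gene or numeric annotation.

    ``feature_y`` may be another gene symbol (matrix row) or a numeric
    annotation field such as the proliferation index.  Pairs with a
    missing value drop out; fewer than 3 remaining pairs is an error.
    """
    gene_x = gene_x.strip().upper()
    if gene_x not in ds.values.index:
        raise KeyError(f"gene {gene_x!r} absent from the expression matrix")
    ann = _apply_strata(ds.annotation, strata)
    x = ds.values.loc[gene_x, ann.index]
    if feature_y.strip().upper() in ds.values.index:
        y = ds.values.loc[feature_y.strip().upper(), ann.index]
    elif feature_y in ann.columns:
        y = pd.to_numeric(ann[feature_y], errors="coerce")
    else:
        raise KeyError(f"{feature_y!r} is neither a gene nor an annotation field")
    paired = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(paired) < 3:
        raise UndefinedResultError(
            f"correlation needs >= 3 complete pairs, got {len(paired)}"
        )
    return stats.spearman(paired["x"].to_numpy(), paired["y"].to_numpy())


# ---------------------------------------------------------------------------
# qPCR ΔCt operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaCtProfile:
    """Per-tissue ΔCt = Ct(assay) − Ct(reference), in cycles.

    Lower ΔCt means higher expression.  Defined only for tissues where
    both Ct values are present.
    """

    assay: str
    reference: str
    values: pd.Series  # indexed by tissue


def delta_ct(ct: CtTable, assay: str, reference: str | None = None) -> DeltaCtProfile:
    """ΔCt profile of one assay against the reference transcript.

    Tissues missing either Ct value are dropped (count logged), never
    imputed.
    """
    ref = reference if reference is not None else ct.reference
    if ref not in ct.ct.index:
        raise ValueError(f"reference assay {ref!r} absent from the Ct table")
    if assay not in ct.ct.index:
        raise ValueError(f"assay {assay!r} absent from the Ct table")
    diff = ct.ct.loc[assay] - ct.ct.loc[ref]
    n_dropped = int(diff.isna().sum())
    if n_dropped:
        logger.info("delta_ct(%s): %d tissue(s) dropped for missing Ct", assay, n_dropped)
    return DeltaCtProfile(assay=assay, reference=ref, values=diff.dropna())


def correlate_assays(p1: DeltaCtProfile, p2: DeltaCtProfile) -> CorrelationResult:
    """Spearman correlation of two ΔCt profiles over shared tissues.

    Because both profiles are on the ΔCt scale (which is inversely
    monotone in expression), the ΔCt–ΔCt correlation has the same sign
    as the corresponding expression–expression correlation.
    """
    shared = p1.values.index.intersection(p2.values.index)
    if len(shared) < 3:
        raise UndefinedResultError(
            f"assay correlation needs >= 3 shared tissues, got {len(shared)}"
        )
    return stats.spearman(p1.values[shared].to_numpy(), p2.values[shared].to_numpy())
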