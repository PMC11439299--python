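"""Well-level aggregation and group comparisons.

The experimental unit is the plate well, not the cell or the image
field: per-cell calls are first reduced to per-well percentages of
labeled cells (``UNLABELED`` cells enter neither numerator nor
denominator), wells of a treatment are summarized as mean +/- SE, and
treatments are compared per localization class with a two-tailed
two-sample t-test (pooled-variance Student t by default, Welch
optionally) plus a fold-ratio effect size.

The t-test can be run either from per-well data or directly from
published summary statistics (mean, SE, n per group), which makes a
printed summary table reproducible without the underlying wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LOCALIZATION_CLASSES",
    "WellSummary",
    "TTestResult",
    "GroupComparison",
    "summarize_well",
    "summarize_wells",
    "group_mean_se",
    "t_test_from_summary",
    "t_test_from_wells",
    "ratio_effect",
    "compare_groups",
    "round_half_up",
    "comparison_report",
]

#: Localization classes carried through aggregation, in report order.
LOCALIZATION_CLASSES = ("NUCLEAR", "CYTOPLASMIC", "BOTH")

_PCT_COLUMNS = {"NUCLEAR": "pct_nuclear", "CYTOPLASMIC": "pct_cytoplasmic", "BOTH": "pct_both"}


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal rounding, halves away from zero (as in printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class WellSummary:
    """Localization percentages of one well's labeled cells."""

    well: str
    treatment: str
    n_labeled: int
    pct_nuclear: float
    pct_cytoplasmic: float
    pct_both: float
    valid: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_well(records: pd.DataFrame) -> WellSummary:
    """Reduce one well's cell records to localization percentages.

    ``records`` must carry ``well``, ``treatment`` and ``call`` columns
    and belong to a single well.  Percentages use labeled cells (calls
    in {NUCLEAR, CYTOPLASMIC, BOTH}) as the denominator.  A well with
    no labeled cells yields a flagged (``valid=False``) summary with
    NaN percentages and a warning; such wells are excluded from group
    statistics.
    """
    wells = records["well"].unique()
    if len(wells) != 1:
        raise ValueError(f"records span {len(wells)} wells, expected exactly 1: {sorted(map(str, wells))}")
    well = str(wells[0])
    treatment = str(records["treatment"].iloc[0])
    counts = records["call"].value_counts()
    n_labeled = int(sum(counts.get(c, 0) for c in LOCALIZATION_CLASSES))
    if n_labeled == 0:
        warnings.warn(f"well {well!r}: no labeled cells; percentages undefined")
        return WellSummary(well, treatment, 0, float("nan"), float("nan"), float("nan"), valid=False)
    pct = {c: 100.0 * counts.get(c, 0) / n_labeled for c in LOCALIZATION_CLASSES}
    return WellSummary(well, treatment, n_labeled, pct["NUCLEAR"], pct["CYTOPLASMIC"], pct["BOTH"])


def summarize_wells(records: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`summarize_well` per well; one row per well."""
    rows = [summarize_well(grp).as_dict() for _, grp in records.groupby("well", sort=True)]
    return pd.DataFrame(
        rows, columns=["well", "treatment", "n_labeled", "pct_nuclear", "pct_cytoplasmic", "pct_both", "valid"]
    )


def group_mean_se(values: "np.ndarray | list[float] | pd.Series") -> tuple[float, float, int]:
    """Mean, standard error (sample sd / sqrt(n)) and n of well percentages."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n < 2:
        raise ValueError(f"need at least 2 wells to compute a standard error, got {n}")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(n)), int(n)


@dataclass
class TTestResult:
    """Two-tailed two-sample t-test outcome."""

    t: float
    df: float
    p: float


def t_test_from_summary(
    mean_a: float,
    se_a: float,
    n_a: int,
    mean_b: float,
    se_b: float,
    n_b: int,
    variant: str = "pooled",
) -> TTestResult:
    """Two-tailed independent-samples t-test from summary statistics.

    ``pooled`` (default) assumes equal variances with
    ``df = n_a + n_b - 2``; ``welch`` uses the Welch-Satterthwaite
    approximation.  Group standard deviations are recovered from the
    standard errors as ``sd = se * sqrt(n)``.

    Degenerate inputs (both SEs zero) give p = 1 for equal means and
    p = 0 with a warning for unequal means.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    if n_a < 2 or n_b < 2:
        raise ValueError(f"need n >= 2 per group, got n_a={n_a}, n_b={n_b}")
    df_pooled = n_a + n_b - 2
    if se_a == 0 and se_b == 0:
        if mean_a == mean_b:
            return TTestResult(t=0.0, df=float(df_pooled), p=1.0)
        warnings.warn("zero variance in both groups with unequal means: p = 0 (degenerate input)")
        t = float("inf") if mean_a > mean_b else float("-inf")
        return TTestResult(t=t, df=float(df_pooled), p=0.0)
    sd_a = se_a * np.sqrt(n_a)
    sd_b = se_b * np.sqrt(n_b)
    res = sps.ttest_ind_from_stats(
        mean1=mean_a, std1=sd_a, nobs1=n_a,
        mean2=mean_b, std2=sd_b, nobs2=n_b,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = float(df_pooled)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def ratio_effect(mean_a: float, mean_b: float) -> float:
    """Fold ratio of two group means: larger / smaller, to 1 decimal.

    Rounding is half away from zero, matching how such ratios are
    reported ("x times more").
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError(f"ratio effect requires positive means, got {mean_a} and {mean_b}")
    return round_half_up(max(mean_a, mean_b) / min(mean_a, mean_b), 1)


@dataclass
class GroupComparison:
    """One localization class compared between two treatment groups."""

    class_name: str
    group_a: str
    group_b: str
    mean_a: float
    se_a: float
    n_a: int
    mean_b: float
    se_b: float
    n_b: int
    t: float
    df: float
    p: float
    ratio: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def t_test_from_wells(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    class_name: str,
    variant: str = "pooled",
    group_a: str | None = None,
    group_b: str | None = None,
) -> GroupComparison:
    """Compare one localization class between two groups of wells.

    ``summaries_a`` / ``summaries_b`` are well-summary frames (as from
    :func:`summarize_wells`); invalid wells (no labeled cells) are
    dropped first.  The result is fully reproducible from the per-well
    percentages alone.
    """
    if class_name not in _PCT_COLUMNS:
        raise ValueError(f"unknown class {class_name!r}; expected one of {LOCALIZATION_CLASSES}")
    col = _PCT_COLUMNS[class_name]
    frames = []
    for summ in (summaries_a, summaries_b):
        if "valid" in summ.columns:
            summ = summ[summ["valid"].astype(bool)]
        frames.append(summ)
    a, b = frames
    mean_a, se_a, n_a = group_mean_se(a[col])
    mean_b, se_b, n_b = group_mean_se(b[col])
    tt = t_test_from_summary(mean_a, se_a, n_a, mean_b, se_b, n_b, variant=variant)
    ratio = ratio_effect(mean_a, mean_b) if mean_a > 0 and mean_b > 0 else None
    name_a = group_a if group_a is not None else str(a["treatment"].iloc[0])
    name_b = group_b if group_b is not None else str(b["treatment"].iloc[0])
    return GroupComparison(
        class_name=class_name,
        group_a=name_a, group_b=name_b,
        mean_a=mean_a, se_a=se_a, n_a=n_a,
        mean_b=mean_b, se_b=se_b, n_b=n_b,
        t=tt.t, df=tt.df, p=tt.p, ratio=ratio,
    )


def compare_groups(
    wells: pd.DataFrame,
    group_a: str,
    group_b: str,
    variant: str = "pooled",
) -> list[GroupComparison]:
    """Run the three per-class comparisons between two treatments.

    ``wells`` is a well-summary frame covering both groups.  No
    multiple-testing correction is applied across the three classes;
    each p-value is reported as-is.
    """
    available = sorted(wells["treatment"].unique())
    for g in (group_a, group_b):
        if g not in available:
            raise ValueError(f"unknown group {g!r}; available groups: {available}")
    a = wells[wells["treatment"] == group_a]
    b = wells[wells["treatment"] == group_b]
    return [
        t_test_from_wells(a, b, cls, variant=variant, group_a=group_a, group_b=group_b)
        for cls in LOCALIZATION_CLASSES
    ]


_CLASS_HEADERS = {
    "NUCLEAR": "Nuclei labeled (%)",
    "CYTOPLASMIC": "Cytoplasm labeled (%)",
    "BOTH": "Nuclei and Cytoplasm labeled (%)",
}


def comparison_report(comparisons: list[GroupComparison]) -> str:
    """Markdown summary table: mean +/- SE per class per group, p row, ratios.

    Means and SEs print to 2 decimals, p-values to 2 decimals (half
    away from zero), ratios to 1 decimal — the conventional precision
    of such localization tables.
    """
    if not comparisons:
        raise ValueError("no comparisons to report")
    by_class = {c.class_name: c for c in comparisons}
    classes = [c for c in LOCALIZATION_CLASSES if c in by_class]
    first = comparisons[0]
    header = ["Group"] + [_CLASS_HEADERS[c] for c in classes]
    lines = [
        "| " + " | ".join(header) + " |",
        "|" + "---|" * len(header),
    ]
    for side in ("a", "b"):
        name = getattr(first, f"group_{side}")
        cells = [
            f"{getattr(by_class[c], f'mean_{side}'):.2f} ± {getattr(by_class[c], f'se_{side}'):.2f}"
            for c in classes
        ]
        lines.append("| " + " | ".join([name] + cells) + " |")
    lines.append(
        "| p-value | " + " | ".join(f"{round_half_up(by_class[c].p, 2):.2f}" for c in classes) + " |"
    )
    lines.append(
        "| ratio (larger/smaller) | "
        + " | ".join("—" if by_class[c].ratio is None else f"{by_class[c].ratio:.1f}" for c in classes)
        + " |"
    )
    n_note = f"\nn = {first.n_a} wells ({first.group_a}), {first.n_b} wells ({first.group_b}); "
    n_note += "two-tailed independent-samples t-test, df = "
    n_note += ", ".join(f"{by_class[c].df:g}" for c in classes) + "."
    lines.append(n_note)
    return "\n".join(lines)
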