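"""Reliability screening of radiomic features: QCD and ICC.

Two statistics drive the screening:

* **QCD**, the quartile coefficient of dispersion
  ``(Q3 - Q1) / (Q3 + Q1) * 100`` of one feature across subjects within one
  delineation arm — a robust relative-dispersion measure. Undefined when
  ``Q1 + Q3 <= 0`` (possible for signed features such as skewness); an
  undefined QCD never counts as "small variation".
* **ICC**, the two-way random-effects, single-rater, absolute-agreement
  intraclass correlation

  ``ICC = (MS_R - MS_E) / (MS_R + (k - 1) MS_E + (k / n)(MS_C - MS_E))``

  from the standard two-way ANOVA decomposition of an n-subjects x k-raters
  rating matrix, computed here for every pair of delineation arms (k = 2).

Thresholds: ICC < 0.4 poor, 0.4-0.59 fair, 0.6-0.74 good, >= 0.75
excellent; QCD < 10% small, 10-20% intermediate, >= 20% large.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityAnova",
    "ReproRecord",
    "FeatureTable",
    "qcd",
    "icc_two_way",
    "classify_icc",
    "classify_qcd",
    "pairwise_icc",
    "arm_qcd",
    "count_meeting",
    "select_robust",
    "ReproResults",
]

#: Intra-observer arm pairs under the 1,2 = observer-1 / 3,4 = observer-2
#: session convention; every other pair crosses observers.
INTRA_OBSERVER_PAIRS = {(1, 2), (3, 4)}


@dataclass(frozen=True)
class ReliabilityAnova:
    """Mean squares of the two-way ANOVA behind one ICC."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class ReproRecord:
    """Reliability of one feature under one arm comparison."""

    feature: str
    comparison: str
    tissue: str
    icc: float | None
    icc_class: str
    intra_observer: bool


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x features values of one delineation arm."""

    arm: str
    tissue: str
    data: pd.DataFrame  # index: subject ids; columns: feature names

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError(f"feature table {self.arm}/{self.tissue} has missing cells")


def qcd(values) -> float | None:
    """Quartile coefficient of dispersion, in percent.

    Quartiles use linear interpolation between order statistics. Returns
    ``None`` (undefined) when ``Q1 + Q3 <= 0``.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError(f"QCD requires at least 2 values, got {x.size}")
    q1, q3 = np.percentile(x, (25, 75))
    denom = q1 + q3
    if denom <= 0:
        return None
    return float((q3 - q1) / denom * 100.0)


def icc_two_way(ratings) -> tuple[float | None, ReliabilityAnova]:
    """Two-way random-effects, single-rater, absolute-agreement ICC.

    Parameters
    ----------
    ratings
        n x k matrix (n subjects, k raters), no missing cells.

    Returns
    -------
    (icc, anova)
        ``icc`` is ``None`` for a constant matrix (no variance to
        apportion); the ANOVA mean squares are returned alongside.
    """
    m = np.asarray(ratings, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC requires >= 2 subjects and >= 2 raters, got {n} x {k}")
    if np.isnan(m).any():
        raise ValueError("ratings matrix has missing cells")

    gm = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - gm) ** 2)
    ss_cols = n * np.sum((col_means - gm) ** 2)
    resid = m - row_means[:, None] - col_means[None, :] + gm
    ss_err = np.sum(resid**2)

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    anova = ReliabilityAnova(ms_r, ms_c, ms_e, n, k)

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        # constant matrix: no subject, rater or error variance at all
        return None, anova
    return float((ms_r - ms_e) / denom), anova


def classify_icc(icc: float | None) -> str:
    """Reliability class of an ICC value (poor/fair/good/excellent)."""
    if icc is None:
        return "undefined"
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def classify_qcd(q: float | None, inclusive_small: bool = False) -> str:
    """Variation class of a QCD percentage (small/intermediate/large).

    ``inclusive_small`` switches the small-variation rule from the primary
    strict ``QCD < 10`` to ``QCD <= 10``.
    """
    if q is None:
        return "undefined"
    small = q <= 10.0 if inclusive_small else q < 10.0
    if small:
        return "small"
    if q < 20.0:
        return "intermediate"
    return "large"


def _arm_index(arm_label: str) -> int:
    return int(arm_label[-1])


def pairwise_icc(tables: list[FeatureTable]) -> list[ReproRecord]:
    """ICC of every feature for all unordered pairs of the given arms.

    For the standard 4 arms of one modality + tissue this yields the 6
    comparisons (1,2), (1,3), (1,4), (2,3), (2,4), (3,4), of which (1,2)
    and (3,4) are intra-observer.
    """
    if len(tables) < 2:
        raise ValueError("pairwise ICC requires at least 2 arms")
    tissues = {t.tissue for t in tables}
    if len(tissues) != 1:
        raise ValueError(f"arms span multiple tissues: {sorted(tissues)}")
    base = tables[0].data
    for t in tables[1:]:
        if list(t.data.index) != list(base.index):
            missing = sorted(set(base.index).symmetric_difference(t.data.index))
            raise ValueError(
                f"subject sets differ between arms {tables[0].arm} and {t.arm}: {missing}"
            )
        if list(t.data.columns) != list(base.columns):
            raise ValueError(f"feature sets differ between arms {tables[0].arm} and {t.arm}")

    records: list[ReproRecord] = []
    tissue = tables[0].tissue
    for ta, tb in combinations(tables, 2):
        pair = (_arm_index(ta.arm), _arm_index(tb.arm))
        intra = tuple(sorted(pair)) in INTRA_OBSERVER_PAIRS
        label = f"{ta.arm}/{tb.arm}"
        a = ta.data.to_numpy()
        b = tb.data.to_numpy()
        for j, feat in enumerate(base.columns):
            icc, _ = icc_two_way(np.column_stack([a[:, j], b[:, j]]))
            records.append(
                ReproRecord(
                    feature=feat,
                    comparison=label,
                    tissue=tissue,
                    icc=icc,
                    icc_class=classify_icc(icc),
                    intra_observer=intra,
                )
            )
    return records


def arm_qcd(table: FeatureTable, inclusive_small: bool = False) -> pd.DataFrame:
    """Per-feature QCD (and class) across subjects within one arm."""
    rows = []
    for feat in table.data.columns:
        q = qcd(table.data[feat].to_numpy())
        rows.append(
            {
                "feature": feat,
                "arm": table.arm,
                "tissue": table.tissue,
                "qcd": np.nan if q is None else q,
                "qcd_class": classify_qcd(q, inclusive_small=inclusive_small),
            }
        )
    return pd.DataFrame(rows)


def count_meeting(
    icc_records: list[ReproRecord],
    qcd_table: pd.DataFrame | None = None,
    icc_threshold: float = 0.75,
    qcd_threshold: float = 10.0,
) -> dict[str, dict[str, int]]:
    """Counts of features meeting the reliability thresholds.

    Returns ``{"icc": {comparison: count of ICC >= threshold},
    "qcd": {arm: count of QCD < threshold}}`` (undefined values excluded).
    """
    icc_counts: dict[str, int] = {}
    for rec in icc_records:
        icc_counts.setdefault(rec.comparison, 0)
        if rec.icc is not None and rec.icc >= icc_threshold:
            icc_counts[rec.comparison] += 1
    out = {"icc": icc_counts, "qcd": {}}
    if qcd_table is not None:
        for arm, grp in qcd_table.groupby("arm"):
            out["qcd"][str(arm)] = int((grp["qcd"] < qcd_threshold).sum())
    return out


def select_robust(
    tumor_icc: list[ReproRecord],
    peritumor_icc: list[ReproRecord],
    tumor_qcd: pd.DataFrame,
    peritumor_qcd: pd.DataFrame,
    icc_threshold: float = 0.75,
    qcd_threshold: float = 10.0,
    semantics: str = "all",
) -> list[str]:
    """Features robust to delineation variability in *both* tissues.

    A feature is robust when its ICC meets the threshold in all (or, with
    ``semantics="any"``, at least one of) the supplied arm comparisons and
    its QCD is below the threshold in all (resp. any) arms — in both the
    tumor and the peritumoral records. Undefined values fail the test.
    """
    if semantics not in ("all", "any"):
        raise ValueError(f"semantics must be 'all' or 'any', got {semantics!r}")
    agg = all if semantics == "all" else any

    def icc_ok(records: list[ReproRecord]) -> set[str]:
        per_feature: dict[str, list[bool]] = {}
        for rec in records:
            per_feature.setdefault(rec.feature, []).append(
                rec.icc is not None and rec.icc >= icc_threshold
            )
        return {f for f, oks in per_feature.items() if agg(oks)}

    def qcd_ok(table: pd.DataFrame) -> set[str]:
        ok = {}
        for feat, grp in table.groupby("feature"):
            flags = (grp["qcd"].notna() & (grp["qcd"] < qcd_threshold)).tolist()
            ok[feat] = agg(flags)
        return {f for f, v in ok.items() if v}

    robust = (
        icc_ok(tumor_icc) & icc_ok(peritumor_icc) & qcd_ok(tumor_qcd) & qcd_ok(peritumor_qcd)
    )
    order = {rec.feature: i for i, rec in enumerate(tumor_icc)}
    return sorted(robust, key=lambda f: order.get(f, len(order)))


@dataclass
class ReproResults:
    """Bundled reliability results of one modality group (or the whole study).

    Carries the long-format ICC records, per-arm QCD tables and the derived
    counts; ``summary()`` renders the per-comparison counts the way the
    field reports them ("77/107 (72.0%)").
    """

    icc_records: dict[str, list[ReproRecord]]  # tissue -> records
    qcd_tables: dict[str, pd.DataFrame]  # tissue -> long table
    icc_threshold: float = 0.75
    qcd_threshold: float = 10.0

    def counts(self, tissue: str) -> dict[str, dict[str, int]]:
        return count_meeting(
            self.icc_records[tissue],
            self.qcd_tables.get(tissue),
            icc_threshold=self.icc_threshold,
            qcd_threshold=self.qcd_threshold,
        )

    def n_features(self, tissue: str) -> int:
        return len({r.feature for r in self.icc_records[tissue]})

    def icc_frame(self, tissue: str) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": r.feature,
                    "comparison": r.comparison,
                    "tissue": r.tissue,
                    "icc": np.nan if r.icc is None else r.icc,
                    "icc_class": r.icc_class,
                    "intra_observer": r.intra_observer,
                }
                for r in self.icc_records[tissue]
            ]
        )

    def summary(self) -> str:
        lines = []
        for tissue in self.icc_records:
            total = self.n_features(tissue)
            counts = self.counts(tissue)
            lines.append(f"== {tissue} ==")
            lines.append(f"ICC >= {self.icc_threshold:g} per comparison:")
            for comp, cnt in counts["icc"].items():
                lines.append(f"  {comp}: {format_count(cnt, total)}")
            if counts["qcd"]:
                lines.append(f"QCD < {self.qcd_threshold:g}% per arm:")
                for arm, cnt in counts["qcd"].items():
                    lines.append(f"  {arm}: {format_count(cnt, total)}")
        return "\n".join(lines)


def format_count(count: int, total: int, decimals: int = 1) -> str:
    """Render a count as ``"77/107 (72.0%)"``."""
    pct = 0.0 if total == 0 else 100.0 * count / total
    return f"{count}/{total} ({pct:.{decimals}f}%)"
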