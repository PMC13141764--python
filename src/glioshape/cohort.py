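"""Marker calling and univariate association analysis of boundary shape.

Implements the pathology interpretation thresholds (all inclusive ``>=``),
the per-variable 2x2 contingency construction against the linear/curved
shape label, the cross-product odds ratio with the Woolf log-interval, the
chi-square test, and the Spearman/VIF collinearity screen used before
multivariable modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortError
from .simulate import PUBLISHED_MARGINS

__all__ = [
    "MARKER_THRESHOLDS",
    "CUT_POINTS",
    "ContingencyTable",
    "AssociationResult",
    "ScreenResult",
    "call_marker_status",
    "compute_ki67_index",
    "build_contingency",
    "odds_ratio",
    "chi_square",
    "spearman_screen",
    "vif_screen",
    "association_table",
]

#: inclusive positivity thresholds on the assay fraction
MARKER_THRESHOLDS = {
    "IDH1": 0.30,       # fraction of immunoreactive tumor cells (focal staining)
    "ATRX": 0.10,       # fraction of stained tumor nuclei
    "TP53": 0.10,       # fraction of stained tumor nuclei
    "1p/19q": 0.25,     # fraction of probe signals with concurrent 1p and 19q loss
    "MGMT": 0.10,       # mean methylation level across CpG sites
}

#: dichotomization cut-points for continuous covariates (overridable)
CUT_POINTS = {"age": 38.0, "volume": 20.17, "ki67_index": 0.10}


def call_marker_status(marker: str, measurement: float) -> str:
    """Positive/negative call from a raw assay fraction, inclusive at the cut."""
    if marker not in MARKER_THRESHOLDS:
        raise CohortError("unknown-marker", f"unknown marker {marker!r}")
    if not (0.0 <= measurement <= 1.0) or not np.isfinite(measurement):
        raise CohortError("bad-fraction",
                          f"measurement must be in [0, 1], got {measurement}")
    return "positive" if measurement >= MARKER_THRESHOLDS[marker] else "negative"


def compute_ki67_index(stained: int, total: int) -> float:
    """Proliferation index: stained tumor nuclei over total tumor nuclei."""
    if total == 0:
        raise CohortError("empty-field", "no tumor nuclei counted")
    if not (0 <= stained <= total):
        raise CohortError("bad-fraction", "need 0 <= stained <= total")
    return stained / total


# --------------------------------------------------------------------------
# contingency analysis
# --------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """2x2 (or larger) counts; columns are the shape labels (L, C)."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str] = field(default_factory=lambda: ["L", "C"])
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise CohortError("bad-table", "negative cell count")
        if self.counts.sum() == 0:
            raise CohortError("degenerate-table", "all cells zero")


@dataclass
class AssociationResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    orientation: str
    zero_cell_adjusted: bool = False


@dataclass
class ScreenResult:
    rho: pd.DataFrame
    rho_p: pd.DataFrame
    vif: pd.Series
    excluded: dict[str, str]


def _dichotomize(series: pd.Series, variable: str,
                 cut_points: dict[str, float]) -> tuple[pd.Series, list[str]]:
    cut = cut_points[variable]
    labels = [f"<={cut:g}", f">{cut:g}"]
    out = pd.Series(np.where(series <= cut, labels[0], labels[1]),
                    index=series.index)
    out[series.isna()] = np.nan
    return out, labels


def build_contingency(cohort: pd.DataFrame, variable: str,
                      level_order: list[str] | None = None,
                      cut_points: dict[str, float] | None = None
                      ) -> ContingencyTable:
    """Counts of patients per (variable level, shape label) cell.

    Continuous variables named in the cut-point dictionary are dichotomized
    first; missing values are dropped (complete-case per variable) and their
    count recorded on the returned table.
    """
    if variable not in cohort.columns:
        raise CohortError("unknown-variable", f"no column {variable!r}")
    if "shape_label" not in cohort.columns:
        raise CohortError("unknown-variable", "cohort lacks shape_label")
    cp = dict(CUT_POINTS)
    if cut_points:
        cp.update(cut_points)
    col = cohort[variable]
    if variable in cp:
        col, default_levels = _dichotomize(col, variable, cp)
    else:
        default_levels = sorted(pd.Series(col.dropna().unique()).astype(str))
    levels = level_order or default_levels
    shape = cohort["shape_label"]
    ok = col.notna() & shape.notna()
    n_dropped = int((~ok).sum())
    counts = np.zeros((len(levels), 2), dtype=int)
    for i, lev in enumerate(levels):
        for j, lab in enumerate(["L", "C"]):
            counts[i, j] = int(((col == lev) & (shape == lab) & ok).sum())
    table = ContingencyTable(counts, row_labels=list(levels),
                             n_dropped=n_dropped)
    return table


def odds_ratio(table: ContingencyTable,
               orientation: str = "row1-first") -> AssociationResult:
    """Cross-product odds ratio with a 95% Woolf (log) interval.

    With ``orientation="row2-first"`` the rows are swapped before the
    cross-product, making explicit which level is the reference.  Zero
    cells trigger the Haldane–Anscombe +0.5 adjustment (flagged).
    """
    if table.counts.shape != (2, 2):
        raise CohortError("bad-table", "odds ratio needs a 2x2 table")
    if orientation not in ("row1-first", "row2-first"):
        raise CohortError("bad-orientation", f"unknown orientation {orientation!r}")
    m = table.counts.astype(float)
    if orientation == "row2-first":
        m = m[::-1]
    if (m.sum(axis=1) == 0).any():
        raise CohortError("degenerate-table", "a row is all zero")
    adjusted = False
    if (m == 0).any():
        m = m + 0.5
        adjusted = True
    a, b = m[0]
    c, d = m[1]
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    chi2, p = chi_square(table, correction=False)
    return AssociationResult(or_estimate=float(or_), ci_low=float(lo),
                             ci_high=float(hi), chi2=chi2, p=p,
                             orientation=orientation,
                             zero_cell_adjusted=adjusted)


def chi_square(table: ContingencyTable, correction: bool = False
               ) -> tuple[float, float]:
    """Pearson chi-square with optional Yates correction; two-tailed p."""
    counts = table.counts
    expected = stats.contingency.expected_freq(counts)
    if (expected == 0).any():
        raise CohortError("zero-expected", "a cell has zero expected count")
    res = stats.chi2_contingency(counts, correction=correction)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# collinearity screen
# --------------------------------------------------------------------------

def spearman_screen(cohort: pd.DataFrame, covariates: list[str]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and two-tailed p over complete cases per pair.

    Constant covariates give undefined rho, reported as NaN.
    """
    k = len(covariates)
    rho = pd.DataFrame(np.eye(k), index=covariates, columns=covariates)
    pmat = pd.DataFrame(np.zeros((k, k)), index=covariates, columns=covariates)
    for i in range(k):
        for j in range(i + 1, k):
            pair = cohort[[covariates[i], covariates[j]]].apply(
                pd.to_numeric, errors="coerce").dropna()
            if len(pair) < 3 or pair.iloc[:, 0].nunique() < 2 \
                    or pair.iloc[:, 1].nunique() < 2:
                r = p = np.nan
            else:
                r, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return rho, pmat


def _vif_one(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_screen(cohort: pd.DataFrame, covariates: list[str],
               rho_limit: float = 0.7, p_limit: float = 0.05,
               vif_limit: float = 10.0) -> ScreenResult:
    """Collinearity screen: exclude covariates that are simultaneously
    highly correlated (|rho| > 0.7 with p < 0.05) and inflated (VIF > 10).

    When a correlated pair triggers, the member with the larger VIF is
    dropped (ties broken toward the later covariate in declared order), and
    VIFs are re-evaluated among the survivors.
    """
    data = cohort[covariates].apply(pd.to_numeric, errors="coerce").dropna()
    if len(data) <= len(covariates):
        raise CohortError("bad-design", "need more complete rows than covariates")
    rho, pmat = spearman_screen(data, covariates)
    active = list(covariates)
    excluded: dict[str, str] = {}

    def vifs(names: list[str]) -> pd.Series:
        X = data[names].to_numpy(float)
        return pd.Series([_vif_one(X, j) for j in range(len(names))],
                         index=names)

    while True:
        v = vifs(active)
        trigger = None
        for i, a in enumerate(active):
            for bname in active[i + 1:]:
                r = rho.loc[a, bname]
                p = pmat.loc[a, bname]
                if (np.isfinite(r) and abs(r) > rho_limit and p < p_limit
                        and (v[a] > vif_limit or v[bname] > vif_limit)):
                    if v[bname] >= v[a]:
                        drop, keep = bname, a
                    else:
                        drop, keep = a, bname
                    trigger = (drop, f"|rho|={abs(r):.3f} with {keep}, "
                                     f"VIF={v[drop]:.1f}")
                    break
            if trigger:
                break
        if trigger is None:
            break
        active.remove(trigger[0])
        excluded[trigger[0]] = trigger[1]
        if len(active) < 2:
            break
    final_v = vifs(active) if len(active) >= 1 else pd.Series(dtype=float)
    return ScreenResult(rho=rho, rho_p=pmat, vif=final_v, excluded=excluded)


# --------------------------------------------------------------------------
# the published association surface
# --------------------------------------------------------------------------

def association_table(cohort: pd.DataFrame,
                      variables: list[str] | None = None,
                      cut_points: dict[str, float] | None = None
                      ) -> pd.DataFrame:
    """Univariate association of each variable with the shape label.

    One row per variable: level order, per-shape counts, chi-square p,
    cross-product OR with the Woolf CI.  Orientation per variable follows
    the declared reference coding of the published table where the variable
    is known there, otherwise row1-first.
    """
    if variables is None:
        variables = [v for v in PUBLISHED_MARGINS
                     if _resolve_column(cohort, v) is not None]
    rows = []
    for var in variables:
        col = _resolve_column(cohort, var)
        if col is None:
            continue
        meta = PUBLISHED_MARGINS.get(var, {})
        cp = dict(CUT_POINTS)
        if cut_points:
            cp.update(cut_points)
        # dichotomized columns generate their own "<=cut/>cut" labels
        level_order = None if col in cp else meta.get("levels")
        table = build_contingency(cohort, col, level_order=level_order,
                                  cut_points=cut_points)
        orientation = meta.get("orientation", "row1-first")
        res = odds_ratio(table, orientation=orientation)
        rows.append({
            "variable": var,
            "levels": "/".join(table.row_labels),
            "n_L": int(table.counts[:, 0].sum()),
            "n_C": int(table.counts[:, 1].sum()),
            "count_11": int(table.counts[0, 0]),
            "count_12": int(table.counts[0, 1]),
            "count_21": int(table.counts[1, 0]),
            "count_22": int(table.counts[1, 1]),
            "or": res.or_estimate,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p": res.p,
            "orientation": res.orientation,
            "n_dropped": table.n_dropped,
        })
    return pd.DataFrame(rows)


_COLUMN_FOR_VARIABLE = {
    "age": "age", "gender": "gender", "side": "side", "volume": "volume",
    "histology": "histology", "who_grade": "who_grade", "idh1": "idh1",
    "chr1p19q": "chr1p19q", "idh1_with_1p19q": "idh1_with_1p19q",
    "atrx": "atrx", "mgmt": "mgmt", "tp53": "tp53", "ki67": "ki67_index",
    "epilepsy": "epilepsy",
}


def _resolve_column(cohort: pd.DataFrame, variable: str) -> str | None:
    col = _COLUMN_FOR_VARIABLE.get(variable, variable)
    return col if col in cohort.columns else None
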