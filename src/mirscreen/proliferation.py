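"""Proliferation grouping, activator/repressor correlation, and SVM prediction.

miRNAs are binned into a *high* proliferation group (relative cell-number
change > 5% of control) and a *low* group (the lowest decile).  Protein
activators and repressors of proliferation are called by the sign of the
Pearson correlation between each protein's response column and the
cell-number change.  A linear soft-margin SVM predicts the group from
the protein profile, validated by leave-one-out cross-validation with
per-fold standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .screens import ProliferationTable, ScreenMatrix

__all__ = [
    "SVMReport",
    "CorrelationReport",
    "bin_proliferation",
    "correlate_proliferation",
    "svm_loocv",
    "no_change_fraction",
]


@dataclass
class SVMReport:
    """LOOCV confusion matrix (predicted x true over {low, high}) and weights."""

    confusion: np.ndarray            # rows: predicted, cols: true; order low, high
    loocv_accuracy: float
    weights: pd.Series               # per-protein weight of the final linear model
    classes: tuple[str, str] = ("low", "high")

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())


@dataclass
class CorrelationReport:
    """Per-protein Pearson r with proliferation and activator/repressor class."""

    table: pd.DataFrame              # index protein; columns r, class
    r_threshold: float
    flagged: list[str] = field(default_factory=list)  # zero-variance proteins

    def activators(self) -> list[str]:
        return list(self.table.index[self.table["class"] == "activator"])

    def repressors(self) -> list[str]:
        return list(self.table.index[self.table["class"] == "repressor"])


def bin_proliferation(
    table: ProliferationTable,
    high_threshold: float = 0.05,
    low_quantile: float = 0.10,
) -> ProliferationTable:
    """Assign high / low / neither groups by the 5% and lowest-decile rules.

    ``high``: rel_change > high_threshold.  ``low``: rel_change within the
    empirical ``low_quantile`` quantile (linear interpolation; ties at the
    cutoff included).  The rules are applied independently; a miRNA
    satisfying both (possible only when the decile cutoff exceeds the
    high threshold) raises ``ValueError``.
    """
    rel = table.rel_change
    if len(rel) < 10:
        raise ValueError("need at least 10 miRNAs for a meaningful decile")
    cutoff = float(np.quantile(rel, low_quantile))
    high = rel > high_threshold
    low = rel <= cutoff
    both = high & low
    if both.any():
        bad = [table.mirna_ids[i] for i in np.flatnonzero(both)[:5]]
        raise ValueError(
            f"low-decile cutoff {cutoff:.4g} exceeds the high threshold "
            f"{high_threshold:.4g}; conflicting assignment for e.g. {bad}"
        )
    group = np.where(high, "high", np.where(low, "low", "neither")).astype(object)
    return ProliferationTable(list(table.mirna_ids), rel.copy(), group)


def correlate_proliferation(
    screen: ScreenMatrix,
    table: ProliferationTable,
    r_threshold: float = 0.3,
) -> CorrelationReport:
    """Pearson correlation of each protein with the cell-number change.

    ``activator``: r >= r_threshold; ``repressor``: r <= -r_threshold;
    else ``neither``.  Zero-variance proteins get r = NaN, class
    ``neither`` and are flagged.
    """
    common = [m for m in screen.mirna_ids if m in set(table.mirna_ids)]
    rel = table.to_frame().loc[common, "rel_change"].to_numpy()
    x = screen.subset(mirnas=common).values
    rel_c = rel - rel.mean()
    x_c = x - x.mean(axis=0)
    sx = np.sqrt((x_c**2).sum(axis=0))
    sy = np.sqrt((rel_c**2).sum())
    flagged = [p for p, s in zip(screen.protein_ids, sx) if s == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x_c.T @ rel_c) / (sx * sy)
    r[np.asarray(sx) == 0] = np.nan
    cls = np.full(len(r), "neither", dtype=object)
    cls[np.nan_to_num(r) >= r_threshold] = "activator"
    cls[np.nan_to_num(r) <= -r_threshold] = "repressor"
    df = pd.DataFrame({"r": r, "class": cls},
                      index=pd.Index(screen.protein_ids, name="protein"))
    return CorrelationReport(df, r_threshold, flagged)


def svm_loocv(
    screen: ScreenMatrix,
    table: ProliferationTable,
    C: float = 1.0,
) -> SVMReport:
    """Leave-one-out-validated linear SVM predicting low vs high proliferation.

    Only miRNAs grouped low or high are used.  Each fold standardizes
    features on its training set and transforms the held-out sample with
    the training statistics.  The confusion matrix aggregates the fold
    predictions; a final model on all grouped miRNAs provides the
    per-protein weight vector.
    """
    tf = table.to_frame()
    grouped = tf[tf["group"].isin(["low", "high"])]
    if (grouped["group"] == "low").sum() == 0 or (grouped["group"] == "high").sum() == 0:
        raise ValueError("both low and high groups must be non-empty")
    ids = [m for m in screen.mirna_ids if m in set(grouped.index)]
    x = screen.subset(mirnas=ids).values
    y = (grouped.loc[ids, "group"] == "high").astype(int).to_numpy()
    n = len(y)
    confusion = np.zeros((2, 2), dtype=int)  # [predicted, true], 0=low 1=high
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError(f"fold leaving out {ids[i]} has a single-class training set")
        scaler = StandardScaler().fit(x[mask])
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(x[mask]), y[mask])
        pred = int(clf.predict(scaler.transform(x[i][None, :]))[0])
        confusion[pred, y[i]] += 1
    acc = float(np.trace(confusion) / confusion.sum())
    scaler = StandardScaler().fit(x)
    final = SVC(kernel="linear", C=C).fit(scaler.transform(x), y)
    weights = pd.Series(final.coef_.ravel(), index=screen.protein_ids, name="weight")
    return SVMReport(confusion, acc, weights)


def no_change_fraction(table: ProliferationTable, band: float = 0.01) -> float:
    """Descriptive: fraction of miRNAs with |rel_change| below the band."""
    return float(np.mean(np.abs(table.rel_change) < band))
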