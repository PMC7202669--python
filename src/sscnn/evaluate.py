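"""Confusion-matrix analytics and label-proportion accuracy adjustment.

Overall accuracy is the number of correctly predicted labels divided by the
number of all assigned labels — equivalently the trace of the percent
confusion matrix.  The column-normalized matrix carries true positive rates
(recalls) on its diagonal and false negative rates elsewhere; the
row-normalized matrix carries positive predictive values (precisions) and
false discovery rates.

Because the per-label recalls differ, the overall accuracy of a predictor
depends on the label composition of the test set.  ``extrapolate_accuracy``
computes the accuracy a fixed set of recalls would yield on a set with given
label proportions, and ``adjust_to_reference`` re-weights one test set's
accuracy to another set's proportions so that accuracies on differently
composed sets become comparable.

Recalls derived from full-precision counts are exact; when a matrix is
entered from a one-decimal printed table, recalls recomputed from the
rounded entries can disagree with the printed recalls by a few tenths of a
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import AlphabetScheme, get_scheme

__all__ = [
    "ConfusionSummary",
    "RatesTable",
    "confusion",
    "confusion_from_percent",
    "rates",
    "extrapolate_accuracy",
    "adjust_to_reference",
    "skew_grid",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Raw counts (predicted rows x true columns) with derived marginals."""

    counts: np.ndarray
    letters: tuple

    def __post_init__(self) -> None:
        k = len(self.letters)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the alphabet")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def percent(self) -> np.ndarray:
        """Counts as percent of all assigned labels; sums to 100."""
        return self.counts / self.total * 100.0

    @property
    def true_freq(self) -> np.ndarray:
        """Column marginal: percent of true labels per class."""
        return self.percent.sum(axis=0)

    @property
    def pred_freq(self) -> np.ndarray:
        """Row marginal: percent of predicted labels per class."""
        return self.percent.sum(axis=1)

    @property
    def overall_accuracy(self) -> float:
        """Trace of the percent matrix (percent correct)."""
        return float(np.trace(self.percent))

    def true_fractions(self) -> dict:
        return dict(zip(self.letters, self.true_freq / 100.0))


@dataclass(frozen=True)
class RatesTable:
    """Per-label recall/precision and their off-diagonal complements.

    ``fnr`` is column-normalized (each column sums to 100 with the TPR on
    the diagonal); ``fdr`` is row-normalized likewise.  Labels absent from
    the true labels have undefined TPR (NaN), absent predictions undefined
    PPV — reported as missing, never as zero.
    """

    letters: tuple
    tpr: dict
    ppv: dict
    fnr: np.ndarray
    fdr: np.ndarray


def confusion(true_labels: str, pred_labels: str,
              scheme: AlphabetScheme | str) -> ConfusionSummary:
    """Count a confusion matrix over non-'X' positions.

    Positions whose *true* label is 'X' (no assigned secondary structure)
    are excluded entirely.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label strings differ in length")
    letters = scheme.letters
    index = {l: i for i, l in enumerate(letters)}
    counts = np.zeros((len(letters), len(letters)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        if t == "X":
            continue
        if t not in index:
            raise ValueError(f"true label {t!r} outside alphabet {letters}")
        if p not in index:
            raise ValueError(f"predicted label {p!r} outside alphabet {letters}")
        counts[index[p], index[t]] += 1
    return ConfusionSummary(counts=counts, letters=letters)


def confusion_from_percent(percent_matrix, letters) -> ConfusionSummary:
    """Wrap a percent matrix (e.g. entered from a printed table).

    The entries are treated as counts on a 0-100 scale; all derived
    quantities follow, with printed-precision caveats for the rates.
    """
    mat = np.asarray(percent_matrix, dtype=np.float64)
    return ConfusionSummary(counts=mat, letters=tuple(letters))


def rates(cm: ConfusionSummary) -> RatesTable:
    """Recall/precision tables from a confusion summary.

    TPR = diagonal / column sum, PPV = diagonal / row sum; the off-diagonal
    cells of the column- and row-normalized matrices are the FNRs and FDRs.
    """
    counts = cm.counts.astype(np.float64)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        colnorm = np.where(col > 0, counts / col * 100.0, np.nan)
        rownorm = np.where(row[:, None] > 0, counts / row[:, None] * 100.0, np.nan)
    tpr = {l: (float(colnorm[i, i]) if col[i] > 0 else None)
           for i, l in enumerate(cm.letters)}
    ppv = {l: (float(rownorm[i, i]) if row[i] > 0 else None)
           for i, l in enumerate(cm.letters)}
    return RatesTable(letters=cm.letters, tpr=tpr, ppv=ppv,
                      fnr=colnorm, fdr=rownorm)


def extrapolate_accuracy(recalls: dict, fractions: dict,
                         tol: float = 1e-6) -> float:
    """Accuracy on a set with the given label proportions.

    ``sum_l fraction_l * TPR_l`` — the overall accuracy a predictor with
    fixed per-label recalls attains on a test set with those label
    fractions.  Fractions must be non-negative and sum to 1.
    """
    total = float(sum(fractions.values()))
    if abs(total - 1.0) > max(tol, 1e-6):
        raise ValueError(f"fractions sum to {total}, expected 1")
    acc = 0.0
    for label, frac in fractions.items():
        if frac < 0:
            raise ValueError(f"negative fraction for label {label!r}")
        if frac == 0:
            continue
        r = recalls.get(label)
        if r is None:
            raise ValueError(f"recall undefined for label {label!r} "
                             f"with nonzero fraction")
        acc += frac * r
    return acc


def adjust_to_reference(cm: ConfusionSummary, reference_fractions: dict) -> float:
    """Accuracy of ``cm`` re-weighted to a reference label composition."""
    return extrapolate_accuracy(rates(cm).tpr, reference_fractions)


def skew_grid(recalls: dict, grid_step: float = 0.01) -> tuple:
    """Extrapolated accuracy over the (H%, E%) simplex for 3-label recalls.

    Returns ``(h_values, e_values, grid)`` where ``grid[i, j]`` is the
    accuracy at helix fraction ``h_values[i]`` and sheet fraction
    ``e_values[j]`` with coil taking the remainder; infeasible points
    (H + E > 1) are NaN.
    """
    required = {"H", "E", "C"}
    if set(recalls) != required:
        raise ValueError(f"3-label recalls required, got {sorted(recalls)}")
    hs = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    es = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    H, E = np.meshgrid(hs, es, indexing="ij")
    C = 1.0 - H - E
    grid = recalls["H"] * H + recalls["E"] * E + recalls["C"] * C
    grid[C < -1e-12] = np.nan
    return hs, es, grid
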