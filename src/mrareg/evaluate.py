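"""Evaluation of inferred networks against a reference.

Discretizes connectivity coefficients to signs, counts the six-way
confusion (true positive/negative/zero, false positive/negative/zero)
over the off-diagonal cells, and derives sensitivity, specificity,
squared error, ROC/AUROC and the distance of an operating point to the
chance diagonal.  The full 3x3 contingency (reference sign x predicted
sign) is kept internally so both the sign-aware counts and conventional
binary metrics come from a single tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import ConnectivityMatrix

__all__ = [
    "EvaluationReport",
    "discretize_sign",
    "confusion_and_sesp",
    "topx_threshold",
    "roc_curve",
    "auroc",
    "distance_to_diagonal",
    "evaluate_network",
]


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)


def discretize_sign(matrix, mode: str = "signed") -> np.ndarray:
    """Reduce coefficients to {-1, 0, 1} (``signed``) or {0, 1} (``binary``).

    ``signed`` takes the sign with sign(0) = 0; ``binary`` keeps only
    edge existence.  Idempotent.  The diagonal is returned as-is and
    ignored by all downstream counting.
    """
    v = _values(matrix)
    if not np.all(np.isfinite(v)):
        raise ValueError("matrix entries must be finite")
    if mode == "signed":
        return np.sign(v)
    if mode == "binary":
        return (v != 0).astype(float)
    raise ValueError("mode must be 'signed' or 'binary'")


@dataclass
class EvaluationReport:
    """Confusion counts and summary metrics over off-diagonal edges.

    ``t_plus/t_minus/t_zero`` count cells where prediction and reference
    agree on +1/-1/0; ``f_plus`` counts predicted +1 with reference
    != +1, and symmetrically for ``f_minus`` and ``f_zero``.
    ``p_nonzero`` and ``n_zero`` are the reference's nonzero and zero
    off-diagonal edge counts; Se = (T+ + T-)/P, Sp = T0/N.
    """

    t_plus: int
    t_minus: int
    t_zero: int
    f_plus: int
    f_minus: int
    f_zero: int
    p_nonzero: int
    n_zero: int
    se: float | None
    sp: float | None
    table: np.ndarray  # 3x3: rows reference in (-1,0,1), cols predicted
    squared_error: float | None = None
    auroc: float | None = None
    dist_diag: float | None = None


def confusion_and_sesp(reference, predicted) -> EvaluationReport:
    """Tabulate discretized predicted vs reference edges (diagonal excluded).

    Both inputs must already be discretized to {-1, 0, 1} (binary {0, 1}
    inputs work unchanged: the -1 row/column is then empty).
    """
    ref = _values(reference)
    pred = _values(predicted)
    if ref.shape != pred.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {pred.shape}")
    for name, m in (("reference", ref), ("predicted", pred)):
        if not np.isin(m[~np.eye(m.shape[0], dtype=bool)], (-1, 0, 1)).all():
            raise ValueError(f"{name} matrix is not discretized to -1/0/1")
    mask = ~np.eye(ref.shape[0], dtype=bool)
    r = ref[mask].astype(int)
    p = pred[mask].astype(int)
    table = np.zeros((3, 3), dtype=int)
    for rv, pv in zip(r, p):
        table[rv + 1, pv + 1] += 1
    t_minus, t_zero, t_plus = table[0, 0], table[1, 1], table[2, 2]
    f_minus = int(table[:, 0].sum() - table[0, 0])
    f_zero = int(table[:, 1].sum() - table[1, 1])
    f_plus = int(table[:, 2].sum() - table[2, 2])
    p_nonzero = int((r != 0).sum())
    n_zero = int((r == 0).sum())
    se = (t_plus + t_minus) / p_nonzero if p_nonzero else None
    sp = t_zero / n_zero if n_zero else None
    return EvaluationReport(
        int(t_plus), int(t_minus), int(t_zero),
        f_plus, f_minus, f_zero, p_nonzero, n_zero, se, sp, table,
    )


def topx_threshold(matrix, x_percent: float) -> ConnectivityMatrix | np.ndarray:
    """Keep the top x% off-diagonal coefficients by magnitude, zero the rest.

    The threshold is the smallest magnitude among the top
    ceil(x% * N(N-1)) entries; entries strictly below it are zeroed, so
    ties at the threshold all survive.  The diagonal is untouched.
    """
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must lie in (0, 100]")
    v = _values(matrix).copy()
    mask = ~np.eye(v.shape[0], dtype=bool)
    mags = np.abs(v[mask])
    k = int(np.ceil(x_percent * mags.size / 100.0))
    thresh = np.sort(mags)[::-1][k - 1]
    v[mask & (np.abs(v) < thresh)] = 0.0
    if isinstance(matrix, ConnectivityMatrix):
        return ConnectivityMatrix(v, list(matrix.node_names), matrix.exact)
    return v


def _offdiag_scores(reference, scores):
    ref = _values(reference)
    s = _values(scores)
    if ref.shape != s.shape:
        raise ValueError("shape mismatch between reference and scores")
    mask = ~np.eye(ref.shape[0], dtype=bool)
    y = (ref[mask] != 0).astype(int)
    return y, np.abs(s[mask])


def roc_curve(reference, scores):
    """ROC over off-diagonal edges, scoring by coefficient magnitude.

    Returns ``(fpr, tpr, thresholds, auroc)``.  The area is computed by
    the trapezoid rule over the threshold sweep, which equals the
    mid-rank Mann-Whitney statistic.
    """
    y, s = _offdiag_scores(reference, scores)
    if y.min() == y.max():
        raise ValueError("reference edges are all-zero or all-nonzero: AUROC undefined")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, area


def auroc(reference, scores) -> float:
    """Area under the ROC curve (see :func:`roc_curve`)."""
    return roc_curve(reference, scores)[3]


def distance_to_diagonal(se: float, sp: float) -> float:
    """Signed perpendicular distance of (1-sp, se) to the chance diagonal.

    (se + sp - 1)/sqrt(2): 1/sqrt(2) for a perfect classifier, 0 on the
    random-selection line, negative when worse than random.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("se and sp must lie in [0, 1]")
    return (se + sp - 1.0) / np.sqrt(2.0)


def evaluate_network(
    reference: ConnectivityMatrix,
    estimate,
    mode: str = "signed",
    scores=None,
) -> EvaluationReport:
    """One-stop evaluation of an estimated network against the reference.

    Discretizes both matrices (``mode``), tabulates the confusion
    counts, and adds the exact squared error, the distance to the
    chance diagonal, and - when the reference has both null and
    non-null edges - the AUROC computed from ``scores`` (pre-selection
    magnitudes when given, else the estimate itself).
    """
    est_values = _values(estimate)
    report = confusion_and_sesp(
        discretize_sign(reference, mode), discretize_sign(est_values, mode)
    )
    report.squared_error = float(
        np.sum((_values(reference) - est_values) ** 2)
    )
    if report.se is not None and report.sp is not None:
        report.dist_diag = distance_to_diagonal(report.se, report.sp)
    score_matrix = est_values if scores is None else _values(scores)
    try:
        report.auroc = auroc(reference, score_matrix)
    except ValueError:
        report.auroc = None
    return report
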