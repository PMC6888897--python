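"""Derive an up/down gene signature from a two-group experiment by fold change.

The signature is the set of genes whose knockdown-vs-control log2 fold
change passes a fold cutoff (default 2-fold, boundary inclusive): genes with
log2FC >= log2(cutoff) go in the ``up`` list, genes with
log2FC <= -log2(cutoff) in ``down``. Fold changes are computed on group
means — the difference of means on the log2 scale, or the log2 ratio of
means on the linear scale (genes with a non-positive group mean are excluded
and logged, since their ratio is undefined).

No significance filter is applied by default; an optional Welch t-test with
Benjamini–Hochberg correction (:func:`ttest_qvalues`) can be combined with
the fold cutoff via ``build_signature(..., qvalues=..., q_max=...)``.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, ValidationError
from .io_formats import ExpressionMatrix, Signature

logger = logging.getLogger(__name__)

__all__ = ["Signature", "fold_changes", "ttest_qvalues", "build_signature"]

_CTRL_ALIASES = {"ctrl", "control"}


def _split_groups(
    expr: ExpressionMatrix,
    groups: Mapping[str, str],
    case: str | None,
    ctrl: str | None,
) -> tuple[list[str], list[str]]:
    """Resolve the (case samples, ctrl samples) partition from a label map."""
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ParameterError(f"expected exactly 2 group labels, got {labels}")
    if ctrl is None and case is None:
        recognized = [l for l in labels if l.lower() in _CTRL_ALIASES]
        if len(recognized) != 1:
            raise ParameterError(
                f"cannot infer control group from labels {labels}; pass case=/ctrl="
            )
        ctrl = recognized[0]
    if ctrl is None:
        ctrl = next(l for l in labels if l != case)
    if case is None:
        case = next(l for l in labels if l != ctrl)
    if {case, ctrl} != set(labels):
        raise ParameterError(f"case={case!r}/ctrl={ctrl!r} do not match labels {labels}")

    missing = [s for s in groups if s not in expr.data.columns]
    if missing:
        raise ParameterError(f"labeled samples absent from matrix: {missing[:10]}")
    case_samples = [s for s in expr.sample_ids if groups.get(s) == case]
    ctrl_samples = [s for s in expr.sample_ids if groups.get(s) == ctrl]
    if not case_samples or not ctrl_samples:
        raise ParameterError("each group needs at least one sample")
    return case_samples, ctrl_samples


def fold_changes(
    expr: ExpressionMatrix,
    groups: Mapping[str, str],
    case: str | None = None,
    ctrl: str | None = None,
) -> pd.Series:
    """Per-gene log2 fold change (case minus control) on group means.

    On the log2 scale this is ``mean(case) - mean(ctrl)``; on the linear
    scale ``log2(mean(case) / mean(ctrl))``, excluding (and logging) genes
    where either group mean is <= 0.
    """
    case_samples, ctrl_samples = _split_groups(expr, groups, case, ctrl)
    mean_case = expr.data[case_samples].mean(axis=1)
    mean_ctrl = expr.data[ctrl_samples].mean(axis=1)
    if expr.scale == "log2":
        return (mean_case - mean_ctrl).rename("log2fc")
    ok = (mean_case > 0) & (mean_ctrl > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("excluded %d genes with non-positive group means", n_bad)
    return np.log2(mean_case[ok] / mean_ctrl[ok]).rename("log2fc")


def ttest_qvalues(
    expr: ExpressionMatrix,
    groups: Mapping[str, str],
    case: str | None = None,
    ctrl: str | None = None,
) -> pd.Series:
    """Welch two-sample t-test per gene with Benjamini–Hochberg correction."""
    case_samples, ctrl_samples = _split_groups(expr, groups, case, ctrl)
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ParameterError("t-test needs >=2 samples per group")
    a = expr.data[case_samples].to_numpy()
    b = expr.data[ctrl_samples].to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(res.pvalue, nan=1.0)  # zero-variance genes: no evidence
    q = stats.false_discovery_control(p, method="bh")
    return pd.Series(q, index=expr.data.index, name="qvalue")


def build_signature(
    fc: pd.Series,
    cutoff_fold: float = 2.0,
    qvalues: pd.Series | None = None,
    q_max: float = 0.05,
    meta: dict | None = None,
) -> Signature:
    """Select signature genes by a symmetric fold-change cutoff.

    The boundary is inclusive: a gene at exactly ``cutoff_fold``-fold change
    is admitted. When ``qvalues`` is given, genes must additionally satisfy
    ``q <= q_max``. Raises if no gene passes in either direction.
    """
    if cutoff_fold <= 1:
        raise ParameterError("cutoff_fold must be > 1")
    thr = float(np.log2(cutoff_fold))
    keep_up = fc >= thr
    keep_down = fc <= -thr
    if qvalues is not None:
        sig_mask = qvalues.reindex(fc.index).fillna(1.0) <= q_max
        keep_up &= sig_mask
        keep_down &= sig_mask
    up = list(fc.index[keep_up])
    down = list(fc.index[keep_down])
    if not up and not down:
        raise ValidationError(f"no signature genes at this cutoff ({cutoff_fold}-fold)")
    info = {
        "cutoff_fold": cutoff_fold,
        "n_genes_tested": int(len(fc)),
        "q_filtered": qvalues is not None,
    }
    if meta:
        info.update(meta)
    return Signature(up=up, down=down, meta=info)
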