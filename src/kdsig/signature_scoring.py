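"""Per-sample knockdown (KD) scores and score-based stratification.

Each gene is z-scored across the cohort being scored (sample standard
deviation, n-1 denominator), so every retained gene row has mean 0 and unit
SD. The KD score of a sample is then

    kd_score = sum of z over signature up-genes - sum of z over down-genes

A high KD score means the sample's transcriptome resembles the knockdown
state. Signature genes absent from the matrix are skipped and reported;
the sums are not divided by list length (a length-normalized variant is
available via ``normalized=True``).

Stratification splits samples into low/high (or low/mid/high) groups by
median, tertiles, or a fixed cutoff; ties go to the low group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, StratificationError, ValidationError
from .io_formats import ExpressionMatrix, Signature

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-sample KD scores plus bookkeeping of signature coverage."""

    scores: pd.Series  # index: sample_id, values: kd_score
    n_up_used: int
    n_down_used: int
    missing_up: list[str] = field(default_factory=list)
    missing_down: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_up_used + self.n_down_used < 1:
            raise ValidationError("no signature genes were used")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.scores.index,
                "kd_score": self.scores.to_numpy(),
                "n_up_used": self.n_up_used,
                "n_down_used": self.n_down_used,
            }
        )

    def __len__(self) -> int:
        return len(self.scores)


def zscore_by_gene(expr: ExpressionMatrix) -> pd.DataFrame:
    """Z-score each gene across samples (ddof=1); drop zero-variance genes.

    The cohort being scored is its own reference population, so every
    retained row sums to zero exactly (up to float round-off).
    """
    if expr.shape[1] < 2:
        raise ValidationError("z-score undefined for a single-sample matrix")
    sd = expr.data.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("dropped %d zero-variance genes before z-scoring", int(flat.sum()))
    data = expr.data.loc[~flat]
    return data.sub(data.mean(axis=1), axis=0).div(sd[~flat], axis=0)


def kd_score(
    z: pd.DataFrame, signature: Signature, normalized: bool = False
) -> ScoreTable:
    """Knockdown score per sample from a z-matrix and a signature.

    ``sum(z[up]) - sum(z[down])`` per sample; with ``normalized=True`` each
    sum is replaced by the mean over the genes actually present, making
    scores comparable across signatures of different size.
    """
    up_present = [g for g in signature.up if g in z.index]
    down_present = [g for g in signature.down if g in z.index]
    missing_up = [g for g in signature.up if g not in z.index]
    missing_down = [g for g in signature.down if g not in z.index]
    if not up_present and not down_present:
        raise ValidationError(
            f"no signature genes present in matrix; missing: "
            f"{(missing_up + missing_down)[:20]}"
        )
    if missing_up or missing_down:
        logger.warning(
            "signature genes missing from matrix: %d up, %d down",
            len(missing_up),
            len(missing_down),
        )
    up_part = z.loc[up_present].sum(axis=0) if up_present else 0.0
    down_part = z.loc[down_present].sum(axis=0) if down_present else 0.0
    if normalized:
        if up_present:
            up_part = up_part / len(up_present)
        if down_present:
            down_part = down_part / len(down_present)
    scores = (up_part - down_part).rename("kd_score")
    if np.isscalar(scores):  # both parts scalar cannot happen (validated above)
        raise ValidationError("no signature genes present")
    return ScoreTable(
        scores=scores,
        n_up_used=len(up_present),
        n_down_used=len(down_present),
        missing_up=missing_up,
        missing_down=missing_down,
        meta={"normalized": normalized},
    )


def stratify(
    scores: ScoreTable | pd.Series,
    rule: str = "median",
    cutoff: float | None = None,
) -> pd.Series:
    """Assign each sample a group label from its score.

    rule="median": low = score <= median (ties low), high otherwise;
    rule="tertiles": low/mid/high by the 1/3 and 2/3 quantiles (ties to the
    lower group); rule="fixed": low = score <= ``cutoff``. Median and fixed
    rules require at least 2 samples per resulting group.
    """
    s = scores.scores if isinstance(scores, ScoreTable) else pd.Series(scores)
    if s.nunique() <= 1:
        raise StratificationError("all scores identical; cannot stratify")
    if rule == "median":
        thr = float(np.median(s.to_numpy()))
        labels = pd.Series(np.where(s <= thr, "low", "high"), index=s.index, name="group")
        _require_group_sizes(labels, ("low", "high"), 2)
    elif rule == "tertiles":
        q1, q2 = np.quantile(s.to_numpy(), [1 / 3, 2 / 3])
        lab = np.where(s <= q1, "low", np.where(s <= q2, "mid", "high"))
        labels = pd.Series(lab, index=s.index, name="group")
    elif rule == "fixed":
        if cutoff is None:
            raise ParameterError("rule='fixed' requires a cutoff")
        labels = pd.Series(
            np.where(s <= cutoff, "low", "high"), index=s.index, name="group"
        )
        _require_group_sizes(labels, ("low", "high"), 2)
    else:
        raise ParameterError(f"unknown stratification rule {rule!r}")
    return labels


def _require_group_sizes(labels: pd.Series, expected: tuple[str, ...], min_n: int) -> None:
    counts = labels.value_counts()
    for g in expected:
        if counts.get(g, 0) < min_n:
            raise StratificationError(
                f"group {g!r} has {counts.get(g, 0)} samples (< {min_n})"
            )
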