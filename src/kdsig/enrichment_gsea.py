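"""Preranked gene set enrichment analysis (GSEA), implemented natively.

Genes are ranked by a differential metric (signal-to-noise, Welch t, or
Pearson correlation against a continuous covariate), best to worst, with
deterministic lexicographic tie-breaking. For a gene set the weighted
Kolmogorov–Smirnov-like running sum increments by ``|metric|^p`` (normalized
over the set's hits) at each member gene and decrements by ``1/(N - N_hits)``
at each non-member; the enrichment score (ES) is the signed
maximum-magnitude deviation of this walk, which always returns to 0.

The null distribution reassigns set membership uniformly at random among the
ranked genes (gene permutation — appropriate for preranked input and small
cohorts, unlike class-label permutation). The normalized enrichment score
(NES) divides ES by the mean magnitude of same-sign null scores, and the
nominal p-value is the add-one-corrected fraction of same-sign null scores
at least as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, ValidationError
from .io_formats import ExpressionMatrix, GeneSetCollection

_SD_FLOOR_FRAC = 0.2  # signal-to-noise SD floor, as in classic GSEA
_SD_FLOOR_ABS = 0.2


@dataclass
class RankedList:
    """Genes ordered best-to-worst with their (non-increasing) metric values."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValidationError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValidationError("metric must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    es: float
    running_sum: np.ndarray
    hit_positions: np.ndarray
    nes: float = np.nan
    p_nominal: float | None = None
    n_perm: int = 0
    sign_underflow: bool = False  # no same-sign null scores were observed
    set_name: str = ""
    set_size: int = 0


def rank_genes(
    expr: ExpressionMatrix,
    labels: Mapping[str, str] | pd.Series,
    metric: str = "signal2noise",
    case: str | None = None,
) -> RankedList:
    """Rank genes by a per-gene association metric, descending.

    For two-group metrics (``signal2noise``, ``t_stat``) ``labels`` maps
    sample to one of two group labels; the metric is case minus control
    where ``case`` defaults to the lexicographically greater label. For
    ``pearson``, ``labels`` is a numeric per-sample covariate and the metric
    is the Pearson correlation of each gene with it. Ties in the metric are
    broken by gene id (lexicographic) so rankings are deterministic.
    """
    if metric in ("signal2noise", "t_stat"):
        lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
        lab = lab.reindex(expr.data.columns).dropna().astype(str)
        groups = sorted(lab.unique())
        if len(groups) != 2:
            raise ParameterError(f"two-group metric needs exactly 2 labels, got {groups}")
        if case is None:
            case = groups[1]
        ctrl = groups[0] if case == groups[1] else groups[1]
        a_cols = lab.index[lab == case]
        b_cols = lab.index[lab == ctrl]
        if len(a_cols) < 3 or len(b_cols) < 3:
            raise ParameterError("two-group metrics need >=3 samples per group")
        a = expr.data[a_cols].to_numpy()
        b = expr.data[b_cols].to_numpy()
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        if metric == "signal2noise":
            sa = _floored_sd(a.std(axis=1, ddof=1), ma)
            sb = _floored_sd(b.std(axis=1, ddof=1), mb)
            values = (ma - mb) / (sa + sb)
        else:
            va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
            denom = np.sqrt(va / a.shape[1] + vb / b.shape[1])
            values = (ma - mb) / np.maximum(denom, 1e-12)
    elif metric == "pearson":
        cov = pd.Series(labels, dtype=float).reindex(expr.data.columns)
        if cov.isna().any():
            raise ParameterError("pearson metric needs a numeric value for every sample")
        x = expr.data.to_numpy()
        y = cov.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
        values = (xc @ yc) / np.maximum(denom, 1e-300)
    else:
        raise ParameterError(f"unknown ranking metric {metric!r}")

    order = (
        pd.DataFrame({"gene": expr.data.index, "metric": values})
        .sort_values(["metric", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return RankedList(genes=order["gene"].tolist(), metric=order["metric"].to_numpy())


def _floored_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Floor each group SD at max(0.2 * |mean|, 0.2) to stabilize the ratio."""
    floor = np.maximum(_SD_FLOOR_FRAC * np.abs(mean), _SD_FLOOR_ABS)
    return np.maximum(sd, floor)


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0
) -> EnrichmentResult:
    """Weighted KS-like enrichment score and full running sum for one set."""
    index = {g: i for i, g in enumerate(ranked.genes)}
    hits = np.array(sorted(index[g] for g in set(gene_set) if g in index), dtype=int)
    n = len(ranked)
    if hits.size == 0:
        raise ValidationError("gene set has no overlap with the ranked list")
    if hits.size == n:
        raise ValidationError("gene set covers the entire ranked list")

    steps = np.full(n, -1.0 / (n - hits.size))
    w = np.abs(ranked.metric[hits]) ** weight
    total = w.sum()
    if total == 0:  # all hit metrics zero: fall back to unweighted increments
        w = np.ones_like(w)
        total = w.sum()
    steps[hits] = w / total
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return EnrichmentResult(
        es=es,
        running_sum=running,
        hit_positions=hits,
        set_size=int(hits.size),
    )


def _null_es(
    abs_metric_p: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES from random same-size membership, vectorized over permutations.

    Between consecutive hits the running sum decreases linearly, so the
    extremum occurs immediately before or at a hit; only those 2k candidate
    values are evaluated per permutation.
    """
    n = abs_metric_p.size
    dec = 1.0 / (n - k)
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(4e6 / max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m x k sorted random hit positions
        pos = np.argsort(rng.random((m, n)), axis=1, kind="quicksort")[:, :k]
        pos.sort(axis=1)
        w = abs_metric_p[pos]
        tot = w.sum(axis=1, keepdims=True)
        flat = tot[:, 0] == 0
        if flat.any():  # all-zero weights: unweighted walk
            w[flat] = 1.0
            tot[flat] = k
        cw = np.cumsum(w, axis=1) / tot
        j = np.arange(k)
        drop = (pos - j) * dec  # miss decrements accumulated before hit j
        after = cw - drop
        before = np.concatenate([np.zeros((m, 1)), cw[:, :-1]], axis=1) - drop
        cand = np.concatenate([after, before], axis=1)
        idx = np.argmax(np.abs(cand), axis=1)
        out[done : done + m] = cand[np.arange(m), idx]
        done += m
    return out


def gsea(
    ranked: RankedList,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> dict[str, EnrichmentResult]:
    """Run preranked GSEA for every set; returns per-set results with NES and p.

    The null reassigns set membership uniformly at random (same set size)
    among the ranked genes. NES = ES / mean(|null ES| of matching sign);
    p_nominal = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign
    null). When no null score shares the observed sign, p is reported as
    1/(1 + n_perm) with ``sign_underflow`` set.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    if isinstance(sets, GeneSetCollection):
        items = [(gs.name, gs.genes) for gs in sets]
    else:
        items = list(sets.items())
    rng = np.random.default_rng([505, int(seed)])
    abs_p = np.abs(ranked.metric) ** weight

    results: dict[str, EnrichmentResult] = {}
    null_cache: dict[int, np.ndarray] = {}
    for name, genes in items:
        res = enrichment_score(ranked, genes, weight=weight)
        k = res.set_size
        if k not in null_cache:
            null_cache[k] = _null_es(abs_p, k, n_perm, rng)
        null = null_cache[k]
        same_sign = null >= 0 if res.es >= 0 else null < 0
        null_ss = null[same_sign]
        if null_ss.size == 0:
            res.nes = np.nan
            res.p_nominal = 1.0 / (1 + n_perm)
            res.sign_underflow = True
        else:
            res.nes = float(res.es / np.mean(np.abs(null_ss)))
            extreme = np.abs(null_ss) >= abs(res.es)
            res.p_nominal = float((1 + int(extreme.sum())) / (1 + null_ss.size))
        res.n_perm = n_perm
        res.set_name = name
        results[name] = res
    return results


def results_table(results: Mapping[str, EnrichmentResult]) -> pd.DataFrame:
    """Flatten GSEA results into a tidy table sorted by p then |NES|."""
    rows = [
        {
            "set": r.set_name,
            "size": r.set_size,
            "es": r.es,
            "nes": r.nes,
            "p_nominal": r.p_nominal,
            "sign_underflow": r.sign_underflow,
        }
        for r in results.values()
    ]
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["p_nominal", "nes"], key=abs, ascending=[True, False])
        df = df.reset_index(drop=True)
    return df
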