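"""Synthetic discovery experiments and patient cohorts with known ground truth.

Three generators emulate the statistical structure the downstream analysis
assumes, so that every stage (signature derivation, scoring, stratification,
survival testing, enrichment) can be exercised offline against planted truth:

``make_discovery``
    A two-condition knockdown-vs-control experiment on the log2 scale.
    Non-differential genes fluctuate around gene-specific baselines with
    Gaussian noise; a planted subset is shifted by ±``effect_log2fc`` in the
    knockdown group. Default planted counts are 84 up and 73 down.

``make_cohort``
    A patient cohort whose hazard depends on a latent signature activity
    *a* ~ N(0, 1). Signature up-genes gain a mean shift ``+a * effect`` and
    down-genes ``-a * effect``, so a high-activity patient resembles the
    knockdown state. Survival is exponential with hazard
    ``baseline_hazard * exp(-beta * a)`` — high activity means a high
    knockdown score and a *lower* hazard — with independent exponential
    censoring.

``make_marker_panel``
    Linear-scale VIM/CDH1 expression for epithelial, EMT-intermediate and
    mesenchymal cell lines: epithelial lines have VIM/CDH1 ratios well below
    2, mesenchymal well above 2, intermediates near the boundary.

All generators are pure functions of their parameters and a single integer
seed; each operation owns a named, independent random stream derived from
that seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io_formats import ClinicalTable, ExpressionMatrix, Signature

# per-operation stream keys so generators never share state
_STREAMS = {"discovery": 101, "cohort": 202, "markers": 303}

#: VIM/CDH1 ratio band within which generated panels place intermediate lines
DEFAULT_INTERMEDIATE_BAND = (1.5, 2.5)

_BASELINE_LO, _BASELINE_HI = 3.0, 12.0  # log2 baseline expression range


@dataclass
class DiscoveryTruth:
    """Ground truth of a planted two-condition experiment."""

    up_genes: list[str]
    down_genes: list[str]
    effect_log2fc: float
    sigma: float


@dataclass
class CohortTruth:
    """Ground truth of a simulated expression–survival cohort."""

    activity: pd.Series  # latent signature activity per patient
    beta: float  # hazard log-effect per unit activity
    baseline_hazard: float
    censor_rate: float
    effect: float  # expression shift per unit activity


def _rng(stream: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


def make_discovery(
    n_genes: int = 1000,
    n_ctrl: int = 5,
    n_kd: int = 5,
    n_up: int = 84,
    n_down: int = 73,
    effect_log2fc: float = 1.5,
    sigma: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, str], DiscoveryTruth]:
    """Simulate a knockdown-vs-control discovery experiment on the log2 scale.

    Returns the expression matrix, a sample -> {"ctrl", "kd"} mapping, and
    the planted truth. Reproducible bit-for-bit from ``seed``.
    """
    if n_up + n_down > n_genes:
        raise ParameterError(f"n_up + n_down = {n_up + n_down} exceeds n_genes = {n_genes}")
    if n_ctrl < 2 or n_kd < 2:
        raise ParameterError("need at least 2 samples per group")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if effect_log2fc < 0:
        raise ParameterError("effect_log2fc must be >= 0")

    rng = _rng("discovery", seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"ctrl_{i + 1}" for i in range(n_ctrl)] + [f"kd_{i + 1}" for i in range(n_kd)]

    baseline = rng.uniform(_BASELINE_LO, _BASELINE_HI, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_ctrl + n_kd))

    planted = rng.choice(n_genes, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]
    values[np.ix_(up_idx, range(n_ctrl, n_ctrl + n_kd))] += effect_log2fc
    values[np.ix_(down_idx, range(n_ctrl, n_ctrl + n_kd))] -= effect_log2fc

    expr = ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples), scale="log2"
    )
    groups = {s: ("ctrl" if s.startswith("ctrl") else "kd") for s in samples}
    truth = DiscoveryTruth(
        up_genes=[genes[i] for i in up_idx],
        down_genes=[genes[i] for i in down_idx],
        effect_log2fc=effect_log2fc,
        sigma=sigma,
    )
    return expr, groups, truth


def make_cohort(
    signature: Signature,
    n_patients: int = 200,
    beta: float = 1.0,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.01,
    sigma: float = 0.3,
    effect: float = 1.0,
    n_background: int = 100,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Simulate an expression–survival cohort driven by latent signature activity.

    Each patient draws activity ``a ~ N(0, 1)``. Signature up-genes are
    shifted by ``+a * effect`` (down-genes by ``-a * effect``) on the log2
    scale on top of gene baselines and N(0, sigma) noise; ``n_background``
    unrelated genes carry noise only. Event times are exponential with
    hazard ``baseline_hazard * exp(-beta * a)``; censoring is an independent
    exponential with rate ``censor_rate`` (0 disables censoring). Times are
    in months. Censoring uses inverse-transform draws on a dedicated uniform
    stream, so the censored fraction is pathwise monotone in ``censor_rate``
    at fixed seed.
    """
    if baseline_hazard <= 0:
        raise ParameterError("baseline_hazard must be > 0")
    if censor_rate < 0:
        raise ParameterError("censor_rate must be >= 0")
    if n_patients < 2:
        raise ParameterError("need at least 2 patients")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")

    rng = _rng("cohort", seed)
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    sig_genes = list(signature.up) + list(signature.down)
    bg_genes = [f"BG{i:04d}" for i in range(n_background)]
    genes = sig_genes + bg_genes

    activity = rng.standard_normal(n_patients)
    baseline = rng.uniform(_BASELINE_LO, _BASELINE_HI, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, sigma, size=(len(genes), n_patients))
    n_up = len(signature.up)
    values[:n_up, :] += effect * activity[None, :]
    values[n_up : len(sig_genes), :] -= effect * activity[None, :]

    hazard = baseline_hazard * np.exp(-beta * activity)
    u_event = rng.random(n_patients)
    t_event = -np.log(u_event) / hazard
    u_censor = rng.random(n_patients)
    if censor_rate > 0:
        t_censor = -np.log(u_censor) / censor_rate
    else:
        t_censor = np.full(n_patients, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    expr = ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=patients), scale="log2"
    )
    clinical = ClinicalTable(
        data=pd.DataFrame({"sample_id": patients, "time": time, "event": event})
    )
    truth = CohortTruth(
        activity=pd.Series(activity, index=patients, name="activity"),
        beta=beta,
        baseline_hazard=baseline_hazard,
        censor_rate=censor_rate,
        effect=effect,
    )
    return expr, clinical, truth


def make_marker_panel(
    n_epithelial: int = 27,
    n_mesenchymal: int = 19,
    n_intermediate: int = 6,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate linear-scale VIM and CDH1 expression for a cell-line panel.

    Default panel sizes (27 epithelial, 19 mesenchymal, 6 intermediate)
    mirror a typical breast-cancer cell-line collection. Log2 VIM/CDH1
    ratios are drawn per phenotype — N(-2, 0.7) epithelial, N(+3, 0.7)
    mesenchymal, N(+1, 0.15) intermediate (ratio concentrated inside
    :data:`DEFAULT_INTERMEDIATE_BAND`) — so the ratio-threshold classifier
    recovers labels with high probability.

    Returns a 2-gene (VIM, CDH1) x lines linear matrix and the true labels.
    """
    for name, n in (
        ("n_epithelial", n_epithelial),
        ("n_mesenchymal", n_mesenchymal),
        ("n_intermediate", n_intermediate),
    ):
        if n < 0:
            raise ParameterError(f"{name} must be >= 0")
    if n_epithelial + n_mesenchymal + n_intermediate == 0:
        raise ParameterError("panel must contain at least one cell line")

    rng = _rng("markers", seed)
    specs = [
        ("epithelial", "E", n_epithelial, -2.0, 0.7),
        ("mesenchymal", "M", n_mesenchymal, 3.0, 0.7),
        ("intermediate", "I", n_intermediate, 1.0, 0.15),
    ]
    cols: list[str] = []
    labels: list[str] = []
    vim: list[float] = []
    cdh1: list[float] = []
    for label, prefix, n, mu, sd in specs:
        log2_cdh1 = rng.normal(7.0, 1.0, size=n)
        log2_ratio = rng.normal(mu, sd, size=n)
        cdh1.extend(2.0**log2_cdh1)
        vim.extend(2.0 ** (log2_cdh1 + log2_ratio))
        cols.extend(f"{prefix}{i + 1:02d}" for i in range(n))
        labels.extend([label] * n)

    expr = ExpressionMatrix(
        data=pd.DataFrame([vim, cdh1], index=["VIM", "CDH1"], columns=cols),
        scale="linear",
    )
    return expr, pd.Series(labels, index=cols, name="phenotype")
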