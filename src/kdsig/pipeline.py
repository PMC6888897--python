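"""End-to-end orchestration: simulate/load, derive, score, stratify, test, enrich.

A single declarative config (YAML or dict) drives a six-stage run:

1. ``discovery`` — load a two-group discovery matrix, or simulate one;
2. ``signature`` — derive the up/down signature by fold-change cutoff;
3. ``cohort`` — load a patient expression matrix + clinical table, or
   simulate a cohort whose hazard tracks latent signature activity;
4. ``score`` — z-score the cohort, compute KD scores, stratify;
5. ``survival`` — Kaplan–Meier curves per stratum, log-rank test, optional
   best-cutoff scan, KM plot;
6. ``gsea`` — rank cohort genes (low vs high stratum) and test gene sets.

Every stage is a pure function of its declared inputs and the run seed, so
re-running a config reproduces byte-identical result files. A JSON manifest
records the package version, seed, a parameter hash and per-stage row
counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ParameterError, PipelineError
from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    Signature,
    read_clinical,
    read_expression,
    read_gmt,
    read_groups,
    write_clinical,
    write_expression,
    write_signature,
)
from .signature_builder import build_signature, fold_changes, ttest_qvalues
from .signature_scoring import kd_score, stratify, zscore_by_gene
from .survival_analysis import KMCurve, best_cutoff, km_estimate, logrank_test
from .enrichment_gsea import gsea, rank_genes, results_table
from .synthetic_cohort import make_cohort, make_discovery

logger = logging.getLogger(__name__)

STAGES = ("discovery", "signature", "cohort", "score", "survival", "gsea")


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run."""

    outdir: str
    seed: int = 1
    discovery: dict = field(default_factory=lambda: {"synthetic": {}})
    signature: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=lambda: {"synthetic": {}})
    score: dict = field(default_factory=dict)
    stratify: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    gsea: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ParameterError("config must set 'outdir'")
        return cls(**raw)

    def validate_paths(self) -> None:
        """Pre-flight check: every referenced input file must exist."""
        problems: list[str] = []
        for stage_name, keys in (
            ("discovery", ("expr", "groups")),
            ("cohort", ("expr", "clinical")),
            ("gsea", ("gmt",)),
        ):
            section = getattr(self, stage_name) or {}
            for key in keys:
                p = section.get(key)
                if p is not None and not Path(p).exists():
                    problems.append(f"{stage_name}.{key}: {p} does not exist")
        for stage_name in ("discovery", "cohort"):
            section = getattr(self, stage_name) or {}
            if "synthetic" not in section and not section.get("expr"):
                problems.append(f"{stage_name}: needs either 'synthetic' or 'expr'")
        cohort = self.cohort or {}
        if self.survival.get("enabled", True) and "synthetic" not in cohort:
            if not cohort.get("clinical"):
                problems.append("survival enabled but cohort.clinical path missing")
        if problems:
            raise ParameterError("pre-flight validation failed: " + "; ".join(problems))

    def param_hash(self) -> str:
        payload = json.dumps(
            {f: getattr(self, f) for f in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_logger(outdir / "run.log")
    manifest: dict[str, Any] = {
        "package": "kdsig",
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stages": [],
    }
    state: dict[str, Any] = {}
    for name in STAGES:
        fn = globals()[f"_stage_{name}"]
        logger.info("stage %s: start", name)
        try:
            record = fn(config, state, outdir)
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        record["name"] = name
        manifest["stages"].append(record)
        logger.info("stage %s: %s", name, record.get("status", "ok"))
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return outdir


def _setup_run_logger(path: Path) -> None:
    root = logging.getLogger("kdsig")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    handler = logging.FileHandler(path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root.addHandler(handler)
    root.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_discovery(config: RunConfig, state: dict, outdir: Path) -> dict:
    section = config.discovery or {}
    if "synthetic" in section:
        params = dict(section["synthetic"] or {})
        params.setdefault("seed", config.seed)
        expr, groups, truth = make_discovery(**params)
        state["discovery_truth"] = truth
    else:
        expr = read_expression(section["expr"], scale=section.get("scale", "log2"))
        groups = read_groups(section["groups"])
    state["discovery_expr"] = expr
    state["discovery_groups"] = groups
    write_expression(expr, outdir / "discovery_expr.tsv")
    pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values())}
    ).to_csv(outdir / "discovery_groups.csv", index=False, lineterminator="\n")
    return {"status": "ok", "n_genes": expr.shape[0], "n_samples": expr.shape[1]}


def _stage_signature(config: RunConfig, state: dict, outdir: Path) -> dict:
    section = config.signature or {}
    expr = state["discovery_expr"]
    groups = state["discovery_groups"]
    fc = fold_changes(expr, groups, case=section.get("case"), ctrl=section.get("ctrl"))
    qvalues = None
    if section.get("q_filter", False):
        qvalues = ttest_qvalues(expr, groups, case=section.get("case"), ctrl=section.get("ctrl"))
    sig = build_signature(
        fc,
        cutoff_fold=section.get("cutoff_fold", 2.0),
        qvalues=qvalues,
        q_max=section.get("q_max", 0.05),
        meta={"source": "pipeline"},
    )
    state["signature"] = sig
    write_signature(sig, outdir / "signature.tsv")
    return {"status": "ok", "n_up": len(sig.up), "n_down": len(sig.down)}


def _stage_cohort(config: RunConfig, state: dict, outdir: Path) -> dict:
    section = config.cohort or {}
    if "synthetic" in section:
        params = dict(section["synthetic"] or {})
        params.setdefault("seed", config.seed)
        expr, clinical, truth = make_cohort(state["signature"], **params)
        state["cohort_truth"] = truth
    else:
        expr = read_expression(section["expr"], scale=section.get("scale", "log2"))
        clinical = read_clinical(section["clinical"]) if section.get("clinical") else None
    state["cohort_expr"] = expr
    state["clinical"] = clinical
    write_expression(expr, outdir / "cohort_expr.tsv")
    if clinical is not None:
        write_clinical(clinical, outdir / "clinical.csv")
    return {"status": "ok", "n_genes": expr.shape[0], "n_samples": expr.shape[1]}


def _stage_score(config: RunConfig, state: dict, outdir: Path) -> dict:
    z = zscore_by_gene(state["cohort_expr"])
    table = kd_score(z, state["signature"], normalized=config.score.get("normalized", False))
    rule = config.stratify.get("rule", "median")
    labels = stratify(table, rule=rule, cutoff=config.stratify.get("cutoff"))
    state["scores"] = table
    state["strata"] = labels
    table.to_frame().to_csv(outdir / "scores.csv", index=False, lineterminator="\n")
    labels.rename("group").to_frame().assign(sample_id=labels.index)[
        ["sample_id", "group"]
    ].to_csv(outdir / "strata.csv", index=False, lineterminator="\n")
    return {
        "status": "ok",
        "n_samples": len(table),
        "n_up_used": table.n_up_used,
        "n_down_used": table.n_down_used,
        "rule": rule,
    }


def _stage_survival(config: RunConfig, state: dict, outdir: Path) -> dict:
    section = config.survival or {}
    if not section.get("enabled", True):
        return {"status": "skipped"}
    clinical: ClinicalTable = state["clinical"]
    if clinical is None:
        raise ParameterError("survival stage enabled but no clinical table loaded")
    labels = state["strata"].reindex(clinical.sample_ids)
    if labels.isna().any():
        raise ParameterError("clinical table contains samples without scores")
    time, event = clinical.time, clinical.event

    curves: dict[str, KMCurve] = {}
    rows = []
    for g in sorted(labels.unique()):
        mask = (labels == g).to_numpy()
        curve = km_estimate(time[mask], event[mask])
        curves[g] = curve
        for t, s, n, d in zip(
            curve.event_times, curve.survival, curve.at_risk, curve.n_events
        ):
            rows.append({"group": g, "time": t, "survival": s, "at_risk": n, "events": d})
    pd.DataFrame(rows).to_csv(outdir / "km_curves.csv", index=False, lineterminator="\n")

    result: dict[str, Any] = {}
    if labels.nunique() == 2:
        lr = logrank_test(time, event, labels.to_numpy())
        result["logrank"] = {
            "chi_square": lr.chi_square,
            "df": lr.df,
            "p_value": lr.p_value,
            "observed": lr.observed,
            "expected": lr.expected,
            "hr_estimate": lr.hr_estimate,
            "groups": list(lr.groups),
        }
    if section.get("best_cutoff", False):
        scores = state["scores"].scores.reindex(clinical.sample_ids).to_numpy()
        bc = best_cutoff(
            scores,
            time,
            event,
            n_perm=section.get("n_perm", 1000),
            seed=config.seed,
        )
        result["best_cutoff"] = {
            "cutoff": bc.cutoff,
            "p_nominal": bc.p_nominal,
            "p_adjusted": bc.p_adjusted,
            "n_candidates": bc.n_candidates,
        }
    (outdir / "logrank.json").write_text(
        json.dumps(result, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    if section.get("plot", True):
        plot_km(curves, outdir / "km.png", time_unit=clinical.time_unit)
    return {"status": "ok", "n_groups": int(labels.nunique())}


def _stage_gsea(config: RunConfig, state: dict, outdir: Path) -> dict:
    section = config.gsea or {}
    if not section.get("enabled", True):
        return {"status": "skipped"}
    expr = state["cohort_expr"]
    labels = state["strata"]
    # rank by association with the high-score (knockdown-like) stratum
    ranked = rank_genes(
        expr,
        labels[labels.isin(["low", "high"])],
        metric=section.get("metric", "signal2noise"),
        case="low",
    )
    if section.get("gmt"):
        sets = read_gmt(section["gmt"])
    else:
        sig: Signature = state["signature"]
        sets = {"SIGNATURE_UP": sig.up, "SIGNATURE_DOWN": sig.down}
    results = gsea(
        ranked,
        sets,
        n_perm=section.get("n_perm", 1000),
        seed=config.seed,
        weight=section.get("weight", 1.0),
    )
    table = results_table(results)
    table.to_csv(outdir / "gsea_results.csv", index=False, lineterminator="\n")
    return {"status": "ok", "n_sets": len(table)}


# ---------------------------------------------------------------------------
# plotting & report
# ---------------------------------------------------------------------------


def plot_km(curves: dict[str, KMCurve], path: str | Path, time_unit: str = "months") -> None:
    """Step plot of one or more KM curves (pyplot-free, backend-agnostic)."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(5, 4))
    ax = fig.add_subplot(111)
    for g in sorted(curves):
        c = curves[g]
        t = np.r_[0.0, c.event_times]
        s = np.r_[1.0, c.survival]
        ax.step(t, s, where="post", label=f"{g} (n={c.n_total})")
    ax.set_xlabel(f"time ({time_unit})")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def report(run_dir: str | Path) -> str:
    """Summarize a completed run as markdown; writes ``report.md`` alongside."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"{run_dir} has no manifest.json; not a completed run")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    stages = {s["name"]: s for s in manifest["stages"]}

    lines = [
        "# kdsig run report",
        "",
        f"- package version: {manifest['version']}",
        f"- seed: {manifest['seed']}",
        f"- parameter hash: {manifest['param_hash']}",
        "",
    ]

    sig_path = run_dir / "signature.tsv"
    if not sig_path.exists():
        raise PipelineError(f"missing artifact: {sig_path}")
    sig_stage = stages.get("signature", {})
    lines += [
        "## Signature",
        "",
        f"- up-regulated genes: {sig_stage.get('n_up')}",
        f"- down-regulated genes: {sig_stage.get('n_down')}",
        "",
    ]

    scores_path = run_dir / "scores.csv"
    if not scores_path.exists():
        raise PipelineError(f"missing artifact: {scores_path}")
    scores = pd.read_csv(scores_path)["kd_score"]
    qs = scores.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
    lines += [
        "## KD scores",
        "",
        f"- samples scored: {len(scores)}",
        "- quantiles (min / Q1 / median / Q3 / max): "
        + " / ".join(f"{v:.3f}" for v in qs),
        "",
    ]

    if stages.get("survival", {}).get("status") == "ok":
        lr_path = run_dir / "logrank.json"
        if not lr_path.exists():
            raise PipelineError(f"missing artifact: {lr_path}")
        lr = json.loads(lr_path.read_text(encoding="utf-8")).get("logrank")
        lines += ["## Survival", ""]
        if lr:
            hr = lr["hr_estimate"]
            lines += [
                f"- log-rank chi-square = {lr['chi_square']:.4f} (df={lr['df']}), "
                f"p = {lr['p_value']:.3g}",
                f"- hazard ratio ({lr['groups'][0]} vs {lr['groups'][1]}): "
                + (f"{hr:.3f}" if hr is not None else "undefined"),
            ]
        if (run_dir / "km.png").exists():
            lines.append("- KM plot: km.png")
        lines.append("")

    if stages.get("gsea", {}).get("status") == "ok":
        gsea_path = run_dir / "gsea_results.csv"
        if not gsea_path.exists():
            raise PipelineError(f"missing artifact: {gsea_path}")
        table = pd.read_csv(gsea_path)
        lines += ["## Enrichment (top sets)", ""]
        for _, row in table.head(5).iterrows():
            lines.append(
                f"- {row['set']} (size {row['size']}): NES = {row['nes']:.3f}, "
                f"p = {row['p_nominal']:.3g}"
            )
        lines.append("")

    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text, encoding="utf-8")
    return text
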