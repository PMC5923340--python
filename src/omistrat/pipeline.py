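"""Orchestration of the full three-tier stratification experiment.

``run_pipeline`` ties the stages together — cohort acquisition, quality
filters, proteomics normalization, D7/D1 ratios, univariate screening,
cascaded mRMR ranking and the model grid (three tiers x top-10/20/30 x
{elastic net A/B, LDA, PLS-DA}) — writing every artifact as TSV with a
provenance header, so a run is fully determined by its configuration and
seed. ``report`` renders a human-readable markdown summary from the
artifacts alone, without recomputing anything.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .cohort_io import (
    CohortMetadata,
    OmicsTable,
    cohort_summary,
    outcome_rate_percent,
    read_cohort,
)
from .preprocessing import (
    QCReport,
    RatioTable,
    compute_ratios,
    filter_metabolites,
    merge_ratio_tables,
    normalize_proteins,
    zscore,
)
from .univariate_stats import screen
from .feature_ranking import cascade_rank
from .classifiers import (
    ElasticNetConfig,
    ModelResult,
    compare_models,
    fit_elastic_net_both,
    fit_lda,
    fit_plsda,
    make_split,
)
from . import synthetic_data

__all__ = ["RunConfig", "run_pipeline", "report", "load_model_results"]

TIER_LABELS = {"tier1": "metabolites", "tier2": "met+prot", "tier3": "all"}


@dataclass
class RunConfig:
    """Everything that determines a pipeline run (besides the code version)."""

    preset: str | None = "reference"   # reference | qc_challenge | None (read cohort_dir)
    cohort_dir: str | None = None
    seed: int = 0
    out_dir: str = "run"
    max_missing_frac: float = 0.20
    min_above_lod_frac: float = 0.50
    lod_impute: str = "half_lod"
    cascade_sizes: tuple[int, int, int, int] = (50, 50, 20, 17)
    top_k: tuple[int, ...] = (10, 20, 30)
    models: tuple[str, ...] = ("enet", "lda", "plsda")
    strategies: tuple[str, ...] = ("A", "B")
    n_repetitions: int = 50
    n_components: int = 3
    alpha: float = 0.05
    fdr: float = 0.15
    zscore_scope: str = "train"  # train | all

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("cascade_sizes", "top_k", "models", "strategies"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("cascade_sizes", "top_k", "models", "strategies"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _prov(config: RunConfig, stage: str) -> dict:
    return {"tool": f"omistrat {_version}", "stage": stage, "seed": config.seed}


def _write(path: Path, df: pd.DataFrame, prov: dict) -> None:
    with open(path, "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending entity."""


def _get_cohort(config: RunConfig):
    if config.preset == "reference":
        return synthetic_data.reference_cohort(config.seed)
    if config.preset == "qc_challenge":
        tables, meta, ev, _ = synthetic_data.qc_challenge_cohort(config.seed)
        return tables, meta, ev
    if config.cohort_dir is None:
        raise PipelineError("cohort: no preset and no cohort_dir given")
    return read_cohort(config.cohort_dir)


def run_pipeline(config: RunConfig) -> Path:
    """Execute preprocess -> screen -> rank -> fit -> compare; return run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    config.to_yaml(out / "config.yaml")

    try:
        tables, metadata, evidence = _get_cohort(config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"cohort: {exc}") from exc
    metadata.require_both_groups()

    # --- cohort summary ------------------------------------------------
    clin_tabs = [t for k, t in tables.items() if k[0] == "clinical"]
    summ = cohort_summary(clin_tabs or list(tables.values()), metadata)
    flat = summ.copy()
    flat.columns = ["_".join(c) for c in flat.columns]
    prov = _prov(config, "summary")
    prov["outcome_rate_percent"] = summ.attrs["outcome_rate_percent"]
    prov["n_S"], prov["n_NS"] = summ.attrs["n_S"], summ.attrs["n_NS"]
    _write(out / "cohort_summary.tsv", flat.reset_index(), prov)

    # --- preprocessing: filters, normalization, ratios ------------------
    reports: list[QCReport] = []
    ratio_layers: dict[str, RatioTable] = {}
    layer_in: dict[str, int] = {}
    met_d1, met_d7 = tables.get(("metabolite", "D1")), tables.get(("metabolite", "D7"))
    if met_d1 is not None:
        layer_in["metabolite"] = met_d1.values.shape[1]
        try:
            retained, rep = filter_metabolites(
                met_d1, met_d7, metadata,
                max_missing_frac=config.max_missing_frac,
                min_above_lod_frac=config.min_above_lod_frac,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"preprocess/metabolite filter: {exc}") from exc
        reports.append(rep)
        sub = lambda t: OmicsTable(  # noqa: E731
            layer=t.layer, timepoint=t.timepoint, values=t.values[retained],
            below_lod_mask=None if t.below_lod_mask is None
            else t.below_lod_mask[retained],
            lod=None if t.lod is None else t.lod[retained],
        )
        met_d1, met_d7 = sub(met_d1), sub(met_d7)
        tables[("metabolite", "D1")], tables[("metabolite", "D7")] = met_d1, met_d7
        ratio, rep2 = compute_ratios(met_d1, met_d7, metadata,
                                     lod_impute=config.lod_impute)
        reports.append(rep2)
        ratio_layers["metabolite"] = ratio

    if ("protein", "D1") in tables and evidence is not None:
        layer_in["protein"] = len(evidence.detected)
        raw = {tp: np.exp2(tables[("protein", tp)].values) for tp in ("D1", "D7")}
        try:
            normed, rep = normalize_proteins(raw, evidence)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"preprocess/protein normalization: {exc}") from exc
        reports.append(rep)
        tables.update(normed)
        ratio, rep2 = compute_ratios(
            normed[("protein", "D1")], normed[("protein", "D7")], metadata
        )
        reports.append(rep2)
        ratio_layers["protein"] = ratio

    if ("clinical", "D1") in tables:
        layer_in["clinical"] = tables[("clinical", "D1")].values.shape[1]
        ratio, rep2 = compute_ratios(
            tables[("clinical", "D1")], tables[("clinical", "D7")], metadata
        )
        reports.append(rep2)
        ratio_layers["clinical"] = ratio

    qc = QCReport.merge(*reports)
    _write(out / "qc_report.tsv", qc.records, _prov(config, "preprocess"))
    merged = merge_ratio_tables(*ratio_layers.values())
    _write(out / "ratios.tsv", merged.values, _prov(config, "preprocess"))
    _write(out / "ratio_layers.tsv", merged.layers.to_frame("layer"),
           _prov(config, "preprocess"))

    # --- univariate screen ----------------------------------------------
    try:
        scr = screen(tables, metadata, ratios=ratio_layers,
                     alpha=config.alpha, fdr=config.fdr)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"screen: {exc}") from exc
    _write(out / "screen.tsv", scr, _prov(config, "screen"))

    # --- cascaded mRMR ranking -------------------------------------------
    try:
        rankings = cascade_rank(merged, sizes=config.cascade_sizes)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"rank: {exc}") from exc
    for name, rk in rankings.items():
        _write(out / f"ranking_{name}.tsv", rk.table, _prov(config, "rank"))

    # --- model grid --------------------------------------------------------
    split = make_split(metadata, seed=config.seed)
    y = merged.y()
    y_map = pd.Series(y, index=merged.values.index)
    results: list[ModelResult] = []
    fit_counter = 0
    for tier_key in ("tier1", "tier2", "tier3"):
        tier = TIER_LABELS[tier_key]
        ranking = rankings[tier_key]
        for k in config.top_k:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                feats = ranking.top(k)
            X = merged.values[feats]
            if config.zscore_scope == "all":
                z = zscore(X)
                X_all = z.transformed[0]
                X_tr, X_te = X_all.loc[split.train], X_all.loc[split.test]
            else:
                z = zscore(X.loc[split.train], X.loc[split.test])
                X_tr, X_te = z.transformed
            y_tr = y_map.loc[split.train].to_numpy()
            y_te = y_map.loc[split.test].to_numpy()
            fit_counter += 1
            if "enet" in config.models:
                cfg = ElasticNetConfig(
                    n_repetitions=config.n_repetitions,
                    seed=config.seed * 1000 + fit_counter,
                )
                both = fit_elastic_net_both(X_tr, y_tr, X_te, y_te, cfg,
                                            tier=tier, top_k=k)
                for strat in config.strategies:
                    results.append(both[strat])
            if "lda" in config.models and k == 10:
                results.append(fit_lda(X_tr, y_tr, X_te, y_te,
                                       tier=tier, top_k=k))
            if "plsda" in config.models and k in (10, 20):
                results.append(
                    fit_plsda(X_tr, y_tr, X_te, y_te,
                              n_components=config.n_components,
                              tier=tier, top_k=k)
                )

    for r in results:
        stem = r.label.replace("/", "_").replace("+", "p")
        coef = pd.DataFrame({"feature": r.features})
        coef["coefficient"] = (
            r.coefficients.reindex(r.features).to_numpy()
            if r.coefficients is not None else np.nan
        )
        if r.vip is not None:
            coef["vip"] = r.vip.reindex(r.features).to_numpy()
        prov = _prov(config, "fit")
        prov.update(
            family=r.family, tier=r.tier, top_k=r.top_k,
            strategy=r.selection.get("strategy", ""),
            intercept=r.intercept,
            correct=r.correct, total=r.total,
        )
        if "lambda" in r.selection:
            prov["lambda"] = r.selection["lambda"]
        _write(out / "models" / f"{stem}.coef.tsv",
               coef.set_index("feature"), prov)
        _write(out / "models" / f"{stem}.predictions.tsv",
               r.predictions.set_index("sample_id"), prov)
        if r.scores is not None:
            _write(out / "models" / f"{stem}.scores.tsv", r.scores, prov)

    if len(results) >= 2:
        comparison = compare_models(results)
        _write(out / "comparison.tsv", comparison, _prov(config, "compare"))

    info = {
        "outcome_rate_percent": int(summ.attrs["outcome_rate_percent"]),
        "n_S": int(summ.attrs["n_S"]),
        "n_NS": int(summ.attrs["n_NS"]),
        "feature_funnel": {
            layer: {
                "in": int(layer_in[layer]),
                "retained": len(ratio_layers[layer].feature_ids),
            }
            for layer in ratio_layers
        },
        "n_features_modeled": {
            layer: len(rt.feature_ids) for layer, rt in ratio_layers.items()
        },
        "tier_input_sizes": {
            "tier2": int(len(rankings["tier2"].table)),
            "tier3": int(len(rankings["tier3"].table)),
        },
        "n_model_bundles": len(results),
        "models_all_test_correct": int(sum(r.all_test_correct for r in results)),
        "train": list(split.train),
        "test": list(split.test),
    }
    Path(out / "run_info.yaml").write_text(yaml.safe_dump(info, sort_keys=False))
    return out


# ----------------------------------------------------------------------
# Loading fitted models back from a run directory
# ----------------------------------------------------------------------

def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
    return meta


def load_model_results(run_dir: str | Path) -> list[ModelResult]:
    """Rebuild lightweight :class:`ModelResult` objects from a run's model
    TSVs (enough for consensus tables and reporting)."""
    run_dir = Path(run_dir)
    results = []
    for coef_path in sorted((run_dir / "models").glob("*.coef.tsv")):
        meta = _read_header(coef_path)
        coef = pd.read_csv(coef_path, sep="\t", index_col=0, comment="#")
        pred = pd.read_csv(
            coef_path.with_suffix("").with_suffix(".predictions.tsv")
            if False else str(coef_path).replace(".coef.tsv", ".predictions.tsv"),
            sep="\t", comment="#",
        )
        r = ModelResult(
            family=meta["family"],
            tier=meta["tier"],
            top_k=int(meta["top_k"]),
            features=list(coef.index),
            coefficients=coef["coefficient"] if "coefficient" in coef else None,
            vip=coef["vip"] if "vip" in coef else None,
            intercept=float(meta["intercept"]) if meta.get("intercept") else None,
            selection={"strategy": meta.get("strategy", "")} if meta.get(
                "strategy") else {},
            predictions=pred,
            correct=int(meta["correct"]),
            total=int(meta["total"]),
        )
        results.append(r)
    return results


# ----------------------------------------------------------------------
# Report
# ----------------------------------------------------------------------

REQUIRED_ARTIFACTS = (
    "config.yaml", "run_info.yaml", "cohort_summary.tsv", "qc_report.tsv",
    "screen.tsv", "ranking_tier1.tsv", "ranking_tier2.tsv",
    "ranking_tier3.tsv", "comparison.tsv",
)


def report(run_dir: str | Path) -> str:
    """Markdown summary of a completed run, built purely from artifacts."""
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise PipelineError(
            f"report: run directory incomplete, missing {missing}"
        )
    info = yaml.safe_load((run_dir / "run_info.yaml").read_text())
    scr = pd.read_csv(run_dir / "screen.tsv", sep="\t", comment="#")
    comparison = pd.read_csv(run_dir / "comparison.tsv", sep="\t", comment="#",
                             index_col=0)

    lines = ["# Stratification run report", ""]
    lines += [
        "## Cohort",
        "",
        f"- survivors (S): {info['n_S']}, non-survivors (NS): {info['n_NS']}",
        f"- 28-day outcome rate: {info['outcome_rate_percent']}%",
        "",
        "## Feature funnel",
        "",
    ]
    for layer, c in info["feature_funnel"].items():
        lines.append(f"- {layer}: {c['in']} in, {c['retained']} retained")
    lines += [
        "",
        f"- features entering models (post-ratio): "
        + ", ".join(f"{k}: {v}" for k, v in info["n_features_modeled"].items()),
        f"- tier-2 ranking input: {info['tier_input_sizes']['tier2']} features; "
        f"tier-3 input: {info['tier_input_sizes']['tier3']} features",
        "",
        "## Significant features (p < alpha and q < FDR)",
        "",
    ]
    sig = scr[scr["significant"] == True]  # noqa: E712
    if len(sig) == 0:
        lines.append("none")
    else:
        for (layer, comp), grp in sig.groupby(["layer", "comparison"]):
            feats = ", ".join(grp["feature_id"].head(15))
            lines.append(f"- {layer} / {comp}: {len(grp)} features ({feats})")
    lines += ["", "## Top-ranked features per tier", ""]
    for tier_key, label in TIER_LABELS.items():
        rk = pd.read_csv(run_dir / f"ranking_{tier_key}.tsv", sep="\t",
                         comment="#")
        top = ", ".join(rk["feature"].head(10))
        lines.append(f"- {label}: {top}")
    lines += [
        "",
        "## Models",
        "",
        f"- fitted bundles: {info['n_model_bundles']}; bundles classifying "
        f"every test observation correctly: {info['models_all_test_correct']}",
        "",
        "## Consensus features (selected by all models they entered)",
        "",
    ]
    consensus = comparison.index[comparison["selected_by_all"] == True]  # noqa: E712
    lines.append(", ".join(consensus) if len(consensus) else "none")
    lines.append("")
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
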