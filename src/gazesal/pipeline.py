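"""End-to-end orchestration: simulate -> saliency -> score -> stats -> report.

A run directory is fully determined by the configuration and seed: every
stage writes CSV/JSON artifacts plus a manifest entry keyed by a hash of
the configuration subtree it depends on, so re-running with an unchanged
config skips completed stages (and a stats-only change never recomputes
saliency maps).  Re-running from scratch with the same config reproduces
every CSV byte-identically.

Two saliency models are scored: ``bottom_up`` — the package's graph-based
model computed from the rendered stimuli — and ``top_down_external`` — the
object-prior surrogate standing in for an externally supplied semantic
model's exported maps (any real exported map directory can be swapped in).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gazesal import cohort as _cohort
from gazesal import inference, preprocess, saliency, scoring
from gazesal.cohort import CohortConfig, GroupParams, generate_cohort, object_prior_map, render_stimulus
from gazesal.saliency import GBVSConfig, SaliencyMap, gbvs_saliency

logger = logging.getLogger("gazesal.pipeline")

MODELS = ("bottom_up", "top_down_external")
PERIODS = ("all", "early", "late")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    gbvs: GBVSConfig = field(default_factory=GBVSConfig)
    seed: int = 0
    #: stimuli are rendered at screen resolution x render_scale for the
    #: bottom-up model (the maps are resolution-free for NSS scoring)
    render_scale: float = 0.1
    density_sigma_px: float = 64.0
    density_weighting: str = "duration"
    periods: tuple[str, ...] = PERIODS
    alpha_sequential: float = 0.05
    alpha_correlation: float = 0.001
    clinical_csv: str | None = None

    def __post_init__(self) -> None:
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "group_params" in c:
                c["group_params"] = {k: GroupParams(**v) if isinstance(v, dict) else v
                                     for k, v in c["group_params"].items()}
            for key in ("categories",):
                if key in c and isinstance(c[key], list):
                    c[key] = tuple(c[key])
            d["cohort"] = CohortConfig(**c)
        if "gbvs" in d and isinstance(d["gbvs"], dict):
            d["gbvs"] = GBVSConfig(**d["gbvs"])
        if "periods" in d and isinstance(d["periods"], list):
            d["periods"] = tuple(d["periods"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_manifest(run_dir: Path) -> dict:
    p = run_dir / "manifest.json"
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _save_manifest(run_dir: Path, manifest: dict) -> None:
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_done(manifest: dict, name: str, h: str, run_dir: Path) -> bool:
    st = manifest["stages"].get(name)
    if not st or st.get("hash") != h:
        return False
    return all((run_dir / a).exists() for a in st.get("artifacts", []))


def _finish_stage(manifest: dict, run_dir: Path, name: str, h: str,
                  artifacts: list[str], **info) -> None:
    manifest["stages"][name] = {"hash": h, "artifacts": artifacts, **info}
    _save_manifest(run_dir, manifest)
    logger.info("stage %s done: %s", name, info or artifacts)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    manifest = _load_manifest(run_dir)
    h = _hash({"cohort": dataclasses.asdict(config.cohort), "seed": config.seed})
    arts = ["fixations.csv", "stimuli.json"]
    if _stage_done(manifest, "simulate", h, run_dir):
        logger.info("stage simulate cached")
        return
    table, specs, _maps = generate_cohort(config.cohort)
    table.to_csv(run_dir / "fixations.csv", index=False)
    (run_dir / "stimuli.json").write_text(json.dumps(
        [dataclasses.asdict(s) for s in specs], indent=1))
    _finish_stage(manifest, run_dir, "simulate", h, arts, rows=len(table))


def _read_specs(run_dir: Path) -> list[_cohort.StimulusSpec]:
    raw = json.loads((run_dir / "stimuli.json").read_text())
    out = []
    for d in raw:
        d["object_regions"] = tuple(tuple(r) for r in d["object_regions"])
        if d.get("salient_region") is not None:
            d["salient_region"] = tuple(d["salient_region"])
        out.append(_cohort.StimulusSpec(**d))
    return out


def stage_saliency(config: RunConfig, run_dir: Path) -> None:
    manifest = _load_manifest(run_dir)
    h = _hash({"gbvs": dataclasses.asdict(config.gbvs), "render_scale": config.render_scale,
               "cohort": dataclasses.asdict(config.cohort), "seed": config.seed})
    maps_dir = run_dir / "maps"
    if _stage_done(manifest, "saliency", h, run_dir):
        logger.info("stage saliency cached")
        return
    maps_dir.mkdir(exist_ok=True)
    specs = _read_specs(run_dir)
    arts = []
    for spec in specs:
        img = render_stimulus(spec, scale=config.render_scale)
        bu = gbvs_saliency(img, config.gbvs)
        td_shape = bu.values.shape
        td = object_prior_map(spec, td_shape)
        np.save(maps_dir / f"{spec.stimulus_id}_bottom_up.npy", bu.values)
        np.save(maps_dir / f"{spec.stimulus_id}_top_down_external.npy", td)
        arts += [f"maps/{spec.stimulus_id}_bottom_up.npy",
                 f"maps/{spec.stimulus_id}_top_down_external.npy"]
    _finish_stage(manifest, run_dir, "saliency", h, arts, n_stimuli=len(specs))


def stage_score(config: RunConfig, run_dir: Path) -> None:
    manifest = _load_manifest(run_dir)
    h = _hash({"cohort": dataclasses.asdict(config.cohort), "seed": config.seed,
               "gbvs": dataclasses.asdict(config.gbvs), "periods": list(config.periods),
               "render_scale": config.render_scale})
    arts = ["nss.csv", "cleaning_report.json", "fixations_clean.csv"]
    if _stage_done(manifest, "score", h, run_dir):
        logger.info("stage score cached")
        return
    screen = preprocess.ScreenGeometry(config.cohort.screen_w, config.cohort.screen_h)
    table = preprocess.read_fixation_table(run_dir / "fixations.csv", screen)
    clean, report = preprocess.clean_fixations(table, screen)
    clean.to_csv(run_dir / "fixations_clean.csv", index=False)
    store = {}
    for spec in _read_specs(run_dir):
        store[spec.stimulus_id] = {
            m: np.load(run_dir / "maps" / f"{spec.stimulus_id}_{m}.npy") for m in MODELS}
    nss, counters = scoring.build_nss_table(
        clean, store, periods=config.periods,
        screen=(config.cohort.screen_w, config.cohort.screen_h))
    nss.to_csv(run_dir / "nss.csv", index=False)
    (run_dir / "cleaning_report.json").write_text(json.dumps(
        {"cleaning": report.as_dict(), "scoring": counters}, indent=2, sort_keys=True))
    _finish_stage(manifest, run_dir, "score", h, arts,
                  rows_in=report.rows_in, rows_kept=report.rows_kept,
                  nss_records=len(nss))


def stage_stats(config: RunConfig, run_dir: Path) -> None:
    manifest = _load_manifest(run_dir)
    h = _hash({"cohort": dataclasses.asdict(config.cohort), "seed": config.seed,
               "alpha_sequential": config.alpha_sequential,
               "alpha_correlation": config.alpha_correlation,
               "periods": list(config.periods), "clinical": config.clinical_csv})
    arts = ["sequential_test.csv", "oculomotor_summary.csv", "group_stats.csv",
            "duration_by_index.csv"]
    nss = pd.read_csv(run_dir / "nss.csv")
    for model in MODELS:
        for period in config.periods:
            arts.append(f"lme_{model}_{period}.csv")
    if _stage_done(manifest, "stats", h, run_dir):
        logger.info("stage stats cached")
        return
    clean = pd.read_csv(run_dir / "fixations_clean.csv")

    for model in MODELS:
        for period in config.periods:
            sub = nss[(nss["model"] == model) & (nss["period"] == period)]
            out = run_dir / f"lme_{model}_{period}.csv"
            try:
                res = inference.fit_lme(sub)
                fe = res.fixed_effects.copy()
                fe["model"], fe["period"] = model, period
                fe["icc"], fe["r2_marginal"], fe["r2_conditional"] = (
                    res.icc, res.r2_marginal, res.r2_conditional)
                fe["singular"], fe["n_obs"] = res.singular, res.n_obs
                fe.to_csv(out, index=False)
            except ValueError as exc:
                raise RuntimeError(f"stats stage: LME {model}/{period} failed: {exc}") from exc

    means = preprocess.subject_index_means(clean)
    seq = inference.sequential_duration_test(means, alpha=config.alpha_sequential)
    seq.per_index.to_csv(run_dir / "sequential_test.csv", index=False)

    rep = preprocess.summarize_oculomotor(clean)
    rep.per_subject.to_csv(run_dir / "oculomotor_summary.csv", index=False)
    rep.group_stats.to_csv(run_dir / "group_stats.csv", index=False)
    rep.duration_by_index.to_csv(run_dir / "duration_by_index.csv", index=False)

    if config.clinical_csv:
        clinical = pd.read_csv(config.clinical_csv)
        corr = inference.correlate_clinical(rep.per_subject, clinical,
                                            alpha=config.alpha_correlation)
        corr.to_csv(run_dir / "correlations.csv", index=False)
        arts.append("correlations.csv")
    _finish_stage(manifest, run_dir, "stats", h, arts, nss_rows=len(nss))


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def write_report(run_dir) -> Path:
    """Render ``report.md`` (plus deterministic figures) from the run's CSVs.

    Sections whose inputs are missing are marked unavailable rather than
    failing; the report references only files inside the run directory.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    lines = ["# gazesal run report", ""]
    manifest_p = run_dir / "manifest.json"
    if manifest_p.exists():
        manifest = json.loads(manifest_p.read_text())
        lines += [f"- config hash: `{manifest.get('config_hash', 'n/a')}`",
                  f"- seed: {manifest.get('seed', 'n/a')}", ""]

    dbi_p = run_dir / "duration_by_index.csv"
    lines.append("## Fixation-duration dynamics")
    if dbi_p.exists():
        dbi = pd.read_csv(dbi_p)
        fig, ax = plt.subplots(figsize=(7, 4))
        for g, sub in dbi.groupby("group"):
            ax.errorbar(sub["fix_index"], sub["mean_duration_ms"], yerr=sub["se_ms"],
                        label=g, capsize=2)
        ax.set_xlabel("fixation index")
        ax.set_ylabel("mean duration (ms)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "fig_duration_by_index.png", dpi=110)
        plt.close(fig)
        lines += ["", "![duration by index](fig_duration_by_index.png)", ""]
        seq_p = run_dir / "sequential_test.csv"
        if seq_p.exists():
            seq = pd.read_csv(seq_p)
            n_sig = int(seq["declared_significant"].sum())
            lines.append(
                f"Sequential closed testing: {n_sig} leading fixation indices show a "
                f"significant group difference in duration.")
    else:
        lines.append("*unavailable*")
    lines.append("")

    nss_p = run_dir / "nss.csv"
    lines.append("## NSS by model, period and group")
    if nss_p.exists():
        nss = pd.read_csv(nss_p)
        summary = (nss.groupby(["model", "period", "group"], observed=True)["nss"]
                   .agg(["mean", "sem", "count"]).reset_index())
        fig, ax = plt.subplots(figsize=(7, 4))
        labels = [f"{m[:6]}/{p[:5]}/{g}" for m, p, g in
                  zip(summary["model"], summary["period"], summary["group"])]
        ax.bar(range(len(summary)), summary["mean"], yerr=summary["sem"])
        ax.set_xticks(range(len(summary)))
        ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=7)
        ax.set_ylabel("mean NSS")
        fig.tight_layout()
        fig.savefig(run_dir / "fig_nss_summary.png", dpi=110)
        plt.close(fig)
        lines += ["", "![NSS summary](fig_nss_summary.png)", "",
                  summary.to_markdown(index=False, floatfmt=".3f"), ""]
    else:
        lines += ["*unavailable*", ""]

    lines.append("## Mixed-model results")
    any_lme = False
    for p in sorted(run_dir.glob("lme_*.csv")):
        any_lme = True
        fe = pd.read_csv(p)
        lines += [f"### {p.stem}", "",
                  fe[["term", "estimate", "ci_low", "ci_high", "df", "p"]]
                  .to_markdown(index=False, floatfmt=".3f"), ""]
    if not any_lme:
        lines += ["*unavailable*", ""]

    lines.append("## Oculomotor group summaries")
    gs_p = run_dir / "group_stats.csv"
    if gs_p.exists():
        gs = pd.read_csv(gs_p)
        lines += ["", gs.to_markdown(index=False, floatfmt=".2f"), ""]
    else:
        lines += ["*unavailable*", ""]

    lines.append("## Clinical correlations")
    corr_p = run_dir / "correlations.csv"
    if corr_p.exists():
        corr = pd.read_csv(corr_p)
        lines += ["", corr.to_markdown(index=False, floatfmt=".3f"), ""]
    else:
        lines += ["*unavailable (no clinical table provided)*", ""]

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

STAGES = ("simulate", "saliency", "score", "stats", "report")


def run_pipeline(config: RunConfig, out_dir, stages=STAGES) -> Path:
    """Run the requested stages into ``out_dir`` and return the directory."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(run_dir)
    manifest["config_hash"] = _hash(json.loads(json.dumps(config.to_dict(), default=str)))
    manifest["seed"] = config.seed
    _save_manifest(run_dir, manifest)
    config.to_yaml(run_dir / "config.yaml")
    for name in stages:
        logger.info("stage %s ...", name)
        if name == "simulate":
            stage_simulate(config, run_dir)
        elif name == "saliency":
            stage_saliency(config, run_dir)
        elif name == "score":
            stage_score(config, run_dir)
        elif name == "stats":
            stage_stats(config, run_dir)
        elif name == "report":
            write_report(run_dir)
        else:
            raise ValueError(f"unknown stage {name!r}")
    return run_dir
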