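"""End-to-end orchestration: ingest -> topics -> sentiment -> impact ->
trust axis -> term volumes, from a single configuration.

Stages communicate through serialized files in the output directory so each
is independently rerunnable, and a manifest records the configuration hash
and the record counts at every stage (read -> deduplicated -> topic-filtered,
the funnel structure of a scraped-corpus analysis).  Per-stage seeds derive
from the global seed by fixed offsets; two runs with the same configuration
and corpus produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np

from . import ingest, sentiment, synthetic, topics, trust, volume
from .impact import ImpactConfig, ImpactResult, run_impact
from .ingest import PeriodConfig
from .sentiment import LexiconClassifier
from .synthetic import FILLER_WORDS
from .topics import LdaConfig
from .trust import AnchorSet, SgnsConfig, TermSet

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (stage seed = global_seed * 1000 + offset, mod 2^31)
_STAGE_OFFSETS = {
    "corpus": 1,
    "lda": 2,
    "impact_engagement": 3,
    "impact_sentiment": 4,
    "sgns_pre": 5,
    "sgns_post": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1000 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    """All stage settings plus the global seed.

    ``selected_topics`` may be an explicit list of topic indices or None, in
    which case topics are chosen by inspecting top terms for the salient
    terms of interest (the operator-aid heuristic in
    :func:`trustshift.topics.salient_topics`).
    """

    period: PeriodConfig
    lda: LdaConfig
    selected_topics: Sequence[int] | None = None
    topic_threshold: float = 0.95
    salient_terms: tuple[str, ...] = (
        "abortion", "roe", "privacy", "doctor", "hipaa", "data", "health",
    )
    impact_engagement: ImpactConfig = field(
        default_factory=lambda: ImpactConfig(scale="log1p")
    )
    impact_sentiment: ImpactConfig = field(
        default_factory=lambda: ImpactConfig(scale="raw")
    )
    sgns: SgnsConfig = field(default_factory=SgnsConfig)
    anchors: AnchorSet = field(default_factory=AnchorSet)
    terms: TermSet = field(default_factory=TermSet)
    tfidf_quantile: float = 0.95
    lda_stop_words: tuple[str, ...] = FILLER_WORDS
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (dates as ISO strings)."""
    import yaml

    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)

    def _date(v):  # YAML may hand back str or datetime.date
        return v if isinstance(v, date) else date.fromisoformat(str(v))

    period = PeriodConfig(
        pre_start=_date(raw["period"]["pre_start"]),
        boundary=_date(raw["period"]["boundary"]),
        end=_date(raw["period"]["end"]),
    )
    kwargs: dict = {"period": period, "lda": LdaConfig(**raw.get("lda", {}))}
    if "impact_engagement" in raw:
        kwargs["impact_engagement"] = ImpactConfig(**raw["impact_engagement"])
    if "impact_sentiment" in raw:
        kwargs["impact_sentiment"] = ImpactConfig(**raw["impact_sentiment"])
    if "sgns" in raw:
        kwargs["sgns"] = SgnsConfig(**raw["sgns"])
    if "anchors" in raw:
        kwargs["anchors"] = AnchorSet(
            positive=tuple(raw["anchors"]["positive"]),
            negative=tuple(raw["anchors"]["negative"]),
        )
    if "terms" in raw:
        kwargs["terms"] = TermSet(
            clinician=tuple(raw["terms"]["clinician"]),
            health_information=tuple(raw["terms"]["health_information"]),
        )
    for key in ("selected_topics", "topic_threshold", "tfidf_quantile", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "salient_terms" in raw:
        kwargs["salient_terms"] = tuple(raw["salient_terms"])
    return PipelineConfig(**kwargs)


class StageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def run_all(cfg: PipelineConfig, corpus_path: str | Path, outdir: str | Path) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": {},
        "stages": [],
        "outputs": {},
    }
    stage = "ingest"
    try:
        records = ingest.read_corpus(corpus_path)
        manifest["counts"]["read"] = len(records)
        records = ingest.deduplicate(records)
        manifest["counts"]["deduplicated"] = len(records)
        records = ingest.label_periods(records, cfg.period)
        manifest["counts"]["period_labeled"] = len(records)
        ingest.tokenize_records(records)
        ingest.export_csv(records, outdir / "corpus_clean.csv")
        manifest["outputs"]["corpus_clean"] = "corpus_clean.csv"
        manifest["stages"].append(stage)

        stage = "topic_filter"
        lda_cfg = dataclasses.replace(cfg.lda, seed=stage_seed(cfg.seed, "lda"))
        lda_docs = [
            ingest.filter_tokens(rec.tokens, cfg.lda_stop_words) for rec in records
        ]
        model = topics.fit_lda(lda_docs, lda_cfg)
        topics.save_model(model, outdir / "lda")
        scores, _ = topics.score_documents(model)
        selected = (
            list(cfg.selected_topics)
            if cfg.selected_topics is not None
            else topics.salient_topics(model, cfg.salient_terms)
        )
        if not selected:
            raise ValueError("no topic matched the salient terms; set selected_topics")
        manifest["selected_topics"] = selected
        records, _ = topics.filter_by_topics(
            records, scores, selected, cfg.topic_threshold
        )
        manifest["counts"]["topic_filtered"] = len(records)
        with (outdir / "topic_top_terms.csv").open("w") as fh:
            fh.write("topic,rank,term,weight,count\n")
            for k in range(model.n_topics):
                for rank, (term, weight, count) in enumerate(
                    topics.top_terms(model, k, 10), start=1
                ):
                    fh.write(f"{k},{rank},{term},{weight:.6f},{count}\n")
        manifest["outputs"]["topic_top_terms"] = "topic_top_terms.csv"
        manifest["stages"].append(stage)

        stage = "sentiment"
        classifier = LexiconClassifier()
        results = sentiment.classify_records(records, classifier)
        boundary = cfg.period.boundary
        engagement = sentiment.daily_engagement(records, boundary)
        daily_sent = sentiment.daily_sentiment(records, results, boundary)
        engagement.to_csv(outdir / "engagement.csv")
        daily_sent.to_csv(outdir / "sentiment.csv")
        manifest["outputs"]["engagement"] = "engagement.csv"
        manifest["outputs"]["sentiment"] = "sentiment.csv"
        manifest["stages"].append(stage)

        stage = "impact"
        impact_results: dict[str, ImpactResult] = {}
        for name, series, icfg in (
            ("engagement", engagement, cfg.impact_engagement),
            ("sentiment", daily_sent, cfg.impact_sentiment),
        ):
            icfg = dataclasses.replace(
                icfg, seed=stage_seed(cfg.seed, f"impact_{name}")
            )
            res = run_impact(series, icfg)
            res.to_csv(outdir / f"impact_{name}.csv",
                       dates=[d for d in series.dates if d > boundary])
            res.to_json(outdir / f"impact_{name}.json")
            manifest["outputs"][f"impact_{name}"] = f"impact_{name}.json"
            manifest[f"impact_{name}"] = {
                "rel_effect_pct": round(res.rel_effect, 4),
                "p_value": round(res.p_value, 6),
            }
            impact_results[name] = res
        manifest["stages"].append(stage)

        stage = "trust_axis"
        period_docs = {
            p: [rec.tokens for rec in records if rec.period == p]
            for p in ("pre", "post")
        }
        models = {}
        for p in ("pre", "post"):
            scfg = dataclasses.replace(
                cfg.sgns, seed=stage_seed(cfg.seed, f"sgns_{p}")
            )
            models[p] = trust.train_sgns(period_docs[p], scfg)
            models[p].save_word2vec(outdir / f"embeddings_{p}.txt")
        report = trust.compare_periods(
            models["pre"], models["post"], cfg.anchors, cfg.terms
        )
        report.to_csv(outdir / "trust_report.csv")
        manifest["outputs"]["trust_report"] = "trust_report.csv"
        manifest["stages"].append(stage)

        stage = "term_volume"
        neg, pos = volume.split_by_polarity(records, results)
        table = volume.volume_table(neg, pos, cfg.terms)
        table.to_csv(outdir / "volume_table.csv")
        tfidf_docs = [
            ingest.filter_tokens(rec.tokens, cfg.lda_stop_words) for rec in records
        ]
        tfidf = volume.compute_tfidf(tfidf_docs)
        exemplar_path = outdir / "exemplars.jsonl"
        exemplar_path.write_text("")
        all_terms = cfg.terms.clinician + cfg.terms.health_information
        for term in all_terms:
            ex = volume.select_exemplars(tfidf, records, term, cfg.tfidf_quantile)
            volume.export_exemplars(ex, term, exemplar_path, append=True)
        manifest["outputs"]["volume_table"] = "volume_table.csv"
        manifest["outputs"]["exemplars"] = "exemplars.jsonl"
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - manifest must name the stage
        partial = outdir / "manifest_partial.json"
        with partial.open("w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise StageError(stage, manifest, exc) from exc

    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_demo(seed: int, outdir: str | Path, spec=None, cfg: PipelineConfig | None = None) -> dict:
    """Generate the desk-scale synthetic corpus and run every stage on it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else synthetic.demo_spec(
        seed=stage_seed(seed, "corpus")
    )
    records, gt = synthetic.generate_corpus(spec)
    corpus_path = outdir / "corpus.jsonl"
    synthetic.write_corpus_jsonl(records, corpus_path)
    gt.to_json(outdir / "ground_truth.json")
    if cfg is None:
        cfg = demo_pipeline_config(seed, spec)
    manifest = run_all(cfg, corpus_path, outdir)
    return manifest


def demo_pipeline_config(seed: int, spec) -> PipelineConfig:
    """Stage settings sized for the desk-scale demo corpus."""
    return PipelineConfig(
        period=PeriodConfig(
            pre_start=spec.pre_start, boundary=spec.pre_end, end=spec.post_end
        ),
        lda=LdaConfig(n_topics=5, alpha=0.1, n_iterations=150, burn_in=50),
        topic_threshold=0.95,
        impact_engagement=ImpactConfig(
            scale="log1p", n_chains=2, n_iterations=1000, burn_in=250
        ),
        impact_sentiment=ImpactConfig(
            scale="raw", n_chains=2, n_iterations=1000, burn_in=250
        ),
        sgns=SgnsConfig(dim=50, epochs=5, min_count=5),
        seed=seed,
    )


def make_report(outdir: str | Path) -> Path:
    """Render report.md plus figures from the stage files (never recomputes).

    Missing stage outputs produce a placeholder section instead of failing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    lines = ["# Analysis report", ""]

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append("## Corpus funnel")
        for key in ("read", "deduplicated", "period_labeled", "topic_filtered"):
            if key in manifest.get("counts", {}):
                lines.append(f"- {key}: {manifest['counts'][key]}")
        lines.append("")
    else:
        manifest = {}
        lines.append("_manifest missing_\n")

    top_terms_path = outdir / "topic_top_terms.csv"
    lines.append("## Topic top terms")
    if top_terms_path.exists():
        df = pd.read_csv(top_terms_path)
        sel = manifest.get("selected_topics", sorted(df["topic"].unique())[:2])
        fig, axes = plt.subplots(1, max(len(sel), 1), figsize=(5 * max(len(sel), 1), 4))
        axes = np.atleast_1d(axes)
        for ax, k in zip(axes, sel):
            sub = df[df["topic"] == k].head(10)
            ax.barh(sub["term"], sub["weight"])
            ax.invert_yaxis()
            ax.set_title(f"Topic {k}")
        fig.tight_layout()
        fig.savefig(figdir / "topic_top_terms.png", dpi=100)
        plt.close(fig)
        lines.append("![top terms](figures/topic_top_terms.png)")
        for k in sel:
            terms = ", ".join(df[df["topic"] == k].head(5)["term"])
            lines.append(f"- topic {k} top terms: {terms}")
    else:
        lines.append("_topic stage output missing_")
    lines.append("")

    for name in ("engagement", "sentiment"):
        lines.append(f"## Counterfactual impact: {name}")
        csv_path = outdir / f"impact_{name}.csv"
        json_path = outdir / f"impact_{name}.json"
        series_path = outdir / f"{name}.csv"
        if csv_path.exists() and json_path.exists() and series_path.exists():
            eff = pd.read_csv(csv_path, parse_dates=["date"])
            ser = pd.read_csv(series_path, parse_dates=["date"])
            summ = json.loads(json_path.read_text())
            fig, axes = plt.subplots(3, 1, figsize=(8, 8), sharex=True)
            axes[0].plot(ser["date"], ser["value"], "k-", lw=0.8, label="observed")
            axes[0].plot(eff["date"], eff["predicted"], "b-", label="counterfactual")
            axes[0].fill_between(eff["date"], eff["lower"], eff["upper"], alpha=0.2)
            axes[0].legend()
            axes[0].set_title(f"{name}: observed vs counterfactual")
            axes[1].plot(eff["date"], eff["point_effect"], "b-")
            axes[1].axhline(0, color="grey", lw=0.5)
            axes[1].set_title("pointwise effect")
            axes[2].plot(eff["date"], eff["cum_effect"], "b-")
            axes[2].axhline(0, color="grey", lw=0.5)
            axes[2].set_title("cumulative effect")
            fig.tight_layout()
            fig.savefig(figdir / f"impact_{name}.png", dpi=100)
            plt.close(fig)
            lines.append(f"![impact {name}](figures/impact_{name}.png)")
            lines.append(
                f"- relative effect: {summ['rel_effect_pct']:.2f}% "
                f"(CI {summ['rel_ci_pct'][0]:.2f}% to {summ['rel_ci_pct'][1]:.2f}%), "
                f"tail-area p = {summ['p_value']:.4g}"
            )
        else:
            lines.append("_impact stage output missing_")
        lines.append("")

    lines.append("## Trust-dimension projections")
    trust_path = outdir / "trust_report.csv"
    if trust_path.exists():
        df = pd.read_csv(trust_path)
        scored = df.dropna(subset=["score"])
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, group in zip(axes, sorted(scored["group"].unique())):
            sub = scored[scored["group"] == group]
            for period, color in (("pre", "tab:blue"), ("post", "tab:orange")):
                pp = sub[sub["period"] == period]
                ax.scatter(pp["score"], pp["term"], label=period, color=color)
            ax.axvline(0, color="grey", lw=0.5)
            ax.set_title(group)
            ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / "trust_axis.png", dpi=100)
        plt.close(fig)
        lines.append("![trust axis](figures/trust_axis.png)")
        for _, row in scored.iterrows():
            lines.append(
                f"- {row['term']} ({row['period']}): {row['score']:.4f}"
            )
    else:
        lines.append("_trust stage output missing_")
    lines.append("")

    lines.append("## Term volumes by sentiment")
    vol_path = outdir / "volume_table.csv"
    if vol_path.exists():
        df = pd.read_csv(vol_path)
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, polarity in zip(axes, ("negative", "positive")):
            sub = df[df["polarity"] == polarity]
            for period, color in (("pre", "tab:blue"), ("post", "tab:orange")):
                pp = sub[sub["period"] == period]
                ax.scatter(pp["zscore"], pp["term"], label=period, color=color)
            ax.set_title(f"{polarity} sentiment")
            ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / "volume.png", dpi=100)
        plt.close(fig)
        lines.append("![volumes](figures/volume.png)")
    else:
        lines.append("_volume stage output missing_")
    lines.append("")

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
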