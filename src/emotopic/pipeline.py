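"""End-to-end orchestration: clean → filter → segment → classify →
aggregate → topic sweep → summaries → daily series, with a run manifest.

A run writes all stage outputs under one directory and records per-stage
record counts plus the SHA-256 of every output file in ``manifest.json``.
Re-running with the same config and seed reproduces every output
bit-for-bit (the manifest contains no wall-clock values).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.signal import find_peaks

from . import __version__
from .evaluation import (LabelVectorPair, cohen_kappa, confusion_matrix,
                         prf_multiclass, validity_gate)
from .lexicon import EMOTIONS, load_lexicon, load_stopwords
from .preprocess import (RawPost, preprocess_corpus, read_corpus,
                         write_tokenized_jsonl)
from .sentiment import classify_corpus, corpus_proportions, keyword_tables
from .topic_model import BowCorpus, fit_lda, summarize_topics, sweep_k

log = logging.getLogger("emotopic")


@dataclass
class RunConfig:
    corpus_path: str
    lexicon_path: str
    out_dir: str
    stopwords_path: str | None = None
    user_dict_path: str | None = None      # extra segmentation vocabulary
    gold_labels_path: str | None = None
    # preprocessing
    min_chars: int = 10
    # sentiment
    weighting: str = "intensity"
    use_aux: bool = True
    include_neutral: bool = False
    top_k: int = 10
    # topic model
    k_min: int = 1
    k_max: int = 15
    lda_alpha: float | None = None
    lda_beta: float = 0.01
    iterations: int = 1000
    burn_in: int = 200
    seed: int = 0
    topN: int = 10
    min_count: int = 1
    # evaluation
    averaging: str = "macro"
    thresholds: dict[str, float] = field(
        default_factory=lambda: {"accuracy": 0.85, "recall": 0.80, "f1": 0.80})

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML or JSON; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update(overrides)
        return cls(**raw)


@dataclass
class DailySeries:
    days: list[date]           # consecutive calendar days, first to last post
    counts: np.ndarray         # posts per day, zeros for empty days
    peaks: list[date]          # interior local maxima above the prominence

    def to_rows(self) -> list[dict]:
        peakset = set(self.peaks)
        return [{"date": d.isoformat(), "count": int(c),
                 "peak": d in peakset}
                for d, c in zip(self.days, self.counts)]


def daily_counts(posts: Sequence[RawPost], prominence: float = 0.0) -> DailySeries:
    """Posts per calendar day over the full observed range (empty days as
    zeros); peaks are interior local maxima exceeding both neighbours with
    at least the given prominence.  Days are half-open [00:00, 24:00)
    intervals of the timestamps as given (no timezone conversion)."""
    stamps = []
    for p in posts:
        try:
            stamps.append(datetime.fromisoformat(p.timestamp).date())
        except ValueError as exc:
            raise ValueError(f"post {p.post_id!r}: unparseable timestamp "
                             f"{p.timestamp!r}") from exc
    if not stamps:
        return DailySeries(days=[], counts=np.zeros(0, dtype=int), peaks=[])
    first, last = min(stamps), max(stamps)
    days = [first + timedelta(days=i) for i in range((last - first).days + 1)]
    index = {d: i for i, d in enumerate(days)}
    counts = np.zeros(len(days), dtype=int)
    for d in stamps:
        counts[index[d]] += 1
    peak_idx, _ = find_peaks(counts, prominence=prominence or None)
    return DailySeries(days=days, counts=counts,
                       peaks=[days[i] for i in peak_idx])


# ---------------------------------------------------------------------------
# output writers


def _write_csv(path: Path, fieldnames: list[str], rows: Sequence[Mapping]) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, ensure_ascii=False, sort_keys=True, indent=1),
                    encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure writes a ``FAILED`` marker naming the stage and
    re-raises; already-written stage outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {"config": asdict(config), "version": __version__,
                      "stages": {}, "outputs": {}, "warnings": []}
    stage = "init"
    try:
        stage = "load"
        posts = read_corpus(config.corpus_path)
        lexicon = load_lexicon(config.lexicon_path)
        stopwords = (load_stopwords(config.stopwords_path)
                     if config.stopwords_path else frozenset())
        user_dict = (load_stopwords(config.user_dict_path)
                     if config.user_dict_path else frozenset())
        manifest["stages"]["load"] = {"n_posts": len(posts),
                                      "n_lexicon": len(lexicon),
                                      "n_stopwords": len(stopwords)}
        log.info("loaded %d posts, %d lexicon entries", len(posts), len(lexicon))

        stage = "preprocess"
        docs, dropped = preprocess_corpus(
            posts, lexicon, stopwords=stopwords, min_chars=config.min_chars,
            user_dict=user_dict | stopwords)
        write_tokenized_jsonl(docs, out / "cleaned.jsonl")
        manifest["stages"]["preprocess"] = {
            "n_input": len(posts), "n_retained": len(docs), "n_dropped": dropped}
        assert len(docs) + dropped == len(posts)
        retained_ids = {d.post_id for d in docs}
        retained_posts = [p for p in posts if p.post_id in retained_ids]

        stage = "classify"
        profiles = classify_corpus(docs, lexicon, use_aux=config.use_aux,
                                   weighting=config.weighting)
        with (out / "profiles.jsonl").open("w", encoding="utf-8") as pfh:
            for p in profiles:
                pfh.write(json.dumps(p.as_record(), ensure_ascii=False,
                                     sort_keys=True) + "\n")
        summary = corpus_proportions(profiles,
                                     include_neutral=config.include_neutral)
        if summary.degenerate:
            manifest["warnings"].append(
                "empty corpus: no document carries any lexicon word; "
                "emotion proportions are undefined (reported as zeros)")
        _write_json(out / "summary.json", {
            "proportions": summary.proportions,
            "n_classified": summary.n_classified,
            "n_neutral": summary.n_neutral,
            "degenerate": summary.degenerate})
        manifest["stages"]["classify"] = {
            "n_classified": summary.n_classified, "n_neutral": summary.n_neutral}

        stage = "keywords"
        (out / "keywords").mkdir(exist_ok=True)
        for emotion, stats in keyword_tables(docs, lexicon, k=config.top_k).items():
            _write_csv(out / "keywords" / f"{emotion}.csv",
                       ["word", "frequency", "pos_class", "intensity"],
                       [vars(s) for s in stats])

        stage = "topic_model"
        bow = BowCorpus.from_tokenized([d.tokens for d in docs],
                                       min_count=config.min_count)
        if bow.n_tokens == 0 or bow.V == 0:
            manifest["warnings"].append(
                "empty corpus: no tokens survive preprocessing; "
                "topic modelling skipped")
        else:
            ks = range(config.k_min, config.k_max + 1)
            sweep = sweep_k(bow, ks, alpha=config.lda_alpha, beta=config.lda_beta,
                            iterations=config.iterations, burn_in=config.burn_in,
                            seed=config.seed, topN=config.topN)
            _write_csv(out / "ksweep.csv",
                       ["K", "perplexity", "log_perplexity", "coherence"],
                       sweep.to_rows())
            manifest["stages"]["topic_model"] = {
                "selected_K": sweep.selected_K, "V": bow.V,
                "n_tokens": bow.n_tokens}
            model = fit_lda(bow, sweep.selected_K, alpha=config.lda_alpha,
                            beta=config.lda_beta, iterations=config.iterations,
                            burn_in=config.burn_in,
                            seed=config.seed + sweep.selected_K)
            topics = summarize_topics(model, bow, topN=config.topN)
            (out / "topics").mkdir(exist_ok=True)
            _write_csv(out / "topics" / "topic_keywords.csv",
                       ["topic", "rank", "keyword", "probability"],
                       [{"topic": k, "rank": r + 1, "keyword": w,
                         "probability": f"{p:.6g}"}
                        for k, pairs in enumerate(topics.topics)
                        for r, (w, p) in enumerate(pairs)])
            _write_csv(out / "topics" / "topic_intensity.csv",
                       ["topic", "intensity"],
                       [{"topic": k, "intensity": f"{v:.6g}"}
                        for k, v in enumerate(topics.intensity)])

        stage = "daily_series"
        series = daily_counts(retained_posts)
        _write_csv(out / "daily_counts.csv", ["date", "count", "peak"],
                   series.to_rows())
        manifest["stages"]["daily_series"] = {
            "n_days": len(series.days),
            "n_peaks": len(series.peaks),
            "total": int(series.counts.sum())}

        if config.gold_labels_path:
            stage = "evaluation"
            gold = _read_labels(config.gold_labels_path)
            pred = {p.post_id: p.dominant for p in profiles}
            common = [i for i in gold if pred.get(i) is not None]
            (out / "evaluation").mkdir(exist_ok=True)
            if common:
                pair = LabelVectorPair.from_sequences(
                    [gold[i] for i in common], [pred[i] for i in common],
                    ids=common)
                report = prf_multiclass(pair, averaging=config.averaging)
                gates = validity_gate(report, config.thresholds)
                agreement = cohen_kappa(pair)
                _write_json(out / "evaluation" / "validity.json", {
                    "accuracy": report.accuracy, "precision": report.precision,
                    "recall": report.recall, "f1": report.f1,
                    "averaging": report.averaging,
                    "per_class": dict(report.per_class),
                    "gates": gates,
                    "kappa": None if agreement.degenerate else agreement.kappa,
                    "n": len(common)})
                cm = confusion_matrix(pair)
                _write_csv(out / "evaluation" / "confusion.csv",
                           ["label"] + list(cm.labels),
                           [{"label": lab, **{c: int(cm.matrix[i, j])
                                              for j, c in enumerate(cm.labels)}}
                            for i, lab in enumerate(cm.labels)])
                manifest["stages"]["evaluation"] = {"n_evaluated": len(common)}
            else:
                manifest["warnings"].append(
                    "evaluation skipped: no overlap between gold labels and "
                    "classified documents")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n", encoding="utf-8")
        log.removeHandler(fh)
        fh.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name not in ("manifest.json", "run.log"):
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    _write_json(out / "manifest.json", manifest)
    log.info("run complete: %s", out)
    log.removeHandler(fh)
    fh.close()
    return out


def _read_labels(path: str | Path) -> dict[str, str]:
    """Gold/predicted labels as CSV with columns post_id, label."""
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        return {str(r["post_id"]): r["label"] for r in reader}
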