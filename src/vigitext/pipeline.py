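"""End-to-end pipeline orchestration.

Sequences the analysis stages over a synthetic (or ingested) corpus:
generate/ingest → parse → label (ground truth in oracle mode, otherwise
the trained classifier) → frequency/covariate statistics → co-occurrence
network → registry harmonization → vaccine-profile distances.  Every
emitted file is listed in a JSON manifest together with the seed, a config
hash and per-file content hashes, so a rerun with the same configuration
is verifiably bit-identical.
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

from . import classify, harmonize, network, parsing, profiles, stats, synthetic, tables
from .labels import SYMPTOMS

logger = logging.getLogger("vigitext.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass(frozen=True)
class PipelineConfig:
    """What to run and where to write it.

    Exactly one input source: a synthetic-corpus configuration or a path
    to an existing JSONL message file (the latter runs without ground
    truth, so labelling requires a trained model and oracle mode is
    unavailable).
    """

    output_dir: str | Path
    synthetic: synthetic.SyntheticConfig | None = None
    input_path: str | Path | None = None
    seed: int = 0
    oracle_mode: bool = True
    backend: str = "linear"
    cv_folds: int = 5
    threshold: float = 0.5
    run_stats: bool = True
    run_network: bool = True
    run_harmonization: bool = True
    run_profiles: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_path is None):
            raise ValueError("exactly one of synthetic / input_path must be set")
        if self.input_path is not None and self.oracle_mode:
            raise ValueError("oracle mode needs a synthetic corpus with ground truth")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(dataclasses.asdict(config)).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; return the manifest (also written).

    A stage failure aborts with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "outputs": {},
    }

    def emit(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    stage = "ingest"
    try:
        if config.synthetic is not None:
            logger.info("generating synthetic corpus (n=%d)", config.synthetic.n_messages)
            messages, records = synthetic.generate_corpus(config.synthetic)
            corpus_path = outdir / "corpus.jsonl"
            synthetic.write_corpus_jsonl(messages, corpus_path, seed=config.synthetic.seed)
            truth_path = outdir / "ground_truth.csv"
            synthetic.write_ground_truth(records, truth_path)
            emit(stage, "corpus", corpus_path)
            emit(stage, "ground_truth", truth_path)
        else:
            messages = synthetic.read_corpus_jsonl(config.input_path)
            records = None

        stage = "parse"
        reports = parsing.parse_corpus(messages)
        parsed_path = outdir / "parsed.csv"
        parsing.write_parsed_csv(reports, parsed_path)
        emit(stage, "parsed", parsed_path)

        stage = "label"
        if config.oracle_mode:
            labelsets = np.stack([r.true_labels for r in records])
        else:
            if records is None:
                raise PipelineError(
                    "labelling an ingested corpus needs a trained model; "
                    "use the classifier interface directly"
                )
            examples = classify.examples_from_corpus(messages, records)
            model = classify.train(examples, backend_spec=config.backend, seed=config.seed)
            scores = model.predict_scores([m.text for m in messages])
            labelsets = scores >= config.threshold
        labels_path = outdir / "labels.csv"
        lab = pd.DataFrame(labelsets, columns=SYMPTOMS)
        lab.insert(0, "message_id", [m.message_id for m in messages])
        lab.to_csv(labels_path, index=False)
        emit(stage, "labels", labels_path)

        if config.run_stats:
            stage = "stats"
            _stats_stage(outdir, emit, reports, labelsets)
        if config.run_network:
            stage = "network"
            _network_stage(outdir, emit, labelsets, config.seed)
        if config.run_harmonization:
            stage = "harmonization"
            _harmonization_stage(outdir, emit, labelsets)
        if config.run_profiles:
            stage = "profiles"
            _profiles_stage(outdir, emit)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stats_stage(outdir: Path, emit, reports, labelsets) -> None:
    freq = stats.frequency_table(labelsets, denominator=len(labelsets))
    path = outdir / "frequencies.csv"
    freq.to_csv(path)
    emit("stats", "frequencies", path)

    counts = labelsets.sum(axis=1)
    genders = np.array([r.gender for r in reports])
    frames = []
    if (genders == "female").any() and (genders == "male").any():
        comp = stats.mann_whitney_compare(
            counts[genders == "female"], counts[genders == "male"], "female", "male"
        )
        frames.append(comp.to_frame().assign(variable="gender"))
    doses = np.array([r.dose for r in reports])
    if (doses == "first").any() and (doses == "second").any():
        comp = stats.mann_whitney_compare(
            counts[doses == "first"], counts[doses == "second"], "first", "second"
        )
        frames.append(comp.to_frame().assign(variable="dose"))
    if frames:
        path = outdir / "group_comparisons.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        emit("stats", "group_comparisons", path)

    ages = np.array([r.age if r.age is not None else np.nan for r in reports], float)
    has_age = ~np.isnan(ages)
    if has_age.sum() >= 3 and np.ptp(ages[has_age]) > 0:
        fit = stats.fit_age_slope(ages[has_age], counts[has_age])
        path = outdir / "age_regression.csv"
        pd.DataFrame(
            [
                {
                    "slope_magnitude": fit.slope,
                    "direction": fit.direction,
                    "intercept": fit.intercept,
                    "slope_se": fit.slope_se,
                    "p": fit.p_value,
                    "n": fit.n,
                }
            ]
        ).to_csv(path, index=False)
        emit("stats", "age_regression", path)


def _network_stage(outdir: Path, emit, labelsets, seed: int) -> None:
    corr, degenerate = network.cooccurrence_matrix(labelsets)
    prevalences = labelsets.mean(axis=0)
    graph = network.build_network(corr, prevalences)
    edges_path = outdir / "cooccurrence_edges.tsv"
    network.write_edge_list(graph, edges_path)
    emit("network", "edges", edges_path)
    graphml_path = outdir / "cooccurrence.graphml"
    network.write_graphml(graph, graphml_path)
    emit("network", "graphml", graphml_path)
    partition = network.detect_communities(graph, seed=seed)
    comm_path = outdir / "communities.csv"
    partition.to_frame().to_csv(comm_path, index=False)
    emit("network", "communities", comm_path)


def _harmonization_stage(outdir: Path, emit, labelsets) -> None:
    registry = harmonize.registry_frequency_table(labelsets)
    path = outdir / "registry_categories.csv"
    registry.to_csv(path)
    emit("harmonization", "registry_categories", path)

    trial = harmonize.aggregate_trial_categories(
        tables.load_trial_source_table(), harmonize.moscow_trial_rules()
    )
    path = outdir / "trial_harmonized.csv"
    trial.to_csv(path)
    emit("harmonization", "trial_harmonized", path)


def _profiles_stage(outdir: Path, emit) -> None:
    prof = tables.load_vaccine_profiles()
    matrix = profiles.distance_matrix(prof)
    path = outdir / "profile_distances.csv"
    matrix.to_csv(path)
    emit("profiles", "distance_matrix", path)

    sputnik = tables.sputnik_profile()
    agg = profiles.platform_distances(sputnik, prof, aggregate="sum")
    path = outdir / "platform_distances.csv"
    pd.DataFrame([agg]).to_csv(path, index=False)
    emit("profiles", "platform_distances", path)
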