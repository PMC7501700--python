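"""End-to-end orchestration: load -> predict -> assemble -> analyze ->
prioritize -> screen, from a single config, with a run manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records input digests and per-stage counts so re-runs are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from . import __version__
from . import io as npio
from .datamodel import PipelineConfig, ValidationReport
from .diffusion import NetworkTargetPredictor
from .enrichment import CompoundDiseasePrioritizer
from .network import assemble_network, degree_summary, herb_overlap
from .screening import four_step_screen

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    counts: dict[str, int]
    seed: int
    version: str
    started: str
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    Emits ``predicted.tsv`` (diffusion predictions), ``network.tsv``
    (global known+predicted network), ``degrees.tsv``, ``overlaps.tsv``
    (per-herb shared compounds and targets), ``enrich.tsv`` (per-compound
    Fisher/BH records), ``report.tsv`` (four-step screen audit) and
    ``manifest.json``.
    """
    started = datetime.now(timezone.utc).isoformat()
    if config.out_dir is None:
        raise PipelineError("setup", "config.out_dir is not set")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    required = {
        "load": [
            ("compounds_path", config.compounds_path),
            ("herbs_path", config.herbs_path),
            ("dti_path", config.dti_path),
            ("disease_path", config.disease_path),
        ],
        "predict": [("fingerprints_path", config.fingerprints_path)],
    }
    digests: dict[str, str] = {}
    for stage, paths in required.items():
        for key, p in paths:
            if p is None or not Path(p).exists():
                raise PipelineError(stage, f"missing input file for {key}: {p}")
            digests[key] = _digest(p)
    if config.main_components_path is not None:
        if not Path(config.main_components_path).exists():
            raise PipelineError(
                "screen", f"missing input file: {config.main_components_path}"
            )
        digests["main_components_path"] = _digest(config.main_components_path)

    counts: dict[str, int] = {}

    load = _stage("load")(
        lambda: (
            npio.read_compound_table(config.compounds_path),
            npio.read_herb_table(config.herbs_path),
            npio.read_fingerprint_table(config.fingerprints_path),
            npio.read_dti_table(config.dti_path),
            npio.read_gene_sets_gmt(config.disease_path),
        )
    )
    compounds, herbs, fingerprints, known_dtis, gene_sets = load()
    report: ValidationReport = npio.validate_dataset(
        compounds, herbs, fingerprints, known_dtis, gene_sets
    )
    for msg in report.warnings:
        log.warning("%s", msg)
    disease = gene_sets[0]
    counts.update(
        compounds=len(compounds),
        herbs=len(herbs),
        known_dtis=len(known_dtis),
        disease_genes=len(disease),
    )

    @_stage("predict")
    def predict():
        predictor = NetworkTargetPredictor(
            alpha=config.alpha,
            beta=config.beta,
            gamma=config.gamma,
            k=config.k,
            top_n=config.top_n,
        ).fit(fingerprints, known_dtis)
        records = predictor.predict_records()
        npio.write_dti_table(records, out / "predicted.tsv")
        return records

    predicted = predict()
    counts["predicted_dtis"] = len(predicted)

    @_stage("network")
    def build():
        net = assemble_network(known_dtis, predicted)
        npio.write_network_tsv(net, out / "network.tsv")
        summary = degree_summary(net)
        summary.degree_table.to_csv(out / "degrees.tsv", sep="\t", index=False)
        rows = []
        for item in ("compounds", "targets"):
            m = herb_overlap(herbs, item, net)
            frame = m.counts.reset_index(names="herb_id")
            frame.insert(0, "item", item)
            rows.append(frame)
        import pandas as pd

        pd.concat(rows).to_csv(out / "overlaps.tsv", sep="\t", index=False)
        return net, summary

    net, summary = build()
    counts["network_edges"] = net.n_edges
    counts["network_edges_known"] = net.edge_count("known")
    counts["network_edges_predicted"] = net.edge_count("predicted")
    counts["network_compounds"] = len(net.compounds)
    counts["network_targets"] = len(net.targets)

    @_stage("prioritize")
    def prioritize():
        model = CompoundDiseasePrioritizer(
            universe_policy=config.universe_policy, q_star=config.q_star
        ).fit(net, disease)
        frame = _enrichment_frame(model)
        frame.to_csv(out / "enrich.tsv", sep="\t", index=False)
        return model

    prioritizer = prioritize()
    counts["compounds_tested"] = len(prioritizer.records_)
    counts["compounds_significant"] = len(prioritizer.significant_)

    @_stage("screen")
    def screen():
        if config.main_components_path is not None:
            with open(config.main_components_path) as fh:
                main = {line.strip() for line in fh if line.strip()}
        else:
            # no HPLC list supplied: every compound is a candidate
            main = {c.compound_id for c in compounds}
        rep = four_step_screen(
            main,
            compounds,
            prioritizer.records_,
            admet_threshold=config.admet_threshold,
            q_star=config.q_star,
        )
        rep.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
        return rep

    screen_report = screen()
    counts["retained"] = len(screen_report.retained)

    manifest = RunManifest(
        config=config.to_dict(),
        input_digests=digests,
        counts=counts,
        seed=config.seed,
        version=__version__,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    return manifest


def _enrichment_frame(model: CompoundDiseasePrioritizer):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
            }
            for r in model.records_
        ]
    )
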