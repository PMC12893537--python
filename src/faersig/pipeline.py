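"""End-to-end pipeline: ingest -> dedup -> PS filter -> contingency ->
prior fit -> scoring -> strata/exclusion/comparator/onset -> export.

Every run writes a manifest (config hash, seed, per-stage row counts) so
that identical configurations reproduce byte-identical outputs, and a
quality log so nothing is dropped silently.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import contingency, ingest, profiles, stats
from .errors import ConfigError, StageError
from .records import QualityLog, ReportRecord
from .synthetic import SyntheticConfig, write_ascii
from .vocab import (
    DrugDictionary,
    VocabularyMap,
    load_default_drug_dictionary,
    load_drug_dictionary,
    load_toy_vocabulary,
    load_vocabulary,
)

logger = logging.getLogger("faersig")

DEFAULT_PROFILE_PTS = (
    "haematoma",
    "haemorrhage",
    "muscle haemorrhage",
    "heparin-induced thrombocytopenia",
    "thrombosis with thrombocytopenia syndrome",
)


@dataclass
class RunConfig:
    """Full analysis specification; exactly one of input_paths / synthetic."""

    target_drug: str
    input_paths: Optional[list[str]] = None
    synthetic: Optional[SyntheticConfig] = None
    vocabulary_path: Optional[str] = None
    dictionary_path: Optional[str] = None
    thresholds: stats.Thresholds = field(default_factory=stats.Thresholds)
    strata: list[str] = field(default_factory=lambda: ["age_group", "sex"])
    run_exclusion: bool = True
    comparators: list[str] = field(default_factory=list)
    profile_pts: list[str] = field(default_factory=lambda: list(DEFAULT_PROFILE_PTS))
    outdir: str = "faersig_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_paths is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_paths or synthetic must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "thresholds" in d and d["thresholds"] is not None:
            d["thresholds"] = stats.Thresholds(**d["thresholds"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(
    config: RunConfig, workdir: Path
) -> tuple[list[ReportRecord], VocabularyMap, DrugDictionary, QualityLog]:
    if config.dictionary_path:
        ddict = load_drug_dictionary(config.dictionary_path)
    else:
        ddict = load_default_drug_dictionary()
    if config.synthetic is not None:
        ascii_dir = workdir / "ascii"
        paths = write_ascii(config.synthetic, ascii_dir, seed=config.seed)
        vocab = (
            load_vocabulary(config.vocabulary_path)
            if config.vocabulary_path
            else config.synthetic.vocabulary()
        )
    else:
        paths = [Path(p) for p in config.input_paths or []]
        vocab = (
            load_vocabulary(config.vocabulary_path)
            if config.vocabulary_path
            else load_toy_vocabulary()
        )
    records, qlog = ingest.load_reports(paths, ddict)
    return records, vocab, ddict, qlog


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Any stage failure removes partial outputs and raises a StageError
    naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "target_drug": config.target_drug,
        "counting_unit": "(report, event-label) pair",
        "stages": {},
    }
    stage = "ingest"
    try:
        records, vocab, ddict, qlog = _load_inputs(config, outdir)
        manifest["stages"]["ingest"] = len(records)
        logger.info("ingest: %d report versions", len(records))

        stage = "dedup"
        deduped = ingest.deduplicate(records)
        manifest["stages"]["dedup"] = len(deduped)

        stage = "ps_filter"
        target_std, _ = ddict.classify(config.target_drug)
        target_reports = ingest.select_primary_suspect(deduped, target_std)
        manifest["stages"]["ps_filter"] = len(target_reports)
        logger.info(
            "dedup: %d cases; %d with %s as primary suspect",
            len(deduped), len(target_reports), target_std,
        )

        stage = "contingency"
        pt_tables = contingency.build_tables(deduped, target_std, vocab, level="PT")
        soc_tables = contingency.soc_rollup(deduped, target_std, vocab)
        contingency.tables_to_frame(pt_tables).to_csv(outdir / "contingency_pt.csv", index=False)
        contingency.tables_to_frame(soc_tables).to_csv(outdir / "contingency_soc.csv", index=False)
        manifest["stages"]["contingency_pt"] = len(pt_tables)
        manifest["stages"]["contingency_soc"] = len(soc_tables)

        stage = "fit_mgps"
        cells = contingency.all_pair_tables(deduped, vocab, level="PT")
        fit = stats.fit_mgps(cells)
        manifest["mgps"] = {
            **dataclasses.asdict(fit.params),
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_cells": fit.n_cells,
        }
        with open(outdir / "hyperparams.json", "w", encoding="utf-8") as fh:
            json.dump(manifest["mgps"], fh, indent=1)

        stage = "score"
        th = config.thresholds
        signals_pt = stats.score_tables(pt_tables, fit.params, th)
        signals_soc = stats.score_tables(soc_tables, fit.params, th)
        signals_pt.to_csv(outdir / "signals_pt.csv", index=False)
        signals_soc.to_csv(outdir / "signals_soc.csv", index=False)
        manifest["stages"]["signals_pt"] = int(signals_pt["flag_combined"].sum())
        manifest["stages"]["signals_soc"] = int(signals_soc["flag_combined"].sum())

        stage = "profiles"
        profiles.demographics(target_reports).to_csv(outdir / "demographics.csv", index=False)
        onset = profiles.onset_analysis(target_reports)
        onset.to_frame().to_csv(outdir / "onset.csv", index=False)
        qlog = qlog.merge(onset.quality)
        profiles.concomitant_profile(
            deduped, target_std, config.profile_pts, ddict
        ).to_csv(outdir / "concomitant_profile.csv", index=False)

        for dim in config.strata:
            strat = profiles.stratified_signal_tables(
                deduped, target_std, profiles.StratumSpec(dim), vocab, fit.params,
                thresholds=th,
            )
            strat.to_csv(outdir / f"signals_by_{dim}.csv", index=False)

        if config.run_exclusion:
            stage = "exclusion"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                excl = profiles.exclusion_analysis(
                    deduped, target_std, ddict, vocab, fit.params, thresholds=th
                )
            excl.to_csv(outdir / "signals_exclusion.csv", index=False)
            manifest["stages"]["exclusion_signals"] = int(excl["flag_combined"].sum()) if len(excl) else 0

        if config.comparators:
            stage = "comparators"
            comp_std = [ddict.classify(c)[0] for c in config.comparators]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = profiles.comparator_analysis(
                    deduped, comp_std, vocab, fit.params, thresholds=th
                )
            comp.to_csv(outdir / "signals_comparators.csv", index=False)

        stage = "export"
        (outdir / "quality_log.csv").write_text(qlog.to_csv(), encoding="utf-8")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        # remove partial outputs, keep the directory
        for p in outdir.glob("*"):
            if p.is_file():
                p.unlink()
            else:
                shutil.rmtree(p, ignore_errors=True)
        if isinstance(exc, (ConfigError, StageError)):
            raise
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def load_signal_table(outdir: Path | str, name: str = "signals_pt.csv") -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / name)
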