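"""End-to-end orchestration with a reproducibility manifest.

``run_pipeline`` executes the full chain — simulate (or ingest user
data) -> quantify + screen -> preprocess -> select (x3 methods x FD/SD)
-> vegetation indices -> stratified split -> model grid — writing every
intermediate artifact under a run directory and finishing with a
manifest (config hash, per-stage seeds, SHA-256 digest of every output
file, stage timings).  Stage seeds derive from the master seed through
``numpy.random.SeedSequence.spawn``, so any stage can be re-run in
isolation and deterministic stages regenerate bit-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig, config_hash
from .containers import (SpectraSet, read_sample_table,
                         read_spectra, write_sample_table, write_spectra)
from .evaluate import reports_to_frame, run_model_grid, stratified_split
from .indices import build_feature_matrix
from .preprocess import bandwise_correlation, preprocess_pipeline
from .quantify import quantify_table, screen_samples
from .selection import make_selector
from .simulate import GeneratorParams, generate_dataset

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger(__name__)

#: stage order; each stage gets its own spawned seed
STAGES = ("simulate", "quantify", "preprocess", "select", "indices",
          "split", "train")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)      #: path -> sha256
    timings_s: dict = field(default_factory=dict)
    version: str = __version__
    status: str = "running"

    def record(self, root: Path, *paths: Path) -> None:
        for p in paths:
            self.files[str(Path(p).relative_to(root))] = _digest(Path(p))

    def write(self, root: Path) -> Path:
        out = root / "manifest.json"
        out.write_text(json.dumps({
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "stage_seeds": self.stage_seeds,
            "files": self.files,
            "timings_s": self.timings_s,
            "version": self.version,
            "status": self.status,
        }, indent=1))
        return out


def stage_seeds(master_seed: int) -> dict:
    """Deterministic per-stage seeds spawned from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31 - 1))
            for name, c in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0,
                 out_dir="run", spectra_path=None, samples_path=None,
                 generator: GeneratorParams | None = None,
                 derivatives=("fd", "sd"),
                 selectors=("cars", "sfla", "rfecv"),
                 learners=None) -> RunManifest:
    """Run the full analysis; returns the manifest (also written to disk).

    Supplying ``spectra_path``/``samples_path`` short-circuits the
    simulation stage and runs the pipeline on user data instead.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest = RunManifest(config_hash=config_hash(cfg), master_seed=seed,
                           stage_seeds=seeds)
    log.info("run_pipeline: config %s, master seed %d",
             manifest.config_hash, seed)

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
            def __exit__(self_, *exc):
                manifest.timings_s[name] = round(
                    time.perf_counter() - self_.t0, 3)
        return _T()

    try:
        # -- data ----------------------------------------------------------
        with timed("simulate"):
            if spectra_path is not None and samples_path is not None:
                spectra = read_spectra(spectra_path, kind="raw")
                table = read_sample_table(samples_path)
            else:
                spectra, table = generate_dataset(
                    generator or GeneratorParams(), seed=seeds["simulate"])
            write_spectra(spectra, out / "spectra_raw.csv")
            write_sample_table(table, out / "samples.csv")
        manifest.record(out, out / "spectra_raw.csv", out / "samples.csv")

        # -- quantify + screen ---------------------------------------------
        with timed("quantify"):
            table = quantify_table(table)
            table, screen_report = screen_samples(table)
            keep = [sid in set(table.sample_ids) for sid in
                    spectra.sample_ids]
            keep_idx = np.flatnonzero(keep)
            spectra = SpectraSet(
                spectra.wavelengths_nm, spectra.values[keep_idx],
                [spectra.sample_ids[i] for i in keep_idx],
                spectra.month[keep_idx],
                [spectra.group[i] for i in keep_idx], spectra.kind)
            write_sample_table(table, out / "samples_screened.csv")
            (out / "screening.json").write_text(
                json.dumps(screen_report.to_dict(), indent=1))
        manifest.record(out, out / "samples_screened.csv",
                        out / "screening.json")

        # -- preprocess ------------------------------------------------------
        with timed("preprocess"):
            kinds = preprocess_pipeline(spectra, cfg.resample_interval_nm,
                                        cfg.sg_window, cfg.sg_polyorder)
            y = table.ant
            for kind in ("raw", "smoothed", "fd", "sd"):
                write_spectra(kinds[kind], out / f"spectra_{kind}.csv")
                bandwise_correlation(kinds[kind], y).to_frame().to_csv(
                    out / f"correlation_{kind}.csv", index=False)
        manifest.record(out, *(out / f"spectra_{k}.csv"
                               for k in ("raw", "smoothed", "fd", "sd")),
                        *(out / f"correlation_{k}.csv"
                          for k in ("raw", "smoothed", "fd", "sd")))

        # -- selection -------------------------------------------------------
        with timed("select"):
            sel_rng = np.random.default_rng(seeds["select"])
            selections = {}
            for kind in derivatives:
                s = kinds[kind]
                for method in selectors:
                    sub_seed = int(sel_rng.integers(0, 2 ** 31 - 1))
                    cfg_m = getattr(cfg, method)
                    sel = make_selector(method, s.wavelengths_nm,
                                        seed=sub_seed, config=cfg_m)
                    sel.fit(s.values, y)
                    res = sel.selection_result_
                    selections[(kind, res.method)] = res
                    res.to_json(out / f"selection_{kind}_{method}.json")
        manifest.record(out, *(out / f"selection_{k}_{m}.json"
                               for k in derivatives for m in selectors))

        # -- vegetation indices ---------------------------------------------
        with timed("indices"):
            features = {}
            for (kind, method), res in selections.items():
                s = kinds[kind].select_bands(res.selected_indices)
                fm = build_feature_matrix(s, y, k=cfg.top_k,
                                          families=cfg.index_families)
                features[(kind, method)] = fm
                fm.to_frame().to_csv(
                    out / f"features_{kind}_{method}.csv")
        manifest.record(out, *(out / f"features_{k}_{m}.csv"
                               for (k, m) in features))

        # -- split + models ---------------------------------------------------
        with timed("split"):
            split = stratified_split(y, cfg.split_ratio, cfg.n_strata,
                                     seed=seeds["split"])
            split.to_json(out / "split.json")
        manifest.record(out, out / "split.json")

        with timed("train"):
            reports = run_model_grid(features, y, split, learners=learners,
                                     seed=seeds["train"])
            frame = reports_to_frame(reports)
            frame.to_csv(out / "model_reports.csv", index=False)
            (out / "model_reports.json").write_text(json.dumps(
                [r.to_dict() for r in reports], indent=1))
        manifest.record(out, out / "model_reports.csv",
                        out / "model_reports.json")
        manifest.status = "complete"
    except Exception:
        manifest.status = "failed"
        manifest.write(out)
        raise
    manifest.write(out)
    return manifest
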