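"""End-to-end replay pipeline: simulate -> classify -> REF screen -> kinetics.

`run_pipeline` wires the four analysis stages together under one seeded
configuration, writes every intermediate table, and emits a JSON manifest
(parameters, seeds, SHA-256 of each artifact) plus a human-readable report.
Identical configurations produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from . import kinetics, raman, sip, synthgen
from .errors import ParameterError, StageError

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("sipracs")


@dataclass
class RunConfig:
    """All pipeline parameters with defaults matching the study conditions."""

    seed: int = 0
    outdir: str = "sipracs_out"
    stages: tuple = ("spectra", "classify", "sip", "ref", "kinetics")

    # single-cell Raman screen
    n_cells: int = 150
    n_labeled: int = 10
    noise_sd: float = 0.02
    boundary: float = raman.DEFAULT_BOUNDARY
    band_window: tuple = raman.DEFAULT_BAND_WINDOW
    write_spectra: bool = True

    # SIP experiment / REF screen
    n_asvs: int = 20
    active_ids: tuple = (1,)
    labeling_strength: float = 1.0
    n_replicates: int = 6
    dispersion: float = 500.0
    abundance_min: float = 0.005
    ref_min: float = 1.5

    # kinetics / enzymes
    c0: float = 5.0
    k: float = math.log(5.0 / 2.01) / 7.0
    times: tuple = (0.0, 7.0, 14.0)
    decay_noise_sd: float = 0.25
    enzyme_slope: float = 0.15  # U/ml per % removal
    enzyme_intercept: float = 1.0
    enzyme_noise_sd: float = 0.3
    # spectrum input files (optional; when set, 'classify' reads these
    # instead of the simulated cohort)
    spectra_paths: tuple = ()

    def validate(self) -> None:
        if self.n_cells < 1 or not (0 <= self.n_labeled <= self.n_cells):
            raise ParameterError("need n_cells >= 1 and 0 <= n_labeled <= n_cells")
        unknown = set(self.stages) - {"spectra", "classify", "sip", "ref", "kinetics"}
        if unknown:
            raise ParameterError(f"unknown stage(s): {sorted(unknown)}")
        for p in self.spectra_paths:
            if not Path(p).exists():
                raise ParameterError(f"spectrum input not found: {p}")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(raw) - valid
    if unknown:
        raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("stages", "band_window", "times", "active_ids", "spectra_paths"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and return the manifest.

    Stage order is fixed (simulate spectra -> classify -> simulate SIP ->
    REF screen -> kinetics); any stage failure raises StageError with partial
    outputs retained on disk.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # independent child seeds per stage, all below 2**31
    ss = np.random.SeedSequence(cfg.seed)
    stage_seed = {
        name: int(child.generate_state(1, np.uint32)[0])
        for name, child in zip(
            ("spectra", "sip", "decay", "enzyme"), ss.spawn(4)
        )
    }
    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": stage_seed,
        "parameters": asdict(cfg),
        "outputs": {},
    }
    report: list[str] = ["SIP-RACS replay report", "======================", ""]

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    cohort: list[raman.RamanSpectrum] = []

    if "spectra" in cfg.stages:
        try:
            log.info("stage=spectra n_cells=%d n_labeled=%d seed=%d",
                     cfg.n_cells, cfg.n_labeled, stage_seed["spectra"])
            cohort = synthgen.make_screen_cohort(
                n_cells=cfg.n_cells,
                n_labeled=cfg.n_labeled,
                noise_sd=cfg.noise_sd,
                seed=stage_seed["spectra"],
            )
            if cfg.write_spectra:
                spectra_dir = outdir / "spectra"
                spectra_dir.mkdir(exist_ok=True)
                for s in cohort:
                    sio.write_spectrum(s, spectra_dir / f"{s.cell_id}.tsv")
                register("spectra_first_cell", spectra_dir / f"{cohort[0].cell_id}.tsv")
            report.append(
                f"spectra: simulated {cfg.n_cells} single-cell spectra "
                f"({cfg.n_labeled} labeled, noise_sd={cfg.noise_sd})"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("spectra", str(exc)) from exc

    if "classify" in cfg.stages:
        try:
            if cfg.spectra_paths:
                cohort = [sio.read_spectrum(p) for p in cfg.spectra_paths]
            if not cohort:
                raise StageError("classify", "no spectra to classify")
            results = [
                raman.classify_labeling(
                    raman.preprocess(s), boundary=cfg.boundary, window=tuple(cfg.band_window)
                )
                for s in cohort
            ]
            path = outdir / "classifications.tsv"
            sio.write_classifications(results, path)
            register("classifications", path)
            n_labeled = sum(1 for r in results if r.labeled is True)
            n_indet = sum(1 for r in results if r.labeled is None)
            shifts = [r.shift for r in results if r.labeled]
            mean_shift = float(np.mean(shifts)) if shifts else float("nan")
            manifest["classification"] = {
                "n_cells": len(results),
                "n_labeled": n_labeled,
                "n_indeterminate": n_indet,
                "mean_labeled_shift_cm1": mean_shift,
            }
            report.append(
                f"classify: {n_labeled}/{len(results)} cells called 13C-labeled "
                f"(mean shift {mean_shift:.1f} cm-1, {n_indet} indeterminate)"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("classify", str(exc)) from exc

    t12 = t13 = None
    if "sip" in cfg.stages:
        try:
            design = synthgen.SIPDesign(
                n_asvs=cfg.n_asvs,
                active_ids=frozenset(cfg.active_ids),
                labeling_strength=cfg.labeling_strength,
                n_replicates=cfg.n_replicates,
                dispersion=cfg.dispersion,
                seed=stage_seed["sip"],
            )
            t12, t13 = synthgen.make_sip_experiment(design)
            for table, name in ((t12, "fraction_12C.tsv"), (t13, "fraction_13C.tsv")):
                path = outdir / name
                sio.write_fraction_table(table, path)
                register(name.removesuffix(".tsv"), path)
            report.append(
                f"sip: simulated {cfg.n_asvs}-ASV paired fraction tables "
                f"(active {tuple(sorted(cfg.active_ids))}, "
                f"strength {cfg.labeling_strength}, {cfg.n_replicates} reps/class)"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("sip", str(exc)) from exc

    if "ref" in cfg.stages:
        try:
            if t12 is None:
                raise StageError("ref", "no fraction tables (run the 'sip' stage)")
            scfg = sip.ScreenConfig(abundance_min=cfg.abundance_min, ref_min=cfg.ref_min)
            records = sip.compute_ref(t12, t13, scfg)
            active = sip.screen_active(records, scfg)
            path = outdir / "ref_records.tsv"
            sio.write_ref_records(records, path)
            register("ref_records", path)
            summary = {
                "thresholds": {"abundance_min": scfg.abundance_min, "ref_min": scfg.ref_min},
                "active": [
                    {"asv_id": r.asv_id, "ref": r.ref, "mean_abundance": r.mean_abundance}
                    for r in active
                ],
            }
            path = outdir / "active_asvs.json"
            sio.write_json(summary, path)
            register("active_asvs", path)
            manifest["ref_screen"] = {
                "n_asvs": len(records),
                "n_active": len(active),
                "top_ref": active[0].ref if active else None,
            }
            top = f"{active[0].asv_id} (REF={active[0].ref:.2f})" if active else "none"
            report.append(f"ref: {len(active)} active ASV(s); top: {top}")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("ref", str(exc)) from exc

    if "kinetics" in cfg.stages:
        try:
            design = synthgen.DecayDesign(
                c0=cfg.c0,
                k=cfg.k,
                times=tuple(cfg.times),
                noise_sd=cfg.decay_noise_sd,
                n_replicates=cfg.n_replicates,
                seed=stage_seed["decay"],
            )
            series = synthgen.make_decay_series(design)
            path = outdir / "decay_series.tsv"
            sio.write_decay_series(series, path)
            register("decay_series", path)

            fit = kinetics.fit_first_order(series)
            means = series.replicate_means
            removals = np.array(
                [kinetics.removal_percent(means[0], m) for m in means]
            )
            panel = synthgen.make_enzyme_panel(
                slope=cfg.enzyme_slope,
                intercept=cfg.enzyme_intercept,
                noise_sd=cfg.enzyme_noise_sd,
                removals=removals,
                seed=stage_seed["enzyme"],
            )
            path = outdir / "enzyme_panel.tsv"
            sio.write_enzyme_panel([panel], path)
            register("enzyme_panel", path)
            corr = (
                kinetics.correlate_activity_removal(panel, removals)
                if removals.size >= 3
                else None
            )
            summary = {
                "k_per_day": fit.k,
                "half_life_days": fit.half_life,
                "r_squared": fit.r_squared,
                "removal_percent_by_time": {
                    str(t): kinetics.format_percent(r)
                    for t, r in zip(series.times, removals)
                },
                "enzyme_correlation": (
                    None
                    if corr is None
                    else {"enzyme": panel.enzyme, "r": corr.r, "r_squared": corr.r_squared,
                          "p_value": corr.p_value}
                ),
            }
            path = outdir / "kinetics.json"
            sio.write_json(summary, path)
            register("kinetics", path)
            manifest["kinetics"] = summary
            final = kinetics.format_percent(removals[-1])
            report.append(
                f"kinetics: k={fit.k:.4f}/day, removal at day "
                f"{series.times[-1]:g} = {final}%"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("kinetics", str(exc)) from exc

    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(report) + "\n")
    register("report", report_path)
    sio.write_json(manifest, outdir / "manifest.json")
    return manifest
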