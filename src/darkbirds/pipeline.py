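"""Configuration-driven end-to-end runs.

A run is described by a single YAML/dict configuration with a master
seed; per-stage seeds are derived deterministically from it (spawned
seed sequences), so reruns with the same configuration are reproducible
and changing one stage's seed leaves the others untouched. Artifacts
(input tables, fit summaries, draw matrices, totals, rate summaries,
manifest) are written as CSV/JSON/YAML into the output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from darkbirds import (
    chronology,
    data_prep,
    extrapolation,
    fossil_model,
    integration,
    rates,
    synthetic,
    upper_bounds,
)

logger = logging.getLogger(__name__)

STAGES = [
    "data",
    "prep",
    "fit",
    "posterior",
    "extrapolate",
    "bounds",
    "integrate",
    "chronology",
    "rates",
]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "tables"
    outdir: str = "darkbirds_run"
    seed: int = 0
    n_draws: int = 1000
    family: str = "lm"  # forward model: "lm" | "quasipoisson"
    hdi: bool = False
    window: int = 100
    level: float = 0.95
    extant_present: int = 10865
    span: tuple[int, int] = rates.DEFAULT_SPAN
    central: str = "median"
    # synthetic-mode generator settings
    n_archipelagos: int = 69
    grid_nx: int = 30
    grid_ny: int = 30
    grid_autocorr: float = 0.6
    lm_sigma: float = 0.75
    # tables-mode input paths
    archipelago_path: str | None = None
    grid_path: str | None = None
    mapping_path: str | None = None
    species_path: str | None = None
    # model details
    max_retries: int = 100
    cell_area: float = upper_bounds.DEFAULT_CELL_AREA
    sar_z: float = 0.25
    run_loocv: bool = True
    # explicit per-stage seeds; stages not listed derive from the master
    stage_seed_overrides: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        if stage in self.stage_seed_overrides:
            return int(self.stage_seed_overrides[stage])
        i = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[i]
        return int(child.generate_state(1)[0] % (2**31))


def validate_config(raw: dict) -> RunConfig:
    """Normalize a raw config mapping, filling defaults and checking keys."""
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    cfg = RunConfig(**raw)
    if cfg.mode not in ("synthetic", "tables"):
        raise ValueError("mode must be 'synthetic' or 'tables'")
    if cfg.n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if cfg.seed < 0:
        raise ValueError("seed must be non-negative")
    if cfg.mode == "tables":
        missing = [
            name
            for name in ("archipelago_path", "grid_path", "mapping_path", "species_path")
            if getattr(cfg, name) is None
        ]
        if missing:
            raise ValueError(f"tables mode requires paths: {missing}")
    bad_stages = sorted(set(cfg.stage_seed_overrides) - set(STAGES))
    if bad_stages:
        raise ValueError(f"stage_seed_overrides for unknown stage(s): {bad_stages}")
    cfg.span = tuple(cfg.span)
    return cfg


def load_config(path) -> RunConfig:
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: RunConfig | dict, stop_after: str | None = None) -> Path:
    """Execute prep -> fit -> extrapolate -> bounds -> integrate ->
    chronologies -> rates, persisting artifacts at each stage.

    ``stop_after`` (a stage name from :data:`STAGES`) ends the run early
    with all artifacts produced so far intact.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(dict(config))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGES},
        "timings_s": {},
    }
    t0 = time.time()
    stage = "data"
    try:
        if cfg.mode == "synthetic":
            arch, truth = synthetic.generate_archipelago_dataset(
                n_archipelagos=cfg.n_archipelagos, lm_sigma=cfg.lm_sigma, seed=cfg.stage_seed("data")
            )
            grid, mapping, grid_truth = synthetic.generate_grid_dataset(
                nx=cfg.grid_nx,
                ny=cfg.grid_ny,
                autocorr=cfg.grid_autocorr,
                archipelago_ids=list(arch["archipelago_id"]),
                seed=cfg.stage_seed("data") + 1,
            )
            species = synthetic.generate_species_register(arch, seed=cfg.stage_seed("data") + 2)
            synthetic.write_dataset(out / "data", arch, truth, grid, mapping, species)
        else:
            arch, _, grid, mapping, species = data_prep.read_tables(
                cfg.archipelago_path, None, cfg.grid_path, cfg.mapping_path, cfg.species_path
            )
        manifest["timings_s"][stage] = round(time.time() - t0, 3)
        if stop_after == stage:
            return _finish(out, manifest)

        stage = "prep"
        t = time.time()
        retained, corr = data_prep.screen_collinearity(arch)
        design = data_prep.prepare_design(arch, retained, synthetic.DEFAULT_TRANSFORMS)
        vif = data_prep.compute_vif(design)
        corr.to_csv(out / "predictor_correlations.csv")
        vif.to_csv(out / "vif.csv")
        manifest["retained_predictors"] = retained
        manifest["timings_s"][stage] = round(time.time() - t, 3)
        if stop_after == stage:
            return _finish(out, manifest)

        stage = "fit"
        t = time.time()
        lm = fossil_model.fit_fossil_lm(design, arch["n_fossil"])
        glm = fossil_model.fit_fossil_glm(design, arch["n_fossil"])
        fit_summary = {"lm": lm.to_dict(), "quasipoisson": glm.to_dict()}
        if cfg.run_loocv:
            fit_summary["loocv"] = {
                "lm": fossil_model.loocv_goodness("lm", design, arch["n_fossil"]).to_dict(),
                "quasipoisson": fossil_model.loocv_goodness(
                    "quasipoisson", design, arch["n_fossil"]
                ).to_dict(),
            }
        _json_dump(fit_summary, out / "fit.json")
        manifest["timings_s"][stage] = round(time.time() - t, 3)
        if stop_after == stage:
            return _finish(out, manifest)

        stage = "posterior"
        t = time.time()
        fit = lm if cfg.family == "lm" else glm
        posterior = fossil_model.simulate_posterior(fit, cfg.n_draws, seed=cfg.stage_seed("posterior"))
        manifest["timings_s"][stage] = round(time.time() - t, 3)
        if stop_after == stage:
            return _finish(out, manifest)

        stage = "extrapolate"
        t = time.time()
        rng = np.random.default_rng(cfg.stage_seed("extrapolate"))
        undiscovered = extrapolation.extrapolate_all(arch, posterior, design, rng)
        extrapolation.draws_frame(undiscovered).to_csv(out / "undiscovered_draws.csv", index=False)
        manifest["timings_s"][stage] = round(time.time() - t, 3)
        if stop_after == stage:
            return _finish(out, manifest)

        stage = "bounds"
        t = time.time()
        rac = upper_bounds.fit_rac_glm(grid, n_draws=cfg.n_draws, seed=cfg.stage_seed("bounds"))
        bounds = upper_bounds.upper_bounds_for_all(
            rac, arch, mapping, cell_area=cfg.cell_area, z=cfg.sar_z
        )
        _json_dump(
            {
                "mcfadden_r2": rac.fit.mcfadden_r2,
                "morans_step1": rac.morans_step1,
                "morans_refit": rac.morans_refit,
            },
            out / "bounds_fit.json",
        )
        manifest["timings_s"][stage] = round(time.time() - t, 3)
        if stop_after == stage:
            return _finish(out, manifest)

        stage = "integrate"
        t = time.time()
        rng = np.random.default_rng(cfg.stage_seed("integrate"))
        accepted, report = integration.rejection_sample(
            undiscovered, bounds, rng, max_retries=cfg.max_retries
        )
        strata = species["region_id"].map(
            arch.set_index("archipelago_id")["is_pacific"].map({True: "pacific", False: "non_pacific"})
        ).fillna("non_pacific")
        observed = integration.observed_component_draws(species, cfg.n_draws, rng, strata=strata)
        n_cont = int(
            (
                (species["category"] == "fossil") & (species["region_type"] == "continental_realm")
            ).sum()
        )
        totals = integration.assemble_totals(
            accepted,
            arch,
            observed,
            extant_present=cfg.extant_present,
            n_continental_fossil=n_cont,
            level=cfg.level,
            hdi=cfg.hdi,
        )
        pd.DataFrame(accepted).to_csv(out / "accepted_draws.csv", index=False)
        report.rates.to_csv(out / "rejection_rates.csv")
        summary = {
            "totals": totals.to_dict(),
            "rejection": {
                "median_rate": report.median_rate,
                "mean_rate": report.mean_rate,
                "truncation_events": report.truncation_events,
            },
        }
        _json_dump(summary, out / "summary.json")
        manifest["timings_s"][stage] = round(time.time() - t, 3)
        if stop_after == stage:
            return _finish(out, manifest)

        stage = "chronology"
        t = time.time()
        chron = chronology.generate_chronologies(
            species,
            arch,
            accepted,
            n_draws=cfg.n_draws,
            seed=cfg.stage_seed("chronology"),
        )
        manifest["timings_s"][stage] = round(time.time() - t, 3)
        if stop_after == stage:
            return _finish(out, manifest)

        stage = "rates"
        t = time.time()
        rolled = []
        for c in chron:
            series = rates.extinction_rate_series(c, span=cfg.span, extant_present=cfg.extant_present)
            rolled.append(rates.rolling_mean_rate(series, window=cfg.window))
        summary_rates = rates.summarize_rate_draws(rolled, level=cfg.level, central=cfg.central)
        peak_rate = float(summary_rates.central.max())
        rate_df = pd.DataFrame(
            {
                "year": summary_rates.years,
                "central": summary_rates.central,
                "lo": summary_rates.lo,
                "hi": summary_rates.hi,
            }
        )
        # keep the persisted rate table light: only years with any signal
        rate_df.loc[rate_df["central"] > 0].to_csv(out / "rate_summary.csv", index=False)
        summary["rates"] = {
            "peak_rate_per_species_year": peak_rate,
            "peak_year": int(summary_rates.years[int(np.argmax(summary_rates.central))]),
            "peak_times_background": float(rates.rate_to_background_ratio(peak_rate)),
            "peaks": summary_rates.peaks,
        }
        _json_dump(summary, out / "summary.json")
        manifest["timings_s"][stage] = round(time.time() - t, 3)
    except Exception as err:  # persist partial state, then re-raise with stage
        manifest["failed_stage"] = stage
        _finish(out, manifest)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return _finish(out, manifest)


def _finish(out: Path, manifest: dict) -> Path:
    manifest["total_s"] = round(sum(manifest["timings_s"].values()), 3)
    _json_dump(manifest, out / "manifest.json")
    return out
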