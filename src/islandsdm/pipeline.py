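"""End-to-end orchestration with resumable stages.

Stage order: synth -> predictors -> occurrences -> fit -> project ->
hotspots -> overlap -> report. Each stage persists its state under the run
directory and records status/seed/timing in manifest.json; a rerun skips
completed stages unless forced. All randomness derives from the config's
master seed, so a fixed (config, seed) pair reproduces every output table
byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import diversity as dv
from . import esm as esm_mod
from . import occurrences as occ_mod
from . import overlap as ov
from . import predictors as pred_mod
from . import projection as proj_mod
from . import synth
from .config import STAGES, PipelineConfig
from .grid import LayerStack
from .scenario import ScenarioSpec, BASELINE

log = logging.getLogger(__name__)


class Pipeline:
    """Run-directory-backed execution of the full analysis."""

    def __init__(self, config: PipelineConfig, run_dir: str | Path):
        config.validate()
        self.cfg = config
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        (self.run_dir / "state").mkdir(exist_ok=True)
        self.state: dict = {}
        self.manifest_path = self.run_dir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}, "config": config.to_dict()}
        config.to_yaml(self.run_dir / "config.yaml")

    # -- plumbing --------------------------------------------------------
    def _save_manifest(self):
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, default=str))

    def _state_file(self, stage: str) -> Path:
        return self.run_dir / "state" / f"{stage}.joblib"

    def _stage_done(self, stage: str) -> bool:
        info = self.manifest["stages"].get(stage)
        return bool(info and info.get("status") == "done" and self._state_file(stage).exists())

    def _load_stage(self, stage: str):
        self.state.update(joblib.load(self._state_file(stage)))

    def run(self, stages: list[str] | None = None, force: bool = False) -> Path:
        """Execute (or resume) the pipeline; returns the run directory."""
        todo = stages or STAGES
        for stage in STAGES:
            if stage not in todo:
                if self._stage_done(stage):
                    self._load_stage(stage)
                continue
            if self._stage_done(stage) and not force:
                log.info("stage %s: cached", stage)
                self.manifest["stages"][stage]["cached"] = True
                self._save_manifest()
                self._load_stage(stage)
                continue
            t0 = time.time()
            seed = self.cfg.seed_for(stage)
            log.info("stage %s: running (seed=%d)", stage, seed)
            try:
                out = getattr(self, f"_stage_{stage}")(seed)
            except Exception as e:
                self.manifest["stages"][stage] = {"status": "failed", "error": str(e)}
                self._save_manifest()
                raise
            joblib.dump(out, self._state_file(stage))
            self.state.update(out)
            self.manifest["stages"][stage] = {
                "status": "done",
                "cached": False,
                "seed": seed,
                "seconds": round(time.time() - t0, 2),
            }
            self._save_manifest()
        return self.run_dir

    # -- stages ----------------------------------------------------------
    def _stage_synth(self, seed: int) -> dict:
        cfg = self.cfg
        ss = np.random.SeedSequence(seed)
        seeds = [int(s) for s in np.random.default_rng(ss).integers(0, 2**31 - 1, size=6)]
        arch = synth.make_archipelago(seeds[0], n_islands=cfg.n_islands, grid_shape=cfg.grid_shape, cell_km=cfg.cell_km)
        clim = synth.make_monthly_climate(
            arch, lapse_rate=cfg.lapse_rate, seasonal_amp=cfg.seasonal_amp,
            wet_season_share=cfg.wet_season_share, seed=seeds[1],
        )
        climates = {"baseline": clim}
        for spec in cfg.scenario_specs():
            dt, pf = cfg.scenario_forcing(spec)
            climates[spec.label] = synth.apply_scenario(clim, dt, pf, spec)

        bio = pred_mod.derive_bioclim(clim)
        topo = pred_mod.derive_topographic(arch.dem)
        vs_env = LayerStack({name: bio[name] for name in bio.names})
        vs_env.add("hli", topo["hli"])
        species = synth.default_virtual_species(vs_env, arch)[: cfg.n_species]
        occ_parts, truths = [], {}
        rng = np.random.default_rng(seeds[2])
        for vs in species:
            n_rec = max(10, int(round(cfg.n_records_per_species * (vs.prevalence / 0.15))))
            df, suit = synth.sample_virtual_occurrences(
                vs, vs_env, arch, n_records=n_rec, bias_strength=cfg.bias_strength,
                seed=int(rng.integers(2**31 - 1)),
            )
            occ_parts.append(df)
            truths[vs.name] = suit
        occ_raw = pd.concat(occ_parts, ignore_index=True)
        pa_polys = synth.make_protected_areas(arch, coverage=cfg.pa_coverage, seed=seeds[3])
        ghm = synth.make_human_modification(arch, seed=seeds[4])
        dist_settle = synth.distance_to_settlements(arch)

        occ_raw.to_csv(self.run_dir / "occurrences_raw.csv", index=False)
        ov.write_geojson(pa_polys, self.run_dir / "protected_areas.geojson")
        return {
            "arch": arch, "climates": climates, "species": species, "truths": truths,
            "occ_raw": occ_raw, "pa_polys": pa_polys, "ghm": ghm, "dist_settle": dist_settle,
        }

    def _stage_predictors(self, seed: int) -> dict:
        cfg = self.cfg
        arch = self.state["arch"]
        stacks = {
            label: pred_mod.build_predictor_stack(clim, arch)
            for label, clim in self.state["climates"].items()
        }
        report = pred_mod.filter_collinear(
            stacks["baseline"], samples=cfg.collinearity_samples,
            rho_max=cfg.rho_max, vif_max=cfg.vif_max, seed=seed,
        )
        retained = report.retained
        log.info("predictors: retained %d of %d (%s)", len(retained), len(stacks["baseline"]), ", ".join(retained))
        block_size = cfg.block_size_km or esm_mod.median_autocorrelation_range(
            stacks["baseline"].subset(retained), seed=seed
        )
        (self.run_dir / "collinearity.json").write_text(json.dumps(report.to_dict(), indent=1))
        if cfg.write_rasters:
            stacks["baseline"].subset(retained).write_dir(self.run_dir / "predictors_baseline")
        return {"stacks": stacks, "collinearity": report, "retained": retained, "block_size": float(block_size)}

    def _stage_occurrences(self, seed: int) -> dict:
        cfg = self.cfg
        arch = self.state["arch"]
        occ = occ_mod.dedupe(self.state["occ_raw"], arch.land_mask)
        occ = occ_mod.thin(occ, cfg.resolved_thin_dist(), seed=seed, repeats=cfg.thin_repeats)
        occ, dropped = occ_mod.filter_min_records(occ, cfg.min_records)
        dist_stack = LayerStack({"dist_settlements": self.state["dist_settle"]})
        bias = occ_mod.fit_bias_model(occ, dist_stack, arch.land_mask, seed=seed)
        occ.to_csv(self.run_dir / "occurrences_clean.csv", index=False)
        (self.run_dir / "bias_model.json").write_text(json.dumps(bias.to_dict(), indent=1))
        log.info("occurrences: %d records, %d species (%d dropped); bias w=%s",
                 len(occ), occ["species"].nunique(), len(dropped), bias.w)
        return {"occ_clean": occ, "dropped_species": dropped, "bias_model": bias}

    def _stage_fit(self, seed: int) -> dict:
        cfg = self.cfg
        arch = self.state["arch"]
        retained_stack = self.state["stacks"]["baseline"].subset(self.state["retained"])
        occ = self.state["occ_clean"]
        rng = np.random.default_rng(seed)
        ensembles, eval_rows = {}, []
        for sp, grp in occ.groupby("species", sort=True):
            if cfg.fit_species is not None and sp not in cfg.fit_species:
                continue
            presences = grp[["lon", "lat"]].to_numpy()
            n_eligible = esm_mod.count_eligible_cells(presences, arch.land_mask, cfg.pa_min_dist)
            n_per_set = min(cfg.pa_per_set_cap, cfg.pa_per_set_mult * len(presences), n_eligible)
            sp_seed = int(rng.integers(2**31 - 1))
            if n_per_set < max(20, len(presences) // 2):
                log.warning("fit: %s has only %d eligible pseudo-absence cells; skipped", sp, n_eligible)
                continue
            pa_sets = esm_mod.generate_pseudo_absences(
                sp, presences, arch.land_mask, min_dist=cfg.pa_min_dist,
                n_sets=cfg.n_pa_sets, n_per_set=n_per_set, seed=sp_seed,
            )
            ens = esm_mod.fit_esm(
                sp, presences, pa_sets, retained_stack,
                block_size=self.state["block_size"], n_folds=cfg.n_folds,
                n_repeats=cfg.cv_repeats,
                learner_params={"n_estimators": cfg.rf_trees, "min_samples_leaf": cfg.rf_min_samples_leaf},
                final_learner_params={"n_estimators": cfg.rf_final_trees} if cfg.rf_final_trees else None,
                pair_tss_min=cfg.pair_tss_min,
                seed=sp_seed,
            )
            ensembles[sp] = ens
            row = {"species": sp, "n_presences": ens.n_presences, "ensemble_tss": ens.ensemble_tss,
                   "admitted": ens.admitted(cfg.tss_min), "threshold": ens.threshold}
            if ens.eval_report:
                row.update(ens.eval_report.to_dict())
            if cfg.n_null >= 19 and ens.modellable and np.isfinite(ens.ensemble_tss):
                row["null_p"] = self._null_p(ens, presences, sp_seed)
            eval_rows.append(row)
        eval_df = pd.DataFrame(eval_rows)
        eval_df.to_csv(self.run_dir / "evaluation.csv", index=False)
        admitted = [s for s in ensembles if ensembles[s].admitted(cfg.tss_min)]
        log.info("fit: %d/%d species admitted at TSS >= %.2f", len(admitted), len(ensembles), cfg.tss_min)
        return {"ensembles": ensembles, "eval_table": eval_df, "admitted": admitted}

    def _null_p(self, ens, presences, seed: int) -> float:
        """Null-model significance: refit on randomized presences (reduced protocol)."""
        cfg = self.cfg
        arch = self.state["arch"]
        retained_stack = self.state["stacks"]["baseline"].subset(self.state["retained"])
        rows, cols = np.nonzero(arch.land)

        def null_fit(rng):
            sel = rng.choice(rows.size, len(presences), replace=False)
            lon, lat = arch.dem.cell_center(rows[sel], cols[sel])
            pts = np.column_stack([lon, lat])
            try:
                n_eligible = esm_mod.count_eligible_cells(pts, arch.land_mask, cfg.pa_min_dist)
                n_per = min(cfg.pa_per_set_cap, cfg.pa_per_set_mult * len(pts), n_eligible)
                if n_per < 20:
                    return -1.0
                pa = esm_mod.generate_pseudo_absences("null", pts, arch.land_mask, cfg.pa_min_dist, 1, n_per, int(rng.integers(2**31 - 1)))
                e = esm_mod.fit_esm(
                    "null", pts, pa, retained_stack, block_size=self.state["block_size"],
                    n_folds=cfg.n_folds, n_repeats=1,
                    learner_params={"n_estimators": cfg.rf_trees, "min_samples_leaf": cfg.rf_min_samples_leaf},
                    pair_tss_min=cfg.pair_tss_min, seed=int(rng.integers(2**31 - 1)),
                )
                return e.ensemble_tss if np.isfinite(e.ensemble_tss) else -1.0
            except ValueError:
                return -1.0

        return esm_mod.null_model_test(ens.ensemble_tss, null_fit, n_null=cfg.n_null, seed=seed)

    def _stage_project(self, seed: int) -> dict:
        cfg = self.cfg
        stacks = self.state["stacks"]
        ensembles = self.state["ensembles"]
        admitted = self.state["admitted"]
        retained = self.state["retained"]
        occ = self.state["occ_clean"]
        truths = self.state["truths"]

        current_maps, future_maps, change_rows = {}, {}, []
        suitability = {}
        # baseline suitability is kept for every modellable species (truth
        # diagnostics); binary maps and range change only for admitted ones
        for sp, ens in ensembles.items():
            if ens.modellable:
                suitability[(sp, "baseline")] = proj_mod.project(ens, stacks["baseline"].subset(retained))
        for sp in admitted:
            ens = ensembles[sp]
            suit0, _ = proj_mod.clamp(ens, stacks["baseline"].subset(retained), suitability[(sp, "baseline")])
            current_maps[sp] = proj_mod.binarize(suit0, ens.threshold, sp, BASELINE)
            for spec in cfg.scenario_specs():
                stack = stacks[spec.label].subset(retained)
                suit = proj_mod.project(ens, stack)
                suit, _ = proj_mod.clamp(ens, stack, suit)
                bmap = proj_mod.binarize(suit, ens.threshold, sp, spec)
                future_maps[(sp, spec.label)] = bmap
                rc = proj_mod.range_change(current_maps[sp], bmap, cfg.dispersal_mode, cfg.buffer_km)
                change_rows.append({
                    "species": sp, "gcm": spec.gcm, "rcp": spec.rcp, "slice": spec.slice,
                    "mode": rc.dispersal_mode, "loss_cells": rc.loss_cells, "gain_cells": rc.gain_cells,
                    "stable_cells": rc.stable_cells, "change_pct": rc.change_pct,
                })
        change_df = pd.DataFrame(change_rows)
        change_df.to_csv(self.run_dir / "range_change.csv", index=False)

        # extrapolation: reference = training environments pooled over admitted species
        analogue = {}
        if admitted:
            ref_rows = []
            rng = np.random.default_rng(seed)
            land_rows, land_cols, Xbase = stacks["baseline"].subset(retained).to_matrix()
            occ_adm = occ[occ["species"].isin(admitted)]
            Xocc = stacks["baseline"].subset(retained).values_at(occ_adm["lon"].to_numpy(), occ_adm["lat"].to_numpy())
            Xocc = Xocc[np.isfinite(Xocc).all(axis=1)]
            n_bg = min(cfg.exdet_reference_cap - len(Xocc), 3 * len(Xocc))
            bg = Xbase[rng.choice(len(Xbase), size=max(0, n_bg), replace=False)] if n_bg > 0 else np.empty((0, Xocc.shape[1]))
            reference = np.vstack([Xocc, bg])
            for spec in cfg.scenario_specs():
                rep, _ = proj_mod.exdet_stack(retained, reference, stacks[spec.label].subset(retained))
                analogue[spec.label] = rep.analogue_fraction
        (self.run_dir / "extrapolation.json").write_text(json.dumps(analogue, indent=1))

        # niche truncation: study sample vs unbiased truth-weighted sample
        trunc_rows = []
        rng = np.random.default_rng(seed + 1)
        base_stack = stacks["baseline"].subset(retained)
        for sp in admitted:
            grp = occ[occ["species"] == sp]
            X_study = base_stack.values_at(grp["lon"].to_numpy(), grp["lat"].to_numpy())
            X_study = X_study[np.isfinite(X_study).all(axis=1)]
            truth = truths[sp]
            rows_t, cols_t = np.nonzero(np.nan_to_num(truth.data) > 0)
            w = truth.data[rows_t, cols_t]
            if len(rows_t) < 10 or len(X_study) < 10:
                continue
            take = rng.choice(len(rows_t), size=min(1500, len(rows_t)), replace=True, p=w / w.sum())
            X_full = base_stack.to_matrix(rows_t[take], cols_t[take])
            X_full = X_full[np.isfinite(X_full).all(axis=1)]
            trunc_rows.append({"species": sp, "truncation_index": proj_mod.niche_truncation_index(X_study, X_full, grid_bins=60)})
        pd.DataFrame(trunc_rows).to_csv(self.run_dir / "niche_truncation.csv", index=False)

        return {"current_maps": current_maps, "future_maps": future_maps, "range_change": change_df,
                "analogue": analogue, "suitability": suitability, "truncation": pd.DataFrame(trunc_rows)}

    def _stage_hotspots(self, seed: int) -> dict:
        cfg = self.cfg
        arch = self.state["arch"]
        ghm = self.state["ghm"]
        current_maps = self.state["current_maps"]
        future_maps = self.state["future_maps"]
        if not current_maps:
            raise RuntimeError("no admitted species; cannot build diversity maps")

        div = {"current": dv.stack_diversity(list(current_maps.values()), BASELINE)}
        for spec in cfg.scenario_specs():
            maps = [future_maps[(sp, spec.label)] for sp in current_maps]
            div[spec.label] = dv.stack_diversity(maps, spec)

        hotspots, shift_rows, ghm_rows = {}, [], []
        rng = np.random.default_rng(seed)
        for label, d in div.items():
            for metric, grid in (("SR", d.sr), ("CWE", d.cwe)):
                try:
                    hotspots[(metric, label)] = dv.l1_hotspots(grid, arch.dem, cfg.hotspot_quantile, metric, d.scenario)
                except ValueError as e:
                    log.warning("hotspots %s/%s: %s", metric, label, e)
            contrast = dv.human_mod_contrast(d, ghm, cfg.ghm_breaks)
            ghm_rows.append({"scenario": label, "kw_H": contrast["kw_H"], "kw_p": contrast["kw_p"],
                             **{f"median_sr_{k}": v["median_sr"] for k, v in contrast["classes"].items()}})
        for spec in cfg.scenario_specs():
            for metric in ("SR", "CWE"):
                cur = hotspots.get((metric, "current"))
                fut = hotspots.get((metric, spec.label))
                if cur is None or fut is None:
                    continue
                res = dv.shift_tests(cur, fut, n_perm=cfg.shift_n_perm, seed=int(rng.integers(2**31 - 1)))
                shift_rows.append({"metric": metric, "gcm": spec.gcm, "rcp": spec.rcp, "slice": spec.slice, **res.to_dict()})
        shift_df = pd.DataFrame(shift_rows)
        shift_df.to_csv(self.run_dir / "shift_tests.csv", index=False)
        pd.DataFrame(ghm_rows).to_csv(self.run_dir / "ghm_contrast.csv", index=False)
        hs_rows = [
            {"metric": m, "scenario": lbl, "lon": lo, "lat": la, "elevation": el}
            for (m, lbl), hs in hotspots.items()
            for lo, la, el in zip(hs.lon, hs.lat, hs.elevation)
        ]
        pd.DataFrame(hs_rows).to_csv(self.run_dir / "hotspots.csv", index=False)
        if cfg.write_rasters:
            for label, d in div.items():
                d.sr.write_ascii(self.run_dir / f"sr_{label}.asc")
                d.cwe.write_ascii(self.run_dir / f"cwe_{label}.asc")
        return {"diversity": div, "hotspots": hotspots, "shift_tests": shift_df,
                "ghm_contrast": pd.DataFrame(ghm_rows)}

    def _stage_overlap(self, seed: int) -> dict:
        cfg = self.cfg
        arch = self.state["arch"]
        pa_mask = ov.rasterize_pa(self.state["pa_polys"], arch.land_mask)
        reports = []
        for (metric, label), hs in self.state["hotspots"].items():
            rep = ov.overlap_fraction(hs, pa_mask)
            spec = hs.scenario
            reports.append((rep, spec.gcm, spec.rcp, spec.slice if label != "current" else "current"))
        table, trend = ov.overlap_table(reports)
        table.to_csv(self.run_dir / "overlap.csv", index=False)
        (self.run_dir / "overlap_trend.json").write_text(json.dumps(trend, indent=1))
        return {"pa_mask": pa_mask, "overlap_table": table, "overlap_trend": trend}

    def _stage_report(self, seed: int) -> dict:
        lines = ["# Pipeline report", ""]
        ev = self.state["eval_table"]
        if len(ev):
            lines += [f"Species modelled: {len(ev)}; admitted (TSS >= {self.cfg.tss_min}): {int(ev['admitted'].sum())}",
                      f"Mean ensemble TSS: {ev['ensemble_tss'].mean():.3f}", ""]
        rc = self.state["range_change"]
        if len(rc):
            lines.append("## Mean range change (%) by RCP and slice")
            piv = rc.pivot_table(values="change_pct", index="rcp", columns="slice", aggfunc="mean")
            lines.append(piv.round(1).to_string())
            lines.append("")
        lines.append("## Analogue climate fraction (%) per scenario")
        for k, v in self.state["analogue"].items():
            lines.append(f"- {k}: {v:.2f}")
        lines.append("")
        lines.append("## Protected-area overlap trend")
        for k, v in self.state["overlap_trend"].items():
            lines.append(f"- {k}: {v}")
        text = "\n".join(lines) + "\n"
        (self.run_dir / "report.md").write_text(text)
        return {"report_text": text}


def run_pipeline(config: PipelineConfig, run_dir: str | Path, stages=None, force: bool = False) -> Pipeline:
    """Convenience wrapper: build a Pipeline, run it, return it."""
    p = Pipeline(config, run_dir)
    p.run(stages=stages, force=force)
    return p
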