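"""End-to-end orchestration: simulate → describe → indices → kriging → PCA →
PMF → health risk → source-risk apportionment, with a JSON run manifest."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from ._defaults import METALS
from .describe import pearson_matrix, summarize
from .geospatial import OrdinaryKriging, make_grid
from .indices import ecological_risk, risk_class_shares
from .io import (MetalParams, RunConfig, SampleTable, config_hash,
                 load_params, read_samples, write_manifest)
from .pca import PCAModel
from .pmf import (PMFModel, build_uncertainty, factor_contributions,
                  residual_diagnostics, select_n_factors, snr_classes)
from .risk import RiskModel, sankey_export, source_risk_apportion
from .synth import default_spec, generate_cohort

log = logging.getLogger("soilrisk.pipeline")

__all__ = ["run_all"]


def _register(manifest: dict, outdir: Path, name: str, obj) -> Path:
    path = outdir / name
    if isinstance(obj, pd.DataFrame) or isinstance(obj, pd.Series):
        obj.to_csv(path)
    elif isinstance(obj, (dict, list)):
        path.write_text(json.dumps(obj, indent=2, default=str))
    else:
        path.write_text(str(obj))
    manifest["outputs"].append(str(path))
    return path


def run_all(config: str | Path | None = None, *, seed: int | None = None,
            samples_csv: str | Path | None = None,
            outdir: str | Path | None = None) -> dict:
    """Run every stage on a real sample CSV or on a simulated cohort.

    Returns the run manifest (also written to ``manifest.json``); the
    manifest records the failure point if a stage raises.
    """
    params, profiles, run = load_params(config)
    if seed is not None:
        run.seed = int(seed)
    out = Path(outdir or run.outdir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__, "seed": run.seed,
        "config_hash": config_hash(config), "outputs": [],
        "timings_s": {}, "warnings": [], "status": "running",
    }
    t_all = time.time()
    try:
        # --- input ---------------------------------------------------------
        t0 = time.time()
        if samples_csv is not None:
            samples = read_samples(samples_csv, policy=run.sample_policy)
            truth = None
        else:
            spec = default_spec(seed=run.seed)
            samples, truth = generate_cohort(spec)
            samples.to_csv(out / "samples.csv")
            manifest["outputs"].append(str(out / "samples.csv"))
            _register(manifest, out, "truth.json", truth.to_json())
        manifest["n_samples"] = len(samples)
        manifest["timings_s"]["input"] = round(time.time() - t0, 3)

        # --- descriptive stage --------------------------------------------
        t0 = time.time()
        _register(manifest, out, "summary.csv", summarize(samples, params))
        r, p = pearson_matrix(samples)
        _register(manifest, out, "correlation.csv", r)
        _register(manifest, out, "correlation_p.csv", p)
        manifest["timings_s"]["describe"] = round(time.time() - t0, 3)

        # --- pollution indices --------------------------------------------
        t0 = time.time()
        idx = ecological_risk(samples, params)
        _register(manifest, out, "igeo.csv", idx.igeo)
        eco = idx.eri.copy()
        eco["RI"] = idx.ri
        eco["RI_class"] = idx.ri_class
        _register(manifest, out, "ecorisk.csv", eco)
        _register(manifest, out, "igeo_class_shares.csv",
                  risk_class_shares(idx.igeo_class, params.igeo_classes))
        _register(manifest, out, "eri_class_shares.csv",
                  risk_class_shares(idx.eri_class, params.eri_classes))
        manifest["class_schemes"] = {
            "igeo": [list(x) for x in params.igeo_classes],
            "eri": [list(x) for x in params.eri_classes],
            "ri": [list(x) for x in params.ri_classes]}
        manifest["timings_s"]["indices"] = round(time.time() - t0, 3)

        # --- kriging -------------------------------------------------------
        t0 = time.time()
        grid = make_grid(tuple(run.grid["origin"]), run.grid["cell"],
                         run.grid["nx"], run.grid["ny"])
        surfaces = []
        conc = samples.concentrations()
        for m in METALS:
            ok = OrdinaryKriging(samples.coords(), conc[m].to_numpy(),
                                 log_transform=run.log_concentrations)
            surf = ok.predict(grid, metal=m).to_frame()
            surf["metal"] = m
            surfaces.append(surf)
        _register(manifest, out, "kriged_surfaces.csv", pd.concat(surfaces))
        manifest["timings_s"]["kriging"] = round(time.time() - t0, 3)

        # --- PCA diagnostics -----------------------------------------------
        t0 = time.time()
        pca = PCAModel.from_samples(samples).fit()
        _register(manifest, out, "pca_loadings.csv", pca.summary())
        manifest["kmo"] = pca.kmo
        manifest["bartlett_p"] = pca.bartlett_p
        manifest["timings_s"]["pca"] = round(time.time() - t0, 3)

        # --- PMF -----------------------------------------------------------
        t0 = time.time()
        if run.pmf_enabled:
            unc = build_uncertainty(samples, params)
            _register(manifest, out, "uncertainty.csv", unc)
            manifest["snr_class"] = snr_classes(conc, unc).to_dict()
            p_chosen, q_table = select_n_factors(
                conc, unc, scan=run.n_factors_scan,
                restarts=run.pmf_restarts, seed=run.seed)
            _register(manifest, out, "q_table.csv", q_table)
            sol = PMFModel(conc, unc, p_chosen, restarts=run.pmf_restarts,
                           seed=run.seed).fit()
            _register(manifest, out, "profiles.csv", sol.profiles())
            _register(manifest, out, "contributions.csv", sol.contributions())
            metal_shares, overall = factor_contributions(sol)
            _register(manifest, out, "factor_shares.csv", metal_shares)
            _register(manifest, out, "residual_normality.csv",
                      residual_diagnostics(sol))
            manifest["pmf"] = {"n_factors": p_chosen,
                               "q_true": sol.q_true, "q_robust": sol.q_robust,
                               "overall_shares_pct": overall.round(2).to_dict()}
        else:
            n = run.n_factors_scan[0]
            metal_shares = pd.DataFrame(
                100.0 / n, index=[f"F{k+1}" for k in range(n)], columns=METALS)
            manifest["warnings"].append(
                "pmf disabled: source-risk uses equal factor shares")
        manifest["timings_s"]["pmf"] = round(time.time() - t0, 3)

        # --- health risk and source apportionment --------------------------
        t0 = time.time()
        risk = RiskModel(conc, params, profiles).fit()
        _register(manifest, out, "risk.csv", risk.table())
        manifest["risk"] = {
            c: {"THI": r.thi, "TCR": r.tcr,
                "THI_flag": r.thi_flag, "TCR_flag": r.tcr_flag}
            for c, r in risk.cohorts.items()}
        src = {c: source_risk_apportion(r, metal_shares)
               for c, r in risk.cohorts.items()}
        _register(manifest, out, "source_risk.csv",
                  pd.concat(src, names=["cohort", "factor"]))
        _register(manifest, out, "sankey.json",
                  sankey_export(risk.cohorts, metal_shares))
        manifest["timings_s"]["risk"] = round(time.time() - t0, 3)

        manifest["status"] = "ok"
    except Exception as exc:  # manifest records the failure point
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["timings_s"]["total"] = round(time.time() - t_all, 3)
        write_manifest(out / "manifest.json", manifest)
    return manifest
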