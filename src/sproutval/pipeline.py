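"""End-to-end orchestration of the marker-validation pipeline.

``run_all`` executes, from a single config, the sequence

    germination index -> BLUPs / variance components / heritability
    -> marker QC -> single-marker association -> stability
    -> all-subsets AIC model selection -> haplotype comparison
    -> selection efficiency

and writes one CSV per report (variance components, environment
comparison, QC, association, top models, haplotype classes, selection
comparison) plus a run manifest and a rounded text summary.  Stage
outputs are pure functions of (inputs, config, seed): rerunning with
the same config yields byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sproutval import association as assoc_mod
from sproutval import haplotype_selection as hap_mod
from sproutval import marker_qc as qc_mod
from sproutval import model_selection as sel_mod
from sproutval import phenotype as phen_mod
from sproutval import variance_models as vm_mod
from sproutval.synthetic_data import MarkerSpec, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh) or {}


def _sim_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg.get("sim", {}))
    if "markers" in sim:
        sim["markers"] = tuple(MarkerSpec(**m) for m in sim["markers"])
    if "env_means" in sim and sim["env_means"] is not None:
        sim["env_means"] = tuple(sim["env_means"])
    sim.setdefault("rng_seed", int(cfg.get("seed", 0)))
    return SimulationConfig(**sim)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config, out_dir) -> dict:
    """Run every pipeline stage; returns the run manifest (also written).

    ``config`` is a dict or a YAML path.  It must either set
    ``simulate: true`` (with optional ``sim:`` generator overrides) or
    provide an ``input:`` section with ``plots``, ``calls`` and
    ``markers`` file paths.  Optional sections: ``qc`` (threshold
    overrides), ``alpha``, ``k_top``, ``seed``.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg.get("alpha", 0.05))
    k_top = int(cfg.get("k_top", 10))
    from sproutval import __version__ as _version
    manifest: dict = {
        "version": _version,
        "config": cfg,
        "seed": int(cfg.get("seed", 0)),
        "inputs": {},
        "outputs": {},
    }

    def save(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["outputs"][name] = _digest(path)
        return path

    # ---- inputs ------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.get("simulate", False):
            sim = _sim_config(cfg)
            matrix, meta, truth, plots = simulate_dataset(sim)
            manifest["inputs"]["simulated"] = {
                "rng_seed": sim.rng_seed,
                "n_genotypes": sim.n_genotypes,
                "n_environments": sim.n_environments,
            }
        else:
            inp = cfg.get("input") or {}
            for key in ("plots", "calls", "markers"):
                if key not in inp:
                    raise ValueError(f"config missing input section entry '{key}'")
            plots = phen_mod.read_plot_records(inp["plots"])
            matrix = qc_mod.read_call_matrix(inp["calls"])
            meta = qc_mod.read_marker_meta(inp["markers"])
            manifest["inputs"] = {k: _digest(Path(v)) for k, v in inp.items()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- germination index ------------------------------------------
    stage = "gi"
    try:
        gi = phen_mod.gi_table(plots)
        save("gi.csv", gi)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- variance models / BLUPs ------------------------------------
    stage = "blup"
    try:
        within = []
        for env, grp in gi.groupby("environment_id", sort=True):
            b, _ = vm_mod.fit_within_env(grp)
            b.insert(1, "environment_id", env)
            within.append(b)
        blups_within = pd.concat(within, ignore_index=True)
        save("blups_within.csv", blups_within)

        blups_across, vc = vm_mod.fit_across_env(gi)
        save("blups_across.csv", blups_across)

        shares = vm_mod.variance_shares(vc)
        h2 = vm_mod.heritability(vc)
        vc_table = pd.DataFrame([
            {"component": "genotype", "variance": vc.sigma2_g,
             "pct_of_total": shares["genotype"], "heritability": h2},
            {"component": "environment", "variance": vc.sigma2_e,
             "pct_of_total": shares["environment"], "heritability": np.nan},
            {"component": "gxe", "variance": vc.sigma2_gxe,
             "pct_of_total": shares["gxe"], "heritability": np.nan},
            {"component": "rep_within_env", "variance": vc.sigma2_rep,
             "pct_of_total": np.nan, "heritability": np.nan},
            {"component": "residual", "variance": vc.sigma2_eps,
             "pct_of_total": shares["residual"], "heritability": np.nan},
        ])
        save("variance_components.csv", vc_table)

        env_cmp = vm_mod.compare_env_means(
            blups_within.rename(columns={"blup": "blup"}), alpha=alpha)
        save("env_comparison.csv", env_cmp)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- marker QC ---------------------------------------------------
    stage = "qc"
    try:
        matrix_h, meta_h = qc_mod.harmonize_strand(matrix, meta)
        th = qc_mod.QCThresholds(**cfg.get("qc", {}))
        report = qc_mod.apply_filters(qc_mod.qc_stats(matrix_h, meta_h), th)
        save("qc_report.csv", report)
        kept = qc_mod.retained_markers(report)
        filtered = qc_mod.drop_heterozygotes(matrix_h[kept], meta_h)
        fpath = out / "filtered_calls.csv"
        qc_mod.write_matrix(filtered, fpath)
        manifest["outputs"]["filtered_calls.csv"] = _digest(fpath)
        ld_groups = qc_mod.detect_complete_ld(filtered)
        save("ld_groups.csv", pd.DataFrame(
            [{"group": i + 1, "marker_id": m, "representative": grp[0]}
             for i, grp in enumerate(ld_groups) for m in grp]))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- association -------------------------------------------------
    stage = "association"
    try:
        blups_by_env = {env: grp[["genotype_id", "blup"]]
                        for env, grp in blups_within.groupby("environment_id")}
        blups_by_env[assoc_mod.ACROSS] = blups_across[["genotype_id", "blup"]]
        assoc = assoc_mod.associate_all(blups_by_env, filtered)
        save("association.csv", assoc)
        stability = assoc_mod.classify_stability(assoc, alpha=alpha)
        save("stability.csv", stability)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- model selection ---------------------------------------------
    stage = "model_selection"
    try:
        pool = sel_mod.candidate_pool(stability, ld_groups)
        across = assoc[assoc["environment_id"] == assoc_mod.ACROSS].set_index("marker_id")
        tol = {}
        for mid in pool:
            if mid in across.index and across.loc[mid, "tolerant_allele"]:
                tol[mid] = across.loc[mid, "tolerant_allele"]
            else:  # marker significant per-env but monomorphic across? fall back
                st = stability.set_index("marker_id")
                tol[mid] = st.loc[mid, "tolerant_allele"]
        indicators = sel_mod.tolerant_indicator_matrix(filtered, pool, tol)
        models = sel_mod.all_subsets_regression(
            blups_across[["genotype_id", "blup"]], indicators, k_top=k_top)
        save("top_models.csv", sel_mod.models_table(models, pool))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- haplotypes and selection efficiency -------------------------
    stage = "haplotype"
    try:
        single = models[0].marker_subset[0] if len(models[0].marker_subset) == 1 \
            else max(pool, key=lambda m: across.loc[m, "pve"] if m in across.index else -1)
        single_class = hap_mod._allele_classes(filtered[single])
        marker_members = single_class[single_class == tol[single]].index.tolist()

        hap_rows, sel_rows = [], []
        blups_long = blups_within[["genotype_id", "environment_id", "blup"]]
        for model in models:
            if len(model.marker_subset) < 2:
                continue
            mid = f"model{model.rank}"
            classes = hap_mod.build_haplotypes(
                filtered, list(model.marker_subset), tol, model_id=mid)
            try:
                table = hap_mod.haplotype_mixed_model(blups_long, classes, alpha=alpha)
            except ValueError as exc:
                logger.warning("model %s: %s; haplotype comparison skipped", mid, exc)
                continue
            table.insert(1, "markers", "|".join(model.marker_subset))
            hap_rows.append(table)
            sel_rows.append((mid, table, classes))

        sel_out = []
        for mid, table, classes in sel_rows:
            best_label = table[~table["rare"]].iloc[0]["haplotype"]
            best_members = next(c.members for c in classes if c.haplotype == best_label)
            cmp = hap_mod.selection_efficiency(
                best_members, marker_members,
                blups_across[["genotype_id", "blup"]], model_id=mid)
            sel_out.append(dataclasses.asdict(cmp))
        if hap_rows:
            save("haplotypes.csv", pd.concat(hap_rows, ignore_index=True))
        if sel_out:
            save("selection_comparison.csv", pd.DataFrame(sel_out))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- summary and manifest ---------------------------------------
    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        fh.write(f"sproutval {_version}\n")
        fh.write(f"heritability (entry-mean basis): {h2:.2f}\n")
        fh.write("variance shares (%): "
                 + ", ".join(f"{k}={v}" for k, v in shares.items()) + "\n")
        fh.write("environment means (GI, Tukey letters):\n")
        for row in env_cmp.itertuples(index=False):
            fh.write(f"  {row.environment_id}: {row.mean:.2f} {row.letter}\n")
        fh.write(f"markers retained by QC: {len(kept)} of {len(report)}\n")
        fh.write(f"stable markers: {int(stability['stable'].sum())}\n")
        fh.write(f"candidate pool after LD collapse: {len(pool)}\n")
        if models:
            m1 = models[0]
            fh.write(f"best model (AIC {m1.aic:.2f}, PVE {m1.pve:.1f}%): "
                     + " + ".join(m1.marker_subset) + "\n")
    manifest["outputs"]["summary.txt"] = _digest(summary)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
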