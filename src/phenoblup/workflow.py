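"""End-to-end pipeline stages over a run directory.

Each stage reads the files earlier stages wrote (or that a user
provides in the same dialects) and writes its own outputs plus
provenance sidecars, so the whole analysis is reproducible from a
config mapping and a seed: simulate -> preprocess -> kernels ->
heritability -> evaluate.  The command-line interface is a thin wrapper
over these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .design import degree_audit
from .errors import ConfigurationError
from .evaluation import (
    make_cv_new_dent_flint,
    make_cv_sparse,
    run_scenario,
    standard_model_catalog,
    summarize_results,
)
from .heritability import plot_scan, scan_bivariate, scan_univariate, summarize_scan
from .kernels import (
    KernelMatrix,
    filter_markers,
    impute_missing,
    repair_psd,
    sca_kernel,
    scale_unit_variance,
    spectral_relationship,
    vanraden_gca_kinship,
)
from .simulate import (
    SimConfig,
    simulate_factorial,
    simulate_genotypes,
    simulate_hybrid_phenotypes,
    simulate_spectra,
)
from .spectra import normalize, savitzky_golay_first_derivative

log = logging.getLogger("phenoblup")

# flint silage spectra are missing in the second trial, so the second
# silage source carries only a dent GCA kernel (single-random-effect model)
TISSUES = ("leaf", "silage")


def build_sim_config(cfg: dict) -> SimConfig:
    sim = dict(cfg.get("simulate", {}))
    sim.setdefault("seed", cfg.get("seed", 0))
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(sim) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulate config keys: {sorted(unknown)}")
    if "n_wavelengths" in cfg.get("simulate", {}):
        raise ConfigurationError("set wavelength_grid, not n_wavelengths")
    return SimConfig(**sim)


def run_simulate(cfg: dict, outdir) -> None:
    """Generate genotypes, design, phenotypes and raw spectra files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = build_sim_config(cfg)
    geno, dfam, ffam = simulate_genotypes(sc)
    dents = [l for l, p in zip(geno.line_ids, geno.pools) if p == sc.pools[0]]
    flints = [l for l, p in zip(geno.line_ids, geno.pools) if p == sc.pools[1]]
    design = simulate_factorial(dents, flints, sc, dfam, ffam)
    phen, realized = simulate_hybrid_phenotypes(design, geno, sc)

    pio.write_genotypes(geno, out / "genotypes.csv")
    pio.write_design(design, out / "design.csv")
    pio.write_phenotypes(phen, out / "phenotypes.csv")
    degree_audit(design).to_csv(out / "degree_audit.csv", index=False)
    (out / "realized_components.json").write_text(json.dumps(realized, indent=1))

    for tissue in TISSUES:
        for pool in sc.pools:
            sub = geno.subset_pool(pool)
            s = simulate_spectra(sub, sc, tissue=tissue)
            if tissue == "silage" and pool == sc.pools[1]:
                # flint silage observed in the first trial only
                keep = s.meta["trial_id"] == "trial1"
                s = s.select(keep.to_numpy())
            pio.write_spectra(s, out / f"spectra_{tissue}_{pool}.csv")
    (out / "config_used.json").write_text(
        json.dumps({"seed": sc.seed, "hash": pio.config_hash(cfg)}, indent=1)
    )
    log.info("simulated %d hybrids, %d lines", len(design.hybrids), geno.n_lines)


def _pretreat_file(path, window, polyorder):
    s = pio.read_spectra(path)
    out = {}
    for trial, tm in s.meta.groupby("trial_id", sort=False):
        sub = s.select((s.meta["trial_id"] == trial).to_numpy())
        if not sub.is_uniform_grid():
            sub = sub.resample_uniform()
        sub = normalize(sub)
        sub = savitzky_golay_first_derivative(sub, window=window, polyorder=polyorder)
        out[trial] = sub
    return s, out


def run_preprocess(cfg: dict, outdir) -> None:
    """Replicate-average and spatially adjust any raw spectra files.

    Files already in the adjusted state pass through unchanged.
    Adjusted spectra and the per-wavelength broad-sense heritability
    are written back under the same name (plus an ``_H2.tsv`` table).
    """
    from .spectra import adjust_wavelength_means, average_technical_replicates

    out = Path(outdir)
    for path in sorted(out.glob("spectra_*.csv")):
        s = pio.read_spectra(path)
        if s.state not in ("raw", "averaged"):
            continue
        if s.state == "raw":
            s = average_technical_replicates(s)
        adjusted, h2 = adjust_wavelength_means(s)
        pio.write_spectra(adjusted, path)
        h2.to_frame().to_csv(
            out / f"{path.stem}_H2.tsv", sep="\t", index=False
        )
        log.info("adjusted %s", path.name)


def run_kernels(cfg: dict, outdir) -> None:
    """QC genotypes and build all scaled relationship kernels."""
    out = Path(outdir)
    prep = cfg.get("preprocess", {})
    window = int(prep.get("window", 37))
    polyorder = int(prep.get("polyorder", 2))

    geno = pio.read_genotypes(out / "genotypes.csv")
    design = pio.read_design(out / "design.csv")
    geno, audit = filter_markers(geno)
    audit.to_csv(out / "marker_audit.csv", index=False)
    geno = impute_missing(geno)

    pools = sorted(set(geno.pools))
    dent_pool = "dent" if "dent" in pools else pools[0]
    flint_pool = "flint" if "flint" in pools else pools[-1]
    kd = vanraden_gca_kinship(geno.subset_pool(dent_pool), role="GCA_dent")
    kf = vanraden_gca_kinship(geno.subset_pool(flint_pool), role="GCA_flint")
    ks = sca_kernel(kd, kf, design)
    for name, k in (("K_gca_dent", kd), ("K_gca_flint", kf), ("K_sca", ks)):
        pio.write_kernel(repair_psd(scale_unit_variance(k)), out / f"{name}.csv")

    for tissue in TISSUES:
        per_trial: dict[str, dict[str, KernelMatrix]] = {}
        for pool, role in ((dent_pool, "GCA_dent"), (flint_pool, "GCA_flint")):
            path = out / f"spectra_{tissue}_{pool}.csv"
            if not path.exists():
                continue
            _, pretreated = _pretreat_file(path, window, polyorder)
            for trial, sub in pretreated.items():
                h = spectral_relationship(sub, role=role, trial=trial)
                per_trial.setdefault(trial, {})[role] = h
        for trial, roles in per_trial.items():
            kit = {}
            if "GCA_dent" in roles:
                kit["gca_dent"] = roles["GCA_dent"]
            if "GCA_flint" in roles:
                kit["gca_flint"] = roles["GCA_flint"]
            if "GCA_dent" in roles and "GCA_flint" in roles:
                kit["sca"] = sca_kernel(roles["GCA_dent"], roles["GCA_flint"], design)
            for role_key, k in kit.items():
                pio.write_kernel(
                    repair_psd(scale_unit_variance(k)),
                    out / f"H_{tissue}_{trial}_{role_key}.csv",
                )
    log.info("kernels written to %s", out)


def run_heritability(cfg: dict, outdir, make_figure: bool = True) -> None:
    """Per-wavelength variance decomposition of the simulated spectra."""
    out = Path(outdir)
    geno = pio.read_genotypes(out / "genotypes.csv")
    geno, _ = filter_markers(geno)
    geno = impute_missing(geno)
    pools = sorted(set(geno.pools))
    for tissue in TISSUES:
        for pool in pools:
            path = out / f"spectra_{tissue}_{pool}.csv"
            if not path.exists():
                continue
            s = pio.read_spectra(path)
            K = vanraden_gca_kinship(geno.subset_pool(pool))
            trials = list(dict.fromkeys(s.meta["trial_id"]))
            try:
                if len(trials) >= 2:
                    s1 = s.select((s.meta["trial_id"] == trials[0]).to_numpy())
                    s2 = s.select((s.meta["trial_id"] == trials[1]).to_numpy())
                    scan = scan_bivariate(s1, s2, K, pool=pool, tissue=tissue)
                else:
                    scan = scan_univariate(s, K, pool=pool, tissue=tissue)
            except ConfigurationError as err:
                log.warning("skipping scan for %s/%s: %s", tissue, pool, err)
                continue
            scan.table.to_csv(out / f"scan_{tissue}_{pool}.tsv", sep="\t", index=False)
            (out / f"scan_{tissue}_{pool}_summary.json").write_text(
                json.dumps(summarize_scan(scan), indent=1, default=str)
            )
            if make_figure:
                ax = plot_scan(scan, path=str(out / f"scan_{tissue}_{pool}.png"))
                ax.figure.clf()
    log.info("heritability scans written to %s", out)


def _load_bundle(out: Path) -> tuple[dict, dict]:
    bundle = {
        "genomic": {
            "gca_dent": pio.read_kernel(out / "K_gca_dent.csv"),
            "gca_flint": pio.read_kernel(out / "K_gca_flint.csv"),
            "sca": pio.read_kernel(out / "K_sca.csv"),
        }
    }
    combine: dict[str, list[str]] = {}
    for tissue in TISSUES:
        sources = []
        for path in sorted(out.glob(f"H_{tissue}_trial*_gca_dent.csv")):
            trial = path.stem.split("_")[2]
            key = f"{tissue}_{trial}"
            kit = {"gca_dent": pio.read_kernel(path)}
            for role_key in ("gca_flint", "sca"):
                p = out / f"H_{tissue}_{trial}_{role_key}.csv"
                if p.exists():
                    kit[role_key] = pio.read_kernel(p)
            bundle[key] = kit
            sources.append(key)
        if len(sources) > 1:
            combine[f"H.COMB.{tissue.upper()}"] = sources
    all_sources = [k for k in bundle if k != "genomic" and k != "pedigree"]
    if len(all_sources) > 1:
        combine["H.ALL"] = all_sources
    return bundle, combine


def run_evaluate(cfg: dict, outdir) -> pd.DataFrame:
    """Both CV scenarios over the standard model catalog."""
    out = Path(outdir)
    ev = cfg.get("evaluate", {})
    seed = int(cfg.get("seed", 0))
    design = pio.read_design(out / "design.csv")
    phen = pio.read_phenotypes(out / "phenotypes.csv", design)
    bundle, combine = _load_bundle(out)
    catalog = standard_model_catalog(bundle, combine)
    parts = make_cv_sparse(
        design, k=int(ev.get("k", 5)), reps=int(ev.get("reps", 5)), seed=seed
    )
    parts += make_cv_new_dent_flint(
        design, min_predicted=int(ev.get("min_predicted", 10))
    )
    results = run_scenario(catalog, parts, design, phen, bundle)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    summary = summarize_results(results)
    summary.to_csv(out / "results_summary.tsv", sep="\t", index=False)
    log.info("evaluation written to %s", out)
    return summary


def run_all(cfg: dict, outdir, make_figure: bool = False) -> None:
    run_simulate(cfg, outdir)
    run_preprocess(cfg, outdir)
    run_kernels(cfg, outdir)
    run_heritability(cfg, outdir, make_figure=make_figure)
    run_evaluate(cfg, outdir)
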