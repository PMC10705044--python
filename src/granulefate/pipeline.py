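"""End-to-end orchestration: simulate -> quantify -> screen -> active -> respond -> report.

One configuration (a flat mapping, usually loaded from YAML) drives a full
run. Every output is a delimited table under the output directory, and a
``manifest.json`` records the configuration, the master seed, per-stage
parameters, and a SHA-256 hash of every written file — rerunning with an
identical configuration reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .active_community import (
    active_relative_abundance,
    aggregate_family,
    call_active,
    diversity_indices,
)
from .community_response import fit_environment, response_table
from .compounds import load_compound_db
from .degradation_screen import product_timeseries, screen_peaks
from .errors import ConfigurationError, DataError
from .io import read_counts, read_table, read_taxonomy, write_counts, write_table
from .pharma_quant import (
    correct_measurements,
    fit_calibration,
    removal_series,
    total_nitrogen_removal_series,
)
from .synthetic_data import (
    SimConfig,
    simulate_analytes,
    simulate_community,
    simulate_ordination,
    simulate_pharma_series,
)

log = logging.getLogger("granulefate")

DEFAULT_PARAMS = {
    "loq": 10.0,            # μg/L limit of quantification
    "max_ppm": 5.0,
    "min_snr": 10.0,
    "adduct": "[M+H]+",
    "n_trials": 100,
    "active_threshold": 1.0,
    "depth": None,
    "t1_day": 5,
    "t2_day": 17,
    "min_abundance": 0.001,
    "band": 0.5,
    "n_perm": 999,
}

STAGES = ("simulate", "quantify", "screen", "active", "respond", "report")


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    return cfg


def validate_config(config: dict) -> dict:
    """Normalize and validate a pipeline configuration mapping."""
    cfg = dict(config)
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ConfigurationError(
            "config must contain exactly one of 'simulate' (a simulation"
            " block) or 'inputs' (paths to existing tables)"
        )
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params") or {})
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
    cfg["params"] = params
    cfg.setdefault("seed", 0)
    if "inputs" in cfg:
        for key, path in cfg["inputs"].items():
            if not Path(path).exists():
                raise ConfigurationError(f"input {key!r} not found: {path}")
    if "simulate" in cfg:
        sim = cfg["simulate"] or {}
        sim.setdefault("seed", cfg["seed"])
        try:
            SimConfig(**sim)
        except TypeError as exc:
            raise ConfigurationError(f"bad simulation block: {exc}") from exc
        cfg["simulate"] = sim
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Mutable state shared across stages of one pipeline run."""

    def __init__(self, cfg: dict, outdir: Path):
        self.cfg = cfg
        self.outdir = outdir
        self.params = cfg["params"]
        self.seed = int(cfg["seed"])
        self.outputs: dict[str, Path] = {}
        self.tables: dict[str, object] = {}

    def write(self, name: str, df: pd.DataFrame, index: bool = False):
        path = self.outdir / f"{name}.csv"
        write_table(df, path, index=index)
        self.outputs[name] = path
        log.info("  wrote %s (%d rows)", path.name, len(df))


def _stage_simulate(run: _Run):
    sim_cfg = SimConfig(**run.cfg["simulate"])
    pharma = simulate_pharma_series(sim_cfg)
    community = simulate_community(sim_cfg)
    analytes = simulate_analytes(sim_cfg)
    truth = pharma.truth.merge(community.truth)

    run.write("concentrations", pharma.concentrations)
    run.write("recoveries", pharma.recoveries)
    run.write("standards", pharma.standards)
    run.write("peaks", pharma.peaks)
    run.write("analytes", analytes)
    meta_frames = []
    for reactor in ("control", "test"):
        for pool, mats in (("dna", community.dna), ("cdna", community.cdna)):
            name = f"counts_{pool}_{reactor}"
            path = run.outdir / f"{name}.csv"
            write_counts(mats[reactor], path)
            run.outputs[name] = path
        meta_frames.append(community.dna[reactor].sample_meta)
    meta = pd.concat(meta_frames)
    meta.index.name = "sample_id"
    run.write("sample_meta", meta, index=True)
    run.write("taxonomy", community.taxonomy)
    ord_meta = community.dna["test"].sample_meta
    ordination = simulate_ordination(ord_meta, seed=sim_cfg.seed)
    ordination.index.name = "sample_id"
    run.write("ordination_test", ordination, index=True)
    run.write("truth_removal", truth.removal)
    run.write("truth_products", truth.product_presence)
    run.write("truth_zotus", truth.zotu_table())

    run.tables.update(
        concentrations=pharma.concentrations,
        recoveries=pharma.recoveries,
        standards=pharma.standards,
        peaks=pharma.peaks,
        analytes=analytes,
        dna=community.dna,
        cdna=community.cdna,
        taxonomy=community.taxonomy,
        ordination=ordination,
    )


def _stage_load_inputs(run: _Run):
    inputs = run.cfg["inputs"]

    def need(key):
        if key not in inputs:
            raise ConfigurationError(f"inputs block missing {key!r}")
        return inputs[key]

    run.tables["concentrations"] = read_table(need("concentrations"))
    run.tables["recoveries"] = read_table(need("recoveries"))
    run.tables["peaks"] = read_table(need("peaks"))
    run.tables["analytes"] = read_table(need("analytes"))
    if "standards" in inputs:
        run.tables["standards"] = read_table(inputs["standards"])
    meta = None
    if "sample_meta" in inputs:
        meta = pd.read_csv(inputs["sample_meta"], index_col=0)
    dna, cdna = {}, {}
    for key in inputs:
        if key.startswith("counts_dna_"):
            reactor = key.removeprefix("counts_dna_")
            dna[reactor] = read_counts(inputs[key], "DNA")
            cdna_key = f"counts_cdna_{reactor}"
            cdna[reactor] = read_counts(need(cdna_key), "cDNA")
            if meta is not None:
                dna[reactor].sample_meta = meta.loc[dna[reactor].sample_ids]
                cdna[reactor].sample_meta = meta.loc[cdna[reactor].sample_ids]
    if not dna:
        raise ConfigurationError("inputs block holds no counts_dna_* tables")
    run.tables["dna"], run.tables["cdna"] = dna, cdna
    run.tables["taxonomy"] = read_taxonomy(need("taxonomy"))
    if "ordination" in inputs:
        run.tables["ordination"] = pd.read_csv(
            inputs["ordination"], index_col=0
        )


def _stage_quantify(run: _Run):
    standards = run.tables.get("standards")
    if standards is not None:
        curves = []
        for compound, sub in standards.groupby("compound"):
            curve = fit_calibration(
                list(zip(sub["nominal_ugL"], sub["area"])), compound
            )
            curves.append(
                (compound, curve.slope, curve.intercept, curve.r_squared)
            )
        run.write(
            "calibration",
            pd.DataFrame(
                curves, columns=["compound", "slope", "intercept", "r_squared"]
            ),
        )
    corrected = correct_measurements(
        run.tables["concentrations"], run.tables["recoveries"]
    )
    run.write("concentrations_corrected", corrected)
    pharma_removal = removal_series(
        corrected[corrected["reactor"] == "test"], "corrected_conc", "compound"
    )
    run.write("removal_pharma", pharma_removal)
    analytes = run.tables["analytes"]
    tn = total_nitrogen_removal_series(analytes)
    run.write("removal_tn", tn)
    per_analyte = []
    for reactor, sub in analytes.groupby("reactor"):
        r = removal_series(sub, "value", "analyte")
        r.insert(0, "reactor", reactor)
        per_analyte.append(r)
    run.write("removal_analytes", pd.concat(per_analyte, ignore_index=True))
    run.tables["corrected"] = corrected
    run.tables["removal_pharma"] = pharma_removal
    run.tables["removal_tn"] = tn


def _stage_screen(run: _Run):
    db = load_compound_db(run.cfg.get("compound_db"))
    hits = screen_peaks(
        run.tables["peaks"],
        db,
        max_ppm=run.params["max_ppm"],
        min_snr=run.params["min_snr"],
        adduct=run.params["adduct"],
    )
    run.write("screen_hits", hits)
    series = product_timeseries(hits)
    run.write("product_timeseries", series)
    run.tables["product_series"] = series


def _stage_active(run: _Run):
    p = run.params
    compositions = {}
    for reactor in sorted(run.tables["dna"]):
        calls = call_active(
            run.tables["dna"][reactor],
            run.tables["cdna"][reactor],
            n_trials=int(p["n_trials"]),
            threshold=float(p["active_threshold"]),
            depth=p["depth"],
            seed=run.seed,
        )
        run.write(f"active_calls_{reactor}", calls)
        comp = active_relative_abundance(calls, run.tables["dna"][reactor])
        comp.index.name = "zotu_id"
        run.write(f"active_composition_{reactor}", comp, index=True)
        fam = aggregate_family(comp, run.tables["taxonomy"])
        fam_full = fam.full.copy()
        run.write(f"families_full_{reactor}", fam_full, index=True)
        run.write(f"families_{reactor}", fam.reporting, index=True)
        div = diversity_indices(run.tables["dna"][reactor])
        run.write(f"diversity_{reactor}", div, index=True)
        compositions[reactor] = comp
        run.tables.setdefault("families", {})[reactor] = fam.reporting
    run.tables["compositions"] = compositions


def _stage_respond(run: _Run):
    p = run.params
    comp = run.tables["compositions"].get("test")
    if comp is None:
        reactor, comp = next(iter(run.tables["compositions"].items()))
    else:
        reactor = "test"
    t1, t2 = int(p["t1_day"]), int(p["t2_day"])
    s1, s2 = f"{reactor}_d{t1:03d}", f"{reactor}_d{t2:03d}"
    for s in (s1, s2):
        if s not in comp.columns:
            raise DataError(
                f"response timepoint sample {s!r} missing from composition"
            )
    responses = response_table(
        comp, s1, s2,
        min_abundance=float(p["min_abundance"]), band=float(p["band"]),
    )
    run.write("response_ratios", responses)
    run.tables["responses"] = responses

    ordination = run.tables.get("ordination")
    if ordination is None:
        log.info("  no ordination coordinates supplied; skipping vector fit")
        return
    corrected = run.tables["corrected"]
    eff = corrected[
        (corrected["reactor"] == reactor) & (corrected["phase"] == "effluent")
    ]
    env = eff.pivot_table(
        index="sample_id", columns="compound", values="corrected_conc",
        aggfunc="mean",
    )
    env = env.reindex(ordination.index).dropna()
    if len(env) >= 3:
        fits = fit_environment(
            ordination.loc[env.index], env,
            n_perm=int(p["n_perm"]), seed=run.seed,
        )
        run.write("vector_fit", fits)
    else:
        log.info("  fewer than 3 samples with effluent data; no vector fit")


def _stage_report(run: _Run):
    removal = run.tables["removal_pharma"].copy()
    removal.insert(0, "series", "pharmaceutical")
    removal = removal.rename(columns={"compound": "analyte"})
    tn = run.tables["removal_tn"].copy()
    tn = tn.rename(
        columns={"influent_tn": "influent_conc", "effluent_tn": "effluent_conc"}
    )
    tn.insert(0, "series", "total_nitrogen")
    tn["analyte"] = "TN"
    report = pd.concat(
        [removal, tn[["series", "analyte", "day", "reactor",
                      "influent_conc", "effluent_conc", "removal_percent"]]],
        ignore_index=True,
    )
    run.write("report_removal", report)

    run.write("report_products", run.tables["product_series"])

    fam_frames = []
    for reactor, fam in run.tables.get("families", {}).items():
        long = fam.reset_index().melt(
            id_vars="family", var_name="sample_id", value_name="abundance"
        )
        long.insert(0, "reactor", reactor)
        if long["abundance"].isna().all():
            long["empty_composition"] = True
        fam_frames.append(long)
    if fam_frames:
        run.write("report_families", pd.concat(fam_frames, ignore_index=True))

    responses = run.tables["responses"]
    counts = (
        responses["category"].value_counts()
        .reindex(["negative", "neutral", "positive"], fill_value=0)
        .rename_axis("category").reset_index(name="n_zotus")
    )
    run.write("report_response_counts", counts)


def run_pipeline(config: dict, outdir=None, seed=None) -> dict:
    """Execute all stages and return the run manifest.

    ``outdir``/``seed`` override the config's values. On stage failure a
    ``FAILED`` marker naming the stage is left in the output directory and
    the exception propagates; outputs written so far are retained.
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
        if "simulate" in cfg:
            cfg["simulate"]["seed"] = int(seed)
    out = Path(outdir if outdir is not None else cfg.get("outdir", "granulefate_out"))
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(cfg, out)

    stage_fns = [
        ("simulate", _stage_simulate if "simulate" in cfg else _stage_load_inputs),
        ("quantify", _stage_quantify),
        ("screen", _stage_screen),
        ("active", _stage_active),
        ("respond", _stage_respond),
        ("report", _stage_report),
    ]
    timings = {}
    for name, fn in stage_fns:
        log.info("stage %s", name)
        t0 = time.perf_counter()
        try:
            fn(run)
        except Exception as exc:
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            log.error("stage %s failed: %s", name, exc)
            raise
        timings[name] = round(time.perf_counter() - t0, 3)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()

    manifest = {
        "package": "granulefate",
        "version": __version__,
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
        "stage_seconds": timings,
        "outputs": {
            name: _sha256(path) for name, path in sorted(run.outputs.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
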