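"""Config-driven end-to-end run: simulate (or load) -> filter -> window
statistics -> smooth -> tracts -> tract-model fit -> barrier bootstraps.

Stages communicate through files only; every output is listed in a summary
with the seed, parameters, package version and SHA-256 of each file, enough
to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (
    censor_nuisance_sites,
    drop_uninformative,
    filter_by_di,
    read_cohort,
    write_cohort,
    read_chromosome_lengths,
)
from .resampling import circular_bootstrap
from .simulate import SimulationConfig, read_config, simulate_cohort
from .smoothing import SmoothingSpec, smooth_states
from .stats import ternary_table, window_metrics
from .tract_model import fit_tract_model
from .tracts import parse_minority_tracts, write_tracts_bed
from .windows import read_windows, write_windows

log = logging.getLogger("hzkit.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config_path, out_dir) -> Path:
    """Run the full analysis described by a YAML config; returns the results
    directory.  See ``analysis/`` for per-stage drivers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    seed = int(cfg.get("seed", 0))
    summary: dict = {"seed": seed, "version": __version__, "stages": {}, "files": {}}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except Exception as e:  # abort with the stage name
                raise StageError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            summary["stages"][name] = "ok"  # timings go to the log only, so
            # the summary is byte-identical across reruns of the same config
            return result

        return deco

    # -- inputs ----------------------------------------------------------
    if "simulate" in cfg:
        sim_cfg = dict(cfg["simulate"] or {})
        sim_cfg.setdefault("seed", seed)
        config = SimulationConfig(**sim_cfg)

        @stage("simulate")
        def _sim():
            cohort, truth = simulate_cohort(config)
            write_cohort(cohort, out / "cohort.tsv")
            write_windows(truth.windows, out / "windows.bed")
            truth.tracts.to_csv(out / "truth_tracts.tsv", sep="\t", index=False)
            truth.junctions.to_csv(out / "truth_junctions.tsv", sep="\t", index=False)
            return cohort, truth.windows

        cohort, windows = _sim
    else:
        @stage("load")
        def _load():
            cohort = read_cohort(
                cfg["cohort"],
                chromosomes=read_chromosome_lengths(cfg["chromosome_lengths"])
                if "chromosome_lengths" in cfg
                else None,
                sample_groups=cfg.get("sample_groups"),
            )
            return cohort, read_windows(cfg["windows"])

        cohort, windows = _load

    di_threshold = float(cfg.get("di_threshold", -20.0))

    @stage("filter")
    def _filter():
        c = censor_nuisance_sites(cohort)
        c = drop_uninformative(c)
        return filter_by_di(c, di_threshold)

    filtered = _filter

    @stage("stats")
    def _stats():
        tt = ternary_table(filtered, scope="sample")
        tt.to_csv(out / "ternary_sample.tsv", sep="\t", index=False)
        ternary_table(filtered, scope="chromosome").to_csv(
            out / "ternary_chromosome.tsv", sep="\t", index=False
        )
        wm = window_metrics(cohort, windows, di_threshold=di_threshold)
        wm.to_csv(out / "window_metrics.tsv", sep="\t", index=False)
        return wm

    wm = _stats

    @stage("smooth")
    def _smooth():
        spec = SmoothingSpec(**cfg.get("smoothing", {}))
        sm = smooth_states(filtered, spec)
        write_cohort(sm, out / "cohort_smoothed.tsv")
        return sm

    smoothed = _smooth

    @stage("tracts")
    def _tracts():
        hz = smoothed.samples_in_group("HZ")
        tr = parse_minority_tracts(smoothed, samples=hz or None)
        write_tracts_bed(tr, out / "tracts.bed")
        tr[["sample", "chromosome", "ancestry", "x"]].to_csv(
            out / "tract_lengths.tsv", sep="\t", index=False
        )
        return tr

    tracts = _tracts

    @stage("fit")
    def _fit():
        fit_cfg = cfg.get("fit", {})
        results = {}
        for anc, label in (("A", "into_B_background"), ("B", "into_A_background")):
            x = tracts.loc[tracts["ancestry"] == anc, "x"].to_numpy()
            try:
                fit = fit_tract_model(
                    x,
                    l_min=float(fit_cfg.get("l_min", 0.04)),
                    R=float(fit_cfg.get("R", 0.25)),
                    T=fit_cfg.get("T"),
                )
                results[label] = {
                    "theta": fit.theta,
                    "gradient": fit.gradient,
                    "slope_raw": fit.slope_raw,
                    "n_tracts": fit.n_tracts,
                    "t_lower_bound": fit.t_lower_bound,
                }
            except ValueError as e:
                results[label] = {"error": str(e)}
        (out / "tract_fit.json").write_text(json.dumps(results, indent=2))
        return results

    _fit

    @stage("bootstrap")
    def _boot():
        bs_cfg = cfg.get("bootstrap", {})
        reps = int(bs_cfg.get("reps", 1000))
        scheme = bs_cfg.get("scheme", "chrom-circular")
        rng = np.random.default_rng(seed + 1)
        results = {}
        for metric, alternative in (
            ("dbar", "greater"),
            ("junctions_per_bp", "less"),
            ("high_di_per_bp", "greater"),
        ):
            res = circular_bootstrap(
                wm[metric].to_numpy(),
                windows.barrier,
                windows.chrom,
                scheme=scheme,
                reps=reps,
                rng=rng,
                alternative=alternative,
            )
            results[metric] = {
                "observed": res.observed,
                "null_mean": float(np.nanmean(res.null_values)),
                "p_value": res.p_value,
                "scheme": scheme,
                "alternative": alternative,
                "reps": reps,
            }
        (out / "bootstrap.json").write_text(json.dumps(results, indent=2))
        return results

    _boot

    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "summary.json":
            summary["files"][f.name] = _sha256(f)
    summary["config"] = cfg
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
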