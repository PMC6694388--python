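"""End-to-end pipeline driver.

``run_pipeline`` takes a YAML/dict config with sections ``sim`` (or an
input bundle directory), ``cohort``, ``model``, ``profile`` and ``report``,
executes each stage per condition and scheme, and writes plain-text
artifacts plus a manifest recording the seeds and decisions of the run.
All randomness flows from the single config seed through named substreams
(simulation, CV folds, bootstrap). A stage failure aborts with the stage
name; artifacts written before the failure are kept.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codemaps import CodeMaps, load_toy_maps
from .cohort import build_cohort
from .covariates import SCHEME_NAMES, Scheme, build_design, write_design
from .crossval import cross_validate
from .glm import DEFAULT_SPECS, GLMSpec, predict
from .profiling import profile_hospitals, shift_table
from .reporting import (
    payment_distribution_summary, predictive_ratios, quintile_shift,
)
from .simulate import SimConfig, generate_bundle, read_bundle, write_bundle

log = logging.getLogger("payrisk.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _substream(seed: int, name: str) -> int:
    ss = np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _validate(cfg: dict) -> dict:
    cfg = dict(cfg)
    cfg.setdefault("seed", 0)
    model = cfg.setdefault("model", {})
    schemes = model.get("schemes", ["cms_base", "codes_index_history"])
    unknown = [s for s in schemes if s not in SCHEME_NAMES]
    if unknown:
        raise ValueError(f"unknown scheme(s) in config: {unknown}")
    cohort = cfg.setdefault("cohort", {})
    cohort.setdefault("conditions", ["HF"])
    cohort.setdefault("winsor_q", 0.995)
    model.setdefault("schemes", schemes)
    model.setdefault("cv_folds", 5)
    model.setdefault("max_vars", 200)
    model.setdefault("alpha", 0.005)
    prof = cfg.setdefault("profile", {})
    prof.setdefault("enabled", True)
    prof.setdefault("n_boot", 200)
    prof.setdefault("min_cases", 25)
    rep = cfg.setdefault("report", {})
    rep.setdefault("compare", schemes[:2] if len(schemes) >= 2 else None)
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Run simulate -> cohort -> features -> cv -> profile -> report.

    ``config`` is a mapping or a path to a YAML file. Returns the artifact
    directory. Deterministic given the config seed.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _validate(config)
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg.get("out_dir", "payrisk_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "stages": [],
        "decisions": {
            "winsorization": "upper-tail only, per condition cohort",
            "bootstrap_unit": "hospital cluster, percentile CI",
            "expected_payment": "random effect at prior mean 0",
            "fold_unit": "admission",
        },
    }

    def stage(name):
        def deco(fn):
            def wrapped(*a, **k):
                t0 = time.perf_counter()
                log.info("stage %s: start", name)
                try:
                    res = fn(*a, **k)
                except Exception as e:  # noqa: BLE001
                    _write_manifest(out, manifest)
                    raise PipelineError(name, e) from e
                dt = time.perf_counter() - t0
                manifest["stages"].append({"stage": name, "seconds": round(dt, 3)})
                log.info("stage %s: done in %.2fs", name, dt)
                return res
            return wrapped
        return deco

    @stage("simulate")
    def _simulate():
        if "input_dir" in cfg:
            return read_bundle(cfg["input_dir"])
        sim_kwargs = dict(cfg.get("sim", {}))
        sim_kwargs["seed"] = _substream(seed, "simulation")
        bundle = generate_bundle(SimConfig(**sim_kwargs))
        write_bundle(bundle, out / "bundle")
        return bundle

    bundle = _simulate()
    maps = (CodeMaps.from_dir(cfg["maps_dir"]) if "maps_dir" in cfg
            else load_toy_maps())
    model_cfg = cfg["model"]
    results: dict = {}

    for condition in cfg["cohort"]["conditions"]:
        cdir = out / condition
        cdir.mkdir(exist_ok=True)

        @stage(f"cohort[{condition}]")
        def _cohort():
            coh = build_cohort(bundle, condition, cfg["cohort"]["winsor_q"])
            coh.to_csv(cdir / "cohort.csv", index=False)
            return coh

        cohort = _cohort()
        if cohort.empty:
            log.warning("skipping %s: empty cohort", condition)
            continue
        spec = _spec_for(condition, cfg)
        preds: dict[str, np.ndarray] = {}

        for scheme_name in model_cfg["schemes"]:
            scheme = Scheme(scheme_name, maps,
                            model_cfg.get("freq_threshold", 0.005))
            sdir = cdir / scheme_name
            sdir.mkdir(exist_ok=True)

            @stage(f"features[{condition}/{scheme_name}]")
            def _features():
                design = build_design(cohort, bundle, scheme)
                write_design(design, sdir)
                return design

            design = _features()

            @stage(f"cv[{condition}/{scheme_name}]")
            def _cv():
                return cross_validate(
                    cohort, bundle, scheme, spec,
                    k=model_cfg["cv_folds"],
                    seed=_substream(seed, f"folds/{condition}/{scheme_name}"),
                    max_vars=model_cfg["max_vars"],
                    alpha=model_cfg["alpha"],
                )

            cv = _cv()
            preds[scheme_name] = predict(cv.full_fit, design.X.astype(float))
            card = {
                "condition": condition,
                "scheme": scheme_name,
                "family": spec.family,
                "link": spec.link,
                "pseudo_r2_full": cv.pseudo_r2_full,
                "rmse_mean": cv.rmse_mean,
                "rmse_sd": cv.rmse_sd,
                "rmse_folds": cv.rmse_folds,
                "dispersion": cv.full_fit.dispersion,
                "n_obs": cv.full_fit.n_obs,
                "selected": cv.selected_full,
                "coefficients": cv.full_fit.params.to_dict(),
                "predicted_payment": payment_distribution_summary(
                    preds[scheme_name]),
            }
            (sdir / "model_card.json").write_text(json.dumps(card, indent=1))
            results.setdefault(condition, {})[scheme_name] = card

        compare = cfg["report"].get("compare")
        if compare and all(s in preds for s in compare):
            a, b = compare[:2]

            @stage(f"report[{condition}]")
            def _report():
                y = cohort["payment_w"].to_numpy()
                predictive_ratios(preds[b], y).to_csv(
                    cdir / f"predictive_ratios_{b}.csv")
                predictive_ratios(preds[a], y).to_csv(
                    cdir / f"predictive_ratios_{a}.csv")
                qs = quintile_shift(preds[a], preds[b])
                qs.counts.to_csv(cdir / "quintile_shift.csv")
                return qs

            _report()

        if cfg["profile"]["enabled"] and compare:
            cats = {}
            for scheme_name in compare[:2]:
                scheme = Scheme(scheme_name, maps,
                                model_cfg.get("freq_threshold", 0.005))

                @stage(f"profile[{condition}/{scheme_name}]")
                def _profile():
                    design = build_design(cohort, bundle, scheme)
                    prof = profile_hospitals(
                        design.X.astype(float),
                        cohort["payment_w"].to_numpy(),
                        cohort["hospital_id"].to_numpy(),
                        spec,
                        n_boot=cfg["profile"]["n_boot"],
                        seed=_substream(
                            seed, f"bootstrap/{condition}/{scheme_name}"),
                        min_cases=cfg["profile"]["min_cases"],
                    )
                    prof.to_csv(cdir / f"hospital_profiles_{scheme_name}.csv")
                    return prof

                cats[scheme_name] = _profile()["category"]

            @stage(f"shift_table[{condition}]")
            def _shift():
                a, b = compare[:2]
                tab = shift_table(cats[a], cats[b])
                tab.counts.to_csv(cdir / "shift_table.csv")
                return tab

            _shift()

    _write_manifest(out, manifest)
    return out


def _spec_for(condition: str, cfg: dict) -> GLMSpec:
    override = cfg.get("model", {}).get("spec_overrides", {}).get(condition)
    if override:
        return GLMSpec(override["family"], override["link"],
                       allow_any=override.get("allow_any", False))
    if condition in DEFAULT_SPECS:
        return DEFAULT_SPECS[condition]
    raise ValueError(f"no GLM spec for condition {condition!r}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
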