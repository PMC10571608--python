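"""Config-driven orchestration: inputs -> connectomes -> metrics -> models.

A run config (YAML) names the inputs (time-series or connectome files plus
a cohort table and ROI map), one or more model specs with their CV scheme
and optional comparison / permutation / CPM / elastic-net settings, an
output directory, and a master seed.  ``run_pipeline`` executes every
model spec, writing per-subject predictions, summaries, and a
machine-readable manifest (package and library versions, derived seeds,
config hash).  A failing model spec is reported and skipped; the report
marks the run failed if any spec failed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import io as gio
from .cpm import ConnectomePredictiveModel
from .metrics import RoiMap
from .model import LOOCV, GraphPredictiveModel, RepeatedKFold, compare_cv
from .simulate import compute_metric_vectors

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from a master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated run configuration (see the README for the YAML layout)."""

    inputs: Mapping[str, Any]
    cohort_path: Path
    roi_map_path: Path | None
    models: list[Mapping[str, Any]]
    output_dir: Path
    seed: int = 0
    raw: Mapping[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        inputs = raw.get("inputs", {})
        cfg = cls(
            inputs=inputs,
            cohort_path=base / raw["cohort"],
            roi_map_path=(base / raw["roi_map"]) if raw.get("roi_map") else None,
            models=list(raw.get("models", [])),
            output_dir=base / raw.get("output_dir", "graphpm_out"),
            seed=int(raw.get("seed", 0)),
            raw=raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.cohort_path.exists():
            raise FileNotFoundError(f"cohort table not found: {self.cohort_path}")
        if self.roi_map_path is not None and not self.roi_map_path.exists():
            raise FileNotFoundError(f"ROI map not found: {self.roi_map_path}")
        kind = self.inputs.get("kind", "connectomes")
        if kind not in ("connectomes", "metrics"):
            raise ValueError(f"inputs.kind must be 'connectomes' or 'metrics', got {kind!r}")
        d = self.inputs.get("dir")
        if d is None or not (Path(self.cohort_path).parent / d).exists() and not Path(d).exists():
            raise FileNotFoundError(f"input directory not found: {d}")
        if not self.models:
            raise ValueError("run config lists no models")

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _scheme_from(cfg: Mapping[str, Any], seed: int):
    cv = cfg.get("cv", {"scheme": "loocv"})
    if cv.get("scheme", "loocv") == "loocv":
        return LOOCV()
    return RepeatedKFold(
        k=int(cv.get("k", 10)), repeats=int(cv.get("repeats", 1)),
        seed=int(cv.get("seed", seed)),
    )


def _load_connectomes(directory: Path, states: list[str]):
    out = {}
    for f in sorted(directory.glob("*.tsv")):
        stem = f.stem
        for state in states:
            suffix = f"_{state}"
            if stem.endswith(suffix):
                sid = stem[: -len(suffix)]
                out[(sid, state)] = gio.read_connectome(f, sid, state)
                break
    if not out:
        raise FileNotFoundError(f"no connectome files matching '*_<state>.tsv' in {directory}")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every model spec in the config; returns the report bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = gio.read_cohort_table(config.cohort_path)

    states = sorted(
        {s for m in config.models for s in m.get("candidate_states", ("task", "rest"))}
    )
    in_dir = Path(config.inputs["dir"])
    if not in_dir.exists():
        in_dir = Path(config.cohort_path).parent / config.inputs["dir"]
    kind = config.inputs.get("kind", "connectomes")
    connectomes = None
    if kind == "connectomes":
        connectomes = _load_connectomes(in_dir, states)
        roi = gio.read_roi_map(config.roi_map_path) if config.roi_map_path else RoiMap({})
        mvs = compute_metric_vectors(connectomes, roi)
    else:
        mvs = gio.read_metric_vectors(in_dir / "metric_vectors.csv")
    logger.info("loaded %d metric vectors for %d subjects",
                len(mvs), len({m.subject_id for m in mvs}))

    report: dict[str, Any] = {"models": [], "failed": []}
    for i, mcfg in enumerate(config.models):
        name = mcfg.get("name", f"model{i}")
        try:
            report["models"].append(_run_one(mcfg, name, mvs, connectomes, cohort,
                                             config, out_dir))
        except Exception as exc:  # partial-failure policy: report and continue
            logger.exception("model spec %s failed", name)
            report["failed"].append({"name": name, "error": str(exc)})

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "n_models": len(config.models),
        "n_failed": len(report["failed"]),
    }
    gio.write_json(out_dir / "manifest.json", manifest)
    gio.write_json(out_dir / "report.json", report)
    report["manifest"] = manifest
    return report


def _run_one(mcfg, name, mvs, connectomes, cohort, config, out_dir) -> dict:
    spec = gio.read_model_spec({k: v for k, v in mcfg.items() if k != "name"})
    scheme = _scheme_from(mcfg, derive_seed(config.seed, f"{name}:cv"))
    model = GraphPredictiveModel.from_metric_vectors(mvs, cohort, spec)
    logger.info("%s: %d complete cases", name, model.subjects_.size)
    res = model.fit(scheme)
    null = model.fit_null(scheme)
    entry: dict[str, Any] = {
        "name": name,
        "target": spec.target_column,
        "n_used": res.n_used,
        "mse": res.mse,
        "pearson_r": res.pearson_r,
        "mse_null": null.mse,
        "r_null": null.pearson_r,
    }
    perm = mcfg.get("permutation")
    if perm:
        pr = res.permutation_test(
            n_perm=int(perm.get("n_perm", 10_000)),
            seed=derive_seed(config.seed, f"{name}:perm"),
        )
        entry["permutation_p"] = pr.p
    if mcfg.get("compare", False):
        comp = model.compare_to_null(seed=derive_seed(config.seed, f"{name}:compare"))
        entry["comparison"] = {
            "mse_diff": comp.mse_diff, "t": comp.t, "p": comp.p,
            "k": comp.k, "repeats": comp.repeats,
        }
    cpm_cfg = mcfg.get("cpm")
    if cpm_cfg:
        state = cpm_cfg.get("state", spec.candidate_states[0])
        conns = {sid: c for (sid, st), c in (connectomes or {}).items() if st == state}
        if not conns:
            raise ValueError(f"CPM requested but no connectomes for state {state!r}")
        cpm = ConnectomePredictiveModel(
            conns, cohort, spec,
            polarity=cpm_cfg.get("polarity", "positive"),
            weight_mode=cpm_cfg.get("weight_mode", "signed"),
        )
        cres = cpm.fit(scheme)
        entry["cpm"] = {"mse": cres.mse, "pearson_r": cres.pearson_r}
        gcomp = compare_cv(model, cpm, seed=derive_seed(config.seed, f"{name}:gpm-cpm"),
                           labels=("gpm", "cpm"))
        entry["gpm_vs_cpm"] = {"mse_diff": gcomp.mse_diff, "t": gcomp.t, "p": gcomp.p}
        gio.write_predictions(out_dir / f"{name}_cpm_predictions.csv", cres)
    if mcfg.get("elastic_net", False):
        eres = model.fit_elastic_net(scheme)
        entry["elastic_net"] = {"mse": eres.mse, "pearson_r": eres.pearson_r}
    gio.write_predictions(out_dir / f"{name}_predictions.csv", res)
    gio.write_predictions(out_dir / f"{name}_null_predictions.csv", null)
    return entry


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("graphpm", "numpy", "scipy", "pandas", "scikit-learn", "igraph"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
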