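"""End-to-end orchestration of the mapped-power workflow.

Stages run in order, each persisting its artifacts so any stage can be
re-run from the previous stage's outputs:

1. ``simulate`` — dense (A) and sparse (B) pseudo-populations;
2. ``fit`` — full and reduced models per dataset, iOFV tables;
3. ``power`` — ΔOFV pools, minimum-N per path and/or a power surface;
4. ``validate`` — simulation/re-estimation precision and study costs
   for shortlisted designs.

A run manifest (JSON) records every seed, setting and stage timing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, mcmp, nlme
from .design_eval import CostSpec, sse_rse, study_cost
from .popsim import PKDataset, PopulationModel, ResidualModel, crossover_pseudopop, simulate_pseudopop
from .study_design import SamplingArm, StudyLayout, design_sample_count

__all__ = ["WorkflowConfig", "run_workflow"]

log = logging.getLogger("mixpower")


class StageError(RuntimeError):
    """A workflow stage failed; partial outputs remain on disk."""


# ---------------------------------------------------------------------------
# config parsing


def model_from_dict(d: dict) -> PopulationModel:
    ce = {}
    for item in d.get("covariate_effects", []):
        ce[(item["parameter"], item["covariate"])] = float(item["beta"])
    res = d.get("residual", {"kind": "proportional", "value": 0.1})
    return PopulationModel(
        structural=d["structural"],
        theta={k: float(v) for k, v in d["theta"].items()},
        iiv={k: float(v) for k, v in d.get("iiv", {}).items()},
        iov={k: float(v) for k, v in d.get("iov", {}).items()},
        covariate_effects=ce,
        residual=ResidualModel(res["kind"], float(res["value"]),
                               bool(res.get("value_is_sd", False))),
        n_transit=int(d.get("n_transit", 0)),
        dose_amount=float(d.get("dose_amount", 100.0)),
    )


def arm_from_dict(d: dict, label: str):
    if "by_covariate" in d:
        return {int(k): arm_from_dict(v, label) for k, v in d["by_covariate"].items()}
    kind = d["kind"]
    if kind == "fixed_times":
        return SamplingArm(kind, times=tuple(d["times"]), label=label)
    if kind == "random_subset":
        return SamplingArm(kind, times=tuple(tuple(w) for w in d["candidate_sets"]), label=label)
    return SamplingArm(kind, windows=tuple(tuple(w) for w in d["windows"]), label=label)


def _parse_paths(items) -> list:
    out = []
    for item in items:
        if isinstance(item, str):
            out.append(item)
        else:
            rd, rs = item["ratio"]
            out.append(("ratio", int(rd), int(rs)))
    return out


@dataclass
class WorkflowConfig:
    """Validated workflow configuration (see the bundled YAML configs)."""

    name: str
    model: PopulationModel
    layout: StudyLayout
    dense_arm: object
    sparse_arm: object
    pools: dict  # n_with / n_without (or n_subjects), seed_dense, seed_sparse
    power: dict  # settings, paths, bounds, seed, n_max
    fit: dict = field(default_factory=dict)  # inflate, seed, outer_maxiter
    validation: dict | None = None  # replicates, designs, cost, seed
    outdir: Path = Path("mixpower_out")

    @classmethod
    def from_dict(cls, cfg: dict, outdir=None) -> "WorkflowConfig":
        design = cfg["design"]
        val = cfg.get("validation")
        return cls(
            name=cfg.get("name", "study"),
            model=model_from_dict(cfg["model"]),
            layout=StudyLayout(design["layout"]),
            dense_arm=arm_from_dict(design["dense_arm"], "dense"),
            sparse_arm=arm_from_dict(design["sparse_arm"], "sparse"),
            pools=dict(cfg["pools"]),
            power=dict(cfg["power"]),
            fit=dict(cfg.get("fit", {})),
            validation=dict(val) if val else None,
            outdir=Path(outdir or cfg.get("output", "mixpower_out")),
        )

    @classmethod
    def from_file(cls, path, outdir=None) -> "WorkflowConfig":
        return cls.from_dict(io_formats.read_config(path), outdir=outdir)

    @property
    def settings(self) -> mcmp.LRTSettings:
        p = self.power
        return mcmp.LRTSettings(
            threshold=float(p.get("threshold", 3.84)),
            n_draws=int(p.get("n_draws", 10_000)),
            power_target=float(p.get("power_target", 80.0)),
        )

    @property
    def balance(self) -> bool:
        return self.layout.design == "parallel"


# ---------------------------------------------------------------------------
# stages


def _simulate_one(cfg: WorkflowConfig, arm, seed: int) -> PKDataset:
    if cfg.layout.design == "parallel":
        n_with = int(cfg.pools.get("n_with", 500))
        n_without = int(cfg.pools.get("n_without", n_with))
        paired = bool(cfg.pools.get("paired", n_with == n_without))
        return simulate_pseudopop(cfg.model, cfg.layout, arm, n_with, n_without, seed,
                                  paired=paired)
    n = int(cfg.pools.get("n_subjects", 500))
    return crossover_pseudopop(cfg.model, cfg.layout, arm, n, seed)


def stage_simulate(cfg: WorkflowConfig) -> dict:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for tag, arm, seed in (
        ("A_dense", cfg.dense_arm, int(cfg.pools.get("seed_dense", cfg.pools.get("seed", 1)))),
        ("B_sparse", cfg.sparse_arm, int(cfg.pools.get("seed_sparse", cfg.pools.get("seed", 1) + 1))),
    ):
        ds = _simulate_one(cfg, arm, seed)
        path = cfg.outdir / f"dataset_{tag}.csv"
        io_formats.write_dataset(ds, path)
        out[tag] = path
        log.info("simulated %s: %d subjects, %d observations (seed %d)",
                 tag, ds.n_subjects, ds.n_obs, seed)
    return out


def _fit_pair(cfg: WorkflowConfig, data: PKDataset, tag: str):
    inflate = float(cfg.fit.get("inflate", 1.2))
    seed = int(cfg.fit.get("seed", 0))
    maxiter = int(cfg.fit.get("outer_maxiter", nlme.OUTER_MAXITER))
    include_iov = cfg.layout.design == "crossover"
    full_spec = nlme.ModelSpec.from_population_model(
        cfg.model, include_covariates=True, include_iov=include_iov, inflate=inflate)
    t0 = time.perf_counter()
    fit_full = nlme.fit(data, full_spec, seed=seed, outer_maxiter=maxiter)
    reduced_spec = full_spec.reduced().with_estimates(fit_full.estimates)
    fit_reduced = nlme.fit(data, reduced_spec, seed=seed, outer_maxiter=maxiter)
    log.info("fitted %s: OFV full %.2f (conv %s), reduced %.2f (conv %s) in %.1fs",
             tag, fit_full.ofv_total, fit_full.converged,
             fit_reduced.ofv_total, fit_reduced.converged, time.perf_counter() - t0)
    return fit_full, fit_reduced


def stage_fit(cfg: WorkflowConfig) -> dict:
    fits = {}
    for tag in ("A_dense", "B_sparse"):
        path = cfg.outdir / f"dataset_{tag}.csv"
        if not path.exists():
            raise StageError(f"fit stage: missing {path}; run the simulate stage first")
        data = io_formats.read_dataset(path)
        fit_full, fit_reduced = _fit_pair(cfg, data, tag)
        fits[tag] = (fit_full, fit_reduced)
        for which, fr in (("full", fit_full), ("reduced", fit_reduced)):
            pd.DataFrame(
                [{"parameter": k, "estimate": v} for k, v in fr.estimates.items()]
            ).to_csv(cfg.outdir / f"fit_{tag}_{which}.csv", index=False)
        pool = mcmp.build_pools(fit_full, fit_reduced)["A_dense"]
        pool.arm = tag
        io_formats.write_pool(pool, cfg.outdir / f"pool_{tag}.csv")
    return fits


def stage_power(cfg: WorkflowConfig) -> dict:
    pools = {}
    for tag in ("A_dense", "B_sparse"):
        path = cfg.outdir / f"pool_{tag}.csv"
        if not path.exists():
            raise StageError(f"power stage: missing {path}; run the fit stage first")
        pool = io_formats.read_pool(path)
        pool.arm = "A_dense" if tag == "A_dense" else "B_sparse"
        pools[pool.arm] = pool
    settings = cfg.settings
    seed = int(cfg.power.get("seed", 2024))
    n_max = int(cfg.power.get("n_max", 200))
    paths = _parse_paths(cfg.power.get("paths", ["dense_only", "sparse_only"]))
    rows = []
    for path in paths:
        res = mcmp.min_n_search(pools, path, settings, seed=seed,
                                balance=cfg.balance, n_max=n_max)
        rows.append({"path": str(path), **{k: v for k, v in res.items() if k != "path"}})
        log.info("min-N %s: %s", path, res.get("total", "not achieved within bounds"))
    minn = pd.DataFrame(rows)
    minn.to_csv(cfg.outdir / "min_n.csv", index=False)
    result = {"min_n": minn}
    if "bounds" in cfg.power:
        b = cfg.power["bounds"]
        surface = mcmp.power_surface(
            pools, (tuple(b["dense"]), tuple(b["sparse"])), settings,
            seed=seed, balance=cfg.balance, step=b.get("step"))
        io_formats.write_surface(surface, cfg.outdir / "power_surface.csv")
        result["surface"] = surface
    return result


def stage_validate(cfg: WorkflowConfig) -> pd.DataFrame | None:
    if not cfg.validation:
        return None
    v = cfg.validation
    cost_cfg = v.get("cost", {})
    cost_spec = CostSpec(
        float(cost_cfg.get("hosp_dense", 1000)),
        float(cost_cfg.get("hosp_sparse", 750)),
        float(cost_cfg.get("assay", 50)),
    )
    replicates = int(v.get("replicates", 100))
    seed = int(v.get("seed", 7))
    rows = []
    for nd, ns in v.get("designs", []):
        total, dense, sparse = design_sample_count(
            cfg.layout, nd, ns,
            cfg.dense_arm if not isinstance(cfg.dense_arm, dict) else next(iter(cfg.dense_arm.values())),
            cfg.sparse_arm if not isinstance(cfg.sparse_arm, dict) else next(iter(cfg.sparse_arm.values())),
        )
        budget = study_cost(cost_spec, cfg.layout, nd, ns, total)
        row = {"n_dense": nd, "n_sparse": ns, "samples_total": total,
               "samples_dense": dense, "samples_sparse": sparse,
               "cost": budget, "patient_cost": budget / (nd + ns) if nd + ns else 0.0}
        if replicates >= 2:
            prec = sse_rse(cfg.model, cfg.layout, cfg.dense_arm, cfg.sparse_arm,
                           nd, ns, replicates, seed)
            for _, prow in prec.table.iterrows():
                row[f"rse_{prow.parameter}"] = prow.rse_percent
            row["converged_fraction"] = prec.converged_fraction
        rows.append(row)
        log.info("validated design (%d, %d): cost %.0f", nd, ns, budget)
    df = pd.DataFrame(rows)
    df.to_csv(cfg.outdir / "validation.csv", index=False)
    return df


def run_workflow(cfg: WorkflowConfig) -> dict:
    """Run every stage in order; returns the collected report.

    Any stage failure raises :class:`StageError` naming the stage;
    artifacts from completed stages stay on disk.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"name": cfg.name, "stages": {},
                "settings": {"threshold": cfg.settings.threshold,
                             "n_draws": cfg.settings.n_draws,
                             "power_target": cfg.settings.power_target},
                "seeds": {"pools": cfg.pools, "power": cfg.power.get("seed", 2024),
                          "fit": cfg.fit.get("seed", 0)}}
    report = {}
    for name, func in (("simulate", stage_simulate), ("fit", stage_fit),
                       ("power", stage_power), ("validate", stage_validate)):
        t0 = time.perf_counter()
        try:
            report[name] = func(cfg)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 2)}
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
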