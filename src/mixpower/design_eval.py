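"""Validation of shortlisted designs: parameter precision and cost.

Expected precision is obtained by stochastic simulation and
re-estimation: the candidate design is simulated ``replicates`` times,
the full model is refitted to each replicate, and each parameter's
expected relative standard error is::

    RSE(%) = 100 × SD(replicate estimates) / mean(replicate estimates)

Study cost follows the budget rule::

    budget = hospitalisation cost × patient-days + assay cost × samples

with one hospital day per occasion (all printed schedules fit within
24 h), so cross-over patients accrue two patient-days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nlme
from .popsim import PKDataset, PopulationModel, simulate_pseudopop, crossover_pseudopop
from .study_design import SamplingArm, StudyLayout, design_sample_count

__all__ = ["CostSpec", "PrecisionTable", "sse_rse", "study_cost", "simulate_design"]


class ConvergenceFailure(RuntimeError):
    """Too many replicate fits failed to converge for a reliable RSE."""


@dataclass(frozen=True)
class CostSpec:
    """Unit costs: hospitalisation per patient-day (dense/sparse arm)
    and assay cost per sample."""

    hosp_cost_dense: float
    hosp_cost_sparse: float
    assay_cost: float
    days_per_occasion: float = 1.0

    def __post_init__(self) -> None:
        if min(self.hosp_cost_dense, self.hosp_cost_sparse, self.assay_cost,
               self.days_per_occasion) < 0:
            raise ValueError("costs must be non-negative")


@dataclass
class PrecisionTable:
    """Replicate-based precision summary (one row per parameter)."""

    table: pd.DataFrame  # parameter, mean, se, rse_percent
    replicates: int
    converged_fraction: float

    def rse(self, parameter: str) -> float:
        row = self.table[self.table.parameter == parameter]
        if row.empty:
            raise KeyError(parameter)
        return float(row.rse_percent.iloc[0])


def precision_from_estimates(estimates: list[dict], replicates: int,
                             converged_fraction: float = 1.0) -> PrecisionTable:
    """Apply the RSE formula to a list of replicate estimate maps."""
    if not estimates:
        raise ValueError("no converged replicates to summarize")
    df = pd.DataFrame(estimates)
    rows = []
    for p in df.columns:
        vals = df[p].to_numpy(float)
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rse = 100.0 * se / abs(mean) if mean != 0 else np.inf
        rows.append({"parameter": p, "mean": mean, "se": se, "rse_percent": rse})
    return PrecisionTable(pd.DataFrame(rows), replicates, converged_fraction)


def simulate_design(
    model: PopulationModel,
    layout: StudyLayout,
    dense_arm,
    sparse_arm,
    n_dense: int,
    n_sparse: int,
    seed: int,
) -> PKDataset:
    """One realized study of the candidate design (mixed arms allowed).

    Parallel designs split each arm 50/50 by covariate status;
    cross-over subjects carry the covariate on occasion 1 only.  IDs are
    renumbered so dense subjects come first.
    """
    frames = []
    covs = model.covariate_names
    offset = 0
    for arm, n in ((dense_arm, n_dense), (sparse_arm, n_sparse)):
        if n == 0:
            continue
        sub_seed = seed + (0 if arm is dense_arm else 1_000_003)
        if layout.design == "parallel":
            if n % 2:
                raise ValueError("parallel arms must be even for a 50/50 covariate split")
            ds = simulate_pseudopop(model, layout, arm, n // 2, n - n // 2, sub_seed)
        else:
            ds = crossover_pseudopop(model, layout, arm, n, sub_seed)
        df = ds.df.copy()
        df["ID"] = df["ID"] + offset
        offset += n
        frames.append(df)
    if not frames:
        raise ValueError("design has no patients")
    return PKDataset(pd.concat(frames, ignore_index=True), covs, layout.design)


def sse_rse(
    model: PopulationModel,
    layout: StudyLayout,
    dense_arm,
    sparse_arm,
    n_dense: int,
    n_sparse: int,
    replicates: int,
    seed: int,
    spec: nlme.ModelSpec | None = None,
    max_nonconverged_fraction: float = 0.5,
) -> PrecisionTable:
    """Simulation/re-estimation precision of the candidate design.

    Fits the full model (IOV retained only for cross-over layouts) to
    each simulated replicate; non-converged replicates are dropped from
    the RSE and the converged fraction is reported.  More than
    ``max_nonconverged_fraction`` failures is a hard error.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for an empirical SE")
    if spec is None:
        spec = nlme.ModelSpec.from_population_model(
            model, include_covariates=True,
            include_iov=(layout.design == "crossover"), inflate=1.2,
        )
    master = np.random.SeedSequence(seed)
    children = master.spawn(replicates)
    kept = []
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        data = simulate_design(model, layout, dense_arm, sparse_arm,
                               n_dense, n_sparse, rep_seed)
        # replicate fits feed a between-replicate SD, so a single
        # optimizer pass per replicate is the right cost/precision trade
        result = nlme.fit(data, spec, seed=rep_seed, outer_maxiter=60, max_restarts=1,
                          final_cold=False)
        if result.converged:
            kept.append(result.estimates)
    frac = len(kept) / replicates
    if frac < 1.0 - max_nonconverged_fraction:
        raise ConvergenceFailure(
            f"only {len(kept)}/{replicates} replicates converged for "
            f"design ({n_dense} dense, {n_sparse} sparse)"
        )
    return precision_from_estimates(kept, replicates, frac)


def study_cost(
    spec: CostSpec,
    layout: StudyLayout,
    n_dense: int,
    n_sparse: int,
    total_samples: int,
) -> float:
    """Budget of one candidate design in cost units.

    Patient-days are ``occasions × days_per_occasion`` per patient; the
    sample count should come from :func:`study_design.design_sample_count`.
    """
    days = layout.occasions * spec.days_per_occasion
    return (
        spec.hosp_cost_dense * n_dense * days
        + spec.hosp_cost_sparse * n_sparse * days
        + spec.assay_cost * total_samples
    )
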