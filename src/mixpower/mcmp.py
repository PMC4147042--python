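"""Mapped power for mixed dense/sparse study designs.

Per-subject objective-function differences ΔOFV_i = iOFV(reduced) −
iOFV(full), computed once on large pseudo-populations (dataset A: dense
sampling; dataset B: sparse sampling), are resampled to score arbitrary
design combinations without refitting: a candidate design with
``n_dense`` dense and ``n_sparse`` sparse patients is realized by
drawing that many ΔOFV_i values from the two pools, summing them, and
comparing the sum against the likelihood-ratio threshold (3.84, χ²₁ at
p < 0.05).  Power is the fraction of 10,000 such draws whose summed
ΔOFV exceeds the threshold.

For parallel layouts the draws are stratified 50/50 by covariate status,
mirroring the balanced pseudo-population; for cross-over layouts each
pool entry already bundles a subject's two occasions, so draws are
unstratified and the subject remains the independent resampling unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nlme import FitResult

__all__ = [
    "DeltaOFVPool",
    "LRTSettings",
    "PowerSurface",
    "build_pools",
    "power_at",
    "power_surface",
    "min_n",
]


class PoolConsistencyError(ValueError):
    """Full and reduced fits do not describe the same subjects."""


@dataclass(frozen=True)
class LRTSettings:
    """Likelihood-ratio test settings for the power bootstrap."""

    threshold: float = 3.84  # χ²₁ critical value at p < 0.05
    n_draws: int = 10_000
    power_target: float = 80.0  # percent

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class DeltaOFVPool:
    """Per-subject ΔOFV values for one arm of the pseudo-population."""

    entries: pd.DataFrame  # ID, ARM, COV (0/1 or -1 if none), DOFV
    arm: str

    @property
    def values(self) -> np.ndarray:
        return self.entries.DOFV.to_numpy()

    def stratum(self, cov_value: int) -> np.ndarray:
        return self.entries.loc[self.entries.COV == cov_value, "DOFV"].to_numpy()

    @property
    def total(self) -> float:
        return float(self.entries.DOFV.sum())

    def __len__(self) -> int:
        return len(self.entries)


def _pool_from_fits(fit_full: FitResult, fit_reduced: FitResult, arm: str) -> DeltaOFVPool:
    ids_f = set(fit_full.iofv)
    ids_r = set(fit_reduced.iofv)
    if ids_f != ids_r:
        raise PoolConsistencyError(
            f"full/reduced fits cover different subjects ({len(ids_f)} vs {len(ids_r)})"
        )
    covs = [c for c in fit_full.subjects.columns if c not in ("ID", "ARM")]
    cov = covs[0] if covs else None
    rows = []
    for _, srow in fit_full.subjects.iterrows():
        sid = srow.ID
        rows.append({
            "ID": sid,
            "ARM": srow.ARM,
            "COV": int(srow[cov]) if cov else -1,
            "DOFV": fit_reduced.iofv[sid] - fit_full.iofv[sid],
        })
    return DeltaOFVPool(pd.DataFrame(rows), arm)


def build_pools(
    fit_full_A: FitResult,
    fit_reduced_A: FitResult,
    fit_full_B: FitResult | None = None,
    fit_reduced_B: FitResult | None = None,
) -> dict:
    """ΔOFV pools for the dense (A) and, if supplied, sparse (B) arm.

    Each subject's ΔOFV_i is the difference of its iOFV under the
    reduced and the full model, both evaluated at their own MLEs; the
    pool sum therefore equals the total OFV difference of the two fits.
    """
    from .nlme import cross_refine_pair

    fit_full_A, fit_reduced_A = cross_refine_pair(fit_full_A, fit_reduced_A)
    pools = {"A_dense": _pool_from_fits(fit_full_A, fit_reduced_A, "A_dense")}
    if fit_full_B is not None:
        if fit_reduced_B is None:
            raise PoolConsistencyError("sparse arm needs both full and reduced fits")
        fit_full_B, fit_reduced_B = cross_refine_pair(fit_full_B, fit_reduced_B)
        pools["B_sparse"] = _pool_from_fits(fit_full_B, fit_reduced_B, "B_sparse")
    return pools


def _draw_sums(pool: DeltaOFVPool, n: int, M: int, balance: bool,
               rng: np.random.Generator, replace: bool) -> np.ndarray:
    """Sum of n ΔOFV_i draws from one pool, for M bootstrap replicates."""
    if n == 0:
        return np.zeros(M)
    if len(pool) == 0:
        raise ValueError(f"pool {pool.arm} is empty but {n} draws requested")
    if balance:
        if n % 2:
            raise ValueError("balanced draws need an even patient count")
        half = n // 2
        out = np.zeros(M)
        for xval in (1, 0):
            vals = pool.stratum(xval)
            if len(vals) == 0:
                raise ValueError(f"pool {pool.arm} has no covariate={xval} stratum")
            out += _resample_sum(vals, half, M, rng, replace)
        return out
    return _resample_sum(pool.values, n, M, rng, replace)


def _resample_sum(vals: np.ndarray, n: int, M: int, rng, replace: bool) -> np.ndarray:
    if replace:
        idx = rng.integers(0, len(vals), size=(M, n))
        return vals[idx].sum(axis=1)
    if n > len(vals):
        raise ValueError("cannot draw more subjects than the pool holds without replacement")
    out = np.empty(M)
    for m in range(M):
        out[m] = vals[rng.choice(len(vals), size=n, replace=False)].sum()
    return out


def power_at(
    poolA: DeltaOFVPool | None,
    poolB: DeltaOFVPool | None,
    n_dense: int,
    n_sparse: int,
    settings: LRTSettings = LRTSettings(),
    balance: bool = True,
    seed: int = 0,
    with_replacement: bool = True,
) -> float:
    """Mapped power (percent) of the (n_dense, n_sparse) design.

    Draws ``settings.n_draws`` bootstrap studies, each summing
    ``n_dense`` ΔOFV_i values from the dense pool and ``n_sparse`` from
    the sparse pool, and reports the percentage of sums exceeding the
    LRT threshold.  Deterministic given ``seed``.
    """
    if n_dense + n_sparse < 1:
        raise ValueError("design must contain at least one patient")
    rng = np.random.default_rng(seed)
    M = settings.n_draws
    sums = np.zeros(M)
    if n_dense:
        if poolA is None:
            raise ValueError("dense draws requested but no dense pool given")
        sums += _draw_sums(poolA, n_dense, M, balance, rng, with_replacement)
    if n_sparse:
        if poolB is None:
            raise ValueError("sparse draws requested but no sparse pool given")
        sums += _draw_sums(poolB, n_sparse, M, balance, rng, with_replacement)
    return 100.0 * float(np.mean(sums > settings.threshold))


@dataclass
class PowerSurface:
    """Power over the (n_dense, n_sparse) grid, long format."""

    table: pd.DataFrame  # n_dense, n_sparse, power
    settings: LRTSettings
    seed: int
    balance: bool = True

    def power(self, n_dense: int, n_sparse: int) -> float:
        row = self.table[(self.table.n_dense == n_dense) & (self.table.n_sparse == n_sparse)]
        if row.empty:
            raise KeyError(f"({n_dense}, {n_sparse}) not on the surface")
        return float(row.power.iloc[0])


def power_surface(
    pools: dict,
    bounds: tuple,
    settings: LRTSettings = LRTSettings(),
    seed: int = 0,
    balance: bool = True,
    step: int | None = None,
    with_replacement: bool = True,
) -> PowerSurface:
    """Evaluate :func:`power_at` over every grid cell within bounds.

    ``bounds`` is ``((dense_lo, dense_hi), (sparse_lo, sparse_hi))``;
    the step defaults to 2 for balanced (parallel) grids and 1
    otherwise.  Each cell uses an independent child stream of ``seed``
    so the surface is reproducible cell-by-cell.
    """
    (d_lo, d_hi), (s_lo, s_hi) = bounds
    if step is None:
        step = 2 if balance else 1
    poolA = pools.get("A_dense")
    poolB = pools.get("B_sparse")
    rows = []
    ss = np.random.SeedSequence(seed)
    dense_range = list(range(d_lo, d_hi + 1, step))
    sparse_range = list(range(s_lo, s_hi + 1, step))
    children = ss.spawn(len(dense_range) * len(sparse_range))
    i = 0
    for nd in dense_range:
        for ns in sparse_range:
            child_seed = children[i].generate_state(1)[0] % (2**31)
            i += 1
            if nd + ns < 1:
                continue
            p = power_at(poolA, poolB, nd, ns, settings, balance,
                         seed=int(child_seed), with_replacement=with_replacement)
            rows.append({"n_dense": nd, "n_sparse": ns, "power": p})
    return PowerSurface(pd.DataFrame(rows), settings, seed, balance)


def min_n(surface: PowerSurface, path: str | tuple, target: float | None = None):
    """Smallest total N along a path whose power meets the target.

    ``path`` is ``"dense_only"``, ``"sparse_only"`` or ``("ratio", rd, rs)``
    selecting grid cells with n_dense:n_sparse ≈ rd:rs.  Returns a dict
    with total N and the cell; ``None`` total if the target is not
    reached within the surface bounds.
    """
    if target is None:
        target = surface.settings.power_target
    t = surface.table
    if path == "dense_only":
        sel = t[(t.n_sparse == 0) & (t.n_dense > 0)]
    elif path == "sparse_only":
        sel = t[(t.n_dense == 0) & (t.n_sparse > 0)]
    else:
        kind, rd, rs = path
        if kind != "ratio":
            raise ValueError(f"unknown path {path!r}")
        tot = t.n_dense + t.n_sparse
        frac = rd / (rd + rs)
        # cells whose dense fraction is as close to the ratio as the grid allows
        sel = t[(tot > 0) & (abs(t.n_dense - frac * tot) <= 1.0)]
    sel = sel.assign(total=sel.n_dense + sel.n_sparse).sort_values("total")
    hit = sel[sel.power >= target]
    if hit.empty:
        return {"path": path, "total": None, "achieved": False, "target": target}
    row = hit.iloc[0]
    return {
        "path": path,
        "total": int(row.total),
        "n_dense": int(row.n_dense),
        "n_sparse": int(row.n_sparse),
        "power": float(row.power),
        "achieved": True,
        "target": target,
    }


def min_n_search(
    pools: dict,
    path: str | tuple,
    settings: LRTSettings = LRTSettings(),
    seed: int = 0,
    balance: bool = True,
    n_max: int = 400,
    with_replacement: bool = True,
):
    """March along a path until the power target is first met.

    Cheaper than building a full surface when only the minimum-N summary
    is needed; uses the same per-cell child-seed scheme as
    :func:`power_surface` restricted to the path.
    """
    step = 2 if balance else 1
    ss = np.random.SeedSequence(seed)
    poolA = pools.get("A_dense")
    poolB = pools.get("B_sparse")
    for total in range(step, n_max + 1, step):
        if path == "dense_only":
            nd, ns = total, 0
        elif path == "sparse_only":
            nd, ns = 0, total
        else:
            _, rd, rs = path
            frac = rd / (rd + rs)
            nd = int(round(frac * total / step) * step)
            ns = total - nd
            if balance and (nd % 2 or ns % 2):
                continue
        child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)) + total
        p = power_at(poolA, poolB, nd, ns, settings, balance,
                     seed=child_seed, with_replacement=with_replacement)
        if p >= settings.power_target:
            return {"path": path, "total": total, "n_dense": nd, "n_sparse": ns,
                    "power": p, "achieved": True, "target": settings.power_target}
    return {"path": path, "total": None, "achieved": False, "target": settings.power_target}
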