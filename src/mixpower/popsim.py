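"""Pseudo-population simulation under the full covariate model.

Individual parameters follow the standard lognormal random-effect
construction used in population PK::

    p_i,occ = θ_p · exp(η_p + κ_p,occ) · (1 + β_p,c · X_c)

with inter-individual effects η ~ N(0, ω²_IIV), inter-occasion effects
κ ~ N(0, ω²_IOV) redrawn each occasion, and binary covariates X acting
as proportional shifts (1 + β).  Observations carry either proportional
residual error ``y = c·(1 + σ_p·ε)`` or additive error on the log scale
``ln y = ln c + σ_log·ε``; the dataset always stores concentrations on
the natural scale.

The simulator draws per-subject, per-occasion independent random
streams from a single master seed, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pk_models import _onecomp_conc, _transit_conc
from .study_design import SamplingArm, StudyLayout, realize_times

__all__ = ["PopulationModel", "ResidualModel", "PKDataset", "simulate_pseudopop", "crossover_pseudopop"]


@dataclass(frozen=True)
class ResidualModel:
    """Residual-error model: ``proportional`` (value = sd) or
    ``log_additive`` (value = variance on the log scale by default;
    set ``value_is_sd`` to read it as an sd)."""

    kind: str
    value: float
    value_is_sd: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "log_additive"):
            raise ValueError(f"unknown residual model {self.kind!r}")
        if self.value < 0:
            raise ValueError("residual magnitude must be >= 0")

    @property
    def sd(self) -> float:
        if self.kind == "proportional" or self.value_is_sd:
            return self.value
        return float(np.sqrt(self.value))


@dataclass(frozen=True)
class PopulationModel:
    """Structural + stochastic + covariate + residual specification.

    ``structural`` is ``"onecomp"`` (needs θ: ka, CL, V, F) or
    ``"transit"`` (needs θ: MTT, CL, V, F and the fixed integer
    ``n_transit``).  ``iiv``/``iov`` map parameter names to variances ω².
    ``covariate_effects`` maps ``(parameter, covariate)`` to the
    fractional effect β of the binary covariate.
    """

    structural: str
    theta: dict
    iiv: dict = field(default_factory=dict)
    iov: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    residual: ResidualModel = ResidualModel("proportional", 0.1)
    n_transit: int = 0
    dose_amount: float = 100.0
    dose_time: float = 0.0

    def __post_init__(self) -> None:
        if self.structural not in ("onecomp", "transit"):
            raise ValueError(f"unknown structural model {self.structural!r}")
        needed = {"ka", "CL", "V"} if self.structural == "onecomp" else {"MTT", "CL", "V"}
        missing = needed - set(self.theta)
        if missing:
            raise ValueError(f"theta missing {sorted(missing)}")
        for d in (self.iiv, self.iov):
            if any(v < 0 for v in d.values()):
                raise ValueError("random-effect variances must be >= 0")
        for (param, cov), beta in self.covariate_effects.items():
            if 1 + beta <= 0:
                raise ValueError(f"covariate effect on {param} must satisfy 1 + beta > 0")

    @property
    def covariate_names(self) -> list:
        return sorted({cov for _, cov in self.covariate_effects})

    def predict(self, t, params: dict):
        """Structural concentration at times ``t`` for parameter arrays."""
        F = params.get("F", 1.0)
        if self.structural == "onecomp":
            return _onecomp_conc(t, self.dose_amount, self.dose_time,
                                 params["ka"], params["CL"], params["V"], F)
        return _transit_conc(t, self.dose_amount, self.dose_time, self.n_transit,
                             params["MTT"], params["CL"], params["V"], F)

    def individual_params(self, eta: dict, covariates: dict) -> dict:
        """Apply random effects and covariates to the typical values."""
        out = {}
        for p, th in self.theta.items():
            val = th * np.exp(eta.get(p, 0.0))
            for (param, cov), beta in self.covariate_effects.items():
                if param == p:
                    val = val * (1.0 + beta * covariates.get(cov, 0.0))
            out[p] = val
        return out


@dataclass
class PKDataset:
    """Rectangular NONMEM-style records plus design metadata.

    ``df`` columns: ID, OCC (1-based), TIME (h), EVID (1 dose, 0
    observation), AMT, DV (natural scale), ARM plus one column per
    binary covariate.  Covariates are constant within a subject-occasion.
    """

    df: pd.DataFrame
    covariates: list
    design: str = "parallel"

    REQUIRED = ("ID", "OCC", "TIME", "EVID", "AMT", "DV", "ARM")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        obs = self.df[self.df.EVID == 0]
        if (self.df.TIME < 0).any():
            raise ValueError("TIME must be >= 0")
        per_occ = obs.groupby(["ID", "OCC"]).size()
        ids = self.df.ID.unique()
        if len(per_occ) and per_occ.min() < 1:
            raise ValueError("every subject-occasion needs >= 1 observation")
        doses = self.df[self.df.EVID == 1].groupby(["ID", "OCC"]).size()
        if (doses != 1).any():
            raise ValueError("exactly one dose row per subject-occasion required")
        for cov in self.covariates:
            if cov not in self.df.columns:
                raise ValueError(f"covariate column {cov!r} missing")
            if (self.df.groupby(["ID", "OCC"])[cov].nunique() > 1).any():
                raise ValueError(f"covariate {cov!r} varies within a subject-occasion")
        del ids

    @property
    def n_subjects(self) -> int:
        return self.df.ID.nunique()

    @property
    def n_obs(self) -> int:
        return int((self.df.EVID == 0).sum())

    def subset(self, ids) -> "PKDataset":
        return PKDataset(self.df[self.df.ID.isin(ids)].copy(), list(self.covariates), self.design)


def _arm_for(arm, cov_value):
    """Sparse windows may differ by covariate stratum (dict keyed by X)."""
    if isinstance(arm, dict):
        return arm[cov_value]
    return arm


def _simulate(model: PopulationModel, layout: StudyLayout, arm, subjects, seed: int) -> PKDataset:
    """Core record builder.

    ``subjects`` is a list of (subject id, {occasion -> covariate dict}).
    """
    cov_names = model.covariate_names
    master = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in master.spawn(len(subjects))]
    rows = []
    arm_label = None
    for (sid, occ_covs), rng in zip(subjects, streams):
        eta = {p: rng.normal(0.0, np.sqrt(w2)) if w2 > 0 else 0.0 for p, w2 in model.iiv.items()}
        for occ in sorted(occ_covs):
            covs = occ_covs[occ]
            kappa = {p: rng.normal(0.0, np.sqrt(w2)) if w2 > 0 else 0.0 for p, w2 in model.iov.items()}
            eff = {p: eta.get(p, 0.0) + kappa.get(p, 0.0) for p in set(eta) | set(kappa)}
            params = model.individual_params(eff, covs)
            this_arm = _arm_for(arm, covs.get(cov_names[0], 0) if cov_names else 0)
            arm_label = this_arm.label
            times = realize_times(this_arm, rng)
            conc = np.atleast_1d(model.predict(times, params))
            eps = rng.standard_normal(conc.shape)
            if model.residual.kind == "proportional":
                dv = conc * (1.0 + model.residual.sd * eps)
            else:
                with np.errstate(divide="ignore"):
                    dv = np.where(conc > 0, conc * np.exp(model.residual.sd * eps), 0.0)
            base = {"ID": sid, "OCC": occ, "ARM": this_arm.label}
            base.update({c: covs.get(c, 0) for c in cov_names})
            rows.append({**base, "TIME": model.dose_time, "EVID": 1,
                         "AMT": model.dose_amount, "DV": np.nan})
            for t, y in zip(times, dv):
                rows.append({**base, "TIME": float(t), "EVID": 0, "AMT": np.nan, "DV": float(y)})
    df = pd.DataFrame(rows)[["ID", "OCC", "TIME", "EVID", "AMT", "DV", "ARM"] + cov_names]
    return PKDataset(df, cov_names, layout.design)


def simulate_pseudopop(
    model: PopulationModel,
    layout: StudyLayout,
    arm,
    n_with: int,
    n_without: int,
    seed: int,
    paired: bool = False,
) -> PKDataset:
    """Simulate a parallel pseudo-population.

    ``n_with`` subjects carry the binary covariate and ``n_without`` do
    not; each contributes a single occasion.  For a cross-over layout
    this dispatches to :func:`crossover_pseudopop` with ``n_with``
    subjects (the covariate allocation is then per-occasion).

    With ``paired=True`` (requires equal stratum sizes) subject ``i`` of
    the covariate stratum and subject ``i`` of the reference stratum
    share one random stream — identical random effects, sampling-window
    draws and residual noise, differing only in the covariate.  This is
    a common-random-numbers device: each stratum's marginal distribution
    is exactly the model's, but the Monte-Carlo noise of the realized
    between-stratum contrast (which drives mapped power) is strongly
    reduced.  Use it for pseudo-populations feeding the power bootstrap,
    not for replicate studies whose between-stratum noise is itself of
    interest.
    """
    if layout.design == "crossover":
        return crossover_pseudopop(model, layout, arm, n_with, seed)
    if paired and n_with != n_without:
        raise ValueError("paired simulation needs equal covariate strata")
    cov_names = model.covariate_names
    cov = cov_names[0] if cov_names else None
    subjects = []
    for i in range(n_with + n_without):
        x = 1 if i < n_with else 0
        subjects.append((i + 1, {1: {cov: x} if cov else {}}))
    if not paired:
        return _simulate(model, layout, arm, subjects, seed)
    ds1 = _simulate(model, layout, arm, subjects[:n_with], seed)
    ds0 = _simulate(model, layout, arm, subjects[n_with:], seed)
    df = pd.concat([ds1.df, ds0.df], ignore_index=True)
    return PKDataset(df, cov_names, layout.design)


def crossover_pseudopop(
    model: PopulationModel,
    layout: StudyLayout,
    arm,
    n_subjects: int,
    seed: int,
) -> PKDataset:
    """Simulate a cross-over pseudo-population.

    Each subject is observed on two occasions, carrying the binary
    covariate on occasion 1 and not on occasion 2; inter-occasion
    effects are redrawn per occasion.
    """
    cov_names = model.covariate_names
    cov = cov_names[0] if cov_names else None
    subjects = []
    for i in range(n_subjects):
        occ_covs = {occ + 1: ({cov: layout.covariate_for_occasion(occ)} if cov else {})
                    for occ in range(2)}
        subjects.append((i + 1, occ_covs))
    return _simulate(model, replace(layout) if layout.design == "crossover" else StudyLayout("crossover"),
                     arm, subjects, seed)
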