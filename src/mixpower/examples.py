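"""The two bundled worked examples.

``hypothetical``: a one-compartment first-order-absorption drug with a
binary covariate raising clearance by 30%, studied under parallel and
cross-over layouts with a 16-point dense schedule and a 2-sample sparse
schedule (one draw from each of two candidate-time windows).

``dihydroartemisinin``: the anti-malarial, transit-compartment
absorption (7 transit compartments), with pregnancy raising clearance
by 20%, a 10-point dense schedule and a 4-sample sparse schedule whose
windows differ between pregnant and non-pregnant patients.  The
additionally reported literature covariate (parasitemia on F) has no
published magnitude and is omitted; its influence on the pregnancy
covariate's power is assumed second-order.

Dose amounts are not part of either published model; a default of 100
units is used.  Under multiplicative covariates with proportional (or
additive-on-log) residual error the likelihood-ratio statistic is
invariant to the dose scale, which only relabels volume-related
quantities.
"""

from __future__ import annotations

from .design_eval import CostSpec
from .popsim import PopulationModel, ResidualModel
from .study_design import SamplingArm, StudyLayout

__all__ = [
    "hypothetical_model", "hypothetical_dense_arm", "hypothetical_sparse_arm",
    "dha_model", "dha_dense_arm", "dha_sparse_arm",
    "parallel_cost", "crossover_cost",
]

HYPOTHETICAL_DENSE_TIMES = (0, 0.5, 1, 1.5, 2, 2.5, 3, 4, 5, 6, 8, 10, 12, 16, 20, 24)
HYPOTHETICAL_SPARSE_WINDOWS = (
    (0, 0.5, 1, 1.5, 2, 2.5, 3, 4),
    (5, 6, 8, 10, 12, 16, 20, 24),
)
DHA_DENSE_TIMES = (0, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 12)
DHA_SPARSE_WINDOWS_PREGNANT = ((0.42, 0.48), (1.2, 3.4), (3.4, 4.9), (6.0, 8.0))
DHA_SPARSE_WINDOWS_NONPREGNANT = ((0.28, 0.48), (0.5, 0.95), (2.5, 3.7), (5.8, 6.6))


def hypothetical_model(dose_amount: float = 100.0) -> PopulationModel:
    """Hypothetical drug: ka 0.8/h, CL 20 L/h, V 70 L; lognormal IIV
    (variances 0.1/0.08/0.1), IOV on CL (0.02), 30% covariate on CL,
    10% proportional residual error."""
    return PopulationModel(
        structural="onecomp",
        theta={"ka": 0.8, "CL": 20.0, "V": 70.0, "F": 1.0},
        iiv={"ka": 0.1, "CL": 0.08, "V": 0.1},
        iov={"CL": 0.02},
        covariate_effects={("CL", "COV"): 0.3},
        residual=ResidualModel("proportional", 0.1),
        dose_amount=dose_amount,
    )


def hypothetical_dense_arm() -> SamplingArm:
    return SamplingArm("fixed_times", times=HYPOTHETICAL_DENSE_TIMES, label="dense")


def hypothetical_sparse_arm() -> SamplingArm:
    """Two samples per subject-occasion, one drawn uniformly from each
    candidate-time window."""
    return SamplingArm("random_subset", times=HYPOTHETICAL_SPARSE_WINDOWS, label="sparse")


def dha_model(dose_amount: float = 100.0, log_residual_is_sd: bool = False) -> PopulationModel:
    """Dihydroartemisinin: 7 transit compartments, MTT 0.982 h (IOV
    0.23), CL 78 L/h, V 129 L (IIV 0.0162), F fixed at 1 with IIV
    0.0881, 20% pregnancy covariate on CL, additive residual on the log
    scale (0.58, read as a variance by default)."""
    return PopulationModel(
        structural="transit",
        theta={"MTT": 0.982, "CL": 78.0, "V": 129.0, "F": 1.0},
        iiv={"F": 0.0881, "V": 0.0162},
        iov={"MTT": 0.23},
        covariate_effects={("CL", "PREG"): 0.2},
        residual=ResidualModel("log_additive", 0.58, value_is_sd=log_residual_is_sd),
        n_transit=7,
        dose_amount=dose_amount,
    )


def dha_dense_arm() -> SamplingArm:
    return SamplingArm("fixed_times", times=DHA_DENSE_TIMES, label="dense")


def dha_sparse_arm() -> dict:
    """Sparse windows keyed by pregnancy status (1 pregnant, 0 not)."""
    return {
        1: SamplingArm("windows", windows=DHA_SPARSE_WINDOWS_PREGNANT, label="sparse"),
        0: SamplingArm("windows", windows=DHA_SPARSE_WINDOWS_NONPREGNANT, label="sparse"),
    }


def parallel_cost() -> CostSpec:
    """1,000 / 750 units per patient-day (dense/sparse), 50 per sample."""
    return CostSpec(1000.0, 750.0, 50.0)


def crossover_cost() -> CostSpec:
    """Same per-day rates; cross-over patients accrue two patient-days,
    reproducing the printed 2,000 / 1,500 per-patient hospital costs."""
    return CostSpec(1000.0, 750.0, 50.0)


def parallel_layout() -> StudyLayout:
    return StudyLayout("parallel")


def crossover_layout() -> StudyLayout:
    return StudyLayout("crossover")
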