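"""Sampling schedules and study layouts.

A :class:`SamplingArm` describes how blood samples are timed for one arm
of a study:

* ``fixed_times`` — every subject is sampled at the full printed list of
  times (the dense arms);
* ``random_subset`` — per subject and occasion, one time is drawn
  uniformly from each window's discrete candidate set (the hypothetical
  sparse arm: two windows of candidate times, two samples);
* ``windows`` — per subject and occasion, one time is drawn uniformly
  (continuously) from each window interval (the dihydroartemisinin
  sparse arm: four windows, four samples).

A :class:`StudyLayout` fixes the covariate allocation: ``parallel``
(one occasion; half the subjects carry the binary covariate) or
``crossover`` (two occasions; each subject carries the covariate on
occasion 1 only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SamplingArm", "StudyLayout", "realize_times", "design_sample_count"]


class DesignConfigError(ValueError):
    """A sampling arm or layout is internally inconsistent."""


@dataclass(frozen=True)
class SamplingArm:
    """One sampling schedule (dense or sparse).

    ``times`` is the full list for ``fixed_times``, or a list of
    candidate-set lists (one per window) for ``random_subset``.
    ``windows`` is a list of ``(lower, upper)`` intervals in hours.
    """

    kind: str  # fixed_times | random_subset | windows
    times: tuple = ()
    windows: tuple = ()
    label: str = "dense"

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_times", "random_subset", "windows"):
            raise DesignConfigError(f"unknown sampling-arm kind {self.kind!r}")
        if self.kind == "fixed_times":
            ts = tuple(float(t) for t in self.times)
            if not ts:
                raise DesignConfigError("fixed_times arm needs a non-empty time list")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise DesignConfigError("fixed times must be strictly increasing")
            object.__setattr__(self, "times", ts)
        elif self.kind == "random_subset":
            sets = tuple(tuple(float(t) for t in w) for w in self.times)
            if not sets or any(len(w) == 0 for w in sets):
                raise DesignConfigError("random_subset arm needs non-empty candidate sets")
            object.__setattr__(self, "times", sets)
        else:
            ws = tuple((float(lo), float(hi)) for lo, hi in self.windows)
            if not ws or any(hi <= lo for lo, hi in ws):
                raise DesignConfigError("windows must be non-degenerate (lower < upper)")
            object.__setattr__(self, "windows", ws)

    @property
    def samples_per_occasion(self) -> int:
        """Number of samples one subject contributes per occasion."""
        if self.kind == "fixed_times":
            return len(self.times)
        if self.kind == "random_subset":
            return len(self.times)  # one draw per candidate window
        return len(self.windows)


@dataclass(frozen=True)
class StudyLayout:
    """Parallel (between-subject covariate) or cross-over (within-subject)."""

    design: str  # parallel | crossover

    def __post_init__(self) -> None:
        if self.design not in ("parallel", "crossover"):
            raise DesignConfigError(f"unknown design {self.design!r}")

    @property
    def occasions(self) -> int:
        return 1 if self.design == "parallel" else 2

    def covariate_for_occasion(self, occ: int) -> int:
        """Cross-over rule: covariate present on occasion 1, absent on 2."""
        if self.design != "crossover":
            raise DesignConfigError("covariate_for_occasion applies to cross-over layouts")
        return 1 if occ == 0 else 0


def realize_times(arm: SamplingArm, rng: int | np.random.Generator) -> np.ndarray:
    """Realize one subject-occasion's sample times (h), sorted ascending.

    ``fixed_times`` returns the full candidate list verbatim;
    ``random_subset`` draws one time uniformly from each window's
    candidate set; ``windows`` draws one time uniformly from each
    continuous interval.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if arm.kind == "fixed_times":
        return np.asarray(arm.times, float)
    if arm.kind == "random_subset":
        picks = [w[rng.integers(len(w))] for w in arm.times]
        return np.sort(np.asarray(picks, float))
    lows = np.array([lo for lo, _ in arm.windows])
    highs = np.array([hi for _, hi in arm.windows])
    return np.sort(rng.uniform(lows, highs))


def design_sample_count(
    layout: StudyLayout,
    n_dense: int,
    n_sparse: int,
    dense_arm: SamplingArm,
    sparse_arm: SamplingArm,
) -> tuple[int, int, int]:
    """Total / dense / sparse sample counts for a candidate design.

    Linear in both patient counts: each patient contributes
    ``samples_per_occasion × occasions`` samples.
    """
    if n_dense < 0 or n_sparse < 0:
        raise DesignConfigError("patient counts must be non-negative")
    dense = n_dense * layout.occasions * dense_arm.samples_per_occasion
    sparse = n_sparse * layout.occasions * sparse_arm.samples_per_occasion
    return dense + sparse, dense, sparse
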