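"""Design constants and published parameter estimates for the emulated cage study.

The synthetic-data generator emulates a predator/parasitoid functional-response
experiment on the green peach aphid (*Myzus persicae*): a ladybird beetle
(*Harmonia axyridis*) and an aphidiine parasitoid (*Aphidius gifuensis*)
foraging singly or in heterospecific pairs inside caged pepper plants, with
prey either aggregated on one plant or divided uniformly among four.  Seven
initial densities, ten replicate cages each, one 24-hour exposure.

Time convention: rates and handling times are expressed per exposure period
(duration = 1), the convention under which the published estimates below are
self-consistent with their saturation levels (asymptote 1/Th prey per period).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import FRParams

__all__ = [
    "DISTRIBUTIONS",
    "ENEMIES",
    "STUDY_DENSITIES",
    "STUDY_REPLICATES",
    "STUDY_DURATION",
    "ReferenceFit",
    "REFERENCE_ESTIMATES",
    "reference_params",
]

DISTRIBUTIONS = ("aggregate", "uniform")
ENEMIES = ("predator_single", "parasitoid_single", "predator_paired", "parasitoid_paired")

STUDY_DENSITIES = (4, 8, 16, 32, 64, 128, 256)
STUDY_REPLICATES = 10
STUDY_DURATION = 1.0  # one 24-h exposure period


@dataclass(frozen=True)
class ReferenceFit:
    """Published type II estimates for one treatment cell (95% CIs in parentheses in the source)."""

    attack_rate: float
    attack_rate_ci: tuple[float, float]
    handling_time: float
    handling_time_ci: tuple[float, float]
    linear_coefficient: float


#: Published estimates per (enemy, distribution) cell, used as generating
#: truths by the synthetic experiment generator and as recovery targets.
REFERENCE_ESTIMATES: dict[tuple[str, str], ReferenceFit] = {
    ("predator_single", "aggregate"): ReferenceFit(1.590, (1.306, 1.979), 0.006, (0.005, 0.008), -0.006),
    ("predator_single", "uniform"): ReferenceFit(1.145, (0.961, 1.358), 0.007, (0.006, 0.008), -0.005),
    ("parasitoid_single", "aggregate"): ReferenceFit(0.645, (0.465, 0.890), 0.013, (0.007, 0.021), -0.004),
    ("parasitoid_single", "uniform"): ReferenceFit(0.541, (0.424, 0.678), 0.022, (0.015, 0.029), -0.005),
    ("predator_paired", "aggregate"): ReferenceFit(1.908, (1.629, 2.263), 0.007, (0.006, 0.008), -0.007),
    ("predator_paired", "uniform"): ReferenceFit(1.317, (1.024, 1.642), 0.007, (0.006, 0.009), -0.005),
    ("parasitoid_paired", "aggregate"): ReferenceFit(0.177, (0.129, 0.249), 0.015, (0.006, 0.024), -0.002),
    ("parasitoid_paired", "uniform"): ReferenceFit(0.213, (0.162, 0.312), 0.013, (0.002, 0.024), -0.002),
}


def reference_params(enemy: str, distribution: str) -> FRParams:
    """Generating parameters for one treatment cell, on the per-exposure scale."""
    ref = REFERENCE_ESTIMATES[(enemy, distribution)]
    return FRParams(attack_rate=ref.attack_rate, handling_time=ref.handling_time, duration=STUDY_DURATION)
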