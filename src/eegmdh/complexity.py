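"""Exact model-size and arithmetic-cost accounting.

Every retained neuron carries 6 coefficients and its forward pass costs
8 multiplications and 5 additions (b1·x1, b2·x2, x1², b3·x1², x2², b4·x2²,
x1·x2, b5·x1·x2; then five sums).  The reference decremental schedule
40-38-27-22-16-10-8-5 therefore totals 166 neurons, 996 trainable parameters
and 1,328 + 830 = 2,158 arithmetic operations per classified sample.  The
selected output neuron is a member of the last hidden layer, not an extra
unit, and standardization / decode arithmetic is excluded: the counts cover
polynomial neurons only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

from .gmdh import GMDHModel

__all__ = [
    "PARAMS_PER_NEURON",
    "MULTS_PER_NEURON",
    "ADDS_PER_NEURON",
    "ComplexityReport",
    "count_neurons",
    "count_parameters",
    "count_operations",
    "profile_schedule",
    "profile_model",
]

PARAMS_PER_NEURON = 6
MULTS_PER_NEURON = 8
ADDS_PER_NEURON = 5


@dataclass(frozen=True)
class ComplexityReport:
    total_neurons: int
    trainable_parameters: int
    multiplications: int
    additions: int
    total_operations: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        return (f"neurons               {self.total_neurons}\n"
                f"trainable parameters  {self.trainable_parameters}\n"
                f"multiplications       {self.multiplications}\n"
                f"additions             {self.additions}\n"
                f"total operations      {self.total_operations}")


def count_neurons(schedule: Sequence[int]) -> int:
    """Total retained neurons: the sum of layer widths."""
    return int(sum(schedule))


def count_parameters(schedule: Sequence[int]) -> int:
    """6 coefficients per neuron."""
    return PARAMS_PER_NEURON * count_neurons(schedule)


def count_operations(schedule: Sequence[int]) -> tuple[int, int, int]:
    """(multiplications, additions, total) per forward pass."""
    n = count_neurons(schedule)
    mults, adds = MULTS_PER_NEURON * n, ADDS_PER_NEURON * n
    return mults, adds, mults + adds


def profile_schedule(schedule: Sequence[int]) -> ComplexityReport:
    mults, adds, total = count_operations(schedule)
    return ComplexityReport(
        total_neurons=count_neurons(schedule),
        trainable_parameters=count_parameters(schedule),
        multiplications=mults,
        additions=adds,
        total_operations=total,
    )


def profile_model(model: GMDHModel) -> ComplexityReport:
    """Profile a fitted model's realized widths (which may fall below the
    nominal schedule on small inputs); structure-only, independent of the
    coefficient values."""
    return profile_schedule(model.realized_widths())
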