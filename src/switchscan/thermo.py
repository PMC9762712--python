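"""Thermal parameters shared by the linear-response and PMF stages."""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL_MOL_K = 0.001987204259


@dataclass(frozen=True)
class ThermalParameters:
    """Simulation temperature and the derived thermal energy.

    The default 310 K matches body temperature, the condition the RAS
    trajectories were generated at; kBT is then ≈0.616 kcal/mol.
    """

    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy in kcal/mol."""
        return KB_KCAL_MOL_K * self.temperature
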