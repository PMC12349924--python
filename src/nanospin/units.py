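"""Reduced-unit system and SI conversions.

All simulation quantities are expressed in reduced units: the bead
diameter ``sigma`` (length), the Lennard-Jones time ``tau`` (time), the
energy scale ``epsilon`` and the bead mass ``m = 1``.  The physical
interpretation of those units is *derived*, not asserted: the membrane
thickness pins down ``sigma``, the lipid lateral diffusion coefficient
pins down ``tau``, and the simulated temperature pins down ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass

BOLTZMANN_SI = 1.380649e-23  # J/K (exact, SI definition)

#: dimension -> exponents of (sigma, tau, epsilon) in the reduced unit
_DIMENSIONS: dict[str, tuple[float, float, float]] = {
    "length": (1.0, 0.0, 0.0),
    "time": (0.0, 1.0, 0.0),
    "energy": (0.0, 0.0, 1.0),
    # 2D (membrane) pressure / tension / stretching modulus: energy / area
    "pressure_2d": (-2.0, 0.0, 1.0),
    "diffusion": (2.0, -1.0, 0.0),
}


class UnitError(ValueError):
    """Invalid unit-system parameter or unknown dimension."""


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced units and SI.

    Parameters
    ----------
    sigma_SI : float
        Length of one sigma in metres.
    tau_SI : float
        Duration of one tau in seconds.
    epsilon_SI : float
        Energy of one epsilon in joules.
    boltzmann_SI : float
        Boltzmann constant in J/K.
    """

    sigma_SI: float
    tau_SI: float
    epsilon_SI: float
    boltzmann_SI: float = BOLTZMANN_SI

    def __post_init__(self) -> None:
        for name in ("sigma_SI", "tau_SI", "epsilon_SI", "boltzmann_SI"):
            if not getattr(self, name) > 0:
                raise UnitError(f"{name} must be strictly positive")

    def si_per_reduced(self, dimension: str) -> float:
        """SI magnitude of one reduced unit of *dimension*."""
        try:
            a, b, c = _DIMENSIONS[dimension]
        except KeyError:
            supported = ", ".join(sorted(_DIMENSIONS))
            raise UnitError(
                f"unknown dimension {dimension!r}; supported: {supported}"
            ) from None
        return self.sigma_SI**a * self.tau_SI**b * self.epsilon_SI**c

    def to_si(self, value: float, dimension: str) -> float:
        return value * self.si_per_reduced(dimension)

    def to_reduced(self, value: float, dimension: str) -> float:
        return value / self.si_per_reduced(dimension)


def convert(
    value: float, dimension: str, direction: str, units: UnitSystem
) -> float:
    """Convert *value* between reduced and SI units.

    ``direction`` is ``"reduced_to_si"`` or ``"si_to_reduced"``.
    """
    if direction == "reduced_to_si":
        return units.to_si(value, dimension)
    if direction == "si_to_reduced":
        return units.to_reduced(value, dimension)
    raise UnitError(
        f"unknown direction {direction!r}; use 'reduced_to_si' or 'si_to_reduced'"
    )


def derive_unit_system(
    membrane_thickness_physical: float,
    membrane_thickness_model: float,
    D_physical: float,
    D_model: float,
    T_physical: float,
    T_model: float,
    boltzmann_SI: float = BOLTZMANN_SI,
) -> UnitSystem:
    """Derive the SI interpretation of the reduced units by calibration.

    Parameters
    ----------
    membrane_thickness_physical : float
        Bilayer thickness in metres (mammalian membranes: ~5e-9).
    membrane_thickness_model : float
        Bilayer thickness of the model in sigma (~5).
    D_physical : float
        Experimental lipid lateral diffusion coefficient, m^2/s.
    D_model : float
        Model lipid lateral diffusion coefficient, sigma^2/tau.
    T_physical : float
        Physical temperature in kelvin.
    T_model : float
        Simulated temperature in epsilon/k_B.

    Returns
    -------
    UnitSystem
        sigma_SI = thickness ratio, tau_SI = D_model*sigma_SI^2/D_physical,
        epsilon_SI = k_B*T_physical/T_model.
    """
    args = {
        "membrane_thickness_physical": membrane_thickness_physical,
        "membrane_thickness_model": membrane_thickness_model,
        "D_physical": D_physical,
        "D_model": D_model,
        "T_physical": T_physical,
        "T_model": T_model,
    }
    for name, v in args.items():
        if not v > 0:
            raise UnitError(f"{name} must be strictly positive, got {v!r}")
    sigma_SI = membrane_thickness_physical / membrane_thickness_model
    tau_SI = D_model * sigma_SI**2 / D_physical
    epsilon_SI = boltzmann_SI * T_physical / T_model
    return UnitSystem(sigma_SI, tau_SI, epsilon_SI, boltzmann_SI)


def paper_units() -> UnitSystem:
    """Unit system from the published calibration inputs.

    5 nm membrane thickness vs 5 sigma, 5 um^2/s lipid diffusion vs
    1e-2 sigma^2/tau, 310 K vs 1.1 epsilon/k_B.  Evaluates to
    sigma = 1 nm, tau = 2 ns, epsilon = 3.89e-21 J.
    """
    return derive_unit_system(5e-9, 5.0, 5e-12, 1e-2, 310.0, 1.1)


def si_interpretation_table(units: UnitSystem) -> list[tuple[str, float, str]]:
    """Rows of (reduced unit, SI value, SI unit) for reporting."""
    return [
        ("sigma", units.sigma_SI * 1e9, "nm"),
        ("tau", units.tau_SI * 1e9, "ns"),
        ("epsilon", units.epsilon_SI, "J"),
        ("epsilon/sigma^2", units.si_per_reduced("pressure_2d") * 1e3, "mN/m"),
        ("sigma^2/tau", units.si_per_reduced("diffusion") * 1e12, "um^2/s"),
    ]
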