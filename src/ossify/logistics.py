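"""Mineralization-logistics calculus: from static vesicle morphometry to
transport kinetics.

The model treats mineralization as an inverse transport problem: the tissue
volume each cell must mineralize per day is known (from the lacunar
density), the cargo per vesicle is known (mean vesicle volume × filling
factor), so the required vesicle shedding rate follows; combined with the
standing number of vesicles per cell and the intracellular travel distance,
the mean vesicle velocity follows.  Mineral precursor is assumed to have
the same mass density as the bone mineral phase, so the entire chain stays
in volume units.

Units: µm and µm³ throughout, durations in minutes, rates per minute,
intervals in seconds, velocities in µm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

from .morphometry import StackSummary


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass
class SerumBudgetParams:
    """Whole-organism serum calcium budget at hatching.

    Defaults: 0.15 g total body calcium, 2.55 mM serum calcium, skeleton
    mass 8.1 g at a bone density of 1900 kg/m³.
    """

    body_calcium_mass: float = 0.15          # g
    serum_calcium_conc: float = 2.55e-3      # mol/L
    calcium_molar_mass: float = 40.08        # g/mol
    skeleton_mass: float = 8.1               # g
    bone_density: float = 1900.0             # kg/m³

    def __post_init__(self) -> None:
        _require_positive(body_calcium_mass=self.body_calcium_mass,
                          serum_calcium_conc=self.serum_calcium_conc,
                          calcium_molar_mass=self.calcium_molar_mass,
                          skeleton_mass=self.skeleton_mass,
                          bone_density=self.bone_density)


@dataclass
class SerumBudgetResult:
    calcium_amount: float    # mol
    serum_volume: float      # L
    skeleton_volume: float   # mL
    volume_ratio: float      # serum volume / skeleton volume


@dataclass
class LogisticsParams:
    """Inputs of the kinetic chain.

    ``lacunar_density`` is the osteocyte lacunar density (lacunae per mm³),
    a proxy for the density of mineralizing cells; ``precursor_per_vesicle``
    is the mean precursor cargo volume (µm³); ``mineralization_duration``
    the time available to mineralize the per-cell volume (minutes, default
    one day); ``vesicles_per_cell`` the standing census; ``travel_distance``
    the intracellular path to the shedding site (µm).
    """

    lacunar_density: float = 196_000.0       # per mm³
    precursor_per_vesicle: float = 0.058     # µm³
    mineralization_duration: float = 1440.0  # min
    vesicles_per_cell: float = 37.0
    cell_volume_assumed: float = 1000.0      # µm³
    travel_distance: float = 10.0            # µm

    def __post_init__(self) -> None:
        _require_positive(lacunar_density=self.lacunar_density,
                          precursor_per_vesicle=self.precursor_per_vesicle,
                          mineralization_duration=self.mineralization_duration,
                          vesicles_per_cell=self.vesicles_per_cell,
                          cell_volume_assumed=self.cell_volume_assumed,
                          travel_distance=self.travel_distance)


@dataclass
class LogisticsResult:
    per_cell_volume: float   # µm³ to mineralize per cell per duration
    cube_edge: float         # µm, edge of the equivalent cube
    shedding_rate: float     # vesicles per minute
    release_interval: float  # s between releases
    vesicle_velocity: float  # µm/s


@dataclass
class DiffusionComparison:
    diffusive_time: float               # s to cover the distance by diffusion
    effective_diffusive_velocity: float  # µm/s
    feasible_by_diffusion: bool


def serum_budget(params: SerumBudgetParams | None = None) -> SerumBudgetResult:
    """Serum volume needed to supply the skeleton's calcium.

    ``calcium_amount = mass / molar_mass``; ``serum_volume = amount /
    concentration``; the skeleton volume is ``mass / density`` and the
    ratio says how many skeleton volumes of serum must be processed.
    """
    p = params or SerumBudgetParams()
    amount = p.body_calcium_mass / p.calcium_molar_mass            # mol
    serum_volume = amount / p.serum_calcium_conc                   # L
    skeleton_volume = p.skeleton_mass / (p.bone_density / 1000.0)  # mL
    return SerumBudgetResult(calcium_amount=amount, serum_volume=serum_volume,
                             skeleton_volume=skeleton_volume,
                             volume_ratio=serum_volume * 1000.0 / skeleton_volume)


def per_cell_mineralization_volume(lacunar_density: float) -> tuple[float, float]:
    """Tissue volume per cell (µm³) and the equivalent cube edge (µm).

    ``lacunar_density`` is in lacunae per mm³; one mm³ is 10⁹ µm³.
    """
    _require_positive(lacunar_density=lacunar_density)
    volume = 1e9 / lacunar_density
    return volume, volume ** (1.0 / 3.0)


def shedding_rate(per_cell_volume: float, precursor_per_vesicle: float,
                  duration: float) -> float:
    """Vesicles a cell must shed per minute (duration in minutes)."""
    _require_positive(per_cell_volume=per_cell_volume,
                      precursor_per_vesicle=precursor_per_vesicle,
                      duration=duration)
    return per_cell_volume / precursor_per_vesicle / duration


def release_interval(rate: float) -> float:
    """Seconds between successive vesicle releases at ``rate`` per minute."""
    _require_positive(rate=rate)
    return 60.0 / rate


def vesicle_velocity(travel_distance: float, vesicles_per_cell: float,
                     rate: float) -> float:
    """Mean intracellular vesicle velocity in µm/s.

    A standing population of N vesicles releasing at ``rate`` per minute
    has a residence time N/(rate/60) s; covering ``travel_distance`` in
    that time requires distance × rate / (60 N).
    """
    _require_positive(travel_distance=travel_distance,
                      vesicles_per_cell=vesicles_per_cell, rate=rate)
    return travel_distance * rate / (60.0 * vesicles_per_cell)


def diffusion_comparison(travel_distance: float, diffusion_coefficient: float,
                         required_velocity: float,
                         convention: str = "3d") -> DiffusionComparison:
    """Can passive diffusion match the required transport velocity?

    ``diffusive_time`` uses the mean-squared-displacement first-passage
    estimate t = d²/(6D) in 3D (``convention="1d"`` gives d²/(2D)); the
    effective velocity d/t is compared against ``required_velocity``.
    """
    _require_positive(travel_distance=travel_distance,
                      diffusion_coefficient=diffusion_coefficient,
                      required_velocity=required_velocity)
    factors = {"3d": 6.0, "1d": 2.0}
    if convention not in factors:
        raise ValueError("convention must be '3d' or '1d'")
    t = travel_distance**2 / (factors[convention] * diffusion_coefficient)
    v_eff = travel_distance / t
    return DiffusionComparison(diffusive_time=t, effective_diffusive_velocity=v_eff,
                               feasible_by_diffusion=v_eff >= required_velocity)


def end_to_end(params: LogisticsParams | None = None,
               summary: StackSummary | None = None) -> LogisticsResult:
    """Chain the kinetic calculus from lacunar density to vesicle velocity.

    When a :class:`StackSummary` is given, its ``precursor_per_vesicle``
    replaces the parameter value, reproducing the per-stack derived rows.
    """
    p = params or LogisticsParams()
    if summary is not None:
        p = LogisticsParams(lacunar_density=p.lacunar_density,
                            precursor_per_vesicle=summary.precursor_per_vesicle,
                            mineralization_duration=p.mineralization_duration,
                            vesicles_per_cell=p.vesicles_per_cell,
                            cell_volume_assumed=p.cell_volume_assumed,
                            travel_distance=p.travel_distance)
    volume, edge = per_cell_mineralization_volume(p.lacunar_density)
    rate = shedding_rate(volume, p.precursor_per_vesicle, p.mineralization_duration)
    return LogisticsResult(per_cell_volume=volume, cube_edge=edge,
                           shedding_rate=rate,
                           release_interval=release_interval(rate),
                           vesicle_velocity=vesicle_velocity(
                               p.travel_distance, p.vesicles_per_cell, rate))
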