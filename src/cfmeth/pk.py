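"""Steady-state pharmacokinetic model of cell-type-specific cfDNA.

DNA released by dying cells behaves like a drug given by constant-rate
infusion: at steady state its plasma concentration is

    C = d * k0 * t_half / (ln 2 * Vd)

where ``k0`` is the release ("infusion") rate in pg/min, ``t_half`` the
steady-state half-life of circulating DNA, ``Vd`` the volume of
distribution, and ``d`` the proportion of released DNA that reaches plasma
cfDNA at all (observed to span ~3% for megakaryocytes/endothelium down to
0.003% for erythrocyte progenitors).  Dividing by the total plasma cfDNA
concentration gives the fraction of cfDNA attributable to the dying
population — here, lower motor neurons, whose total count (~500,000) is
minute compared with the turnover of blood lineages.

Internal units are pg, min and µl throughout; the public surface accepts
human units (years/days, litres, percent) and converts explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["PKParams", "CfDNADetectabilityModel", "MINUTES_PER_YEAR", "MINUTES_PER_DAY"]

MINUTES_PER_DAY = 24 * 60
MINUTES_PER_YEAR = 365 * MINUTES_PER_DAY  # 525,600


@dataclass(frozen=True)
class PKParams:
    """Constants of the steady-state detectability model.

    Defaults: total lower-motor-neuron count 5e5; 6.46 pg of DNA per diploid
    genome; plasma-availability fraction d = 3% (the megakaryocyte/
    endothelium maximum); steady-state half-life 114 min; plasma volume of
    distribution 3.0 L; total plasma cfDNA concentration 297 pg/µl.
    """

    d: float = 0.03  # fraction of released DNA reaching plasma cfDNA
    t_half_min: float = 114.0
    vd_litres: float = 3.0
    genome_mass_pg: float = 6.46
    n_cells: float = 5e5
    total_cfdna_pg_per_ul: float = 297.0

    def __post_init__(self) -> None:
        if not 0.0 < self.d <= 1.0:
            raise ValueError("d must lie in (0, 1]")
        for name in ("t_half_min", "vd_litres", "genome_mass_pg", "n_cells",
                     "total_cfdna_pg_per_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def vd_ul(self) -> float:
        return self.vd_litres * 1e6

    @classmethod
    def with_d_percent(cls, d_percent: float, **kwargs) -> "PKParams":
        """Construct with ``d`` given in percent (3 -> 0.03)."""
        return cls(d=d_percent / 100.0, **kwargs)


class CfDNADetectabilityModel:
    """Forward and inverse steady-state cfDNA detectability calculations."""

    def __init__(self, params: PKParams | None = None):
        self.params = params or PKParams()

    # -- forward -----------------------------------------------------------

    def steady_state_concentration(self, k0_pg_per_min: float) -> float:
        """Plasma concentration (pg/µl) at release rate ``k0`` (pg/min)."""
        p = self.params
        return p.d * k0_pg_per_min * p.t_half_min / (math.log(2.0) * p.vd_ul)

    def death_rate_from_duration(
        self,
        duration_min: float | None = None,
        duration_years: float | None = None,
        duration_days: float | None = None,
        n_cells: float | None = None,
    ) -> float:
        """DNA release rate (pg/min) if ``n_cells`` die uniformly over the
        duration (give exactly one of minutes, days or years)."""
        duration = _one_duration(duration_min, duration_years, duration_days)
        n = self.params.n_cells if n_cells is None else n_cells
        return n * self.params.genome_mass_pg / duration

    def max_cfdna_fraction(
        self,
        duration_min: float | None = None,
        duration_years: float | None = None,
        duration_days: float | None = None,
    ) -> float:
        """Maximum fraction of plasma cfDNA derived from the population if
        all of it dies over the given disease duration (dimensionless)."""
        k0 = self.death_rate_from_duration(duration_min, duration_years, duration_days)
        return self.steady_state_concentration(k0) / self.params.total_cfdna_pg_per_ul

    def max_cfdna_percent(self, **duration) -> float:
        return 100.0 * self.max_cfdna_fraction(**duration)

    # -- inverse -----------------------------------------------------------

    def required_death_rate(self, target_fraction: float) -> float:
        """Cell deaths per minute needed to sustain a target cfDNA fraction.

        Exact algebraic inverse of :meth:`max_cfdna_fraction`:
        ``required_death_rate(max_cfdna_fraction(T)) * T == n_cells``.
        """
        if target_fraction <= 0:
            raise ValueError("target fraction must be positive")
        if target_fraction > 1:
            raise ValueError("target fraction cannot exceed 1")
        p = self.params
        k0 = (
            target_fraction
            * p.total_cfdna_pg_per_ul
            * math.log(2.0)
            * p.vd_ul
            / (p.d * p.t_half_min)
        )
        return k0 / p.genome_mass_pg

    def required_death_rate_per_day(self, target_fraction: float) -> float:
        return self.required_death_rate(target_fraction) * MINUTES_PER_DAY

    # -- curves ------------------------------------------------------------

    def duration_curve(self, durations_years) -> pd.DataFrame:
        """Fraction (and %) of plasma cfDNA vs disease duration in years."""
        rows = [
            (y, self.max_cfdna_fraction(duration_years=y),
             self.max_cfdna_percent(duration_years=y))
            for y in durations_years
        ]
        return pd.DataFrame(
            rows, columns=["duration_years", "cfdna_fraction", "cfdna_percent"]
        )

    def target_curve(self, target_fractions) -> pd.DataFrame:
        """Required death rate (cells/min and cells/day) vs target fraction."""
        rows = [
            (t, self.required_death_rate(t), self.required_death_rate_per_day(t))
            for t in target_fractions
        ]
        return pd.DataFrame(
            rows, columns=["target_fraction", "deaths_per_min", "deaths_per_day"]
        )


def _one_duration(duration_min, duration_years, duration_days) -> float:
    given = [
        v for v in (duration_min, duration_years, duration_days) if v is not None
    ]
    if len(given) != 1:
        raise ValueError("give exactly one of duration_min/years/days")
    if duration_years is not None:
        duration_min = duration_years * MINUTES_PER_YEAR
    elif duration_days is not None:
        duration_min = duration_days * MINUTES_PER_DAY
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return float(duration_min)
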