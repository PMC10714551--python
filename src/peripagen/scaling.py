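"""Mutation-rate derivation and year/generation unit conversions.

The per-year rate is calibrated from silent-site divergence to a sister
taxon, μ = K_S / (2T); the per-generation rate is μ_year × generation time
(default 25 years, a standard value for long-lived conifers).  K_S is an
input, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_GENERATION_TIME = 25.0  # years
DEFAULT_MU_PER_GEN = 5.58e-9  # per site per generation
DEFAULT_MU_PER_YEAR = 2.23e-10  # per site per year


@dataclass
class RateConstants:
    mu_per_year: float = DEFAULT_MU_PER_YEAR
    generation_time: float = DEFAULT_GENERATION_TIME
    K_S: float = None
    T_split_years: float = None

    @property
    def mu_per_gen(self) -> float:
        return per_year_to_per_gen(self.mu_per_year, self.generation_time)


def mu_from_ks(K_S: float, T_years: float) -> float:
    """μ per site per year from silent divergence: μ = K_S / (2T)."""
    if T_years <= 0:
        raise ValueError("T must be > 0")
    if K_S < 0:
        raise ValueError("K_S must be >= 0")
    return K_S / (2.0 * T_years)


def per_year_to_per_gen(mu_per_year: float, generation_time: float) -> float:
    if mu_per_year <= 0 or generation_time <= 0:
        raise ValueError("rates and generation time must be > 0")
    return mu_per_year * generation_time


def per_gen_to_per_year(mu_per_gen: float, generation_time: float) -> float:
    if mu_per_gen <= 0 or generation_time <= 0:
        raise ValueError("rates and generation time must be > 0")
    return mu_per_gen / generation_time


def scaled_2Nm(N_e: float, m: float) -> float:
    """Population-scaled migration 2Nm (expected migrant lineages/gen)."""
    if N_e <= 0:
        raise ValueError("N_e must be > 0")
    if m < 0:
        raise ValueError("m must be >= 0")
    return 2.0 * N_e * m


def years_to_generations(t_years: float, generation_time: float) -> float:
    if t_years <= 0 or generation_time <= 0:
        raise ValueError("times must be > 0")
    return t_years / generation_time


def generations_to_years(t_gen: float, generation_time: float) -> float:
    if t_gen <= 0 or generation_time <= 0:
        raise ValueError("times must be > 0")
    return t_gen * generation_time
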