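"""Synthetic inputs with the statistical structure the scaling analyses assume.

The analyses in this package consume three kinds of data — forest-plot tables
of (largest-tree mass, total plot biomass), herbivore community tables of
(body mass, density), and gridded nutrient-source domains.  The generators
here emulate each of them from the size-spectrum assumptions themselves:

* forest plots: stem radii drawn from a truncated r^(-2) spectrum with a
  per-plot maximum radius drawn log-uniformly, stem masses from m = c_m r^(8/3),
  and multiplicative lognormal noise on the plot total (the residual
  structure of log-log biomass regressions);
* animal communities: log-spaced cohort masses with densities falling as
  m^(-3/4), the energetic-equivalence density spectrum, normalised to a total
  community density;
* grids: a rectangular all-land basin with a floodplain-like source band,
  sized to Amazon-basin order of magnitude (60 x 40 cells of 50 km).

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import GridDomain
from .transport import HerbivoreCohort, HerbivoreCommunity

__all__ = [
    "GeneratorConfig",
    "sample_truncated_power_law",
    "generate_forest_plots",
    "generate_animal_community",
    "pleistocene_community",
    "generate_amazon_like_grid",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for the forest-plot generator.

    Defaults emulate a compilation of a few hundred forest plots spanning
    roughly three decades of largest-tree mass: 200 plots of 2500 stems,
    radii from 1 cm up to a per-plot maximum drawn log-uniformly between
    0.1 m and 1.5 m, and lognormal noise of sd 0.2 (natural-log scale) on the
    plot biomass total.
    """

    seed: int = 0
    n_plots: int = 200
    stems_per_plot: int = 2500
    r_min: float = 0.01
    r_max_low: float = 0.1
    r_max_high: float = 1.5
    eta: float = 2.0
    c_m: float = 8000.0
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max_low < self.r_max_high):
            raise ValueError("require 0 < r_min < r_max_low < r_max_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_plots < 1 or self.stems_per_plot < 1:
            raise ValueError("n_plots and stems_per_plot must be >= 1")


def sample_truncated_power_law(
    n: int,
    exponent: float,
    lower: float,
    upper: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw n sizes with density proportional to x^(-exponent) on [lower, upper].

    Uses the analytic inverse CDF of the truncated Pareto: with p = 1 - exponent,
    F^{-1}(u) = (lower^p + u (upper^p - lower^p))^(1/p).  ``exponent`` must not
    be 1 (the logarithmic case is outside this package's needs).
    """
    if not (0 < lower < upper):
        raise ValueError("require 0 < lower < upper")
    if exponent == 1:
        raise ValueError("exponent 1 not supported")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    p = 1.0 - exponent
    return (lower**p + u * (upper**p - lower**p)) ** (1.0 / p)


def truncated_power_law_mean(exponent: float, lower: float, upper: float) -> float:
    """Analytic mean of the truncated power-law distribution (for checks)."""
    p = 1.0 - exponent
    q = 2.0 - exponent
    norm = (upper**p - lower**p) / p
    # q = 0 (exponent 2) is the logarithmic case of the first-moment integral
    first = np.log(upper / lower) if q == 0 else (upper**q - lower**q) / q
    return first / norm


def generate_forest_plots(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a table of synthetic forest plots.

    Per plot: draw r_max log-uniformly in [r_max_low, r_max_high]; sample
    stem radii from the truncated r^(-eta) spectrum on [r_min, r_max]; convert
    to masses via c_m r^(8/3); record the largest stem mass (m_max) and the
    plot total (m_tot) under multiplicative lognormal noise.  The noisy total
    is floored at m_max so every record satisfies m_tot >= m_max.

    Returns a DataFrame with columns plot_id, n_stems, m_max, m_tot.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_plots):
        r_max = np.exp(rng.uniform(np.log(config.r_max_low), np.log(config.r_max_high)))
        radii = sample_truncated_power_law(
            config.stems_per_plot, config.eta, config.r_min, r_max, rng
        )
        masses = config.c_m * radii ** (8.0 / 3.0)
        m_max = float(masses.max())
        m_tot = float(masses.sum()) * float(np.exp(rng.normal(0.0, config.noise_sd)))
        records.append(
            {
                "plot_id": f"plot_{i:04d}",
                "n_stems": config.stems_per_plot,
                "m_max": m_max,
                "m_tot": max(m_tot, m_max),
            }
        )
    return pd.DataFrame(records)


def generate_animal_community(
    n_cohorts: int,
    m_min: float,
    m_max: float,
    density_exponent: float = 0.75,
    total_density: float = 25.0,
    label: str = "",
) -> HerbivoreCommunity:
    """Build a cohort community with masses log-spaced on [m_min, m_max].

    Cohort densities fall as mass^(-density_exponent) and are normalised so
    they sum to ``total_density`` individuals per km^2.  The construction is
    deterministic (no sampling): cohorts are idealised mass classes, not
    individual species.
    """
    if not (0 < m_min < m_max):
        raise ValueError("require 0 < m_min < m_max")
    if n_cohorts < 1:
        raise ValueError("need at least one cohort")
    masses = np.logspace(np.log10(m_min), np.log10(m_max), n_cohorts)
    raw = masses ** (-density_exponent)
    densities = total_density * raw / raw.sum()
    cohorts = [
        HerbivoreCohort(mass=float(m), density=float(d))
        for m, d in zip(masses, densities)
    ]
    return HerbivoreCommunity(cohorts, label=label)


def pleistocene_community() -> HerbivoreCommunity:
    """Synthetic Pleistocene-like herbivore community, 10 kg to 10,000 kg.

    Sixteen log-spaced cohorts up to the mass of the largest terrestrial
    Pleistocene herbivore (~10,000 kg), densities falling as m^(-3/4).  This
    is an idealised stand-in for a real regional fauna list, used as the
    reference community for diffusivity calibration.
    """
    return generate_animal_community(
        n_cohorts=16, m_min=10.0, m_max=10_000.0, label="pleistocene-like"
    )


def generate_amazon_like_grid(
    nx: int = 60,
    ny: int = 40,
    dx: float = 50.0,
    source_spec: str = "west:1",
) -> GridDomain:
    """Rectangular all-land basin with a floodplain-like source band.

    ``source_spec`` is "west:W" (source = W westernmost columns) or
    "band:START:W" (source = W columns starting at column START), emulating a
    river floodplain running through the basin.  The default 60 x 40 cells at
    dx = 50 km span 3000 x 2000 km — Amazon-basin order of magnitude.
    """
    land = np.ones((ny, nx), dtype=bool)
    source = np.zeros((ny, nx), dtype=bool)
    parts = source_spec.split(":")
    try:
        if parts[0] == "west":
            (width,) = (int(parts[1]),)
            start = 0
        elif parts[0] == "band":
            start, width = int(parts[1]), int(parts[2])
        else:
            raise ValueError
    except (IndexError, ValueError):
        raise ValueError(f"unrecognised source_spec {source_spec!r}") from None
    if width < 1 or start < 0 or start + width > nx:
        raise ValueError("source band outside grid")
    if width >= nx and start == 0:
        raise ValueError("source must not cover the whole grid")
    source[:, start : start + width] = True
    return GridDomain(nx=nx, ny=ny, dx=dx, land_mask=land, source_mask=source)
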