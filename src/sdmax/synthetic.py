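"""Synthetic environmental stacks, truth suitability, and presence samples.

The generator emulates the statistical structure a presence-background
suitability analysis assumes: spatially autocorrelated bioclim-like layers
(with deliberately collinear pairs so variable pruning has work to do), a
truth suitability surface with a unimodal thermal response peaking at a known
optimum plus a monotone response to a second variable, and presence points
drawn proportionally to truth suitability with optional sampling bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .grid_io import DEFAULT_NODATA, EnvStack, OccurrenceSet, RasterGrid

__all__ = ["TruthConfig", "generate_env_stack", "true_suitability", "sample_occurrences"]

# Plausible value ranges for the default bioclim-like layers (min, max, units).
DEFAULT_RANGES: dict[str, tuple[float, float, str]] = {
    "bio1": (-5.0, 28.0, "degC"),    # annual mean temperature
    "bio2": (4.0, 18.0, "degC"),     # mean diurnal range
    "bio4": (200.0, 1200.0, "/"),    # temperature seasonality
    "bio12": (50.0, 2200.0, "mm"),   # annual precipitation
    "bio13": (10.0, 400.0, "mm"),    # precipitation of wettest month
    "bio17": (0.0, 300.0, "mm"),     # precipitation of driest quarter
    "elev": (0.0, 4000.0, "m"),
}


@dataclass
class TruthConfig:
    """Parameters of the simulated truth.

    The truth suitability is
    ``inv_logit(intercept - (driver - optimum)^2 / (2 breadth^2)
    + secondary_slope * secondary + noise)`` so the response to the driver is
    unimodal (Gaussian on the logit scale, peaking at ``optimum``) and the
    response to the secondary variable is monotone.
    """

    driver_variable: str = "bio1"
    optimum: float = 18.0           # degC, thermal optimum of the species
    breadth: float = 0.8            # degC, s.d. of the Gaussian response
    secondary_variable: str = "bio2"
    secondary_slope: float = 0.1    # per-unit logit slope
    intercept: float = 0.0          # logit at the optimum with secondary at 0
    noise_sd: float = 0.0           # logit-scale noise
    correlated_pairs: list[tuple[str, str, float]] = dc_field(
        default_factory=lambda: [("bio13", "bio12", 0.9)]
    )
    variables: list[str] = dc_field(
        default_factory=lambda: ["bio1", "bio2", "bio4", "bio12", "bio13", "bio17"]
    )
    smoothing_sigma: float = 2.0    # cells, Gaussian kernel of the random fields
    n_presence: int = 500
    bias_strength: float = 0.0      # 0 = unbiased sampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be positive")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must be in [0, 1]")
        for src, tgt, rho in self.correlated_pairs:
            if not -1.0 < rho < 1.0:
                raise ValueError(f"target correlation for ({src},{tgt}) must be in (-1,1)")


class GenerationError(RuntimeError):
    """Requested statistical structure could not be realized."""


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized spatially autocorrelated Gaussian field."""
    f = rng.standard_normal(shape)
    if sigma > 0:
        f = ndimage.gaussian_filter(f, sigma=sigma, mode="reflect")
    f = (f - f.mean()) / f.std()
    return f


def _rescale(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = f.min(), f.max()
    if fmax == fmin:
        return np.full_like(f, (lo + hi) / 2)
    return lo + (f - fmin) * (hi - lo) / (fmax - fmin)


def generate_env_stack(
    header: dict,
    config: TruthConfig,
    scenario_label: str = "current",
    driver_offset: float = 0.0,
    max_redraws: int = 20,
) -> EnvStack:
    """Generate a stack of smoothed random fields with controlled collinearity.

    Each layer is a Gaussian-smoothed white-noise field rescaled to a
    plausible range for its variable. For each ``(source, target, rho)``
    entry in ``config.correlated_pairs`` the target layer is built as a mix
    ``rho * source_field + sqrt(1 - rho^2) * independent_field``, redrawing
    the independent part until the realized Pearson correlation is within
    0.05 of the target.

    ``driver_offset`` shifts the driver layer (a warming scenario analog).
    """
    rng = np.random.default_rng(config.seed)
    shape = (int(header["nrows"]), int(header["ncols"]))
    targets = {tgt: (src, rho) for src, tgt, rho in config.correlated_pairs}

    raw_fields: dict[str, np.ndarray] = {}
    for name in config.variables:
        if name in targets:
            continue
        raw_fields[name] = _smooth_field(rng, shape, config.smoothing_sigma)
    for tgt, (src, rho) in targets.items():
        if src not in raw_fields:
            raise GenerationError(f"correlated pair source {src!r} not among generated variables")
        base = raw_fields[src]
        for _ in range(max_redraws):
            indep = _smooth_field(rng, shape, config.smoothing_sigma)
            mixed = rho * base + np.sqrt(1.0 - rho**2) * indep
            r = float(np.corrcoef(base.ravel(), mixed.ravel())[0, 1])
            if abs(r - rho) <= 0.05:
                raw_fields[tgt] = mixed
                break
        else:
            raise GenerationError(
                f"could not realize correlation {rho} between {src} and {tgt} "
                f"after {max_redraws} redraws"
            )

    layers = []
    for name in config.variables:
        lo, hi, units = DEFAULT_RANGES.get(name, (0.0, 1.0, ""))
        vals = _rescale(raw_fields[name], lo, hi)
        if name == config.driver_variable and driver_offset:
            vals = vals + driver_offset
        layers.append(
            RasterGrid(
                ncols=int(header["ncols"]),
                nrows=int(header["nrows"]),
                xllcorner=float(header["xllcorner"]),
                yllcorner=float(header["yllcorner"]),
                cellsize=float(header["cellsize"]),
                nodata_value=float(header.get("nodata_value", DEFAULT_NODATA)),
                values=vals,
                variable_name=name,
                units=units,
            )
        )
    return EnvStack(layers=layers, scenario_label=scenario_label)


def true_suitability(stack: EnvStack, config: TruthConfig) -> RasterGrid:
    """Truth suitability surface in (0, 1) from the configured response model."""
    try:
        driver = stack[config.driver_variable]
        secondary = stack[config.secondary_variable]
    except KeyError as exc:
        raise ValueError(f"truth configuration needs a variable missing from the stack: {exc}")
    logit = (
        config.intercept
        - (driver.values - config.optimum) ** 2 / (2.0 * config.breadth**2)
        + config.secondary_slope * secondary.values
    )
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed + 1)
        logit = logit + rng.normal(0.0, config.noise_sd, size=logit.shape)
    suit = expit(logit)
    mask = stack.valid_mask()
    out = np.where(mask, suit, driver.nodata_value)
    return driver.with_values(out, variable_name="true_suitability")


def sample_occurrences(
    suitability: RasterGrid,
    config: TruthConfig,
    species: str = "synthetic_species",
) -> OccurrenceSet:
    """Draw presence points with probability proportional to suitability.

    Cells are drawn with replacement proportionally to suitability (times an
    optional smooth bias field of strength ``bias_strength``); each draw is
    jittered to a uniform location inside its cell so that several draws of
    one cell yield distinct coordinates.
    """
    rng = np.random.default_rng(config.seed + 2)
    mask = suitability.valid_mask()
    probs = np.where(mask, suitability.values, 0.0).astype(float)
    probs = np.clip(probs, 0.0, None)
    if config.bias_strength > 0:
        bias = _smooth_field(rng, probs.shape, config.smoothing_sigma)
        bias = _rescale(bias, 1.0 - config.bias_strength, 1.0)
        probs = probs * bias
    total = probs.sum()
    if total <= 0:
        raise ValueError("cannot sample from an all-zero suitability surface")
    flat = probs.ravel() / total
    draws = rng.choice(flat.size, size=config.n_presence, p=flat)
    rows, cols = np.unravel_index(draws, probs.shape)
    jit_x = rng.random(config.n_presence)
    jit_y = rng.random(config.n_presence)
    records = []
    cs = suitability.cellsize
    for r, c, jx, jy in zip(rows, cols, jit_x, jit_y):
        lon = suitability.xllcorner + (c + jx) * cs
        lat = suitability.yllcorner + (suitability.nrows - 1 - r + jy) * cs
        records.append((species, float(lon), float(lat)))
    return OccurrenceSet(records=records)
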