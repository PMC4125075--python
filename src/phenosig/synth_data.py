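"""Seeded generators for synthetic growth panels and expression datasets.

No public growth-curve or promoter-activity dataset accompanies the
analyses this package implements, so every pipeline is exercised on
synthetic data with the statistical structure the analyses assume:

* **Strain panels** — each strain is the reference growth ODE with its own
  jittered kinetic constants; each culture condition (control, plasmid,
  low temperature, low nutrient) perturbs the model the way the matching
  experiment would; replicate optical-density curves differ by
  multiplicative measurement noise (plate-reader error grows with signal;
  default 2% CV) at 10-minute sampling.
* **Expression datasets** — groups of co-regulated promoters share a latent
  condition-specific temporal signal (a localized oscillatory burst);
  each promoter reads the latent signal through its own gain (strong or
  weak regulation) plus independent noise.

Generators are pure functions of (spec, seed): the same inputs always
produce the same data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import IntegrationError, ValidationError
from .growth_io import GrowthCurve
from .growth_model import GrowthModel, apply_perturbation, simulate_growth

__all__ = [
    "StrainPanelSpec",
    "make_strain_panel",
    "make_expression_dataset",
    "panel_to_plate",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "plasmid", "low_temperature", "low_nutrient")


@dataclass(frozen=True)
class StrainPanelSpec:
    """Design of a synthetic strain panel.

    Attributes
    ----------
    n_strains, replicates : int
        Panel size (>= 2 each).
    jitter : float
        Log-normal parameter jitter per strain (fractional SD of the
        kinetic constants around the reference values).
    noise_cv : float
        Multiplicative measurement noise CV on the optical density.
    conditions : tuple of str
        Subset of ``("control", "plasmid", "low_temperature",
        "low_nutrient")`` simulated for every strain.
    condition_jitter : float
        Strain-to-strain variability of the *response* to each non-control
        condition (log-normal factor on the perturbation's strength).  Real
        strains do not react identically to a plasmid, a temperature shift
        or nutrient limitation; this is what makes multi-condition
        multiplexing informative.
    dt, horizon : float
        Sampling interval (default 10 min) and duration in hours.
    low_nutrient_factor : float
        Fraction of the control initial nutrient used in the low-nutrient
        condition.
    """

    n_strains: int = 4
    replicates: int = 3
    jitter: float = 0.10
    noise_cv: float = 0.02
    conditions: tuple = ("control",)
    condition_jitter: float = 0.15
    dt: float = 1.0 / 6.0
    horizon: float = 24.0
    od0: float = 0.05
    low_nutrient_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2 or self.replicates < 2:
            raise ValidationError("need n_strains >= 2 and replicates >= 2")
        if self.noise_cv < 0 or self.jitter < 0:
            raise ValidationError("noise and jitter must be >= 0")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValidationError(f"unknown condition {c!r}")


def _strain_model(base: GrowthModel, jitter: float, rng) -> GrowthModel:
    params = base.params * np.exp(rng.normal(0.0, jitter, len(base.params)))
    return replace(base, params=params)


def _condition_model(model: GrowthModel, condition: str, factor: float,
                     response: float = 1.0) -> GrowthModel:
    """Apply a condition to a strain model, scaled by its strain response."""
    if condition == "control":
        return model
    if condition == "plasmid":
        params = model.params.copy()
        params[3] = 1.2 * response  # k4 clamped to the plasmid-load value
        return replace(model, params=params)
    if condition == "low_temperature":
        return replace(model, params=model.params * min(0.7 * response, 0.95))
    # low nutrient: reduced initial substrate, same kinetics
    x0 = list(model.x0)
    x0[0] *= min(factor * response, 0.9)
    return replace(model, x0=tuple(x0))


def make_strain_panel(spec: StrainPanelSpec | None = None) -> list[GrowthCurve]:
    """Generate labeled growth curves for a panel of synthetic strains.

    Per strain, the reference kinetic constants are jittered once; per
    condition the strain model is perturbed accordingly and simulated; per
    replicate, multiplicative Gaussian noise is applied to the clean OD
    curve.  Strains whose jittered parameters fail to integrate are
    resampled (with a logged message).
    """
    if spec is None:
        spec = StrainPanelSpec()
    rng = np.random.default_rng(spec.seed)
    base = GrowthModel()
    times = np.arange(0.0, spec.horizon + 1e-9, spec.dt)
    curves = []
    well = 0
    for s in range(spec.n_strains):
        for attempt in range(20):
            model = _strain_model(base, spec.jitter, rng)
            responses = {
                c: float(np.exp(rng.normal(0.0, spec.condition_jitter)))
                for c in spec.conditions if c != "control"
            }
            try:
                sims = {
                    c: simulate_growth(
                        _condition_model(model, c, spec.low_nutrient_factor,
                                         responses.get(c, 1.0)),
                        t_end=spec.horizon, dt=spec.dt, od0=spec.od0,
                    )
                    for c in spec.conditions
                }
                break
            except IntegrationError:
                logger.info("strain %d: unstable jittered parameters; resampled", s)
        else:
            raise IntegrationError(f"could not generate a stable strain after 20 tries")
        for c in spec.conditions:
            clean = sims[c].od
            for r in range(spec.replicates):
                noise = 1.0 + spec.noise_cv * rng.standard_normal(len(times))
                od = np.maximum(clean * noise, 1e-6)
                curves.append(
                    GrowthCurve(
                        times=times,
                        od=od,
                        strain=f"strain{s}",
                        condition=c,
                        well=f"W{well:03d}",
                    )
                )
                well += 1
    return curves


def panel_to_plate(curves: list[GrowthCurve]):
    """Split a panel into the wide-CSV data frame dict and layout mapping."""
    layout = {c.well: (c.strain, c.condition) for c in curves}
    return curves, layout


def _latent_signal(times, period: float, center: float, width: float) -> np.ndarray:
    """A localized oscillatory burst: Gaussian window times a sinusoid."""
    envelope = np.exp(-0.5 * ((times - center) / width) ** 2)
    return envelope * np.sin(2.0 * np.pi * times / period)


def make_expression_dataset(
    n_groups: int = 3,
    promoters_per_group: int = 8,
    conditions: int = 6,
    n_points: int = 96,
    dt: float = 1.0 / 6.0,
    noise: float = 0.05,
    gain_range: tuple = (0.5, 1.5),
    seed: int = 0,
):
    """Synthetic promoter-activity profiles with regulon structure.

    Every group of promoters shares a latent temporal signal per condition
    whose burst period and timing are group- and condition-specific; a
    promoter's profile is ``gain * latent + noise`` with a promoter-specific
    gain (constant across conditions, mimicking strong versus weak
    regulation by the shared regulator).

    Returns
    -------
    profiles : list of ndarray
        One ``(n_promoters, n_points)`` matrix per condition.
    labels : ndarray
        True group index per promoter.
    times : ndarray
        Shared time grid (hours).
    """
    if n_groups < 2:
        raise ValidationError("need at least 2 promoter groups")
    rng = np.random.default_rng(seed)
    times = np.arange(n_points) * dt
    duration = n_points * dt
    n_prom = n_groups * promoters_per_group
    labels = np.repeat(np.arange(n_groups), promoters_per_group)
    gains = rng.uniform(*gain_range, size=n_prom)

    # Group-specific burst periods, log-spaced within the admissible band;
    # burst centers spread over the record and shifted per condition.
    periods = np.geomspace(8.0 * dt, duration / 3.0, n_groups)
    centers = np.linspace(0.25, 0.75, n_groups) * duration

    profiles = []
    for c in range(conditions):
        cond_shift = (c + 1) / (conditions + 1)
        mat = np.empty((n_prom, n_points))
        for g in range(n_groups):
            period = periods[g] * (1.0 + 0.3 * cond_shift)
            center = (centers[g] + 0.15 * duration * cond_shift) % duration
            latent = _latent_signal(times, period, center, width=duration / 10.0)
            members = labels == g
            mat[members] = (
                gains[members, None] * latent[None, :]
                + noise * rng.standard_normal((members.sum(), n_points))
            )
        profiles.append(mat)
    return profiles, labels, times
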