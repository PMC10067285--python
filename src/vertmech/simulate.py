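"""Synthetic force-displacement curves and two-group rat cohorts.

No raw traces from vertebral compression testing of the reference rat study
are publicly deposited, so this module provides a generative stand-in with
the curve anatomy the extraction pipeline assumes:

1. a quadratic *toe* region (progressive specimen contact),
2. a *linear elastic* limb of slope ``elastic_slope`` up to the yield load,
3. a smooth *plastic hardening* segment whose tangent decays from the
   elastic slope to zero at the maximum load,
4. a *post-peak* descent with optional discrete microfracture drops, a last
   local maximum at exactly the failure load, and
5. a *terminal fracture drop* of at least half the maximum force, so the
   50%-force-drop endpoint rule always triggers,

plus additive Gaussian sensor noise on the force channel.  Displacement
advances at ``crosshead_speed * sample_interval / 60`` mm per sample
(constant crosshead descent).

The hardening segment is ``Fmax - (Fmax - yL) * ((d_peak - d)/span)**h``
with shape exponent ``h`` (default 2); the span is chosen as
``h * (Fmax - yL) / S`` so the tangent is continuous at the yield point.

Cohorts draw per-specimen parameter tuples from independent normals.  The
packaged reference configuration models the validation study this package
reproduces: 17 sham-operated and 18 ovariectomized (osteoporotic) rats with
group means (stiffness, yield, maximum, failure) = (174.2, 134.6, 154.2,
143.8) and (133.2, 125.8, 133.5, 123.4) in N/mm and N.  Printed dispersions
in that study are labelled SD but are numerically consistent only with SEMs,
so the config carries an explicit ``dispersion_interpretation`` switch
(default ``"sem"``: specimen-level SD = dispersion * sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .curve import ForceDisplacementCurve, write_cohort
from .exceptions import GenerationError

PARAMETERS = ("stiffness", "yield_load", "max_load", "failure_load")


@dataclass(frozen=True)
class CurveModelParams:
    """Generative parameters for one synthetic specimen.

    ``elastic_slope`` (N/mm), ``yield_load``, ``max_load`` and
    ``failure_load`` (N) are the ground-truth counterparts of the four
    extracted parameters.  Geometry defaults (spans in mm) shape the
    post-peak anatomy and rarely need changing.
    """

    elastic_slope: float
    yield_load: float
    max_load: float
    failure_load: float
    toe_displacement: float = 0.05
    hardening_shape: float = 2.0
    terminal_drop_fraction: float = 0.6
    microfracture_drops: tuple[tuple[float, float], ...] = ()
    noise_sd: float = 0.0
    crosshead_speed: float = 2.0
    sample_interval: float = 0.03
    seed: int = 0
    softening_span: float = 0.15
    recovery_span: float = 0.08
    recovery_depth: float | None = None
    drop_span: float = 0.01
    tail_span: float = 0.005

    def __post_init__(self) -> None:
        self.validate()

    @property
    def step(self) -> float:
        """Displacement advance per sample (mm)."""
        return self.crosshead_speed * self.sample_interval / 60.0

    @property
    def dip_depth(self) -> float:
        """How far below the failure load the pre-failure valley sits (N)."""
        if self.recovery_depth is not None:
            return self.recovery_depth
        return max(0.02 * self.max_load, 1.0)

    def validate(self) -> None:
        p = self
        if p.elastic_slope <= 0:
            raise GenerationError("elastic_slope must be positive")
        if not 0 < p.yield_load < p.max_load:
            raise GenerationError(
                f"need 0 < yield_load < max_load, got yL={p.yield_load:g}, "
                f"Fmax={p.max_load:g}")
        if not 0 < p.failure_load < p.max_load:
            raise GenerationError(
                f"need 0 < failure_load < max_load, got fL={p.failure_load:g}, "
                f"Fmax={p.max_load:g}")
        if p.terminal_drop_fraction < 0.5:
            raise GenerationError("terminal_drop_fraction must be >= 0.5 so the "
                                  "force-drop endpoint rule triggers")
        if p.noise_sd < 0:
            raise GenerationError("noise_sd must be non-negative")
        if p.toe_displacement < 0 or p.hardening_shape < 1:
            raise GenerationError("toe_displacement >= 0 and hardening_shape >= 1 "
                                  "required")
        if p.sample_interval <= 0 or p.crosshead_speed <= 0:
            raise GenerationError("sampling settings must be positive")
        # physical realisability of the post-peak anatomy
        valley = p.failure_load - p.dip_depth
        if valley <= 0.52 * p.max_load:
            raise GenerationError(
                f"failure_load {p.failure_load:g} N too close to the 50% "
                f"endpoint level for Fmax={p.max_load:g} N")
        if p.yield_load / p.elastic_slope - p.toe_displacement / 2 < 0.1:
            raise GenerationError("elastic limb shorter than 0.1 mm; no "
                                  "regression region would exist")
        for off, drop in p.microfracture_drops:
            if not 0 < off < p.softening_span - 0.02:
                raise GenerationError(
                    f"microfracture offset {off:g} mm outside the softening "
                    f"segment (0, {p.softening_span - 0.02:g})")
            if drop <= 0:
                raise GenerationError("microfracture drop must be positive")
        if self.total_displacement() > 1.95:
            raise GenerationError(
                f"curve would span {self.total_displacement():.2f} mm and hit "
                "the 2 mm travel endpoint before fracturing")

    def total_displacement(self) -> float:
        p = self
        d_yield = p.yield_load / p.elastic_slope + p.toe_displacement / 2
        span = p.hardening_shape * (p.max_load - p.yield_load) / p.elastic_slope
        return (d_yield + span + p.softening_span + p.recovery_span
                + p.drop_span + p.tail_span)


def _piecewise_force(p: CurveModelParams, d: np.ndarray) -> np.ndarray:
    """Noiseless force at displacements ``d`` for the phase model above."""
    S, yL, Fmax, fL = (p.elastic_slope, p.yield_load, p.max_load,
                       p.failure_load)
    t = p.toe_displacement
    d0 = t / 2.0
    d_yield = yL / S + d0
    span = p.hardening_shape * (Fmax - yL) / S
    d_peak = d_yield + span
    d_valley = d_peak + p.softening_span
    d_fail = d_valley + p.recovery_span
    d_end = d_fail + p.drop_span
    valley = fL - p.dip_depth
    floor = (1.0 - p.terminal_drop_fraction) * Fmax

    f = np.empty_like(d)
    # toe: quadratic run-in meeting the elastic line with matched slope
    m = d <= t
    f[m] = S * d[m] ** 2 / (2.0 * t) if t > 0 else 0.0
    # elastic limb
    m = (d > t) & (d <= d_yield)
    f[m] = S * (d[m] - d0)
    # hardening: tangent decays from S (at yield) to 0 (at peak)
    m = (d > d_yield) & (d <= d_peak)
    f[m] = Fmax - (Fmax - yL) * ((d_peak - d[m]) / span) ** p.hardening_shape
    # post-peak softening down to the pre-failure valley
    m = (d > d_peak) & (d <= d_valley)
    f[m] = Fmax + (valley - Fmax) * (d[m] - d_peak) / p.softening_span
    # recovery: bone re-seats and takes load up to the failure point
    m = (d > d_valley) & (d <= d_fail)
    f[m] = valley + (fL - valley) * (d[m] - d_valley) / p.recovery_span
    # terminal fracture drop
    m = (d > d_fail) & (d <= d_end)
    f[m] = fL + (floor - fL) * (d[m] - d_fail) / p.drop_span
    # tail past the endpoint trigger
    m = d > d_end
    f[m] = np.maximum(floor - 5.0 * (d[m] - d_end), 0.0)

    # discrete microfracture events inside the softening segment: a sharp
    # drop with full re-engagement 0.015 mm later
    for off, drop in p.microfracture_drops:
        notch = (d > d_peak + off) & (d <= d_peak + off + 0.015)
        f[notch] -= drop
        if np.any(f[notch] <= 0.52 * Fmax):
            raise GenerationError(
                f"microfracture drop of {drop:g} N at +{off:g} mm dips below "
                "the 50% endpoint level")
    return f


def generate_curve(params: CurveModelParams) -> ForceDisplacementCurve:
    """Generate one synthetic specimen trace; deterministic given the seed."""
    p = params
    step = p.step
    n = int(np.floor(p.total_displacement() / step)) + 1
    if not 10 <= n <= 2_000_000:
        raise GenerationError(f"sampling settings give {n} samples")
    d = np.arange(n) * step
    f = _piecewise_force(p, d)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        f = f + rng.normal(0.0, p.noise_sd, size=n)
    return ForceDisplacementCurve(
        displacement=d, force=f,
        specimen_id=f"synthetic-{p.seed}",
        crosshead_speed=p.crosshead_speed,
        sample_interval=p.sample_interval,
        provenance="vertmech synthetic curve (generated, not measured)")


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size, and per-parameter mean/dispersion."""

    label: str
    n: int
    means: dict
    dispersions: dict

    def __post_init__(self) -> None:
        if self.n < 2:
            raise GenerationError(f"group '{self.label}' needs n >= 2")
        for key in PARAMETERS:
            if key not in self.means or key not in self.dispersions:
                raise GenerationError(
                    f"group '{self.label}' lacks mean/dispersion for '{key}'")
            if self.means[key] <= 0:
                raise GenerationError(
                    f"group '{self.label}': mean {key} must be positive")
            if self.dispersions[key] < 0:
                raise GenerationError(
                    f"group '{self.label}': dispersion {key} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort recipe.

    ``dispersion_interpretation`` chooses how group dispersions map to the
    specimen-level normal SD: ``"sd"`` uses them directly, ``"sem"``
    multiplies by sqrt(n) (standard error of the mean reading).
    """

    groups: tuple[GroupSpec, ...]
    dispersion_interpretation: str = "sd"
    noise_sd: float = 0.0
    toe_displacement: float = 0.05
    crosshead_speed: float = 2.0
    sample_interval: float = 0.03
    master_seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.dispersion_interpretation not in ("sd", "sem"):
            raise GenerationError(
                "dispersion_interpretation must be 'sd' or 'sem'")
        if len(self.groups) < 1:
            raise GenerationError("cohort needs at least one group")

    def specimen_sd(self, group: GroupSpec, parameter: str) -> float:
        disp = group.dispersions[parameter]
        if self.dispersion_interpretation == "sem":
            return disp * np.sqrt(group.n)
        return disp


def reference_cohort_config(master_seed: int = 0,
                            noise_sd: float = 0.0,
                            dispersion_interpretation: str = "sem",
                            ) -> CohortConfig:
    """The packaged reference rat cohort (17 sham + 18 ovariectomized).

    Group means and printed dispersions for stiffness (N/mm), yield load,
    maximum load and failure load (N) follow the validation study this
    package models; see the module docstring for the SD-vs-SEM reading of
    the dispersions.
    """
    sham = GroupSpec(
        label="SHAM", n=17,
        means={"stiffness": 174.2, "yield_load": 134.6,
               "max_load": 154.2, "failure_load": 143.8},
        dispersions={"stiffness": 16.1, "yield_load": 8.3,
                     "max_load": 9.4, "failure_load": 9.3})
    ovx = GroupSpec(
        label="OVX", n=18,
        means={"stiffness": 133.2, "yield_load": 125.8,
               "max_load": 133.5, "failure_load": 123.4},
        dispersions={"stiffness": 14.0, "yield_load": 7.0,
                     "max_load": 7.7, "failure_load": 7.0})
    return CohortConfig(groups=(sham, ovx),
                        dispersion_interpretation=dispersion_interpretation,
                        noise_sd=noise_sd, master_seed=master_seed)


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _params_for(config: CohortConfig, truth: dict, seed: int
                ) -> CurveModelParams:
    return CurveModelParams(
        elastic_slope=truth["stiffness"], yield_load=truth["yield_load"],
        max_load=truth["max_load"], failure_load=truth["failure_load"],
        toe_displacement=config.toe_displacement, noise_sd=config.noise_sd,
        crosshead_speed=config.crosshead_speed,
        sample_interval=config.sample_interval, seed=seed)


def draw_cohort_parameters(config: CohortConfig) -> pd.DataFrame:
    """Draw the per-specimen truth table for a cohort.

    Each specimen's (stiffness, yield, maximum, failure) tuple is drawn from
    independent normals and redrawn (up to ``max_retries`` times) until it
    parameterises a physically realisable curve.  Deterministic given the
    master seed.
    """
    records = []
    index = 0
    for group in config.groups:
        sds = {k: config.specimen_sd(group, k) for k in PARAMETERS}
        for j in range(group.n):
            seed = _child_seed(config.master_seed, index)
            rng = np.random.default_rng(seed)
            specimen_id = f"{group.label}-{j + 1:02d}"
            for attempt in range(config.max_retries):
                truth = {k: float(rng.normal(group.means[k], sds[k]))
                         for k in PARAMETERS}
                try:
                    _params_for(config, truth, seed)
                except GenerationError:
                    continue
                break
            else:
                raise GenerationError(
                    f"specimen '{specimen_id}': no physically consistent "
                    f"parameter draw within {config.max_retries} retries")
            records.append({"specimen_id": specimen_id,
                            "group_label": group.label, "seed": seed, **truth})
            index += 1
    return pd.DataFrame(records)


def generate_cohort(config: CohortConfig
                    ) -> tuple[list[ForceDisplacementCurve], pd.DataFrame]:
    """Generate all cohort curves plus the truth table of drawn parameters."""
    truth = draw_cohort_parameters(config)
    curves = []
    for rec in truth.to_dict("records"):
        params = _params_for(config, rec, int(rec["seed"]))
        curve = generate_curve(params)
        curve = replace(curve, specimen_id=rec["specimen_id"],
                        group_label=rec["group_label"])
        curves.append(curve)
    return curves, truth


def save_cohort(curves: Sequence[ForceDisplacementCurve],
                truth: pd.DataFrame, directory: str | Path) -> Path:
    """Write curves, manifest and truth table into ``directory``."""
    directory = Path(directory)
    write_cohort(curves, directory)
    truth.to_csv(directory / "truth.csv", index=False,
                 float_format="%.6f")
    return directory


# ---------------------------------------------------------------------------
# human-editable cohort configuration files (YAML)


def cohort_config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    doc = {
        "dispersion_interpretation": config.dispersion_interpretation,
        "noise_sd": config.noise_sd,
        "toe_displacement": config.toe_displacement,
        "crosshead_speed": config.crosshead_speed,
        "sample_interval": config.sample_interval,
        "master_seed": config.master_seed,
        "max_retries": config.max_retries,
        "groups": [
            {"label": g.label, "n": g.n,
             "means": {k: float(g.means[k]) for k in PARAMETERS},
             "dispersions": {k: float(g.dispersions[k]) for k in PARAMETERS}}
            for g in config.groups],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False),
                          encoding="utf-8")


def cohort_config_from_yaml(path: str | Path) -> CohortConfig:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        groups = tuple(
            GroupSpec(label=g["label"], n=int(g["n"]),
                      means=dict(g["means"]),
                      dispersions=dict(g["dispersions"]))
            for g in doc["groups"])
        keys = ("dispersion_interpretation", "noise_sd", "toe_displacement",
                "crosshead_speed", "sample_interval", "master_seed",
                "max_retries")
        extra = {k: doc[k] for k in keys if k in doc}
        return CohortConfig(groups=groups, **extra)
    except (KeyError, TypeError) as err:
        raise GenerationError(f"malformed cohort config {path}: {err}") from err
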