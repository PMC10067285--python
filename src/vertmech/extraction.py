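"""Mechanical parameter extraction from compression force-displacement curves.

The protocol this module implements analyses an axial compression-to-failure
test of a vertebral body.  The recorded trace is first truncated at the test
endpoint (force drop >= 50% of the running maximum, or crosshead travel
beyond 2 mm), then four parameters are read off:

* **Stiffness** ``S = dF/df``: the slope (N/mm) of the least-squares
  regression line over the linear elastic region of the curve, i.e. before
  the elastic limit.  Its reciprocal is the compliance ``N = 1/S`` (mm/N).
* **Yield load** ``yL``: the force at which local stiffness first falls two
  standard deviations below the elastic-region stiffness — the transition
  from elastic (reversible) to plastic (irreversible) deformation,
  interpreted as the onset of microfracturing.
* **Maximum load** ``Fmax``: the largest force recorded during the test.
* **Failure load** ``fL``: the force at final fracturing of the bone,
  operationalised as the last local force maximum between the global peak
  and the endpoint, i.e. the onset of the terminal force drop.

The elastic region itself is found by a sliding-window search: windows of a
configurable width are regressed over the pre-peak span (above a toe-region
force threshold), the steepest window with adequate r-squared is selected,
and the region is grown outwards while the windowed slope stays within a
tolerance of the selected slope.  Local slopes are estimated by centred
least-squares fits over a smaller window (two-point differences are unusable
at realistic noise levels); their dispersion inside the elastic region
supplies the standard deviation used by the yield rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

from .curve import ForceDisplacementCurve, read_curve
from .exceptions import ExtractionError

EndpointReason = Literal["force_drop", "displacement", "end_of_data"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable settings for the extraction pipeline.

    Defaults encode the testing protocol constants (50% force drop, 2 mm
    travel, 2-SD yield rule) plus window-search settings suited to clean
    traces; :meth:`noisy` returns a preset for noisy acquisitions (wider
    windows, relaxed r-squared floor).

    Attributes
    ----------
    drop_fraction : float
        Endpoint rule: stop at the first sample whose force has dropped by at
        least this fraction of the running maximum.
    max_displacement : float
        Endpoint rule: stop once crosshead travel exceeds this (mm).
    min_peak_force : float
        The force-drop rule only arms once the running maximum exceeds this
        (N), so load-cell noise before the specimen takes load cannot end
        the test; 20 N is far below any vertebral peak force.
    toe_fraction : float
        Samples below this fraction of the peak force are toe region and
        excluded from the elastic-region search.
    window_fraction : float
        Sliding-window width as a fraction of the pre-peak sample count.
    min_window : int
        Lower bound (samples, odd) on the sliding-window width.
    r2_floor : float
        Minimum r-squared for a window to be an elastic-region candidate.
    ext_sigma, ext_rel_tol : float
        Region growth stops when the windowed slope falls below
        ``best_slope - max(ext_sigma * slope_se, ext_rel_tol * best_slope)``.
    local_window : int or None
        Width of the local-slope window used for the yield rule; ``None``
        picks ``max(min_window, window/5)`` rounded to odd.
    k_sd : float
        Yield rule: local stiffness must fall ``k_sd`` standard deviations
        below the elastic-region mean local slope.
    yield_rel_floor : float
        Relative floor on the yield threshold, guarding the degenerate case
        of (numerically) zero local-slope dispersion on noiseless traces.
    force_floor : float
        Most negative admissible force sample (N) during analysis.
    """

    drop_fraction: float = 0.5
    max_displacement: float = 2.0
    min_peak_force: float = 20.0
    toe_fraction: float = 0.05
    window_fraction: float = 0.10
    min_window: int = 11
    r2_floor: float = 0.999
    ext_sigma: float = 3.0
    ext_rel_tol: float = 0.002
    local_window: int | None = None
    k_sd: float = 2.0
    yield_rel_floor: float = 0.005
    force_floor: float = -6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_fraction <= 1.0:
            raise ExtractionError("drop_fraction must lie in (0, 1]")
        if self.max_displacement <= 0:
            raise ExtractionError("max_displacement must be positive")
        if self.min_window < 5 or self.min_window % 2 == 0:
            raise ExtractionError("min_window must be odd and >= 5")
        if not 0.0 < self.r2_floor < 1.0:
            raise ExtractionError("r2_floor must lie in (0, 1)")

    @classmethod
    def noisy(cls, **overrides) -> "ExtractionConfig":
        """Preset for noisy traces: wider windows, relaxed r-squared floor.

        The floor only screens out traces with no linear limb at all; window
        selection by steepest admissible slope is what keeps the region off
        the toe and hardening segments, so the noisy floor can be generous.
        """
        settings = dict(window_fraction=0.30, r2_floor=0.95)
        settings.update(overrides)
        return cls(**settings)


@dataclass
class ElasticRegion:
    """The detected linear elastic segment of a truncated curve.

    ``slope`` is the stiffness S (N/mm) from the least-squares regression
    over ``[start_index, end_index]`` (0-based, inclusive);
    ``local_slope_mean``/``local_slope_sd`` summarise the centred windowed
    slopes of the individual digital data inside the region and feed the
    2-SD yield rule.
    """

    start_index: int
    end_index: int
    slope: float
    intercept: float
    r_squared: float
    local_slope_mean: float
    local_slope_sd: float
    window_width: int
    local_window: int

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ExtractionError("elastic region must span at least two samples")
        if self.slope <= 0:
            raise ExtractionError(
                f"elastic region slope {self.slope:g} N/mm is not positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ExtractionError("r_squared outside [0, 1]")
        if self.local_slope_sd < 0:
            raise ExtractionError("local_slope_sd must be non-negative")

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class MechanicalSummary:
    """The four mechanical parameters of one specimen plus diagnostics."""

    stiffness: float
    compliance: float
    yield_load: float
    max_load: float
    failure_load: float
    yield_index: int
    max_index: int
    failure_index: int
    endpoint_index: int
    endpoint_reason: EndpointReason
    elastic_region: ElasticRegion
    yield_at_peak: bool = False
    specimen_id: str = "unknown"
    group_label: str | None = None

    def __post_init__(self) -> None:
        if abs(self.compliance * self.stiffness - 1.0) > 1e-9:
            raise ExtractionError("compliance must be the reciprocal of stiffness")
        if self.yield_load > self.max_load + 1e-9:
            raise ExtractionError("yield load cannot exceed maximum load")
        if self.failure_load > self.max_load + 1e-9:
            raise ExtractionError("failure load cannot exceed maximum load")
        if not (self.yield_index <= self.max_index <= self.failure_index
                <= self.endpoint_index):
            raise ExtractionError("index ordering yield <= max <= failure <= "
                                  "endpoint violated")

    def to_record(self) -> dict:
        """Flat record matching the per-specimen summary CSV schema."""
        return {
            "specimen_id": self.specimen_id,
            "group_label": self.group_label or "",
            "stiffness_N_per_mm": self.stiffness,
            "compliance_mm_per_N": self.compliance,
            "yield_load_N": self.yield_load,
            "max_load_N": self.max_load,
            "failure_load_N": self.failure_load,
            "endpoint_reason": self.endpoint_reason,
            "yield_at_peak": self.yield_at_peak,
            "elastic_r_squared": self.elastic_region.r_squared,
        }


# ---------------------------------------------------------------------------
# sliding least-squares machinery


def _odd(n: int) -> int:
    n = int(round(n))
    return n if n % 2 == 1 else n + 1


def _sliding_fit(x: np.ndarray, y: np.ndarray, w: int):
    """Least-squares slope and r-squared of every length-``w`` window.

    Returns ``(slopes, r2)`` arrays of length ``len(x) - w + 1``; window ``i``
    covers samples ``[i, i + w - 1]``.  Uses running sums on shifted
    coordinates for O(n) cost.
    """
    x = x - x[0]
    y = y - y.mean()
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    n = x.size - w + 1
    i = np.arange(n)
    sx = cx[i + w] - cx[i]
    sy = cy[i + w] - cy[i]
    sxx = cxx[i + w] - cxx[i]
    sxy = cxy[i + w] - cxy[i]
    syy = cyy[i + w] - cyy[i]
    vxx = sxx - sx * sx / w
    vxy = sxy - sx * sy / w
    vyy = syy - sy * sy / w
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(vxx > 0, vxy / np.where(vxx > 0, vxx, 1.0), 0.0)
        denom = vxx * vyy
        r2 = np.where(denom > 0, vxy * vxy / np.where(denom > 0, denom, 1.0), 0.0)
    return slopes, np.clip(r2, 0.0, 1.0)


def _ols(x: np.ndarray, y: np.ndarray):
    """Plain least-squares line fit: (slope, intercept, r2, slope_se)."""
    res = sps.linregress(x, y)
    r2 = min(max(res.rvalue ** 2, 0.0), 1.0)
    return res.slope, res.intercept, r2, res.stderr


# ---------------------------------------------------------------------------
# pipeline operations


def truncate_at_endpoint(curve: ForceDisplacementCurve,
                         drop_fraction: float = 0.5,
                         max_displacement: float = 2.0,
                         min_peak_force: float = 20.0,
                         ) -> tuple[ForceDisplacementCurve, int, EndpointReason]:
    """Truncate a trace at the protocol endpoint.

    Scanning forward, the endpoint is the first sample at which either

    * force has dropped to ``(1 - drop_fraction)`` of the running maximum
      force (once that maximum exceeds ``min_peak_force``), or
    * displacement exceeds ``max_displacement`` mm.

    If neither criterion ever triggers the endpoint is the last sample
    (reason ``"end_of_data"``).  Returns ``(truncated_curve, endpoint_index,
    reason)`` with the endpoint sample included.
    """
    f = curve.force
    d = curve.displacement
    runmax = np.maximum.accumulate(f)
    armed = runmax > max(min_peak_force, 0.0)
    drop_hits = np.nonzero(armed & (f <= (1.0 - drop_fraction) * runmax))[0]
    disp_hits = np.nonzero(d > max_displacement)[0]
    i_drop = int(drop_hits[0]) if drop_hits.size else None
    i_disp = int(disp_hits[0]) if disp_hits.size else None
    if i_drop is None and i_disp is None:
        endpoint, reason = curve.n_samples - 1, "end_of_data"
    elif i_disp is None or (i_drop is not None and i_drop <= i_disp):
        endpoint, reason = i_drop, "force_drop"
    else:
        endpoint, reason = i_disp, "displacement"
    return curve.slice(endpoint), endpoint, reason


def detect_elastic_region(curve: ForceDisplacementCurve,
                          config: ExtractionConfig | None = None) -> ElasticRegion:
    """Locate the linear elastic region of an endpoint-truncated curve.

    See the module docstring for the search procedure.  Raises
    :class:`ExtractionError` when no sliding window reaches the r-squared
    floor ("no linear elastic region found") or the pre-peak span is too
    short to search.
    """
    cfg = config or ExtractionConfig()
    f = curve.force
    d = curve.displacement
    max_idx = int(np.argmax(f))
    if max_idx < 2 * cfg.min_window:
        raise ExtractionError(
            f"curve '{curve.specimen_id}': only {max_idx} samples before the "
            f"force maximum; need at least {2 * cfg.min_window}")
    toe_level = cfg.toe_fraction * f[max_idx]
    toe_start = int(np.argmax(f >= toe_level))
    span = max_idx - toe_start
    w = _odd(max(cfg.min_window, cfg.window_fraction * span))
    if span < w + 2:
        raise ExtractionError(
            f"curve '{curve.specimen_id}': pre-peak span ({span} samples) "
            f"shorter than the search window ({w})")

    x = d[toe_start:max_idx]
    y = f[toe_start:max_idx]
    slopes, r2 = _sliding_fit(x, y, w)
    candidates = r2 >= cfg.r2_floor
    if not candidates.any():
        raise ExtractionError(
            f"curve '{curve.specimen_id}': no linear elastic region found "
            f"(no {w}-sample window reaches r^2 >= {cfg.r2_floor})")
    best = int(np.argmax(np.where(candidates, slopes, -np.inf)))
    best_slope = float(slopes[best])
    if best_slope <= 0:
        raise ExtractionError(
            f"curve '{curve.specimen_id}': steepest admissible window has "
            f"non-positive slope {best_slope:g}")

    _, _, _, slope_se = _ols(x[best:best + w], y[best:best + w])
    slope_se = 0.0 if not np.isfinite(slope_se) else slope_se
    slope_floor = best_slope - max(cfg.ext_sigma * slope_se,
                                   cfg.ext_rel_tol * best_slope)
    ok = (slopes >= slope_floor) & (r2 >= cfg.r2_floor)
    lo = best
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = best
    while hi + 1 < ok.size and ok[hi + 1]:
        hi += 1

    start = toe_start + lo
    end = toe_start + hi + w - 1          # inclusive; < max_idx by construction
    slope, intercept, r_sq, _ = _ols(d[start:end + 1], f[start:end + 1])

    wl = cfg.local_window or _odd(max(cfg.min_window, w / 5))
    if end - start + 1 >= wl + 1:
        lslopes, _ = _sliding_fit(d[start:end + 1], f[start:end + 1], wl)
        local_mean = float(np.mean(lslopes))
        local_sd = float(np.std(lslopes, ddof=1)) if lslopes.size > 1 else 0.0
    else:
        local_mean, local_sd = slope, 0.0

    return ElasticRegion(start_index=start, end_index=end, slope=float(slope),
                         intercept=float(intercept), r_squared=float(r_sq),
                         local_slope_mean=local_mean, local_slope_sd=local_sd,
                         window_width=w, local_window=wl)


def compute_stiffness(region: ElasticRegion) -> tuple[float, float]:
    """Stiffness S (N/mm) and its reciprocal, the compliance N (mm/N)."""
    if region.slope <= 0:
        raise ExtractionError(
            f"non-physical stiffness {region.slope:g} N/mm")
    return region.slope, 1.0 / region.slope


def yield_threshold(region: ElasticRegion, k_sd: float = 2.0,
                    rel_floor: float = 0.005) -> float:
    """Local-slope threshold below which the specimen has yielded.

    ``mean - max(k_sd * sd, rel_floor * mean)`` of the elastic-region local
    slopes; the relative floor guards against a numerically zero dispersion
    on noiseless traces.
    """
    return region.local_slope_mean - max(k_sd * region.local_slope_sd,
                                         rel_floor * region.local_slope_mean)


def detect_yield(curve: ForceDisplacementCurve, region: ElasticRegion,
                 k_sd: float = 2.0,
                 config: ExtractionConfig | None = None,
                 ) -> tuple[float, int, bool]:
    """Yield load by the k-SD local-stiffness-drop rule.

    Centred local slopes (window ``region.local_window``) are scanned forward
    from the end of the elastic region; the yield index is the first window
    centre whose slope falls below :func:`yield_threshold`.  If no centre
    before the force maximum qualifies, the yield is pinned at the peak and
    the ``yield_at_peak`` flag is returned True (degenerate but not an
    error).  Returns ``(yield_load, yield_index, yield_at_peak)``.
    """
    cfg = config or ExtractionConfig()
    f = curve.force
    d = curve.displacement
    max_idx = int(np.argmax(f))
    wl = region.local_window
    hl = wl // 2
    thresh = yield_threshold(region, k_sd, cfg.yield_rel_floor)

    # only fully pre-peak windows: samples beyond the force maximum belong
    # to the post-peak collapse and must not masquerade as a stiffness loss
    c0 = max(hl, region.end_index - hl + 1)
    c1 = min(max_idx - hl, curve.n_samples - 1 - hl)
    if c0 <= c1:
        lo = c0 - hl
        hi = c1 + hl
        lslopes, _ = _sliding_fit(d[lo:hi + 1], f[lo:hi + 1], wl)
        below = np.nonzero(lslopes < thresh)[0]
        if below.size:
            idx = c0 + int(below[0])
            if idx <= max_idx:
                return float(f[idx]), idx, False
    return float(f[max_idx]), max_idx, True


def compute_max_load(curve: ForceDisplacementCurve) -> tuple[float, int]:
    """Largest measured force and the first index attaining it."""
    if curve.n_samples == 0:
        raise ExtractionError("empty curve")
    idx = int(np.argmax(curve.force))
    return float(curve.force[idx]), idx


def compute_failure_load(curve: ForceDisplacementCurve, max_index: int,
                         endpoint_index: int) -> tuple[float, int]:
    """Failure load: force at the onset of the terminal drop.

    The failure index is the last local maximum of force in
    ``[max_index, endpoint_index]`` (a sample at least as large as both
    neighbours); if force decreases monotonically after the peak this is the
    peak itself.
    """
    if max_index > endpoint_index:
        raise ExtractionError("max_index must not exceed endpoint_index")
    f = curve.force
    idx = np.arange(max(max_index, 1), endpoint_index)
    if idx.size:
        is_max = (f[idx] >= f[idx - 1]) & (f[idx] >= f[idx + 1])
        hits = idx[is_max]
        if hits.size:
            i = int(hits[-1])
            return float(f[i]), i
    return float(f[max_index]), max_index


def analyze_curve(curve: ForceDisplacementCurve,
                  config: ExtractionConfig | None = None) -> MechanicalSummary:
    """Run the full extraction pipeline on one curve.

    Composes endpoint truncation, elastic-region detection, stiffness,
    maximum load, yield load and failure load; extraction errors are
    re-raised with the specimen id attached.
    """
    cfg = config or ExtractionConfig()
    curve.validate(force_floor=cfg.force_floor)
    truncated, endpoint_idx, reason = truncate_at_endpoint(
        curve, cfg.drop_fraction, cfg.max_displacement, cfg.min_peak_force)
    try:
        region = detect_elastic_region(truncated, cfg)
        stiffness, compliance = compute_stiffness(region)
        max_load, max_idx = compute_max_load(truncated)
        yield_load, yield_idx, at_peak = detect_yield(truncated, region,
                                                      cfg.k_sd, cfg)
        failure_load, failure_idx = compute_failure_load(
            truncated, max_idx, truncated.n_samples - 1)
    except ExtractionError as err:
        raise ExtractionError(f"specimen '{curve.specimen_id}': {err}") from err
    return MechanicalSummary(
        stiffness=stiffness, compliance=compliance, yield_load=yield_load,
        max_load=max_load, failure_load=failure_load, yield_index=yield_idx,
        max_index=max_idx, failure_index=failure_idx,
        endpoint_index=endpoint_idx, endpoint_reason=reason,
        elastic_region=region, yield_at_peak=at_peak,
        specimen_id=curve.specimen_id, group_label=curve.group_label)


# ---------------------------------------------------------------------------
# model/results interface


class CompressionTest:
    """Mechanical model of one axial compression-to-failure test.

    Wraps a :class:`ForceDisplacementCurve` with extraction settings;
    :meth:`fit` runs the pipeline and returns a
    :class:`CompressionTestResults`.

    Examples
    --------
    >>> test = CompressionTest.from_file("curve_L5-01.csv")   # doctest: +SKIP
    >>> res = test.fit()                                      # doctest: +SKIP
    >>> print(res.summary())                                  # doctest: +SKIP
    """

    def __init__(self, curve: ForceDisplacementCurve,
                 config: ExtractionConfig | None = None):
        self.curve = curve
        self.config = config or ExtractionConfig()

    @classmethod
    def from_file(cls, path, config: ExtractionConfig | None = None
                  ) -> "CompressionTest":
        return cls(read_curve(path), config=config)

    def fit(self) -> "CompressionTestResults":
        summary = analyze_curve(self.curve, self.config)
        truncated = self.curve.slice(summary.endpoint_index)
        return CompressionTestResults(self, summary, truncated)


class CompressionTestResults:
    """Fitted mechanical parameters of one specimen."""

    def __init__(self, model: CompressionTest, mech: MechanicalSummary,
                 truncated: ForceDisplacementCurve):
        self.model = model
        self.mech = mech
        self.truncated = truncated

    # convenience accessors
    @property
    def stiffness(self) -> float:
        return self.mech.stiffness

    @property
    def compliance(self) -> float:
        return self.mech.compliance

    @property
    def yield_load(self) -> float:
        return self.mech.yield_load

    @property
    def max_load(self) -> float:
        return self.mech.max_load

    @property
    def failure_load(self) -> float:
        return self.mech.failure_load

    def to_record(self) -> dict:
        return self.mech.to_record()

    def summary(self) -> str:
        m = self.mech
        r = m.elastic_region
        lines = [
            "Compression test results",
            "=" * 58,
            f"specimen:        {m.specimen_id}"
            + (f"  [{m.group_label}]" if m.group_label else ""),
            f"endpoint:        sample {m.endpoint_index} ({m.endpoint_reason})",
            "-" * 58,
            f"stiffness  S     {m.stiffness:10.2f} N/mm   "
            f"(r^2 = {r.r_squared:.5f})",
            f"compliance N     {m.compliance:10.5f} mm/N",
            f"yield load yL    {m.yield_load:10.2f} N      "
            + ("(at peak)" if m.yield_at_peak else f"(sample {m.yield_index})"),
            f"max load   Fmax  {m.max_load:10.2f} N      (sample {m.max_index})",
            f"failure    fL    {m.failure_load:10.2f} N      "
            f"(sample {m.failure_index})",
            "-" * 58,
            f"elastic region:  samples {r.start_index}..{r.end_index} "
            f"(n={r.length}, window={r.window_width}, local={r.local_window})",
            f"local slope:     {r.local_slope_mean:.2f} +/- "
            f"{r.local_slope_sd:.2f} N/mm",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Annotated force-displacement plot (stiffness line, yL, Fmax, fL)."""
        from .plotting import plot_compression_results
        return plot_compression_results(self, ax=ax)
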