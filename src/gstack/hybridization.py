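"""Two-species Langmuir intensity model and related chip-level operations.

The intensity of a probe is modelled as a hyperbolic function of its
linearized signal ``L`` (the saturation- and background-free intensity
equivalent)::

    I = I_min + L / (1 + L / I_max)

which levels off to the optical background ``I_min`` for ``L -> 0``, is
approximately linear (``I - I_min ~= L``) for ``L << I_max`` and saturates
at ``I_min + I_max`` for large ``L``.  ``L`` decomposes additively into a
non-specific and a specific part, each proportional to the concentration of
the corresponding transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chip_io import ChipData

__all__ = [
    "HybridizationParams",
    "IsothermCurve",
    "langmuir_intensity",
    "linearize_intensity",
    "zone_background",
    "subtract_background",
    "classify_absent",
    "empirical_isotherm",
    "theoretical_isotherm",
    "n_range_level",
    "inflection_abscissa",
]

BACKGROUND_FLOOR = 0.5


@dataclass(frozen=True)
class HybridizationParams:
    """Chip-level constants of the two-species hybridization isotherm."""

    i_max: float
    i_min: float = 0.0
    k_n: float = 0.0
    k_s: float = 0.0
    conc_n: float = 0.0
    conc_s: float = 0.0

    def __post_init__(self) -> None:
        if self.i_max <= 0:
            raise ValueError("i_max must be positive")
        if self.i_min < 0:
            raise ValueError("i_min must be non-negative")
        for name in ("k_n", "k_s", "conc_n", "conc_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class IsothermCurve:
    """A smoothed intensity-vs-expression curve."""

    abscissa: np.ndarray
    ordinate: np.ndarray
    window: int = 1

    def __post_init__(self) -> None:
        abscissa = np.asarray(self.abscissa, dtype=float)
        ordinate = np.asarray(self.ordinate, dtype=float)
        object.__setattr__(self, "abscissa", abscissa)
        object.__setattr__(self, "ordinate", ordinate)
        if abscissa.shape != ordinate.shape:
            raise ValueError("abscissa and ordinate must have equal length")
        # tolerate cumulative-sum roundoff of the window smoother
        tol = 1e-9 * max(1.0, float(np.abs(abscissa).max(initial=0.0)))
        if np.any(np.diff(abscissa) < -tol):
            raise ValueError("abscissa must be non-decreasing")


def langmuir_intensity(L, params: HybridizationParams):
    """Map linearized signal(s) to intensity via the hyperbolic isotherm."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("linearized signal must be non-negative")
    out = params.i_min + L / (1.0 + L / params.i_max)
    return float(out) if out.ndim == 0 else out


def linearize_intensity(I, params: HybridizationParams):
    """Exact inverse of :func:`langmuir_intensity` on ``[i_min, i_min + i_max)``."""
    I = np.asarray(I, dtype=float)
    if np.any(I < params.i_min):
        raise ValueError("intensity below the optical background i_min")
    if np.any(I >= params.i_min + params.i_max):
        raise ValueError("intensity at or above the saturation level i_min + i_max")
    delta = I - params.i_min
    out = delta / (1.0 - delta / params.i_max)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# optical background
# ---------------------------------------------------------------------------


def zone_background(
    chip: ChipData,
    n_zones_x: int = 4,
    n_zones_y: int = 4,
    fraction: float = 0.02,
    smooth: float = 100.0,
) -> np.ndarray:
    """Zone-wise optical background from the lowest ``fraction`` of intensities.

    The chip grid is cut into ``n_zones_x * n_zones_y`` rectangular zones; the
    per-zone background is the mean of the lowest ``fraction`` of intensities
    in that zone and per-probe values are blended between zone centers with
    inverse-squared-distance weights (``smooth`` is added to the squared
    distance, MAS5-like).  Falls back to a whole-chip estimate when any zone
    holds fewer than ``1 / fraction`` probes.
    """
    if not chip.probes:
        raise ValueError("chip has no probes")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    intensities = chip.intensity_array()
    xs = np.array([p.x for p in chip.probes], dtype=float)
    ys = np.array([p.y for p in chip.probes], dtype=float)

    def lowest_mean(values: np.ndarray) -> float:
        k = max(1, int(np.ceil(fraction * values.size)))
        return float(np.sort(values)[:k].mean())

    zone_x = np.minimum((xs * n_zones_x / chip.n_cols).astype(int), n_zones_x - 1)
    zone_y = np.minimum((ys * n_zones_y / chip.n_rows).astype(int), n_zones_y - 1)
    zone_of = zone_y * n_zones_x + zone_x
    counts = np.bincount(zone_of, minlength=n_zones_x * n_zones_y)
    if counts.min() < 1.0 / fraction:
        warnings.warn(
            "zone with too few probes for the requested fraction; "
            "falling back to a whole-chip background estimate",
            stacklevel=2,
        )
        return np.full(intensities.size, lowest_mean(intensities))

    zone_bg = np.empty(n_zones_x * n_zones_y)
    centers = np.empty((n_zones_x * n_zones_y, 2))
    for zy in range(n_zones_y):
        for zx in range(n_zones_x):
            z = zy * n_zones_x + zx
            zone_bg[z] = lowest_mean(intensities[zone_of == z])
            centers[z] = (
                (zx + 0.5) * chip.n_cols / n_zones_x,
                (zy + 0.5) * chip.n_rows / n_zones_y,
            )

    d2 = (xs[:, None] - centers[None, :, 0]) ** 2 + (ys[:, None] - centers[None, :, 1]) ** 2
    weights = 1.0 / (d2 + smooth)
    return (weights @ zone_bg) / weights.sum(axis=1)


def subtract_background(
    intensities: np.ndarray, background: np.ndarray, floor: float = BACKGROUND_FLOOR
) -> np.ndarray:
    """Background-subtracted intensities, floored at a small positive constant."""
    return np.maximum(np.asarray(intensities, dtype=float) - background, floor)


# ---------------------------------------------------------------------------
# absent/present calls
# ---------------------------------------------------------------------------


def classify_absent(
    chip: ChipData,
    values: np.ndarray,
    method: str = "mixture",
    calls: dict[str, str] | None = None,
    random_state: int = 0,
) -> set[str]:
    """Partition probe sets into absent (returned) and present sets.

    ``values`` are per-probe background-corrected intensities (or linearized
    signals) aligned with ``chip.probes``.  This is a documented stand-in for
    external single-chip calibration calls: with ``method="mixture"`` a
    two-component Gaussian mixture on the probe-set median log10 values labels
    the lower component absent; with ``method="override"`` the calls mapping
    (probe_set_id -> "A"/"P") is applied verbatim.
    """
    set_names = list(chip.probe_sets)
    if method == "override":
        if calls is None:
            raise ValueError("method='override' requires a calls mapping")
        missing = [name for name in set_names if name not in calls]
        if missing:
            raise ValueError(f"override calls missing probe sets: {missing}")
        return {name for name in set_names if calls[name].upper().startswith("A")}
    if method != "mixture":
        raise ValueError(f"unknown absent-call method {method!r}")

    values = np.asarray(values, dtype=float)
    medians = np.array(
        [np.median(np.log10(values[idx])) for idx in chip.probe_sets.values()]
    )
    if len(set_names) < 5 or np.ptp(medians) == 0:
        threshold = np.median(medians)
        return {name for name, m in zip(set_names, medians) if m <= threshold}

    from sklearn.mixture import GaussianMixture

    gmm = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    gmm.fit(medians[:, None])
    lower = int(np.argmin(gmm.means_.ravel()))
    posterior = gmm.predict_proba(medians[:, None])[:, lower]
    return {name for name, p in zip(set_names, posterior) if p > 0.5}


# ---------------------------------------------------------------------------
# isotherms
# ---------------------------------------------------------------------------


def _moving_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean, truncated at the ends."""
    if window == 1:
        return np.asarray(values, dtype=float).copy()
    n = values.size
    cumsum = np.concatenate(([0.0], np.cumsum(values)))
    half_lo = (window - 1) // 2
    half_hi = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def empirical_isotherm(
    chip: ChipData,
    expression: dict[str, float] | np.ndarray,
    subset: np.ndarray | None = None,
    window: int = 1000,
    intensities: np.ndarray | None = None,
) -> IsothermCurve:
    """Window-averaged log10 intensity as a function of expression degree.

    ``expression`` is either a per-probe-set mapping or a per-probe array.
    ``subset`` is an optional boolean mask over probes (e.g. the
    (GGG)1-containing sub-ensemble).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if intensities is None:
        intensities = chip.intensity_array()
    if isinstance(expression, dict):
        expr = np.array([expression[p.probe_set_id] for p in chip.probes], dtype=float)
    else:
        expr = np.asarray(expression, dtype=float)
    if subset is not None:
        expr = expr[subset]
        intensities = np.asarray(intensities)[subset]
    if expr.size == 0:
        raise ValueError("no probes selected for the isotherm")
    if expr.size < window:
        warnings.warn(
            f"only {expr.size} probes selected; shrinking window from {window}",
            stacklevel=2,
        )
        window = expr.size
    order = np.argsort(expr, kind="stable")
    expr = expr[order]
    log_i = np.log10(np.asarray(intensities, dtype=float)[order])
    return IsothermCurve(
        abscissa=_moving_mean(expr, window),
        ordinate=_moving_mean(log_i, window),
        window=window,
    )


def theoretical_isotherm(
    params: HybridizationParams,
    scenario: str = "A",
    factor: float = 1.0,
    s_grid: np.ndarray | None = None,
    n_points: int = 601,
    span: float = 4.0,
) -> IsothermCurve:
    """Model isotherm log10 I vs log10 [S] under scenarios A, B or C.

    Scenario A uses the parameters as given; B multiplies the non-specific
    binding constant by ``factor``; C multiplies both binding constants.  The
    abscissa grid is shared across scenarios (it is derived from the reference
    ``k_s``), so curves are directly comparable.
    """
    if scenario not in ("A", "B", "C"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario in ("B", "C") and factor < 1:
        raise ValueError("factor must be >= 1 for scenarios B and C")
    if params.k_s <= 0 or params.k_n <= 0:
        raise ValueError("theoretical isotherms need positive k_s and k_n")
    k_n, k_s = params.k_n, params.k_s
    if scenario in ("B", "C"):
        k_n *= factor
    if scenario == "C":
        k_s *= factor
    if s_grid is None:
        center = -np.log10(params.k_s)
        s_grid = np.linspace(center - span, center + span, n_points)
    s_grid = np.asarray(s_grid, dtype=float)
    L = params.i_max * (k_s * 10.0**s_grid + k_n * params.conc_n)
    intensity = langmuir_intensity(L, params)
    return IsothermCurve(abscissa=s_grid, ordinate=np.log10(intensity))


def n_range_level(curve: IsothermCurve) -> float:
    """Curve level in the non-specific range (at the smallest abscissa)."""
    return float(curve.ordinate[0])


def inflection_abscissa(curve: IsothermCurve) -> float:
    """Abscissa where the intensity crosses halfway between its two plateaus.

    The midpoint is taken on the linear intensity scale, which for a weak
    non-specific plateau coincides with half-saturation of the specific
    binding (and is therefore set by the specific binding constant alone).
    """
    intensity = 10.0**curve.ordinate
    mid = 0.5 * (intensity[0] + intensity[-1])
    return float(np.interp(mid, intensity, curve.abscissa))
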