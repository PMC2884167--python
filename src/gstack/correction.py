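"""NN+GGG hybrid-rank calibration of probe intensities.

The algorithm corrects the non-specifically hybridized ("absent") probes
with a rank-2 (nearest-neighbor) profile trained on absent probe sets free
of triple-G runs, plus per-position excess terms for GGG motifs trained on
the absent sets that do contain them.  Present probes are corrected with a
specific-mode rank-2 profile (sets dominated by specific binding) or a
weighted combination of both profiles.  Corrected linearized intensities
follow from subtracting the sequence increment delta_A from the logged
signal; by default the increment is applied as the chip-level profile value
(so probe-set means of corrected intensities shift for biased sets, which
is the point of the correction), an optional gauge recenters the correction
within each probe set instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._sequtil import PROBE_LENGTH
from .chip_io import ChipData
from .diagnostics import FitReport, count_parameters
from .hybridization import (
    HybridizationParams,
    classify_absent,
    langmuir_intensity,
    linearize_intensity,
    subtract_background,
    zone_background,
)
from .sensitivity import (
    SensitivityProfile,
    experimental_sensitivity,
    fit_profiles,
    set_means,
    _relabel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HybridModel",
    "CorrectionConfig",
    "PipelineResult",
    "find_ggg_runs",
    "split_probesets",
    "fit_basal_nn",
    "fit_ggg_excess",
    "ggg_indicator",
    "correct_probes",
    "run_pipeline",
]

GGG_POSITIONS = PROBE_LENGTH - 3 + 1  # 23 possible start positions


def find_ggg_runs(sequence: str) -> list[int]:
    """1-based start positions of all (overlapping) GGG windows in a 25-mer."""
    return [
        k
        for k in range(1, len(sequence) - 2 + 1)
        if sequence[k - 1 : k + 2] == "GGG"
    ]


def ggg_indicator(chip: ChipData, subset: np.ndarray | None = None) -> np.ndarray:
    """(n, 23) 0/1 matrix: GGG run starting at position k for each probe."""
    probes = chip.probes
    if subset is not None:
        probes = [p for p, keep in zip(probes, subset) if keep]
    out = np.zeros((len(probes), GGG_POSITIONS))
    for i, probe in enumerate(probes):
        for k in find_ggg_runs(probe.sequence):
            out[i, k - 1] = 1.0
    return out


def split_probesets(chip: ChipData, n_set: set[str]) -> tuple[set[str], set[str]]:
    """Split the absent probe sets into GGG-free (PS_NN) and GGG-containing (PS_GGG).

    A probe set joins PS_GGG as soon as any member probe carries at least one
    run of three consecutive guanines anywhere in its sequence.
    """
    ps_nn: set[str] = set()
    ps_ggg: set[str] = set()
    for set_id in n_set:
        members = chip.probe_sets[set_id]
        if any(find_ggg_runs(chip.probes[i].sequence) for i in members):
            ps_ggg.add(set_id)
        else:
            ps_nn.add(set_id)
    return ps_nn, ps_ggg


@dataclass
class HybridModel:
    """Fitted ingredients of the hybrid-rank correction."""

    basal_nn: SensitivityProfile
    ggg_excess: np.ndarray | None = None  # sigma_k(GGG), k = 1..23
    ggg_occupancy: np.ndarray | None = None
    specific_nn: SensitivityProfile | None = None
    specific_fraction: dict[str, float] = field(default_factory=dict)

    def delta_a_ggg(self, ggg_ind: np.ndarray) -> np.ndarray:
        if self.ggg_excess is None:
            return np.zeros(ggg_ind.shape[0])
        return ggg_ind @ self.ggg_excess


def fit_basal_nn(
    chip: ChipData, linearized: np.ndarray, ps_nn: set[str]
) -> tuple[SensitivityProfile, FitReport]:
    """Rank-2 profile trained on the GGG-free absent sub-ensemble."""
    if not ps_nn:
        raise ValueError("PS_NN is empty; cannot train the basal NN model")
    mask = chip.probe_mask(ps_nn)
    n_params = count_parameters(2)
    if int(mask.sum()) < 10 * n_params:
        warnings.warn(
            f"PS_NN holds only {int(mask.sum())} probes for {n_params} "
            "NN parameters (< 10x)",
            stacklevel=2,
        )
    return fit_profiles(chip, rank=2, linearized=linearized, subset=mask, mode="N")


def fit_ggg_excess(
    chip: ChipData,
    linearized: np.ndarray,
    ps_ggg: set[str],
    basal: SensitivityProfile,
) -> tuple[np.ndarray, np.ndarray, FitReport]:
    """Per-position GGG excess terms from the residual sensitivities of PS_GGG.

    The residual Y_exp - Y_basal (basal = set-centered NN increment) is
    regressed on set-centered GGG indicators per start position.  Positions
    with zero GGG occupancy are pinned to zero and flagged.  Returns the
    excess profile, the per-position occupancy and the residual report.
    """
    if not ps_ggg:
        raise ValueError("PS_GGG is empty; no GGG excess to fit")
    mask = chip.probe_mask(ps_ggg)
    labels, _ = chip.set_index()
    labels = _relabel(labels[mask])
    y_exp = experimental_sensitivity(chip, linearized, subset=mask)
    delta_nn = basal.delta_a(chip.sequence_codes()[mask])
    y_basal = delta_nn - set_means(delta_nn, labels)

    indicator = ggg_indicator(chip, subset=mask)
    centered = indicator.copy()
    for col in range(centered.shape[1]):
        centered[:, col] -= set_means(indicator[:, col], labels)
    occupancy = indicator.sum(axis=0).astype(np.int64)

    target = y_exp - y_basal
    gram = centered.T @ centered
    rhs = centered.T @ target
    excess, _, _, _ = scipy.linalg.lstsq(gram, rhs, cond=1e-9, lapack_driver="gelsd")
    excess[occupancy == 0] = 0.0
    if (occupancy == 0).any():
        warnings.warn(
            f"{int((occupancy == 0).sum())} GGG start position(s) without probes; "
            "excess pinned to 0",
            stacklevel=2,
        )
    residuals = target - centered @ excess
    report = FitReport(
        rank=3,
        residuals=residuals,
        probe_indices=np.flatnonzero(mask),
        param_count=int((occupancy > 0).sum()),
    )
    return excess, occupancy, report


# ---------------------------------------------------------------------------
# applying the correction
# ---------------------------------------------------------------------------


def correct_probes(
    chip: ChipData,
    model: HybridModel,
    linearized: np.ndarray,
    absent_ids: set[str],
    specific_threshold: float = 0.8,
    center_within_sets: bool = False,
) -> np.ndarray:
    """Corrected linearized intensities L_0 (log10 L - delta_A, per probe).

    Absent probes get the non-specific increment (basal NN plus GGG excess);
    present probe sets above the specific-fraction threshold get the specific
    profile; mixed sets a linear combination in log space weighted by the
    specific fraction ``w``.  Sets lacking a fraction estimate default to
    ``w = 0`` with a warning.  ``center_within_sets`` recenters the applied
    correction within every probe set (expression-preserving gauge) instead
    of using the chip-level profile values.
    """
    linearized = np.asarray(linearized, dtype=float)
    codes = chip.sequence_codes()
    delta_n = model.basal_nn.delta_a(codes) + model.delta_a_ggg(ggg_indicator(chip))
    if model.specific_nn is not None:
        delta_s = model.specific_nn.delta_a(codes)
    else:
        delta_s = np.zeros(len(chip.probes))

    delta = np.empty(len(chip.probes))
    missing_fraction = 0
    for i, probe in enumerate(chip.probes):
        set_id = probe.probe_set_id
        if set_id in absent_ids:
            delta[i] = delta_n[i]
            continue
        w = model.specific_fraction.get(set_id)
        if w is None:
            missing_fraction += 1
            w = 0.0
        if w > specific_threshold and model.specific_nn is not None:
            delta[i] = delta_s[i]
        else:
            delta[i] = w * delta_s[i] + (1.0 - w) * delta_n[i]
    if missing_fraction:
        warnings.warn(
            f"{missing_fraction} present probe(s) lack a specific-fraction "
            "estimate; defaulting to w = 0",
            stacklevel=2,
        )
    if center_within_sets:
        labels, _ = chip.set_index()
        delta = delta - set_means(delta, labels)
    return 10.0 ** (np.log10(linearized) - delta)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class CorrectionConfig:
    """Thresholds and stage switches of the correction pipeline."""

    model: str = "nn+ggg"  # one of n, nn, nnn, nn+ggg
    absent_method: str = "mixture"  # or "override"
    calls: dict[str, str] | None = None
    background: str | float = "zone"  # "zone", "none" or a constant
    n_zones_x: int = 4
    n_zones_y: int = 4
    background_fraction: float = 0.02
    i_max: float | None = None  # saturation level; None skips linearization
    specific_fraction: dict[str, float] | None = None
    specific_threshold: float = 0.8
    enable_ggg: bool = True
    center_within_sets: bool = False
    output_scale: str = "intensity"  # or "linear"

    def __post_init__(self) -> None:
        if self.model not in ("n", "nn", "nnn", "nn+ggg"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.output_scale not in ("intensity", "linear"):
            raise ValueError(f"unknown output scale {self.output_scale!r}")
        if not 0 < self.specific_threshold < 1:
            raise ValueError("specific_threshold must lie in (0, 1)")


@dataclass
class PipelineResult:
    chip: ChipData
    model: HybridModel
    reports: dict[str, FitReport]
    stats: dict


_MODEL_RANK = {"n": 1, "nn": 2, "nnn": 3}


def run_pipeline(chip: ChipData, config: CorrectionConfig) -> PipelineResult:
    """Execute the full correction: calls, fits, correction, corrected chip.

    Deterministic for fixed input; no partial state escapes on error.
    """
    intensities = chip.intensity_array()
    stats: dict = {"n_probes": len(chip.probes), "n_probe_sets": len(chip.probe_sets)}

    # 0) optical background and linearization
    if config.background == "zone":
        background = zone_background(
            chip,
            n_zones_x=config.n_zones_x,
            n_zones_y=config.n_zones_y,
            fraction=config.background_fraction,
        )
        corrected_i = subtract_background(intensities, background)
    elif config.background == "none":
        corrected_i = intensities.copy()
    else:
        corrected_i = subtract_background(
            intensities, float(config.background) * np.ones_like(intensities)
        )
    if config.i_max is not None:
        params = HybridizationParams(i_max=config.i_max, i_min=0.0)
        above = corrected_i >= 0.95 * config.i_max
        if above.any():
            logger.warning("%d probe(s) above 95%% of saturation", int(above.sum()))
        clipped = np.minimum(corrected_i, config.i_max * (1 - 1e-9))
        linearized = linearize_intensity(clipped, params)
    else:
        params = None
        linearized = corrected_i

    # 1) absent/present calls
    absent_ids = classify_absent(
        chip, linearized, method=config.absent_method, calls=config.calls
    )
    stats["n_absent_sets"] = len(absent_ids)
    logger.info("absent sets: %d / %d", len(absent_ids), len(chip.probe_sets))

    model_name = config.model
    if model_name == "nn+ggg" and not config.enable_ggg:
        model_name = "nn"

    reports: dict[str, FitReport] = {}
    # 2) non-specific side fits
    if model_name == "nn+ggg":
        ps_nn, ps_ggg = split_probesets(chip, absent_ids)
        stats["n_ps_nn"] = len(ps_nn)
        stats["n_ps_ggg"] = len(ps_ggg)
        basal, basal_report = fit_basal_nn(chip, linearized, ps_nn)
        reports["basal_nn"] = basal_report
        if ps_ggg:
            excess, ggg_occ, excess_report = fit_ggg_excess(
                chip, linearized, ps_ggg, basal
            )
            reports["ggg_excess"] = excess_report
        else:
            excess, ggg_occ, excess_report = None, None, None
            warnings.warn("no GGG-containing absent sets; excess stage skipped",
                          stacklevel=2)
        model = HybridModel(basal_nn=basal, ggg_excess=excess, ggg_occupancy=ggg_occ)
        if excess_report is not None:
            combined = FitReport(
                rank=3,
                residuals=np.concatenate(
                    [basal_report.residuals, excess_report.residuals]
                ),
                probe_indices=np.concatenate(
                    [basal_report.probe_indices, excess_report.probe_indices]
                ),
                param_count=basal_report.param_count + excess_report.param_count,
            )
        else:
            combined = basal_report
        reports["absent"] = combined
    else:
        rank = _MODEL_RANK[model_name]
        mask = chip.probe_mask(absent_ids)
        profile, report = fit_profiles(
            chip, rank=rank, linearized=linearized, subset=mask, mode="N"
        )
        model = HybridModel(basal_nn=profile)
        reports["absent"] = report
    stats["ssr_absent"] = reports["absent"].ssr_total

    # 3/4) specific side
    fractions = config.specific_fraction or {}
    model.specific_fraction = dict(fractions)
    specific_sets = {
        set_id
        for set_id, w in fractions.items()
        if w > config.specific_threshold and set_id not in absent_ids
    }
    n_params_s = count_parameters(2)
    if specific_sets:
        mask_s = chip.probe_mask(specific_sets)
        if int(mask_s.sum()) >= n_params_s:
            specific, specific_report = fit_profiles(
                chip, rank=2, linearized=linearized, subset=mask_s, mode="S"
            )
            model.specific_nn = specific
            reports["specific"] = specific_report
            stats["n_specific_sets"] = len(specific_sets)
            stats["ssr_specific"] = specific_report.ssr_total
        else:
            warnings.warn(
                "too few predominantly specific probes to fit the specific "
                "profile; present probes fall back to the non-specific terms",
                stacklevel=2,
            )
    elif len(absent_ids) < len(chip.probe_sets):
        warnings.warn(
            "no probe sets exceed the specific-fraction threshold; present "
            "probes fall back to the non-specific terms",
            stacklevel=2,
        )

    # 5) apply and export
    corrected_l = correct_probes(
        chip,
        model,
        linearized,
        absent_ids,
        specific_threshold=config.specific_threshold,
        center_within_sets=config.center_within_sets,
    )
    if config.output_scale == "intensity" and params is not None:
        corrected_values = langmuir_intensity(corrected_l, params)
    else:
        corrected_values = corrected_l
    corrected_map = {
        (p.x, p.y): float(v) for p, v in zip(chip.probes, corrected_values)
    }
    corrected_chip = ChipData(
        probes=list(chip.probes),
        intensities=corrected_map,
        n_cols=chip.n_cols,
        n_rows=chip.n_rows,
        probe_sets={k: list(v) for k, v in chip.probe_sets.items()},
    )
    stats["absent_ids"] = sorted(absent_ids)
    return PipelineResult(chip=corrected_chip, model=model, reports=reports, stats=stats)
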