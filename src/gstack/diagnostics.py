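"""Model-rank and motif-resolved goodness-of-fit statistics.

All SSR-type quantities are mean squared residuals.  A motif class of length
``s`` at position ``k`` collects the probes whose sequence carries that motif
at that position; since every probe carries exactly one length-``s`` motif at
each ``k``, the occupancy-weighted class SSRs at fixed (s, k) sum exactly to
the total SSR.  Position-subsumed classes ("contains the motif anywhere")
overlap and do not obey that identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._sequtil import PROBE_LENGTH, motif_codes
from .chip_io import ChipData
from .sensitivity import MotifIndex, SensitivityProfile, enumerate_motifs

__all__ = [
    "FitReport",
    "FStatistic",
    "count_parameters",
    "pdnn_parameter_count",
    "motif_param_count",
    "f_statistic",
    "motif_ssr",
    "quality_of_fit",
    "standard_error",
    "delta_sigma_ggg",
    "sensitivity_to_fold",
    "SE_RULE_OF_THUMB",
]

SE_RULE_OF_THUMB = 0.01


@dataclass
class FitReport:
    """Residual bundle of one sensitivity fit.

    ``probe_indices`` map the residuals back onto ``chip.probes`` so motif
    classes can be formed on the fitted ensemble only.
    """

    rank: int
    residuals: np.ndarray
    probe_indices: np.ndarray
    param_count: int

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.probe_indices = np.asarray(self.probe_indices, dtype=np.int64)
        if self.residuals.shape != self.probe_indices.shape:
            raise ValueError("residuals and probe_indices must be aligned")

    @property
    def probe_count(self) -> int:
        return int(self.residuals.size)

    @property
    def ssr_raw(self) -> float:
        """Raw sum of squared residuals."""
        return float(self.residuals @ self.residuals)

    @property
    def ssr_total(self) -> float:
        """Mean squared residual (the reported SSR normalization)."""
        return self.ssr_raw / self.probe_count

    @property
    def degrees_of_freedom(self) -> int:
        return self.probe_count - self.param_count + 1


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------


def count_parameters(rank: int, probe_len: int = PROBE_LENGTH) -> int:
    """Independent parameters of the rank-``r`` model under per-position centering."""
    if not 1 <= rank <= 4:
        raise ValueError(f"rank must be in 1..4, got {rank}")
    return (4**rank - 1) * (probe_len - rank + 1) + 1


def pdnn_parameter_count(probe_len: int = PROBE_LENGTH) -> int:
    """Adjustable parameters of the shared-shape (PDNN-class) nearest-neighbor model.

    One centering constraint leaves ``4**2 - 1`` motif energies, plus one
    shape-function value per nearest-neighbor position.
    """
    return (4**2 - 1) + (probe_len - 1)


def motif_param_count(
    s: int, rank: int, probe_len: int = PROBE_LENGTH, positional: bool = False
) -> int:
    """Model tuples needed to describe a length-``s`` motif.

    ``positional=True`` counts the tuples covering the motif at one fixed
    position; otherwise the motif is counted at all positions.
    """
    per_position = s - rank + 1
    if per_position < 1:
        raise ValueError(f"motif length {s} shorter than model rank {rank}")
    if positional:
        return per_position
    return per_position * (probe_len - s + 1)


# ---------------------------------------------------------------------------
# F-statistics
# ---------------------------------------------------------------------------


class FStatistic(NamedTuple):
    f: float
    df: int
    delta_params: int


def f_statistic(report_low: FitReport, report_high: FitReport) -> FStatistic:
    """Empirical F-value for extending the model rank by one.

    F = [(SSR(r-1) - SSR(r)) / delta_params] / [SSR(r) / df(r)] with
    df(r) = #p - #sigma(r) + 1.  Residuals of array fits are not strictly
    normal, so the value is an empirical measure of fit improvement rather
    than a formal test statistic.
    """
    if report_high.rank != report_low.rank + 1:
        raise ValueError("reports must be nested with rank_high = rank_low + 1")
    if report_high.probe_count != report_low.probe_count:
        raise ValueError("reports must refer to the same probe ensemble")
    delta_params = report_high.param_count - report_low.param_count
    df = report_high.degrees_of_freedom
    ssr_low, ssr_high = report_low.ssr_total, report_high.ssr_total
    if ssr_high == 0.0:
        warnings.warn("SSR of the higher-rank model is zero; F is infinite",
                      stacklevel=2)
        return FStatistic(float("inf"), df, delta_params)
    f = ((ssr_low - ssr_high) / delta_params) / (ssr_high / df)
    return FStatistic(float(f), df, delta_params)


# ---------------------------------------------------------------------------
# motif-resolved residual statistics
# ---------------------------------------------------------------------------


def _class_table(
    report: FitReport, chip: ChipData, s: int, positional: bool
) -> pd.DataFrame:
    """Occupancy, residual sum and squared sum per motif class."""
    if not 1 <= s <= 4:
        raise ValueError(f"motif length must be in 1..4, got {s}")
    index = enumerate_motifs(s)
    codes = chip.sequence_codes()[report.probe_indices]
    mcodes = motif_codes(codes, s)
    res = report.residuals
    res2 = res * res
    n_motifs = index.n_motifs
    rows = []
    if positional:
        for k in index.positions:
            col = mcodes[:, k - 1]
            counts = np.bincount(col, minlength=n_motifs)
            sums = np.bincount(col, weights=res, minlength=n_motifs)
            sums2 = np.bincount(col, weights=res2, minlength=n_motifs)
            for m in np.flatnonzero(counts):
                rows.append((index.motifs[m], k, counts[m], sums[m], sums2[m]))
    else:
        # one membership per (probe, motif) even when the motif repeats
        n = codes.shape[0]
        keys = np.arange(n)[:, None] * n_motifs + mcodes
        unique = np.unique(keys.ravel())
        probe_of = unique // n_motifs
        motif_of = unique % n_motifs
        counts = np.bincount(motif_of, minlength=n_motifs)
        sums = np.bincount(motif_of, weights=res[probe_of], minlength=n_motifs)
        sums2 = np.bincount(motif_of, weights=res2[probe_of], minlength=n_motifs)
        for m in np.flatnonzero(counts):
            rows.append((index.motifs[m], pd.NA, counts[m], sums[m], sums2[m]))
    frame = pd.DataFrame(
        rows, columns=["motif", "position", "occupancy", "res_sum", "res_sum2"]
    )
    frame["occupancy"] = frame["occupancy"].astype(int)
    return frame


def motif_ssr(
    report: FitReport, chip: ChipData, s: int, positional: bool = True
) -> pd.DataFrame:
    """Mean squared residual per motif class, with occupancies and fractions."""
    table = _class_table(report, chip, s, positional)
    table["ssr"] = table["res_sum2"] / table["occupancy"]
    table["fraction"] = table["occupancy"] / report.probe_count
    return table[["motif", "position", "ssr", "occupancy", "fraction"]]


def quality_of_fit(
    report: FitReport, chip: ChipData, s: int, positional: bool = True
) -> pd.DataFrame:
    """Squared class-mean residual: the systematic-bias part of the class SSR."""
    table = _class_table(report, chip, s, positional)
    table["qf"] = (table["res_sum"] / table["occupancy"]) ** 2
    return table[["motif", "position", "qf", "occupancy"]]


def standard_error(
    report: FitReport, chip: ChipData, s: int, positional: bool = True
) -> pd.DataFrame:
    """Sampling standard error of the class-mean residual, with a QC flag.

    Classes with fewer than two members carry SE = NaN.  The ``precise``
    column flags classes meeting the SE < 0.01 rule of thumb.
    """
    table = _class_table(report, chip, s, positional)
    n = table["occupancy"].to_numpy(dtype=float)
    mean = table["res_sum"] / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (table["res_sum2"] - n * mean**2) / (n - 1)
        se = np.sqrt(np.maximum(var, 0.0) / n)
    se = np.where(n >= 2, se, np.nan)
    table["se"] = se
    table["precise"] = table["se"] < SE_RULE_OF_THUMB
    if np.isnan(se).any():
        warnings.warn("classes with occupancy < 2 have undefined SE", stacklevel=2)
    return table[["motif", "position", "se", "occupancy", "precise"]]


# ---------------------------------------------------------------------------
# scalar summaries
# ---------------------------------------------------------------------------


def delta_sigma_ggg(profile: SensitivityProfile) -> float:
    """Relative amplitude of the (GGG)1 effect: sigma_1(GGG) - sigma_12(CCC)."""
    if profile.rank != 3:
        raise ValueError("delta_sigma_ggg needs a rank-3 profile")
    if profile.count("GGG", 1) == 0:
        raise ValueError("no probes populate (GGG) at position 1")
    if profile.count("CCC", 12) == 0:
        raise ValueError("no probes populate (CCC) at position 12")
    return profile.value("GGG", 1) - profile.value("CCC", 12)


def sensitivity_to_fold(sigma: float) -> float:
    """Multiplicative intensity factor implied by a log10 sensitivity increment."""
    return float(10.0**sigma)
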