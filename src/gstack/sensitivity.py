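"""Positional motif sensitivity models.

A model of rank ``r`` assigns a sensitivity term ``sigma_k(b_r)`` to every
motif ``b_r`` of ``r`` adjacent bases starting at probe position ``k``
(1-based, k = 1 is the solution end).  The experimental sensitivity of a
probe is the deviation of its logged (base 10) linearized signal from the
mean over its probe set; the model predicts it as the sum of motif terms,
centered within each probe set.  Profiles are estimated by sparse multiple
linear regression and reported in the per-position centered gauge
(sum of sigma over motifs is zero at every position).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from ._sequtil import BASES, PROBE_LENGTH, motif_codes
from .chip_io import ChipData

__all__ = [
    "MotifIndex",
    "SensitivityProfile",
    "enumerate_motifs",
    "experimental_sensitivity",
    "build_design",
    "fit_profiles",
    "integral_sensitivity",
    "profile_similarity",
    "profile_similarity_matrix",
    "MAX_RANK_SPECIFIC",
]

MAX_RANK = 4
MAX_RANK_SPECIFIC = 3  # specific-mode ensembles are too small for rank 4
DEFAULT_CELL_CAP = 6000


@dataclass(frozen=True)
class MotifIndex:
    """Bijection between (motif, position) cells and design-matrix columns."""

    rank: int
    probe_len: int = PROBE_LENGTH
    motifs: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= MAX_RANK:
            raise ValueError(f"rank must be in 1..{MAX_RANK}, got {self.rank}")
        from itertools import product

        object.__setattr__(
            self,
            "motifs",
            tuple("".join(t) for t in product(BASES, repeat=self.rank)),
        )

    @property
    def n_motifs(self) -> int:
        return 4**self.rank

    @property
    def n_positions(self) -> int:
        return self.probe_len - self.rank + 1

    @property
    def n_cells(self) -> int:
        return self.n_motifs * self.n_positions

    def motif_code(self, motif: str) -> int:
        code = 0
        for base in motif:
            code = code * 4 + BASES.index(base)
        return code

    def column(self, motif: str, k: int) -> int:
        """Flat column index of motif ``motif`` at 1-based position ``k``."""
        if not 1 <= k <= self.n_positions:
            raise ValueError(f"position {k} outside 1..{self.n_positions}")
        return (k - 1) * self.n_motifs + self.motif_code(motif)

    @property
    def positions(self) -> range:
        return range(1, self.n_positions + 1)


def enumerate_motifs(rank: int, probe_len: int = PROBE_LENGTH) -> MotifIndex:
    """All ``4**rank`` motifs (lexicographic over A<C<G<T) at every position."""
    return MotifIndex(rank=rank, probe_len=probe_len)


@dataclass
class SensitivityProfile:
    """Estimated sensitivity terms sigma_k(b_r) with per-cell probe counts.

    ``sigma`` and ``occupancy`` are (n_positions, n_motifs) arrays; cells with
    zero occupancy are pinned to sigma = 0.
    """

    rank: int
    mode: str
    sigma: np.ndarray
    occupancy: np.ndarray
    index: MotifIndex

    def __post_init__(self) -> None:
        if self.mode not in ("N", "S"):
            raise ValueError(f"mode must be 'N' or 'S', got {self.mode!r}")
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=np.int64)
        expected = (self.index.n_positions, self.index.n_motifs)
        if self.sigma.shape != expected or self.occupancy.shape != expected:
            raise ValueError(f"profile arrays must have shape {expected}")

    def value(self, motif: str, k: int) -> float:
        return float(self.sigma[k - 1, self.index.motif_code(motif)])

    def count(self, motif: str, k: int) -> int:
        return int(self.occupancy[k - 1, self.index.motif_code(motif)])

    def recenter(self) -> None:
        """Re-impose the per-position centering gauge over populated cells."""
        populated = self.occupancy > 0
        for k in range(self.index.n_positions):
            mask = populated[k]
            if mask.any():
                self.sigma[k, mask] -= self.sigma[k, mask].mean()
            self.sigma[k, ~mask] = 0.0

    def delta_a(self, codes: np.ndarray) -> np.ndarray:
        """Per-probe sequence increment: sum of sigma over all positions."""
        mcodes = motif_codes(codes, self.rank)
        rows = np.arange(self.index.n_positions)
        return self.sigma[rows[None, :], mcodes].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: rank, motif, position, sigma, occupancy."""
        records = []
        for k in self.index.positions:
            for m, motif in enumerate(self.index.motifs):
                records.append(
                    (self.rank, motif, k, self.sigma[k - 1, m], int(self.occupancy[k - 1, m]))
                )
        return pd.DataFrame(
            records, columns=["rank", "motif", "position", "sigma", "occupancy"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: str = "N") -> "SensitivityProfile":
        rank = int(frame["rank"].iloc[0])
        index = enumerate_motifs(rank)
        sigma = np.zeros((index.n_positions, index.n_motifs))
        occupancy = np.zeros((index.n_positions, index.n_motifs), dtype=np.int64)
        for _, row in frame.iterrows():
            m = index.motif_code(row["motif"])
            sigma[int(row["position"]) - 1, m] = row["sigma"]
            occupancy[int(row["position"]) - 1, m] = row["occupancy"]
        return cls(rank=rank, mode=mode, sigma=sigma, occupancy=occupancy, index=index)

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str = "N") -> "SensitivityProfile":
        return cls.from_frame(pd.read_csv(path, sep="\t"), mode=mode)


# ---------------------------------------------------------------------------
# experimental sensitivities and design matrix
# ---------------------------------------------------------------------------


def set_means(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-probe value of the mean over that probe's set."""
    n_sets = int(labels.max()) + 1 if labels.size else 0
    sums = np.bincount(labels, weights=values, minlength=n_sets)
    counts = np.bincount(labels, minlength=n_sets)
    return (sums / counts)[labels]


def experimental_sensitivity(
    chip: ChipData,
    linearized: np.ndarray,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Y_exp: log10 L minus its probe-set mean (exactly zero-mean per set).

    ``linearized`` is aligned with ``chip.probes``; when ``subset`` (a boolean
    mask) is given, both the returned values and the per-set means are
    restricted to the selected probes.  Probes in singleton sets get Y_exp = 0
    and are flagged with a warning (they carry no information).
    """
    linearized = np.asarray(linearized, dtype=float)
    labels, _ = chip.set_index()
    if subset is not None:
        linearized = linearized[subset]
        labels = _relabel(labels[subset])
    if np.any(linearized <= 0):
        raise ValueError("linearized signals must be positive for log transformation")
    counts = np.bincount(labels)
    if (counts == 1).any():
        warnings.warn(
            f"{int((counts == 1).sum())} singleton probe set(s): "
            "Y_exp = 0, uninformative",
            stacklevel=2,
        )
    log_l = np.log10(linearized)
    return log_l - set_means(log_l, labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Compress arbitrary integer labels into 0..n-1."""
    _, out = np.unique(labels, return_inverse=True)
    return out


def build_design(
    chip: ChipData,
    index: MotifIndex,
    subset: np.ndarray | None = None,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse centered indicator matrix for the sensitivity regression.

    The entry for probe ``p`` and cell ``(b_r, k)`` is the motif indicator
    minus the within-probe-set motif probability, so per-position block sums
    vanish exactly in every row.  Returns the matrix and the per-cell probe
    occupancy (uncentered indicator column sums).
    """
    codes = chip.sequence_codes()
    labels, _ = chip.set_index()
    if subset is not None:
        codes = codes[subset]
        labels = _relabel(labels[subset])
    n = codes.shape[0]
    if n == 0:
        raise ValueError("empty probe subset")
    mcodes = motif_codes(codes, index.rank)
    n_pos = index.n_positions
    cols = (np.arange(n_pos)[None, :] * index.n_motifs + mcodes).ravel()
    rows = np.repeat(np.arange(n), n_pos)
    indicator = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, index.n_cells)
    )
    occupancy = np.asarray(indicator.sum(axis=0)).ravel().astype(np.int64)

    n_sets = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_sets).astype(float)
    membership = sp.csr_matrix(
        (np.ones(n), (np.arange(n), labels)), shape=(n, n_sets)
    )
    probs = sp.diags(1.0 / counts) @ (membership.T @ indicator)
    design = (indicator - membership @ probs).tocsr()
    return design, occupancy


# ---------------------------------------------------------------------------
# least-squares fit
# ---------------------------------------------------------------------------


def solve_min_norm(
    design: sp.spmatrix, y: np.ndarray, cond: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-norm least-squares solution via the (dense) normal equations.

    The centered design has an exact null space (the centering gauge plus the
    junction ambiguity of overlapping motifs); the SVD-based solve pins those
    directions to zero.  ``cond`` is the relative singular-value cutoff
    separating genuine spectrum from the numerical zeros of the singular
    Gram matrix.  Returns the coefficient vector and the residuals.
    """
    gram = np.asarray((design.T @ design).todense())
    rhs = design.T @ y
    coeffs, _, _, _ = scipy.linalg.lstsq(gram, rhs, cond=cond, lapack_driver="gelsd")
    residuals = y - design @ coeffs
    return coeffs, residuals


def fit_profiles(
    chip: ChipData,
    rank: int,
    linearized: np.ndarray,
    subset: np.ndarray | None = None,
    mode: str = "N",
    cell_cap: int = DEFAULT_CELL_CAP,
):
    """Fit a rank-``r`` sensitivity profile by sparse least squares.

    Returns ``(SensitivityProfile, FitReport)``.  The solution is the
    minimum-norm least-squares estimate, re-centered per position over
    populated cells (a pure gauge transformation: fitted values are
    unchanged).  The reported SSR is the mean squared residual.
    """
    from .diagnostics import FitReport, count_parameters

    if mode == "S" and rank > MAX_RANK_SPECIFIC:
        raise ValueError(
            f"specific-mode fits are capped at rank {MAX_RANK_SPECIFIC}"
        )
    index = enumerate_motifs(rank)
    if index.n_cells > cell_cap:
        raise MemoryError(
            f"rank {rank} needs {index.n_cells} cells (> cap {cell_cap}); "
            "consider the NN+GGG hybrid model instead"
        )
    y = experimental_sensitivity(chip, linearized, subset=subset)
    design, occupancy = build_design(chip, index, subset=subset)
    n_probes = design.shape[0]
    n_params = count_parameters(rank)
    if n_probes < n_params:
        raise ValueError(
            f"{n_probes} probes cannot constrain {n_params} parameters"
        )
    if n_probes < 10 * n_params:
        warnings.warn(
            f"only {n_probes} probes for {n_params} parameters "
            "(< 10x); estimates may be noisy",
            stacklevel=2,
        )
    if design.count_nonzero() == 0 or abs(design).max() < 1e-12:
        warnings.warn(
            "degenerate design: no motif variation within probe sets",
            stacklevel=2,
        )
    coeffs, residuals = solve_min_norm(design, y)
    profile = SensitivityProfile(
        rank=rank,
        mode=mode,
        sigma=coeffs.reshape(index.n_positions, index.n_motifs),
        occupancy=occupancy.reshape(index.n_positions, index.n_motifs),
        index=index,
    )
    profile.recenter()
    probe_indices = (
        np.flatnonzero(subset) if subset is not None else np.arange(len(chip.probes))
    )
    report = FitReport(
        rank=rank,
        residuals=residuals,
        probe_indices=probe_indices,
        param_count=n_params,
    )
    return profile, report


# ---------------------------------------------------------------------------
# integral sensitivities and profile similarity
# ---------------------------------------------------------------------------


def integral_sensitivity(
    profile: SensitivityProfile,
    k_range: tuple[int, int] | None = None,
    normalize: bool = True,
) -> pd.Series:
    """Per-motif sum of sigma_k over a position range.

    A reduced range is rescaled by ``full_width / reduced_width`` (when
    ``normalize``) so integrals stay comparable with the full-range values.
    """
    n_pos = profile.index.n_positions
    if k_range is None:
        k_lo, k_hi = 1, n_pos
    else:
        k_lo, k_hi = k_range
    if not (1 <= k_lo <= k_hi <= n_pos):
        raise ValueError(f"k_range {k_range} outside 1..{n_pos} or empty")
    values = profile.sigma[k_lo - 1 : k_hi].sum(axis=0)
    width = k_hi - k_lo + 1
    if normalize and width != n_pos:
        values = values * (n_pos / width)
    return pd.Series(values, index=list(profile.index.motifs), name="integral")


def profile_similarity(profile: SensitivityProfile, b1: str, b2: str) -> float:
    """Shape dissimilarity of two motif profiles, 0 = perfect affine match.

    The profile of ``b2`` is affinely matched (scale ``a``, shift ``c``) to
    the profile of ``b1`` by least squares; the minimized sum of squares is
    normalized by the centered sum of squares of ``b1`` so the score lies in
    [0, 1].
    """
    v1 = profile.sigma[:, profile.index.motif_code(b1)].astype(float)
    v2 = profile.sigma[:, profile.index.motif_code(b2)].astype(float)
    c1 = v1 - v1.mean()
    c2 = v2 - v2.mean()
    norm = float(c1 @ c1)
    if norm <= 1e-20 * max(1.0, float(v1 @ v1)):
        warnings.warn(f"profile of {b1} is constant; similarity undefined, 0 returned",
                      stacklevel=2)
        return 0.0
    var2 = float(c2 @ c2)
    if var2 <= 1e-20 * max(1.0, float(v2 @ v2)):
        warnings.warn(f"profile of {b2} is constant; scale undefined, a=0 used",
                      stacklevel=2)
        return 1.0
    a = float(c1 @ c2) / var2
    ss_min = float(((c1 - a * c2) ** 2).sum())
    return ss_min / norm


def profile_similarity_matrix(profile: SensitivityProfile) -> pd.DataFrame:
    """Pairwise similarity scores of all motif profiles (heatmap-ready)."""
    motifs = list(profile.index.motifs)
    matrix = np.zeros((len(motifs), len(motifs)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, b1 in enumerate(motifs):
            for j, b2 in enumerate(motifs):
                matrix[i, j] = profile_similarity(profile, b1, b2)
    return pd.DataFrame(matrix, index=motifs, columns=motifs)
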