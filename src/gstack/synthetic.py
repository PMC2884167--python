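"""Synthetic chips with known generating profiles and injectable poly-G bias.

Probe sequences are drawn per-base from a configurable composition, grouped
into probe sets sharing one specific and one non-specific transcript
concentration; intensities follow the two-species hyperbolic isotherm with
multiplicative (log-additive Gaussian) noise on the signal above the optical
background.  An injectable GGG excess on the non-specific channel reproduces
the (GGG)1 intensity spike, and a configurable fraction of sets is purely
non-specific ([S] = 0 exactly).  Generation is bit-reproducible from
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._sequtil import BASES, PROBE_LENGTH, complement_codes, decode, motif_codes
from .chip_io import ChipData, ProbeRecord, ROLE_MM, ROLE_PM
from .hybridization import HybridizationParams, langmuir_intensity

__all__ = [
    "GeneratingProfile",
    "SyntheticChipSpec",
    "SyntheticTruth",
    "default_paperlike_profile",
    "generate_chip",
]

_GGG_POSITIONS = PROBE_LENGTH - 3 + 1


@dataclass(frozen=True)
class GeneratingProfile:
    """Ground-truth sensitivity profile used to generate signals.

    ``sigma`` has shape (n_positions, 4**rank) and is centered over motifs at
    every position; ``ggg_excess`` (length 23) is an optional extra increment
    for every GGG run, applied on top of the rank-``r`` terms.
    """

    rank: int
    sigma: np.ndarray
    ggg_excess: np.ndarray | None = None

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "sigma", sigma)
        expected = (PROBE_LENGTH - self.rank + 1, 4**self.rank)
        if sigma.shape != expected:
            raise ValueError(f"sigma must have shape {expected}")
        if self.ggg_excess is not None:
            excess = np.asarray(self.ggg_excess, dtype=float)
            if excess.shape != (_GGG_POSITIONS,):
                raise ValueError(f"ggg_excess must have length {_GGG_POSITIONS}")
            object.__setattr__(self, "ggg_excess", excess)

    def delta_a(self, codes: np.ndarray) -> np.ndarray:
        mcodes = motif_codes(codes, self.rank)
        rows = np.arange(self.sigma.shape[0])
        out = self.sigma[rows[None, :], mcodes].sum(axis=1)
        if self.ggg_excess is not None:
            ggg = 2  # code of G
            tri = motif_codes(codes, 3)
            ggg_code = ggg * 16 + ggg * 4 + ggg
            out = out + (tri == ggg_code) @ self.ggg_excess
        return out

    def without_ggg(self) -> "GeneratingProfile":
        return replace(self, ggg_excess=None)


def _parabola_shape(n_positions: int) -> np.ndarray:
    """Positional weight: maximal mid-sequence, zero at the surface end (k=25)."""
    k = np.arange(1, n_positions + 1, dtype=float)
    return np.clip(1.0 - ((k - 10.0) / 15.0) ** 2, 0.0, None)


# per-base amplitudes ordered A < T < G < C, summing to zero
_BASE_AMPLITUDES = {"A": -0.09, "C": +0.09, "G": +0.03, "T": -0.03}

_DEFAULT_GGG_EXCESS = np.array([0.4] + [0.1] * (_GGG_POSITIONS - 1))


def _pair_coupling() -> np.ndarray:
    """Doubly-centered adjacent-pair interaction (GG, CC inflated; TT negative).

    Zero row and column sums keep the per-position centering of the motif
    profile and leave the single-base content of the model untouched, so
    models of rank >= 2 carry genuinely non-additive structure.
    """
    coupling = np.zeros((4, 4))
    coupling[2, 2] = 0.12  # GG
    coupling[1, 1] = 0.10  # CC
    coupling[3, 3] = -0.08  # TT
    coupling[0, 0] = -0.04  # AA
    coupling -= coupling.mean(axis=1, keepdims=True)
    coupling -= coupling.mean(axis=0, keepdims=True)
    return coupling


def default_paperlike_profile(
    rank: int,
    amplitudes: dict[str, float] | None = None,
    ggg_spike: bool | np.ndarray = False,
    pair_coupling: bool = True,
) -> GeneratingProfile:
    """Parabola-shaped per-base profile with mid-sequence ordering A < T < G < C.

    The per-position curves converge to zero at the surface-attached end
    (k = 25).  For ranks >= 2 a doubly-centered adjacent-pair coupling adds
    non-additive nearest-neighbor structure.  ``ggg_spike`` enables the GGG
    excess: ``True`` installs the default (+0.4 at k = 1, +0.1 at k > 1), an
    array overrides it.
    """
    if rank not in (1, 2, 3):
        raise ValueError("paper-like generating profiles support ranks 1..3")
    amps = dict(_BASE_AMPLITUDES if amplitudes is None else amplitudes)
    if abs(sum(amps.values())) > 1e-12:
        raise ValueError("base amplitudes must sum to zero (centering)")
    n_pos = PROBE_LENGTH - rank + 1
    shape = _parabola_shape(PROBE_LENGTH)
    amp_by_code = np.array([amps[b] for b in BASES])
    coupling = _pair_coupling() if (pair_coupling and rank >= 2) else None
    sigma = np.zeros((n_pos, 4**rank))
    for m in range(4**rank):
        bases = [(m // 4**(rank - 1 - i)) % 4 for i in range(rank)]
        for k in range(n_pos):
            value = np.mean(
                [amp_by_code[b] * shape[k + i] for i, b in enumerate(bases)]
            )
            if coupling is not None:
                pair_terms = [
                    coupling[bases[i], bases[i + 1]]
                    * 0.5 * (shape[k + i] + shape[k + i + 1])
                    for i in range(rank - 1)
                ]
                value += np.mean(pair_terms)
            sigma[k, m] = value
    excess = None
    if isinstance(ggg_spike, np.ndarray):
        excess = ggg_spike
    elif ggg_spike:
        excess = _DEFAULT_GGG_EXCESS.copy()
    return GeneratingProfile(rank=rank, sigma=sigma, ggg_excess=excess)


@dataclass(frozen=True)
class SyntheticChipSpec:
    """Full description of a synthetic chip experiment."""

    n_probe_sets: int
    probes_per_set: int = 11
    pm_mm: bool = False
    base_composition: tuple[float, float, float, float] = (0.32, 0.28, 0.10, 0.30)
    ggg1_enrichment: float = 0.0
    profile: GeneratingProfile = field(
        default_factory=lambda: default_paperlike_profile(2)
    )
    specific_profile: GeneratingProfile | None = None  # default: profile minus GGG
    absent_fraction: float = 0.5
    log_conc_n: tuple[float, float] = (1.0, 0.3)  # log10 [N]: mean, sd
    log_conc_s: tuple[float, float] = (2.5, 0.5)  # log10 [S]: mean, sd
    params: HybridizationParams = field(
        default_factory=lambda: HybridizationParams(
            i_max=1.0e4, i_min=50.0, k_n=1.0, k_s=1.0
        )
    )
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probe_sets < 1 or self.probes_per_set < 1:
            raise ValueError("need at least one probe set with one probe")
        if not 0 <= self.absent_fraction <= 1:
            raise ValueError("absent_fraction must lie in [0, 1]")
        if not 0 <= self.ggg1_enrichment <= 1:
            raise ValueError("ggg1_enrichment must lie in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticTruth:
    """Everything the generator knew: the ground truth for recovery tests."""

    spec: SyntheticChipSpec
    profile: GeneratingProfile
    specific_profile: GeneratingProfile
    set_names: list[str]
    absent_ids: set[str]
    log_conc_n: np.ndarray  # per set
    log_conc_s: np.ndarray  # per set, -inf for absent sets
    l_n: np.ndarray  # per probe
    l_s: np.ndarray  # per probe
    noise: np.ndarray  # per probe, log10 scale
    ggg1_mask: np.ndarray  # per probe: sequence starts with GGG
    specific_fraction: dict[str, float]

    @property
    def calls(self) -> dict[str, str]:
        return {
            name: ("A" if name in self.absent_ids else "P") for name in self.set_names
        }


def generate_chip(spec: SyntheticChipSpec) -> tuple[ChipData, SyntheticTruth]:
    """Generate a chip and its ground truth, deterministically from the spec."""
    rng = np.random.default_rng(spec.seed)
    n_sets = spec.n_probe_sets
    n_pm = n_sets * spec.probes_per_set

    codes = rng.choice(
        4, size=(n_pm, PROBE_LENGTH), p=np.asarray(spec.base_composition)
    ).astype(np.uint8)
    forced = rng.random(n_pm) < spec.ggg1_enrichment
    codes[forced, :3] = 2  # GGG prefix at the solution end
    ggg1_mask_pm = np.all(codes[:, :3] == 2, axis=1)

    set_names = [f"PS{i:06d}" for i in range(n_sets)]
    set_of_pm = np.repeat(np.arange(n_sets), spec.probes_per_set)
    absent = rng.random(n_sets) < spec.absent_fraction
    absent_ids = {set_names[i] for i in np.flatnonzero(absent)}

    log_conc_n = rng.normal(spec.log_conc_n[0], spec.log_conc_n[1], size=n_sets)
    log_conc_s = rng.normal(spec.log_conc_s[0], spec.log_conc_s[1], size=n_sets)
    log_conc_s[absent] = -np.inf  # [S] = 0 exactly

    profile = spec.profile
    specific_profile = (
        spec.specific_profile if spec.specific_profile is not None
        else profile.without_ggg()
    )

    if spec.pm_mm:
        mm_codes = codes.copy()
        mm_codes[:, 12] = complement_codes(mm_codes[:, 12])
        all_codes = np.empty((2 * n_pm, PROBE_LENGTH), dtype=np.uint8)
        all_codes[0::2] = codes
        all_codes[1::2] = mm_codes
        set_of = np.repeat(set_of_pm, 2)
        roles = np.tile([ROLE_PM, ROLE_MM], n_pm)
        ggg1_mask = np.all(all_codes[:, :3] == 2, axis=1)
    else:
        all_codes = codes
        set_of = set_of_pm
        roles = np.array([ROLE_PM] * n_pm)
        ggg1_mask = ggg1_mask_pm
    n_probes = all_codes.shape[0]

    delta_n = profile.delta_a(all_codes)
    delta_s = specific_profile.delta_a(all_codes)
    params = spec.params
    l_n = params.k_n * 10.0 ** (log_conc_n[set_of] + delta_n)
    with np.errstate(over="ignore"):
        l_s = params.k_s * 10.0 ** (log_conc_s[set_of] + delta_s)
    l_s[~np.isfinite(l_s)] = 0.0

    intensity = langmuir_intensity(l_n + l_s, params)
    noise = rng.normal(0.0, spec.noise_sd, size=n_probes) if spec.noise_sd else np.zeros(n_probes)
    intensity = params.i_min + (intensity - params.i_min) * 10.0**noise

    # grid layout: PM/MM stacked in adjacent rows when pm_mm is on
    if spec.pm_mm:
        n_cols = int(np.ceil(np.sqrt(n_pm)))
        pair_col = np.arange(n_pm) % n_cols
        pair_row = np.arange(n_pm) // n_cols
        xs = np.repeat(pair_col, 2)
        ys = np.empty(n_probes, dtype=int)
        ys[0::2] = 2 * pair_row
        ys[1::2] = 2 * pair_row + 1
    else:
        n_cols = int(np.ceil(np.sqrt(n_probes)))
        xs = np.arange(n_probes) % n_cols
        ys = np.arange(n_probes) // n_cols
    n_rows = int(ys.max()) + 1

    probes = []
    intensities: dict[tuple[int, int], float] = {}
    for i in range(n_probes):
        pair = f"pair{i // 2:06d}" if spec.pm_mm else None
        probes.append(
            ProbeRecord(
                probe_set_id=set_names[set_of[i]],
                x=int(xs[i]),
                y=int(ys[i]),
                sequence=decode(all_codes[i]),
                role=str(roles[i]),
                pair_id=pair,
            )
        )
        intensities[(int(xs[i]), int(ys[i]))] = float(intensity[i])

    chip = ChipData(
        probes=probes, intensities=intensities, n_cols=n_cols, n_rows=n_rows
    )

    total = l_n + l_s
    frac = l_s / total
    specific_fraction = {
        set_names[s]: float(frac[set_of == s].mean()) for s in range(n_sets)
    }
    truth = SyntheticTruth(
        spec=spec,
        profile=profile,
        specific_profile=specific_profile,
        set_names=set_names,
        absent_ids=absent_ids,
        log_conc_n=log_conc_n,
        log_conc_s=log_conc_s,
        l_n=l_n,
        l_s=l_s,
        noise=noise,
        ggg1_mask=ggg1_mask,
        specific_fraction=specific_fraction,
    )
    return chip, truth
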