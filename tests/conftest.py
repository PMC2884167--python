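"""Shared fixtures: synthetic chips are generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gstack.hybridization import linearize_intensity
from gstack.synthetic import (
    SyntheticChipSpec,
    default_paperlike_profile,
    generate_chip,
)


def true_linearized(chip, truth):
    """Linearized signals from the generator's hybridization params.

    Noise can push a stray intensity above the saturation asymptote; such
    probes are clipped just below it (they would be flagged in the pipeline).
    """
    params = truth.spec.params
    ceiling = params.i_min + params.i_max * (1 - 1e-9)
    values = np.minimum(chip.intensity_array(), ceiling)
    return linearize_intensity(values, params)


@pytest.fixture(scope="session")
def small_chip():
    """Small noisy chip with PM-only probes, mixed absent/present sets."""
    spec = SyntheticChipSpec(
        n_probe_sets=300, noise_sd=0.1, absent_fraction=0.6, seed=11
    )
    return generate_chip(spec)


@pytest.fixture(scope="session")
def noisefree_rank2_chip():
    """Noise-free chip generated exactly by a rank-2 profile (all absent)."""
    spec = SyntheticChipSpec(
        n_probe_sets=1000, noise_sd=0.0, absent_fraction=1.0, seed=1
    )
    return generate_chip(spec)


@pytest.fixture(scope="session")
def spiked_chip():
    """Noisy chip with the (GGG)1 excess (+0.4 at k=1, +0.1 elsewhere) injected."""
    spec = SyntheticChipSpec(
        n_probe_sets=3500,
        noise_sd=0.1,
        absent_fraction=0.65,
        ggg1_enrichment=0.03,
        seed=7,
        profile=default_paperlike_profile(2, ggg_spike=True),
    )
    return generate_chip(spec)


@pytest.fixture(scope="session")
def spiked_rank2_report(spiked_chip):
    """Plain rank-2 fit on all absent probes of the spiked chip."""
    from gstack.sensitivity import fit_profiles

    chip, truth = spiked_chip
    linearized = true_linearized(chip, truth)
    mask = chip.probe_mask(truth.absent_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile, report = fit_profiles(chip, 2, linearized, subset=mask)
    return profile, report


@pytest.fixture(scope="session")
def spiked_pipeline_results(spiked_chip):
    """Pipeline runs (n, nn, nn+ggg) on the spiked chip with truth inputs."""
    from gstack.correction import CorrectionConfig, run_pipeline

    chip, truth = spiked_chip
    params = truth.spec.params
    results = {}
    for model in ("n", "nn", "nn+ggg"):
        config = CorrectionConfig(
            model=model,
            absent_method="override",
            calls=truth.calls,
            background=params.i_min,
            i_max=params.i_max,
            specific_fraction=truth.specific_fraction,
            output_scale="linear",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results[model] = run_pipeline(chip, config)
    return results


def ggg1_offset(chip, truth, values):
    """Mean log10 offset of absent (GGG)1 probes vs all absent probes."""
    absent = chip.probe_mask(truth.absent_ids)
    log_v = np.log10(values)
    return float(log_v[absent & truth.ggg1_mask].mean() - log_v[absent].mean())
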