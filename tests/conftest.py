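"""Shared fixtures: synthetic nerves, reference electrode setups, and the
(expensive) oracle comparison and inverse fit, built once per session."""

from __future__ import annotations

import logging

import numpy as np
import pytest

import nervecap as nc
from nervecap.ecap import DiameterGrid, FiberType

logging.disable(logging.WARNING)

# Gaussian-model reference parameters: myelinated AP width, ~1 mm contact
# extent, a mid-sized myelinated fiber (d = 4 um).
W_V = 5e-5
W_PHI = 1e-3
V_MYEL_4UM = 4.3e6 * 4e-6
ETA_4UM = np.pi * (4e-6) ** 2 / 4
X_C = 0.06


@pytest.fixture(scope="session")
def gaussian_ap():
    return nc.gaussian_ap(0.1, W_V)


@pytest.fixture(scope="session")
def monopolar_profile():
    grid = np.linspace(0.0, 0.12, 24001)
    prof = nc.gaussian_profile([nc.GaussianContact(50.0, W_PHI, X_C)], grid)
    return nc.taper_ends(prof)


@pytest.fixture(scope="session")
def default_nerve():
    spec = nc.default_fixture()
    return spec, nc.synth_nerve(spec)


@pytest.fixture(scope="session")
def myelinated_nerve():
    """Default fixture restricted to its myelinated populations."""
    spec = nc.NerveSpec(unmyelinated_density=0.0)
    return spec, nc.synth_nerve(spec)


@pytest.fixture(scope="session")
def ap_waveforms():
    return nc.default_ap_waveforms()


@pytest.fixture(scope="session")
def oracle_comparison(gaussian_ap):
    """Reciprocity SFAP vs point-source summation on a straight 300 mm fiber.

    Two point terminals 1 mm off-axis in a homogeneous unit-conductivity
    medium; Gaussian AP propagating at the myelinated velocity of a 4 um
    fiber; >= 2000 segments.
    """
    v, eta = V_MYEL_4UM, ETA_4UM
    cfg = nc.PointElectrodeConfig(((0.14, 1e-3, 0.0), (0.16, 1e-3, 0.0)), sigma=1.0)
    path = ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
    arc = np.linspace(0.0, 0.3, 3001)
    l_init = 0.05
    t_grid = np.linspace(0.0, (0.25 - l_init) / v, 2000)
    oracle = nc.sfap_point_source(gaussian_ap, v, eta, path, arc, cfg, t_grid, l_init)
    prof = nc.taper_ends(nc.point_electrode_profile(cfg, path, arc))
    recip = nc.sfap_reciprocity(gaussian_ap, prof, v, eta, l_init)
    return recip, oracle, dict(v=v, eta=eta, arc=arc, l_init=l_init, t_grid=t_grid, cfg=cfg, path=path)


@pytest.fixture(scope="session")
def inverse_fit():
    """Committed inverse-recovery run: 3-fascicle myelinated nerve, reference
    generated at the ground-truth gamma parameters, fit started from a ±30%
    perturbation with a 500-evaluation budget."""
    spec = nc.NerveSpec(n_fascicles=3, seed=11, unmyelinated_density=0.0)
    nerve = nc.synth_nerve(spec)
    aps = nc.default_ap_waveforms()
    model = nc.ECAPForwardModel(nerve.fascicles, aps, spec.partial_current)
    k_true, th_true = spec.gamma_params[FiberType.MYELINATED_AFFERENT.value]
    reference = model.simulate(k_true, th_true)
    problem = nc.FitProblem(
        model,
        reference,
        (k_true * 1.3, th_true * 0.7),
        ((2.0, 12.0), (2e-7, 2e-6)),
        max_evals=500,
    )
    fit = nc.fit_diameter_distribution(problem)
    return fit, (k_true, th_true), problem
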