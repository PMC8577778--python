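"""Shared fixtures.

The FDTD runs are the expensive part of the suite, so the full-sweep
protocol results and the sphere-oracle comparison are computed once per
session and shared between the property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from aedosim import exposure, fdtd, mie
from aedosim.constants import C0
from aedosim.dielectric import (
    AEDES_FIT2_EPS,
    AEDES_FIT2_SIGMA,
    evaluate_debye,
    wavelength_in_medium,
)
from aedosim.synthetic import PhantomSpec, make_phantom, make_sphere_phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: Dielectric rows used everywhere: real part and conductivity of the
#: homogenized mosquito tissue (two-relaxation Debye fits).
TABLE_ROWS = (AEDES_FIT2_EPS, AEDES_FIT2_SIGMA)


def mosquito_dielectric(f_hz: float) -> tuple[float, float]:
    eps_real, _, _ = evaluate_debye(AEDES_FIT2_EPS, f_hz)
    _, _, sigma = evaluate_debye(AEDES_FIT2_SIGMA, f_hz)
    return float(eps_real), float(sigma)


@pytest.fixture(scope="session")
def male_phantom():
    """Male-mean mosquito phantom (3.5 mm / 0.8 mm^3) at 25 um pitch."""
    mesh, model = make_phantom(PhantomSpec())
    return mesh, model


@pytest.fixture(scope="session")
def female_phantom():
    """Larger, female-like phantom (4.0 mm / 1.2 mm^3)."""
    spec = PhantomSpec(body_length=4.0e-3, total_volume=1.2e-9)
    mesh, model = make_phantom(spec)
    return mesh, model


@pytest.fixture(scope="session")
def phantom_sweep(male_phantom):
    """Full 12-wave frequency sweep (2-240 GHz) on the male phantom.

    Grid pitch per frequency follows min(lambda_medium/10, body/12);
    this is the workhorse result reused by the trend, bundle and
    orientation tests.
    """
    _, model = male_phantom
    config = exposure.ExposureConfig()
    return exposure.run_protocol(model, TABLE_ROWS, config, model_id="male")


@pytest.fixture(scope="session")
def female_sweep(female_phantom):
    """12-wave results for the female-like phantom at 6 and 60 GHz."""
    _, model = female_phantom
    config = exposure.ExposureConfig(frequencies_ghz=(6.0, 60.0))
    return exposure.run_protocol(model, TABLE_ROWS, config, model_id="female")


@pytest.fixture(scope="session")
def sphere_oracle_case():
    """12-wave FDTD absorption of the r = 0.5 mm homogeneous sphere with
    mosquito tissue dielectric at 60 GHz, gridded at lambda_medium/15,
    plus the analytic Mie reference."""
    f = 60e9
    r = 0.5e-3
    eps_real, sigma = mosquito_dielectric(f)
    h = float(wavelength_in_medium(f, eps_real)) / 15.0
    _, model = make_sphere_phantom(r, h)
    domain = fdtd.build_domain(model, eps_real, sigma)
    powers = []
    for _, wave in exposure.standard_12_waves(f):
        sol = fdtd.run_fdtd(domain, wave)
        powers.append(fdtd.compute_pabs(sol, domain))
    p_mie = mie.mie_absorbed_power(r, eps_real, sigma, f)
    return {
        "powers": np.asarray(powers),
        "p_mie": p_mie,
        "radius": r,
        "frequency": f,
        "eps_real": eps_real,
        "sigma": sigma,
        "h": h,
    }
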