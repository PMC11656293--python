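import dataclasses

import pytest

from scintqa.pipeline import full_run
from scintqa.simulate import DeliveryConfig, GeometryConfig, make_calibration_plan


@pytest.fixture(scope="session")
def geom_half() -> GeometryConfig:
    """Half-resolution sensor: same physics, 4x faster frames."""
    return GeometryConfig().scaled(0.5)


@pytest.fixture(scope="session")
def geom_half_clean(geom_half) -> GeometryConfig:
    return dataclasses.replace(geom_half, noiseless=True)


@pytest.fixture(scope="session")
def small_plan():
    """27 spots in 3 layers, the small grid used across unit tests."""
    return make_calibration_plan(3, 3, 20.0, (125.0, 150.0), intensity=0.3)


@pytest.fixture(scope="session")
def small_delivery(small_plan):
    from scintqa.simulate import deliver

    cfg = DeliveryConfig(rng_seed=7)
    return cfg, deliver(small_plan, cfg)


@pytest.fixture(scope="session")
def e2e():
    """Full synthetic QA session, shared by the end-to-end assertions.

    Calibrates on a two-intensity grid irradiation, then measures a held-out
    verification grid under nominal conditions (whose discrepancies define
    the confidence intervals), under a 1 degree table rotation, and under a
    2 mm Y translation.
    """
    nominal, model, meas = full_run(preset="nominal", seed=1)
    ci = nominal.ci
    rotated, _, _ = full_run(preset="rotate1deg", seed=1, model=model, ci=ci)
    translated, _, _ = full_run(preset="translate2mm", seed=1, model=model, ci=ci)
    return {
        "nominal": nominal,
        "rotated": rotated,
        "translated": translated,
        "model": model,
        "measurement": meas,
    }
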