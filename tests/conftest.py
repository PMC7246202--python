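"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from oameta.ingest import StudyRecord, TreatmentArm


def grid_reml_tau2(
    y: np.ndarray,
    v: np.ndarray,
    upper: float = 5.0,
    final_step: float = 1e-7,
) -> float:
    """Brute-force restricted-likelihood maximiser over tau2.

    Staged grid refinement down to a 1e-7 lattice: a coarse pass over
    [0, upper], then windowed refinement around the running argmax.
    Deliberately independent of the package's Fisher-scoring estimator.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)

    def ll(tau2s: np.ndarray) -> np.ndarray:
        s = v[None, :] + tau2s[:, None]
        w = 1.0 / s
        sw = w.sum(axis=1)
        mu = (w * y).sum(axis=1) / sw
        resid = y[None, :] - mu[:, None]
        return -0.5 * (np.log(s).sum(axis=1) + np.log(sw) + (w * resid**2).sum(axis=1))

    lo, hi, step = 0.0, upper, 1e-4
    while True:
        grid = np.arange(lo, hi + step / 2, step)
        best = grid[int(np.argmax(ll(grid)))]
        if step <= final_step:
            return float(best)
        lo = max(0.0, best - 2 * step)
        hi = min(upper, best + 2 * step)
        step = max(final_step, step / 100.0)


def random_meta_instance(rng: np.random.Generator, k_max: int = 8):
    """A random small meta-analysis: k effects with known variances."""
    k = int(rng.integers(2, k_max + 1))
    v = rng.uniform(0.005, 0.05, size=k)
    tau2 = rng.uniform(0.0, 0.1)
    theta = rng.normal(0.0, 0.3)
    y = rng.normal(theta, np.sqrt(v + tau2))
    return y, v


@pytest.fixture
def simple_record() -> StudyRecord:
    """Two-arm phytoplankton record with mean/SE summaries."""
    return StudyRecord(
        study_id="s1",
        experiment_id="e1",
        species="Phaeocystis antarctica",
        group="phytoplankton",
        trophic_level="autotroph",
        response_name="chlorophyll_a",
        direction="higher_is_better",
        duration_days=14.0,
        arms=[
            TreatmentArm(co2_uatm=400.0, mean=100.0, se=5.0, n=6, is_control=True),
            TreatmentArm(co2_uatm=900.0, mean=80.0, se=5.0, n=6),
        ],
    )


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The named fixture suite written once per session."""
    from oameta.synthdata import make_fixture_suite

    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out)
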