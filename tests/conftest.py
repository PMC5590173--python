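import numpy as np
import pytest

from mmtmc.basis import ReducedFit, SplineSpec, evaluate_spline
from mmtmc.simulate import StudyConfig, run_study, scenario_spec

#: single master seed for every replicated study in the suite
SUITE_SEED = 20240917


def quadratic_fit(vcov_scale: float = 0.0, center: float = 20.0) -> ReducedFit:
    """A ReducedFit whose curve is exactly (x - center)^2 / 100 on [0, 30].

    The quadratic B-spline basis (with intercept) reproduces quadratics, so
    the least-squares projection is exact; useful as a closed-form toy.
    """
    spec = SplineSpec(
        family="quadratic_bspline",
        internal_knots=(10.0, 20.0),
        boundary_knots=(0.0, 30.0),
        intercept=True,
    )
    x = np.linspace(0, 30, 601)
    B = evaluate_spline(x, spec).values
    target = (x - center) ** 2 / 100
    beta, *_ = np.linalg.lstsq(B, target, rcond=None)
    return ReducedFit(
        beta=beta,
        vcov=vcov_scale * np.eye(spec.dim),
        temp_spline=spec,
        temp_grid=np.round(np.arange(0, 30.05, 0.1), 10),
        observed_temps=np.linspace(0, 30, 3001),
    )


@pytest.fixture(scope="session")
def toy_quadratic_fit() -> ReducedFit:
    return quadratic_fit()


@pytest.fixture(scope="session")
def u_study():
    """200-replicate U-shape study (5 years, phi 1.3, n_sim 2000) with the
    unrestricted and prior-restricted empirical estimators plus Argmin2."""
    spec = scenario_spec(1)
    results, truth = run_study(
        spec,
        n_replicates=200,
        methods=("Argmin2", "Empirical1", "Empirical2_minimal"),
        config=StudyConfig(n_sim=2000),
        seed=SUITE_SEED,
    )
    return results, truth


@pytest.fixture(scope="session")
def sector_study():
    """200-replicate sector-shape study with both empirical estimators and
    retained Monte Carlo samples (for percentile-pair re-summaries)."""
    spec = scenario_spec(4)
    results, truth = run_study(
        spec,
        n_replicates=200,
        methods=("Empirical1", "Empirical2_minimal"),
        config=StudyConfig(n_sim=2000),
        seed=SUITE_SEED + 1,
        keep_samples=True,
    )
    return results, truth


@pytest.fixture(scope="session")
def fitted_replicate():
    """One fitted reduced fit from a reverse-J replicate (well-behaved,
    interior minimum), shared by argmin/sampler tests."""
    from mmtmc.simulate import build_truth, fit_replicate, generate_dataset

    spec = scenario_spec(2)
    truth = build_truth(spec, seed=SUITE_SEED)
    data = generate_dataset(spec, seed=SUITE_SEED + 2, truth=truth)
    return fit_replicate(data, truth), truth
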