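import numpy as np
import pytest

import fracimmune as fi


@pytest.fixture(scope="session")
def scenario1():
    return fi.load_scenario("scenario1")


@pytest.fixture(scope="session")
def scenario2():
    return fi.load_scenario("scenario2")


@pytest.fixture(scope="session")
def scenario3():
    return fi.load_scenario("scenario3")


@pytest.fixture(scope="session")
def scenario_trajectories(scenario1, scenario2, scenario3):
    """Full-horizon simulations of the three packaged scenarios.

    Session-scoped: the quadratic-memory integrator makes these the most
    expensive objects in the suite, and several tests inspect them.
    """
    out = {}
    for cfg in (scenario1, scenario2, scenario3):
        out[cfg.name] = fi.simulate(cfg.params, cfg.y0, cfg.t_end, cfg.h)
    return out


def random_params(rng, orders=None, require_e2=False, max_denominator=10):
    """Draw a random positive parameter set for property tests.

    Rates are log-uniform over a biologically plausible range; orders are
    random reduced rationals with bounded denominator unless given.  With
    ``require_e2`` the draw is repeated until the interior equilibrium
    exists biologically.
    """
    while True:
        rates = dict(
            beta_P=float(np.exp(rng.uniform(np.log(0.1), np.log(10)))),
            Lambda=float(np.exp(rng.uniform(np.log(0.5), np.log(20)))),
            c=float(np.exp(rng.uniform(np.log(0.1), np.log(10)))),
            a=float(np.exp(rng.uniform(np.log(0.05), np.log(10)))),
            mu=float(np.exp(rng.uniform(np.log(0.1), np.log(10)))),
            nu=float(np.exp(rng.uniform(np.log(0.05), np.log(10)))),
            delta=float(np.exp(rng.uniform(np.log(0.05), np.log(5)))),
        )
        if orders is None:
            den = int(rng.integers(1, max_denominator + 1))
            num = int(rng.integers(1, den + 1))
            a1 = fi.RationalOrder(num, den)
            den = int(rng.integers(1, max_denominator + 1))
            num = int(rng.integers(1, den + 1))
            a2 = fi.RationalOrder(num, den)
        else:
            a1, a2 = orders
        params = fi.ModelParams(**rates, alpha1=a1, alpha2=a2)
        if not require_e2 or fi.equilibria(params)[2].exists_biologically:
            return params
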