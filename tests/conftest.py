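import numpy as np
import pytest

import loalfuse as lf


@pytest.fixture(scope="session")
def spec_a():
    return lf.scenario1_spec("main_terms")


@pytest.fixture(scope="session")
def data_a(spec_a):
    """Moderate two-time-point dataset for pipeline-level tests."""
    return lf.generate(spec_a, 1000, seed=20240917)


@pytest.fixture(scope="session")
def beta_a(data_a):
    return lf.fit_working_coefficients(
        data_a, regressors=lf.scenario1_q_regressors(data_a)
    )


@pytest.fixture(scope="session")
def loal_fit_a(data_a, beta_a):
    return lf.fit_loal(data_a, beta_a)


def neg_loglik_ref(X, y, coef):
    """Reference Bernoulli negative log-likelihood (independent of the solver)."""
    lp = X @ coef
    return float(np.sum(np.log1p(np.exp(-np.abs(lp))) + np.maximum(lp, 0) - y * lp))


def grad_neg_loglik_ref(X, y, coef):
    from scipy.special import expit

    return X.T @ (expit(X @ coef) - y)
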