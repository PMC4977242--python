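import numpy as np
import pytest

import plateaulc as plc

#: below-knot quadratic coefficients of the reference ONSD learning curve
PRINTED_COEFFS = (19.73, -1.614, 0.03843)


@pytest.fixture(scope="session")
def printed_coefficients():
    return PRINTED_COEFFS


@pytest.fixture(scope="session")
def printed_curve():
    """Smooth-join curve implied by the reference coefficients."""
    a, b, c = PRINTED_COEFFS
    knot, plateau = plc.knot_from_coefficients(a, b, c)
    return plc.LearningCurve(plateau=plateau, curvature=c, knot=knot)


@pytest.fixture()
def simulated_records():
    """A 60-subject simulated measurement table (balanced, 4 sites)."""
    return plc.simulate_dataset(plc.SimulationConfig(n_subjects=60, seed=11))


def brute_force_fit(index, y, knot_range=None):
    """Independent oracle for the quadratic-plateau fit.

    Exhaustive search over integer knots; at each knot the best (plateau,
    curvature) pair is located on a dense lattice and then refined with the
    closed-form simple-regression solution on the regressor
    x = (I - K)^2 * 1[I <= K].  Returns (rss, knot, plateau, curvature) or a
    flat fit when no knot supports a positive curvature.
    """
    index = np.asarray(index, dtype=float)
    y = np.asarray(y, dtype=float)
    if knot_range is None:
        uniq = np.unique(index)
        knot_range = range(int(np.ceil(uniq[1])), int(np.floor(uniq[-2])) + 1)
    best = None
    for k in knot_range:
        x = np.where(index <= k, (index - k) ** 2, 0.0)
        # coarse lattice bracket (kept deliberately crude; the closed form
        # below does the real work)
        p_grid = np.linspace(y.min(), y.max(), 21)
        c_grid = np.linspace(1e-8, max(1.0, np.ptp(y) / max(x.max(), 1.0)) * 2, 21)
        lattice_rss = np.array(
            [[np.sum((y - (p + c * x)) ** 2) for c in c_grid] for p in p_grid]
        )
        assert np.isfinite(lattice_rss).all()
        # closed-form least squares for y = P + c x
        sxx = np.sum((x - x.mean()) ** 2)
        if sxx == 0:
            continue
        c_hat = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        p_hat = y.mean() - c_hat * x.mean()
        rss = float(np.sum((y - (p_hat + c_hat * x)) ** 2))
        assert rss <= lattice_rss.min() + 1e-9  # lattice can never beat OLS
        if c_hat <= 0:
            continue
        if best is None or rss < best[0]:
            best = (rss, float(k), p_hat, c_hat)
    if best is None:
        mean = float(y.mean())
        return float(np.sum((y - mean) ** 2)), None, mean, 0.0
    return best
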