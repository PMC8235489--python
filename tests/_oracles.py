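"""Independent brute-force oracles used by unit and acceptance tests."""

import numpy as np

from fgmi.hinge import hinge_objective


def grid_search_hinge_optimum(X, y, alpha, lo=-5.0, hi=5.0, step=0.01):
    """Dense 2-D grid search for the regularized hinge objective minimum.

    Exhaustively evaluates sum_n max(0, 1 - y_n w.x_n) + alpha ||w||^2 on
    the grid and returns the smallest value found.  Only for 2-feature
    problems; independent of the package's solver.
    """
    assert X.shape[1] == 2
    grid = np.arange(lo, hi + step / 2, step)
    W = np.stack(np.meshgrid(grid, grid), axis=-1).reshape(-1, 2)
    margins = (W @ X.T) * y[np.newaxis, :]
    hinge = np.maximum(0.0, 1.0 - margins).sum(axis=1)
    obj = hinge + alpha * (W ** 2).sum(axis=1)
    best = int(np.argmin(obj))
    return float(obj[best]), W[best]


def random_hinge_toy(rng):
    """A random 4-point, 2-feature binary problem with both labels present."""
    X = rng.uniform(-2.0, 2.0, size=(4, 2))
    y = np.array([1.0, 1.0, -1.0, -1.0])
    return X, y


def check_solver_against_grid(fit_fn, rng, alpha=0.1, tol=1e-3, n_toys=5):
    """Assert the solver's objective never exceeds the grid optimum + tol
    and that its objective trace is non-increasing."""
    for _ in range(n_toys):
        X, y = random_hinge_toy(rng)
        w, trace = fit_fn(X, y, alpha)
        achieved = hinge_objective(w, X, y, alpha)
        grid_opt, _ = grid_search_hinge_optimum(X, y, alpha)
        assert achieved <= grid_opt + tol, (achieved, grid_opt)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(1.0, np.abs(trace[:-1])))
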