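"""Shared plain-function helpers (importable, unlike conftest fixtures)."""

import numpy as np

from perioscope import SpatialSeries


def make_series(values, length_bp=None, step_bp=1_000) -> SpatialSeries:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if length_bp is None:
        length_bp = n * step_bp
    return SpatialSeries(
        genome_id="test",
        length_bp=length_bp,
        window_bp=step_bp,
        step_bp=step_bp,
        centers=np.arange(n, dtype=float) * step_bp,
        values=values,
    )


def dft_periodogram_oracle(x):
    """Direct O(n^2) DFT sum: I_k = (1/n)|sum_t (x_t - xbar) e^{-2pi i k t/n}|^2."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    t = np.arange(n)
    out = []
    for k in range(1, n // 2 + 1):
        w = np.exp(-2j * np.pi * k * t / n)
        s = np.sum(xc * w)
        out.append(abs(s) ** 2 / n)
    return np.array(out)


def grid_search_sine_oracle(x, y, T, rounds=12, n_grid=41):
    """Coarse-to-fine exhaustive grid minimization of
    sum (y - a sin(2pi (x+b)/T) - c)^2 over (a, b, c).

    For each candidate b the SSE over the (a, c) grid is evaluated exactly
    via its sufficient statistics, which keeps the search brute-force in
    all three parameters yet tractable.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(y)
    yy = float(y @ y)
    ysum = float(y.sum())
    sd = max(float(y.std()), 1e-6)
    a_lo, a_hi = 0.0, 4.0 * sd
    b_lo, b_hi = 0.0, T
    c_lo, c_hi = float(y.mean()) - 4.0 * sd, float(y.mean()) + 4.0 * sd
    best = None
    for _ in range(rounds):
        a_grid = np.linspace(a_lo, a_hi, n_grid)
        b_grid = np.linspace(b_lo, b_hi, 2 * n_grid)
        c_grid = np.linspace(c_lo, c_hi, n_grid)
        for b in b_grid:
            s = np.sin(2 * np.pi * (x + b) / T)
            ss = float(s @ s)
            ys = float(y @ s)
            ssum = float(s.sum())
            A, C = np.meshgrid(a_grid, c_grid, indexing="ij")
            sse = (yy - 2 * A * ys - 2 * C * ysum + A * A * ss
                   + 2 * A * C * ssum + C * C * n)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            if best is None or sse[i, j] < best[0]:
                best = (float(sse[i, j]), float(a_grid[i]), float(b % T), float(c_grid[j]))
        _, a0, b0, c0 = best
        da = (a_hi - a_lo) / (n_grid - 1)
        db = (b_hi - b_lo) / (2 * n_grid - 1)
        dc = (c_hi - c_lo) / (n_grid - 1)
        a_lo, a_hi = max(0.0, a0 - 3 * da), a0 + 3 * da
        b_lo, b_hi = b0 - 3 * db, b0 + 3 * db
        c_lo, c_hi = c0 - 3 * dc, c0 + 3 * dc
        best = (best[0], a0, b0, c0)
    _, a0, b0, c0 = best
    return a0, b0 % T, c0


def fisher_g_null_draws(m, n_draws, rng):
    """Monte-Carlo null for Fisher's g: m i.i.d. exponential ordinates."""
    E = rng.exponential(1.0, size=(n_draws, m))
    return E.max(axis=1) / E.sum(axis=1)
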