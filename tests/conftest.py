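"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from retinad import synth
from retinad.types import ErgTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bright_params():
    """A representative young transgenic bright-flash parameter set."""
    return synth.ErgParams(
        a_amp=157.6,
        b_amp=217.5,
        pstr_amp=123.0,
        op_amps=(52.05, 69.4, 52.05),
        noise_sd=0.0,
    )


@pytest.fixture
def flat_trace():
    return ErgTrace(np.zeros(500), sampling_rate=1000.0, flash_time=50.0)


def make_trace(samples, fs=1000.0, flash=50.0):
    return ErgTrace(np.asarray(samples, float), sampling_rate=fs, flash_time=flash)


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_min_path(grad: np.ndarray):
    """Exhaustive enumeration of every monotone left-to-right path.

    A path visits one row per column, moving at most one row between
    columns; cost is the sum of edge weights 2 - (g_a + g_b) + 1e-5 as
    in the graph segmentation.  Returns (best_cost, best_path) with the
    first enumerated path winning ties (enumeration is in lexicographic
    row order, so ties resolve to the smallest rows).
    """
    g = np.asarray(grad, dtype=float)
    H, W = g.shape
    best_cost = np.inf
    best_path = None
    path = np.zeros(W, dtype=int)

    def recurse(col, cost):
        nonlocal best_cost, best_path
        if col == W:
            if cost < best_cost:
                best_cost = cost
                best_path = path.copy()
            return
        prev = path[col - 1]
        for r in range(max(0, prev - 1), min(H, prev + 2)):
            path[col] = r
            edge = 2.0 - (g[prev, col - 1] + g[r, col]) + 1e-5
            recurse(col + 1, cost + edge)

    for start in range(H):
        path[0] = start
        recurse(1, 0.0)
    return best_cost, best_path


def hand_anova(groups):
    """Textbook one-way ANOVA from sums of squares."""
    all_vals = np.concatenate([np.asarray(v, float) for v in groups])
    grand = all_vals.mean()
    ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups)
    ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups)
    df1 = len(groups) - 1
    df2 = all_vals.size - len(groups)
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    f = ms_between / ms_within
    from scipy.stats import f as fdist

    return f, float(fdist.sf(f, df1, df2))


def hand_ttest(x, y):
    """Classic equal-variance two-sample t-test from first principles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = (
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    from scipy.stats import t as tdist

    return t, 2.0 * float(tdist.sf(abs(t), nx + ny - 2))


def hand_tukey_p(groups, i, j):
    """Tukey HSD adjusted p for one pair via the studentized range."""
    from scipy.stats import studentized_range

    groups = [np.asarray(v, float) for v in groups]
    k = len(groups)
    df = sum(v.size for v in groups) - k
    ms_within = sum(((v - v.mean()) ** 2).sum() for v in groups) / df
    ni, nj = groups[i].size, groups[j].size
    se = np.sqrt(ms_within / 2.0 * (1.0 / ni + 1.0 / nj))
    q = abs(groups[i].mean() - groups[j].mean()) / se
    return float(studentized_range.sf(q, k, df))
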