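import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cropshift as cs
from cropshift.rf_core import FeatureTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Small synthetic world shared across modules
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_grid():
    return cs.make_grid(24, 48, land_fraction=0.6, seed=11)


@pytest.fixture(scope="session")
def small_climate(small_grid):
    return cs.generate_climate(small_grid, seed=12)


@pytest.fixture(scope="session")
def small_drivers(small_grid, small_climate):
    return cs.generate_drivers(small_grid, small_climate, n_regions=6,
                               n_soils=5, seed=13)


@pytest.fixture(scope="session")
def small_aez(small_climate):
    return cs.compute_aez(small_climate)


@pytest.fixture(scope="session")
def small_world(small_grid, small_climate, small_drivers, small_aez):
    """Grid + climate + drivers (with zones attached) + true cover."""
    drivers = small_drivers.with_aez(small_aez.zone_id)
    cover = cs.true_cover_function(drivers, small_aez.zone_id,
                                   noise_sd=0.02, seed=14)
    return {
        "grid": small_grid,
        "climate": small_climate,
        "drivers": drivers,
        "aez": small_aez,
        "cover": cover,
    }


# ---------------------------------------------------------------------------
# Tiny regression tables
# ---------------------------------------------------------------------------

def make_table(X, y, categorical=None, categories=None):
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    cat = np.zeros(p, dtype=bool) if categorical is None else np.asarray(categorical)
    cols = [f"x{j}" for j in range(p)]
    return FeatureTable(X, np.asarray(y, dtype=float), cols, cat,
                        categories or {})


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def noisy_table():
    """200 rows, 5 continuous features, y driven by x0 and x1."""
    rng = np.random.default_rng(42)
    X = rng.random((200, 5))
    y = np.clip(0.6 * X[:, 0] + 0.3 * (X[:, 1] > 0.5) + 0.02 * rng.standard_normal(200), 0, 1)
    return make_table(X, y)


# ---------------------------------------------------------------------------
# Independent oracles (brute force; deliberately simple scalar code)
# ---------------------------------------------------------------------------

def exhaustive_best_split(X, y, min_leaf, features=None):
    """Enumerate every (feature, rule): all midpoints for continuous
    columns, all level bipartitions for categorical ones (flagged by a set
    of column indices in ``features`` metadata — here all continuous unless
    X columns hold small ints and the caller says so).  Returns
    (sse, feature, kind, payload) with the fit_tree tie-break: lowest SSE,
    then lowest feature, then lowest threshold / smallest left mask."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    cats = features or {}
    best = None

    def sse_split(mask_left_rows):
        nl = mask_left_rows.sum()
        nr = n - nl
        if nl < min_leaf or nr < min_leaf:
            return None
        yl, yr = y[mask_left_rows], y[~mask_left_rows]
        return float(np.sum((yl - yl.mean()) ** 2) + np.sum((yr - yr.mean()) ** 2))

    for j in range(p):
        xj = X[:, j]
        if j in cats:
            levels = sorted(set(int(v) for v in xj))
            if len(levels) < 2:
                continue
            k = len(levels)
            for sub in range(1, 2 ** k - 1):
                chosen = [levels[i] for i in range(k) if (sub >> i) & 1]
                if levels[0] not in chosen:
                    continue
                rows = np.isin(xj.astype(int), chosen)
                sse = sse_split(rows)
                if sse is None:
                    continue
                mask = sum(1 << c for c in chosen)
                cand = (sse, j, "cat", mask)
                if best is None or cand[0] < best[0] or (
                        cand[0] == best[0] and (cand[1], cand[3]) < (best[1], best[3])):
                    best = cand
        else:
            xs = np.unique(xj)
            for a, b in zip(xs[:-1], xs[1:]):
                thr = (a + b) / 2.0
                rows = xj <= thr
                sse = sse_split(rows)
                if sse is None:
                    continue
                cand = (sse, j, "num", thr)
                if best is None or cand[0] < best[0] or (
                        cand[0] == best[0] and (cand[1], cand[3]) < (best[1], best[3])):
                    best = cand
    return best


def thermal_zone_oracle(gdd, tmin, th):
    """Straight-line reimplementation of the zonation rules."""
    if gdd < th.gdd_none_max:
        return 0
    if tmin >= th.tmin_tropical:
        return 1
    if gdd < th.gdd_boreal_max:
        return 3
    return 2


def moisture_oracle(temp, precip, th):
    """Scalar month-by-month water-balance recount."""
    days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    heat = sum((max(0.0, t) / 5.0) ** 1.514 for t in temp)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    g = 0
    for t, p, d in zip(temp, precip, days):
        pet = 16.0 * (10.0 * max(0.0, t) / heat) ** a * d / 30.0 if (t > 0 and heat > 0) else 0.0
        if t > th.base_temp and p >= th.pet_fraction * pet:
            g += 1
    return int(g * th.n_moisture // 13)


def agreement_oracle(votes):
    """Signed majority count for one cell's direction votes."""
    n_pos = sum(1 for v in votes if v == 1)
    n_neg = sum(1 for v in votes if v == -1)
    if n_pos > n_neg:
        return n_pos
    if n_neg > n_pos:
        return -n_neg
    return 0


@pytest.fixture(scope="session")
def oracles():
    return {
        "best_split": exhaustive_best_split,
        "thermal": thermal_zone_oracle,
        "moisture": moisture_oracle,
        "agreement": agreement_oracle,
    }
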