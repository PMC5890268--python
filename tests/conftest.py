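from datetime import datetime

import numpy as np
import pytest

from catenaflux.fluxes import ChamberGeometry, ChamberTrace
from catenaflux.synthetic import CatenaConfig


@pytest.fixture(scope="session")
def catena() -> CatenaConfig:
    return CatenaConfig(seed=0)


@pytest.fixture
def geometry() -> ChamberGeometry:
    return ChamberGeometry(volume_m3=0.02951, area_m2=0.1964)


def make_trace(t, co2, ch4=None, geometry=None, temp_c=25.0, rh_pct=90.0,
               press_kpa=101.325, ambient=None, zone="slope",
               chamber_id="S1") -> ChamberTrace:
    """Hand-built chamber trace for unit tests."""
    t = np.asarray(t, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    ch4 = np.asarray(ch4, dtype=float) if ch4 is not None \
        else np.full_like(t, 1900.0)
    return ChamberTrace(
        chamber_id=chamber_id, zone=zone,
        closure_start=datetime(2015, 3, 1, 12, 0),
        t_s=t, co2_ppm=co2, ch4_ppb=ch4,
        temp_c=temp_c, rh_pct=rh_pct, press_kpa=press_kpa,
        geometry=geometry or ChamberGeometry(volume_m3=0.02951,
                                             area_m2=0.1964),
        ambient=ambient or {"co2": float(co2[0]), "ch4": float(ch4[0])})


def brute_force_breakpoints(y, n_breaks, min_len):
    """Exhaustive enumeration oracle for the optimal-partition problem.

    Scans every admissible breakpoint tuple and returns the one minimising
    total per-segment OLS RSS (ties broken lexicographically).  Independent
    of the dynamic-programming implementation: segment RSS is computed by
    direct least squares on the raw data.
    """
    from itertools import combinations

    y = np.asarray(y, dtype=float)
    n = y.size

    def seg_rss_direct(i, j):
        x = np.arange(i, j, dtype=float)
        a = np.column_stack([np.ones(j - i), x])
        resid = y[i:j] - a @ np.linalg.lstsq(a, y[i:j], rcond=None)[0]
        return float(resid @ resid)

    if n_breaks == 0:
        return [], seg_rss_direct(0, n)
    # tabulate admissible segments once (still direct least squares)
    rss = {}
    for i in range(0, n - min_len + 1):
        for j in range(i + min_len, n + 1):
            rss[(i, j)] = seg_rss_direct(i, j)
    best, best_bps = np.inf, None
    for bps in combinations(range(min_len, n - min_len + 1), n_breaks):
        edges = [0, *bps, n]
        if any(edges[k + 1] - edges[k] < min_len for k in range(len(edges) - 1)):
            continue
        total = sum(rss[(edges[k], edges[k + 1])]
                    for k in range(len(edges) - 1))
        if total < best - 1e-12:
            best, best_bps = total, list(bps)
    return best_bps, best
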