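import numpy as np
import pytest

from membraneloc import fixtures, synthetic


@pytest.fixture(scope="session")
def pure_dmpc_scan():
    """Noise-free pure-lipid thermogram: pre-transition + main transition."""
    return synthetic.simulate_thermogram(fixtures.dsc_thermogram_spec(0.0))


@pytest.fixture(scope="session")
def high_drug_scan():
    """Noise-free 2:1 lipid:drug thermogram (broadened, depressed onset)."""
    return synthetic.simulate_thermogram(fixtures.dsc_thermogram_spec(0.5))


@pytest.fixture(scope="session")
def small_bilayer_frames():
    """A reduced bilayer (fewer waters) with enough frames for statistics."""
    spec = synthetic.BilayerCompositionSpec(
        lipids_per_leaflet=16, drugs_per_leaflet=4, waters_per_leaflet=50,
        n_frames=200, seed=7,
    )
    return spec, synthetic.simulate_bilayer_frames(spec)


def dense_scan_crossings(T, Cp, fraction=0.05):
    """Brute-force 5%-rule oracle: outermost threshold crossings on a dense
    linear interpolation of the trace (10^-3 °C resolution)."""
    grid = np.arange(T[0], T[-1], 1e-3)
    vals = np.interp(grid, T, Cp)
    thr = fraction * vals.max()
    i_pk = int(np.argmax(vals))
    below_lo = np.flatnonzero(vals[:i_pk] < thr)
    below_hi = np.flatnonzero(vals[i_pk:] < thr)
    lo = grid[below_lo[-1]] if len(below_lo) else grid[0]
    hi = grid[i_pk + below_hi[0]] if len(below_hi) else grid[-1]
    return lo, hi
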