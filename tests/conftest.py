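import time

import numpy as np
import pytest

from fireflora import (SyntheticConfig, generate_scenario, recovery_metrics,
                       run_scenario)
from fireflora.fire_layer import FireCell, GridSpec


@pytest.fixture
def plain_grid():
    """Small projected grid without geographic referencing (2.5 km cells)."""
    def make(n_rows=10, n_cols=10, cell=2500.0):
        return GridSpec(origin_x=0.0, origin_y=0.0, cell_size_m=cell,
                        n_rows=n_rows, n_cols=n_cols)
    return make


@pytest.fixture
def make_cells():
    """Build a FireCell dict from (row, col, himawari_k) triples."""
    def make(triples):
        return {(r, c): FireCell(r, c, t_max_himawari=t)
                for r, c, t in triples}
    return make


@pytest.fixture(scope="session")
def small_scenario():
    """A compact synthetic study system for fast end-to-end checks."""
    cfg = SyntheticConfig(seed=11, extent=(149.0, -34.0, 151.2, -32.2),
                          n_species=25, n_fires=4,
                          fire_size_range_ha=(10_000.0, 150_000.0),
                          spurious_rate=5.0)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline at the default study conditions (200 x 200 grid,
    300 virtual species), timed; shared by the recovery checks."""
    cfg = SyntheticConfig(seed=1)
    t0 = time.monotonic()
    scenario = generate_scenario(cfg)
    results = run_scenario(scenario)
    elapsed = time.monotonic() - t0
    metrics = recovery_metrics(scenario, results)
    return {"scenario": scenario, "results": results, "metrics": metrics,
            "elapsed_s": elapsed}


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Brute-force connected components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if dr or dc]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                queue = [(r0, c0)]
                seen[r0, c0] = True
                comp = []
                while queue:
                    r, c = queue.pop()
                    comp.append((r, c))
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                comps.append(frozenset(comp))
    return set(comps)
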