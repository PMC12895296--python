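import numpy as np
import pytest

from swampflux.pipeline import RunConfig, run_pipeline
from swampflux.scene import FloodDynamics, generate_flood_truth_series, generate_terrain


@pytest.fixture(scope="session")
def terrain64():
    return generate_terrain(64, 64, pixel_size_m=25.0, n_channels=2, seed=7)


@pytest.fixture(scope="session")
def truth_series(terrain64):
    return generate_flood_truth_series(terrain64, FloodDynamics(seed=11))


@pytest.fixture(scope="session")
def default_years():
    return RunConfig().years


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """One default-configuration pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    report = run_pipeline(RunConfig(seed=1), outdir)
    return report, outdir


def bfs_channel_distance(drainage_mask: np.ndarray) -> np.ndarray:
    """Independent breadth-first 8-connected distance to the channel set."""
    from collections import deque

    dist = np.full(drainage_mask.shape, -1, dtype=int)
    queue = deque()
    for r, c in zip(*np.nonzero(drainage_mask)):
        dist[r, c] = 0
        queue.append((r, c))
    n_rows, n_cols = drainage_mask.shape
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and dist[rr, cc] < 0:
                    dist[rr, cc] = dist[r, c] + 1
                    queue.append((rr, cc))
    return dist
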