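"""Shared fixtures: one seeded phantom and the pipeline stages derived from
it, computed once per session (block matching dominates the suite's cost)."""

from __future__ import annotations

import numpy as np
import pytest

from wrdmd import (
    BlockMatchConfig,
    ReconstructionConfig,
    build_snapshot_matrix,
    compute_dmd,
    default_renography_phantom,
    mean_motion_magnitude,
    order_modes,
    reconstruct,
    run_wdmd,
)

PHANTOM_SEED = 7


@pytest.fixture(scope="session")
def phantom():
    return default_renography_phantom(seed=PHANTOM_SEED)


@pytest.fixture(scope="session")
def bm_config():
    return BlockMatchConfig()


@pytest.fixture(scope="session")
def raw_profile(phantom, bm_config):
    return mean_motion_magnitude(phantom.stack, bm_config, scheme="consecutive")


@pytest.fixture(scope="session")
def vs_first_profile(phantom, bm_config):
    return mean_motion_magnitude(phantom.stack, bm_config, scheme="vs_first")


@pytest.fixture(scope="session")
def wdmd_result(phantom):
    return run_wdmd(phantom.stack, W=3)


@pytest.fixture(scope="session")
def c1_decomposition(wdmd_result):
    decomp = compute_dmd(build_snapshot_matrix(wdmd_result.c1))
    return decomp, order_modes(decomp)


@pytest.fixture(scope="session")
def corrected(c1_decomposition):
    decomp, ordering = c1_decomposition
    return reconstruct(decomp, ordering, ReconstructionConfig(k=3))


@pytest.fixture(scope="session")
def corrected_profile(corrected, bm_config):
    return mean_motion_magnitude(corrected, bm_config, scheme="consecutive")


def brute_force_block_match(ref, target, config):
    """Independent exhaustive-search oracle: plain triple loop, same declared
    cost and tie rule (min cost, then min squared norm, then row-major)."""
    ref = np.asarray(ref, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    m, n = ref.shape
    bh, bw = config.block_height, config.block_width
    results = []
    r0 = 0
    while r0 + bh <= m:
        c0 = 0
        while c0 + bw <= n:
            candidates = []
            for dr in range(-config.max_disp_r, config.max_disp_r + 1):
                for dc in range(-config.max_disp_c, config.max_disp_c + 1):
                    r1, c1 = r0 + dr, c0 + dc
                    if r1 < 0 or c1 < 0 or r1 + bh > m or c1 + bw > n:
                        continue
                    a = ref[r0 : r0 + bh, c0 : c0 + bw]
                    b = target[r1 : r1 + bh, c1 : c1 + bw]
                    if config.cost == "mse":
                        cost = float(np.mean((a - b) ** 2))
                    else:
                        cost = float(np.mean(np.abs(a - b)))
                    candidates.append((cost, dr * dr + dc * dc, dr, dc))
            best = None
            for cand in candidates:  # first in row-major order wins exact ties
                if best is None or cand[:2] < best[:2]:
                    best = cand
            results.append((best[2], best[3]))
            c0 += bw - config.overlap_c
        r0 += bh - config.overlap_r
    return np.asarray(results, dtype=np.intp).reshape(-1, 2)


@pytest.fixture(scope="session")
def block_match_oracle():
    return brute_force_block_match
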