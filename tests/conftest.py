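"""Shared fixtures: small simulated datasets and rendered fields."""

from __future__ import annotations

import numpy as np
import pytest

from fiberglow import RenderConfig, SimulationConfig, render_images, simulate_fibers


@pytest.fixture(scope="session")
def noise_free_render() -> RenderConfig:
    return RenderConfig(shot_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_noise_free_run(noise_free_render):
    """60 fibers rendered without noise, with ground truth."""
    cfg = SimulationConfig(n_fibers=60, seed=9, render=noise_free_render)
    fibers, truth = simulate_fibers(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    fields = render_images(fibers, cfg.render, rng)
    return cfg, fibers, truth, fields


@pytest.fixture(scope="session")
def noisy_run():
    """120 fibers rendered with the default noise model."""
    cfg = SimulationConfig(n_fibers=120, seed=33)
    fibers, truth = simulate_fibers(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    fields = render_images(fibers, cfg.render, rng)
    return cfg, fibers, truth, fields


def match_trace_to_layout(trace, layouts):
    """Return the ground-truth layout whose path passes nearest the trace midpoint."""
    mid = trace.polyline[len(trace.polyline) // 2]
    best, bd = None, np.inf
    for lay in layouts:
        d = np.min(np.sum((lay.path - mid) ** 2, axis=1))
        if d < bd:
            bd, best = d, lay
    return best
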