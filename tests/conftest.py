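"""Shared fixtures: reference synthetic patterns and renders.

Session-scoped so the more expensive pattern/render pairs are built once.
"""

from __future__ import annotations

import numpy as np
import pytest

import nanopillar as npl
from nanopillar.synth import PatternSpec, RenderSpec


@pytest.fixture(scope="session")
def ordered_pattern() -> npl.TipSet:
    """Short-range-ordered pattern at 10 tips/µm² with 306-nm spacing, 10×10 µm."""
    spec = PatternSpec(
        density=10.0,
        exclusion_radius=150.0,
        spacing=306.0,
        jitter_sd=10.0,
        field_width=10_000.0,
        field_height=10_000.0,
        seed=1,
    )
    return npl.generate_pattern(spec)


@pytest.fixture(scope="session")
def ordered_render(ordered_pattern) -> npl.Micrograph:
    return npl.render_micrograph(ordered_pattern, RenderSpec(seed=1))


@pytest.fixture(scope="session")
def csr_pattern() -> npl.TipSet:
    """Complete spatial randomness: 2500 points on 10×10 µm."""
    spec = PatternSpec(
        density=25.0,
        exclusion_radius=0.0,
        spacing=None,
        jitter_sd=0.0,
        field_width=10_000.0,
        field_height=10_000.0,
        seed=2,
    )
    return npl.generate_pattern(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
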