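"""Shared fixtures: small in-memory phantom cohorts and grid helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ovaseg.phantom import PhantomSpec, generate_phantom

SMALL_GRID = dict(grid_shape=(64, 64, 16), spacing=(3.0, 3.0, 5.0))


def make_cohort(n: int, seed: int, **spec_overrides) -> dict[str, dict]:
    """In-memory cohort in the same layout load_cohort returns."""
    out: dict[str, dict] = {}
    for i in range(n):
        spec = PhantomSpec(
            **{**SMALL_GRID, **spec_overrides, "seed": (seed * 100003 + i * 1009) % (2**31 - 1)}
        )
        v, masks = generate_phantom(spec)
        v.subject_id = f"s{i:03d}"
        for m in masks.values():
            m.subject_id = v.subject_id
        out[v.subject_id] = {
            "volume": v,
            "masks": {name: {"truth": lm} for name, lm in masks.items()},
        }
    return out


@pytest.fixture(scope="session")
def small_cohort() -> dict[str, dict]:
    return make_cohort(4, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
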