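"""Shared fixtures: random small panels and genomes built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from nbselect.genome_io import VariantPanel


def make_panel(
    calls: np.ndarray,
    groups: list[str],
    positions: np.ndarray | None = None,
    chrom: str = "chr01",
) -> VariantPanel:
    """Panel from a calls matrix (samples x sites) and per-sample groups."""
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    if positions is None:
        positions = np.arange(s, dtype=np.int64)
    samples = [f"s{i:02d}" for i in range(n)]
    return VariantPanel(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=["A"] * s,
        alt=["T"] * s,
        calls=calls,
        samples=samples,
        groups=dict(zip(samples, groups)),
    )


def random_panel(
    rng: np.random.Generator,
    n: int,
    s: int,
    groups: list[str] | None = None,
    missing_rate: float = 0.0,
) -> VariantPanel:
    calls = rng.integers(0, 2, size=(n, s)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n, s)) < missing_rate] = -1
    if groups is None:
        groups = ["wild_weedy"] * n
    positions = np.sort(rng.choice(max(10 * s, s + 1), size=s, replace=False))
    return make_panel(calls, groups, positions)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
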