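"""Synthetic descriptor data with the statistical structure of QSPR sets.

Real descriptor matrices pair a few informative variables with blocks of
highly collinear descriptors and a long tail of near-noise columns.  The
generator reproduces that structure — not the chemistry — so every other
module can be exercised with a known ground truth:

* each block is built from one shared latent factor,
  x = sqrt(rho)*f_block + sqrt(1-rho)*u, giving pairwise correlation rho
  in expectation within the block;
* independent standard-normal noise columns follow the blocks;
* y = y_offset + sum_j beta_j x_j + eps with eps ~ N(0, sigma^2), the
  support and coefficients of which are returned for recovery tests.

All randomness derives from one seed through named substreams, so X is
bit-identical across runs that differ only in the noise level sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import DescriptorTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "make_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic descriptor table.

    ``blocks`` lists (size, rho) pairs of collinear descriptor blocks laid
    out first, followed by ``m_noise`` independent noise columns.
    ``support`` maps variable indices (into the full matrix) to true
    regression coefficients beta; ``noise_sd`` is the property-noise
    standard deviation sigma in y units.
    """

    n: int = 100
    blocks: tuple = ()
    m_noise: int = 0
    support: tuple = ()  # ((index, beta), ...)
    noise_sd: float = 1.0
    y_offset: float = 0.0
    seed: int = 0

    @property
    def m(self) -> int:
        return sum(size for size, _ in self.blocks) + self.m_noise

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for size, rho in self.blocks:
            if size < 1 or not 0.0 <= rho < 1.0:
                raise ValueError(f"invalid block ({size}, {rho}); need 0 <= rho < 1")
        if self.m_noise < 0:
            raise ValueError("m_noise must be >= 0")
        if self.m == 0:
            raise ValueError("spec describes zero variables")
        for j, _ in self.support:
            if not 0 <= j < self.m:
                raise ValueError(f"support index {j} out of range 0..{self.m - 1}")


@dataclass
class GroundTruth:
    support: np.ndarray  # indices of informative variables
    beta: np.ndarray  # aligned coefficients
    noise_sd: float
    y_offset: float


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Generate a descriptor table and its ground truth from a spec."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_x, rng_noise_cols, rng_eps = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    cols = []
    for size, rho in spec.blocks:
        f = rng_x.standard_normal((spec.n, 1))
        u = rng_x.standard_normal((spec.n, size))
        cols.append(np.sqrt(rho) * f + np.sqrt(1.0 - rho) * u)
    if spec.m_noise:
        cols.append(rng_noise_cols.standard_normal((spec.n, spec.m_noise)))
    X = np.hstack(cols)

    support = np.array([j for j, _ in spec.support], dtype=int)
    beta = np.array([b for _, b in spec.support], dtype=float)
    y = spec.y_offset + (X[:, support] @ beta if support.size else np.zeros(spec.n))
    if spec.noise_sd > 0:
        y = y + rng_eps.normal(0.0, spec.noise_sd, spec.n)

    table = DescriptorTable(
        X=X,
        variable_names=[f"x{j + 1}" for j in range(spec.m)],
        object_names=[f"obj{i + 1}" for i in range(spec.n)],
        y=y,
    )
    return table, GroundTruth(support, beta, spec.noise_sd, spec.y_offset)


_FIXTURES = {
    # hand-checkable: 12 objects, 6 variables, 2 informative, noiseless-ish
    "tiny": SyntheticSpec(
        n=12,
        blocks=((2, 0.5),),
        m_noise=4,
        support=((0, 2.0), (2, -1.0)),
        noise_sd=0.1,
        seed=42,
    ),
    # contains an exactly duplicated column pair (rho -> 1 handled by copy below)
    "blocks": SyntheticSpec(
        n=60,
        blocks=((5, 0.999), (3, 0.7)),
        m_noise=10,
        support=((0, 1.5), (5, 1.0), (9, 0.8)),
        noise_sd=0.5,
        seed=7,
    ),
    # dimensions of a cleaned 3D-descriptor matrix for ~200 structures
    "paper_shaped": SyntheticSpec(
        n=209,
        blocks=tuple([(8, 0.95)] * 40),
        m_noise=2688 - 320,
        support=tuple((8 * b, 3.0) for b in range(10))
        + tuple((320 + 17 * t, 1.5) for t in range(10)),
        noise_sd=5.0,
        y_offset=338.0,
        seed=2013,
    ),
}


def make_fixture(name: str) -> DescriptorTable:
    """Return a canned seeded table: 'tiny', 'blocks', or 'paper_shaped'."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    table, _ = generate(_FIXTURES[name])
    if name == "blocks":
        # guarantee an exact duplicate pair for correlation-filter tests
        table.X[:, 1] = table.X[:, 0]
    return table


def fixture_spec(name: str) -> SyntheticSpec:
    """The generator parameters behind a named fixture (for ground-truth tests)."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return _FIXTURES[name]
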