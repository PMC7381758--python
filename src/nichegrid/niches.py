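"""Combinatorial pools of rectangular climatic niches.

A niche on one axis is a closed tolerance interval [x, y] of amplitude
alpha = y - x.  For an axis spanning [rho_min, rho_max], amplitudes run

    alpha_i = alpha_1 + (i - 1) * mu,        i = 1..p,
    p       = floor((alpha_max - alpha_1) / mu + 1),
    alpha_max = rho_max - rho_min,

and for each amplitude the interval starts step by the overlap s:

    x_{i,j} = rho_min + (j - 1) * s,         j = 1..q_i,
    q_i     = floor((alpha_max + s - alpha_i) / s + 1),
    y_{i,j} = x_{i,j} + alpha_i.

The axis count is r = sum_i q_i and a two-axis pool is the full cross
product, R = r_t * r_p.  Interval ends may exceed rho_max by construction;
they are kept (the printed pool sizes require them).

All of the arithmetic above is carried out on exact rationals
(``fractions.Fraction``): the floor operations are step-sensitive at
mu = s = 0.1 and accumulated floating point changes the counts.  Every
niche is unique within a pool (competitive exclusion), and subsampling a
pool records the correction factor phi = 1/fraction used by the total
pseudo-species estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np

from .exceptions import ConfigurationError, DimensionError


@dataclass(frozen=True)
class NicheAxisSpec:
    """One climatic axis of the niche pool (bounds, amplitude and overlap steps)."""

    rho_min: float
    rho_max: float
    alpha_1: float
    mu: float
    s: float
    axis_id: str = "temperature"

    def __post_init__(self) -> None:
        if not self.rho_min < self.rho_max:
            raise ConfigurationError("axis requires rho_min < rho_max")
        if self.alpha_1 <= 0 or self.mu <= 0 or self.s <= 0:
            raise ConfigurationError("alpha_1, mu and s must all be > 0")
        if Fraction(str(self.alpha_1)) > self.alpha_max_exact:
            raise ConfigurationError("alpha_1 exceeds alpha_max = rho_max - rho_min")

    # exact-rational views of the parameters (strings avoid binary-float dust)
    @property
    def _exact(self) -> tuple[Fraction, Fraction, Fraction, Fraction, Fraction]:
        return tuple(
            Fraction(str(v))
            for v in (self.rho_min, self.rho_max, self.alpha_1, self.mu, self.s)
        )

    @property
    def alpha_max_exact(self) -> Fraction:
        lo, hi = Fraction(str(self.rho_min)), Fraction(str(self.rho_max))
        return hi - lo

    @property
    def alpha_max(self) -> float:
        return float(self.alpha_max_exact)


# Axis settings used throughout: thermal axis -1.8..44 degC with 0.1 steps;
# precipitation axis 0..3000 mm, fine (100/50) for mapping and coarse
# (400/200) for the range-splitting runs.
THERMAL_SPEC = NicheAxisSpec(-1.8, 44.0, 1.0, 0.1, 0.1, axis_id="temperature")
PRECIP_SPEC_FINE = NicheAxisSpec(0.0, 3000.0, 100.0, 100.0, 50.0, axis_id="precipitation")
PRECIP_SPEC_COARSE = NicheAxisSpec(0.0, 3000.0, 100.0, 400.0, 200.0, axis_id="precipitation")


def build_amplitudes(spec: NicheAxisSpec) -> np.ndarray:
    """Ordered niche amplitudes alpha_1 .. alpha_p (exact count, float values)."""
    lo, hi, a1, mu, s = spec._exact
    amax = hi - lo
    p = math.floor((amax - a1) / mu + 1)
    return np.array([float(a1 + k * mu) for k in range(p)])


@dataclass
class AxisNiches:
    """All (start, end, amplitude) intervals of one axis, amplitude-major order."""

    spec: NicheAxisSpec
    x: np.ndarray
    y: np.ndarray
    alpha: np.ndarray

    @property
    def r(self) -> int:
        return self.x.size


def build_axis_niches(spec: NicheAxisSpec) -> AxisNiches:
    """Enumerate every interval of one axis; order is (amplitude asc, start asc)."""
    lo, hi, a1, mu, s = spec._exact
    amax = hi - lo
    p = math.floor((amax - a1) / mu + 1)
    xs: list[float] = []
    ys: list[float] = []
    alphas: list[float] = []
    for i in range(p):
        alpha_i = a1 + i * mu
        q_i = math.floor((amax + s - alpha_i) / s + 1)
        for j in range(q_i):
            x = lo + j * s
            xs.append(float(x))
            ys.append(float(x + alpha_i))
            alphas.append(float(alpha_i))
    return AxisNiches(
        spec=spec, x=np.asarray(xs), y=np.asarray(ys), alpha=np.asarray(alphas)
    )


def axis_count(spec: NicheAxisSpec) -> int:
    """Closed-form axis count r = sum_i q_i without materializing intervals."""
    lo, hi, a1, mu, s = spec._exact
    amax = hi - lo
    p = math.floor((amax - a1) / mu + 1)
    return sum(
        math.floor((amax + s - (a1 + i * mu)) / s + 1) for i in range(p)
    )


@dataclass(frozen=True)
class Niche:
    """One rectangular niche: a closed interval per axis."""

    niche_id: int
    intervals: tuple[tuple[float, float], ...]  # ((x, y), ...) one per axis
    axis_ids: tuple[str, ...]


def niche_contains(niche: Niche, values: Sequence[float]) -> bool:
    """True iff every axis value lies inside the closed interval of that axis."""
    if len(values) != len(niche.intervals):
        raise DimensionError(
            f"niche has {len(niche.intervals)} axes, got {len(values)} values"
        )
    return all(x <= v <= y for (x, y), v in zip(niche.intervals, values))


@dataclass
class NichePool:
    """A pool of niches over 1 or 2 axes, optionally a seeded subsample.

    ``member_index`` is None for the full pool; otherwise an (n, n_axes)
    array of per-axis interval indices identifying the sampled members.
    Member ``k`` of the full 2-axis pool has linear id ``i * r_p + j``
    (axis-0-major), giving a stable, reproducible enumeration order.
    """

    axes: tuple[AxisNiches, ...]
    member_index: np.ndarray | None = None
    sampled_fraction: float = 1.0
    seed: int | None = None
    phi: float = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2:
            raise ConfigurationError("a pool has 1 or 2 axes")
        self.phi = 1.0 / self.sampled_fraction

    # ----- sizes -----------------------------------------------------------
    @property
    def n_axes(self) -> int:
        return len(self.axes)

    @property
    def r_per_axis(self) -> tuple[int, ...]:
        return tuple(a.r for a in self.axes)

    @property
    def R_full(self) -> int:
        """Total size of the underlying (unsampled) pool."""
        return int(np.prod([a.r for a in self.axes], dtype=object))

    def __len__(self) -> int:
        if self.member_index is None:
            return self.R_full
        return self.member_index.shape[0]

    @property
    def is_full(self) -> bool:
        return self.member_index is None

    # ----- member access ---------------------------------------------------
    def _decode(self, linear_ids: np.ndarray) -> np.ndarray:
        """Linear ids -> (n, n_axes) per-axis indices, axis-0-major."""
        if self.n_axes == 1:
            return linear_ids[:, None]
        r_p = self.axes[1].r
        return np.column_stack([linear_ids // r_p, linear_ids % r_p])

    def member_axis_indices(self) -> np.ndarray:
        """(n, n_axes) per-axis interval indices for every member."""
        if self.member_index is not None:
            return self.member_index
        if self.n_axes == 1:
            return np.arange(self.axes[0].r)[:, None]
        return self._decode(np.arange(self.R_full))

    def get_niche(self, k: int) -> Niche:
        idx = self.member_axis_indices()[k]
        intervals = tuple(
            (float(a.x[i]), float(a.y[i])) for a, i in zip(self.axes, idx)
        )
        return Niche(
            niche_id=int(k),
            intervals=intervals,
            axis_ids=tuple(a.spec.axis_id for a in self.axes),
        )

    def iter_member_chunks(
        self, chunk_size: int = 512
    ) -> Iterator[tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]]:
        """Yield (member ids, per-axis (x, y) arrays) in chunks."""
        n = len(self)
        idx_all = self.member_axis_indices()
        for start in range(0, n, chunk_size):
            sel = idx_all[start : start + chunk_size]
            ids = np.arange(start, start + sel.shape[0])
            per_axis = [
                (a.x[sel[:, d]], a.y[sel[:, d]]) for d, a in enumerate(self.axes)
            ]
            yield ids, per_axis

    # ----- export ----------------------------------------------------------
    def to_dataframe(self):
        import pandas as pd

        idx = self.member_axis_indices()
        frames = []
        for d, a in enumerate(self.axes):
            frames.append(
                pd.DataFrame(
                    {
                        "niche_id": np.arange(len(self)),
                        "axis": a.spec.axis_id,
                        "x": a.x[idx[:, d]],
                        "y": a.y[idx[:, d]],
                        "alpha": a.alpha[idx[:, d]],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def build_pool(spec: NicheAxisSpec) -> NichePool:
    """Full single-axis pool for one spec."""
    return NichePool(axes=(build_axis_niches(spec),))


def build_product_pool(spec_t: NicheAxisSpec, spec_p: NicheAxisSpec) -> NichePool:
    """Full two-axis pool: every thermal interval crossed with every
    precipitation interval (R = r_t * r_p, enumerated lazily)."""
    return NichePool(axes=(build_axis_niches(spec_t), build_axis_niches(spec_p)))


def _sample_without_replacement(R: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct integers from range(R), sorted; memory stays O(k) for k << R."""
    if k > R:
        raise ConfigurationError("cannot sample more members than the pool holds")
    if R <= 4 * k or R < 1 << 20:
        return np.sort(rng.permutation(R)[:k])
    chosen = np.unique(rng.integers(0, R, size=int(k * 1.1) + 16))
    while chosen.size < k:
        extra = rng.integers(0, R, size=k)
        chosen = np.unique(np.concatenate([chosen, extra]))
    return np.sort(rng.permutation(chosen)[:k])


def sample_pool(pool: NichePool, fraction: float, seed: int | None = None) -> NichePool:
    """Uniform seeded subsample without replacement; phi = 1/fraction.

    Sample size is round(R * fraction) with half-up rounding.  fraction = 1
    returns the pool itself (phi = 1).
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("sampling fraction must be in (0, 1]")
    if fraction == 1.0:
        return pool
    if not pool.is_full:
        raise ConfigurationError("pool is already a subsample; sample the full pool")
    R = pool.R_full
    k = math.floor(R * fraction + 0.5)
    rng = np.random.default_rng(seed)
    linear = _sample_without_replacement(R, k, rng)
    return NichePool(
        axes=pool.axes,
        member_index=pool._decode(linear),
        sampled_fraction=fraction,
        seed=seed,
    )


def containment_counts(pool: NichePool, values: Sequence[float]) -> int:
    """Number of pool members whose niche contains the given axis values.

    For a full 2-axis pool this is the product of the per-axis counts; for
    subsamples the members are tested directly.
    """
    if len(values) != pool.n_axes:
        raise DimensionError("one value per axis is required")
    if pool.is_full:
        total = 1
        for a, v in zip(pool.axes, values):
            total *= int(np.count_nonzero((a.x <= v) & (v <= a.y)))
        return total
    idx = pool.member_index
    ok = np.ones(idx.shape[0], dtype=bool)
    for d, (a, v) in enumerate(zip(pool.axes, values)):
        ok &= (a.x[idx[:, d]] <= v) & (v <= a.y[idx[:, d]])
    return int(np.count_nonzero(ok))
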