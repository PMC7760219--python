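"""Correlated genetic response of a teat trait under MY/SCS selection indices.

An economic index places relative emphasis ``e`` (percent) on milk yield and
the complementary negative emphasis on somatic cell score, giving the weight
vector ``w = (0, e/100, -(1 - e/100))`` on the (teat, MY, SCS) sire
covariance scale.  The expected correlated response of the teat trait per
unit of selection intensity is

    r = w' g1 / sqrt(w' G w)

where ``G`` is the 3x3 sire (co)variance matrix and ``g1`` its first column,
expressed in sire genetic standard deviations of the teat trait.  The
break-even emphasis — the smallest emphasis on MY at which the teat-score
response turns positive (i.e. the trait starts to deteriorate) — depends
only on the sign of the numerator, so it is invariant both to the chosen
normalization and to the (unreported) MY-SCS genetic covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndexSpec",
    "assemble_G",
    "response",
    "emphasis_sweep",
    "breakeven_emphasis",
]


@dataclass(frozen=True)
class IndexSpec:
    """Index weights for one emphasis point.

    `emphasis` is the integer percent placed on MY; SCS receives the
    complementary negative emphasis and the teat trait weight is zero.
    """

    emphasis: int

    def __post_init__(self):
        if not 0 <= self.emphasis <= 100:
            raise ValueError("emphasis must lie in 0..100")

    @property
    def w(self) -> np.ndarray:
        e = self.emphasis / 100.0
        return np.array([0.0, e, -(1.0 - e)])


def assemble_G(var_teat, var_my, var_scs, r_teat_my, r_teat_scs, r_my_scs,
               check: bool = True):
    """Sire (co)variance matrix for (teat, MY, SCS) from variances and
    genetic correlations; ``cov_ij = r_ij * sd_i * sd_j``.

    Raises if any correlation exceeds 1 in magnitude or (with ``check``,
    the default) the resulting matrix is not positive definite, naming the
    violated leading minor.  ``check=False`` permits non-PD combinations for
    quantities — such as the break-even emphasis — that depend only on
    individual covariances.
    """
    for name, r in (("teat-MY", r_teat_my), ("teat-SCS", r_teat_scs), ("MY-SCS", r_my_scs)):
        if abs(r) > 1:
            raise ValueError(f"genetic correlation {name} = {r} exceeds 1 in magnitude")
    sd = np.sqrt(np.array([var_teat, var_my, var_scs], dtype=float))
    R = np.array(
        [
            [1.0, r_teat_my, r_teat_scs],
            [r_teat_my, 1.0, r_my_scs],
            [r_teat_scs, r_my_scs, 1.0],
        ]
    )
    G = R * np.outer(sd, sd)
    if check:
        for k in range(1, 4):
            if np.linalg.det(G[:k, :k]) <= 0:
                raise ValueError(
                    f"assembled G is not positive definite: leading {k}x{k} minor non-positive"
                )
    return G


def response(
    spec: IndexSpec | np.ndarray,
    G: np.ndarray,
    normalization: str = "sd_units",
    genetic_sd: str = "sire",
) -> float:
    """Expected correlated response of the teat trait under index weights.

    normalization "sd_units" (default): ``w'g1 / sqrt(w'Gw)`` divided by the
    teat sire genetic SD; "wGw": ``w'g1 / (w'Gw)`` (the typographically
    alternative reading of the response formula), same SD scaling.
    `genetic_sd` "sire" uses sqrt(G[0,0]); "additive" uses twice that.
    """
    w = spec.w if isinstance(spec, IndexSpec) else np.asarray(spec, dtype=float)
    g1 = G[:, 0]
    q = float(w @ G @ w)
    if q <= 0:
        raise ValueError("index variance w'Gw must be positive")
    num = float(w @ g1)
    if normalization == "sd_units":
        r = num / np.sqrt(q)
    elif normalization == "wGw":
        r = num / q
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    sd = np.sqrt(G[0, 0])
    if genetic_sd == "additive":
        sd = 2.0 * sd
    elif genetic_sd != "sire":
        raise ValueError(f"unknown genetic_sd convention {genetic_sd!r}")
    return r / sd


def emphasis_sweep(G: np.ndarray, grid=None, **kwargs) -> pd.DataFrame:
    """Response curve over the emphasis grid (default 0..100 by 1).

    Returns a DataFrame with columns ``emphasis`` and ``response``; the
    break-even emphasis is the smallest grid point with positive response.
    """
    if grid is None:
        grid = np.arange(101)
    rows = [
        {"emphasis": int(e), "response": response(IndexSpec(int(e)), G, **kwargs)}
        for e in grid
    ]
    return pd.DataFrame(rows)


def breakeven_emphasis(G: np.ndarray, grid_step: int = 1):
    """Break-even MY emphasis: smallest percent at which the response is > 0.

    Closed form: the numerator ``(e/100) cov(t,MY) - (1 - e/100) cov(t,SCS)``
    changes sign at ``e* = 100 rho / (1 + rho)`` with
    ``rho = cov(t,SCS) / cov(t,MY)``; the grid value is the smallest integer
    strictly above ``e*``.  Returns ``(e_grid, e_star)``.
    """
    c_my, c_scs = G[0, 1], G[0, 2]
    if c_my <= 0:
        raise ValueError("break-even emphasis requires a positive teat-MY covariance")
    rho = c_scs / c_my
    e_star = 100.0 * rho / (1.0 + rho)
    e_grid = int(np.floor(e_star / grid_step)) * grid_step + grid_step
    if e_star < 0:
        e_grid = 0
    return e_grid, e_star
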