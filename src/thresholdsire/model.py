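"""Tri-variate threshold-linear sire model fitted by Gibbs sampling.

The model analyses one teat-score trait (4-class ordinal TS, or a binary
collapse TS_a / TS_b) jointly with daily milk yield (MY) and somatic cell
score (SCS).  On the liability/observed scale,

    y(lambda) = X b + Zh h + Zp p + Zs s + e

with fixed effects b (parity-by-stage class for all traits; hygiene and udder
quarter for the teat trait only), herd effects h ~ N(0, I x H), cow
permanent-environment effects p ~ N(0, I x P), sire effects
s ~ N(0, A x S) with A the numerator relationship matrix, and residuals
e ~ N(0, I x R).  Teat scores and production records are never observed on
the same row, so the teat/production residual covariances are structurally
zero and R decomposes into the liability residual variance and a free 2x2
MY/SCS block.

Identifiability of the latent scale is handled by scheme:

* binary traits: single threshold pinned at 0, liability residual variance
  fixed at 1;
* 4-class trait: first two thresholds pinned at 0 and 1, third threshold and
  the liability residual variance estimated.

Estimation is Gibbs sampling with data augmentation: latent liabilities are
drawn from truncated normals, missing SCS values are imputed from their
conditional normal, location effects are drawn blocked per level (fixed
effects jointly), and covariance matrices from conditional inverse-Wishart
distributions with the structural zeros of R re-imposed exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import ndtr, ndtri

from .data_prep import (
    N_PARITY_CLASSES,
    N_STAGE_BINS,
    QUARTERS,
    StackedData,
    collapse_ts,
)
from .pedigree import Pedigree

__all__ = [
    "CovarianceSet",
    "ThresholdSireModel",
    "sample_truncated_normal",
    "chain_plan",
]

logger = logging.getLogger(__name__)

TRAITS = ("teat", "my", "scs")
N_PS = N_PARITY_CLASSES * N_STAGE_BINS


def _bincount2(idx: np.ndarray, values: np.ndarray, nlev: int) -> np.ndarray:
    """Per-level column sums of a 2-column array (bincount beats ufunc.at)."""
    return np.column_stack(
        [
            np.bincount(idx, weights=values[:, 0], minlength=nlev),
            np.bincount(idx, weights=values[:, 1], minlength=nlev),
        ]
    )


def chain_plan(n_iter: int, burn_in: int, thin: int) -> int:
    """Number of stored draws for a chain configuration.

    Draws are stored at iterations ``burn_in + thin, burn_in + 2*thin, ...``
    up to ``n_iter``; the default study configuration (300,000 iterations,
    50,000 burn-in, thinning 50) stores 5,000 draws.
    """
    if thin < 1 or burn_in < 0 or n_iter < 0:
        raise ValueError("invalid chain configuration")
    return max(0, (n_iter - burn_in)) // thin


def sample_truncated_normal(mean, sd, lo, hi, rng: np.random.Generator):
    """Vectorized draws from N(mean, sd^2) truncated to [lo, hi).

    Inverse-CDF method; `lo`/`hi` may be -inf/+inf.  Raises if any interval
    is empty (thresholds out of order).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), mean.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), mean.shape)
    if np.any(lo >= hi):
        raise ValueError("empty truncation interval: thresholds out of order")
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + rng.uniform(size=mean.shape) * (b - a)
    u = np.clip(u, 1e-14, 1.0 - 1e-14)
    x = mean + sd * ndtri(u)
    # numerical safety at extreme tails: keep the draw inside its interval
    return np.clip(x, np.nextafter(lo, hi), np.nextafter(hi, lo))


@dataclass
class CovarianceSet:
    """The four (co)variance structures of the model.

    H, P, S are full symmetric positive-definite 3x3 matrices (trait order
    teat, MY, SCS).  The residual R is represented by its free parameters:
    the liability residual variance ``r11`` and the 2x2 MY/SCS block
    ``Rprod``; the teat/production covariances are structural zeros.
    """

    H: np.ndarray
    P: np.ndarray
    S: np.ndarray
    r11: float
    Rprod: np.ndarray

    def full_R(self) -> np.ndarray:
        R = np.zeros((3, 3))
        R[0, 0] = self.r11
        R[1:, 1:] = self.Rprod
        return R

    def copy(self) -> "CovarianceSet":
        return CovarianceSet(
            self.H.copy(), self.P.copy(), self.S.copy(), float(self.r11),
            self.Rprod.copy(),
        )

    def validate(self) -> None:
        for name, M in (("H", self.H), ("P", self.P), ("S", self.S),
                        ("Rprod", self.Rprod)):
            if np.min(np.linalg.eigvalsh(M)) <= 0:
                raise ValueError(f"{name} is not positive definite")
        if self.r11 <= 0:
            raise ValueError("liability residual variance must be positive")

    @classmethod
    def default_start(cls) -> "CovarianceSet":
        return cls(
            H=np.eye(3) * 0.5,
            P=np.eye(3) * 0.5,
            S=np.eye(3) * 0.1,
            r11=1.0,
            Rprod=np.eye(2),
        )


def _sample_invwishart(df, scale, rng):
    """Draw from IW(df, scale) by Bartlett decomposition of the Wishart of
    the inverse; equivalent in distribution to scipy.stats.invwishart but
    without per-call setup overhead (this sits in the sampler's hot loop)."""
    scale = np.atleast_2d(np.asarray(scale, dtype=float))
    p = scale.shape[0]
    # W ~ Wishart(df, scale^-1)  =>  W^-1 ~ IW(df, scale)
    L_inv = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    diag = np.sqrt(rng.chisquare(df - np.arange(p)))
    A[np.diag_indices(p)] = diag
    if p > 1:
        A[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    F = L_inv @ A  # W = F F'
    Finv = sla.solve_triangular(
        F, np.eye(p), lower=True, check_finite=False
    )
    out = Finv.T @ Finv
    return out if p > 1 else float(out[0, 0])


class ThresholdSireModel:
    """Threshold-linear sire model built from a stacked dataset and a pedigree.

    Parameters
    ----------
    data
        :class:`~thresholdsire.data_prep.StackedData` with teat and/or
        production rows.
    pedigree
        Pedigree containing (at least) the sires appearing in `data`.
    trait
        "TS" (4-class ordinal), "TSa" or "TSb" (binary collapses).
    scheme
        "auto" picks the standard identifiability scheme for the trait (see
        module docstring); "fixed_residual" forces the liability residual to
        1, "estimated_residual" estimates it with thresholds pinned.
    sires_only
        If True, relationships are computed on the pedigree restricted to
        the observed sires and their ancestors; otherwise (default) A is
        built over the full pedigree and the sire block extracted.
    """

    def __init__(
        self,
        data: StackedData,
        pedigree: Pedigree,
        trait: str = "TS",
        scheme: str = "auto",
        sires_only: bool = False,
    ):
        if trait not in ("TS", "TSa", "TSb"):
            raise ValueError(f"unknown trait {trait!r}")
        self.trait = trait
        if scheme == "auto":
            scheme = "estimated_residual" if trait == "TS" else "fixed_residual"
        if scheme not in ("fixed_residual", "estimated_residual"):
            raise ValueError(f"unknown identifiability scheme {scheme!r}")
        self.scheme = scheme
        self.data = data
        self.pedigree = pedigree

        df = data.df
        teat = df[df["block"] == "teat"]
        prod = df[df["block"] == "prod"]
        self.n_teat = len(teat)
        self.n_prod = len(prod)
        self.n_herd = len(data.herd_levels)
        self.n_cow = len(data.cow_levels)
        self.sire_levels = list(data.sire_levels)
        self.n_sire = len(self.sire_levels)

        # ---- teat block ----------------------------------------------------
        score = teat["score"].to_numpy(dtype=np.int64) if self.n_teat else np.empty(0, np.int64)
        if trait == "TS":
            self.cat = score - 1
            self.n_cat = 4
        else:
            self.cat = collapse_ts(score, "a" if trait == "TSa" else "b") if self.n_teat else score
            self.cat = np.asarray(self.cat, dtype=np.int64)
            self.n_cat = 2
        if self.n_teat:
            present = np.bincount(self.cat, minlength=self.n_cat)
            if np.any(present == 0):
                raise ValueError(
                    "empty ordinal category in the data; collapse classes "
                    f"(counts: {present.tolist()})"
                )
        self.herd_t = teat["herd_i"].to_numpy(np.int64)
        self.cow_t = teat["cow_i"].to_numpy(np.int64)
        sire_map = {sid: i for i, sid in enumerate(self.sire_levels)}
        self.sire_t = np.array([sire_map[s] for s in teat["sire"]], dtype=np.int64)
        ps_t = teat["ps"].to_numpy(np.int64)
        hyg_t = teat["hyg"].to_numpy(np.int64)
        qtr_t = teat["qtr"].to_numpy(np.int64)

        # corner-constrained fixed design for the liability: one intercept per
        # observed parity-stage class, hygiene and quarter offsets with the
        # first observed level as reference
        self.ps_levels_t = np.unique(ps_t) if self.n_teat else np.empty(0, np.int64)
        self.hyg_levels = np.unique(hyg_t) if self.n_teat else np.empty(0, np.int64)
        self.qtr_levels = np.unique(qtr_t) if self.n_teat else np.empty(0, np.int64)
        ps_code = {c: i for i, c in enumerate(self.ps_levels_t)}
        nps = len(self.ps_levels_t)
        nhyg = max(0, len(self.hyg_levels) - 1)
        col_names = [f"ps{c + 1}" for c in self.ps_levels_t]
        col_names += [f"hyg{h + 1}" for h in self.hyg_levels[1:]]
        col_names += [f"qtr_{QUARTERS[q]}" for q in self.qtr_levels[1:]]
        self.b0_names = col_names
        self.k0 = len(col_names)
        self.col_ps = np.array([ps_code[c] for c in ps_t], dtype=np.int64)
        hyg_code = {h: nps + i - 1 for i, h in enumerate(self.hyg_levels)}
        qtr_code = {q: nps + nhyg + i - 1 for i, q in enumerate(self.qtr_levels)}
        self.col_hyg = np.array(
            [hyg_code[h] if h != self.hyg_levels[0] else -1 for h in hyg_t],
            dtype=np.int64,
        ) if self.n_teat else np.empty(0, np.int64)
        self.col_qtr = np.array(
            [qtr_code[q] if q != self.qtr_levels[0] else -1 for q in qtr_t],
            dtype=np.int64,
        ) if self.n_teat else np.empty(0, np.int64)
        self._build_X0_crossprod()

        # observed-frequency weights for least-squares means
        if self.n_teat:
            self.ps_weights_t = np.bincount(self.col_ps, minlength=nps) / self.n_teat
            self.hyg_weights = np.bincount(
                np.searchsorted(self.hyg_levels, hyg_t), minlength=len(self.hyg_levels)
            ) / self.n_teat
            self.qtr_weights = np.bincount(
                np.searchsorted(self.qtr_levels, qtr_t), minlength=len(self.qtr_levels)
            ) / self.n_teat

        # ---- production block ---------------------------------------------
        self.herd_p = prod["herd_i"].to_numpy(np.int64)
        self.cow_p = prod["cow_i"].to_numpy(np.int64)
        self.sire_p = np.array([sire_map[s] for s in prod["sire"]], dtype=np.int64)
        self.ps_p = prod["ps"].to_numpy(np.int64)
        self.Y = np.column_stack(
            [prod["my"].to_numpy(float), prod["scs"].to_numpy(float)]
        ) if self.n_prod else np.empty((0, 2))
        self.miss_scs = np.isnan(self.Y[:, 1])
        self.n_ps_p = np.bincount(self.ps_p, minlength=N_PS).astype(float)
        self.ps_levels_p = np.nonzero(self.n_ps_p)[0]

        # ---- sire relationship structure -----------------------------------
        ped = pedigree
        if sires_only:
            ped = restrict_to_sires(pedigree, self.sire_levels)
        A = ped.relationship_matrix()
        pos = ped.index_of(self.sire_levels)
        A_ss = A[np.ix_(pos, pos)]
        self.A_ss = A_ss
        self.Ainv_ss = np.linalg.inv(A_ss)
        self.Ainv_ss = 0.5 * (self.Ainv_ss + self.Ainv_ss.T)

        # thresholds: K-1 cuts; pinned per scheme
        if self.n_cat == 2:
            self.cuts0 = np.array([0.0])
            self.free_cuts = np.array([], dtype=np.int64)
        else:
            self.cuts0 = np.array([0.0, 1.0, 2.0])
            self.free_cuts = np.array([2], dtype=np.int64)

        # inverse-Wishart priors: identity scale with minimal proper df.
        # The identity scale mildly regularizes weakly identified components
        # away from zero; near-scale-free alternatives (e.g. 0.01*I) let
        # poorly informed variance chains collapse toward zero and behave
        # worse in calibration runs.  Override the prior_* attributes before
        # fit() for a different choice.
        self.prior_df3 = 4.0
        self.prior_scale3 = np.eye(3)
        self.prior_df2 = 3.0
        self.prior_scale2 = np.eye(2)
        self.prior_df1 = 2.0
        self.prior_scale1 = 1.0

    # ------------------------------------------------------------------
    def _build_X0_crossprod(self) -> None:
        k0 = self.k0
        XtX = np.zeros((k0, k0))
        cols = [self.col_ps, self.col_hyg, self.col_qtr]
        for ci in cols:
            for cj in cols:
                valid = (ci >= 0) & (cj >= 0)
                np.add.at(XtX, (ci[valid], cj[valid]), 1.0)
        self.X0tX0 = XtX
        if k0:
            ev, V = np.linalg.eigh(XtX)
            if ev[0] < 1e-8 * max(ev[-1], 1.0):
                load = np.abs(V[:, 0])
                bad = [self.b0_names[i] for i in np.argsort(load)[::-1][:3]]
                raise ValueError(
                    "fixed-effect design for the liability is singular; "
                    f"confounded levels include {bad}"
                )

    def _xt_resid(self, resid: np.ndarray) -> np.ndarray:
        rhs = np.bincount(self.col_ps, weights=resid, minlength=self.k0)
        m = self.col_hyg >= 0
        rhs += np.bincount(self.col_hyg[m], weights=resid[m], minlength=self.k0)
        m = self.col_qtr >= 0
        rhs += np.bincount(self.col_qtr[m], weights=resid[m], minlength=self.k0)
        return rhs

    def _fe0(self, b0: np.ndarray) -> np.ndarray:
        if self.n_teat == 0:
            return np.empty(0)
        out = b0[self.col_ps].copy()
        m = self.col_hyg >= 0
        out[m] += b0[self.col_hyg[m]]
        m = self.col_qtr >= 0
        out[m] += b0[self.col_qtr[m]]
        return out

    # ------------------------------------------------------------------
    def fit(
        self,
        n_iter: int = 300_000,
        burn_in: int = 50_000,
        thin: int = 50,
        seed: int = 0,
        fix_covariances: CovarianceSet | None = None,
        start: CovarianceSet | None = None,
        store_effects: bool = True,
        verbose: bool = False,
    ):
        """Run the Gibbs sampler and return a :class:`ThresholdSireResults`.

        The study configuration is the default (300,000 iterations, 50,000
        burn-in, thinning every 50 -> 5,000 stored draws); pass smaller
        values for exploratory runs.  All randomness derives from `seed`.
        `fix_covariances` skips the covariance updates (useful to obtain
        effect solutions at externally estimated components, and for
        Gaussian-submodel checks against closed-form oracles).
        """
        from .results import ThresholdSireResults

        n_store = chain_plan(n_iter, burn_in, thin)
        rng = np.random.default_rng(seed)

        cov = (fix_covariances or start or CovarianceSet.default_start()).copy()
        cov.validate()
        fixed_cov = fix_covariances is not None

        n_t, n_p = self.n_teat, self.n_prod
        nh, nc, ns = self.n_herd, self.n_cow, self.n_sire
        b0 = np.zeros(self.k0)
        bP = np.zeros((N_PS, 2))
        h = np.zeros((nh, 3))
        p = np.zeros((nc, 3))
        s = np.zeros((ns, 3))
        cuts = self.cuts0.copy()
        if n_t and self.n_cat > 2:
            # start free thresholds at their empirical (cumulative-frequency)
            # positions on the pinned 0/1 scale; greatly shortens burn-in for
            # the slowly mixing extreme-order-statistic threshold update
            freq = np.bincount(self.cat, minlength=self.n_cat) / n_t
            z = ndtri(np.cumsum(freq)[:-1])
            cuts = (z - z[0]) / (z[1] - z[0])
        Y = self.Y.copy()
        if n_p and self.miss_scs.any():
            fill = np.nanmean(self.Y[~self.miss_scs, 1]) if (~self.miss_scs).any() else 0.0
            Y[self.miss_scs, 1] = fill
        lam = np.zeros(n_t)
        if n_t:
            lo, hi = self._interval_bounds(cuts)
            lam = np.clip(0.5 * (np.clip(lo, -3, 3) + np.clip(hi, -3, 3)), lo + 1e-3, hi - 1e-3)

        rec = _Recorder(self, n_store, store_effects)
        n0_h = np.bincount(self.herd_t, minlength=nh).astype(float)
        npp_h = np.bincount(self.herd_p, minlength=nh).astype(float)
        n0_c = np.bincount(self.cow_t, minlength=nc).astype(float)
        npp_c = np.bincount(self.cow_p, minlength=nc).astype(float)
        n0_s = np.bincount(self.sire_t, minlength=ns).astype(float)
        npp_s = np.bincount(self.sire_p, minlength=ns).astype(float)
        prod_classes = self.ps_levels_p

        for it in range(1, n_iter + 1):
            Hinv = np.linalg.inv(cov.H)
            Pinv = np.linalg.inv(cov.P)
            Sinv = np.linalg.inv(cov.S)
            Rinv = np.linalg.inv(cov.Rprod)
            L_R = np.linalg.cholesky(cov.Rprod)
            r11 = cov.r11
            sd0 = np.sqrt(r11)

            # --- data augmentation ------------------------------------
            if n_t:
                eta_t = (
                    self._fe0(b0)
                    + h[self.herd_t, 0]
                    + p[self.cow_t, 0]
                    + s[self.sire_t, 0]
                )
                lo, hi = self._interval_bounds(cuts)
                lam = sample_truncated_normal(eta_t, sd0, lo, hi, rng)
                # free thresholds: uniform between adjacent extreme liabilities
                for ci in self.free_cuts:
                    lo_t = lam[self.cat == ci].max()
                    hi_t = lam[self.cat == ci + 1].min()
                    cuts[ci] = rng.uniform(lo_t, hi_t)
            if n_p:
                eta_p = bP[self.ps_p] + h[self.herd_p, 1:] + p[self.cow_p, 1:] + s[self.sire_p, 1:]
                if self.miss_scs.any():
                    m = self.miss_scs
                    cmean = eta_p[m, 1] + cov.Rprod[0, 1] / cov.Rprod[0, 0] * (
                        Y[m, 0] - eta_p[m, 0]
                    )
                    csd = np.sqrt(cov.Rprod[1, 1] - cov.Rprod[0, 1] ** 2 / cov.Rprod[0, 0])
                    Y[m, 1] = cmean + csd * rng.standard_normal(m.sum())

            # --- fixed effects ---------------------------------------
            if n_t and self.k0:
                resid = lam - h[self.herd_t, 0] - p[self.cow_t, 0] - s[self.sire_t, 0]
                C = self.X0tX0 / r11
                rhs = self._xt_resid(resid) / r11
                Lc = np.linalg.cholesky(C)
                half = sla.solve_triangular(Lc, rhs, lower=True)
                mean = sla.solve_triangular(Lc.T, half, lower=False)
                b0 = mean + sla.solve_triangular(
                    Lc.T, rng.standard_normal(self.k0), lower=False
                )
            if n_p:
                resid = Y - h[self.herd_p, 1:] - p[self.cow_p, 1:] - s[self.sire_p, 1:]
                sums = _bincount2(self.ps_p, resid, N_PS)
                cls = prod_classes
                ncls = self.n_ps_p[cls]
                mean = sums[cls] / ncls[:, None]
                z = rng.standard_normal((len(cls), 2))
                bP[cls] = mean + (z @ L_R.T) / np.sqrt(ncls)[:, None]

            # --- random effects (blocked per level) -------------------
            h = self._draw_blocked(
                rng, Hinv, Rinv, r11, nh,
                self.herd_t, self.herd_p, n0_h, npp_h,
                lam - self._fe0(b0) - p[self.cow_t, 0] - s[self.sire_t, 0] if n_t else None,
                (Y - bP[self.ps_p] - p[self.cow_p, 1:] - s[self.sire_p, 1:]) if n_p else None,
            )
            p = self._draw_blocked(
                rng, Pinv, Rinv, r11, nc,
                self.cow_t, self.cow_p, n0_c, npp_c,
                lam - self._fe0(b0) - h[self.herd_t, 0] - s[self.sire_t, 0] if n_t else None,
                (Y - bP[self.ps_p] - h[self.herd_p, 1:] - s[self.sire_p, 1:]) if n_p else None,
            )
            s = self._draw_sires(
                rng, Sinv, Rinv, r11, n0_s, npp_s,
                lam - self._fe0(b0) - h[self.herd_t, 0] - p[self.cow_t, 0] if n_t else None,
                (Y - bP[self.ps_p] - h[self.herd_p, 1:] - p[self.cow_p, 1:]) if n_p else None,
            )

            # --- covariance components --------------------------------
            if not fixed_cov:
                cov.H = _sample_invwishart(
                    self.prior_df3 + nh, self.prior_scale3 + h.T @ h, rng
                )
                cov.P = _sample_invwishart(
                    self.prior_df3 + nc, self.prior_scale3 + p.T @ p, rng
                )
                cov.S = _sample_invwishart(
                    self.prior_df3 + ns, self.prior_scale3 + s.T @ (self.Ainv_ss @ s),
                    rng,
                )
                if n_p:
                    resid = Y - bP[self.ps_p] - h[self.herd_p, 1:] - p[self.cow_p, 1:] - s[self.sire_p, 1:]
                    cov.Rprod = _sample_invwishart(
                        self.prior_df2 + n_p, self.prior_scale2 + resid.T @ resid, rng
                    )
                if n_t and self.scheme == "estimated_residual":
                    resid0 = lam - self._fe0(b0) - h[self.herd_t, 0] - p[self.cow_t, 0] - s[self.sire_t, 0]
                    cov.r11 = float(
                        _sample_invwishart(
                            self.prior_df1 + n_t,
                            np.array([[self.prior_scale1 + resid0 @ resid0]]),
                            rng,
                        )
                    )

            if not np.isfinite(cov.full_R()).all():
                raise FloatingPointError(f"non-finite state at iteration {it}")

            if it > burn_in and (it - burn_in) % thin == 0:
                rec.store(cov, cuts, b0, bP, h, p, s)
            if verbose and it % max(1, n_iter // 20) == 0:
                logger.info("iteration %d / %d", it, n_iter)

        return ThresholdSireResults(
            model=self,
            draws=rec.frame(),
            n_iter=n_iter,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            final_cov=cov,
        )

    # ------------------------------------------------------------------
    def _interval_bounds(self, cuts):
        edges = np.concatenate(([-np.inf], cuts, [np.inf]))
        return edges[self.cat], edges[self.cat + 1]

    def _draw_blocked(
        self, rng, Kinv, Rinv, r11, nlev, idx_t, idx_p, n0, npp, resid_t, resid_p
    ):
        """Draw all levels of a herd- or cow-indexed 3-variate effect.

        The full-conditional precision of level j is block
        ``Kinv + diag(n0_j/r11, npp_j * Rinv)`` because distinct levels never
        share a record; levels are therefore conditionally independent and
        drawn in one batched operation.
        """
        prec = np.broadcast_to(Kinv, (nlev, 3, 3)).copy()
        prec[:, 0, 0] += n0 / r11
        prec[:, 1:, 1:] += npp[:, None, None] * Rinv
        rhs = np.zeros((nlev, 3))
        if resid_t is not None:
            rhs[:, 0] = np.bincount(idx_t, weights=resid_t, minlength=nlev) / r11
        if resid_p is not None:
            rhs[:, 1:] = _bincount2(idx_p, resid_p, nlev) @ Rinv
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
        z = rng.standard_normal((nlev, 3, 1))
        return mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[..., 0]

    def _draw_sires(self, rng, Sinv, Rinv, r11, n0, npp, resid_t, resid_p):
        """Joint draw of the sire-effect vector (A^-1 x S^-1 coupling)."""
        ns = self.n_sire
        prec = np.kron(self.Ainv_ss, Sinv)
        d0 = 3 * np.arange(ns)
        prec[d0, d0] += n0 / r11
        for a in range(2):
            for b in range(2):
                prec[d0 + 1 + a, d0 + 1 + b] += npp * Rinv[a, b]
        rhs = np.zeros(3 * ns)
        if resid_t is not None:
            rhs[d0] = np.bincount(self.sire_t, weights=resid_t, minlength=ns) / r11
        if resid_p is not None:
            rhs.reshape(ns, 3)[:, 1:] = _bincount2(self.sire_p, resid_p, ns) @ Rinv
        c, low = sla.cho_factor(prec, lower=True)
        mean = sla.cho_solve((c, low), rhs)
        draw = mean + sla.solve_triangular(
            c.T, rng.standard_normal(3 * ns), lower=False
        )
        return draw.reshape(ns, 3)


def restrict_to_sires(pedigree: Pedigree, sires) -> Pedigree:
    """Sub-pedigree spanned by `sires` and all their ancestors."""
    pos = {ident: i for i, ident in enumerate(pedigree.ids)}
    keep: set[int] = set()
    stack = [pos[sid] for sid in sires]
    while stack:
        i = stack.pop()
        if i in keep:
            continue
        keep.add(i)
        for par in (pedigree.sire_idx[i], pedigree.dam_idx[i]):
            if par >= 0:
                stack.append(int(par))
    idx = sorted(keep)
    ids = [pedigree.ids[i] for i in idx]
    kept = set(idx)
    sires_out = [
        pedigree.ids[pedigree.sire_idx[i]] if pedigree.sire_idx[i] in kept else "0"
        for i in idx
    ]
    dams_out = [
        pedigree.ids[pedigree.dam_idx[i]] if pedigree.dam_idx[i] in kept else "0"
        for i in idx
    ]
    return Pedigree(ids, sires_out, dams_out)


class _Recorder:
    """Accumulates thinned draws into a flat table."""

    def __init__(self, model: ThresholdSireModel, n_store: int, store_effects: bool):
        self.model = model
        self.store_effects = store_effects
        names: list[str] = []
        for label in ("herd", "pe", "sire"):
            for i in range(3):
                for j in range(i, 3):
                    names.append(f"{label}_{TRAITS[i]}_{TRAITS[j]}")
        names += ["res_teat_teat", "res_my_my", "res_my_scs", "res_scs_scs"]
        names += [f"cut{c + 1}" for c in model.free_cuts]
        if store_effects:
            names += [f"b_teat:{nm}" for nm in model.b0_names]
            for c in model.ps_levels_p:
                names += [f"b_my:ps{c + 1}", f"b_scs:ps{c + 1}"]
        self.names = names
        self.buf = np.empty((n_store, len(names)))
        self.row = 0

    def store(self, cov: CovarianceSet, cuts, b0, bP, h, p, s) -> None:
        vals: list[float] = []
        for M in (cov.H, cov.P, cov.S):
            for i in range(3):
                for j in range(i, 3):
                    vals.append(M[i, j])
        vals += [cov.r11, cov.Rprod[0, 0], cov.Rprod[0, 1], cov.Rprod[1, 1]]
        vals += [cuts[c] for c in self.model.free_cuts]
        if self.store_effects:
            vals += list(b0)
            for c in self.model.ps_levels_p:
                vals += [bP[c, 0], bP[c, 1]]
        self.buf[self.row] = vals
        self.row += 1

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.buf[: self.row], columns=self.names)
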