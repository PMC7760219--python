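"""Posterior results container for the threshold-linear sire model.

Wraps the thinned chain produced by :meth:`ThresholdSireModel.fit` and
derives genetic parameters draw-by-draw: heritability, intra-herd
heritability, cow and herd repeatability, and the genetic / permanent
environment / herd correlations between the teat trait and the production
traits, each summarized by its posterior mean, 95% highest-probability-
density interval and Geweke convergence statistic.  Least-squares means of
the teat fixed effects are mapped from the liability to the probability
scale per draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import posterior as post
from .data_prep import QUARTERS
from .model import CovarianceSet, ThresholdSireModel, TRAITS

__all__ = ["ThresholdSireResults"]

_RES_COL = {"teat": "res_teat_teat", "my": "res_my_my", "scs": "res_scs_scs"}


@dataclass
class ThresholdSireResults:
    model: ThresholdSireModel
    draws: pd.DataFrame
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    final_cov: CovarianceSet

    @property
    def n_stored(self) -> int:
        return len(self.draws)

    # ------------------------------------------------------------------
    def component_draws(self, effect: str, trait: str) -> np.ndarray:
        """Variance draws for one effect ("sire", "pe", "herd", "res") and
        trait ("teat", "my", "scs")."""
        if effect == "res":
            return self.draws[_RES_COL[trait]].to_numpy()
        return self.draws[f"{effect}_{trait}_{trait}"].to_numpy()

    def covariance_draws(self, effect: str, t1: str, t2: str) -> np.ndarray:
        i, j = TRAITS.index(t1), TRAITS.index(t2)
        i, j = min(i, j), max(i, j)
        return self.draws[f"{effect}_{TRAITS[i]}_{TRAITS[j]}"].to_numpy()

    def h2_draws(self, trait: str) -> np.ndarray:
        return post.heritability(
            self.component_draws("sire", trait),
            self.component_draws("pe", trait),
            self.component_draws("herd", trait),
            self.component_draws("res", trait),
        )

    def h2_intra_herd_draws(self, trait: str) -> np.ndarray:
        return post.intra_herd_h2(
            self.component_draws("sire", trait),
            self.component_draws("pe", trait),
            self.component_draws("res", trait),
        )

    def cow_repeatability_draws(self, trait: str) -> np.ndarray:
        return post.cow_repeatability(
            self.component_draws("pe", trait),
            self.component_draws("sire", trait),
            self.component_draws("herd", trait),
            self.component_draws("res", trait),
        )

    def herd_repeatability_draws(self, trait: str) -> np.ndarray:
        return post.herd_repeatability(
            self.component_draws("herd", trait),
            self.component_draws("sire", trait),
            self.component_draws("pe", trait),
            self.component_draws("res", trait),
        )

    def correlation_draws(self, effect: str, t1: str, t2: str) -> np.ndarray:
        return post.correlation(
            self.covariance_draws(effect, t1, t2),
            self.component_draws(effect if effect != "res" else "res", t1),
            self.component_draws(effect if effect != "res" else "res", t2),
        )

    # ------------------------------------------------------------------
    def point_estimates(self, method: str = "mean_of_ratios") -> pd.DataFrame:
        """Genetic-parameter point estimates for all three traits.

        ``mean_of_ratios`` (default) is the posterior mean of the
        per-iteration functional; ``ratio_of_means`` plugs the posterior
        means of the variance components into the formulas.  The two differ
        for nonlinear functionals.
        """
        rows = []
        for trait in TRAITS:
            comp = {e: self.component_draws(e, trait) for e in ("sire", "pe", "herd", "res")}
            if method == "mean_of_ratios":
                fn = {
                    "h2": self.h2_draws(trait).mean(),
                    "h2_intra_herd": self.h2_intra_herd_draws(trait).mean(),
                    "cow_repeatability": self.cow_repeatability_draws(trait).mean(),
                    "herd_repeatability": self.herd_repeatability_draws(trait).mean(),
                }
            elif method == "ratio_of_means":
                m = {e: v.mean() for e, v in comp.items()}
                fn = {
                    "h2": float(post.heritability(m["sire"], m["pe"], m["herd"], m["res"])),
                    "h2_intra_herd": float(post.intra_herd_h2(m["sire"], m["pe"], m["res"])),
                    "cow_repeatability": float(
                        post.cow_repeatability(m["pe"], m["sire"], m["herd"], m["res"])
                    ),
                    "herd_repeatability": float(
                        post.herd_repeatability(m["herd"], m["sire"], m["pe"], m["res"])
                    ),
                }
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({"trait": trait, **{e: v.mean() for e, v in comp.items()}, **fn})
        return pd.DataFrame(rows).set_index("trait")

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior summary table (mean, HPD bounds, Geweke z per parameter).

        Layout mirrors a variance-component report: one row per variance
        component, derived genetic parameter and cross-trait correlation.
        """
        rows = []

        def add(parameter, trait, x):
            x = np.asarray(x, dtype=float)
            lo, hi = post.hpd_interval(x, level)
            try:
                z = post.geweke_z(x)
            except ValueError:
                z = float("nan")
            rows.append(
                {
                    "parameter": parameter,
                    "trait": trait,
                    "mean": x.mean(),
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "geweke_z": z,
                }
            )

        for trait in TRAITS:
            add("sire_variance", trait, self.component_draws("sire", trait))
            add("pe_variance", trait, self.component_draws("pe", trait))
            add("herd_variance", trait, self.component_draws("herd", trait))
            add("residual_variance", trait, self.component_draws("res", trait))
            add("heritability", trait, self.h2_draws(trait))
            add("intra_herd_heritability", trait, self.h2_intra_herd_draws(trait))
            add("cow_repeatability", trait, self.cow_repeatability_draws(trait))
            add("herd_repeatability", trait, self.herd_repeatability_draws(trait))
        for effect in ("sire", "pe", "herd"):
            for t1, t2 in (("teat", "my"), ("teat", "scs"), ("my", "scs")):
                add(f"{effect}_correlation", f"{t1}-{t2}", self.correlation_draws(effect, t1, t2))
        add("residual_correlation", "my-scs", self.correlation_draws("res", "my", "scs"))
        for c in self.model.free_cuts:
            add("threshold", f"cut{c + 1}", self.draws[f"cut{c + 1}"].to_numpy())
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def _b_draws(self, name: str) -> np.ndarray:
        col = f"b_teat:{name}"
        if col in self.draws.columns:
            return self.draws[col].to_numpy()
        return np.zeros(self.n_stored)  # reference (absorbed) level

    def _threshold_draws(self, above: int) -> np.ndarray:
        """Threshold separating classes `above` and `above`+1, per draw."""
        if above < 1 or above > self.model.n_cat - 1:
            raise ValueError(f"`above` must lie in 1..{self.model.n_cat - 1}")
        ci = above - 1
        if ci in self.model.free_cuts:
            return self.draws[f"cut{ci + 1}"].to_numpy()
        return np.full(self.n_stored, self.model.cuts0[ci])

    def lsm_probability(self, factor: str, above: int = 1, level: float = 0.95) -> pd.DataFrame:
        """Least-squares means of a teat fixed effect on the probability scale.

        For every stored draw the liability-scale mean of each level of
        `factor` ("qtr" or "hyg") is formed by averaging the remaining fixed
        effects over their observed class frequencies, then mapped to
        P(score above `above`) = 1 - Phi((t - eta) / residual sd) and
        summarized.
        """
        m = self.model
        if m.n_teat == 0:
            raise ValueError("model has no teat records")
        if not any(c.startswith("b_teat:") for c in self.draws.columns):
            raise ValueError("fixed-effect draws were not stored")
        ps_part = np.zeros(self.n_stored)
        for w, c in zip(m.ps_weights_t, m.ps_levels_t):
            ps_part += w * self._b_draws(f"ps{c + 1}")
        hyg_part = np.zeros(self.n_stored)
        for w, hlev in zip(m.hyg_weights, m.hyg_levels):
            hyg_part += w * self._b_draws(f"hyg{hlev + 1}")
        qtr_part = np.zeros(self.n_stored)
        for w, q in zip(m.qtr_weights, m.qtr_levels):
            qtr_part += w * self._b_draws(f"qtr_{QUARTERS[q]}")

        if factor == "qtr":
            levels = [(QUARTERS[q], f"qtr_{QUARTERS[q]}") for q in m.qtr_levels]
            base = ps_part + hyg_part
        elif factor == "hyg":
            levels = [(f"hygiene_{h + 1}", f"hyg{h + 1}") for h in m.hyg_levels]
            base = ps_part + qtr_part
        else:
            raise ValueError(f"unknown teat fixed factor {factor!r}")

        t = self._threshold_draws(above)
        sd = np.sqrt(self.component_draws("res", "teat"))
        rows = []
        for label, name in levels:
            eta = base + self._b_draws(name)
            prob = post.liability_to_probability(eta, t, sd)
            lo, hi = post.hpd_interval(prob, level)
            rows.append(
                {"level": label, "mean": prob.mean(), "hpd_low": lo, "hpd_high": hi}
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def write(self, prefix: str | Path) -> None:
        """Write the draw table and summary as delimited text."""
        prefix = Path(prefix)
        self.draws.to_csv(prefix.with_suffix(".draws.tsv"), sep="\t", index=False)
        self.summary().to_csv(prefix.with_suffix(".summary.tsv"), sep="\t", index=False)
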