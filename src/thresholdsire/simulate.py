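"""Synthetic study-shaped data with known truth.

Emulates the stacked design of the real study: ~48 herds, ~2,649 cows from
~869 sires (a fraction of cows re-appearing as dams), one teat-scoring visit
per herd yielding four quarter records per cow, and roughly ten monthly
test-day production records per cow from the scoring lactation.  Liabilities
and production phenotypes are drawn generatively from the threshold-linear
sire model itself, so the generator's covariance truth is exactly the
estimand of the fitting machinery.

Default (co)variance truth is the published posterior-mean set for the
4-class teat score analysed with MY and SCS; correlations never reported
(MY-SCS within each random effect) default to small values.  Only the
share of the lowest teat-score class is calibrated (via the liability
intercept); the remaining class shares follow from the pinned-threshold
parameterization and are not separately matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .data_prep import QUARTERS, scc_from_scs
from .model import CovarianceSet, restrict_to_sires
from .pedigree import Pedigree

__all__ = ["SimConfig", "simulate_pedigree", "simulate_records", "sire_map"]


def _cov_from(var, corr):
    sd = np.sqrt(np.asarray(var, dtype=float))
    R = np.array(
        [[1.0, corr[0], corr[1]], [corr[0], 1.0, corr[2]], [corr[1], corr[2], 1.0]]
    )
    return R * np.outer(sd, sd)


def default_covariances(trait: str = "TS") -> CovarianceSet:
    """Published posterior-mean truth for the chosen teat trait column.

    Trait order (teat, MY, SCS).  The MY-SCS correlations inside each random
    effect were not reported and default to small values; binary traits use
    a unit liability residual per their identifiability scheme.
    """
    teat_col = {"TS": 0, "TSa": 1, "TSb": 2}[trait]
    sire_var = [(0.438, 0.128, 0.036)[teat_col], 0.958, 0.148]
    pe_var = [(3.998, 1.449, 0.430)[teat_col], 15.12, 1.488]
    herd_var = [(1.648, 0.506, 0.160)[teat_col], 15.04, 0.624]
    g_tm = (0.86, 0.89, 0.54)[teat_col]
    g_ts = (0.44, 0.36, 0.38)[teat_col]
    p_tm = (0.01, 0.02, -0.003)[teat_col]
    p_ts = (0.14, 0.12, 0.15)[teat_col]
    h_tm = (0.30, 0.30, 0.46)[teat_col]
    h_ts = (-0.25, -0.25, -0.47)[teat_col]
    return CovarianceSet(
        S=_cov_from(sire_var, (g_tm, g_ts, 0.10)),
        P=_cov_from(pe_var, (p_tm, p_ts, 0.10)),
        H=_cov_from(herd_var, (h_tm, h_ts, -0.10)),
        r11=1.281 if trait == "TS" else 1.0,
        Rprod=_cov_from([1.0, 28.01, 1.788], (0.0, 0.0, 0.0))[1:, 1:],
    )


@dataclass
class SimConfig:
    """Generator configuration; defaults reproduce the study's shape."""

    n_herds: int = 48
    n_cows: int = 2649
    n_sires: int = 869
    n_base_dams: int = 2133
    frac_cow_dams: float = 275 / 2649  # cows re-used as dams of later cows
    frac_sires_with_grandsire: float = 0.5
    testday_mean: float = 10.0  # test-days per cow (median ~10)
    testday_sd: float = 2.5
    trait: str = "TS"  # which teat trait the scores encode
    covariances: CovarianceSet | None = None  # None -> published truth
    class_low_target: float | None = None  # share of the lowest score class
    class_top_target: float = 0.0161  # share of the top class (4-class only)
    front_excess: float = 0.20  # liability excess of front vs rear quarters
    hygiene_effects: tuple = (0.0, 0.0, 0.0, 0.0)  # null per the study's finding
    teat_stage_slope: float = 0.03  # liability rise per lactation month
    teat_parity_step: float = 0.15  # liability rise per parity class
    score_month_max: int = 12  # scoring visits span lactation months 1..max
    seed: int = 2021

    def __post_init__(self):
        if self.trait not in ("TS", "TSa", "TSb"):
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.covariances is None:
            self.covariances = default_covariances(self.trait)
        self.covariances.validate()
        if self.class_low_target is None:
            # published shares: 65.7% in the lowest class for TS/TS_a,
            # 90.6% for the TS_b low class
            self.class_low_target = 0.906 if self.trait == "TSb" else 0.657


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Three-tier pedigree: grandsires -> sires/dams -> cows.

    Sires share paternal grandsires (half-sib sire groups); a configurable
    fraction of cows re-appears as dams of later-born cows; everything else
    is a founder.  The construction is generational, hence acyclic.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_gs = max(1, cfg.n_sires // 6)
    ids, sires, dams = [], [], []
    gs_ids = [f"GS{i + 1}" for i in range(n_gs)]
    for g in gs_ids:
        ids.append(g), sires.append("0"), dams.append("0")
    sire_ids = [f"S{i + 1}" for i in range(cfg.n_sires)]
    for sid in sire_ids:
        has_gs = rng.uniform() < cfg.frac_sires_with_grandsire
        ids.append(sid)
        sires.append(rng.choice(gs_ids) if has_gs else "0")
        dams.append("0")
    dam_ids = [f"D{i + 1}" for i in range(cfg.n_base_dams)]
    for d in dam_ids:
        ids.append(d), sires.append("0"), dams.append("0")
    # skewed sire family sizes
    w = rng.gamma(0.6, size=cfg.n_sires)
    w /= w.sum()
    cow_ids = [f"C{i + 1}" for i in range(cfg.n_cows)]
    for i, cid in enumerate(cow_ids):
        ids.append(cid)
        sires.append(sire_ids[rng.choice(cfg.n_sires, p=w)])
        if i > 0 and rng.uniform() < cfg.frac_cow_dams:
            dams.append(cow_ids[rng.integers(0, i)])
        else:
            dams.append(dam_ids[rng.integers(0, cfg.n_base_dams)])
    return Pedigree(ids, sires, dams)


def sire_map(ped: Pedigree) -> dict:
    """Mapping individual -> sire id for all individuals with a known sire."""
    out = {}
    for i, ident in enumerate(ped.ids):
        si = ped.sire_idx[i]
        if si >= 0:
            out[ident] = ped.ids[si]
    return out


def simulate_records(cfg: SimConfig, ped: Pedigree, rng: np.random.Generator | None = None):
    """Draw teat-score and production records under the model truth.

    Returns ``(teat_df, prod_df, truth)`` where the data frames carry the
    raw-record columns :func:`~thresholdsire.data_prep.stack_datasets`
    expects and `truth` holds every generative quantity needed for
    parameter-recovery checks.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    cov = cfg.covariances
    cow_ids = [x for x in ped.ids if isinstance(x, str) and x.startswith("C")]
    n_cows = len(cow_ids)
    sire_of = sire_map(ped)
    sire_ids = sorted({sire_of[c] for c in cow_ids})
    n_sires = len(sire_ids)
    s_pos = {s: i for i, s in enumerate(sire_ids)}

    # --- random effects ----------------------------------------------------
    L_H = np.linalg.cholesky(cov.H)
    L_P = np.linalg.cholesky(cov.P)
    L_S = np.linalg.cholesky(cov.S)
    h = rng.standard_normal((cfg.n_herds, 3)) @ L_H.T
    p = rng.standard_normal((n_cows, 3)) @ L_P.T
    # s ~ N(0, A_ss x S): relationships among sires run through their own
    # ancestors only, so the sire block of A is computed on that closure
    sub = restrict_to_sires(ped, sire_ids)
    A_ss = sub.relationship_matrix()[np.ix_(sub.index_of(sire_ids), sub.index_of(sire_ids))]
    L_A = np.linalg.cholesky(A_ss + 1e-10 * np.eye(n_sires))
    s = L_A @ rng.standard_normal((n_sires, 3)) @ L_S.T

    # --- cow-level design --------------------------------------------------
    herd_w = rng.dirichlet(np.full(cfg.n_herds, 6.0))
    herd = rng.choice(cfg.n_herds, size=n_cows, p=herd_w)
    parity = rng.choice([1, 2, 3, 4, 5], size=n_cows, p=[0.35, 0.27, 0.18, 0.12, 0.08])
    score_month = rng.integers(1, cfg.score_month_max + 1, size=n_cows)
    hygiene = rng.choice([1, 2, 3, 4], size=n_cows, p=[0.45, 0.30, 0.17, 0.08])
    cow_sire = np.array([s_pos[sire_of[c]] for c in cow_ids])
    pclass = np.minimum(parity, 3)

    # --- teat block ---------------------------------------------------------
    qtr_eff = np.array([cfg.front_excess, cfg.front_excess, 0.0, 0.0])
    hyg_eff = np.asarray(cfg.hygiene_effects, dtype=float)
    trend = cfg.teat_stage_slope * (score_month - 1) + cfg.teat_parity_step * (pclass - 1)
    fx_cow = trend + hyg_eff[hygiene - 1]
    fx_rows = np.repeat(fx_cow, 4) + np.tile(qtr_eff, n_cows)
    total_sd = np.sqrt(cov.S[0, 0] + cov.P[0, 0] + cov.H[0, 0] + cov.r11)
    z_low = ndtri(cfg.class_low_target)
    intercept = -total_sd * z_low - fx_rows.mean()
    eta = (
        intercept
        + fx_rows
        + np.repeat(h[herd, 0], 4)
        + np.repeat(p[:, 0], 4)
        + np.repeat(s[cow_sire, 0], 4)
    )
    lam = eta + np.sqrt(cov.r11) * rng.standard_normal(4 * n_cows)
    if cfg.trait == "TS":
        mu_bar = intercept + fx_rows.mean()
        t3 = mu_bar + total_sd * ndtri(1.0 - cfg.class_top_target)
        cuts = np.array([0.0, 1.0, t3])
        score = 1 + np.searchsorted(cuts, lam, side="right")
    else:
        cuts = np.array([0.0])
        binary = (lam > 0).astype(int)
        # encode so that the standard collapsing scheme recovers the trait
        score = binary + 1 if cfg.trait == "TSa" else binary + 2
    teat_df = pd.DataFrame(
        {
            "cow": np.repeat(cow_ids, 4),
            "herd": np.repeat(herd, 4) + 1,
            "parity": np.repeat(parity, 4),
            "month": np.repeat(score_month, 4),
            "hygiene": np.repeat(hygiene, 4),
            "quarter": np.tile(QUARTERS, n_cows),
            "score": score,
        }
    )

    # --- production block ----------------------------------------------------
    n_td = np.clip(np.rint(rng.normal(cfg.testday_mean, cfg.testday_sd, n_cows)), 3, 15).astype(int)
    cow_rep = np.repeat(np.arange(n_cows), n_td)
    month = np.concatenate([np.arange(1, k + 1) for k in n_td])
    my_base = np.array([27.0, 29.5, 31.0])[np.minimum(parity, 3)[cow_rep] - 1]
    my_curve = 3.0 * np.exp(-0.5 * ((month - 2.0) / 2.0) ** 2) - 0.35 * np.maximum(month - 2, 0)
    scs_prof = 3.1 + 0.25 * (np.minimum(parity, 3)[cow_rep] - 1) + 0.05 * month
    e = rng.standard_normal((len(month), 2)) @ np.linalg.cholesky(cov.Rprod).T
    my = my_base + my_curve + h[herd[cow_rep], 1] + p[cow_rep, 1] + s[cow_sire[cow_rep], 1] + e[:, 0]
    scs = scs_prof + h[herd[cow_rep], 2] + p[cow_rep, 2] + s[cow_sire[cow_rep], 2] + e[:, 1]
    n_truncated = int((my < 0.1).sum())
    my = np.maximum(my, 0.1)
    prod_df = pd.DataFrame(
        {
            "cow": np.asarray(cow_ids, dtype=object)[cow_rep],
            "herd": herd[cow_rep] + 1,
            "parity": parity[cow_rep],
            "month": month,
            "my": my,
            "scc": scc_from_scs(scs),
        }
    )

    truth = {
        "covariances": cov.copy(),
        "cuts": cuts,
        "intercept": float(intercept),
        "quarter_effects": qtr_eff,
        "hygiene_effects": hyg_eff,
        "herd_effects": h,
        "pe_effects": p,
        "sire_effects": s,
        "sire_ids": sire_ids,
        "cow_sire_index": cow_sire,
        "n_my_truncated": n_truncated,
        "class_frequencies": np.bincount(score, minlength=5)[1:] / (4 * n_cows),
    }
    return teat_df, prod_df, truth


def write_dataset(
    outdir: str | Path,
    ped: Pedigree,
    teat_df: pd.DataFrame,
    prod_df: pd.DataFrame,
    truth: dict | None = None,
) -> None:
    """Write pedigree + raw record files in the delimited formats read back
    by the preparation stage, plus (optionally) the generative truth as a
    JSON sidecar for recovery checks."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"id": ped.ids, "sire": ped.sires, "dam": ped.dams}).to_csv(
        outdir / "pedigree.txt", sep="\t", index=False, header=False
    )
    teat_df.to_csv(outdir / "teat_records.tsv", sep="\t", index=False)
    prod_df.to_csv(outdir / "production_records.tsv", sep="\t", index=False)
    if truth is not None:
        cov = truth["covariances"]
        sidecar = {
            "covariances": {
                "H": cov.H.tolist(), "P": cov.P.tolist(), "S": cov.S.tolist(),
                "r11": cov.r11, "Rprod": cov.Rprod.tolist(),
            },
            "cuts": np.asarray(truth["cuts"]).tolist(),
            "intercept": truth["intercept"],
            "quarter_effects": np.asarray(truth["quarter_effects"]).tolist(),
            "hygiene_effects": np.asarray(truth["hygiene_effects"]).tolist(),
            "sire_ids": list(truth["sire_ids"]),
            "sire_effects": np.asarray(truth["sire_effects"]).tolist(),
            "class_frequencies": np.asarray(truth["class_frequencies"]).tolist(),
            "n_my_truncated": truth["n_my_truncated"],
        }
        (outdir / "truth.json").write_text(json.dumps(sidecar))
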