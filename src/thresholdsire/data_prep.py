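"""Raw-record preparation: SCS transform, trait collapsing, class coding, stacking.

Two raw sources feed the analysis: teat-end scores (one visit per herd, four
quarter records per cow, hyperkeratosis scored 1-4) and monthly test-day
production records (daily milk yield in kg and somatic cell count per mL).
The analysis dataset stacks the two so that no row carries both a teat score
and a production response; the residual covariance between the two blocks is
structurally zero because the phenotypes are never co-observed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "scs_from_scc",
    "scc_from_scs",
    "collapse_ts",
    "parity_stage_class",
    "stack_datasets",
    "StackedData",
    "QUARTERS",
    "N_PARITY_CLASSES",
    "N_STAGE_BINS",
]

logger = logging.getLogger(__name__)

QUARTERS = ("FL", "FR", "RL", "RR")

N_PARITY_CLASSES = 3  # first, second, third-and-later lactations
N_STAGE_BINS = 12  # lactation months 1..11, with months 12-15 pooled
MAX_MONTH = 15  # records beyond the 15th month collapse into the last bin


def scs_from_scc(scc):
    """Somatic cell score, SCS = log2(SCC / 100,000) + 3.

    `scc` is somatic cell count per mL and must be positive.
    """
    scc = np.asarray(scc, dtype=float)
    if np.any(scc <= 0):
        raise ValueError("SCC must be positive to take the log transform")
    out = np.log2(scc / 100_000.0) + 3.0
    return out if out.ndim else float(out)


def scc_from_scs(scs):
    """Inverse transform: SCC = 100,000 * 2**(SCS - 3)."""
    scs = np.asarray(scs, dtype=float)
    out = 100_000.0 * np.exp2(scs - 3.0)
    return out if out.ndim else float(out)


def collapse_ts(ts, scheme: str):
    """Collapse the 4-class teat score to a binary trait.

    scheme "a": class 1 vs {2,3,4} (any callosity ring).
    scheme "b": {1,2} vs {3,4} (rough / very rough ring).
    Returns 0 for the low class, 1 for the high class.
    """
    ts = np.asarray(ts)
    if np.any((ts < 1) | (ts > 4)):
        raise ValueError("teat score must lie in 1..4")
    if scheme == "a":
        out = (ts > 1).astype(np.int64)
    elif scheme == "b":
        out = (ts > 2).astype(np.int64)
    else:
        raise ValueError(f"unknown collapsing scheme {scheme!r}; use 'a' or 'b'")
    return out if out.ndim else int(out)


def parity_stage_class(parity, month):
    """Parity-by-stage-of-lactation class, coded 1..36.

    Parity is truncated to {1, 2, 3+}; lactation month to 12 stage bins
    (months 1..11 individually, months 12 and later pooled so records up to
    month 15 enter the final bin).  Class = (parity-1)*12 + stage.
    """
    parity = np.asarray(parity, dtype=np.int64)
    month = np.asarray(month, dtype=np.int64)
    if np.any(parity < 1) or np.any(month < 1):
        raise ValueError("parity and lactation month must be >= 1")
    p = np.minimum(parity, N_PARITY_CLASSES)
    m = np.minimum(month, N_STAGE_BINS)
    out = (p - 1) * N_STAGE_BINS + m
    return out if out.ndim else int(out)


@dataclass
class StackedData:
    """The stacked analysis dataset plus its level dictionaries.

    One row is either a teat-quarter score (block "teat": columns `score`,
    `hyg`, `qtr` populated) or a test-day production record (block "prod":
    `my` and `scs` populated, `scs` possibly missing).  Integer index columns
    `herd_i`, `cow_i`, `ps` are 0-based; `sire` holds the pedigree identifier
    of the cow's sire.
    """

    df: pd.DataFrame
    herd_levels: list
    cow_levels: list
    sire_levels: list
    filter_log: dict = field(default_factory=dict)

    @property
    def n_teat(self) -> int:
        return int((self.df["block"] == "teat").sum())

    @property
    def n_prod(self) -> int:
        return int((self.df["block"] == "prod").sum())

    def write(self, path: str | Path) -> None:
        """Write the stacked table as TSV with a JSON sidecar of level maps."""
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "herd_levels": [str(x) for x in self.herd_levels],
            "cow_levels": [str(x) for x in self.cow_levels],
            "sire_levels": [str(x) for x in self.sire_levels],
            "filter_log": self.filter_log,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def read(cls, path: str | Path) -> "StackedData":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            df=df,
            herd_levels=sidecar["herd_levels"],
            cow_levels=sidecar["cow_levels"],
            sire_levels=sidecar["sire_levels"],
            filter_log=sidecar.get("filter_log", {}),
        )


def stack_datasets(
    teat: pd.DataFrame,
    prod: pd.DataFrame,
    sire_of: dict | pd.Series,
) -> StackedData:
    """Stack teat-score and production records into the analysis dataset.

    Parameters
    ----------
    teat
        Columns ``cow, herd, parity, month, hygiene, quarter, score``.  One
        row per scored quarter; cows without all four quarters are dropped.
    prod
        Columns ``cow, herd, parity, month, my, scc`` (or a precomputed
        ``scs`` column).  Only records from the cow's scoring lactation are
        retained; records of cows never teat-scored are dropped.
    sire_of
        Mapping cow id -> sire id (normally from the pedigree).  Cows with no
        sire entry are dropped with a logged count.

    Returns
    -------
    StackedData with ``4 * n_scored_cows + n_retained_testdays`` rows.
    """
    teat = teat.copy()
    prod = prod.copy()
    if isinstance(sire_of, pd.Series):
        sire_of = sire_of.to_dict()
    log: dict[str, int] = {}

    # -- teat side: require the full set of four quarter records ------------
    qcounts = teat.groupby("cow")["quarter"].nunique()
    complete = set(qcounts.index[qcounts == 4])
    dropped = teat.loc[~teat["cow"].isin(complete), "cow"].nunique()
    if dropped:
        logger.warning("dropping %d cows without all four quarter scores", dropped)
    log["cows_incomplete_quarters"] = int(dropped)
    teat = teat[teat["cow"].isin(complete)]

    # cows must map to a sire through the pedigree
    in_ped = teat["cow"].map(lambda c: c in sire_of)
    log["teat_cows_not_in_pedigree"] = int(teat.loc[~in_ped, "cow"].nunique())
    if log["teat_cows_not_in_pedigree"]:
        logger.warning(
            "dropping %d scored cows absent from the pedigree",
            log["teat_cows_not_in_pedigree"],
        )
    teat = teat[in_ped]
    scored = set(teat["cow"])

    # -- production side: same cows, same lactation as the scoring ----------
    scoring_parity = teat.groupby("cow")["parity"].first()
    n0 = len(prod)
    prod = prod[prod["cow"].isin(scored)]
    log["prod_rows_unscored_cows"] = int(n0 - len(prod))
    n0 = len(prod)
    prod = prod[prod["parity"].values == scoring_parity.reindex(prod["cow"]).values]
    log["prod_rows_other_lactation"] = int(n0 - len(prod))

    if "scs" not in prod.columns:
        prod["scs"] = np.nan
        ok = prod["scc"].notna() & (prod["scc"] > 0)
        prod.loc[ok, "scs"] = scs_from_scc(prod.loc[ok, "scc"].to_numpy())
        log["prod_rows_missing_scs"] = int((~ok).sum())

    # -- build index columns -------------------------------------------------
    herd_levels = sorted(set(teat["herd"]) | set(prod["herd"]))
    cow_levels = sorted(scored)
    sire_levels = sorted({sire_of[c] for c in cow_levels})
    herd_map = {h: i for i, h in enumerate(herd_levels)}
    cow_map = {c: i for i, c in enumerate(cow_levels)}

    qmap = {q: i for i, q in enumerate(QUARTERS)}
    teat_rows = pd.DataFrame(
        {
            "block": "teat",
            "score": teat["score"].astype(np.int64).to_numpy(),
            "my": np.nan,
            "scs": np.nan,
            "herd_i": teat["herd"].map(herd_map).to_numpy(),
            "cow_i": teat["cow"].map(cow_map).to_numpy(),
            "sire": teat["cow"].map(sire_of).to_numpy(),
            "ps": parity_stage_class(teat["parity"], teat["month"]) - 1,
            "hyg": teat["hygiene"].astype(np.int64).to_numpy() - 1,
            "qtr": teat["quarter"].map(qmap).to_numpy(),
        }
    )
    prod_rows = pd.DataFrame(
        {
            "block": "prod",
            "score": pd.array([pd.NA] * len(prod), dtype="Int64"),
            "my": prod["my"].to_numpy(dtype=float),
            "scs": prod["scs"].to_numpy(dtype=float),
            "herd_i": prod["herd"].map(herd_map).to_numpy(),
            "cow_i": prod["cow"].map(cow_map).to_numpy(),
            "sire": prod["cow"].map(sire_of).to_numpy(),
            "ps": parity_stage_class(prod["parity"], prod["month"]) - 1,
            "hyg": -1,
            "qtr": -1,
        }
    )
    df = pd.concat([teat_rows, prod_rows], ignore_index=True)
    log["n_teat_rows"] = len(teat_rows)
    log["n_prod_rows"] = len(prod_rows)
    logger.info("stacked dataset: %s", log)
    return StackedData(
        df=df,
        herd_levels=herd_levels,
        cow_levels=cow_levels,
        sire_levels=sire_levels,
        filter_log=log,
    )
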