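"""Stable-isotope sample QC and regurgitate diet composition.

Isotope QC flags blood samples whose C:N mass ratio reaches 3.5 (lipid bias;
lipid-extraction would be required).  Diet composition summarises
sample × prey-species item counts into the standard four-column table:
items per species, % of all items, samples containing the species, and % of
samples — percentages printed at one decimal with half-up rounding.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError

logger = logging.getLogger(__name__)

CN_LIPID_THRESHOLD = 3.5

DIET_COLUMNS = ("sample_id", "individual_id", "stage", "species", "prey_group", "count")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.45 -> 0.5), as in printed composition tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def qc_isotopes(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split isotope samples into (passed, flagged).

    Blood samples with C:N >= 3.5 are flagged for lipid bias; feathers are
    keratin and exempt from the rule.
    """
    for col in ("tissue", "cn_ratio"):
        if col not in samples.columns:
            raise SchemaError(f"isotope table missing column {col!r}")
    flag = (samples["tissue"] == "blood") & (samples["cn_ratio"] >= CN_LIPID_THRESHOLD)
    if flag.any():
        logger.warning("%d blood samples flagged for lipid bias (C:N >= %.1f)",
                       int(flag.sum()), CN_LIPID_THRESHOLD)
    return samples.loc[~flag].copy(), samples.loc[flag].copy()


def diet_composition(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-species composition of regurgitate samples.

    ``samples`` is long-format with at least sample_id, species, count (and
    optionally prey_group).  Returns one row per species present: total item
    count, % of all items, number of samples containing the species and % of
    samples, with percentages half-up rounded to one decimal.  The sample is
    the counting unit for the "individuals associated" columns.
    """
    for col in ("sample_id", "species", "count"):
        if col not in samples.columns:
            raise SchemaError(f"diet table missing column {col!r}")
    if len(samples) == 0:
        raise InsufficientDataError("no diet samples")
    df = samples[samples["count"] > 0]
    total_items = int(df["count"].sum())
    n_samples = int(samples["sample_id"].nunique())
    rows = []
    for species, grp in df.groupby("species", sort=False):
        n_items = int(grp["count"].sum())
        n_with = int(grp["sample_id"].nunique())
        rows.append({
            "species": species,
            "prey_group": grp["prey_group"].iloc[0] if "prey_group" in grp else "",
            "n_items": n_items,
            "pct_items": round_half_up(100.0 * n_items / total_items),
            "n_individuals": n_with,
            "pct_individuals": round_half_up(100.0 * n_with / n_samples),
        })
    return pd.DataFrame(rows)


def dominant_prey_consistency(samples: pd.DataFrame) -> pd.DataFrame:
    """Whether each repeatedly-sampled individual keeps the same dominant prey.

    Dominant species per sample is the largest item count, ties broken
    alphabetically and flagged.  Only individuals with >= 2 samples are
    reported; ``consistent`` is True when every sample shares one dominant
    species.
    """
    for col in ("sample_id", "individual_id", "species", "count"):
        if col not in samples.columns:
            raise SchemaError(f"diet table missing column {col!r}")
    dom = []
    for sid, grp in samples[samples["count"] > 0].groupby("sample_id"):
        top = grp["count"].max()
        winners = sorted(grp.loc[grp["count"] == top, "species"])
        dom.append({"sample_id": sid,
                    "individual_id": grp["individual_id"].iloc[0],
                    "dominant": winners[0],
                    "tied": len(winners) > 1})
    dom = pd.DataFrame(dom)
    out = []
    for ind, grp in dom.groupby("individual_id"):
        if len(grp) < 2:
            continue
        out.append({"individual_id": ind,
                    "n_samples": len(grp),
                    "consistent": grp["dominant"].nunique() == 1,
                    "any_tie": bool(grp["tied"].any())})
    return pd.DataFrame(out, columns=["individual_id", "n_samples", "consistent", "any_tie"])


def load_prey_table() -> pd.DataFrame:
    """The published regurgitate composition marginals shipped with the package
    (13 prey species, 222 items across 26 samples)."""
    with resources.files("foragespec.data").joinpath("prey_composition_published.csv").open() as fh:
        return pd.read_csv(fh)


def reconstruct_prey_samples(prey_table: pd.DataFrame | None = None,
                             n_samples: int = 26) -> pd.DataFrame:
    """Synthetic long-format sample table consistent with published marginals.

    The printed composition table reports only per-species totals (item count
    and number of samples containing the species), not the raw sample × species
    matrix.  This reconstructs *a* matrix with exactly those marginals: each
    species' occurrences are placed in consecutive samples (modulo
    ``n_samples``, with a running offset so every sample receives items), one
    item per occupied sample plus the remainder in the first.  Composition
    summaries computed from it reproduce the printed marginals exactly; the
    within-sample structure is synthetic.
    """
    tab = load_prey_table() if prey_table is None else prey_table
    rows = []
    offset = 0
    for _, rec in tab.iterrows():
        m, c = int(rec["n_samples"]), int(rec["n_items"])
        slots = [(offset + j) % n_samples for j in range(m)]
        counts = np.ones(m, int)
        counts[0] += c - m
        for slot, cnt in zip(slots, counts):
            rows.append({"sample_id": f"S{slot:02d}",
                         "individual_id": f"B{slot:02d}",
                         "stage": "chick_rearing",
                         "species": rec["species"],
                         "prey_group": rec["prey_group"],
                         "count": int(cnt)})
        offset += m
    return pd.DataFrame(rows, columns=list(DIET_COLUMNS))
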