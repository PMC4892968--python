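"""Accuracy assessment: injection-site discrepancies, percentage
agreement with expert counts, and sparse-connection concordance.

Three validation instruments:

* the Euclidean distance between the automatically mapped injection-site
  center of mass and the stereotaxic position estimated independently by
  an expert neuroanatomist, per injection (the packaged reference table of
  17 frontal-lobe injections ships with the package);
* the Pearson correlation between automated and expert per-area
  percentages of extrinsic labeled cells over matched (injection, area)
  pairs;
* concordance counts for sparse connections — how often a connection the
  expert scored at or below a small percentage threshold is also scored
  that low by the automated pipeline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientData


def euclidean_discrepancy(auto, expert):
    """Euclidean distance (mm) between two stereotaxic (ML, AP, DV) triples."""
    a = np.asarray(auto, dtype=float)
    e = np.asarray(expert, dtype=float)
    return float(np.sqrt(np.sum((a - e) ** 2)))


def load_table1():
    """The packaged injection-site reference table (17 cases).

    Columns: case, tracer, structure, abbreviation, automated and expert
    (ML, AP, DV) coordinates in mm, and the published discrepancy in mm.
    """
    with resources.files("tracemap.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def load_supergroups():
    """Illustrative supergroup definitions (area -> group) as a flat map."""
    with resources.files("tracemap.data").joinpath("supergroups.json").open() as fh:
        raw = json.load(fh)
    mapping = {}
    for group, members in raw.items():
        if group.startswith("_"):
            continue
        for m in members:
            mapping[m] = group
    return mapping


def discrepancy_table(rows):
    """Recompute per-case discrepancies and their mean.

    ``rows`` must carry auto_ml/auto_ap/auto_dv and expert_* columns.
    Returns ``(table, mean)`` where the table gains a ``recomputed_mm``
    column.  Because published coordinates are rounded to 0.1 mm, the
    recomputation is expected to land within about 0.05 mm of any
    published per-case value.
    """
    if len(rows) < 1:
        raise InsufficientData("need at least one row")
    out = rows.copy()
    auto = out[["auto_ml", "auto_ap", "auto_dv"]].to_numpy(dtype=float)
    expert = out[["expert_ml", "expert_ap", "expert_dv"]].to_numpy(dtype=float)
    out["recomputed_mm"] = np.sqrt(np.sum((auto - expert) ** 2, axis=1))
    return out, float(out["recomputed_mm"].mean())


_INTERVAL = re.compile(r"^\s*([0-9.]+)\s*[-–]\s*([0-9.]+)\s*%?\s*$")


def parse_percentage(value):
    """Parse a percentage cell; interval strings ("0.05-0.1") -> midpoint.

    Expert tables report very sparse connections as a range rather than a
    single value; the midpoint is used for correlation.
    """
    if isinstance(value, str):
        m = _INTERVAL.match(value)
        if m:
            return 0.5 * (float(m.group(1)) + float(m.group(2)))
        return float(value.rstrip("% "))
    return float(value)


@dataclass
class AgreementReport:
    """Pairwise agreement between expert and automated percentage tables."""

    n_pairs: int
    pearson_r: float
    pearson_r_nonzero: float  # excluding pairs where both sides are zero
    n_pairs_nonzero: int
    outliers: list = field(default_factory=list)
    sparse: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "n_pairs": self.n_pairs,
            "pearson_r": self.pearson_r,
            "pearson_r_nonzero": self.pearson_r_nonzero,
            "n_pairs_nonzero": self.n_pairs_nonzero,
            "outliers": self.outliers,
            "sparse": self.sparse,
        }


def _paired(expert, auto):
    e = pd.Series({k: parse_percentage(v) for k, v in dict(expert).items()})
    a = pd.Series({k: parse_percentage(v) for k, v in dict(auto).items()})
    keys = sorted(set(e.index) & set(a.index))
    return e.loc[keys], a.loc[keys], keys


def percentage_agreement(expert, auto, outlier_threshold=5.0):
    """Pearson correlation between matched percentage tables.

    ``expert`` and ``auto`` map matched (injection, area) keys to
    percentages (interval strings allowed on the expert side).  The
    correlation is reported both over all matched pairs and with
    zero-on-both-sides pairs excluded, since it is ambiguous whether such
    pairs should count as agreement.  Pairs differing by more than
    ``outlier_threshold`` percentage points are listed as outliers.
    """
    e, a, keys = _paired(expert, auto)
    if len(keys) < 3:
        raise InsufficientData(f"need >= 3 matched pairs, got {len(keys)}")
    r = float(stats.pearsonr(e.to_numpy(), a.to_numpy())[0])
    nz = ~((e == 0) & (a == 0))
    if nz.sum() >= 3:
        r_nz = float(stats.pearsonr(e[nz].to_numpy(), a[nz].to_numpy())[0])
    else:
        r_nz = np.nan
    outliers = [
        {"key": str(k), "expert": float(e[k]), "auto": float(a[k])}
        for k in keys
        if abs(e[k] - a[k]) > outlier_threshold
    ]
    return AgreementReport(
        n_pairs=len(keys),
        pearson_r=r,
        pearson_r_nonzero=r_nz,
        n_pairs_nonzero=int(nz.sum()),
        outliers=outliers,
    )


def sparse_concordance(expert, auto, threshold=0.05):
    """Concordance of sparse connections at a percentage threshold.

    Counts, over matched keys: connections the expert scored <= threshold
    and how many of those the automated table also scored <= threshold;
    likewise for exact zeros.  Comparisons use <= at the default 0.05%.
    """
    e, a, keys = _paired(expert, auto)
    le_e = e <= threshold
    le_both = le_e & (a <= threshold)
    zero_e = e == 0
    zero_both = zero_e & (a == 0)
    frac = lambda num, den: float(num / den) if den else 1.0
    return {
        "threshold": threshold,
        "n_expert_le": int(le_e.sum()),
        "n_both_le": int(le_both.sum()),
        "fraction_le": frac(int(le_both.sum()), int(le_e.sum())),
        "n_expert_zero": int(zero_e.sum()),
        "n_both_zero": int(zero_both.sum()),
        "fraction_zero": frac(int(zero_both.sum()), int(zero_e.sum())),
    }
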