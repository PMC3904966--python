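"""Exact two-tailed Mann-Whitney U comparison and annotated summary tables.

Replicate group sizes here are small (typically 3-15), so the exact null
distribution of U is obtained by enumerating all C(n1+n2, n1) labelings
whenever n1 + n2 <= 16; larger samples fall back to the normal
approximation with tie correction.  Ties are handled with mid-ranks in
both regimes.  The two-tailed p-value counts labelings whose U is at
least as far from the null mean n1*n2/2 as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_LIMIT = 16


class StatsError(ValueError):
    pass


@dataclass
class ComparisonResult:
    u: float             # U statistic of the first group
    p: float             # two-tailed p-value
    alpha: float
    method: str          # 'exact' or 'asymptotic'
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def _u_statistic(values: np.ndarray, first_mask: np.ndarray) -> float:
    """Mid-rank U of the group selected by first_mask."""
    ranks = sps.rankdata(values)
    n1 = int(first_mask.sum())
    return float(ranks[first_mask].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(group_a, group_b, alpha: float = 0.05) -> ComparisonResult:
    """Two-tailed Mann-Whitney U test, exact by enumeration for small samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise StatsError("values must be finite")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    mask = np.zeros(n1 + n2, dtype=bool)
    mask[:n1] = True
    u_obs = _u_statistic(pooled, mask)
    mu = n1 * n2 / 2.0

    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; p = 1", stacklevel=2)
        return ComparisonResult(u=u_obs, p=1.0, alpha=alpha, method="degenerate",
                                n1=n1, n2=n2)

    if n1 + n2 <= EXACT_LIMIT:
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        observed_dev = abs(u_obs - mu)
        extreme = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= observed_dev - 1e-12:
                extreme += 1
        p = extreme / comb(n1 + n2, n1)
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return ComparisonResult(u=u_obs, p=min(p, 1.0), alpha=alpha, method=method,
                            n1=n1, n2=n2)


REFERENCE_PROTEIN = "alphaS"
REFERENCE_PH = 7.4
LOW_PH = 3.5


def significance_table(replicates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Summary table with between-protein (*) and between-pH (+) flags.

    ``replicates`` is a long table with columns protein_id, construct, ph,
    value (one row per replicate measurement).  Each output cell carries
    mean, SD and n; a star marks cells that differ from the reference
    protein at the same construct/pH, a plus marks low-pH cells that differ
    from the same construct at reference pH.
    """
    required = {"protein_id", "construct", "ph", "value"}
    missing = required - set(replicates.columns)
    if missing:
        raise StatsError(f"replicate table missing columns: {sorted(missing)}")

    groups = {key: g["value"].to_numpy()
              for key, g in replicates.groupby(["protein_id", "construct", "ph"])}
    rows = []
    for (prot, cons, ph), values in groups.items():
        star = plus = False
        ref_protein = groups.get((REFERENCE_PROTEIN, cons, ph))
        if prot != REFERENCE_PROTEIN and ref_protein is not None:
            star = mann_whitney_exact(values, ref_protein, alpha).significant
        ref_ph = groups.get((prot, cons, REFERENCE_PH))
        if ph == LOW_PH and ref_ph is not None:
            plus = mann_whitney_exact(values, ref_ph, alpha).significant
        rows.append({
            "protein_id": prot, "construct": cons, "ph": ph,
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
            "n": int(values.size),
            "vs_alphaS_significant": star,
            "vs_ph74_significant": plus,
            "annotation": ("*" if star else "") + ("+" if plus else ""),
        })
    return pd.DataFrame(rows).sort_values(["protein_id", "construct", "ph"],
                                          ignore_index=True)
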