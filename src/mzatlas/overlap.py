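"""Clone-sharing analyses across sites, isotypes and subsets.

Covers: clone x (site, isotype) abundance matrices with Ward clustering on
manhattan distances between per-column clone-frequency distributions;
directional sharing percentages between subset/site pairs; GC-membership
rates of clone classes; per-donor Fisher exact tests on IgA-containing
clones combined by Fisher's method (X^2 = -2 sum ln p_i ~ chi^2 on 2k df);
and the cross-donor public-sequence rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2, fisher_exact


def clone_abundance_matrix(records: pd.DataFrame, clone_col: str = "clone_id",
                           by: tuple[str, str] = ("site", "c_call")
                           ) -> pd.DataFrame:
    """Clones x (site, isotype) counts of unique sequences.

    Row sums equal clone unique-sequence totals.  Display with
    ``np.log10(m + 1)`` (zeros map to zero).
    """
    for col in (clone_col, *by):
        if col not in records.columns or records[col].isna().any():
            raise ValueError(f"unlabelled sequences in column {col!r}")
    m = (records.groupby([clone_col, *by], observed=True).size()
         .unstack(list(by), fill_value=0))
    m.columns = [f"{a}|{b}" for a, b in m.columns]
    return m


def hcluster_site_isotype(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward dendrogram over columns of the clone-abundance matrix.

    Each column is normalised to a clone-frequency distribution (counts
    divided by the column total); distances are manhattan (L1).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    totals = matrix.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-total column(s): "
                         f"{list(totals.index[totals == 0])}")
    freq = (matrix / totals).T.to_numpy(float)
    d = pdist(freq, metric="cityblock")
    return linkage(d, method="ward"), list(matrix.columns)


@dataclass
class SharingSummary:
    subset_a: str
    subset_b: str
    site_a: str
    site_b: str
    numerator: int
    denominator: int

    @property
    def percentage(self) -> float | None:
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator


def sharing_percentages(records: pd.DataFrame, subset_a: str, subset_b: str,
                        site_a: str, site_b: str,
                        clone_col: str = "clone_id",
                        weighted: bool = False) -> SharingSummary:
    """Percentage of subset-A sequences at site a whose clone contains at
    least one subset-B member at site b.

    Directional: sharing(A->B) and sharing(B->A) use different denominators
    and both are worth reporting.  ``weighted`` counts duplicate-weighted
    sequences instead of unique sequences.
    """
    a_rows = records[(records["subset"] == subset_a)
                     & (records["site"] == site_a)]
    b_clones = set(records.loc[(records["subset"] == subset_b)
                               & (records["site"] == site_b), clone_col])
    w = a_rows["duplicate_count"] if weighted else pd.Series(1, index=a_rows.index)
    shared = a_rows[clone_col].isin(b_clones)
    return SharingSummary(subset_a, subset_b, site_a, site_b,
                          int(w[shared].sum()), int(w.sum()))


def gc_membership_rates(records: pd.DataFrame, defining_subset: str,
                        gc_subset: str = "gc", clone_col: str = "clone_id",
                        galt_sites: tuple[str, ...] = ("PP", "A", "CF")
                        ) -> tuple[int, int, float]:
    """Of the clones containing the defining subset in GALT, how many also
    contain GC members?  Returns (n_clones, n_with_gc, percent)."""
    in_galt = records["site"].isin(galt_sites)
    cls = set(records.loc[in_galt & (records["subset"] == defining_subset),
                          clone_col])
    gc_clones = set(records.loc[in_galt & (records["subset"] == gc_subset),
                                clone_col])
    n = len(cls)
    n_gc = len(cls & gc_clones)
    pct = 100.0 * n_gc / n if n else 0.0
    return n, n_gc, pct


@dataclass
class OverlapTestResult:
    per_donor: pd.DataFrame   # donor, a_pos, a_tot, b_pos, b_tot, p
    combined_x2: float
    combined_df: int
    combined_p: float
    pooled_table: tuple[tuple[int, int], tuple[int, int]]
    pooled_p: float


def fisher_method(pvalues: list[float]) -> tuple[float, int, float]:
    """Combine independent p-values: X^2 = -2 sum ln p ~ chi^2(2k)."""
    ps = [min(max(p, np.finfo(float).tiny), 1.0) for p in pvalues]
    x2 = -2.0 * float(np.sum(np.log(ps)))
    df = 2 * len(ps)
    return x2, df, float(chi2.sf(x2, df))


def _contains_table(records: pd.DataFrame, class_a: str, class_b: str,
                    target_subset: str, clone_col: str,
                    galt_sites: tuple[str, ...]
                    ) -> tuple[int, int, int, int]:
    in_galt = records["site"].isin(galt_sites)
    a = set(records.loc[in_galt & (records["subset"] == class_a), clone_col])
    b = set(records.loc[in_galt & (records["subset"] == class_b), clone_col])
    tgt = set(records.loc[in_galt & (records["subset"] == target_subset),
                          clone_col])
    return len(a & tgt), len(a), len(b & tgt), len(b)


def iga_overlap_test(records: pd.DataFrame, class_a: str = "mz",
                     class_b: str = "igm_only", target_subset: str = "csm_iga",
                     clone_col: str = "clone_id",
                     galt_sites: tuple[str, ...] = ("PP", "A", "CF")
                     ) -> OverlapTestResult:
    """Do clones containing subset B cells include IgA members more often
    than clones containing subset A cells?

    Per donor: 2x2 table [clone class x contains-target-member], two-sided
    Fisher exact; donors with a degenerate (zero-margin) table are excluded.
    Combined by Fisher's method over the included donors; a pooled-table
    Fisher exact over all donors is reported alongside.
    """
    rows = []
    pooled = np.zeros(4, dtype=int)
    for donor, sub in records.groupby("donor"):
        a_pos, a_tot, b_pos, b_tot = _contains_table(
            sub, class_a, class_b, target_subset, clone_col, galt_sites)
        pooled += (a_pos, a_tot, b_pos, b_tot)
        table = [[a_pos, a_tot - a_pos], [b_pos, b_tot - b_pos]]
        degenerate = a_tot == 0 or b_tot == 0
        p = np.nan if degenerate else float(fisher_exact(table)[1])
        rows.append({"donor": donor, "a_pos": a_pos, "a_tot": a_tot,
                     "b_pos": b_pos, "b_tot": b_tot, "p": p,
                     "included": not degenerate})
    per_donor = pd.DataFrame(rows)
    included = per_donor.loc[per_donor["included"], "p"].tolist()
    if not included:
        raise ValueError("no donor with a non-degenerate table")
    x2, df, comb_p = fisher_method(included)
    a_pos, a_tot, b_pos, b_tot = pooled
    pooled_table = ((int(a_pos), int(a_tot - a_pos)),
                    (int(b_pos), int(b_tot - b_pos)))
    pooled_p = float(fisher_exact(np.array(pooled_table))[1])
    return OverlapTestResult(per_donor, x2, df, comb_p, pooled_table, pooled_p)


def public_clone_rate(records: pd.DataFrame) -> float:
    """Percentage of unique sequences whose exact nucleotide sequence occurs
    in more than one donor."""
    if records["donor"].nunique() < 2:
        raise ValueError("public-clone rate needs at least 2 donors")
    donors_per_seq = records.groupby("sequence")["donor"].nunique()
    public = set(donors_per_seq.index[donors_per_seq > 1])
    return 100.0 * records["sequence"].isin(public).mean()
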