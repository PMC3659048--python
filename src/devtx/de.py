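"""Count-based pairwise differential expression and stage-preferential calls.

For each gene and each pair of stage libraries a two-sided Fisher's exact
test is applied to the 2x2 table

    [[count_A, total_A - count_A],
     [count_B, total_B - count_B]]

built from the (rounded) raw read counts, with Benjamini-Hochberg FDR
control per stage pair.  A gene is differentially expressed when FDR <
``fdr_cut`` and the RPKM fold change exceeds ``fc_cut``; it is preferential
at one stage when it beats every other stage on both criteria.

The two-sided p-value is the sum of hypergeometric probabilities of all
tables (with the observed margins) no more probable than the observed one.
For small tables (grand total <= ``EXACT_LIMIT``) the tail is accumulated in
exact integer arithmetic; larger tables use log-pmf comparisons with a
1e-7 relative guard against ties broken by rounding, the convention used by
the classical implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR_CUT = 1e-3
DEFAULT_FC_CUT = 4.0          # pairwise DE; preferential calls use 2
PREFERENTIAL_FC_CUT = 2.0
DEFAULT_FOLD_EPS = 1e-3
EXACT_LIMIT = 2000            # grand total below which the exact integer path runs
_REL_GUARD = 1e-7


def fisher_pvalues_for_margins(total_a: int, total_b: int, k: int) -> np.ndarray:
    """Two-sided Fisher p-values for every table with the given margins.

    ``k = count_a + count_b`` successes split between libraries of sizes
    ``total_a`` and ``total_b``; entry ``i`` of the result is the p-value for
    the table with ``count_a = a_min + i`` where ``a_min = max(0, k - total_b)``.
    """
    m = total_a + total_b
    a_min = max(0, k - total_b)
    a_max = min(k, total_a)
    if a_max < a_min:
        raise ValueError("impossible margins")
    support = np.arange(a_min, a_max + 1)
    if m <= EXACT_LIMIT:
        weights = [math.comb(k, int(a)) * math.comb(m - k, total_a - int(a)) for a in support]
        total = sum(weights)
        order = sorted(range(len(weights)), key=weights.__getitem__)
        acc = 0
        cum = [0] * len(weights)
        for pos in order:
            acc += weights[pos]
            cum[pos] = acc
        # equal weights must share the same (inclusive) tail sum
        by_weight: Dict[int, int] = {}
        for pos in order:
            by_weight[weights[pos]] = cum[pos]
        return np.array([by_weight[weights[i]] / total for i in range(len(weights))])

    logpmf = (
        gammaln(k + 1)
        - gammaln(support + 1)
        - gammaln(k - support + 1)
        + gammaln(m - k + 1)
        - gammaln(total_a - support + 1)
        - gammaln(m - k - total_a + support + 1)
        + gammaln(total_a + 1)
        + gammaln(total_b + 1)
        - gammaln(m + 1)
    )
    pmf = np.exp(logpmf)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    # include all tables no more probable than the observed one (with guard)
    j = np.searchsorted(sorted_pmf, sorted_pmf * (1 + _REL_GUARD), side="right")
    pvals = np.empty(len(support))
    pvals[order] = cum[np.clip(j, 1, len(cum)) - 1]
    return np.minimum(pvals, 1.0)


def fisher_de(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided Fisher's exact p-value for one gene in two libraries."""
    for count, total in ((count_a, total_a), (count_b, total_b)):
        if count < 0 or total <= 0 or count > total:
            raise ValueError(
                f"invalid counts: count={count}, total={total}"
            )
    k = count_a + count_b
    a_min = max(0, k - total_b)
    pvals = fisher_pvalues_for_margins(total_a, total_b, k)
    return float(pvals[count_a - a_min])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    rpkm_a: np.ndarray, rpkm_b: np.ndarray, eps: float = DEFAULT_FOLD_EPS
) -> np.ndarray:
    """Larger-over-smaller RPKM ratio, stabilised by ``eps``."""
    a = np.asarray(rpkm_a, dtype=float) + eps
    b = np.asarray(rpkm_b, dtype=float) + eps
    return np.maximum(a, b) / np.minimum(a, b)


def call_de(
    fdr: np.ndarray,
    fold: np.ndarray,
    fdr_cut: float = DEFAULT_FDR_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
) -> np.ndarray:
    """DE call: FDR strictly below the cut and fold strictly above the cut."""
    return (np.asarray(fdr) < fdr_cut) & (np.asarray(fold) > fc_cut)


@dataclass
class PairwiseDEResult:
    """All-pairs Fisher DE results in long format plus per-pair lookups."""

    table: pd.DataFrame                              # gene, stage_a, stage_b, p, fdr, fold, direction, is_de
    fdr_lookup: Dict[Tuple[str, str], pd.Series]     # unordered pair -> per-gene FDR
    stages: List[str]

    def fdr(self, stage_a: str, stage_b: str) -> pd.Series:
        key = (stage_a, stage_b) if (stage_a, stage_b) in self.fdr_lookup else (stage_b, stage_a)
        return self.fdr_lookup[key]

    @property
    def de_gene_ids(self) -> List[str]:
        t = self.table
        return sorted(t.loc[t["is_de"], "gene"].unique())


def pairwise_de(
    counts: pd.DataFrame,
    library_totals: Mapping[str, float],
    rpkm: pd.DataFrame,
    fdr_cut: float = DEFAULT_FDR_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
    eps: float = DEFAULT_FOLD_EPS,
    fdr_scope: str = "per_pair",
) -> PairwiseDEResult:
    """Fisher's exact DE for every gene in every pair of stage libraries.

    ``counts`` holds per-gene fractional read counts (one column per stage);
    they are rounded half-up to integers because the test takes raw read
    numbers.  FDR is controlled per stage pair by default (``fdr_scope =
    'per_pair'``) or over all pairs jointly (``'global'``).
    """
    if fdr_scope not in ("per_pair", "global"):
        raise ValueError(f"unknown fdr_scope: {fdr_scope!r}")
    stages = list(counts.columns)
    genes = counts.index
    ints = np.floor(counts.to_numpy() + 0.5).astype(np.int64)  # round half-up
    totals = {s: int(round(library_totals[s])) for s in stages}

    frames = []
    for sa, sb in combinations(stages, 2):
        ca = ints[:, stages.index(sa)]
        cb = ints[:, stages.index(sb)]
        ta, tb = totals[sa], totals[sb]
        p = np.array([fisher_de(int(a), ta, int(b), tb) for a, b in zip(ca, cb)])
        ra = rpkm[sa].to_numpy()
        rb = rpkm[sb].to_numpy()
        fold = fold_change(ra, rb, eps=eps)
        direction = np.where(ra > rb, "up_a", np.where(rb > ra, "up_b", "tie"))
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "stage_a": sa,
                    "stage_b": sb,
                    "p": p,
                    "fold": fold,
                    "direction": direction,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if fdr_scope == "global":
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    else:
        table["fdr"] = np.nan
        for _, idx in table.groupby(["stage_a", "stage_b"]).groups.items():
            table.loc[idx, "fdr"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    table["is_de"] = call_de(table["fdr"].to_numpy(), table["fold"].to_numpy(), fdr_cut, fc_cut)

    fdr_lookup = {
        (sa, sb): pd.Series(
            sub["fdr"].to_numpy(), index=sub["gene"].to_numpy()
        ).reindex(genes)
        for (sa, sb), sub in table.groupby(["stage_a", "stage_b"])
    }
    cols = ["gene", "stage_a", "stage_b", "p", "fdr", "fold", "direction", "is_de"]
    return PairwiseDEResult(table=table[cols], fdr_lookup=fdr_lookup, stages=stages)


@dataclass
class StagePreferentialCall:
    gene_id: str
    preferred_stage: str
    min_fold: float
    max_fdr: float


def stage_preferential(
    pairwise: PairwiseDEResult,
    rpkm: pd.DataFrame,
    fdr_cut: float = DEFAULT_FDR_CUT,
    fold_cut: float = PREFERENTIAL_FC_CUT,
) -> pd.DataFrame:
    """Genes significantly higher at one stage than at every other stage.

    A gene is preferential at stage *s* iff, against every other stage *t*,
    the pair FDR is below ``fdr_cut``, expression is strictly higher at *s*,
    and RPKM(s) >= ``fold_cut`` x RPKM(t).  At most one stage can win, so
    each gene appears at most once.  Ties in RPKM block the call.
    """
    stages = pairwise.stages
    genes = rpkm.index
    r = rpkm[stages].to_numpy()
    fdr = np.empty((len(genes), len(stages), len(stages)))
    fdr[:] = np.nan
    for i, sa in enumerate(stages):
        for j, sb in enumerate(stages):
            if i < j:
                v = pairwise.fdr(sa, sb).to_numpy()
                fdr[:, i, j] = v
                fdr[:, j, i] = v

    rows = []
    for i, s in enumerate(stages):
        others = [j for j in range(len(stages)) if j != i]
        sig = np.all(fdr[:, i, others] < fdr_cut, axis=1)
        higher = np.all(r[:, [i]] > r[:, others], axis=1)
        folded = np.all(r[:, [i]] >= fold_cut * r[:, others], axis=1)
        hit = sig & higher & folded
        for g in np.nonzero(hit)[0]:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = r[g, i] / r[g, others]
            rows.append(
                StagePreferentialCall(
                    gene_id=genes[g],
                    preferred_stage=s,
                    min_fold=float(np.nanmin(ratios)) if np.isfinite(ratios).any() else np.inf,
                    max_fdr=float(fdr[g, i, others].max()),
                )
            )
    return pd.DataFrame(
        [(c.gene_id, c.preferred_stage, c.min_fold, c.max_fdr) for c in rows],
        columns=["gene", "preferred_stage", "min_fold", "max_fdr"],
    )


def collective_preferential(
    rpkm: pd.DataFrame,
    stage_subset: Sequence[str],
    pairwise: PairwiseDEResult,
    fdr_cut: float = DEFAULT_FDR_CUT,
    fold_cut: float = PREFERENTIAL_FC_CUT,
) -> List[str]:
    """Genes whose *minimum* RPKM over ``stage_subset`` beats every other stage.

    Included iff min RPKM over the subset is >= ``fold_cut`` x (and strictly
    above) the RPKM of every outside stage, with FDR < ``fdr_cut`` for every
    (subset stage, outside stage) pair.
    """
    stages = pairwise.stages
    subset = [s for s in stages if s in set(stage_subset)]
    outside = [s for s in stages if s not in set(stage_subset)]
    if not subset or not outside:
        raise ValueError("stage subset must be a non-empty proper subset")
    r = rpkm[stages]
    min_in = r[subset].min(axis=1)
    max_out = r[outside].max(axis=1)
    ok = (min_in >= fold_cut * max_out) & (min_in > max_out)
    for s in subset:
        for t in outside:
            ok &= pairwise.fdr(s, t).reindex(rpkm.index) < fdr_cut
    return sorted(rpkm.index[ok])
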