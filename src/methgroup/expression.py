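"""TPM normalization, one-vs-rest differential expression and hypergeometric
gene-set over-representation.

DE is a two-sided Welch t-test on log2(TPM + 1) of one molecular group
against all remaining samples; genes are flagged significant at
|log2FC| > 1 and raw p < 0.05, with Benjamini-Hochberg q reported alongside.
Enrichment is the classic one-sided hypergeometric over-representation test
over a fixed gene universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionCohort

__all__ = [
    "tpm",
    "differential_expression",
    "enrich",
    "volcano_table",
]

LOG2FC_THRESHOLD = 1.0
P_THRESHOLD = 0.05


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: per sample, length-normalized counts scaled
    to sum to 1e6."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for every gene")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero count column(s): {bad}")
    return rate.div(totals, axis=1) * 1e6


def differential_expression(
    tpm_matrix: pd.DataFrame,
    labels: np.ndarray,
    group: int,
    fc_threshold: float = LOG2FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """One-vs-rest DE for one group on log2(TPM + 1).

    Returns one row per gene: log2FC (group mean minus rest mean), two-sided
    Welch-t p, BH q over the genes of this table, and the significance flag
    |log2FC| > fc_threshold and p < p_threshold.
    """
    labels = np.asarray(labels)
    in_group = labels == group
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("both sides of the comparison need >= 2 samples")
    y = np.log2(tpm_matrix.to_numpy(dtype=float) + 1.0)
    a, b = y[:, in_group], y[:, ~in_group]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance on both sides: equal means -> p = 1; unequal -> p -> 0
    degenerate = np.isnan(p)
    if degenerate.any():
        eq = np.isclose(log2fc, 0.0)
        p = np.where(degenerate & eq, 1.0, p)
        p = np.where(degenerate & ~eq, 0.0, p)
        t = np.where(degenerate, 0.0, t)
    q = multipletests(p, method="fdr_bh")[1]
    significant = (np.abs(log2fc) > fc_threshold) & (p < p_threshold)
    return pd.DataFrame(
        {
            "gene_id": tpm_matrix.index,
            "group": group,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": q,
            "significant": significant,
        }
    ).set_index("gene_id")


def enrich(
    query: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    With N = |universe|, K = |set ∩ universe|, n = |query| and o the overlap,
    p = P(X >= o) for X ~ Hypergeom(N, K, n); q is BH across sets.  Gene
    sets are intersected with the universe; the query must be contained in
    the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside universe, e.g. {extra}")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        inset = members & universe
        K = len(inset)
        o = len(inset & query)
        if n == 0 or K == 0:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(o - 1, N, K, n))
        expected = K * n / N
        denom = (K - o) * (n - o)
        odds = (o * (N - K - n + o)) / denom if denom > 0 else np.inf
        rows.append((name, o, K, N, n, expected, odds, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "universe_size", "query_size",
                 "expected_overlap", "odds_ratio", "p"],
    )
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1] if len(df) else []
    return df.sort_values(["p", "set"]).reset_index(drop=True)


def volcano_table(de: pd.DataFrame,
                  fc_threshold: float = LOG2FC_THRESHOLD,
                  p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    """Plot-ready volcano classification: enriched / suppressed / ns."""
    out = de.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    cls = np.where(
        (out["log2fc"] > fc_threshold) & (out["p"] < p_threshold), "enriched",
        np.where(
            (out["log2fc"] < -fc_threshold) & (out["p"] < p_threshold),
            "suppressed", "ns",
        ),
    )
    out["class"] = cls
    return out
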