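"""Per-cytosine methylation calling.

A cytosine with ``meth`` methylated reads out of ``depth`` total is tested
against the bisulfite non-conversion error rate estimated from an
unmethylated control sequence (in plants, typically the chloroplast genome).
Under the null of no methylation every read reports methylated with
probability equal to the error rate, so the test is a one-sided binomial
upper tail; false discovery is controlled with Benjamini–Hochberg across all
tested sites of an accession.

Cytosine tables are pandas DataFrames with columns
``chrom, pos, strand, context, depth, meth`` (positions 0-based).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTEXTS = ("CG", "CHG", "CHH")


def estimate_error_rate(control: pd.DataFrame) -> float:
    """Pooled non-conversion rate from an unmethylated control.

    All control cytosines are pooled into a single ratio
    ``sum(meth) / sum(depth)``; per-site testing of the control is not
    meaningful because the control is unmethylated by assumption.

    Raises ``ValueError`` when the control carries no reads.
    """
    total = int(control["depth"].sum())
    if total <= 0:
        raise ValueError("control has zero total depth; cannot estimate error rate")
    return float(control["meth"].sum()) / total


def binomial_tail_p(meth: np.ndarray, depth: np.ndarray, error_rate: float) -> np.ndarray:
    """Exact one-sided upper tail P(X >= meth | n=depth, p=error_rate)."""
    return stats.binom.sf(np.asarray(meth) - 1, np.asarray(depth), error_rate)


def call_methylation(records: pd.DataFrame, error_rate: float, *,
                     alpha: float = 0.05, min_depth: int = 4,
                     per_context: bool = False) -> pd.DataFrame:
    """Call methylation states for one accession.

    Sites with ``depth < min_depth`` are dropped before testing.  Each
    retained site gets the exact binomial upper-tail p-value against
    ``error_rate``; q-values are Benjamini–Hochberg over all tested sites
    jointly across contexts (set ``per_context=True`` to stratify the FDR
    step within each context instead).  A site is called methylated by the
    textbook step-up rule (reject at q <= alpha).

    Returns a copy of the retained records with ``p``, ``q`` and
    ``methylated`` columns appended.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError(f"error_rate must be in (0, 1), got {error_rate}")
    out = records.loc[records["depth"] >= min_depth].copy()
    out["p"] = binomial_tail_p(out["meth"].to_numpy(), out["depth"].to_numpy(), error_rate)
    q = np.ones(len(out))
    rej = np.zeros(len(out), dtype=bool)
    if len(out):
        if per_context:
            ctx = out["context"].to_numpy()
            for c in np.unique(ctx):
                m = ctx == c
                rej[m], q[m], _, _ = multipletests(out["p"].to_numpy()[m],
                                                   alpha=alpha, method="fdr_bh")
        else:
            rej, q, _, _ = multipletests(out["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["methylated"] = rej
    return out


def context_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of methylated vs tested sites per context.

    Returns a DataFrame indexed by context with columns ``n_methylated``,
    ``n_tested`` and ``fraction`` (NaN for a context with no tested sites,
    which is the undefined flag).
    """
    rows = {}
    for c in CONTEXTS:
        sub = calls.loc[calls["context"] == c]
        n_tested = len(sub)
        n_meth = int(sub["methylated"].sum()) if n_tested else 0
        frac = n_meth / n_tested if n_tested else np.nan
        rows[c] = (n_meth, n_tested, frac)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["n_methylated", "n_tested", "fraction"])
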