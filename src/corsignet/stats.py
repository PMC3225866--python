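"""Paired cross-dataset statistics: Wilcoxon signed-rank and Fisher tests.

The cross-dataset stage compares a feature's per-dataset (normal, tumor)
value pairs with the paired Wilcoxon signed-rank test.  Two p-value routes
are implemented explicitly:

* ``exact`` — the exact two-sided tail of W+ under the null that each
  nonzero difference is independently positive or negative with
  probability 1/2.  Computed by a dynamic-programming convolution over
  integer ranks (identical to enumerating all 2^n sign assignments).
  Rank ties are broken deterministically by input order, which leaves W+
  well defined whenever tied |differences| do not mix signs.
* ``approx`` — Gaussian approximation with continuity correction 0.5 and
  the tie-corrected variance n(n+1)(2n+1)/24 - sum(t^3 - t)/48.

``auto`` uses the exact tail when the nonzero |differences| are free of
ties and the approximation otherwise.  Two-sided p is
min(1, 2 * min(lower tail, upper tail)).  No multiple-testing correction
is applied (features are reported with raw p at the conventional 0.05
threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSet

logger = logging.getLogger(__name__)

Mode = Literal["auto", "exact", "approx"]


@dataclass(frozen=True)
class PairedComparison:
    feature: str
    pairs: tuple[tuple[float, float], ...]
    n_used: int
    w_plus: float
    p_two_sided: float
    method: Literal["exact", "normal_approx"]
    tendency: Literal["Up", "Down"]


@dataclass(frozen=True)
class EnrichmentResult:
    overlap: int
    p_one_sided: float
    odds_ratio: float


def _exact_signed_rank_tails(ranks: Sequence[int], w: int) -> tuple[float, float]:
    """(P[W+ <= w], P[W+ >= w]) by DP over sign assignments of integer ranks."""
    total = sum(ranks)
    counts = [0] * (total + 1)
    counts[0] = 1
    for r in ranks:
        for s in range(total, r - 1, -1):
            counts[s] += counts[s - r]
    denom = 2 ** len(ranks)
    lower = sum(counts[: w + 1]) / denom
    upper = sum(counts[w:]) / denom
    return lower, upper


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]],
    mode: Mode = "auto",
    feature: str = "",
) -> PairedComparison:
    """Paired Wilcoxon signed-rank test on (normal, tumor) value pairs.

    Differences are tumor - normal; zero differences are dropped; |d| is
    ranked with midranks and W+ sums the ranks of positive differences.
    """
    pairs = tuple((float(a), float(b)) for a, b in pairs)
    d = np.array([t - n for n, t in pairs], dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    n = d.size
    absd = np.abs(d)
    midranks = sps.rankdata(absd)
    w_plus = float(midranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    tendency = "Up" if d.mean() > 0 else "Down"

    use_exact = mode == "exact" or (mode == "auto" and not has_ties)
    if use_exact:
        # deterministic integer ranks; ties broken by input order
        int_ranks = sps.rankdata(absd, method="ordinal").astype(int)
        w_int = int(int_ranks[d > 0].sum())
        lower, upper = _exact_signed_rank_tails(list(int_ranks), w_int)
        p = min(1.0, 2.0 * min(lower, upper))
        return PairedComparison(
            feature=feature, pairs=pairs, n_used=n, w_plus=float(w_int),
            p_two_sided=p, method="exact", tendency=tendency,
        )

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_sizes = np.unique(absd, return_counts=True)
    var -= float((tie_sizes**3 - tie_sizes).sum()) / 48.0
    cc = -0.5 if w_plus > mu else 0.5
    z = (w_plus - mu + cc) / np.sqrt(var)
    p = min(1.0, float(2.0 * sps.norm.sf(abs(z))))
    return PairedComparison(
        feature=feature, pairs=pairs, n_used=n, w_plus=w_plus,
        p_two_sided=p, method="normal_approx", tendency=tendency,
    )


def fisher_enrichment(
    query: GeneSet | frozenset[str],
    reference: GeneSet | frozenset[str],
    universe: GeneSet | frozenset[str],
) -> EnrichmentResult:
    """One-sided (greater) Fisher's exact test for gene-set overlap.

    The 2x2 table partitions the universe by query and reference
    membership; the p-value is the upper hypergeometric tail on the
    overlap.  The sample odds ratio accompanies it (inf when a
    complementary cell is empty).
    """
    q = query.symbols if isinstance(query, GeneSet) else frozenset(query)
    r = reference.symbols if isinstance(reference, GeneSet) else frozenset(reference)
    u = universe.symbols if isinstance(universe, GeneSet) else frozenset(universe)
    if not q <= u:
        raise ValueError("query is not a subset of the universe")
    if not r <= u:
        raise ValueError("reference is not a subset of the universe")
    overlap = len(q & r)
    table = [
        [overlap, len(q) - overlap],
        [len(r) - overlap, len(u) - len(q) - len(r) + overlap],
    ]
    odds, p = sps.fisher_exact(table, alternative="greater")
    return EnrichmentResult(overlap=overlap, p_one_sided=float(p), odds_ratio=float(odds))


def compare_feature_across_datasets(
    table: pd.DataFrame,
    mode: Mode = "auto",
    modes_by_feature: dict[str, Mode] | None = None,
) -> pd.DataFrame:
    """Cross-dataset paired comparison for every feature.

    ``table`` is tidy with columns ``dataset, feature, normal, tumor``.
    Returns one row per feature with cohort means, the tumor tendency and
    the Wilcoxon p (omitted when fewer than two datasets are available).
    Datasets missing one cohort value are excluded with a warning.
    ``modes_by_feature`` overrides the p-value route per feature.
    """
    required = {"dataset", "feature", "normal", "tumor"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for feat, sub in table.groupby("feature", sort=False):
        ok = sub.dropna(subset=["normal", "tumor"])
        if len(ok) < len(sub):
            missing = sorted(set(sub.dataset) - set(ok.dataset))
            logger.warning("feature %s: excluding dataset(s) %s", feat, missing)
        if ok.empty:
            continue
        normal_mean = float(ok.normal.mean())
        tumor_mean = float(ok.tumor.mean())
        row = {
            "feature": feat,
            "n_datasets": len(ok),
            "normal_mean": normal_mean,
            "tumor_mean": tumor_mean,
            "tendency": "Up" if tumor_mean > normal_mean else "Down",
            "p_two_sided": np.nan,
            "method": "",
        }
        if len(ok) >= 2:
            feat_mode = (modes_by_feature or {}).get(feat, mode)
            try:
                cmp = wilcoxon_signed_rank(
                    list(zip(ok.normal, ok.tumor)), mode=feat_mode, feature=feat
                )
            except ValueError as exc:
                logger.warning("feature %s: %s", feat, exc)
            else:
                row.update(
                    tendency=cmp.tendency,
                    p_two_sided=cmp.p_two_sided,
                    method=cmp.method,
                )
        rows.append(row)
    return pd.DataFrame(rows)


#: P-value route used when recomputing the published cross-dataset table:
#: the motif-count columns carry genuine ties (normal approximation); the
#: remaining features are continuous at source, so ties in their printed,
#: rounded values are rounding artifacts and the exact tail applies.
PUBLISHED_TABLE_MODES: dict[str, Mode] = {
    "integration_motif": "approx",
    "maintenance_motif": "approx",
}


def published_table_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Cross-dataset statistics of the published twenty-cohort feature table."""
    return compare_feature_across_datasets(
        table, mode="exact", modes_by_feature=PUBLISHED_TABLE_MODES
    )
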