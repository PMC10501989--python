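"""Gene-level hit calling for reporter-sorted screens.

Guide counts from the two sorted bins are turned into per-guide log2
fold changes (reporter-negative over reporter-positive, so that
knockouts of positive regulators of the reporter score positive), each
gene's guides are compared against the non-targeting (NT) guide
reference with a two-sided Wilcoxon rank-sum test, and evidence is
combined across screen replicates by averaging enrichment scores and
Fisher's method on the per-screen p-values.

The modelling surface is :class:`ScreenModel` / :class:`ScreenResults`;
the individual statistics (:func:`gene_rank_test`,
:func:`fisher_combine`, ...) are importable on their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import comb

from .quant import (
    BINS,
    NON_TARGETING,
    REPORTER_NEG,
    REPORTER_POS,
    CountTable,
    GuideLibrary,
    filter_low_counts,
)

POSITIVE_REGULATOR = "POSITIVE_REGULATOR"
NEGATIVE_REGULATOR = "NEGATIVE_REGULATOR"
NO_DIRECTION = "NONE"

EXACT = "EXACT"
NORMAL_APPROX = "NORMAL_APPROX"
AUTO = "AUTO"

#: smallest p fed to Fisher's method, keeping the statistic finite
P_FLOOR = 1e-300

#: AUTO switches from exact enumeration to the normal approximation when
#: the permutation null has more than this many assignments
AUTO_EXACT_LIMIT = 100_000


def normalize_log2fc(table: CountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-guide log2 fold change between sorted bins, per screen.

    For guide count ``c`` in a bin with library size ``N`` and ``G``
    guides, abundance is ``(c + pc) / (N + pc * G)``; the returned value
    is ``log2`` of the reporter-negative over reporter-positive
    abundance ratio.  The pseudocount keeps every value finite.

    Returns a DataFrame (guides x screens) of log2fc values.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    out = {}
    g = len(table.guides)
    for screen in table.screens:
        sub = table.screen_counts(screen)
        n_neg = float(sub[REPORTER_NEG].sum())
        n_pos = float(sub[REPORTER_POS].sum())
        if n_neg == 0 or n_pos == 0:
            raise ValueError(f"screen {screen!r}: zero library size in a bin")
        neg = (sub[REPORTER_NEG] + pseudocount) / (n_neg + pseudocount * g)
        pos = (sub[REPORTER_POS] + pseudocount) / (n_pos + pseudocount * g)
        out[screen] = np.log2(neg / pos)
    return pd.DataFrame(out)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of the permutation null.

    Pooled values are midranked (ties get the average rank); the null is
    the distribution of the first sample's rank sum over all
    C(n+m, n) equally likely assignments of ranks to samples.  Doubled
    midranks are integers, so the distribution is built exactly with a
    generating-function recurrence (one coefficient per achievable
    doubled rank sum x chosen-count) — algebraically identical to full
    enumeration.  Two-sided p doubles the smaller tail, capped at 1;
    both tails include the observed value.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * sps.rankdata(pooled)).astype(np.int64)  # doubled midranks
    w_obs = int(ranks2[:n].sum())
    max_s = int(ranks2.sum())
    # dist[j, s] = number of j-subsets of the doubled ranks summing to s
    dist = np.zeros((n + 1, max_s + 1))
    dist[0, 0] = 1.0
    for r in ranks2:
        dist[1 : n + 1, r:] += dist[0:n, : max_s + 1 - r]
    row = dist[n]
    total = row.sum()
    p_low = row[: w_obs + 1].sum() / total
    p_high = row[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def gene_rank_test(
    gene_fcs: Sequence[float],
    nt_fcs: Sequence[float],
    mode: Literal["EXACT", "NORMAL_APPROX", "AUTO"] = AUTO,
) -> float:
    """Two-sided Wilcoxon rank-sum p of a gene's guide log2fc values
    against the non-targeting reference.

    ``EXACT`` enumerates the tie-aware permutation null; ``NORMAL_APPROX``
    uses the standard normal approximation with tie-corrected variance
    and continuity correction; ``AUTO`` is exact while the null has at
    most 1e5 assignments.
    """
    x = np.asarray(gene_fcs, dtype=float)
    y = np.asarray(nt_fcs, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0  # total tie: no evidence either way
    if mode == AUTO:
        mode = EXACT if comb(len(x) + len(y), len(x)) <= AUTO_EXACT_LIMIT else NORMAL_APPROX
    if mode == EXACT:
        return _exact_ranksum_p(x, y)
    if mode == NORMAL_APPROX:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return float(min(1.0, res.pvalue))
    raise ValueError(f"unknown mode {mode!r}")


def enrichment_score(gene_fcs: Sequence[float]) -> float:
    """Gene enrichment score: the arithmetic mean of guide log2fc values."""
    arr = np.asarray(gene_fcs, dtype=float)
    if arr.size == 0:
        raise ValueError("empty fold-change list")
    return float(arr.mean())


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: X = -2 sum(ln p_i) ~ chi-square(2k) under the null.

    Returns ``(fisher_stat, combined_p)``; ``k = 1`` reduces to the
    input p.  p values must lie in (0, 1] — floor at :data:`P_FLOOR`
    before calling if needed.
    """
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = float(-2.0 * np.log(ps).sum())
    return x, float(sps.chi2.sf(x, 2 * ps.size))


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


@dataclass
class ScreenConfig:
    """Knobs of the hit-calling procedure.

    count_threshold
        Guides below this count in either sorted bin are excluded per
        screen (20 for genome-wide screens, 50 for focused ones).
    pseudocount
        Added to counts and (scaled) to library sizes before log2.
    min_guides
        Genes with fewer surviving guides in a screen are not tested
        there.
    alpha
        Hit-calling significance level on the combined p.
    mode
        Rank-test mode: EXACT, NORMAL_APPROX or AUTO.
    """

    count_threshold: int = 20
    pseudocount: float = 1.0
    min_guides: int = 2
    alpha: float = 0.05
    mode: str = AUTO

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class ScreenModel:
    """Gene-level hit-calling model for a reporter-sorted CRISPR screen.

    Parameters
    ----------
    table
        Guide x (screen, bin) counts; every screen must carry both the
        reporter-positive and reporter-negative bin.
    library
        Guide library mapping guides to genes; must contain NT guides.
    config
        Procedure knobs; defaults follow the standard genome-wide
        settings.

    Examples
    --------
    >>> model = ScreenModel(table, library)            # doctest: +SKIP
    >>> res = model.fit()                              # doctest: +SKIP
    >>> res.gene_results.head()                        # doctest: +SKIP
    """

    def __init__(
        self,
        table: CountTable,
        library: GuideLibrary,
        config: Optional[ScreenConfig] = None,
    ):
        self.table = table
        self.library = library
        self.config = config or ScreenConfig()
        if not library.non_targeting_ids:
            raise ValueError("library has no non-targeting guides")

    @classmethod
    def from_files(cls, counts_tsv, library_csv, config=None) -> "ScreenModel":
        lib = GuideLibrary.from_csv(library_csv)
        table = CountTable.from_tsv(counts_tsv, lib)
        return cls(table, lib, config)

    def fit(self) -> "ScreenResults":
        cfg = self.config
        retained = filter_low_counts(self.table, cfg.count_threshold)
        log2fc = normalize_log2fc(self.table, cfg.pseudocount)
        nt_set = set(self.library.non_targeting_ids)

        per_screen_rows = []
        per_gene_screens: dict[str, dict[str, tuple[float, float, int]]] = {}
        for screen in self.table.screens:
            kept = retained[screen]
            nt_kept = [g for g in kept if g in nt_set]
            if not nt_kept:
                raise ValueError(
                    f"screen {screen!r}: no non-targeting guides survive the "
                    f"count filter"
                )
            nt_fcs = log2fc.loc[nt_kept, screen].to_numpy()
            by_gene: dict[str, list[float]] = {}
            for gid in kept:
                gene = self.library.gene_of(gid)
                if gene == NON_TARGETING:
                    continue
                by_gene.setdefault(gene, []).append(float(log2fc.at[gid, screen]))
            for gene, fcs in by_gene.items():
                if len(fcs) < cfg.min_guides:
                    continue
                score = enrichment_score(fcs)
                p = gene_rank_test(fcs, nt_fcs, cfg.mode)
                per_screen_rows.append(
                    {
                        "gene": gene,
                        "screen": screen,
                        "n_guides": len(fcs),
                        "enrichment_score": score,
                        "p_value": p,
                    }
                )
                per_gene_screens.setdefault(gene, {})[screen] = (score, p, len(fcs))

        all_genes = sorted(
            {
                self.library.gene_of(g)
                for g in self.library.guide_ids
                if self.library.gene_of(g) != NON_TARGETING
            }
        )
        rows = []
        for gene in all_genes:
            screens = per_gene_screens.get(gene, {})
            if not screens:
                rows.append(
                    {
                        "gene": gene,
                        "n_screens": 0,
                        "mean_enrichment": np.nan,
                        "fisher_stat": np.nan,
                        "combined_p": 1.0,
                        "direction": NO_DIRECTION,
                        "untestable": True,
                    }
                )
                continue
            scores = [v[0] for v in screens.values()]
            ps = [max(v[1], P_FLOOR) for v in screens.values()]
            mean_enr = float(np.mean(scores))
            stat, combined = fisher_combine(ps)
            direction = (
                POSITIVE_REGULATOR
                if mean_enr > 0
                else NEGATIVE_REGULATOR
                if mean_enr < 0
                else NO_DIRECTION
            )
            rows.append(
                {
                    "gene": gene,
                    "n_screens": len(screens),
                    "mean_enrichment": mean_enr,
                    "fisher_stat": stat,
                    "combined_p": combined,
                    "direction": direction,
                    "untestable": False,
                }
            )
        gene_df = pd.DataFrame(rows)
        testable = ~gene_df["untestable"]
        q = np.full(len(gene_df), np.nan)
        if testable.any():
            q[testable.to_numpy()] = bh_qvalues(
                gene_df.loc[testable, "combined_p"].to_numpy()
            )
        gene_df["q_value"] = q
        # deterministic ordering: p asc, |score| desc, gene name
        gene_df["_abs"] = gene_df["mean_enrichment"].abs().fillna(-1.0)
        gene_df = (
            gene_df.sort_values(
                ["combined_p", "_abs", "gene"], ascending=[True, False, True]
            )
            .drop(columns="_abs")
            .reset_index(drop=True)
        )
        per_screen_df = pd.DataFrame(
            per_screen_rows,
            columns=["gene", "screen", "n_guides", "enrichment_score", "p_value"],
        )
        return ScreenResults(self, gene_df, per_screen_df, retained, log2fc)


class ScreenResults:
    """Fitted hit-calling results.

    Attributes
    ----------
    gene_results
        One row per gene: n_screens, mean_enrichment, fisher_stat,
        combined_p, q_value, direction — sorted by combined_p.
    per_screen
        One row per (gene, screen) actually tested.
    retained_guides
        Per-screen guide lists surviving the count filter.
    log2fc
        The guide x screen fold-change matrix used for testing.
    """

    def __init__(self, model, gene_results, per_screen, retained_guides, log2fc):
        self.model = model
        self.gene_results = gene_results
        self.per_screen = per_screen
        self.retained_guides = retained_guides
        self.log2fc = log2fc

    def hits(self, alpha: Optional[float] = None, side: str = "any") -> pd.DataFrame:
        """Genes with combined_p < alpha, optionally one direction only."""
        alpha = self.model.config.alpha if alpha is None else alpha
        df = self.gene_results
        mask = df["combined_p"] < alpha
        if side != "any":
            mask &= df["direction"] == side
        return df[mask]

    def volcano_table(self, alpha: Optional[float] = None, side: str = "any") -> pd.DataFrame:
        """(gene, x, y, hit) table: x = mean enrichment, y = -log10 p."""
        alpha = self.model.config.alpha if alpha is None else alpha
        df = self.gene_results
        y = -np.log10(df["combined_p"].to_numpy())
        hit = (df["combined_p"] < alpha).to_numpy()
        if side != "any":
            hit &= (df["direction"] == side).to_numpy()
        return pd.DataFrame(
            {
                "gene": df["gene"],
                "mean_enrichment": df["mean_enrichment"],
                "neg_log10_p": y,
                "hit": hit,
            }
        ).reset_index(drop=True)

    def plot_volcano(self, ax=None, alpha: Optional[float] = None, side: str = "any"):
        """Volcano plot: enrichment score vs -log10 combined p."""
        import matplotlib.pyplot as plt

        tab = self.volcano_table(alpha, side)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(
            tab.loc[~tab.hit, "mean_enrichment"],
            tab.loc[~tab.hit, "neg_log10_p"],
            s=8,
            c="0.6",
            label="not significant",
        )
        ax.scatter(
            tab.loc[tab.hit, "mean_enrichment"],
            tab.loc[tab.hit, "neg_log10_p"],
            s=12,
            c="crimson",
            label="hit",
        )
        ax.set_xlabel("mean enrichment (log2 reporter-neg / reporter-pos)")
        ax.set_ylabel("-log10 combined p")
        ax.legend(frameon=False)
        return ax

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the top-ranked genes."""
        cfg = self.model.config
        df = self.gene_results
        tested = df[~df["untestable"]]
        lines = [
            "Reporter-sorted screen hit calling",
            "==================================",
            f"screens combined:    {len(self.model.table.screens)}",
            f"genes tested:        {len(tested)} / {len(df)}",
            f"count threshold:     {cfg.count_threshold}",
            f"rank-test mode:      {cfg.mode}",
            f"hits (p < {cfg.alpha:g}):    {int((tested['combined_p'] < cfg.alpha).sum())}",
            "",
            "top genes by combined p:",
        ]
        cols = ["gene", "n_screens", "mean_enrichment", "combined_p", "q_value", "direction"]
        lines.append(tested.head(top)[cols].to_string(index=False))
        return "\n".join(lines)


def run_screen_analysis(
    table: CountTable,
    library: GuideLibrary,
    config: Optional[ScreenConfig] = None,
) -> ScreenResults:
    """Functional entry point: build a :class:`ScreenModel` and fit it."""
    return ScreenModel(table, library, config).fit()
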