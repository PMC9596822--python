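"""Pooled-screen enrichment analysis with a non-targeting control null.

The pipeline goes: normalize counts -> per-guide log2 fold change
(treated vs. pre-treatment baseline) -> center on the non-targeting
control median -> empirical control-null p-values -> site-level
aggregation with a modified robust rank aggregation (alpha-RRA) score
and permutation significance, Benjamini-Hochberg corrected.

The alpha-RRA statistic follows the MAGeCK approach: guide p-values are
converted to percentiles among all targeting guides; for a site with k
guides and sorted percentiles u_(1) <= ... <= u_(k), only u_(j) <= alpha
contribute, and

    rho = min_j  P( Beta(j, k - j + 1) <= u_(j) )

i.e. the smallest order-statistic tail probability among the skewed
ranks; rho = 1 when no guide passes alpha.  Significance comes from
permutations drawing k percentiles from the pool of targeting guides.
Instead of a negative-binomial test, guide-level p-values come from the
empirical distribution of the non-targeting controls, which keeps the
null assumption-free and self-contained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Guide x sample read counts with sample roles and control flags.

    ``counts`` is indexed by guide id; ``roles`` maps sample name to
    ``"baseline"`` or ``"treated"``; ``is_control`` flags non-targeting
    guides.
    """

    counts: pd.DataFrame
    roles: pd.Series
    is_control: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.roles.index)
        if missing:
            raise ValueError(f"samples without a role: {sorted(missing)}")
        bad = set(self.roles.loc[list(self.counts.columns)]) - {"baseline", "treated"}
        if bad:
            raise ValueError(f"invalid roles: {sorted(bad)}")
        for role in ("baseline", "treated"):
            if not len(self.samples(role)):
                raise ValueError(f"need at least one {role} sample")
        self.is_control = self.is_control.reindex(self.counts.index).fillna(False).astype(bool)

    def samples(self, role: str) -> list[str]:
        return [c for c in self.counts.columns if self.roles[c] == role]

    @property
    def n_guides(self) -> int:
        return self.counts.shape[0]


def normalize_counts(
    matrix: CountMatrix, method: Literal["total", "control_median"] = "control_median"
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize a count matrix; returns (normalized counts, size factors).

    ``total`` scales every sample to counts-per-million.
    ``control_median`` uses a median-of-ratios factor computed over the
    non-targeting controls (each control's counts divided by its
    geometric mean across samples), which is robust to a large fraction
    of guides shifting under selection.  Falls back to ``total`` with a
    warning when fewer than 10 controls are present.
    """
    counts = matrix.counts.astype(float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    if method == "control_median":
        ctrl = counts.loc[matrix.is_control]
        if ctrl.shape[0] < 10:
            logger.warning(
                "only %d control guides; falling back to total-count normalization",
                ctrl.shape[0],
            )
            method = "total"
        else:
            # median-of-ratios over controls with nonzero geometric mean
            logg = np.log(ctrl.where(ctrl > 0))
            gm = np.exp(logg.mean(axis=1))
            usable = gm > 0
            ratios = ctrl.loc[usable].div(gm[usable], axis=0)
            factors = ratios.median(axis=0)
            if (factors <= 0).any():
                raise ValueError("non-positive control-median size factor")
    if method == "total":
        factors = counts.sum(axis=0) / 1e6
    return counts.div(factors, axis=1), factors.rename("size_factor")


def guide_log2fc(
    normalized: pd.DataFrame,
    treated: Iterable[str],
    baseline: Iterable[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-guide log2 fold change of treated over baseline means.

    Replicates are averaged on the normalized scale before the ratio;
    the pseudocount keeps the ratio finite at zero counts.
    """
    treated, baseline = list(treated), list(baseline)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    for s in treated + baseline:
        if s not in normalized.columns:
            raise KeyError(f"sample {s!r} not in matrix")
    mt = normalized[treated].mean(axis=1)
    mb = normalized[baseline].mean(axis=1)
    return np.log2((mt + pseudocount) / (mb + pseudocount)).rename("log2fc")


def enrichment_table(
    matrix: CountMatrix,
    method: Literal["total", "control_median"] = "control_median",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-guide enrichment statistics.

    Columns: baseline_mean, treated_mean, log2fc, centered_lfc (control
    median subtracted), p_enriched / p_depleted (empirical control-null,
    see :func:`empirical_pvalues`), is_control.
    """
    normalized, _ = normalize_counts(matrix, method)
    treated = matrix.samples("treated")
    baseline = matrix.samples("baseline")
    lfc = guide_log2fc(normalized, treated, baseline, pseudocount)
    is_ctrl = matrix.is_control
    if not is_ctrl.any():
        raise ValueError("no control guides; control-centered statistics impossible")
    centered = lfc - lfc[is_ctrl].median()
    table = pd.DataFrame(
        {
            "baseline_mean": normalized[baseline].mean(axis=1),
            "treated_mean": normalized[treated].mean(axis=1),
            "log2fc": lfc,
            "centered_lfc": centered,
            "is_control": is_ctrl,
        }
    )
    table["p_enriched"] = empirical_pvalues(table, "enriched")
    table["p_depleted"] = empirical_pvalues(table, "depleted")
    return table


def empirical_pvalues(table: pd.DataFrame, side: Literal["enriched", "depleted"]) -> pd.Series:
    """Control-null empirical p-values for every guide.

    For the enriched side, ``p_g = (1 + #{controls with LFC >= LFC_g})
    / (1 + n_controls)``; the depleted side uses <=.  The +1 smoothing
    keeps p in (0, 1].
    """
    if side not in ("enriched", "depleted"):
        raise ValueError(f"side must be 'enriched' or 'depleted', got {side!r}")
    ctrl = np.sort(table.loc[table["is_control"], "centered_lfc"].to_numpy())
    n_ctrl = len(ctrl)
    if n_ctrl < 10:
        raise ValueError(f"need >= 10 control guides for an empirical null, have {n_ctrl}")
    x = table["centered_lfc"].to_numpy()
    if side == "enriched":
        n_ge = n_ctrl - np.searchsorted(ctrl, x, side="left")
        p = (1.0 + n_ge) / (1.0 + n_ctrl)
    else:
        n_le = np.searchsorted(ctrl, x, side="right")
        p = (1.0 + n_le) / (1.0 + n_ctrl)
    return pd.Series(p, index=table.index, name=f"p_{side}")


def call_enriched(table: pd.DataFrame, fold_threshold: float = 2.0) -> list[str]:
    """Targeting guides enriched beyond a fold threshold over controls.

    A guide is called when its control-centered log2 fold change exceeds
    ``log2(fold_threshold)``; controls are never returned.
    """
    if not table["is_control"].any():
        raise ValueError("no control guides; centering impossible")
    mask = (~table["is_control"]) & (table["centered_lfc"] > np.log2(fold_threshold))
    return list(table.index[mask])


@dataclass(frozen=True)
class SiteScore:
    """Site-level aggregated enrichment result."""

    site: str
    n_guides: int
    rho: float
    p_value: float
    q_value: float
    direction: str  # enriched | depleted


def _rho_scores(u_sorted: np.ndarray, alpha: float) -> float:
    """Modified RRA score for one site from sorted percentiles."""
    k = len(u_sorted)
    j = np.arange(1, k + 1)
    mask = u_sorted <= alpha
    if not mask.any():
        return 1.0
    probs = stats.beta.cdf(u_sorted[mask], j[mask], k - j[mask] + 1)
    return float(probs.min())


def _null_rho(
    pool: np.ndarray, k: int, n_perm: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Null rho distribution for sites of k guides: random draws from the
    percentile pool."""
    draws = rng.choice(pool, size=(n_perm, k), replace=True)
    draws.sort(axis=1)
    j = np.arange(1, k + 1)
    beta = stats.beta.cdf(draws, j, k - j + 1)
    beta = np.where(draws <= alpha, beta, np.inf)
    rho = beta.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def rra_site_scores(
    pvalues: pd.Series,
    site_of_guide: pd.Series,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "enriched",
    tiebreak: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate guide p-values to site-level alpha-RRA scores.

    ``pvalues`` is indexed by guide id over all *targeting* guides (one
    direction at a time); ``site_of_guide`` maps guide id -> site key.
    Empirical control-null p-values are discrete (atoms of 1/(1+n_ctrl)),
    so ``tiebreak`` — a same-indexed series where smaller means stronger
    evidence, typically the negated centered LFC — orders guides within
    a p-value atom.  Tied guides are exchangeable under the null, so the
    tiebreak leaves percentiles uniform while letting strong hits keep
    their rank resolution.  Without it, ties get average ranks.
    Returns a DataFrame indexed by site with columns n_guides, rho,
    p_value (permutation, +1 smoothed), q_value (BH), direction, sorted
    by p then rho.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    guides = pvalues.index
    site_of_guide = site_of_guide.reindex(guides)
    orphan = site_of_guide.isna()
    if orphan.any():
        logger.warning("%d guides without a site are ignored", int(orphan.sum()))
        guides = guides[~orphan]
    p = pvalues.loc[guides].to_numpy(dtype=float)
    if tiebreak is None:
        # percentiles among all targeting guides; average ranks break ties
        u = stats.rankdata(p, method="average") / len(p)
    else:
        tb = tiebreak.reindex(guides).to_numpy(dtype=float)
        order = np.lexsort((tb, p))
        ranks = np.empty(len(p), dtype=float)
        ranks[order] = np.arange(1, len(p) + 1)
        u = ranks / len(p)
    u_of_guide = pd.Series(u, index=guides)

    rng = np.random.default_rng(seed)
    groups = u_of_guide.groupby(site_of_guide.loc[guides])
    sizes = groups.size()
    null_by_k = {
        int(k): _null_rho(u, int(k), n_perm, alpha, rng) for k in sorted(sizes.unique())
    }
    rows = []
    for site_key, uu in groups:
        u_sorted = np.sort(uu.to_numpy())
        rho = _rho_scores(u_sorted, alpha)
        null = null_by_k[len(u_sorted)]
        pval = (1.0 + np.count_nonzero(null <= rho)) / (1.0 + n_perm)
        rows.append({"site": site_key, "n_guides": len(u_sorted), "rho": rho, "p_value": pval})
    out = pd.DataFrame(rows).set_index("site")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["direction"] = direction
    return out.sort_values(["p_value", "rho"])


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def analyze_screen(
    matrix: CountMatrix,
    site_of_guide: pd.Series,
    method: Literal["total", "control_median"] = "control_median",
    pseudocount: float = 1.0,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """End-to-end analysis: guide table, hit calls, site scores.

    Returns a dict with keys ``guides`` (enrichment table), ``hits``
    (twofold-enriched guide ids), and ``sites`` (concatenated enriched
    and depleted site score tables).
    """
    table = enrichment_table(matrix, method, pseudocount)
    hits = call_enriched(table, fold_threshold)
    targeting = table.index[~table["is_control"]]
    scores = []
    for direction, col, sign in (
        ("enriched", "p_enriched", -1.0),
        ("depleted", "p_depleted", 1.0),
    ):
        scores.append(
            rra_site_scores(
                table.loc[targeting, col],
                site_of_guide,
                alpha=alpha,
                n_perm=n_perm,
                seed=seed,
                direction=direction,
                tiebreak=sign * table.loc[targeting, "centered_lfc"],
            )
        )
    return {"guides": table, "hits": hits, "sites": pd.concat(scores)}


def overlap_counts(
    set_a: Iterable, set_b: Iterable, set_c: Iterable | None = None
) -> dict[str, int]:
    """Venn-region sizes for two or three sets of site keys."""
    a, b = set(set_a), set(set_b)
    if set_c is None:
        return {
            "A_only": len(a - b),
            "B_only": len(b - a),
            "AB": len(a & b),
        }
    c = set(set_c)
    return {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB_only": len((a & b) - c),
        "AC_only": len((a & c) - b),
        "BC_only": len((b & c) - a),
        "ABC": len(a & b & c),
    }
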