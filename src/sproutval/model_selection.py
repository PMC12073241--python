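"""All-subsets multiple regression of across-environment GI on stable markers.

Because candidate markers can be linked or collinear, every non-empty
subset of the stable-marker pool (one representative per complete-LD
group) is fitted by OLS on tolerant-allele indicators and ranked by the
least-squares Akaike information criterion

    AIC = n * ln(RSS / n) + 2 * (k + 1)

with k predictors plus an intercept (the error-variance term adds a
constant across models and drops out of rankings).  Lower AIC is
better; the top models are reported with per-marker tolerant-allele
effects and PVE = R^2 x 100.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_POOL = 20


@dataclass(frozen=True)
class ModelCandidate:
    marker_subset: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    pve: float
    aic: float
    rank: int = 0


def ols_aic(rss: float, n: int, k: int) -> float:
    """Least-squares AIC, ``n*ln(RSS/n) + 2*(k+1)``, k = predictor count.

    Adding a predictor that leaves RSS unchanged therefore raises AIC by
    exactly 2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rss = max(rss, 1e-300)  # guard log(0) on perfect fits
    return float(n * np.log(rss / n) + 2.0 * (k + 1))


def candidate_pool(stability: pd.DataFrame, ld_groups: list[list[str]]) -> list[str]:
    """Stable markers with one representative per complete-LD group.

    ``stability`` is the table from
    :func:`sproutval.association.classify_stability`.  Within an LD
    group the first stable member (input order) represents the group;
    the rest are redundant and dropped.
    """
    stable = stability.loc[stability["stable"], "marker_id"].tolist()
    stable_set = set(stable)
    drop = set()
    for group in ld_groups:
        members = [m for m in group if m in stable_set]
        drop.update(members[1:])
    pool = [m for m in stable if m not in drop]
    if not pool:
        raise ValueError("candidate pool is empty: no stable markers")
    return pool


def tolerant_indicator_matrix(calls: pd.DataFrame, pool: list[str],
                              tolerant_alleles: dict[str, str]) -> pd.DataFrame:
    """0/1 tolerant-allele indicators, complete cases over the pool.

    Genotypes missing a homozygous call at any pool marker are excluded
    so that every subset model is fitted on one common genotype set and
    AIC values are comparable across subsets.
    """
    from sproutval.association import _allele_classes

    cols = {}
    for mid in pool:
        al = _allele_classes(calls[mid])
        cols[mid] = (al == tolerant_alleles[mid]).where(al.notna())
    X = pd.DataFrame(cols, index=calls.index).dropna()
    return X.astype(float)


def all_subsets_regression(blups: pd.DataFrame, indicators: pd.DataFrame,
                           k_top: int = 10) -> list[ModelCandidate]:
    """Fit every non-empty marker subset by OLS and rank by AIC.

    Parameters
    ----------
    blups
        Across-environment BLUP table (genotype_id, blup).
    indicators
        Tolerant-allele indicator matrix from
        :func:`tolerant_indicator_matrix` (complete cases).
    k_top
        Number of top-ranked models to return.

    Rank-deficient (collinear) subsets are skipped with a log entry.
    AIC ties below 1e-9 break toward the smaller subset, then
    lexicographic marker order.
    """
    pool = list(indicators.columns)
    p = len(pool)
    if p > MAX_POOL:
        raise ValueError(f"pool of {p} markers exceeds the 2^p guard ({MAX_POOL})")
    merged = blups.set_index("genotype_id")[["blup"]].join(indicators, how="inner")
    y = merged["blup"].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 genotypes with complete calls")
    Xfull = merged[pool].to_numpy(dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))

    candidates = []
    n_skipped = 0
    for size in range(1, p + 1):
        for subset in itertools.combinations(range(p), size):
            X = np.column_stack([np.ones(n), Xfull[:, subset]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                n_skipped += 1
                logger.info("skipping singular subset %s",
                            tuple(pool[i] for i in subset))
                continue
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            rss = float(resid @ resid)
            aic = ols_aic(rss, n, size)
            pve = 100.0 * (1.0 - rss / tss) if tss > 0 else 0.0
            names = tuple(pool[i] for i in subset)
            candidates.append((aic, size, names, beta, pve))
    if n_skipped:
        logger.info("skipped %d singular subsets of %d", n_skipped, 2 ** p - 1)

    candidates.sort(key=lambda c: (round(c[0] / 1e-9) * 1e-9, c[1], c[2]))
    out = []
    for rank, (aic, size, names, beta, pve) in enumerate(candidates[:k_top], start=1):
        out.append(ModelCandidate(
            marker_subset=names,
            coefficients={m: float(b) for m, b in zip(names, beta[1:])},
            intercept=float(beta[0]),
            pve=pve, aic=aic, rank=rank))
    return out


def models_table(models: list[ModelCandidate], pool: list[str]) -> pd.DataFrame:
    """Top-models report: one row per model, effect per marker column, PVE, AIC."""
    rows = []
    for m in models:
        row = {"model": m.rank}
        for mid in pool:
            row[mid] = m.coefficients.get(mid, np.nan)
        row["pve"] = m.pve
        row["aic"] = m.aic
        rows.append(row)
    return pd.DataFrame(rows)
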