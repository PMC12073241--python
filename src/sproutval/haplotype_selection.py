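"""Haplotype-class comparison and selection-efficiency evaluation.

For each top regression model, genotypes with complete homozygous calls
at the model's markers are partitioned into multi-locus haplotype
classes (one allele per marker, each tagged tolerant or susceptible).
Class means of GI are compared under the mixed model

    Y_ijk = mu + haplotype_i + e_j + g_k(haplotype_i)
            + haplotype_i x e_j + eps_ijk

with haplotype, environment and their interaction fixed and genotype
within haplotype random.  With complete environment coverage of the
per-environment BLUP response, haplotype comparisons resolve to the
genotype-within-haplotype stratum (containment degrees of freedom):
least-squares means are class averages of per-genotype across-
environment means, compared by Tukey-Kramer at the chosen alpha.
Classes represented by a single genotype are flagged rare and excluded
from the letter display.

Selection efficiency contrasts the best haplotype class with the
tolerant class of the best single marker: a Welch t-test on member
across-environment BLUPs, and the overlap of each selected set with the
top-20% most dormant (lowest-BLUP) genotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sproutval._tukey import tukey_pairwise_p, compact_letter_display
from sproutval.association import _allele_classes

logger = logging.getLogger(__name__)

RARE_N = 2  # classes below this size are excluded from mean comparisons


@dataclass(frozen=True)
class HaplotypeClass:
    model_id: str
    haplotype: str                   # e.g. "G(tol)/T(sus)"
    alleles: tuple[str, ...]
    tolerant_mask: tuple[bool, ...]
    members: tuple[str, ...]
    n: int
    rare: bool


@dataclass(frozen=True)
class SelectionComparison:
    model_id: str
    best_haplotype_gi: float
    single_marker_class_gi: float
    t_test_p: float | None
    n_haplotype_in_top20: int
    n_marker_in_top20: int
    top20_size: int
    n_haplotype: int
    n_marker: int


def build_haplotypes(calls: pd.DataFrame, markers: list[str],
                     tolerant_alleles: dict[str, str],
                     model_id: str = "model") -> list[HaplotypeClass]:
    """Partition genotypes into multi-locus haplotype classes.

    Genotypes with a missing or heterozygous call at any of the model's
    markers are excluded; each observed allele combination forms one
    class.  Classes are returned sorted by descending size.
    """
    allele_cols = {m: _allele_classes(calls[m]) for m in markers}
    tab = pd.DataFrame(allele_cols, index=calls.index).dropna()
    classes = []
    for alleles, grp in tab.groupby(markers, sort=True):
        alleles = (alleles,) if isinstance(alleles, str) else tuple(alleles)
        tol = tuple(a == tolerant_alleles[m] for a, m in zip(alleles, markers))
        label = "/".join(f"{a}({'tol' if t else 'sus'})" for a, t in zip(alleles, tol))
        members = tuple(grp.index.tolist())
        n = len(members)
        if n < RARE_N:
            logger.info("model %s: haplotype %s carried by a single genotype "
                        "(%s); flagged rare", model_id, label, members[0])
        classes.append(HaplotypeClass(
            model_id=model_id, haplotype=label, alleles=alleles,
            tolerant_mask=tol, members=members, n=n, rare=n < RARE_N))
    classes.sort(key=lambda c: (-c.n, c.haplotype))
    return classes


def haplotype_mixed_model(blups_by_env: pd.DataFrame,
                          classes: list[HaplotypeClass],
                          alpha: float = 0.05) -> pd.DataFrame:
    """LSMeans and Tukey-Kramer letters for haplotype classes.

    Parameters
    ----------
    blups_by_env
        Long table of per-environment genotype BLUPs (columns
        genotype_id, environment_id, blup).
    classes
        Output of :func:`build_haplotypes`.
    alpha
        Family-wise level of the Tukey-Kramer letter display.

    Returns
    -------
    DataFrame with one row per class (ascending LSMean): haplotype, n,
    lsmean_gi, letter (empty for rare classes), rare.
    """
    usable = [c for c in classes if not c.rare]
    if len(usable) < 2:
        raise ValueError("need >= 2 non-rare haplotype classes to compare")

    # per-genotype across-environment means (whole-plot stratum response)
    gmeans = blups_by_env.groupby("genotype_id")["blup"].agg(["mean", "count"])
    n_env = blups_by_env["environment_id"].nunique()
    if (gmeans["count"] != n_env).any():
        logger.warning("incomplete environment coverage for some genotypes; "
                       "haplotype contrasts use available environments")

    class_means, class_ns, within_ss = [], [], 0.0
    for c in usable:
        vals = gmeans.loc[list(c.members), "mean"].to_numpy()
        class_means.append(float(vals.mean()))
        class_ns.append(vals.size)
        within_ss += float(np.sum((vals - vals.mean()) ** 2))
    k = len(usable)
    dfe = sum(class_ns) - k  # containment: genotype-within-haplotype stratum
    mse = within_ss / dfe if dfe > 0 else 0.0
    if dfe <= 0:
        logger.warning("no genotype-within-haplotype degrees of freedom; "
                       "all contrasts flagged")

    pmat = tukey_pairwise_p(np.array(class_means), np.array(class_ns), mse, max(dfe, 1))
    order = np.argsort(class_means, kind="stable")  # 'a' = most dormant (lowest GI)
    letters = compact_letter_display(pmat, order, alpha=alpha)

    rows = []
    for idx in order:
        c = usable[idx]
        rows.append({"model_id": c.model_id, "haplotype": c.haplotype,
                     "n": c.n, "lsmean_gi": class_means[idx],
                     "letter": letters[idx], "rare": False})
    for c in classes:
        if c.rare:
            vals = gmeans.loc[list(c.members), "mean"].to_numpy()
            rows.append({"model_id": c.model_id, "haplotype": c.haplotype,
                         "n": c.n, "lsmean_gi": float(vals.mean()),
                         "letter": "", "rare": True})
    return pd.DataFrame(rows)


def selection_efficiency(haplotype_members, marker_members,
                         across_blups: pd.DataFrame,
                         model_id: str = "model",
                         top_fraction: float = 0.20) -> SelectionComparison:
    """Compare haplotype-based and single-marker selection.

    Parameters
    ----------
    haplotype_members, marker_members
        Genotype ids of the best haplotype class and of the single
        marker's tolerant class.
    across_blups
        Across-environment BLUP table (genotype_id, blup).
    top_fraction
        Fraction defining the most-dormant benchmark set
        (floor(top_fraction * n) genotypes with lowest BLUP GI; ties
        broken by genotype id and logged).

    Returns
    -------
    :class:`SelectionComparison` with the two class mean GIs, a
    two-sided Welch t-test p-value (None when either class has < 2
    members or zero pooled variance), and each set's overlap with the
    top-20% set.
    """
    hap = list(haplotype_members)
    mark = list(marker_members)
    if not hap or not mark:
        raise ValueError("both genotype sets must be nonempty")
    b = across_blups.set_index("genotype_id")["blup"]
    hv = b.loc[hap].to_numpy(dtype=float)
    mv = b.loc[mark].to_numpy(dtype=float)

    if len(hv) < 2 or len(mv) < 2:
        p = None
    elif np.var(hv) == 0 and np.var(mv) == 0:
        p = 1.0 if hv.mean() == mv.mean() else None
    else:
        p = float(stats.ttest_ind(hv, mv, equal_var=False).pvalue)

    n = len(b)
    top_size = math.floor(top_fraction * n)
    ranked = b.reset_index().sort_values(["blup", "genotype_id"], kind="stable")
    if top_size < n and ranked["blup"].iloc[top_size - 1] == ranked["blup"].iloc[top_size]:
        logger.info("tie at the top-%d%% boundary broken by genotype id",
                    int(100 * top_fraction))
    top = set(ranked["genotype_id"].iloc[:top_size])

    return SelectionComparison(
        model_id=model_id,
        best_haplotype_gi=float(hv.mean()),
        single_marker_class_gi=float(mv.mean()),
        t_test_p=p,
        n_haplotype_in_top20=len(top.intersection(hap)),
        n_marker_in_top20=len(top.intersection(mark)),
        top20_size=top_size,
        n_haplotype=len(hv),
        n_marker=len(mv),
    )
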