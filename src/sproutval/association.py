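"""Single-marker allelic-effect regression on genotype BLUPs.

Each marker's effect on the germination index is estimated by simple
linear regression of genotype BLUP GI on a 0/1 allele-class indicator,
fitted within each environment and across environments.  For a
two-class predictor the OLS slope equals the difference of class means;
R^2 x 100 is reported as the percent of phenotypic variance explained
(PVE).  The "tolerant" allele is the class with the lower mean GI
(stronger dormancy) in that fit, and the effect is expressed both in GI
units and relative to the susceptible-class mean.  A marker is called
stable when it is significant in at least two environments with a
consistent tolerant allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ACROSS = "across"


@dataclass(frozen=True)
class AssociationResult:
    """Allelic effect of one marker in one fit (environment or across).

    ``effect`` is the tolerant-class mean minus the susceptible-class
    mean (non-positive by orientation); ``relative_change`` expresses it
    as a percentage of the susceptible-class mean; ``pve`` is R^2 x 100.
    """

    marker_id: str
    environment_id: str
    effect: float
    relative_change: float
    pve: float
    p_value: float
    tolerant_allele: str
    susceptible_allele: str
    n_tolerant: int
    n_susceptible: int
    low_power: bool = False
    skipped_reason: str | None = None


@dataclass(frozen=True)
class StabilityCall:
    marker_id: str
    n_significant_envs: int
    direction_consistent: bool
    stable: bool
    tolerant_allele: str | None = None


class MonomorphicMarkerError(ValueError):
    pass


def _allele_classes(calls: pd.Series):
    """Homozygous calls -> allele label per genotype (NaN elsewhere)."""
    s = calls.astype("string")
    valid = ~(s.isna() | (s == "NA") | (s == ""))
    hom = valid & (s.str.len() == 2) & (s.str[0] == s.str[1])
    return s.str[0].where(hom)


def single_marker_regression(blups: pd.DataFrame, calls: pd.Series,
                             environment_id: str = ACROSS) -> AssociationResult:
    """Regress genotype BLUP GI on a single marker's allele indicator.

    Parameters
    ----------
    blups
        DataFrame with columns genotype_id, blup (one fit's BLUPs).
    calls
        Homozygous diploid calls indexed by genotype_id; heterozygous or
        missing genotypes are dropped pairwise.
    environment_id
        Label recorded on the result ('across' for the across-environment
        fit).
    """
    mid = str(calls.name)
    alleles = _allele_classes(calls)
    df = blups.set_index("genotype_id")[["blup"]].join(alleles.rename("allele"), how="inner")
    df = df.dropna(subset=["allele"])
    classes = sorted(df["allele"].unique())
    if len(classes) < 2:
        raise MonomorphicMarkerError(
            f"marker {mid}: monomorphic among non-missing genotypes in {environment_id}")
    if len(classes) > 2:
        raise ValueError(f"marker {mid}: more than two allele classes {classes}")

    m = {a: df.loc[df["allele"] == a, "blup"].mean() for a in classes}
    # tolerant = lower-mean class; ties keep lexicographic order
    tol, sus = sorted(classes, key=lambda a: (m[a], a))
    y = df["blup"].to_numpy(dtype=float)
    x = (df["allele"] == tol).to_numpy(dtype=float)
    n_tol, n_sus = int(x.sum()), int((1 - x).sum())
    low_power = min(n_tol, n_sus) < 2
    if low_power:
        logger.warning("marker %s in %s: allele class below 2 genotypes "
                       "(tolerant n=%d, susceptible n=%d); low power",
                       mid, environment_id, n_tol, n_sus)

    res = stats.linregress(x, y)
    effect = float(res.slope)
    pve = float(res.rvalue ** 2 * 100.0)
    p = float(res.pvalue) if not np.isnan(res.pvalue) else 1.0
    if np.allclose(y, y[0]):
        # constant phenotype: no variance to explain
        effect, pve, p = 0.0, 0.0, 1.0
    rel = relative_change(effect, m[sus]) if m[sus] > 0 else np.nan
    if m[sus] <= 0:
        logger.warning("marker %s in %s: susceptible-class mean <= 0; "
                       "relative change undefined", mid, environment_id)
    return AssociationResult(
        marker_id=mid, environment_id=environment_id, effect=effect,
        relative_change=rel, pve=pve, p_value=p,
        tolerant_allele=tol, susceptible_allele=sus,
        n_tolerant=n_tol, n_susceptible=n_sus, low_power=low_power)


def relative_change(effect: float, susceptible_class_mean: float) -> float:
    """Allelic effect as a percentage of the susceptible-class mean."""
    if susceptible_class_mean <= 0:
        raise ValueError("susceptible-class mean must be positive")
    return 100.0 * effect / susceptible_class_mean


def associate_all(blups_by_env: dict[str, pd.DataFrame], calls: pd.DataFrame) -> pd.DataFrame:
    """Per-marker regression in every environment and across environments.

    ``blups_by_env`` maps environment id (including 'across') to a BLUP
    table.  Monomorphic markers are skipped with a logged reason and
    appear with skipped_reason set.
    """
    rows = []
    for env, blups in blups_by_env.items():
        for mid in calls.columns:
            try:
                r = single_marker_regression(blups, calls[mid], environment_id=env)
            except MonomorphicMarkerError as exc:
                logger.info("%s", exc)
                r = AssociationResult(
                    marker_id=mid, environment_id=env, effect=np.nan,
                    relative_change=np.nan, pve=np.nan, p_value=np.nan,
                    tolerant_allele="", susceptible_allele="",
                    n_tolerant=0, n_susceptible=0, skipped_reason="monomorphic")
            rows.append(r.__dict__)
    return pd.DataFrame(rows)


def classify_stability(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Stability call per marker from its per-environment results.

    A marker is stable when it has a significant effect (p < alpha) in
    at least two environments and the tolerant allele is the same in all
    significant environments.  The across-environment fit does not count
    toward the environment tally.
    """
    envs = results[results["environment_id"] != ACROSS]
    rows = []
    for mid, grp in envs.groupby("marker_id", sort=True):
        ok = grp[grp["p_value"] < alpha]  # skipped fits carry p = NaN and drop out
        n_sig = len(ok)
        tol_alleles = set(ok["tolerant_allele"])
        consistent = len(tol_alleles) <= 1
        stable = bool(n_sig >= 2 and consistent)
        rows.append({
            "marker_id": mid,
            "n_significant_envs": n_sig,
            "direction_consistent": consistent,
            "stable": stable,
            "tolerant_allele": tol_alleles.pop() if len(tol_alleles) == 1 else None,
        })
    return pd.DataFrame(rows)
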