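"""KASP call-matrix quality control.

The call matrix is a genotypes x markers DataFrame of diploid calls
("GG", "GT", ...) with missing cells as NA; marker metadata carries the
two assay alleles, the chromosome, an optional strand-complement flag
(for assays designed on the strand opposite to the one the source
polymorphism was reported on) and an optional known tolerant allele.

The QC cascade excludes markers in a fixed order -- excess missing data,
excess heterozygosity, monomorphy, low minor allele frequency -- and
each excluded marker is labelled with the first filter it fails.  Rates
follow the conventions of candidate-marker panels in inbred material:
heterozygosity among non-missing calls, MAF among homozygous calls only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

EXCLUSION_REASONS = ("high_missing", "high_het", "monomorphic", "low_maf")


@dataclass(frozen=True)
class QCThresholds:
    """Filter cut-offs for the QC cascade.

    Defaults retain markers with moderate missingness (up to 20%),
    essentially-homozygous calls (het rate up to 5%) and a minor allele
    frequency of at least 3%.
    """

    max_missing: float = 0.20
    max_het: float = 0.05
    min_maf: float = 0.03


def _classify_calls(calls: pd.Series, allele1: str, allele2: str):
    """Split one marker's calls into hom1/hom2/het/missing boolean masks."""
    s = calls.astype("string")
    missing = (s.isna() | (s == "NA") | (s == "")).fillna(True)
    hom1 = (s == allele1 + allele1).fillna(False)
    hom2 = (s == allele2 + allele2).fillna(False)
    het = ((s == allele1 + allele2) | (s == allele2 + allele1)).fillna(False)
    known = missing | hom1 | hom2 | het
    if not known.all():
        bad = s[~known].unique().tolist()
        raise ValueError(
            f"marker {calls.name}: calls {bad} not formed from alleles "
            f"({allele1}, {allele2})")
    return hom1.to_numpy(), hom2.to_numpy(), het.to_numpy(), missing.to_numpy()


def qc_stats(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-marker QC rates.

    Returns a DataFrame indexed like ``meta`` with columns marker_id,
    missing_rate (over all genotypes), het_rate (among non-missing
    calls), maf (among homozygous calls; NaN when no homozygous call),
    n_missing, n_het, n_hom1, n_hom2.
    """
    if matrix.empty:
        raise ValueError("empty call matrix")
    meta = meta.set_index("marker_id", drop=False) if "marker_id" in meta.columns else meta
    rows = []
    n = len(matrix)
    for mid in matrix.columns:
        a1, a2 = meta.loc[mid, "allele1"], meta.loc[mid, "allele2"]
        hom1, hom2, het, miss = _classify_calls(matrix[mid], a1, a2)
        n_miss, n_het = int(miss.sum()), int(het.sum())
        n1, n2 = int(hom1.sum()), int(hom2.sum())
        n_called = n - n_miss
        n_hom = n1 + n2
        if n_called == 0:
            logger.warning("marker %s has zero non-missing calls; MAF undefined", mid)
        rows.append({
            "marker_id": mid,
            "missing_rate": n_miss / n,
            "het_rate": n_het / n_called if n_called else np.nan,
            "maf": min(n1, n2) / n_hom if n_hom else np.nan,
            "n_missing": n_miss,
            "n_het": n_het,
            "n_hom1": n1,
            "n_hom2": n2,
        })
    return pd.DataFrame(rows)


def apply_filters(report: pd.DataFrame,
                  thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Apply the QC cascade to a rates report.

    Cascade order: missing -> heterozygosity -> monomorphy -> MAF; each
    excluded marker carries the first reason that fails.  Returns the
    report with ``status`` ('retained'/'excluded') and ``reason``
    columns added.
    """
    th = thresholds or QCThresholds()
    logger.info("QC thresholds: max_missing=%.3g max_het=%.3g min_maf=%.3g",
                th.max_missing, th.max_het, th.min_maf)
    out = report.copy()
    statuses, reasons = [], []
    for row in out.itertuples(index=False):
        if row.missing_rate > th.max_missing:
            reason = "high_missing"
        elif not np.isnan(row.het_rate) and row.het_rate > th.max_het:
            reason = "high_het"
        elif np.isnan(row.maf) or row.maf == 0.0:
            reason = "monomorphic"
        elif row.maf < th.min_maf:
            reason = "low_maf"
        else:
            reason = "none"
        reasons.append(reason)
        statuses.append("retained" if reason == "none" else "excluded")
    out["status"] = statuses
    out["reason"] = reasons
    return out


def retained_markers(report: pd.DataFrame) -> list[str]:
    return report.loc[report["status"] == "retained", "marker_id"].tolist()


def drop_heterozygotes(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Set heterozygous cells to missing, leaving homozygous calls intact.

    Candidate-marker effects in inbred panels are estimated on
    homozygous classes only; residual heterozygous calls (seed mixtures,
    assay noise) are treated as no-calls.
    """
    meta = meta.set_index("marker_id", drop=False) if "marker_id" in meta.columns else meta
    out = matrix.copy()
    for mid in out.columns:
        a1, a2 = meta.loc[mid, "allele1"], meta.loc[mid, "allele2"]
        _, _, het, _ = _classify_calls(out[mid], a1, a2)
        out.loc[het, mid] = pd.NA
    return out


def harmonize_strand(matrix: pd.DataFrame, meta: pd.DataFrame):
    """Map strand-flagged markers to the expected-strand alleles.

    KASP assays are sometimes designed on the DNA strand complementary
    to the one on which the source polymorphism was reported; to compare
    with the original studies, calls and allele labels of flagged
    markers are mapped through A<->T, C<->G.  The operation is an
    involution: applying it twice restores the input.

    Returns ``(matrix, meta)`` with flagged markers complemented.
    """
    meta_idx = meta.set_index("marker_id", drop=False) if "marker_id" in meta.columns else meta
    out_m = matrix.copy()
    out_meta = meta.copy()
    flag_col = "strand_complement" if "strand_complement" in meta_idx.columns else None
    if flag_col is None:
        return out_m, out_meta
    for mid in matrix.columns:
        if not bool(meta_idx.loc[mid, flag_col]):
            continue
        a1, a2 = meta_idx.loc[mid, "allele1"], meta_idx.loc[mid, "allele2"]
        if a1 not in COMPLEMENT or a2 not in COMPLEMENT:
            raise ValueError(
                f"marker {mid}: cannot strand-complement non-nucleotide alleles ({a1}, {a2})")
        out_m[mid] = matrix[mid].map(
            lambda c: c if pd.isna(c) or c == "NA"
            else "".join(COMPLEMENT[b] for b in c)).astype(matrix[mid].dtype)
        sel = out_meta["marker_id"] == mid if "marker_id" in out_meta.columns else out_meta.index == mid
        out_meta.loc[sel, "allele1"] = COMPLEMENT[a1]
        out_meta.loc[sel, "allele2"] = COMPLEMENT[a2]
    return out_m, out_meta


def detect_complete_ld(matrix: pd.DataFrame, markers=None) -> list[list[str]]:
    """Group markers whose allele classes partition the genotypes identically.

    Two markers are in complete LD (squared allelic correlation 1) when,
    over genotypes with non-missing homozygous calls at both, the class
    partitions coincide under some allele relabelling.  Grouping is an
    equivalence relation (union-find closure); only groups of size >= 2
    are returned, each ordered by input marker order with the first
    member the nominated representative.

    The matrix is expected to be homozygous-only (run
    :func:`drop_heterozygotes` first); both markers must be polymorphic
    on the shared genotype set.
    """
    if markers is None:
        markers = list(matrix.columns)
    parent = {m: m for m in markers}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    codes = {}
    for m in markers:
        s = matrix[m].astype("string")
        valid = ~(s.isna() | (s == "NA") | (s == ""))
        codes[m] = (pd.factorize(s[valid])[0], np.flatnonzero(valid.to_numpy()))

    for m1, m2 in itertools.combinations(markers, 2):
        c1, i1 = codes[m1]
        c2, i2 = codes[m2]
        shared, a_idx, b_idx = np.intersect1d(i1, i2, return_indices=True)
        if shared.size < 2:
            continue
        v1, v2 = c1[a_idx], c2[b_idx]
        if len(np.unique(v1)) < 2 or len(np.unique(v2)) < 2:
            continue
        # identical partitioning iff the class cross-table is a permutation
        tab = pd.crosstab(v1, v2).to_numpy()
        if np.all((tab > 0).sum(axis=0) == 1) and np.all((tab > 0).sum(axis=1) == 1):
            r1, r2 = find(m1), find(m2)
            if r1 != r2:
                parent[r2] = r1

    groups: dict[str, list[str]] = {}
    for m in markers:
        groups.setdefault(find(m), []).append(m)
    return [g for g in groups.values() if len(g) >= 2]


def read_call_matrix(path) -> pd.DataFrame:
    """Read a genotypes-as-rows, markers-as-columns call matrix CSV."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    return df.replace({"NA": pd.NA, "": pd.NA})


def read_marker_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "strand_complement" in df.columns:
        df["strand_complement"] = df["strand_complement"].astype(bool)
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.fillna("NA").to_csv(path, index_label="genotype_id")
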