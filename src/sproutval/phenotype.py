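"""Germination-index phenotyping.

The germination index (GI) summarises a staged germination test in which
``N`` seeds are incubated and germinated seeds are counted after 3 and 6
days.  Early germination is weighted more heavily:

    GI = (6 * n3 + 3 * n6) / (6 * N)

where ``n3`` is the number of seeds germinated by day 3 and ``n6`` the
number germinating between day 3 and day 6.  GI lies in [0, 1]; low GI
indicates strong seed dormancy and hence pre-harvest sprouting
resistance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SEEDS_PER_TEST = 40


class InvalidRecordError(ValueError):
    """A plot record violates the germination-count invariants."""


class DuplicateKeyError(ValueError):
    """Duplicate (genotype, environment, replicate) keys in a phenotype table."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"duplicate (genotype, environment, replicate) keys: {self.keys}")


@dataclass(frozen=True)
class PlotGermination:
    """Staged germination counts for one field plot.

    ``n6`` is the *incremental* count of seeds germinating between day 3
    and day 6, not the cumulative day-6 count: the two cohorts carry
    different weights in the GI formula.
    """

    genotype_id: str
    environment_id: str
    replicate: int
    n3: int
    n6: int
    N: int = DEFAULT_SEEDS_PER_TEST

    def __post_init__(self) -> None:
        if self.N < 1:
            raise InvalidRecordError(f"plot {self._key()}: N must be >= 1, got {self.N}")
        if self.n3 < 0 or self.n6 < 0:
            raise InvalidRecordError(
                f"plot {self._key()}: negative germination count (n3={self.n3}, n6={self.n6})"
            )
        if self.n3 + self.n6 > self.N:
            raise InvalidRecordError(
                f"plot {self._key()}: n3 + n6 = {self.n3 + self.n6} exceeds N = {self.N}"
            )
        if self.replicate < 1:
            raise InvalidRecordError(f"plot {self._key()}: replicate must be >= 1")
        if self.N != DEFAULT_SEEDS_PER_TEST:
            logger.warning(
                "plot %s uses N=%d seeds (the standard test uses %d); the GI formula generalizes",
                self._key(), self.N, DEFAULT_SEEDS_PER_TEST,
            )

    def _key(self) -> tuple:
        return (self.genotype_id, self.environment_id, self.replicate)

    @property
    def gi(self) -> float:
        return compute_gi(self.n3, self.n6, self.N)


@dataclass(frozen=True)
class GIRecord:
    """Plot-level germination index.

    GI is inversely related to dormancy: lower GI means a more dormant,
    more sprouting-resistant genotype.
    """

    genotype_id: str
    environment_id: str
    replicate: int
    gi: float


def compute_gi(n3: int, n6: int, N: int) -> float:
    """Germination index from staged counts.

    Parameters
    ----------
    n3
        Seeds germinated by day 3 of incubation.
    n6
        Seeds germinated between day 3 and day 6 (incremental count).
    N
        Total seeds tested.

    Returns
    -------
    float
        ``(6*n3 + 3*n6) / (6*N)``, in [0, 1].
    """
    if N < 1:
        raise InvalidRecordError(f"N must be >= 1, got {N}")
    if n3 < 0 or n6 < 0:
        raise InvalidRecordError(f"negative germination count (n3={n3}, n6={n6})")
    if n3 + n6 > N:
        raise InvalidRecordError(f"n3 + n6 = {n3 + n6} exceeds N = {N}")
    return (6.0 * n3 + 3.0 * n6) / (6.0 * N)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used in report tables.

    GI values are carried at full precision through every fit and only
    rounded at report time.
    """
    factor = 10.0 ** ndigits
    # small nudge absorbs binary representation error at exact .5 boundaries
    return float(np.floor(np.abs(x) * factor + 0.5 + 1e-9) / factor * np.sign(x))


def build_phenotype_table(records) -> list[GIRecord]:
    """Compute GI for a collection of plot records.

    Raises :class:`DuplicateKeyError` if two records share a
    (genotype, environment, replicate) key.
    """
    seen: dict[tuple, int] = {}
    dupes = []
    out = []
    for rec in records:
        key = (rec.genotype_id, rec.environment_id, rec.replicate)
        if key in seen:
            dupes.append(key)
        seen[key] = 1
        out.append(GIRecord(rec.genotype_id, rec.environment_id, rec.replicate, rec.gi))
    if dupes:
        raise DuplicateKeyError(dupes)
    return out


def gi_table(records) -> pd.DataFrame:
    """Phenotype table as a DataFrame (columns genotype_id, environment_id, replicate, gi)."""
    gir = build_phenotype_table(records)
    return pd.DataFrame(
        {
            "genotype_id": [r.genotype_id for r in gir],
            "environment_id": [r.environment_id for r in gir],
            "replicate": [r.replicate for r in gir],
            "gi": [r.gi for r in gir],
        }
    )


def read_plot_records(path: str | Path) -> list[PlotGermination]:
    """Read plot germination counts from delimited text.

    The delimiter is auto-detected from the extension (.tsv/.txt = tab,
    otherwise comma).  Required columns: genotype_id, environment_id,
    replicate, n3, n6; optional N (default 40).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"genotype_id", "environment_id", "replicate", "n3", "n6"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "N" not in df.columns:
        df["N"] = DEFAULT_SEEDS_PER_TEST
    return [
        PlotGermination(
            genotype_id=str(row.genotype_id),
            environment_id=str(row.environment_id),
            replicate=int(row.replicate),
            n3=int(row.n3),
            n6=int(row.n6),
            N=int(row.N),
        )
        for row in df.itertuples(index=False)
    ]


def write_gi_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
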