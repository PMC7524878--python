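"""GC peak-table ingestion and abundance-matrix assembly.

Peak tables hold relative peak areas (% of total ion signal) per compound
for one accession. Interconverting isomers are pooled by exact summation
before scoring; the default pooling map joins menthone with isomenthone
(the two diastereomers interconvert by enolization) and the two citral
isomers. Areas are never renormalized after pooling or assembly: the
bioactivity score is defined on raw relative peak areas, and renormalizing
would change it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AREA_SUM_TOLERANCE = 1e-6

#: isomer pools applied by default before scoring
DEFAULT_POOLING = {
    "menthone": "menthone/isomenthone",
    "isomenthone": "menthone/isomenthone",
    "alpha-citral": "citral",
    "beta-citral": "citral",
    "α-citral": "citral",
    "β-citral": "citral",
}


class PeakTableError(ValueError):
    pass


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split())


@dataclass
class PeakTable:
    """One accession's GC peaks: (compound, relative area %) rows."""

    accession: str
    areas: dict[str, float]

    def __post_init__(self) -> None:
        for compound, area in self.areas.items():
            if area < 0:
                raise PeakTableError(
                    f"negative area {area} for {compound!r} in {self.accession!r}"
                )
        total = sum(self.areas.values())
        if total > 100.0 + AREA_SUM_TOLERANCE:
            raise PeakTableError(
                f"areas sum to {total} > 100 in {self.accession!r}"
            )

    @property
    def total_area(self) -> float:
        return sum(self.areas.values())


def load_peak_table(path, accession: str | None = None, **read_csv_kwargs) -> PeakTable:
    """Load a (compound, area) CSV into a validated PeakTable.

    Compound names are whitespace-normalized (case preserved). The accession
    id defaults to the file stem. Duplicate compounds are an error: pooling
    must be explicit, not a side effect of loading.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    missing = {"compound", "area"} - set(df.columns)
    if missing:
        raise PeakTableError(f"{path}: missing columns {sorted(missing)}")
    areas: dict[str, float] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        name = _normalize_name(row.compound)
        area = float(row.area)
        if area < 0:
            raise PeakTableError(f"{path} row {row_number}: negative area {area}")
        if name in areas:
            raise PeakTableError(
                f"{path} row {row_number}: duplicate compound {name!r} "
                "(pool explicitly instead)"
            )
        areas[name] = area
    return PeakTable(accession or Path(path).stem, areas)


def pool_isomers(
    pt: PeakTable, pooling: dict[str, str] | None = None
) -> PeakTable:
    """Sum member compounds into pooled names; total area is preserved.

    ``pooling`` maps member name -> pooled name; members absent from the
    table are ignored. A pooled name that collides with an unpooled compound
    already present is an error.
    """
    if pooling is None:
        pooling = DEFAULT_POOLING
    pooled_names = set(pooling.values())
    colliding = {
        c for c in pt.areas
        if c in pooled_names and c not in pooling
    }
    # a compound already carrying the pooled name is fine only if nothing
    # maps into that name from this table
    for name in colliding:
        if any(m in pt.areas for m, p in pooling.items() if p == name):
            raise PeakTableError(
                f"pooled name {name!r} collides with existing compound "
                f"in {pt.accession!r}"
            )
    out: dict[str, float] = {}
    for compound, area in pt.areas.items():
        target = pooling.get(compound, compound)
        out[target] = out.get(target, 0.0) + area
    return PeakTable(pt.accession, out)


@dataclass
class AbundanceMatrix:
    """Accessions x compounds matrix of relative peak areas (%).

    Missing compounds are 0. Row order follows input order; column order is
    sorted for determinism.
    """

    accessions: list[str]
    compounds: list[str]
    a: np.ndarray  # shape (n_accessions, n_compounds)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (len(self.accessions), len(self.compounds)):
            raise ValueError("matrix shape mismatch")
        if np.any(self.a < 0):
            raise ValueError("negative abundances")
        if np.any(self.a.sum(axis=1) > 100.0 + AREA_SUM_TOLERANCE):
            raise ValueError("row sums exceed 100")

    @property
    def n(self) -> int:
        return len(self.accessions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.accessions, columns=self.compounds)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("accession").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "AbundanceMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


def build_abundance_matrix(
    tables: list[PeakTable], renormalize: bool = False
) -> AbundanceMatrix:
    """Assemble peak tables into one matrix over the union of compounds.

    Numeric values are placed, never changed; absent compounds become 0.
    ``renormalize=True`` rescales each row to sum to 100 (i.e. expresses
    areas relative to identified peaks only) — off by default because the
    bioactivity score is defined on raw relative areas and renormalization
    changes every score.
    """
    if not tables:
        raise PeakTableError("no peak tables given")
    ids = [t.accession for t in tables]
    if len(set(ids)) != len(ids):
        raise PeakTableError("duplicate accession ids")
    compounds = sorted(set().union(*(t.areas.keys() for t in tables)))
    a = np.zeros((len(tables), len(compounds)))
    index = {c: j for j, c in enumerate(compounds)}
    for i, t in enumerate(tables):
        for compound, area in t.areas.items():
            a[i, index[compound]] = area
    if renormalize:
        sums = a.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise PeakTableError("cannot renormalize an all-zero peak table")
        a = 100.0 * a / sums
    return AbundanceMatrix(ids, compounds, a)
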