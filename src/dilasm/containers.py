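"""Core data containers shared across the pipeline.

Tables are thin, validated wrappers around :class:`pandas.DataFrame`; the
distance matrix mirrors the conventions of community-ecology software
(symmetric, zero diagonal, sample ids as the only external keys).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "DistanceMatrix",
    "Ordination",
    "SampleDesign",
    "RegionalPool",
    "FunctionalCatalog",
    "AssemblyResult",
    "SyntheticExperiment",
]


class CommunityMatrix:
    """Taxa x samples abundance table.

    Parameters
    ----------
    table:
        DataFrame with taxon ids as the index and sample ids as columns.
    mode:
        ``"counts"`` for non-negative read counts, ``"relative"`` for
        column-normalized relative abundances (each column sums to 1).
    """

    def __init__(self, table: pd.DataFrame, mode: Literal["counts", "relative"] = "counts"):
        if mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {mode!r}")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        if table.columns.has_duplicates:
            dups = table.columns[table.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = table.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            raise ValueError("negative abundances")
        if mode == "relative" and values.size:
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = table.columns[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
                raise ValueError(f"relative-mode columns do not sum to 1: {bad}")
        self.table = table
        self.mode = mode

    @property
    def taxa(self) -> list[str]:
        return list(self.table.index)

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns)

    def to_relative(self) -> "CommunityMatrix":
        """Column-normalize to relative abundances."""
        sums = self.table.sum(axis=0)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0].tolist()
            raise ValueError(f"zero-sum sample columns: {bad}")
        return CommunityMatrix(self.table / sums, mode="relative")

    def drop_empty_taxa(self) -> "CommunityMatrix":
        keep = self.table.sum(axis=1) > 0
        return CommunityMatrix(self.table.loc[keep], mode=self.mode)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CommunityMatrix({len(self.taxa)} taxa x {len(self.samples)} samples, mode={self.mode})"


class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample ids."""

    def __init__(self, data: np.ndarray, ids: Sequence[str]):
        data = np.asarray(data, dtype=float)
        ids = list(ids)
        if data.ndim != 2 or data.shape[0] != data.shape[1]:
            raise ValueError("distance matrix must be square")
        if data.shape[0] != len(ids):
            raise ValueError("ids length does not match matrix size")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in distance matrix")
        if not np.allclose(data, data.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if data.size and data.min() < -1e-12:
            raise ValueError("negative distances")
        data = np.clip((data + data.T) / 2.0, 0.0, None)
        np.fill_diagonal(data, 0.0)
        self.data = data
        self.ids = ids
        self._index = {s: i for i, s in enumerate(ids)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.data[self._index[a], self._index[b]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (scipy condensed) vector."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[s] for s in ids]
        return DistanceMatrix(self.data[np.ix_(idx, idx)], ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class Ordination:
    """NMDS result: low-dimensional coordinates plus Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_starts_used: int
    converged: bool


@dataclass(frozen=True)
class SampleDesign:
    """One sequenced sample of the microcosm factorial design.

    ``lg_dil`` is the -log10 dilution of the inoculum suspension; 0 marks
    the untreated control soils. ``covariates`` carries the Ca/Fe/SO4
    concentrations used by the VPA CONC block (arbitrary units).
    """

    sample_id: str
    soil_type: str
    ph_level: float
    lg_dil: int
    replicate: int
    subsample: int = 1
    covariates: dict = field(default_factory=dict)

    @property
    def treatment(self) -> tuple:
        return (self.soil_type, self.ph_level, self.lg_dil)


@dataclass
class RegionalPool:
    """Regional species pool of one source soil."""

    soil_type: str
    taxon_abundance: dict[str, float]
    ph_optimum: dict[str, float]
    niche_breadth: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.taxon_abundance.values()):
            raise ValueError("pool abundances must be positive")
        missing = set(self.taxon_abundance) - set(self.ph_optimum)
        if missing:
            raise ValueError(f"pool members without pH optimum: {sorted(missing)[:5]}")

    @property
    def members(self) -> list[str]:
        return list(self.taxon_abundance)


@dataclass
class FunctionalCatalog:
    """gene -> category and category -> functional-group maps.

    FunGp1 marks specialized categories (genes confined to narrow clades),
    FunGp2 broad categories (genes spread over most taxa).
    """

    gene_to_category: dict[str, str]
    category_to_fungp: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.gene_to_category.values() if c not in self.category_to_fungp}
        if bad:
            raise ValueError(f"categories without functional group: {sorted(bad)}")
        bad = {f for f in self.category_to_fungp.values() if f not in ("FunGp1", "FunGp2")}
        if bad:
            raise ValueError(f"unknown functional groups: {sorted(bad)}")

    @property
    def categories(self) -> list[str]:
        return list(self.category_to_fungp)

    def genes_in(self, category: str) -> list[str]:
        return [g for g, c in self.gene_to_category.items() if c == category]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "category": c, "fungp": self.category_to_fungp[c]}
            for g, c in self.gene_to_category.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class AssemblyResult:
    """Per-pair phylogenetic turnover and its null-model z-score.

    ``bnti`` is (observed betaMNTD - null mean) / null SD; the label follows
    the +/-2 thresholds (variable selection above +2, homogeneous selection
    below -2, stochastic in between).
    """

    pair: tuple[str, str]
    bmntd_obs: float
    null_mean: float
    null_sd: float
    n_null: int
    bnti: float
    label: str


@dataclass
class SyntheticExperiment:
    """Bundle of everything one simulated microcosm experiment produces."""

    tree: "object"
    design: list[SampleDesign]
    otu_table: CommunityMatrix
    gene_table: pd.DataFrame
    catalog: FunctionalCatalog
    truth: pd.DataFrame

    @property
    def metadata(self) -> pd.DataFrame:
        rows = []
        for s in self.design:
            row = {
                "sample_id": s.sample_id,
                "soil": s.soil_type,
                "pH": s.ph_level,
                "lg_dil": s.lg_dil,
                "replicate": s.replicate,
                "subsample": s.subsample,
            }
            row.update(s.covariates)
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")
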