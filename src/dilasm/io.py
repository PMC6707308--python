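"""Canonical on-disk formats: TSV tables, Newick trees, JSON results.

Write-then-read round trips are identity for every table; sample ids are the
only external keys.
"""

from __future__ import annotations

import json
import os

import pandas as pd

from .containers import CommunityMatrix, DistanceMatrix, FunctionalCatalog, SampleDesign
from .trees import parse_newick, write_newick  # noqa: F401  (re-exported)

__all__ = [
    "read_community",
    "write_community",
    "read_metadata",
    "write_metadata",
    "read_distance",
    "write_distance",
    "read_catalog",
    "write_catalog",
    "read_tree",
    "write_tree",
    "write_json",
]

read_tree = parse_newick
write_tree = write_newick


def read_community(path: str, mode: str = "counts") -> CommunityMatrix:
    """Read a taxa x samples TSV (first column = taxon ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(int) if mode == "counts" else df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    return CommunityMatrix(df, mode=mode)


def write_community(m: CommunityMatrix, path: str) -> None:
    m.table.rename_axis("taxon").to_csv(path, sep="\t")


def read_metadata(path: str) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample_id in metadata: {dup}")
    cov_cols = [c for c in df.columns if c in ("Ca", "Fe", "SO4")]
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleDesign(
                sample_id=str(row["sample_id"]),
                soil_type=str(row["soil"]),
                ph_level=float(row["pH"]),
                lg_dil=int(row["lg_dil"]),
                replicate=int(row["replicate"]),
                subsample=int(row.get("subsample", 1)),
                covariates={c: float(row[c]) for c in cov_cols},
            )
        )
    return out


def write_metadata(design: list[SampleDesign], path: str) -> None:
    rows = []
    for s in design:
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
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_distance(path: str) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"distance matrix in {path} has mismatched row/column ids")
    return DistanceMatrix(df.to_numpy(dtype=float), list(df.index))


def write_distance(d: DistanceMatrix, path: str) -> None:
    d.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def read_catalog(path: str) -> FunctionalCatalog:
    df = pd.read_csv(path, sep="\t")
    gene_to_category = dict(zip(df["gene"].astype(str), df["category"].astype(str)))
    if len(gene_to_category) != len(df):
        raise ValueError("duplicate gene ids in catalog")
    category_to_fungp = (
        df.drop_duplicates("category").set_index("category")["fungp"].astype(str).to_dict()
    )
    return FunctionalCatalog(gene_to_category, category_to_fungp)


def write_catalog(cat: FunctionalCatalog, path: str) -> None:
    cat.to_frame().to_csv(path, sep="\t", index=False)


def write_json(obj, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
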