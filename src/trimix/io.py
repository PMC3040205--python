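"""Readers and writers for the plain-text interchange formats.

Everything is TSV/CSV: at the scale of a 40-locus AIM panel and ~1000
individuals, text formats are adequate and diffable. Lines starting with
``#`` are provenance comments and are skipped by every reader, so a
writer/reader pair is a bijection on valid data.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ANCESTRIES, MISSING, AlleleFrequencyPanel, GenotypeMatrix
from .estimate import AncestryVector
from .summary import CohortSummary

__all__ = [
    "read_panel",
    "write_panel",
    "read_genotypes",
    "write_genotypes",
    "read_structure_genotypes",
    "read_ancestry",
    "write_ancestry",
    "read_census",
    "write_census",
    "read_summary",
    "write_summary",
    "load_table1_census",
    "load_table2_means",
]

NA_SENTINEL = "NA"
_FLOAT_FMT = "%.10g"


def _write_with_header(df: pd.DataFrame, path, sep: str, header_comments: list[str] | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------- panel ---


def write_panel(panel: AlleleFrequencyPanel, path, header_comments=None) -> None:
    df = pd.DataFrame({"locus_id": panel.locus_ids})
    for k, pop in enumerate(panel.pop_ids):
        df[pop] = panel.freqs[k]
    _write_with_header(df, path, "\t", header_comments)


def read_panel(path) -> AlleleFrequencyPanel:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"locus_id": str})
    if "locus_id" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: panel file needs a locus_id column plus population columns")
    pops = [c for c in df.columns if c != "locus_id"]
    freqs = df[pops].to_numpy(dtype=float).T
    return AlleleFrequencyPanel(pop_ids=pops, locus_ids=df["locus_id"].tolist(), freqs=freqs)


# ------------------------------------------------------------ genotypes ---


def write_genotypes(
    genotypes: GenotypeMatrix, path, na: str = NA_SENTINEL, header_comments=None
) -> None:
    df = pd.DataFrame(
        {"id": genotypes.individual_ids, "region": genotypes.regions, "color": genotypes.colors}
    )
    vals = genotypes.values.astype(object)
    vals[genotypes.values == MISSING] = na
    for j, lid in enumerate(genotypes.locus_ids):
        df[lid] = vals[:, j]
    _write_with_header(df, path, "\t", header_comments)


def read_genotypes(path, na: str = NA_SENTINEL) -> GenotypeMatrix:
    """Read a genotype TSV, validating every cell.

    Offending values are reported with their 1-based data row and locus id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = ["id", "region", "color"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    locus_ids = [c for c in df.columns if c not in required]
    if not locus_ids:
        raise ValueError(f"{path}: no locus columns found")
    ids = df["id"].tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate individual id {dup.iloc[0]!r}")

    values = np.full((len(df), len(locus_ids)), MISSING, dtype=np.int16)
    for j, lid in enumerate(locus_ids):
        col = df[lid].str.strip()
        for i, cell in enumerate(col):
            if cell == na or cell == "":
                continue
            if cell not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: invalid genotype {cell!r} at row {i + 1}, locus {lid!r} "
                    "(expected 0, 1, 2 or missing)"
                )
            values[i, j] = int(cell)
    return GenotypeMatrix(
        individual_ids=ids,
        locus_ids=locus_ids,
        values=values,
        regions=df["region"].tolist(),
        colors=df["color"].tolist(),
    )


def read_structure_genotypes(path, short_allele: str = "1", missing: str = "-9") -> GenotypeMatrix:
    """Read the classic two-row-per-individual STRUCTURE dialect.

    First line is whitespace-separated locus names; each individual then
    occupies two consecutive rows of ``id allele_1 ... allele_L``. The
    genotype is the count of ``short_allele`` across the two rows; a
    ``missing`` code on either row marks the locus missing.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3 or (len(lines) - 1) % 2:
        raise ValueError(f"{path}: expected a locus header plus two rows per individual")
    locus_ids = lines[0]
    ids, rows = [], []
    for r1, r2 in zip(lines[1::2], lines[2::2]):
        if r1[0] != r2[0]:
            raise ValueError(f"{path}: row pair mismatch for id {r1[0]!r}")
        if len(r1) != len(locus_ids) + 1 or len(r2) != len(locus_ids) + 1:
            raise ValueError(f"{path}: wrong number of alleles for id {r1[0]!r}")
        ids.append(r1[0])
        row = np.empty(len(locus_ids), dtype=np.int16)
        for j, (a1, a2) in enumerate(zip(r1[1:], r2[1:])):
            if missing in (a1, a2):
                row[j] = MISSING
            else:
                row[j] = (a1 == short_allele) + (a2 == short_allele)
        rows.append(row)
    return GenotypeMatrix(individual_ids=ids, locus_ids=locus_ids, values=np.vstack(rows))


# ------------------------------------------------------------- ancestry ---


def write_ancestry(
    ancestries: list[AncestryVector],
    genotypes_or_labels,
    path,
    header_comments=None,
) -> None:
    """Write per-individual estimates next to their ids and labels.

    ``genotypes_or_labels`` is either the source :class:`GenotypeMatrix`
    or a list of (id, region, color) triples.
    """
    if isinstance(genotypes_or_labels, GenotypeMatrix):
        meta = list(
            zip(
                genotypes_or_labels.individual_ids,
                genotypes_or_labels.regions,
                genotypes_or_labels.colors,
            )
        )
    else:
        meta = list(genotypes_or_labels)
    if len(meta) != len(ancestries):
        raise ValueError("metadata and ancestry lengths differ")
    df = pd.DataFrame(
        {
            "id": [m[0] for m in meta],
            "region": [m[1] for m in meta],
            "color": [m[2] for m in meta],
            **{a: [av.q[k] for av in ancestries] for k, a in enumerate(ANCESTRIES)},
            "loglik": [av.loglik for av in ancestries],
            "n_used": [av.n_used for av in ancestries],
            "converged": [av.converged for av in ancestries],
        }
    )
    _write_with_header(df, path, "\t", header_comments)


def read_ancestry(path) -> tuple[list[AncestryVector], list[tuple[str, str]]]:
    """Read an ancestry TSV back into vectors plus (region, color) labels."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out, labels = [], []
    for _, row in df.iterrows():
        q = np.array([row[a] for a in ANCESTRIES], dtype=float)
        if np.isnan(q).any():
            av = AncestryVector(
                q=(np.nan,) * 3, loglik=np.nan, n_used=0, converged=False, error="failed estimate"
            )
        else:
            q = q / q.sum()
            av = AncestryVector(
                q=tuple(float(x) for x in q),
                loglik=float(row["loglik"]),
                n_used=int(row["n_used"]),
                converged=bool(row["converged"]),
            )
        out.append(av)
        labels.append((str(row["region"]), str(row["color"])))
    return out, labels


# --------------------------------------------------------------- census ---


def read_census(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = ["region", "white_pct", "brown_pct", "black_pct"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValueError(f"{path}: census file has no rows")
    pct = df[["white_pct", "brown_pct", "black_pct"]].to_numpy(dtype=float)
    if (pct < 0).any():
        raise ValueError(f"{path}: negative census percentage")
    return df[required]


def write_census(df: pd.DataFrame, path, header_comments=None) -> None:
    _write_with_header(df, path, ",", header_comments)


# -------------------------------------------------------------- summary ---


def write_summary(summaries: list[CohortSummary], path, header_comments=None) -> None:
    rows = []
    for s in summaries:
        row = {"region": s.region, "color": s.color, "n": s.n}
        for k, a in enumerate(ANCESTRIES):
            row[f"{a}_mean"] = s.mean[k]
            row[f"{a}_se"] = s.se[k]
        row["X"] = s.X
        row["Y"] = s.Y
        rows.append(row)
    _write_with_header(pd.DataFrame(rows), path, ",", header_comments)


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = ["region", "color"] + [f"{a}_mean" for a in ANCESTRIES]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


# ------------------------------------------------------------- fixtures ---


def _data_path(name: str):
    return importlib.resources.files("trimix.data").joinpath(name)


def load_table1_census() -> pd.DataFrame:
    """Packaged census percentages for the six sampled states."""
    with importlib.resources.as_file(_data_path("table1_census.csv")) as p:
        return read_census(p)


def load_table2_means() -> pd.DataFrame:
    """Packaged per-(region, color) ancestry means and standard errors."""
    with importlib.resources.as_file(_data_path("table2_means.csv")) as p:
        return read_summary(p)
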