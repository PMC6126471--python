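"""Species calling on a mixed-species gene-barcode matrix.

Turns a cellranger-style triplet (MatrixMarket counts + features TSV +
barcodes TSV) whose feature identifiers carry species prefixes (e.g. ``hg19_``
and ``mm10_``) into the (N1, N2, N12) triple the estimator needs.

The calling rule is deliberately simple and transparent: a barcode whose total
UMI count falls below ``min_umi`` is background; otherwise it is called
``mixed`` when the minor species' share of its UMIs is at least
``minor_fraction`` (boundary inclusive, so an exact 50/50 split is mixed), and
the majority species otherwise.  The summary counts follow the inclusive
convention of :mod:`barnyard.model`: ``n_type1`` counts {type1, mixed} calls,
``n_type2`` counts {type2, mixed}, ``n_mixed`` counts {mixed}.

Ambient-RNA correction, empty-droplet testing and per-barcode doublet scoring
are out of scope.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .model import DropletCounts, ValidationError

__all__ = ["SpeciesMatrix", "CellCalls", "read_matrix", "call_cells", "synthesize_matrix", "write_matrix"]

CALL_LABELS = ("type1", "type2", "mixed", "background")


@dataclass(frozen=True)
class SpeciesMatrix:
    """Sparse UMI count matrix (features x barcodes) with per-feature species labels.

    ``feature_species`` holds 0 for type 1 and 1 for type 2, one entry per
    feature row.
    """

    barcodes: tuple[str, ...]
    feature_ids: tuple[str, ...]
    feature_species: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        n_feat, n_bc = self.counts.shape
        if len(self.feature_ids) != n_feat or len(self.feature_species) != n_feat:
            raise ValidationError(
                f"feature annotation length mismatch: matrix has {n_feat} rows, "
                f"{len(self.feature_ids)} ids, {len(self.feature_species)} labels"
            )
        if len(self.barcodes) != n_bc:
            raise ValidationError(
                f"barcode list length {len(self.barcodes)} != matrix columns {n_bc}"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValidationError("count matrix contains non-integer entries")

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class CellCalls:
    """Per-barcode species calls and the droplet-count summary they imply."""

    table: pd.DataFrame  # columns: barcode, umi_type1, umi_type2, call
    summary: DropletCounts
    min_umi: int
    minor_fraction: float


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_column(path: Path, column: int = 0) -> list[str]:
    with _open_text(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    return [r[column] for r in rows]


def read_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    species_prefixes: Sequence[str],
) -> SpeciesMatrix:
    """Read a cellranger-style triplet and assign each feature to a species.

    ``species_prefixes`` is a pair of literal, case-sensitive prefixes on the
    feature identifiers (first column of the features TSV); the first prefix
    is type 1, the second type 2.  Every feature must match exactly one prefix.
    Plain or gzipped files are accepted.
    """
    if len(species_prefixes) != 2 or species_prefixes[0] == species_prefixes[1]:
        raise ValidationError(f"need two distinct species prefixes, got {species_prefixes!r}")
    p1, p2 = species_prefixes

    with _open_text(Path(mtx_path)) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    feature_ids = _read_tsv_column(Path(features_path))
    barcodes = _read_tsv_column(Path(barcodes_path))
    if mat.shape != (len(feature_ids), len(barcodes)):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match {len(feature_ids)} features "
            f"x {len(barcodes)} barcodes from the sidecar files"
        )

    species = np.empty(len(feature_ids), dtype=np.int8)
    bad = []
    for i, fid in enumerate(feature_ids):
        m1, m2 = fid.startswith(p1), fid.startswith(p2)
        if m1 == m2:  # neither, or both (overlapping prefixes)
            bad.append(fid)
        else:
            species[i] = 0 if m1 else 1
    if bad:
        raise ValidationError(
            f"{len(bad)} feature id(s) do not match exactly one species prefix "
            f"({p1!r}, {p2!r}): {', '.join(bad[:10])}"
        )
    return SpeciesMatrix(
        barcodes=tuple(barcodes),
        feature_ids=tuple(feature_ids),
        feature_species=species,
        counts=mat,
    )


def call_cells(
    matrix: SpeciesMatrix, min_umi: int = 100, minor_fraction: float = 0.1
) -> CellCalls:
    """Call every barcode as type1 / type2 / mixed / background.

    Background: total UMIs < ``min_umi``.  Mixed: minor-species UMI share >=
    ``minor_fraction`` (inclusive; 50/50 above threshold is mixed).  Otherwise
    the majority species.  Deterministic and scale-free above the UMI floor.
    """
    if not 0 < minor_fraction < 0.5:
        raise ValidationError(f"minor_fraction must be in (0, 0.5), got {minor_fraction}")
    if min_umi < 1:
        raise ValidationError(f"min_umi must be >= 1, got {min_umi}")

    counts = matrix.counts
    umi1 = np.asarray(counts[matrix.feature_species == 0].sum(axis=0)).ravel()
    umi2 = np.asarray(counts[matrix.feature_species == 1].sum(axis=0)).ravel()
    total = umi1 + umi2

    calls = np.full(matrix.n_barcodes, "background", dtype=object)
    called = total >= min_umi
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_share = np.minimum(umi1, umi2) / np.where(total > 0, total, 1)
    mixed = called & (minor_share >= minor_fraction)
    calls[called & ~mixed & (umi1 >= umi2)] = "type1"
    calls[called & ~mixed & (umi1 < umi2)] = "type2"
    calls[mixed] = "mixed"

    n_mixed = int(mixed.sum())
    summary = DropletCounts(
        n_type1=float((calls == "type1").sum() + n_mixed),
        n_type2=float((calls == "type2").sum() + n_mixed),
        n_mixed=float(n_mixed),
    )
    table = pd.DataFrame(
        {
            "barcode": list(matrix.barcodes),
            "umi_type1": umi1.astype(np.int64),
            "umi_type2": umi2.astype(np.int64),
            "call": calls,
        }
    )
    return CellCalls(table=table, summary=summary, min_umi=min_umi, minor_fraction=minor_fraction)


def synthesize_matrix(
    cells_type1: np.ndarray,
    cells_type2: np.ndarray,
    umis_per_cell: float = 1000.0,
    n_features_per_species: int = 3,
    species_prefixes: Sequence[str] = ("hg_", "mm_"),
    rng: Optional[np.random.Generator] = None,
) -> SpeciesMatrix:
    """Build a synthetic cellranger-style count matrix from simulated droplets.

    ``cells_type1``/``cells_type2`` are per-droplet cell counts (e.g. from
    :func:`barnyard.simulate.simulate_cells`); only non-empty droplets become
    barcodes.  Each droplet's per-species UMI total is Poisson with mean
    ``umis_per_cell`` per cell, split across that species' features uniformly
    at random.  No ambient contamination is simulated, so with deep UMIs every
    call is unambiguous.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    c1 = np.asarray(cells_type1)
    c2 = np.asarray(cells_type2)
    if c1.shape != c2.shape:
        raise ValidationError("per-droplet cell count arrays must have equal length")
    nonempty = (c1 + c2) >= 1
    c1, c2 = c1[nonempty], c2[nonempty]
    n_bc = int(nonempty.sum())
    k = n_features_per_species

    umi1 = rng.poisson(umis_per_cell * c1)
    umi2 = rng.poisson(umis_per_cell * c2)
    cols = []
    for sp_offset, umis in ((0, umi1), (k, umi2)):
        block = rng.multinomial(umis, np.full(k, 1.0 / k))  # (n_bc, k)
        cols.append((sp_offset, block))
    dense = np.zeros((2 * k, n_bc), dtype=np.int64)
    for offset, block in cols:
        dense[offset : offset + k, :] = block.T

    p1, p2 = species_prefixes
    feature_ids = [f"{p1}gene{i}" for i in range(k)] + [f"{p2}gene{i}" for i in range(k)]
    barcodes = [f"BC{i:08d}" for i in range(n_bc)]
    return SpeciesMatrix(
        barcodes=tuple(barcodes),
        feature_ids=tuple(feature_ids),
        feature_species=np.array([0] * k + [1] * k, dtype=np.int8),
        counts=sp.csr_matrix(dense),
    )


def write_matrix(matrix: SpeciesMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write a SpeciesMatrix as an uncompressed matrix.mtx / features.tsv / barcodes.tsv triplet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    scipy.io.mmwrite(paths["mtx"], sp.coo_matrix(matrix.counts), field="integer")
    with open(paths["features"], "w") as fh:
        for fid in matrix.feature_ids:
            fh.write(f"{fid}\t{fid}\tGene Expression\n")
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(matrix.barcodes) + ("\n" if matrix.barcodes else ""))
    return paths
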