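"""Text formats used by animal-breeding solvers.

Pedigree: whitespace-delimited ``id sire dam gen sex fN fA fB fC`` with
1-based ids and 0 for an unknown parent.  Genotypes: animal id plus a
fixed-width gene-content string (0/1/2, 5 = missing).  Phenotypes: CSV
with header.  Matrices: coordinate ``i j value`` triples (1-based, upper
triangle including the diagonal).  Gamma: labelled symmetric matrix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomic import MarkerMatrix
from .pedigree import UNKNOWN, GammaMatrix, Pedigree


def write_pedigree(path, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        for i in range(ped.n):
            comp = (ped.breed_comp[i] if ped.breed_comp is not None
                    else np.full(4, np.nan))
            sex = ped.sex[i] if ped.sex is not None else 0
            gen = ped.birth_gen[i] if ped.birth_gen is not None else 0
            fh.write(f"{i + 1} {ped.sire[i] + 1} {ped.dam[i] + 1} "
                     f"{gen} {sex} "
                     + " ".join(f"{c:.6f}" for c in comp) + "\n")


def read_pedigree(path) -> Pedigree:
    rows = np.loadtxt(path, ndmin=2)
    sire = rows[:, 1].astype(np.int64) - 1
    dam = rows[:, 2].astype(np.int64) - 1
    comp = rows[:, 5:9] if rows.shape[1] >= 9 else None
    return Pedigree(sire, dam, breed_comp=comp,
                    sex=rows[:, 4].astype(np.int8),
                    birth_gen=rows[:, 3].astype(np.int64))


def write_genotypes(path, markers: MarkerMatrix) -> None:
    geno = np.rint(markers.geno).astype(int)
    with open(path, "w") as fh:
        for i, aid in enumerate(markers.animal_ids):
            s = "".join(str(g) for g in geno[i])
            fh.write(f"{int(aid) + 1} {s}\n")


def read_genotypes(path) -> MarkerMatrix:
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            aid, s = line.split()
            ids.append(int(aid) - 1)
            rows.append(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))
    return MarkerMatrix(np.vstack(rows).astype(np.int8), np.array(ids))


def write_marker_metadata(path, markers: MarkerMatrix) -> None:
    pd.DataFrame({
        "marker": markers.marker_ids,
        "chrom_class": markers.chrom_class,
        "freq": markers.allele_frequency(),
        "call_rate": markers.call_rate(),
        "het_freq": markers.het_frequency(),
    }).to_csv(path, index=False)


def write_phenotypes(path, phen: pd.DataFrame) -> None:
    phen.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_gamma(path, gamma: GammaMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(gamma.labels) + "\n")
        for row in gamma.values:
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")


def read_gamma(path) -> GammaMatrix:
    with open(path) as fh:
        labels = fh.readline().split()
        vals = np.loadtxt(fh, ndmin=2)
    return GammaMatrix(vals, labels=labels)


def write_coordinate_matrix(path, mat) -> None:
    """Upper triangle (incl. diagonal) as 1-based ``i j value`` triples."""
    m = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        for i, j, v in zip(m.row, m.col, m.data):
            if j >= i and v != 0.0:
                fh.write(f"{i + 1} {j + 1} {v:.12g}\n")


def read_coordinate_matrix(path, size: int | None = None) -> sp.csr_matrix:
    tri = np.loadtxt(path, ndmin=2)
    i = tri[:, 0].astype(int) - 1
    j = tri[:, 1].astype(int) - 1
    v = tri[:, 2]
    if size is None:
        size = int(max(i.max(), j.max())) + 1
    off = i != j
    rows = np.concatenate([i, j[off]])
    cols = np.concatenate([j, i[off]])
    vals = np.concatenate([v, v[off]])
    return sp.coo_matrix((vals, (rows, cols)), shape=(size, size)).tocsr()


def write_group_assignment(path, assignment) -> None:
    """Unknown-slot mapping: ``animal slot group-label`` per line."""
    labels = assignment.definition.labels
    with open(path, "w") as fh:
        for i, g in enumerate(assignment.sire_group):
            if g >= 0:
                fh.write(f"{i + 1} sire {labels[g]}\n")
        for i, g in enumerate(assignment.dam_group):
            if g >= 0:
                fh.write(f"{i + 1} dam {labels[g]}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
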