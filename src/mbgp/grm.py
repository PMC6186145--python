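"""Multi-breed genomic relationship matrices.

The multi-breed GRM centers genotype dosages with breed-specific allele
frequencies and scales each 2x2 breed block separately: within-breed blocks
are divided by that breed's sum of expected marker variances
``sum_j 2 p_kj (1 - p_kj)``, and the cross-breed block by the geometric mean
of the two breed scales.  Restricted to one breed's block this reduces to the
standard VanRaden method-1 GRM built with that breed's own frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, breed_frequencies

__all__ = [
    "MultiBreedGRM",
    "center_by_breed",
    "build_multibreed_grm",
    "export_grm",
    "import_grm",
]


@dataclass
class MultiBreedGRM:
    """A symmetric relationship matrix with breed-blocked scaling.

    ``scales`` records each breed's denominator ``sum_j 2 p_kj (1 - p_kj)``
    so that numerators remain recoverable (they are additive over disjoint
    marker sets).
    """

    values: np.ndarray
    individual_ids: list[str]
    breeds: np.ndarray
    marker_set: str
    scales: dict[str, float]
    n_markers: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.individual_ids) != n or len(self.breeds) != n:
            raise ValueError("ID/breed lists do not match GRM dimension")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("GRM must be exactly symmetric")
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("breed scales must be strictly positive")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def subset(self, rows: np.ndarray) -> np.ndarray:
        """Dense sub-matrix for the given row indices (rows == cols)."""
        rows = np.asarray(rows, dtype=int)
        return self.values[np.ix_(rows, rows)]


def center_by_breed(
    g: GenotypeMatrix,
    freqs: dict[str, np.ndarray] | None,
    marker_indices: np.ndarray,
) -> dict[str, np.ndarray]:
    """Center each breed's dosages by twice its own allele frequencies.

    Returns one matrix per breed (rows in that breed's original order):
    ``Z_k[i, j] = x_ij - 2 p_kj``.  A frequency of exactly 0 or 1 inside the
    marker set is rejected — such a marker is monomorphic within a breed and
    should have been removed by quality control.
    """
    marker_indices = np.asarray(marker_indices, dtype=int)
    if marker_indices.size == 0:
        raise ValueError("marker set is empty")
    if freqs is None:
        freqs = breed_frequencies(g, marker_indices)
        freq_at_set = freqs
    else:
        freq_at_set = {b: np.asarray(p, dtype=float)[marker_indices]
                       for b, p in freqs.items()}
    out = {}
    for label in g.breed_labels:
        p = freq_at_set[label]
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError(
                f"marker monomorphic in breed {label!r}: frequencies must be in (0,1)"
            )
        rows = g.breed_rows(label)
        out[label] = g.codes[np.ix_(rows, marker_indices)].astype(float) - 2.0 * p
    return out


def build_multibreed_grm(
    g: GenotypeMatrix,
    marker_indices: np.ndarray,
    freqs: dict[str, np.ndarray] | None = None,
    name: str = "GRM",
) -> MultiBreedGRM:
    """Assemble the breed-blocked GRM over the given marker set.

    When ``freqs`` is omitted, allele frequencies are recomputed from the
    currently included individuals of each breed (the frequencies that also
    define the centering).  Cross-breed entries are scaled by the geometric
    mean of the two within-breed denominators, which makes the matrix
    symmetric by construction.
    """
    marker_indices = np.asarray(marker_indices, dtype=int)
    if marker_indices.size == 0:
        raise ValueError("marker set is empty")
    if freqs is None:
        freqs = breed_frequencies(g, marker_indices)
        freqs_full = None
    else:
        freqs_full = freqs
    z_by_breed = center_by_breed(g, freqs_full, marker_indices)

    la, lb = g.breed_labels
    p_at = (freqs if freqs_full is None
            else {b: np.asarray(p)[marker_indices] for b, p in freqs.items()})
    scales = {b: float(np.sum(2.0 * p_at[b] * (1.0 - p_at[b]))) for b in (la, lb)}
    if any(s <= 0 for s in scales.values()):
        raise ValueError("GRM denominator is not positive")

    n = g.n_individuals
    z = np.empty((n, marker_indices.size))
    sqrt_scale = np.empty(n)
    breeds = g.breeds
    for label in (la, lb):
        rows = g.breed_rows(label)
        z[rows] = z_by_breed[label]
        sqrt_scale[rows] = np.sqrt(scales[label])
    values = (z @ z.T) / np.outer(sqrt_scale, sqrt_scale)
    values = (values + values.T) / 2.0  # enforce exact symmetry

    return MultiBreedGRM(
        values=values,
        individual_ids=list(g.individual_ids),
        breeds=breeds,
        marker_set=name,
        scales=scales,
        n_markers=int(marker_indices.size),
    )


# ---------------------------------------------------------------------------
# serialization: GCTA-style text triplets, or a binary .npz container
# ---------------------------------------------------------------------------

def export_grm(grm: MultiBreedGRM, prefix, fmt: str = "gcta") -> None:
    """Write a GRM to disk.

    ``gcta``: ``<prefix>.grm.txt`` with 1-based lower-triangle rows
    ``i  j  n_markers  value``, plus ``<prefix>.grm.id`` (breed, individual)
    and a ``<prefix>.grm.meta.json`` sidecar holding the marker-set name and
    breed scales.  ``npz``: a lossless binary container with the same
    metadata embedded.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {"marker_set": grm.marker_set, "scales": grm.scales,
            "n_markers": grm.n_markers}
    if fmt == "gcta":
        n = grm.n_individuals
        i, j = np.tril_indices(n)
        tab = pd.DataFrame({
            "i": i + 1, "j": j + 1,
            "n_markers": grm.n_markers,
            "value": grm.values[i, j],
        })
        tab.to_csv(f"{prefix}.grm.txt", sep="\t", index=False, header=False,
                   float_format="%.12g")
        pd.DataFrame({"breed": grm.breeds, "iid": grm.individual_ids}).to_csv(
            f"{prefix}.grm.id", sep="\t", index=False, header=False)
        Path(f"{prefix}.grm.meta.json").write_text(json.dumps(meta))
    elif fmt == "npz":
        np.savez_compressed(
            f"{prefix}.grm.npz",
            values=grm.values,
            individual_ids=np.array(grm.individual_ids),
            breeds=np.asarray(grm.breeds),
            meta=np.array(json.dumps(meta)),
        )
    else:
        raise ValueError(f"unknown GRM format {fmt!r}")


def import_grm(prefix, fmt: str = "gcta",
               expected_ids: list[str] | None = None) -> MultiBreedGRM:
    """Read a GRM written by :func:`export_grm`.

    If ``expected_ids`` is given (e.g. from a phenotype table), a mismatch in
    content or order is an explicit error rather than a silent realignment.
    """
    prefix = Path(prefix)
    if fmt == "gcta":
        ids_tab = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None,
                              names=["breed", "iid"], dtype=str)
        ids = ids_tab["iid"].tolist()
        breeds = ids_tab["breed"].to_numpy()
        tab = pd.read_csv(f"{prefix}.grm.txt", sep="\t", header=None,
                          names=["i", "j", "n_markers", "value"])
        n = len(ids)
        values = np.zeros((n, n))
        ii = tab["i"].to_numpy() - 1
        jj = tab["j"].to_numpy() - 1
        values[ii, jj] = tab["value"].to_numpy()
        values[jj, ii] = tab["value"].to_numpy()
        meta = json.loads(Path(f"{prefix}.grm.meta.json").read_text())
        n_markers = int(tab["n_markers"].iloc[0])
    elif fmt == "npz":
        with np.load(f"{prefix}.grm.npz") as z:
            values = z["values"]
            ids = [str(s) for s in z["individual_ids"]]
            breeds = np.asarray([str(s) for s in z["breeds"]])
            meta = json.loads(str(z["meta"]))
        n_markers = int(meta["n_markers"])
    else:
        raise ValueError(f"unknown GRM format {fmt!r}")

    if expected_ids is not None and list(expected_ids) != list(ids):
        raise ValueError("GRM individual IDs do not match the expected ID list")
    return MultiBreedGRM(
        values=values,
        individual_ids=ids,
        breeds=breeds,
        marker_set=str(meta["marker_set"]),
        scales={k: float(v) for k, v in meta["scales"].items()},
        n_markers=n_markers,
    )
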