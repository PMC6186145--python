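"""Synthetic two-breed genotype and phenotype simulation.

Genotypes are drawn under a Balding–Nichols drift model: each marker has an
ancestral allele frequency, and each breed's frequency is a Beta draw around
it with variance controlled by a fixation index (FST).  Markers are
independent (no linkage disequilibrium), so breed structure is the only
source of covariance between individuals.

Phenotypes follow a strictly additive architecture: a subset of markers is
causal, every causal marker carries a pair of allele-substitution effects
(one per breed) drawn from a bivariate standard normal with a configurable
between-breed correlation, true breeding values are genotype-dosage sums of
those effects, and residuals are Gaussian with a variance set from the
realized breeding-value variance and the target heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SimulationTruth",
    "simulate_two_breed_genotypes",
    "breed_frequencies",
    "qc_min_minor_copies",
    "sample_causal_effects",
    "true_breeding_values",
    "simulate_phenotypes",
    "write_raw",
    "read_raw",
    "write_phenotypes",
    "read_phenotypes",
    "genotypes_from_vcf",
]


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes for individuals from exactly two breeds.

    ``codes[i, j]`` counts copies (0/1/2) of the reference allele of marker
    ``j`` in individual ``i``.  Individuals are ordered breed-A block first,
    then breed-B; downstream incidence matrices rely on that convention.
    """

    codes: np.ndarray
    individual_ids: list[str]
    breed_of: dict[str, str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        n, m = self.codes.shape
        if n == 0 or m == 0:
            raise ValueError("genotype matrix must have >=1 individual and marker")
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ValueError("ID lists do not match genotype dimensions")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual IDs")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker IDs")
        missing = [i for i in self.individual_ids if i not in self.breed_of]
        if missing:
            raise ValueError(f"individuals without a breed label: {missing[:5]}")
        if not np.isin(self.codes, (0, 1, 2)).all():
            raise ValueError("genotype codes must be 0, 1 or 2 (missing not supported)")
        labels = sorted(set(self.breed_of[i] for i in self.individual_ids))
        if len(labels) != 2:
            raise ValueError(f"exactly two breeds required, found {labels}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def breeds(self) -> np.ndarray:
        """Breed label per individual, in row order."""
        return np.array([self.breed_of[i] for i in self.individual_ids])

    @property
    def breed_labels(self) -> tuple[str, str]:
        """The two breed labels in order of first appearance."""
        seen: list[str] = []
        for i in self.individual_ids:
            b = self.breed_of[i]
            if b not in seen:
                seen.append(b)
        return tuple(seen)  # type: ignore[return-value]

    def breed_rows(self, label: str) -> np.ndarray:
        """Row indices of individuals belonging to ``label``."""
        breeds = self.breeds
        rows = np.flatnonzero(breeds == label)
        if rows.size == 0:
            raise ValueError(f"breed {label!r} has no individuals")
        return rows

    def subset_markers(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            codes=self.codes[:, indices],
            individual_ids=list(self.individual_ids),
            breed_of=dict(self.breed_of),
            marker_ids=[self.marker_ids[j] for j in indices],
        )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated phenotype replicate.

    ``effects`` maps breed label to the allele-substitution effect vector of
    the causal markers (trait units per allele copy); ``top_indices`` marks
    the causal subset playing the role of pre-selected markers.
    ``sigma2_a`` is the realized (denominator ``n``) variance of the true
    breeding values within each breed.
    """

    causal_indices: np.ndarray
    top_indices: np.ndarray
    effects: dict[str, np.ndarray]
    tbv: np.ndarray
    h2: float
    rg_sim: float
    sigma2_a: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.top_indices = np.asarray(self.top_indices, dtype=int)
        for b, a in self.effects.items():
            if len(a) != len(self.causal_indices):
                raise ValueError(f"effect vector for breed {b!r} has wrong length")
        if not set(self.top_indices).issubset(set(self.causal_indices)):
            raise ValueError("pre-selected subset must be causal")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        if abs(self.rg_sim) > 1:
            raise ValueError("|rg| must be <= 1")


def simulate_two_breed_genotypes(
    n_breed_a: int,
    n_breed_b: int,
    n_markers: int,
    fst: float = 0.1,
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int | np.random.Generator = 0,
    breed_labels: tuple[str, str] = ("A", "B"),
) -> GenotypeMatrix:
    """Draw unlinked genotypes for two diverged breeds.

    Per marker an ancestral frequency ``p`` is uniform on
    ``ancestral_maf_range``; each breed's frequency is Beta-distributed with
    mean ``p`` and variance ``fst * p * (1 - p)``; genotypes are then
    ``Binomial(2, p_breed)`` per individual (Hardy–Weinberg within breed).
    """
    if n_breed_a <= 0 or n_breed_b <= 0 or n_markers <= 0:
        raise ValueError("counts must be positive")
    if not 0 < fst < 1:
        raise ValueError("fst must lie strictly inside (0, 1)")
    lo, hi = ancestral_maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("ancestral MAF range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)

    p_anc = rng.uniform(lo, hi, size=n_markers)
    # Beta with mean p and variance fst*p*(1-p): shape parameters p*c, (1-p)*c
    # where c = (1 - fst) / fst.
    c = (1.0 - fst) / fst
    p_a = rng.beta(p_anc * c, (1.0 - p_anc) * c)
    p_b = rng.beta(p_anc * c, (1.0 - p_anc) * c)

    codes_a = rng.binomial(2, p_a, size=(n_breed_a, n_markers))
    codes_b = rng.binomial(2, p_b, size=(n_breed_b, n_markers))
    codes = np.vstack([codes_a, codes_b]).astype(np.int8)

    la, lb = breed_labels
    ids_a = [f"{la}_{i:05d}" for i in range(n_breed_a)]
    ids_b = [f"{lb}_{i:05d}" for i in range(n_breed_b)]
    ids = ids_a + ids_b
    breed_of = {**{i: la for i in ids_a}, **{i: lb for i in ids_b}}
    marker_ids = [f"snp{j:06d}" for j in range(n_markers)]
    return GenotypeMatrix(codes, ids, breed_of, marker_ids)


def breed_frequencies(
    g: GenotypeMatrix, marker_indices: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Observed allele frequencies per breed, computed from that breed's rows."""
    if marker_indices is None:
        marker_indices = np.arange(g.n_markers)
    marker_indices = np.asarray(marker_indices, dtype=int)
    out = {}
    for label in g.breed_labels:
        rows = g.breed_rows(label)
        out[label] = g.codes[np.ix_(rows, marker_indices)].mean(axis=0) / 2.0
    return out


def qc_min_minor_copies(g: GenotypeMatrix, min_copies: int) -> np.ndarray:
    """Indices of markers with >= ``min_copies`` minor-allele copies in each breed.

    The tally is breed-wise: a marker survives only if the rarer allele is
    seen at least ``min_copies`` times among the 2n allele copies of *every*
    breed separately, mirroring routine SNP-chip quality control.
    """
    if min_copies < 0:
        raise ValueError("min_copies must be >= 0")
    keep = np.ones(g.n_markers, dtype=bool)
    for label in g.breed_labels:
        rows = g.breed_rows(label)
        alt = g.codes[rows].sum(axis=0)
        total = 2 * rows.size
        minor = np.minimum(alt, total - alt)
        keep &= minor >= min_copies
    return np.flatnonzero(keep)


def sample_causal_effects(
    n_causal: int,
    rg: float,
    seed: int | np.random.Generator = 0,
    breed_labels: tuple[str, str] = ("A", "B"),
) -> dict[str, np.ndarray]:
    """Paired allele-substitution effects, one vector per breed.

    Each causal marker's pair is bivariate normal with mean 0, unit
    variances and correlation ``rg``; at ``rg = 1`` the two vectors are
    identical, at ``rg = 0`` independent.
    """
    if n_causal <= 0:
        raise ValueError("n_causal must be positive")
    if abs(rg) > 1:
        raise ValueError("|rg| must be <= 1")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_causal)
    z2 = rng.standard_normal(n_causal)
    a_first = z1
    a_second = rg * z1 + np.sqrt(max(0.0, 1.0 - rg * rg)) * z2
    la, lb = breed_labels
    return {la: a_first, lb: a_second}


def true_breeding_values(
    g: GenotypeMatrix,
    causal_indices: np.ndarray,
    effects: dict[str, np.ndarray],
) -> np.ndarray:
    """TBV_i = sum_j x_ij * a_j over causal loci, with i's own breed's effects.

    Raw 0/1/2 dosages are used, uncentered.
    """
    causal_indices = np.asarray(causal_indices, dtype=int)
    for b, a in effects.items():
        if len(a) != len(causal_indices):
            raise ValueError(f"effect vector for breed {b!r} has wrong length")
    x = g.codes[:, causal_indices].astype(float)
    tbv = np.empty(g.n_individuals)
    breeds = g.breeds
    for label in g.breed_labels:
        rows = breeds == label
        tbv[rows] = x[rows] @ effects[label]
    return tbv


def simulate_phenotypes(
    g: GenotypeMatrix,
    tbv: np.ndarray,
    h2: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Phenotype = TBV + Gaussian residual, heritability set within breed.

    The residual variance in breed k is ``sigma2_a_k * (1/h2 - 1)`` where
    ``sigma2_a_k`` is the realized variance of that breed's TBVs, so the
    simulated trait has heritability ``h2`` in both breeds by construction.
    Returns the phenotypes and the per-breed realized TBV variances.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1]; residual variance undefined at 0")
    tbv = np.asarray(tbv, dtype=float)
    if tbv.shape != (g.n_individuals,):
        raise ValueError("tbv length must match the number of individuals")
    rng = np.random.default_rng(seed)
    y = tbv.copy()
    sigma2_a: dict[str, float] = {}
    breeds = g.breeds
    for label in g.breed_labels:
        rows = np.flatnonzero(breeds == label)
        s2a = float(np.var(tbv[rows]))
        sigma2_a[label] = s2a
        var_e = s2a * (1.0 / h2 - 1.0)
        if var_e > 0:
            y[rows] = y[rows] + rng.normal(0.0, np.sqrt(var_e), size=rows.size)
    return y, sigma2_a


# ---------------------------------------------------------------------------
# text I/O: PLINK-style additive table, phenotype/truth tables, VCF ingest
# ---------------------------------------------------------------------------

def write_raw(g: GenotypeMatrix, raw_path, breed_path) -> None:
    """Write a PLINK ``.raw``-dialect additive table and a breed-map TSV."""
    geno = pd.DataFrame(g.codes, columns=g.marker_ids)
    geno.insert(0, "IID", g.individual_ids)
    geno.to_csv(raw_path, sep=" ", index=False)
    pd.DataFrame(
        {"individual_id": g.individual_ids,
         "breed": [g.breed_of[i] for i in g.individual_ids]}
    ).to_csv(breed_path, sep="\t", index=False)


def read_raw(raw_path, breed_path) -> GenotypeMatrix:
    geno = pd.read_csv(raw_path, sep=r"\s+")
    breed = pd.read_csv(breed_path, sep="\t")
    ids = geno["IID"].astype(str).tolist()
    marker_ids = [c for c in geno.columns if c != "IID"]
    breed_of = dict(zip(breed["individual_id"].astype(str), breed["breed"].astype(str)))
    codes = geno[marker_ids].to_numpy(dtype=np.int8)
    return GenotypeMatrix(codes, ids, breed_of, marker_ids)


def write_phenotypes(path, g: GenotypeMatrix, y: np.ndarray,
                     tbv: np.ndarray | None = None,
                     dedc: np.ndarray | None = None) -> pd.DataFrame:
    """Phenotype table TSV: individual_id, breed, phenotype, tbv, dedc."""
    n = g.n_individuals
    df = pd.DataFrame({
        "individual_id": g.individual_ids,
        "breed": g.breeds,
        "phenotype": np.asarray(y, dtype=float),
        "tbv": np.full(n, np.nan) if tbv is None else np.asarray(tbv, dtype=float),
        "dedc": np.ones(n) if dedc is None else np.asarray(dedc, dtype=float),
    })
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "breed": str})
    required = {"individual_id", "breed", "phenotype", "dedc"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table must contain columns {sorted(required)}")
    return df


def genotypes_from_vcf(vcf_path, breed_path) -> GenotypeMatrix:
    """Convert diploid biallelic VCF GT fields to additive codes.

    Requires cyvcf2.  Multiallelic or missing genotypes are rejected —
    post-QC data are assumed complete.
    """
    from cyvcf2 import VCF  # local import: optional dependency

    vcf = VCF(str(vcf_path))
    ids = list(vcf.samples)
    codes_cols, marker_ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic site not supported: {var.ID or var.POS}")
        dosage = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        if (dosage == 2).any():
            raise ValueError(f"missing genotype at {var.ID or var.POS}")
        codes_cols.append(np.where(dosage == 3, 2, dosage))
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    breed = pd.read_csv(breed_path, sep="\t")
    breed_of = dict(zip(breed["individual_id"].astype(str), breed["breed"].astype(str)))
    codes = np.column_stack(codes_cols).astype(np.int8)
    return GenotypeMatrix(codes, ids, breed_of, marker_ids)
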