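"""Replicated simulation scenarios: marker-set taxonomy and study runner.

One scenario simulates many replicates of the two-breed design, and for each
replicate builds the named marker sets, their multi-breed GRMs, fits the
requested model designs (bivariate parameter estimation and/or
cross-validated prediction accuracy), and aggregates estimates over
replicates into a summary table (mean and empirical standard error of the
mean per cell).

Marker-set taxonomy (simulation mode), mirroring the pre-selection logic of
chip-based studies at configurable scale:

* ``ALL`` — every post-QC marker.
* ``CAUSAL`` — all causal markers (pre-selected subset + random causal).
* ``NON_CAUSAL`` — the complement of ``CAUSAL`` in ``ALL``.
* ``TOP`` — the causal subset playing the role of pre-selected markers.
* ``50K`` — ``ALL`` minus ``TOP`` (random causal + all non-causal), the
  stand-in for an unselected chip panel.
* ``TOP_RN`` — ``TOP`` plus randomly drawn non-causal markers (false
  positives / random noise), redrawn per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import simdata
from .grm import MultiBreedGRM, build_multibreed_grm
from .greml import build_model, genetic_correlation, heritability_report, reml_fit
from .prediction import cross_validate
from .simdata import GenotypeMatrix, SimulationTruth

__all__ = [
    "MarkerSet",
    "DesignSpec",
    "ScenarioConfig",
    "ScenarioResult",
    "build_marker_sets",
    "simulate_replicate",
    "run_scenario",
]


@dataclass
class MarkerSet:
    """A named, sorted, duplicate-free list of marker indices."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise ValueError(f"marker set {self.name!r} is empty")
        if np.unique(idx).size != idx.size:
            raise ValueError(f"marker set {self.name!r} has duplicate indices")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return int(self.indices.size)


def build_marker_sets(
    truth: SimulationTruth,
    g: GenotypeMatrix,
    n_rn: int = 150,
    seed: int | np.random.Generator = 0,
) -> dict[str, MarkerSet]:
    """Construct the six named marker sets from one replicate's ground truth."""
    m = g.n_markers
    causal = np.asarray(truth.causal_indices, dtype=int)
    top = np.asarray(truth.top_indices, dtype=int)
    if causal.max(initial=-1) >= m:
        raise ValueError("causal indices out of range for this genotype matrix")
    all_idx = np.arange(m)
    non_causal = np.setdiff1d(all_idx, causal)
    if n_rn > non_causal.size:
        raise ValueError("requested more random-noise markers than non-causal available")
    rng = np.random.default_rng(seed)
    rn = rng.choice(non_causal, size=n_rn, replace=False)
    sets = {
        "ALL": MarkerSet("ALL", all_idx),
        "CAUSAL": MarkerSet("CAUSAL", causal),
        "NON_CAUSAL": MarkerSet("NON_CAUSAL", non_causal),
        "TOP": MarkerSet("TOP", top),
        "50K": MarkerSet("50K", np.setdiff1d(all_idx, top)),
        "TOP_RN": MarkerSet("TOP_RN", np.union1d(top, rn)),
    }
    return sets


@dataclass
class DesignSpec:
    """One model design: family plus the marker set per GRM.

    ``fit_params`` requests a full-data bivariate (or single-breed) fit for
    genetic-parameter estimation; ``cv`` requests the k-fold prediction
    accuracy for the validation breed.
    """

    family: str
    marker_sets: tuple[str, ...]
    fit_params: bool = True
    cv: bool = False

    @property
    def label(self) -> str:
        return f"{self.family}:{'+'.join(self.marker_sets)}"


@dataclass
class ScenarioConfig:
    """Study conditions for one replicated scenario.

    Defaults are the desk-scale rendition of the two-breed stature design:
    1,000 + 400 individuals, 3,000 markers of which 283 are causal (133
    pre-selected + 150 random), trait heritability 0.8, divergence FST 0.1,
    and a quality-control floor of 10 minor-allele copies per breed.
    """

    n_breed_a: int = 1000
    n_breed_b: int = 400
    n_markers: int = 3000
    n_top: int = 133
    n_random_causal: int = 150
    n_rn: int = 150
    fst: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    min_minor_copies: int = 10
    h2: float = 0.8
    rg: float = 1.0
    reps: int = 20
    cv_folds: int = 5
    master_seed: int = 0
    breed_labels: tuple[str, str] = ("A", "B")
    designs: list[DesignSpec] = field(default_factory=list)
    oversample: float = 1.4  # raw markers simulated per post-QC marker kept

    @property
    def n_causal(self) -> int:
        return self.n_top + self.n_random_causal


def _replicate_seeds(config: ScenarioConfig, rep: int) -> dict[str, int]:
    """Deterministic per-replicate sub-seeds.

    Derived from ``SeedSequence(master_seed, spawn_key=(rep,))`` so any
    subset of replicates can be re-run independently; the fold seed is one
    of them, so all designs of a replicate share validation sets.
    """
    ss = np.random.SeedSequence(config.master_seed, spawn_key=(rep,))
    vals = np.random.default_rng(ss).integers(2**31, size=6)
    keys = ("genotypes", "architecture", "effects", "phenotypes", "folds",
            "marker_sets")
    return {k: int(v) for k, v in zip(keys, vals)}


def simulate_replicate(
    config: ScenarioConfig, rep: int
) -> tuple[GenotypeMatrix, SimulationTruth, pd.DataFrame, dict[str, int]]:
    """Simulate one replicate: genotypes, QC, causal architecture, phenotypes."""
    seeds = _replicate_seeds(config, rep)
    n_raw = int(np.ceil(config.n_markers * config.oversample))
    g_raw = simdata.simulate_two_breed_genotypes(
        config.n_breed_a, config.n_breed_b, n_raw,
        fst=config.fst, ancestral_maf_range=config.ancestral_maf_range,
        seed=seeds["genotypes"], breed_labels=config.breed_labels,
    )
    kept = simdata.qc_min_minor_copies(g_raw, config.min_minor_copies)
    if kept.size < config.n_markers:
        raise ValueError(
            f"only {kept.size} markers survive QC; increase oversample")
    g = g_raw.subset_markers(kept[: config.n_markers])

    rng = np.random.default_rng(seeds["architecture"])
    causal = np.sort(rng.choice(g.n_markers, size=config.n_causal, replace=False))
    top = np.sort(rng.choice(causal, size=config.n_top, replace=False))
    effects = simdata.sample_causal_effects(
        config.n_causal, config.rg, seed=seeds["effects"],
        breed_labels=config.breed_labels)
    tbv = simdata.true_breeding_values(g, causal, effects)
    y, sigma2_a = simdata.simulate_phenotypes(g, tbv, config.h2,
                                              seed=seeds["phenotypes"])
    truth = SimulationTruth(
        causal_indices=causal, top_indices=top, effects=effects,
        tbv=tbv, h2=config.h2, rg_sim=config.rg, sigma2_a=sigma2_a,
    )
    pheno = simdata.write_phenotypes(None, g, y, tbv=tbv)
    return g, truth, pheno, seeds


def _design_reference(design: DesignSpec, pheno: pd.DataFrame,
                      labels: tuple[str, str]) -> list[str]:
    la, lb = labels
    fam = design.family.upper()
    if fam.startswith("MB"):
        return pheno["individual_id"].tolist()
    breed = la if fam.startswith("AB") else lb
    return pheno.loc[pheno["breed"] == breed, "individual_id"].tolist()


@dataclass
class ScenarioResult:
    """Per-replicate estimates and their across-replicate summary."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    config: ScenarioConfig

    def write(self, replicates_path, summary_path) -> None:
        self.replicates.to_csv(replicates_path, sep="\t", index=False,
                               float_format="%.8g")
        self.summary.to_csv(summary_path, sep="\t", index=False,
                            float_format="%.8g")


def run_scenario(config: ScenarioConfig,
                 reml_opts: dict | None = None) -> ScenarioResult:
    """Run every design over every replicate and aggregate.

    A replicate whose REML fit fails is recorded with ``converged = False``
    and excluded from the summary means; the summary reports the count of
    replicates entering each cell.
    """
    if not config.designs:
        raise ValueError("scenario has no designs")
    for d in config.designs:
        n_sets = len(d.marker_sets)
        if d.family.upper().endswith("SG") and n_sets != 1:
            raise ValueError(f"{d.label}: single-GRM family needs one marker set")
        if d.family.upper().endswith("MG") and n_sets < 2:
            raise ValueError(f"{d.label}: multi-GRM family needs >=2 marker sets")
    reml_opts = reml_opts or {}
    la, lb = config.breed_labels
    rows = []
    for rep in range(config.reps):
        g, truth, pheno, seeds = simulate_replicate(config, rep)
        sets = build_marker_sets(truth, g, n_rn=config.n_rn,
                                 seed=seeds["marker_sets"])
        needed = sorted({s for d in config.designs for s in d.marker_sets})
        grms: dict[str, MultiBreedGRM] = {
            name: build_multibreed_grm(g, sets[name].indices, name=name)
            for name in needed
        }
        for design in config.designs:
            base = {
                "rep": rep, "seed": seeds["genotypes"],
                "design": design.label, "family": design.family.upper(),
                "rg_sim": config.rg, "h2_sim": config.h2,
            }
            accuracy = np.nan
            if design.cv:
                cv = cross_validate(
                    pheno, grms, design.family, list(design.marker_sets),
                    validation_breed=lb, k=config.cv_folds,
                    seed=seeds["folds"], target_col="tbv",
                    reml_opts=reml_opts,
                )
                accuracy = cv.mean_accuracy
            if design.fit_params:
                ref = _design_reference(design, pheno, config.breed_labels)
                model = build_model(pheno, grms, list(design.marker_sets),
                                    include_ids=ref)
                try:
                    fit = reml_fit(model, **reml_opts)
                except Exception as exc:  # noqa: BLE001 - record, don't abort
                    rows.append({**base, "component": design.marker_sets[0],
                                 "converged": False, "error": str(exc),
                                 "accuracy": accuracy})
                    continue
                h2_tab = heritability_report(fit).set_index(["component", "breed"])
                for cname in design.marker_sets:
                    entry = fit.params["components"][cname]
                    row = {**base, "component": cname,
                           "converged": bool(fit.converged),
                           "n_iter": fit.n_iter,
                           "loglik": fit.loglik,
                           "accuracy": accuracy}
                    for bl in fit.breed_labels:
                        row[f"var_{bl}"] = entry[f"var_{bl}"]
                        row[f"h2_{bl}"] = h2_tab.loc[(cname, bl), "h2"]
                        row[f"resid_{bl}"] = fit.params["residual"][f"var_{bl}"]
                        row[f"boundary_{bl}"] = bool(
                            fit.boundary["components"][cname][f"var_{bl}"])
                    if len(fit.breed_labels) == 2:
                        rg, rg_se = genetic_correlation(fit, cname)
                        row["cov"] = entry["cov"]
                        row["rg_hat"] = rg
                        row["rg_se"] = rg_se
                    rows.append(row)
            else:
                rows.append({**base, "component": "+".join(design.marker_sets),
                             "converged": True, "accuracy": accuracy})
    replicates = pd.DataFrame(rows)
    summary = summarize_replicates(replicates)
    return ScenarioResult(replicates=replicates, summary=summary, config=config)


def parameter_recovery_study(
    master_seed: int = 0,
    reps: int = 20,
    include_accuracy: bool = True,
    base: ScenarioConfig | None = None,
    reml_opts: dict | None = None,
) -> dict[float, ScenarioResult]:
    """The desk-scale parameter-recovery study over rg in {1, 0.5, 0.25}.

    At every simulated genetic correlation the single-GRM causal-marker
    model (MBSG:CAUSAL) is fitted; at rg = 1 the two multi-GRM partitions
    (CAUSAL + NON_CAUSAL and TOP + 50K) are fitted as well.  When
    ``include_accuracy`` is set, the across-breed causal-marker design
    (ABSG:CAUSAL) is cross-validated at every rg so the accuracy decline
    with decreasing rg can be measured.  Scenario seeds derive from
    ``master_seed`` so the whole study is reproducible from one integer.
    """
    base = base or ScenarioConfig()
    results: dict[float, ScenarioResult] = {}
    for idx, rg in enumerate((1.0, 0.5, 0.25)):
        designs = [DesignSpec("MBSG", ("CAUSAL",))]
        if rg == 1.0:
            designs += [
                DesignSpec("MBMG", ("CAUSAL", "NON_CAUSAL")),
                DesignSpec("MBMG", ("TOP", "50K")),
            ]
        if include_accuracy:
            designs.append(DesignSpec("ABSG", ("CAUSAL",),
                                      fit_params=False, cv=True))
        scen_seed = int(np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(idx,))
        ).integers(2**31))
        config = replace(base, rg=rg, reps=reps, designs=designs,
                         master_seed=scen_seed)
        results[rg] = run_scenario(config, reml_opts=reml_opts)
    return results


def summarize_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean and empirical SE of the mean per (design, component) cell.

    NaN cells (e.g. a genetic correlation undefined at a boundary) are
    excluded, with the contributing replicate count reported per metric.
    """
    metrics = [c for c in replicates.columns
               if c.startswith(("h2_", "var_", "resid_", "rg_hat"))
               or c in ("accuracy", "cov")]
    ok = replicates[replicates["converged"].fillna(False)]
    out = []
    for (design, comp), grp in ok.groupby(["design", "component"], sort=True):
        row: dict = {"design": design, "component": comp,
                     "n_converged": len(grp)}
        for metric in metrics:
            if metric not in grp:
                continue
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[f"{metric}_mean"] = np.nan
                row[f"{metric}_se"] = np.nan
                row[f"{metric}_n"] = 0
            else:
                row[f"{metric}_mean"] = float(vals.mean())
                row[f"{metric}_se"] = float(vals.std(ddof=1) / np.sqrt(vals.size)
                                            if vals.size > 1 else 0.0)
                row[f"{metric}_n"] = int(vals.size)
        out.append(row)
    return pd.DataFrame(out)
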