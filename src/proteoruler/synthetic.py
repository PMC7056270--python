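"""Synthetic label-free proteomics datasets with known ground truth.

The generator emulates the design of a T-cell activation study: biological
triplicates of naive wild-type cells and of TCR-activated cells from
wild-type and conditional-knockout genotypes, for CD4 and CD8 cells.  Every
protein carries a planted copies-per-cell value for each condition, so every
downstream stage (ruler quantification, differential statistics, mass
ranking) has an exact oracle.

Effect classes
--------------
``myc_dependent_induced``   low in naive cells, strongly induced on
                            activation in the wild type only; the knockout
                            stays at naive level.
``myc_independent_induced`` induced on activation in all genotypes.
``downregulated``           abundant in naive cells, reduced on activation
                            in all genotypes.
``unchanged``               flat across conditions (the null class).
``histone``                 condition-invariant; total histone mass is
                            calibrated exactly to the ruler's histone-mass
                            convention so that noise-free data are recovered
                            exactly.

Measurement model
-----------------
``intensity(sample, protein) = k_s * copies(condition) * MW * 2**eps`` with
``eps ~ Normal(0, sigma)`` in log2 units and an arbitrary per-sample scale
``k_s`` that the ruler must cancel.  Each intensity is independently set to
missing with a fixed probability (missingness completely at random), and
decoy/contaminant rows are appended with their flags set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import condition_labels
from .ruler import RulerConfig, histone_mass_per_cell, quality_category

__all__ = [
    "EFFECT_CLASSES",
    "GroundTruthProteome",
    "SimulationParams",
    "make_design",
    "make_ground_truth",
    "simulate_intensities",
    "simulate_dataset",
]

EFFECT_CLASSES = (
    "myc_dependent_induced",
    "myc_independent_induced",
    "downregulated",
    "unchanged",
    "histone",
)

DEFAULT_CLASS_FRACTIONS = {
    "myc_dependent_induced": 0.06,
    "myc_independent_induced": 0.06,
    "downregulated": 0.06,
    "unchanged": 0.81,
    "histone": 0.01,
}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults emulate the study design.

    Induced-class fold changes are drawn log-uniformly from ``fold_range``
    (activation-induced transporters rise from hundreds of copies per naive
    cell by up to ~100-fold).  ``histone_mass_fraction`` sets histone mass to
    ~4% of the naive proteome; the absolute histone mass equals the ruler
    convention of ``ruler_config`` so the generator and estimator share one
    calibration.  ``slc7a5_dep_fraction_*`` control how many induced
    proteins also fail to induce in an Slc7a5-knockout genotype.
    """

    noise_sigma_log2: float = 0.25
    missing_rate: float = 0.05
    n_decoys: int = 20
    n_contaminants: int = 20
    fold_range: tuple[float, float] = (4.0, 100.0)
    baseline_log10_range: tuple[float, float] = (2.0, 6.0)
    histone_mass_fraction: float = 0.04
    mol_weight_kda_log10_range: tuple[float, float] = (1.0, 2.6)
    sample_scale_log10_spread: float = 0.5
    slc7a5_dep_fraction_myc_dependent: float = 0.8
    slc7a5_dep_fraction_myc_independent: float = 0.2
    ruler_config: RulerConfig = field(default_factory=RulerConfig)

    def __post_init__(self):
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be a probability")
        if self.noise_sigma_log2 < 0:
            raise ValueError("noise_sigma_log2 must be non-negative")


@dataclass
class GroundTruthProteome:
    """Planted proteome: per-protein metadata and copies per condition.

    ``table`` columns: ``protein_id, gene_name, mol_weight_da, is_histone,
    effect_class, slc7a5_dependent`` plus one ``copies.<condition>`` column
    per condition.
    """

    table: pd.DataFrame
    conditions: list[str]
    params: SimulationParams
    seed: int

    def copies(self) -> pd.DataFrame:
        """Planted copies per cell, proteins x conditions."""
        cols = {c: self.table[f"copies.{c}"].to_numpy() for c in self.conditions}
        return pd.DataFrame(cols, index=self.table["protein_id"])


def make_design(
    genotypes: tuple[str, ...] = ("WT", "Myc_cKO"),
    cell_types: tuple[str, ...] = ("CD4", "CD8"),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Study design: naive wild-type plus TCR-activated cells of every
    genotype, per cell type, in biological replicates (default triplicates)."""
    rows = []
    for ct in cell_types:
        combos = [("WT", "naive")] + [(g, "TCR") for g in genotypes]
        for g, stim in combos:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_{ct}_{stim}_r{rep}",
                        "genotype": g,
                        "cell_type": ct,
                        "stimulation": stim,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _condition_multiplier(effect_class: str, slc7a5_dep: bool, genotype: str,
                          stimulation: str, fold: float) -> float:
    """Planted fold relative to the naive baseline for one condition."""
    if stimulation == "naive" or effect_class in ("unchanged", "histone"):
        return 1.0
    knocked_out = (
        (genotype == "Myc_cKO" and effect_class == "myc_dependent_induced")
        or (genotype == "Slc7a5_cKO" and slc7a5_dep)
    )
    if effect_class in ("myc_dependent_induced", "myc_independent_induced"):
        return 1.0 if knocked_out else fold
    if effect_class == "downregulated":
        return 1.0 / fold
    raise ValueError(f"unknown effect class {effect_class!r}")


def make_ground_truth(
    n_proteins: int,
    class_fractions: dict[str, float] | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
    design: pd.DataFrame | None = None,
) -> GroundTruthProteome:
    """Plant a proteome with known copies per condition.

    Class counts follow ``class_fractions`` (must sum to 1 within 1e-9).
    Baseline abundances are log-uniform; induced/repressed classes realise a
    per-protein fold from ``params.fold_range``; histone copies are
    condition-invariant with total histone mass equal to the ruler's
    histone-mass-per-cell convention, and non-histone baselines are rescaled
    so histones make up ``params.histone_mass_fraction`` of naive cell mass.
    Deterministic given ``seed``.
    """
    params = params or SimulationParams()
    fractions = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    unknown = set(fractions) - set(EFFECT_CLASSES)
    if unknown:
        raise ValueError(f"unknown effect classes {sorted(unknown)}")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1 (tolerance 1e-9)")
    design = design if design is not None else make_design()

    rng = np.random.default_rng(seed)
    # largest-remainder apportionment of class counts, >=1 histone always
    classes = [c for c in EFFECT_CLASSES if fractions.get(c, 0) > 0]
    raw = np.array([fractions[c] * n_proteins for c in classes])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_proteins - counts.sum()]:
        counts[i] += 1
    count_of = dict(zip(classes, counts))
    if count_of.get("histone", 0) < 1:
        if "histone" not in count_of:
            raise ValueError("at least one histone protein is required for the ruler")
        donor = max(count_of, key=lambda c: (count_of[c], c != "histone"))
        count_of[donor] -= 1
        count_of["histone"] += 1

    labels = np.repeat(classes, [count_of[c] for c in classes])
    n = len(labels)
    lo, hi = params.baseline_log10_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=n)
    # histones are DNA-stoichiometric and roughly equimolar in a real cell,
    # not spread over decades like the bulk proteome
    n_hist = count_of["histone"]
    baseline[labels == "histone"] = rng.uniform(0.5, 1.5, size=n_hist)
    mwlo, mwhi = params.mol_weight_kda_log10_range
    mol_weight = 1000.0 * 10.0 ** rng.uniform(mwlo, mwhi, size=n)
    flo, fhi = params.fold_range
    fold = np.exp(rng.uniform(np.log(flo), np.log(fhi), size=n))
    slc7a5_dep = np.zeros(n, dtype=bool)
    for cls, frac in (
        ("myc_dependent_induced", params.slc7a5_dep_fraction_myc_dependent),
        ("myc_independent_induced", params.slc7a5_dep_fraction_myc_independent),
    ):
        m = labels == cls
        slc7a5_dep[m] = rng.random(m.sum()) < frac

    is_hist = labels == "histone"
    avogadro = params.ruler_config.avogadro
    m_hist_target = histone_mass_per_cell(params.ruler_config)
    hist_mass = (baseline * mol_weight / avogadro)[is_hist].sum()
    baseline[is_hist] *= m_hist_target / hist_mass
    # rescale the rest so histones are the configured fraction of naive mass
    other_mass_target = m_hist_target * (1 - params.histone_mass_fraction) / params.histone_mass_fraction
    other_mass = (baseline * mol_weight / avogadro)[~is_hist].sum()
    baseline[~is_hist] *= other_mass_target / other_mass

    conditions = list(dict.fromkeys(condition_labels(design)))
    table = pd.DataFrame(
        {
            "protein_id": [f"SYN{i:05d}" for i in range(n)],
            "gene_name": [
                f"Hist1h{j}" if c == "histone" else f"Gene{i:05d}"
                for j, (i, c) in enumerate(zip(range(n), labels))
            ],
            "mol_weight_da": mol_weight,
            "is_histone": is_hist,
            "effect_class": labels,
            "slc7a5_dependent": slc7a5_dep,
        }
    )
    cond_meta = {
        c: (c.split(".")[0], c.split(".")[2]) for c in conditions
    }  # genotype, stimulation
    for cond in conditions:
        geno, stim = cond_meta[cond]
        mult = np.array(
            [
                _condition_multiplier(cls, dep, geno, stim, f)
                for cls, dep, f in zip(labels, slc7a5_dep, fold)
            ]
        )
        table[f"copies.{cond}"] = baseline * mult
    return GroundTruthProteome(table=table, conditions=conditions, params=params, seed=seed)


def simulate_intensities(
    truth: GroundTruthProteome,
    design: pd.DataFrame,
    seed: int = 0,
    params: SimulationParams | None = None,
) -> pd.DataFrame:
    """Simulate a protein-groups table from a planted proteome.

    Intensities are mass-proportional (``copies * MW``) with log-normal
    noise and an arbitrary per-sample scale factor; entries go missing
    completely at random; reversed-decoy and contaminant rows are appended
    with flags set.  Razor+unique / unique peptide counts are drawn so all
    three quantification-quality categories occur.  Deterministic given
    ``seed`` (noise only; the ground truth is fixed by ``truth``).

    Raises
    ------
    KeyError
        if the design contains a condition absent from the ground truth.
    """
    params = params or truth.params
    rng = np.random.default_rng(seed)
    conds = condition_labels(design)
    missing_conds = set(conds) - set(truth.conditions)
    if missing_conds:
        raise KeyError(f"design conditions absent from ground truth: {sorted(missing_conds)}")

    copies = truth.copies()
    n, n_samples = len(copies), len(design)
    mw = truth.table["mol_weight_da"].to_numpy()

    spread = params.sample_scale_log10_spread
    k = 10.0 ** rng.uniform(-spread, spread, size=n_samples)
    eps = rng.normal(0.0, params.noise_sigma_log2, size=(n, n_samples))
    base = copies[list(conds)].to_numpy() * mw[:, None]
    intens = base * k[None, :] * np.exp2(eps)
    miss = rng.random((n, n_samples)) < params.missing_rate
    intens[miss] = np.nan
    intens[base == 0] = np.nan

    # peptide counts: draw a category then counts consistent with it
    cat = rng.choice(3, size=n, p=[0.5, 0.3, 0.2])  # high, medium, low
    razor = np.empty(n, dtype=int)
    unique = np.empty(n, dtype=int)
    cfg = params.ruler_config
    for i, c in enumerate(cat):
        while True:
            if c == 0:
                r = rng.integers(cfg.high_min_peptides, 40)
                u = rng.integers(int(np.ceil(r * cfg.high_min_unique_fraction)), r + 1)
            elif c == 1:
                r = rng.integers(cfg.medium_min_peptides, 20)
                u = rng.integers(int(np.ceil(r * cfg.medium_min_unique_fraction)), r + 1)
            else:
                r = rng.integers(1, 6)
                u = rng.integers(0, r + 1)
            if quality_category(int(r), int(u), cfg) == ("high", "medium", "low")[c]:
                razor[i], unique[i] = r, u
                break

    groups = pd.DataFrame(
        {
            "group_id": truth.table["protein_id"].to_numpy(),
            "gene_name": truth.table["gene_name"].to_numpy(),
            "mol_weight_da": mw,
            "razor_unique_peptides": razor,
            "unique_peptides": unique,
            "flag_contaminant": False,
            "flag_reverse": False,
            "flag_only_by_site": False,
        }
    )
    sample_ids = list(design["sample_id"])
    for j, s in enumerate(sample_ids):
        groups[s] = intens[:, j]

    extra_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN when missing_rate=1
        med = np.nanmedian(intens)
    med_intensity = med if np.isfinite(med) else 1e6
    for i in range(params.n_decoys):
        extra_rows.append(("REV__DEC%04d" % i, "", True, False))
    for i in range(params.n_contaminants):
        extra_rows.append(("CON__CON%04d" % i, "Con%04d" % i, False, True))
    if extra_rows:
        ids, genes, revs, cons = map(list, zip(*extra_rows))
        extra = pd.DataFrame(
            {
                "group_id": ids,
                "gene_name": genes,
                "mol_weight_da": 1000.0 * 10.0 ** rng.uniform(1.0, 2.0, len(ids)),
                "razor_unique_peptides": rng.integers(1, 10, len(ids)),
                "unique_peptides": 0,
                "flag_contaminant": cons,
                "flag_reverse": revs,
                "flag_only_by_site": False,
            }
        )
        extra["unique_peptides"] = np.minimum(
            extra["razor_unique_peptides"], rng.integers(0, 10, len(ids))
        )
        for s in sample_ids:
            extra[s] = med_intensity * np.exp2(rng.normal(0, 2, len(ids)))
        groups = pd.concat([groups, extra], ignore_index=True)
    return groups


def simulate_dataset(
    n_proteins: int = 2000,
    seed: int = 0,
    params: SimulationParams | None = None,
    class_fractions: dict[str, float] | None = None,
    design: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthProteome]:
    """Convenience wrapper: design + ground truth + simulated table.

    Seeds for the truth and the noise are fanned out from ``seed`` by fixed
    offsets.  Returns ``(protein_groups, design, truth)``.
    """
    params = params or SimulationParams()
    design = design if design is not None else make_design()
    truth = make_ground_truth(
        n_proteins, class_fractions=class_fractions, params=params,
        seed=seed, design=design,
    )
    groups = simulate_intensities(truth, design, seed=seed + 1, params=params)
    return groups, design, truth
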