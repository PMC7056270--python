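"""Histone-ruler copy-number estimation, quality categories and filters.

The proteomic ruler converts label-free MS intensities into absolute protein
copies per cell without spike-ins.  Histones are bound to DNA in fixed
stoichiometry, so the total histone mass in a cell is taken equal to the
mass of its genome (ploidy x genome size x mean base-pair molar mass / N_A).
Anchoring the summed histone intensity of a sample to that mass turns every
other protein's intensity into a mass per cell, and dividing by the
molecular weight gives copies per cell:

    mass_i,s   = (I_i,s / H_s) * m_hist
    copies_i,s = mass_i,s * N_A / MW_i

where ``H_s`` is the summed intensity of histone groups in sample ``s``.
Any per-sample global intensity factor cancels in the ratio, which is what
makes the estimate comparable across samples and runs.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import samples_by_condition

__all__ = [
    "RulerConfig",
    "CopyNumberResult",
    "filter_groups",
    "detection_filter",
    "histone_mass_per_cell",
    "histone_mask",
    "quality_category",
    "estimate_copy_numbers",
    "total_protein_content",
]

log = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class RulerConfig:
    """Physical constants and conventions of the copy-number estimator.

    Parameters
    ----------
    avogadro : Avogadro constant, mol^-1.
    genome_size_bp : haploid genome size in base pairs (default mouse,
        2.73e9 bp).
    ploidy : genome copies per cell (default 2, a diploid somatic cell).
    bp_molar_mass : mean molar mass of one DNA base pair, g/mol.
    histone_patterns : case-insensitive gene-name glob patterns identifying
        histone groups (core H2A/H2B/H3/H4, linker H1, clustered ``Hist*``
        names).
    histone_mass_override_g : if set, use this histone mass per cell in
        grams instead of the DNA-mass equivalence (useful for calibration
        and testing).
    min_detected_replicates : detection filter: a protein is kept iff some
        condition has detected intensity in at least this many replicates.
    high_min_peptides / high_min_unique_fraction : thresholds for the
        "high accuracy" quantification category (>= 8 razor+unique peptides
        of which >= 75% unique).
    medium_min_peptides / medium_min_unique_fraction : thresholds for the
        "medium accuracy" category (>= 3 razor+unique, >= 50% unique).
    """

    avogadro: float = AVOGADRO
    genome_size_bp: float = 2.73e9
    ploidy: float = 2.0
    bp_molar_mass: float = 615.8771
    histone_patterns: tuple[str, ...] = ("H1*", "H2A*", "H2B*", "H3*", "H4*", "Hist*")
    histone_mass_override_g: float | None = None
    min_detected_replicates: int = 2
    high_min_peptides: int = 8
    high_min_unique_fraction: float = 0.75
    medium_min_peptides: int = 3
    medium_min_unique_fraction: float = 0.50

    def __post_init__(self):
        if not (self.avogadro > 0 and self.genome_size_bp > 0 and self.ploidy > 0 and self.bp_molar_mass > 0):
            raise ValueError("ruler constants must be positive")
        if (self.high_min_peptides, self.high_min_unique_fraction) <= (
            self.medium_min_peptides,
            self.medium_min_unique_fraction,
        ):
            raise ValueError("high-quality thresholds must be stricter than medium")


@dataclass
class CopyNumberResult:
    """Per-protein copy numbers, masses and detection, plus metadata.

    All frames are indexed by ``group_id``; ``copies`` / ``mass`` /
    ``detected`` have one column per sample, ``mean_copies`` one column per
    condition.  Not-detected entries carry 0 copies (detection is tracked
    separately).  The identity ``mass = copies * MW / N_A`` holds exactly.
    """

    copies: pd.DataFrame
    mass: pd.DataFrame
    detected: pd.DataFrame
    mean_copies: pd.DataFrame
    quality: pd.Series
    mol_weight_da: pd.Series
    gene_name: pd.Series
    design: pd.DataFrame
    avogadro: float = AVOGADRO

    @property
    def group_ids(self) -> pd.Index:
        return self.copies.index

    def mean_mass(self) -> pd.DataFrame:
        """Condition-mean mass per cell in grams (zeros included)."""
        bycond = samples_by_condition(self.design)
        return pd.DataFrame(
            {cond: self.mass[sids].mean(axis=1) for cond, sids in bycond.items()}
        )

    def detected_replicates(self) -> pd.DataFrame:
        """Number of detected replicates per protein x condition."""
        bycond = samples_by_condition(self.design)
        return pd.DataFrame(
            {cond: self.detected[sids].sum(axis=1) for cond, sids in bycond.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten into one wide table (for :func:`~proteoruler.io_tables.write_table`)."""
        out = pd.DataFrame(
            {
                "group_id": self.group_ids,
                "gene_name": self.gene_name.to_numpy(),
                "mol_weight_da": self.mol_weight_da.to_numpy(),
                "quality": self.quality.to_numpy(),
            }
        )
        for s in self.copies.columns:
            out[f"copies.{s}"] = self.copies[s].to_numpy()
        for s in self.mass.columns:
            out[f"mass.{s}"] = self.mass[s].to_numpy()
        for s in self.detected.columns:
            out[f"detected.{s}"] = self.detected[s].astype(int).to_numpy()
        for c in self.mean_copies.columns:
            out[f"mean_copies.{c}"] = self.mean_copies[c].to_numpy()
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, design: pd.DataFrame,
                   avogadro: float = AVOGADRO) -> "CopyNumberResult":
        frame = frame.set_index(frame["group_id"].astype(str))
        pick = lambda prefix: frame[
            [c for c in frame.columns if c.startswith(prefix)]
        ].rename(columns=lambda c: c[len(prefix):])
        return cls(
            copies=pick("copies."),
            mass=pick("mass."),
            detected=pick("detected.").astype(bool),
            mean_copies=pick("mean_copies."),
            quality=frame["quality"],
            mol_weight_da=frame["mol_weight_da"],
            gene_name=frame["gene_name"].fillna(""),
            design=design,
            avogadro=avogadro,
        )


def filter_groups(groups: pd.DataFrame) -> pd.DataFrame:
    """Drop contaminant, reversed-decoy and only-identified-by-site rows.

    Order-preserving; logs the count removed per flag (a row with several
    flags is counted under each but removed once).
    """
    for flag in ("flag_contaminant", "flag_reverse", "flag_only_by_site"):
        n = int(groups[flag].sum())
        if n:
            log.info("filter_groups: %d rows flagged %s", n, flag)
    keep = ~(groups["flag_contaminant"] | groups["flag_reverse"] | groups["flag_only_by_site"])
    return groups.loc[keep].reset_index(drop=True)


def detection_filter(
    groups: pd.DataFrame, design: pd.DataFrame, cfg: RulerConfig | None = None
) -> pd.DataFrame:
    """Keep proteins detected in >= ``min_detected_replicates`` replicates of
    at least one condition.  Detection means a present, positive intensity."""
    cfg = cfg or RulerConfig()
    bycond = samples_by_condition(design)
    detected = groups[design["sample_id"]].notna()
    best = pd.concat(
        [detected[sids].sum(axis=1) for sids in bycond.values()], axis=1
    ).max(axis=1)
    keep = best >= cfg.min_detected_replicates
    log.info("detection_filter: kept %d of %d proteins", int(keep.sum()), len(groups))
    return groups.loc[keep].reset_index(drop=True)


def histone_mass_per_cell(cfg: RulerConfig | None = None) -> float:
    """Histone mass per cell in grams: the DNA-mass equivalence
    ``ploidy * genome_size_bp * bp_molar_mass / N_A`` (or the configured
    override)."""
    cfg = cfg or RulerConfig()
    if cfg.histone_mass_override_g is not None:
        return cfg.histone_mass_override_g
    return cfg.ploidy * cfg.genome_size_bp * cfg.bp_molar_mass / cfg.avogadro


def histone_mask(gene_names: pd.Series, cfg: RulerConfig | None = None) -> pd.Series:
    """Boolean mask of histone groups, by case-insensitive gene-name glob."""
    cfg = cfg or RulerConfig()
    pats = [p.lower() for p in cfg.histone_patterns]
    return gene_names.fillna("").astype(str).str.lower().map(
        lambda g: any(fnmatch.fnmatchcase(g, p) for p in pats)
    )


def quality_category(razor_unique: int, unique: int, cfg: RulerConfig | None = None) -> str:
    """Quantification-accuracy category from peptide counts.

    ``high``: >= 8 razor+unique peptides, >= 75% of them unique;
    ``medium``: >= 3 razor+unique, >= 50% unique; else ``low``.
    """
    cfg = cfg or RulerConfig()
    if razor_unique <= 0:
        return "low"
    frac = unique / razor_unique
    if razor_unique >= cfg.high_min_peptides and frac >= cfg.high_min_unique_fraction:
        return "high"
    if razor_unique >= cfg.medium_min_peptides and frac >= cfg.medium_min_unique_fraction:
        return "medium"
    return "low"


def estimate_copy_numbers(
    groups: pd.DataFrame, design: pd.DataFrame, cfg: RulerConfig | None = None
) -> CopyNumberResult:
    """Estimate copies and mass per cell for every protein group and sample.

    Per sample ``s`` the summed intensity ``H_s`` of detected histone groups
    anchors the scale: ``mass_i,s = I_i,s / H_s * m_hist`` and
    ``copies_i,s = mass_i,s * N_A / MW_i``.  Not-detected intensities give 0
    copies with ``detected=False``.  Condition means are arithmetic means
    over replicates, zeros included.

    Raises
    ------
    ValueError
        if a sample has no detected histone intensity (the ruler is
        undefined there), naming the sample.
    """
    cfg = cfg or RulerConfig()
    sample_ids = list(design["sample_id"])
    gid = groups["group_id"].astype(str)
    if gid.duplicated().any():
        dup = gid[gid.duplicated()].iloc[0]
        raise ValueError(f"duplicate group_id {dup!r}; group ids must be unique")

    intens = groups[sample_ids].astype(float)
    intens.index = gid
    detected = intens.notna() & (intens > 0)
    intens = intens.where(detected, 0.0)

    is_hist = histone_mask(groups["gene_name"], cfg).to_numpy()
    if not is_hist.any():
        raise ValueError("no histone groups matched the configured gene-name patterns")
    h_sum = intens.loc[is_hist].sum(axis=0)
    for s in sample_ids:
        if not h_sum[s] > 0:
            raise ValueError(f"no detected histone intensity in sample {s!r}: ruler undefined")
    log.info("estimate_copy_numbers: %d histone groups anchor the ruler: %s",
             int(is_hist.sum()), ", ".join(gid[is_hist].head(20)))

    m_hist = histone_mass_per_cell(cfg)
    mass = intens.div(h_sum, axis=1) * m_hist
    mw = groups["mol_weight_da"].astype(float)
    mw.index = gid
    copies = mass.mul(cfg.avogadro / mw, axis=0)

    bycond = samples_by_condition(design)
    mean_copies = pd.DataFrame(
        {cond: copies[sids].mean(axis=1) for cond, sids in bycond.items()}
    )
    quality = pd.Series(
        [
            quality_category(r, u, cfg)
            for r, u in zip(groups["razor_unique_peptides"], groups["unique_peptides"])
        ],
        index=gid,
        name="quality",
    )
    gene = groups["gene_name"].fillna("").astype(str)
    gene.index = gid
    return CopyNumberResult(
        copies=copies,
        mass=mass,
        detected=detected,
        mean_copies=mean_copies,
        quality=quality,
        mol_weight_da=mw,
        gene_name=gene,
        design=design,
        avogadro=cfg.avogadro,
    )


def total_protein_content(result: CopyNumberResult, design: pd.DataFrame | None = None) -> pd.Series:
    """Total protein content per condition in ug per million cells.

    Sums mass per cell over proteins within each sample (grams/cell, x1e12
    converts to ug per 1e6 cells) and averages over the condition's
    replicates.
    """
    design = design if design is not None else result.design
    per_sample = result.mass[design["sample_id"]].sum(axis=0) * 1e12
    bycond = samples_by_condition(design)
    return pd.Series(
        {cond: per_sample[sids].mean() for cond, sids in bycond.items()},
        name="total_protein_ug_per_million_cells",
    )
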