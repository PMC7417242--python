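"""Synthetic colony pedigrees and biallelic SNP genotypes.

Emulates the statistical structure the sibship analysis assumes: a panel
of independent biallelic loci with common variants (minor allele
frequency above 0.33 by default, frequencies uniform on the admissible
band), haremic colonies in which one or two sires breed with multiple
dams, six offspring per colony, Mendelian transmission, a symmetric
per-allele genotyping-error rate, and uniform-at-random missing calls
(bounded at the 15% per-individual filter the analysis applies).

The generator produces the cohort the Monte-Carlo sampler draws from,
with genotypes and a truth pedigree, so the kinship classifier and the
full pipeline run end-to-end without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import RecruitCohort, build_cohort
from .kinship import MISSING, GenotypeMatrix

__all__ = [
    "LocusPanel",
    "PedigreeSpec",
    "sample_panel",
    "simulate_colony",
    "generate_trc_genotyped",
    "true_pair_relations",
]


@dataclass(frozen=True)
class LocusPanel:
    """Allele-"A" frequencies of a panel of independent biallelic loci."""

    frequencies: np.ndarray
    maf_min: float = 0.33

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size and (np.minimum(f, 1 - f) < self.maf_min - 1e-12).any():
            raise ValueError("panel violates its minor-allele-frequency bound")

    @property
    def n_loci(self) -> int:
        return len(self.frequencies)


def sample_panel(
    n_loci: int = 300, maf_min: float = 0.33, rng: np.random.Generator | None = None
) -> LocusPanel:
    """Panel with frequencies uniform on ``[maf_min, 1 - maf_min]``."""
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    if n_loci < 0:
        raise ValueError("n_loci must be nonnegative")
    if rng is None:
        rng = np.random.default_rng()
    freqs = rng.uniform(maf_min, 1.0 - maf_min, size=n_loci)
    return LocusPanel(frequencies=freqs, maf_min=maf_min)


@dataclass(frozen=True)
class PedigreeSpec:
    """Colony pedigree parameters.

    ``sires_per_colony`` of 2 models the sneaker/secondary-male pattern in
    which a colony's brood is sired by two males; dams are always multiple
    (haremic structure), so offspring within a colony are a mix of full
    and half siblings.
    """

    n_colonies: int = 1
    sires_per_colony: int = 1
    dams_per_colony: int = 3
    offspring_per_colony: int = 6
    missing_rate: float = 0.05
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sires_per_colony not in (1, 2):
            raise ValueError("sires_per_colony must be 1 or 2")
        if self.dams_per_colony < 1 or self.offspring_per_colony < 1:
            raise ValueError("need at least one dam and one offspring")
        if not 0.0 <= self.missing_rate <= 0.15:
            raise ValueError("missing_rate must lie in [0, 0.15]")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")


def _hwe_alleles(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, L, 2) allele array drawn in Hardy-Weinberg proportions."""
    return (rng.random((n, freqs.size, 2)) < freqs[None, :, None]).astype(np.int8)


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Mendelian allele per locus from a (L, 2) parent."""
    pick = rng.integers(0, 2, size=parent.shape[0])
    return parent[np.arange(parent.shape[0]), pick]


def simulate_colony(
    panel: LocusPanel,
    spec: PedigreeSpec,
    rng: np.random.Generator,
    colony_id: int = 0,
):
    """Simulate one colony: parents in HWE, offspring by Mendelian transmission.

    Returns ``(offspring_alleles, pedigree, parents)``:
    ``offspring_alleles`` is an (offspring, loci, 2) allele array,
    ``pedigree`` a frame with columns offspring, sire, dam, colony, and
    ``parents`` the ``(sires, dams)`` allele arrays the offspring were
    drawn from.  Genotyping error (allele flips at ``spec.error_rate``) is
    applied to the offspring here; missingness is applied when the
    genotype matrix is assembled.
    """
    f = np.asarray(panel.frequencies)
    sires = _hwe_alleles(f, spec.sires_per_colony, rng)
    dams = _hwe_alleles(f, spec.dams_per_colony, rng)
    n_off = spec.offspring_per_colony
    sire_of = rng.integers(0, spec.sires_per_colony, size=n_off)
    dam_of = rng.integers(0, spec.dams_per_colony, size=n_off)
    alleles = np.empty((n_off, f.size, 2), dtype=np.int8)
    for o in range(n_off):
        alleles[o, :, 0] = _transmit(sires[sire_of[o]], rng)
        alleles[o, :, 1] = _transmit(dams[dam_of[o]], rng)
    if spec.error_rate > 0:
        flips = rng.random(alleles.shape) < spec.error_rate
        alleles = np.where(flips, 1 - alleles, alleles).astype(np.int8)
    ped = pd.DataFrame(
        {
            "offspring": [f"C{colony_id:04d}O{o + 1}" for o in range(n_off)],
            "sire": [f"C{colony_id:04d}S{s + 1}" for s in sire_of],
            "dam": [f"C{colony_id:04d}D{d + 1}" for d in dam_of],
            "colony": colony_id,
        }
    )
    return alleles, ped, (sires, dams)


def generate_trc_genotyped(
    n_total: int,
    family_size: int = 6,
    panel: LocusPanel | None = None,
    spec: PedigreeSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, RecruitCohort, pd.DataFrame]:
    """A genotyped TRC: ``K = floor(n_total / family_size)`` colonies.

    Returns the genotype matrix (with error and missingness applied), the
    matching family-structured cohort, and the truth pedigree.  Recruit
    order aligns with the cohort's family labels: recruits of colony ``k``
    occupy rows ``k * s .. (k + 1) * s - 1``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if panel is None:
        panel = sample_panel(rng=rng)
    if spec is None:
        spec = PedigreeSpec(offspring_per_colony=family_size)
    if spec.offspring_per_colony != family_size:
        raise ValueError("spec.offspring_per_colony must equal family_size")
    cohort = build_cohort(n_total, family_size)
    blocks, peds = [], []
    for k in range(cohort.n_families):
        alleles, ped, _ = simulate_colony(panel, spec, rng, colony_id=k)
        blocks.append(alleles.sum(axis=2))
        peds.append(ped)
    geno = np.concatenate(blocks, axis=0).astype(np.int8)
    if spec.missing_rate > 0:
        mask = rng.random(geno.shape) < spec.missing_rate
        geno = np.where(mask, MISSING, geno).astype(np.int8)
    pedigree = pd.concat(peds, ignore_index=True)
    G = GenotypeMatrix(geno, list(pedigree["offspring"]))
    return G, cohort, pedigree


def true_pair_relations(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth relation for every within-colony pair of offspring.

    Pairs sharing sire and dam are full sibs; sharing exactly one parent,
    half sibs.  Cross-colony pairs are unrelated and omitted.
    """
    out = []
    for _, grp in pedigree.groupby("colony"):
        recs = grp.to_dict("records")
        for a in range(len(recs)):
            for b in range(a + 1, len(recs)):
                ra, rb = recs[a], recs[b]
                shared = (ra["sire"] == rb["sire"]) + (ra["dam"] == rb["dam"])
                rel = {2: "full_sib", 1: "half_sib", 0: "unrelated"}[shared]
                out.append((ra["offspring"], rb["offspring"], rel))
    return pd.DataFrame(out, columns=["individual_i", "individual_j", "relation"])
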