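"""Seeded simulation of F1 hybrids and backcrosses from natural parents.

An F1 receives, at every locus, one allele drawn uniformly from a
*F. spiralis* parent's pair and one from a *F. vesiculosus* parent's pair.
A backcross pairs an F1 with a natural individual of the recurrent species
under the same per-locus allele draw.  By default one parent pair is fixed
per hybrid (a true cross); ``parent_mode="per-locus"`` redraws parents at
every locus instead.  Every simulated allele is logged with the parent that
contributed it, so provenance is fully traceable; a parent's missing locus
yields a missing hybrid locus (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .genotype_io import (
    MISSING,
    SIMULATED_HYBRID,
    SPIRALIS,
    VESICULOSUS,
    GenotypeDataset,
    Individual,
    LocusGenotype,
)

SCENARIOS = ("F1", "BC_spi", "BC_ves", "BC_mixed")


@dataclass
class HybridSet:
    """Simulated hybrids plus a full per-locus parent/allele log."""

    scenario: str
    hybrids: list[Individual]
    parent_log: pd.DataFrame  # hybrid_id, locus, parent_id, allele, species
    seed: int

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")

    def __len__(self) -> int:
        return len(self.hybrids)

    def write_parent_log(self, path: str | Path) -> None:
        self.parent_log.to_csv(path, sep="\t", index=False)


def _eligible_pool(
    dataset: GenotypeDataset,
    species: str,
    eligible_locations: set[str] | None,
    excluded_ids: set[str],
) -> list[Individual]:
    pool = [
        ind
        for ind in dataset.individuals
        if ind.species == species
        and (eligible_locations is None or ind.location in eligible_locations)
        and ind.id not in excluded_ids
    ]
    if not pool:
        raise ConfigurationError(
            f"empty eligible parent pool for species {species!r} "
            f"(locations={sorted(eligible_locations) if eligible_locations else 'any'})"
        )
    return pool


def _draw_offspring_locus(
    rng: np.random.Generator,
    parent_a: Individual,
    parent_b: Individual,
    locus_idx: int,
) -> tuple[LocusGenotype, list[tuple[str, str, object]]]:
    """One allele from each parent's pair; missing parent locus -> missing."""
    ga, gb = parent_a.genotype[locus_idx], parent_b.genotype[locus_idx]
    if ga.missing or gb.missing:
        return MISSING, [
            (parent_a.id, parent_a.species, None),
            (parent_b.id, parent_b.species, None),
        ]
    allele_a = ga.alleles[rng.integers(2)]
    allele_b = gb.alleles[rng.integers(2)]
    return (
        LocusGenotype(allele_a, allele_b),
        [(parent_a.id, parent_a.species, allele_a), (parent_b.id, parent_b.species, allele_b)],
    )


def _simulate_cross(
    rng: np.random.Generator,
    pool_a: Sequence[Individual],
    pool_b: Sequence[Individual],
    n: int,
    n_loci: int,
    loci: Sequence[str],
    scenario: str,
    hybrid_class: str,
    id_prefix: str,
    parent_mode: str,
) -> tuple[list[Individual], list[dict]]:
    if parent_mode not in ("fixed", "per-locus"):
        raise ValidationError(f"unknown parent_mode {parent_mode!r}")
    hybrids: list[Individual] = []
    log_rows: list[dict] = []
    for h in range(n):
        pa = pool_a[rng.integers(len(pool_a))]
        pb = pool_b[rng.integers(len(pool_b))]
        genotype = []
        hid = f"{id_prefix}_{h + 1:03d}"
        for j in range(n_loci):
            if parent_mode == "per-locus":
                pa = pool_a[rng.integers(len(pool_a))]
                pb = pool_b[rng.integers(len(pool_b))]
            g, contribs = _draw_offspring_locus(rng, pa, pb, j)
            genotype.append(g)
            for parent_id, parent_species, allele in contribs:
                log_rows.append(
                    {
                        "hybrid_id": hid,
                        "locus": loci[j],
                        "parent_id": parent_id,
                        "allele": allele,
                        "species": parent_species,
                    }
                )
        # hybrids are placed where their parents were sampled
        location = (pa if rng.integers(2) else pb).location
        region = pa.region if location == pa.location else pb.region
        hybrids.append(
            Individual(
                id=hid,
                species=SIMULATED_HYBRID,
                location=location,
                region=region,
                genotype=tuple(genotype),
                hybrid_class=hybrid_class,
            )
        )
    return hybrids, log_rows


def simulate_f1(
    dataset: GenotypeDataset,
    eligible_locations: set[str] | None,
    n: int,
    excluded_ids: set[str] = frozenset(),
    seed: int = 0,
    parent_mode: str = "fixed",
) -> HybridSet:
    """Simulate ``n`` F1 hybrids from natural spiralis x vesiculosus parents.

    Parents are drawn uniformly from each species' pool restricted to
    ``eligible_locations`` (typically the locations where the network
    flagged hybridization) minus ``excluded_ids`` (natural putative hybrids,
    excluded to avoid compounding backcrossing).
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    excluded = set(excluded_ids)
    pool_spi = _eligible_pool(dataset, SPIRALIS, eligible_locations, excluded)
    pool_ves = _eligible_pool(dataset, VESICULOSUS, eligible_locations, excluded)
    hybrids, log_rows = _simulate_cross(
        rng, pool_spi, pool_ves, n, dataset.n_loci, dataset.loci,
        "F1", "F1", "F1", parent_mode,
    )
    return HybridSet("F1", hybrids, pd.DataFrame(log_rows), seed)


def simulate_backcross(
    f1_set: HybridSet,
    dataset: GenotypeDataset,
    backcross_species: str,
    eligible_locations: set[str] | None = None,
    excluded_ids: set[str] = frozenset(),
    seed: int = 0,
    n: int | None = None,
    parent_mode: str = "fixed",
) -> HybridSet:
    """Backcross F1 hybrids against natural individuals of one species."""
    if backcross_species not in (SPIRALIS, VESICULOSUS):
        raise ValidationError(f"backcross_species must be a natural species")
    if not f1_set.hybrids:
        raise ConfigurationError("empty F1 set")
    n = len(f1_set) if n is None else n
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    pool_nat = _eligible_pool(dataset, backcross_species, eligible_locations, set(excluded_ids))
    scenario = "BC_spi" if backcross_species == SPIRALIS else "BC_ves"
    hybrids, log_rows = _simulate_cross(
        rng, f1_set.hybrids, pool_nat, n, dataset.n_loci, dataset.loci,
        scenario, scenario, scenario, parent_mode,
    )
    return HybridSet(scenario, hybrids, pd.DataFrame(log_rows), seed)


def merge_hybrid_sets(scenario: str, sets: Iterable[HybridSet], seed: int) -> HybridSet:
    """Concatenate hybrid sets (e.g. BC_spi + BC_ves -> BC_mixed)."""
    hybrids, logs = [], []
    for hs in sets:
        hybrids.extend(hs.hybrids)
        logs.append(hs.parent_log)
    return HybridSet(scenario, hybrids, pd.concat(logs, ignore_index=True), seed)


def assemble_hybrid_dataset(
    dataset: GenotypeDataset, replace_ids: set[str], hybrids: HybridSet
) -> GenotypeDataset:
    """Replace ``replace_ids`` (natural putative hybrids) by simulated ones.

    Output size is |dataset| - |replace_ids| + |hybrids|; all other natural
    individuals are untouched.
    """
    replace = set(replace_ids)
    unknown = replace - set(dataset.ids)
    if unknown:
        raise ValidationError(f"replace_ids not in dataset: {sorted(unknown)[:10]}")
    natural = [ind for ind in dataset.individuals if ind.id not in replace]
    collisions = {ind.id for ind in natural} & {h.id for h in hybrids.hybrids}
    if collisions:
        raise ValidationError(f"hybrid ids collide with natural ids: {sorted(collisions)}")
    return GenotypeDataset(
        loci=dataset.loci,
        individuals=natural + list(hybrids.hybrids),
        provenance=(
            f"{dataset.provenance} + {len(hybrids)} simulated "
            f"{hybrids.scenario} hybrids (seed={hybrids.seed}, "
            f"replaced={len(replace)})"
        ),
    )


def verify_parent_provenance(hybrids: HybridSet, dataset: GenotypeDataset) -> bool:
    """Check every logged allele is actually carried by the named parent.

    Parents may be natural individuals of ``dataset`` or hybrids of the same
    set (backcross case handled by the caller passing the F1-augmented
    dataset).  Returns True or raises ValidationError.
    """
    carriers: dict[str, Individual] = {ind.id: ind for ind in dataset.individuals}
    for h in hybrids.hybrids:
        carriers.setdefault(h.id, h)
    loci_index = {locus: i for i, locus in enumerate(dataset.loci)}
    for row in hybrids.parent_log.itertuples(index=False):
        if pd.isna(row.allele) or row.allele is None:
            continue
        parent = carriers.get(row.parent_id)
        if parent is None:
            raise ValidationError(f"logged parent {row.parent_id!r} not found")
        g = parent.genotype[loci_index[row.locus]]
        if g.missing or int(row.allele) not in g.alleles:
            raise ValidationError(
                f"hybrid {row.hybrid_id!r}: allele {row.allele} not carried by "
                f"parent {row.parent_id!r} at locus {row.locus!r}"
            )
    return True
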