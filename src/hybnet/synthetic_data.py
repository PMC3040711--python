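"""Two-species synthetic microsatellite datasets with controllable divergence.

The generator emulates the statistical structure the network method
consumes: two sister species whose allele-length distributions sit on
stepwise-mutation ladders displaced by a configurable number of repeat
units (the RD signal), a shared ancestral allele pool sampled with
probability ``shared_poly_fraction`` (the SAD / ancestral-polymorphism
signal), mild regional substructure, and sympatric versus allopatric
regions.  Optionally, simulated F1/backcross hybrids are injected into
sympatric regions with their true labels kept in an out-of-band sidecar so
detection cannot leak truth.

Per allele draw: with probability ``shared_poly_fraction`` the allele comes
from the shared ancestral pool (centered on the ancestral modal length),
otherwise from the species pool (ancestral mode shifted by
``+/- divergence_steps`` repeat units, plus a small fixed regional shift).
Pools are symmetric truncated-geometric ladders on repeat counts: the modal
allele has probability ~0.5 and each further step halves the mass, giving
expected heterozygosity around 0.7 — typical for microsatellite panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .genotype_io import (
    MISSING,
    SPIRALIS,
    VESICULOSUS,
    GenotypeDataset,
    Individual,
    LocusGenotype,
)
from . import hybrid_sim


@dataclass
class RegionSpec:
    """A sampling region; sympatric regions host both species.

    ``weight`` is the relative share of a species' sample allocated to the
    region (allopatric refugial areas typically hold a large share of each
    species' range-wide sample).
    """

    name: str
    sympatric: bool
    species: tuple[str, ...]
    weight: float = 1.0

    def __post_init__(self):
        self.species = tuple(self.species)


DEFAULT_REGIONS = (
    RegionSpec("America", True, (SPIRALIS, VESICULOSUS)),
    RegionSpec("NorthSea", True, (SPIRALIS, VESICULOSUS)),
    RegionSpec("Channel", True, (SPIRALIS, VESICULOSUS)),
    RegionSpec("NWIberia", True, (SPIRALIS, VESICULOSUS)),
    RegionSpec("SouthPortugal", False, (SPIRALIS,), weight=2.5),
    RegionSpec("Morocco", False, (VESICULOSUS,), weight=2.5),
)


@dataclass
class SyntheticConfig:
    """Parameters of the two-species generator.

    Defaults mirror the shape of a 572-individual, 9-locus dinucleotide
    panel sampled over 6 regions (4 sympatric, 2 allopatric).
    """

    n_per_species: int = 286
    n_loci: int = 9
    repeat_unit: int = 2  # nucleotides per repeat
    divergence_steps: int = 8  # repeat-unit steps between each species mode and the ancestral mode
    shared_poly_fraction: float = 0.1  # probability an allele is ancestral (shared)
    step_p: float = 0.65  # modal-allele mass of the geometric step ladder
    max_steps: int = 4  # ladder truncation (pool of 2*max_steps+1 alleles)
    region_shift_steps: int = 3  # max |regional shift| of the species mode, in steps
    regions: tuple[RegionSpec, ...] = DEFAULT_REGIONS
    locations_per_region: int = 2
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.shared_poly_fraction <= 1.0):
            raise ConfigurationError("shared_poly_fraction must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0.0 < self.step_p <= 1.0):
            raise ConfigurationError("step_p must be in (0, 1]")
        if self.n_per_species <= 0 or self.n_loci <= 0 or self.repeat_unit <= 0:
            raise ConfigurationError("counts must be positive")
        self.regions = tuple(
            r if isinstance(r, RegionSpec) else RegionSpec(**r) for r in self.regions
        )
        if not any(r.sympatric for r in self.regions):
            raise ConfigurationError("at least one sympatric region is required")

    # -- (de)serialization -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["regions"] = [asdict(r) for r in self.regions]
        Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "regions" in data:
            data["regions"] = tuple(RegionSpec(**r) for r in data["regions"])
        return cls(**data)


def _step_ladder(p: float, max_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric truncated geometric ladder over repeat-count steps.

    P(step s) ∝ r^|s| with r = (1-p)/(1+p), so the untruncated modal-allele
    probability is exactly ``p``; truncation at ``max_steps`` renormalizes.
    """
    steps = np.arange(-max_steps, max_steps + 1)
    r = (1 - p) / (1 + p)
    probs = r ** np.abs(steps)
    return steps, probs / probs.sum()


def _species_sign(species: str) -> int:
    return -1 if species == SPIRALIS else +1


def generate_dataset(config: SyntheticConfig) -> GenotypeDataset:
    """Generate a two-species dataset under ``config`` (reproducible)."""
    rng = np.random.default_rng(config.seed)
    steps, step_probs = _step_ladder(config.step_p, config.max_steps)

    # per-locus ancestral modal lengths, anchored on the repeat ladder
    base = 100 + config.repeat_unit * rng.integers(0, 40, size=config.n_loci)

    # fixed small regional shifts of the species mode (substructure)
    region_shift = {
        (r.name, sp, j): int(rng.integers(-config.region_shift_steps,
                                          config.region_shift_steps + 1))
        for r in config.regions
        for sp in (SPIRALIS, VESICULOSUS)
        for j in range(config.n_loci)
    }

    def draw_allele(species: str, region: str, locus: int) -> int:
        if rng.random() < config.shared_poly_fraction:
            mode = base[locus]
        else:
            shift = config.divergence_steps * _species_sign(species)
            shift += region_shift[(region, species, locus)]
            mode = base[locus] + config.repeat_unit * shift
        step = steps[rng.choice(len(steps), p=step_probs)]
        return max(config.repeat_unit, int(mode + config.repeat_unit * step))

    # per-species sample allocation across its regions, remainder to first
    individuals: list[Individual] = []
    for species, prefix in ((SPIRALIS, "spi"), (VESICULOSUS, "ves")):
        sp_regions = [r for r in config.regions if species in r.species]
        if not sp_regions:
            raise ConfigurationError(f"no region hosts species {species!r}")
        weights = np.array([r.weight for r in sp_regions], dtype=float)
        shares = weights / weights.sum() * config.n_per_species
        counts = np.floor(shares).astype(int)
        # largest-remainder rounding to hit n_per_species exactly
        for r_idx in np.argsort(-(shares - counts))[: config.n_per_species - counts.sum()]:
            counts[r_idx] += 1
        idx = 0
        for region, n_here in zip(sp_regions, counts):
            for i in range(n_here):
                idx += 1
                loc = f"{region.name}-{i % config.locations_per_region + 1}"
                genotype = []
                for j in range(config.n_loci):
                    if config.missing_rate and rng.random() < config.missing_rate:
                        genotype.append(MISSING)
                    else:
                        genotype.append(
                            LocusGenotype(
                                draw_allele(species, region.name, j),
                                draw_allele(species, region.name, j),
                            )
                        )
                individuals.append(
                    Individual(
                        id=f"{prefix}_{idx:04d}",
                        species=species,
                        location=loc,
                        region=region.name,
                        genotype=tuple(genotype),
                    )
                )
    loci = tuple(f"L{j + 1:02d}" for j in range(config.n_loci))
    return GenotypeDataset(
        loci=loci,
        individuals=individuals,
        provenance=f"hybnet synthetic dataset (seed={config.seed})",
    )


def sympatric_regions(dataset: GenotypeDataset) -> set[str]:
    """Regions where both natural species were sampled."""
    by_region: dict[str, set[str]] = {}
    for ind in dataset.individuals:
        by_region.setdefault(ind.region, set()).add(ind.species)
    return {r for r, sp in by_region.items() if {SPIRALIS, VESICULOSUS} <= sp}


@dataclass
class InjectionResult:
    """Hybrid-augmented dataset plus the out-of-band ground truth."""

    dataset: GenotypeDataset
    truth: pd.DataFrame  # id, hybrid_class, masked_species, location, region

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def inject_hybrids(
    dataset: GenotypeDataset,
    scenario: str,
    n: int,
    seed: int = 0,
    replace_ids: set[str] = frozenset(),
    bc_split: tuple[int, int] | None = None,
) -> InjectionResult:
    """Inject ``n`` simulated hybrids of ``scenario`` into sympatric regions.

    Hybrids are relabeled ("masked") as one of the two natural species —
    random for F1s, the recurrent parent species for backcrosses — so that
    network detection sees them exactly as natural individuals; the sidecar
    truth table keeps their real class.  ``bc_split`` fixes the BC_mixed
    split (default an even split, e.g. 9 + 8 for n = 17).
    """
    if n == 0:
        return InjectionResult(dataset, pd.DataFrame(
            columns=["id", "hybrid_class", "masked_species", "location", "region"]))
    symp = sympatric_regions(dataset)
    if not symp:
        raise ConfigurationError("dataset has no sympatric region")
    eligible = {
        ind.location for ind in dataset.individuals if ind.region in symp
    }
    rng = np.random.default_rng(seed)
    sub_seed = lambda: int(rng.integers(2**31 - 1))

    if scenario == "F1":
        hyb = hybrid_sim.simulate_f1(dataset, eligible, n, set(replace_ids), sub_seed())
    elif scenario in ("BC_spi", "BC_ves"):
        f1 = hybrid_sim.simulate_f1(dataset, eligible, n, set(replace_ids), sub_seed())
        species = SPIRALIS if scenario == "BC_spi" else VESICULOSUS
        hyb = hybrid_sim.simulate_backcross(
            f1, dataset, species, eligible, set(replace_ids), sub_seed(), n=n
        )
    elif scenario == "BC_mixed":
        n_spi, n_ves = bc_split if bc_split else ((n + 1) // 2, n // 2)
        if n_spi + n_ves != n:
            raise ConfigurationError(f"bc_split {bc_split} does not sum to n={n}")
        f1 = hybrid_sim.simulate_f1(dataset, eligible, n, set(replace_ids), sub_seed())
        bc_s = hybrid_sim.simulate_backcross(
            f1, dataset, SPIRALIS, eligible, set(replace_ids), sub_seed(), n=n_spi
        )
        bc_v = hybrid_sim.simulate_backcross(
            f1, dataset, VESICULOSUS, eligible, set(replace_ids), sub_seed(), n=n_ves
        )
        # disambiguate ids before merging
        for tag, hs in (("s", bc_s), ("v", bc_v)):
            for h in hs.hybrids:
                h.id = f"{h.id}{tag}"
            hs.parent_log["hybrid_id"] = hs.parent_log["hybrid_id"] + tag
        hyb = hybrid_sim.merge_hybrid_sets("BC_mixed", (bc_s, bc_v), seed)
    else:
        raise ValidationError(f"unknown scenario {scenario!r}")

    merged = hybrid_sim.assemble_hybrid_dataset(dataset, set(replace_ids), hyb)

    # mask hybrid labels; ground truth goes to the sidecar only
    truth_rows = []
    for ind in merged.individuals:
        if ind.species != "simulated_hybrid":
            continue
        true_class = ind.hybrid_class
        if true_class == "F1":
            masked = SPIRALIS if rng.integers(2) else VESICULOSUS
        elif true_class == "BC_spi":
            masked = SPIRALIS
        else:
            masked = VESICULOSUS
        ind.species = masked
        ind.hybrid_class = None
        truth_rows.append(
            {
                "id": ind.id,
                "hybrid_class": true_class,
                "masked_species": masked,
                "location": ind.location,
                "region": ind.region,
            }
        )
    merged.validate()
    return InjectionResult(merged, pd.DataFrame(truth_rows))


def score_detection(
    detected_ids: set[str], truth: pd.DataFrame, natural_ids: Sequence[str]
) -> dict[str, float]:
    """Recall over ground-truth hybrids and false-positive rate over naturals."""
    truth_ids = set(truth["id"])
    natural = set(natural_ids) - truth_ids
    recall = len(detected_ids & truth_ids) / len(truth_ids) if truth_ids else float("nan")
    fp_rate = len(detected_ids & natural) / len(natural) if natural else 0.0
    return {"recall": recall, "false_positive_rate": fp_rate}
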