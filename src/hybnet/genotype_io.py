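"""Domain types for diploid microsatellite genotypes and file I/O.

Individuals carry two allele lengths (in nucleotides) per locus.  Datasets
are exchanged either in GenePop 4.x (the de-facto standard for
microsatellite genotype tables) or in a documented CSV dialect:

    id,species,location,region,hybrid_class,<locus>_1,<locus>_2,...

Empty allele cells denote a missing locus genotype; a half-empty pair is a
ploidy violation and is rejected.  GenePop carries no species metadata, so
the GenePop reader takes a sidecar CSV (columns ``id,species`` plus optional
``location,region,hybrid_class``) or an id-prefix rule.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

SPIRALIS = "spiralis"
VESICULOSUS = "vesiculosus"
SIMULATED_HYBRID = "simulated_hybrid"
SPECIES_LABELS = (SPIRALIS, VESICULOSUS, SIMULATED_HYBRID)
NATURAL_SPECIES = (SPIRALIS, VESICULOSUS)

HYBRID_CLASSES = ("F1", "BC_spi", "BC_ves")


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered diploid genotype at one microsatellite locus.

    Allele lengths are strictly positive integers (nucleotides); a missing
    genotype has both alleles absent.  Alleles are normalized to sorted
    order on construction so ``(a, A)`` and ``(A, a)`` compare equal.
    """

    allele_1: int | None = None
    allele_2: int | None = None

    def __post_init__(self):
        a, b = self.allele_1, self.allele_2
        if (a is None) != (b is None):
            raise ValidationError(
                f"half-missing genotype ({a!r}, {b!r}): diploid loci need "
                "both alleles or neither"
            )
        if a is not None:
            a, b = int(a), int(b)
            if a <= 0 or b <= 0:
                raise ValidationError(f"allele lengths must be positive, got ({a}, {b})")
            if a > b:
                a, b = b, a
            object.__setattr__(self, "allele_1", a)
            object.__setattr__(self, "allele_2", b)

    @property
    def missing(self) -> bool:
        return self.allele_1 is None

    @property
    def alleles(self) -> tuple[int, int]:
        if self.missing:
            raise ValidationError("missing genotype has no alleles")
        return (self.allele_1, self.allele_2)

    @classmethod
    def missing_genotype(cls) -> "LocusGenotype":
        return cls(None, None)


MISSING = LocusGenotype.missing_genotype()


@dataclass
class Individual:
    """One sampled or simulated diploid individual with metadata."""

    id: str
    species: str
    location: str
    region: str
    genotype: tuple[LocusGenotype, ...]
    hybrid_class: str | None = None

    def __post_init__(self):
        self.genotype = tuple(self.genotype)
        if self.species not in SPECIES_LABELS:
            raise ValidationError(
                f"individual {self.id!r}: unknown species {self.species!r}; "
                f"expected one of {SPECIES_LABELS}"
            )
        if (self.hybrid_class is not None) != (self.species == SIMULATED_HYBRID):
            raise ValidationError(
                f"individual {self.id!r}: hybrid_class must be set iff "
                f"species == {SIMULATED_HYBRID!r}"
            )
        if self.hybrid_class is not None and self.hybrid_class not in HYBRID_CLASSES:
            raise ValidationError(
                f"individual {self.id!r}: unknown hybrid_class {self.hybrid_class!r}"
            )


@dataclass
class GenotypeDataset:
    """A collection of individuals typed at one shared locus panel."""

    loci: tuple[str, ...]
    individuals: list[Individual]
    provenance: str = ""

    def __post_init__(self):
        self.loci = tuple(self.loci)
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        k = len(self.loci)
        for ind in self.individuals:
            if ind.id in seen:
                raise ValidationError(f"duplicated individual id {ind.id!r}")
            seen.add(ind.id)
            if len(ind.genotype) != k:
                raise ValidationError(
                    f"individual {ind.id!r} has {len(ind.genotype)} loci, "
                    f"panel has {k}"
                )

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def by_id(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)

    def subset(self, ids: Iterable[str]) -> "GenotypeDataset":
        wanted = set(ids)
        return GenotypeDataset(
            loci=self.loci,
            individuals=[i for i in self.individuals if i.id in wanted],
            provenance=self.provenance,
        )

    def species_of(self, species: str) -> list[Individual]:
        return [i for i in self.individuals if i.species == species]

    def allele_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(alleles, missing)``: float array (n, k, 2) with NaN at
        missing loci, and the boolean missing mask (n, k)."""
        n, k = len(self), self.n_loci
        alleles = np.full((n, k, 2), np.nan)
        for i, ind in enumerate(self.individuals):
            for j, g in enumerate(ind.genotype):
                if not g.missing:
                    alleles[i, j, 0] = g.allele_1
                    alleles[i, j, 1] = g.allele_2
        missing = np.isnan(alleles[:, :, 0])
        return alleles, missing


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_META_COLS = ["id", "species", "location", "region", "hybrid_class"]


def read_csv_genotypes(path: str | Path) -> GenotypeDataset:
    """Read the documented CSV dialect into a validated dataset."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    for col in ("id", "species", "location", "region"):
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} absent")
    allele_cols = [c for c in df.columns if c not in _META_COLS]
    if len(allele_cols) % 2 != 0:
        raise SchemaError(
            f"{path}: odd number of allele columns ({len(allele_cols)}); "
            "each locus needs <locus>_1 and <locus>_2"
        )
    loci: list[str] = []
    for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
        m1, m2 = re.fullmatch(r"(.+)_1", c1), re.fullmatch(r"(.+)_2", c2)
        if not (m1 and m2 and m1.group(1) == m2.group(1)):
            raise SchemaError(f"{path}: allele columns {c1!r}, {c2!r} are not a locus pair")
        loci.append(m1.group(1))

    individuals: list[Individual] = []
    for row_idx, row in df.iterrows():
        genotype = []
        for locus in loci:
            a1, a2 = row[f"{locus}_1"].strip(), row[f"{locus}_2"].strip()
            if a1 == "" and a2 == "":
                genotype.append(MISSING)
            elif a1 == "" or a2 == "":
                raise ValidationError(
                    f"{path}: individual {row['id']!r}, locus {locus!r}: "
                    "exactly one empty allele cell (ploidy violation)"
                )
            else:
                genotype.append(LocusGenotype(int(a1), int(a2)))
        hyb = row.get("hybrid_class", "")
        individuals.append(
            Individual(
                id=row["id"],
                species=row["species"],
                location=row["location"],
                region=row["region"],
                genotype=tuple(genotype),
                hybrid_class=(hyb or None) if isinstance(hyb, str) else None,
            )
        )
    return GenotypeDataset(loci=tuple(loci), individuals=individuals, provenance=str(path))


def _write_csv(dataset: GenotypeDataset, path: Path) -> None:
    header = _META_COLS + [f"{loc}_{i}" for loc in dataset.loci for i in (1, 2)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for ind in dataset.individuals:
            row = [ind.id, ind.species, ind.location, ind.region, ind.hybrid_class or ""]
            for g in ind.genotype:
                row.extend(["", ""] if g.missing else [g.allele_1, g.allele_2])
            writer.writerow(row)


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------


def _parse_genepop_allele(code: str, width: int, line_no: int) -> int | None:
    val = int(code)
    if val == 0:
        return None
    return val


def read_genepop(
    path: str | Path,
    metadata: str | Path | pd.DataFrame | None = None,
    species_rule: Callable[[str], str] | None = None,
    allele_offset: dict[str, int] | int = 0,
) -> GenotypeDataset:
    """Read a GenePop 4.x file (2- or 3-digit allele coding).

    Allele codes are taken as allele lengths in nucleotides; ``allele_offset``
    (scalar or per-locus) is added when codes are repeat counts or truncated
    lengths.  ``"00"``/``"000"`` codes map to missing.  POP blocks become
    location labels (``pop1``, ``pop2``, ... unless the sidecar provides a
    ``location`` column).  Species come from the sidecar ``metadata`` table
    or from ``species_rule(id)``; a sidecar at ``<path>.meta.csv`` is picked
    up automatically.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file", line=1)
    provenance = lines[0].strip()

    loci: list[str] = []
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if line.upper() == "POP":
            break
        if not line:
            raise ParseError(f"{path}: blank line in locus block", line=i + 1)
        # locus names may be one per line or comma-separated
        loci.extend(name.strip() for name in line.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no POP delimiter found", line=len(lines))
    if not loci:
        raise ParseError(f"{path}: no locus names before first POP", line=2)

    if isinstance(allele_offset, int):
        offsets = {loc: allele_offset for loc in loci}
    else:
        offsets = {loc: allele_offset.get(loc, 0) for loc in loci}

    rows: list[tuple[str, str, list[LocusGenotype]]] = []  # (id, pop_label, genotype)
    pop_idx = 0
    for j in range(i, len(lines)):
        line = lines[j].strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_idx += 1
            continue
        if pop_idx == 0:
            raise ParseError(f"{path}: individual line before first POP", line=j + 1)
        if "," not in line:
            raise ParseError(f"{path}: individual line lacks ',' separator", line=j + 1)
        name, _, geno_part = line.partition(",")
        name = name.strip()
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise ValidationError(
                f"{path} line {j + 1}: individual {name!r} has {len(codes)} "
                f"loci, header declares {len(loci)}"
            )
        genotype = []
        for locus, code in zip(loci, codes):
            if len(code) not in (4, 6) or not code.isdigit():
                raise ParseError(
                    f"{path}: bad allele code {code!r} for locus {locus!r}", line=j + 1
                )
            w = len(code) // 2
            a1 = _parse_genepop_allele(code[:w], w, j + 1)
            a2 = _parse_genepop_allele(code[w:], w, j + 1)
            if (a1 is None) or (a2 is None):
                genotype.append(MISSING)
            else:
                off = offsets[locus]
                genotype.append(LocusGenotype(a1 + off, a2 + off))
        rows.append((name, f"pop{pop_idx}", genotype))

    meta = _load_metadata(path, metadata)
    individuals = []
    for name, pop_label, genotype in rows:
        species, location, region, hybrid_class = None, pop_label, "", None
        if meta is not None and name in meta.index:
            rec = meta.loc[name]
            species = rec.get("species") or None
            location = rec.get("location") or pop_label
            region = rec.get("region") or ""
            hybrid_class = rec.get("hybrid_class") or None
        if species is None and species_rule is not None:
            species = species_rule(name)
        if species is None:
            raise ValidationError(
                f"{path}: no species for individual {name!r}; provide a "
                "metadata sidecar or a species_rule"
            )
        individuals.append(
            Individual(name, species, location, region, tuple(genotype), hybrid_class)
        )
    return GenotypeDataset(tuple(loci), individuals, provenance=provenance)


def _load_metadata(
    genepop_path: Path, metadata: str | Path | pd.DataFrame | None
) -> pd.DataFrame | None:
    if metadata is None:
        sidecar = genepop_path.with_name(genepop_path.name + ".meta.csv")
        if not sidecar.exists():
            return None
        metadata = sidecar
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, dtype=str, keep_default_na=False)
    if "id" not in metadata.columns or "species" not in metadata.columns:
        raise SchemaError("metadata sidecar needs at least columns id,species")
    return metadata.set_index("id")


def _write_genepop(dataset: GenotypeDataset, path: Path) -> None:
    max_len = max(
        (g.allele_2 for ind in dataset.individuals for g in ind.genotype if not g.missing),
        default=0,
    )
    if max_len > 999:
        raise ValidationError(
            f"allele length {max_len} exceeds GenePop 3-digit coding"
        )
    lines = [dataset.provenance or "hybnet genotype export"]
    lines.extend(dataset.loci)
    # one POP block per location, in first-appearance order
    locations: list[str] = []
    for ind in dataset.individuals:
        if ind.location not in locations:
            locations.append(ind.location)
    for loc in locations:
        lines.append("POP")
        for ind in dataset.individuals:
            if ind.location != loc:
                continue
            codes = []
            for g in ind.genotype:
                if g.missing:
                    codes.append("000000")
                else:
                    codes.append(f"{g.allele_1:03d}{g.allele_2:03d}")
            lines.append(f"{ind.id}, " + " ".join(codes))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    # GenePop has no species field; metadata travels in a sidecar
    meta_path = path.with_name(path.name + ".meta.csv")
    with open(meta_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "species", "location", "region", "hybrid_class"])
        for ind in dataset.individuals:
            writer.writerow(
                [ind.id, ind.species, ind.location, ind.region, ind.hybrid_class or ""]
            )


def write_dataset(
    dataset: GenotypeDataset, path: str | Path, format: str = "csv"
) -> None:
    """Write ``dataset`` to ``path``; ``format`` is ``"csv"`` or ``"genepop"``.

    Round-trip guarantee: reading the written file(s) back reproduces the
    dataset field-by-field (GenePop writes a ``<path>.meta.csv`` sidecar for
    the metadata the format cannot carry).
    """
    path = Path(path)
    if format == "csv":
        _write_csv(dataset, path)
    elif format == "genepop":
        _write_genepop(dataset, path)
    else:
        raise ValidationError(f"unknown format {format!r}")
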