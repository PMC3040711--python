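"""Inter-individual genetic distances and the genetic diversity spectrum.

Two metrics are implemented, carrying signal from different time scales:

* **Rozenfeld distance (RD)** — the Goldstein-type allele-length distance
  adapted to individuals.  At each locus the dissimilarity is the minimal
  pairing of the two diploid allele sets,

      d_i(A, B) = min(|A_i - B_i| + |a_i - b_i|, |A_i - b_i| + |a_i - B_i|),

  and RD is the mean of d_i over loci.  Because allele lengths evolve by
  stepwise mutation, RD accumulates divergence and retains phylogenetic
  signal.

* **Shared-allele distance (SAD)** — one minus the proportion of alleles
  shared identical-in-state, P_SA = (1/2n_u) Σ_u S, where S counts shared
  alleles per locus by min-count (multiset) matching and n_u is the number
  of loci compared.  SAD sees only allele identity, hence recent gene flow.

Missing data policy (both metrics): a locus missing in either individual is
excluded from numerator and denominator (pairwise deletion); a pair with no
jointly typed locus has no defined distance and raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DistanceUndefinedError, MissingGenotypeError, ValidationError
from .genotype_io import GenotypeDataset, Individual, LocusGenotype

RD = "RD"
SAD = "SAD"
METRICS = (RD, SAD)


def _check_metric(metric: str) -> str:
    metric = metric.upper()
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return metric


def locus_dissimilarity(g_a: LocusGenotype, g_b: LocusGenotype) -> int:
    """Minimal-pairing allele-length dissimilarity d_i at one locus."""
    if g_a.missing or g_b.missing:
        raise MissingGenotypeError("locus_dissimilarity needs two non-missing genotypes")
    a1, a2 = g_a.alleles
    b1, b2 = g_b.alleles
    return min(abs(a1 - b1) + abs(a2 - b2), abs(a1 - b2) + abs(a2 - b1))


def _shared_alleles(g_a: LocusGenotype, g_b: LocusGenotype) -> int:
    """Shared-allele count S in {0, 1, 2} by min-count multiset matching."""
    a1, a2 = g_a.alleles
    b1, b2 = g_b.alleles
    # for 2-allele multisets the best pairing realizes the min-count match
    return max((a1 == b1) + (a2 == b2), (a1 == b2) + (a2 == b1))


def _comparable(a: Individual, b: Individual) -> list[int]:
    return [
        i
        for i, (ga, gb) in enumerate(zip(a.genotype, b.genotype))
        if not (ga.missing or gb.missing)
    ]


def rozenfeld_distance(a: Individual, b: Individual) -> float:
    """RD between two individuals: mean of d_i over jointly typed loci."""
    loci = _comparable(a, b)
    if not loci:
        raise DistanceUndefinedError(
            f"no comparable locus between {a.id!r} and {b.id!r}"
        )
    return sum(locus_dissimilarity(a.genotype[i], b.genotype[i]) for i in loci) / len(loci)


def shared_allele_distance(a: Individual, b: Individual) -> float:
    """SAD = 1 - P_SA between two individuals, in [0, 1]."""
    loci = _comparable(a, b)
    if not loci:
        raise DistanceUndefinedError(
            f"no comparable locus between {a.id!r} and {b.id!r}"
        )
    s_total = sum(_shared_alleles(a.genotype[i], b.genotype[i]) for i in loci)
    return 1.0 - s_total / (2 * len(loci))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix under one metric.

    ``node_meta`` carries per-individual attributes (species, location,
    region, hybrid_class) so downstream network construction can annotate
    nodes without re-reading the dataset.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    metric: str
    node_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, rtol=0, atol=0):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix must have zero diagonal")
        if np.any(self.values < 0):
            raise ValidationError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def offdiag_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        """Square TSV with an id header row/column."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write(f"# metric={self.metric}\n")
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, ind_id in enumerate(self.ids):
                fh.write(
                    ind_id + "\t" + "\t".join(repr(float(v)) for v in self.values[i]) + "\n"
                )

    def to_long_tsv(self, path: str | Path, header: str | None = None) -> None:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("id_a\tid_b\tdistance\n")
            n = len(self.ids)
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{float(self.values[i, j])!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        path = Path(path)
        metric = "RD"
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        body = []
        for ln in lines:
            if ln.startswith("#"):
                if "metric=" in ln:
                    metric = ln.split("metric=")[1].strip()
                continue
            body.append(ln)
        ids = tuple(body[0].split("\t")[1:])
        values = np.array(
            [[float(v) for v in ln.split("\t")[1:]] for ln in body[1:]], dtype=float
        )
        return cls(ids=ids, values=values, metric=metric)


def pairwise_matrix(dataset: GenotypeDataset, metric: str) -> DistanceMatrix:
    """All-pairs RD or SAD over a dataset, vectorized per locus.

    Raises :class:`DistanceUndefinedError` listing every pair with zero
    jointly typed loci.
    """
    metric = _check_metric(metric)
    n = len(dataset)
    if n < 2:
        raise ValidationError("pairwise_matrix needs at least 2 individuals")
    alleles, missing = dataset.allele_arrays()
    ok = ~missing  # (n, k)
    num = np.zeros((n, n))
    n_u = np.zeros((n, n), dtype=int)
    for j in range(dataset.n_loci):
        both = np.outer(ok[:, j], ok[:, j])
        a1 = alleles[:, j, 0]
        a2 = alleles[:, j, 1]
        with np.errstate(invalid="ignore"):
            if metric == RD:
                d_same = np.abs(a1[:, None] - a1[None, :]) + np.abs(a2[:, None] - a2[None, :])
                d_cross = np.abs(a1[:, None] - a2[None, :]) + np.abs(a2[:, None] - a1[None, :])
                contrib = np.minimum(d_same, d_cross)
            else:
                s_same = (a1[:, None] == a1[None, :]).astype(int) + (
                    a2[:, None] == a2[None, :]
                ).astype(int)
                s_cross = (a1[:, None] == a2[None, :]).astype(int) + (
                    a2[:, None] == a1[None, :]
                ).astype(int)
                contrib = np.maximum(s_same, s_cross).astype(float)
        contrib = np.where(both, contrib, 0.0)
        num += contrib
        n_u += both

    undefined = (n_u == 0) & ~np.eye(n, dtype=bool)
    if np.any(undefined):
        ii, jj = np.nonzero(np.triu(undefined, k=1))
        pairs = [(dataset.ids[i], dataset.ids[j]) for i, j in zip(ii, jj)]
        raise DistanceUndefinedError(
            f"no comparable locus for {len(pairs)} pair(s): {pairs[:10]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        if metric == RD:
            values = num / n_u
        else:
            values = 1.0 - num / (2.0 * n_u)
    np.fill_diagonal(values, 0.0)
    values = np.where(np.eye(n, dtype=bool), 0.0, values)
    # numerical guard: SAD of identical genotypes is exactly 0
    if metric == SAD:
        values = np.clip(values, 0.0, 1.0)
    meta = {
        ind.id: {
            "species": ind.species,
            "location": ind.location,
            "region": ind.region,
            "hybrid_class": ind.hybrid_class or "",
        }
        for ind in dataset.individuals
    }
    return DistanceMatrix(ids=tuple(dataset.ids), values=values, metric=metric, node_meta=meta)


# ---------------------------------------------------------------------------
# Genetic diversity spectrum
# ---------------------------------------------------------------------------


@dataclass
class GDSpectrum:
    """Frequency distribution of within-group pairwise distances."""

    metric: str
    grouping: str
    bin_edges: np.ndarray
    frequencies: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        centers = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        for group, freqs in self.frequencies.items():
            for lo, c, f in zip(self.bin_edges[:-1], centers, freqs):
                rows.append(
                    {"group": group, "bin_left": lo, "bin_center": c, "frequency": f}
                )
        return pd.DataFrame(rows)


GROUPINGS = ("per_species", "per_location", "all")


def genetic_diversity_spectrum(
    dataset: GenotypeDataset,
    metric: str,
    grouping: str = "per_species",
    bin_width: float | None = None,
) -> GDSpectrum:
    """Histogram of all within-group pairwise distances, normalized per group.

    Default binning follows the discrete support of each metric: width 1
    (integer bins) for RD, width 1/(2k) for SAD.  Groups of size 1 are
    skipped with a warning.
    """
    metric = _check_metric(metric)
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}; expected {GROUPINGS}")
    if bin_width is None:
        bin_width = 1.0 if metric == RD else 1.0 / (2 * dataset.n_loci)

    def group_key(ind: Individual) -> str:
        if grouping == "per_species":
            return ind.species
        if grouping == "per_location":
            return ind.location
        return "all"

    groups: dict[str, list[str]] = {}
    for ind in dataset.individuals:
        groups.setdefault(group_key(ind), []).append(ind.id)

    dists: dict[str, np.ndarray] = {}
    max_d = 0.0
    for name, ids in list(groups.items()):
        if len(ids) < 2:
            warnings.warn(f"GDS: group {name!r} has a single individual; skipped")
            continue
        sub = pairwise_matrix(dataset.subset(ids), metric)
        vals = sub.offdiag_values()
        dists[name] = vals
        max_d = max(max_d, float(vals.max()))

    if not dists:
        raise ValidationError("no group with >= 2 individuals")
    upper = 1.0 if metric == SAD else max_d + bin_width
    n_bins = max(1, int(np.ceil(upper / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    freqs = {}
    for name, vals in dists.items():
        counts, _ = np.histogram(vals, bins=edges)
        # histogram's last bin is closed; values == upper edge land there
        freqs[name] = counts / counts.sum()
    return GDSpectrum(metric=metric, grouping=grouping, bin_edges=edges, frequencies=freqs)
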