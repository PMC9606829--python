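"""Core data model: genetic maps, genotype panels, and call-rate curation.

Genotype calls are unphased biallelic SNP states stored as a compact
``int8`` matrix (individuals x SNPs) with codes :data:`HOM_A`, :data:`HET`,
:data:`HOM_B` and :data:`MISSING`.  Map coordinates are chromosome-local
centiMorgan positions; no physical (bp) coordinates are used anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Genotype call codes (int8).
MISSING: int = -1
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2

#: TSV dialect spellings of the call codes.
CALL_TO_TEXT = {HOM_A: "AA", HET: "AB", HOM_B: "BB", MISSING: "--"}
TEXT_TO_CALL = {v: k for k, v in CALL_TO_TEXT.items()}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class GeneticMap:
    """An ordered SNP map: per-chromosome cM positions.

    Parameters
    ----------
    table:
        DataFrame with columns ``snp_id``, ``chrom``, ``pos_cM``.  Rows are
        sorted to (chrom, pos_cM, snp_id) lexicographic order on
        construction; within a chromosome positions must be non-decreasing
        (guaranteed by the sort) and SNP ids must be unique genome-wide.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"snp_id", "chrom", "pos_cM"}
        if not required.issubset(table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        tab = table.loc[:, ["snp_id", "chrom", "pos_cM"]].copy()
        tab["pos_cM"] = tab["pos_cM"].astype(float)
        tab["chrom"] = tab["chrom"].astype(str)
        tab["snp_id"] = tab["snp_id"].astype(str)
        tab = tab.sort_values(["chrom", "pos_cM", "snp_id"], kind="mergesort")
        tab = tab.reset_index(drop=True)
        if tab["snp_id"].duplicated().any():
            dups = tab.loc[tab["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate SNP id in map: {dups!r}")
        self.table = tab
        self.snp_ids: np.ndarray = tab["snp_id"].to_numpy()
        self.positions: np.ndarray = tab["pos_cM"].to_numpy()
        self.chrom_of: np.ndarray = tab["chrom"].to_numpy()
        self.chromosomes: list[str] = list(dict.fromkeys(self.chrom_of))
        self._slices: dict[str, slice] = {}
        start = 0
        for c in self.chromosomes:
            n = int((self.chrom_of == c).sum())
            self._slices[c] = slice(start, start + n)
            start += n
        self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}

    # -- basic queries -----------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions[self._slices[chrom]]

    def span(self, chrom: str) -> float:
        """cM span of a chromosome: last SNP position minus first."""
        p = self.chrom_positions(chrom)
        return float(p[-1] - p[0]) if len(p) else 0.0

    @property
    def total_cM(self) -> float:
        """Haploid map length: sum of per-chromosome spans."""
        return float(sum(self.span(c) for c in self.chromosomes))

    def index_of(self, snp_id: str) -> int:
        return self._snp_index[snp_id]

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """New map restricted to a boolean/integer SNP index selection."""
        return GeneticMap(self.table.iloc[keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self.table.equals(other.table)

    def __repr__(self) -> str:
        return (f"GeneticMap({len(self.chromosomes)} chromosomes, "
                f"{self.n_snps} SNPs, {self.total_cM:.1f} cM)")

    # -- constructors ------------------------------------------------------
    @classmethod
    def default(cls, n_chromosomes: int = 17, total_cM: float = 1280.0,
                n_snps: int = 2000) -> "GeneticMap":
        """Evenly spaced SNPs on equal-length chromosomes.

        The default emulates the apple consensus map used throughout:
        17 chromosomes summing to a 1280 cM haploid length.  SNPs are
        placed from 0 to the chromosome span inclusive, so per-chromosome
        spans (and hence ``total_cM``) are exact.
        """
        if n_snps < 2 * n_chromosomes:
            raise ValueError("need at least 2 SNPs per chromosome")
        span = total_cM / n_chromosomes
        base, extra = divmod(n_snps, n_chromosomes)
        rows = []
        for k in range(n_chromosomes):
            m = base + (1 if k < extra else 0)
            chrom = f"chr{k + 1:02d}"
            for i, p in enumerate(np.linspace(0.0, span, m)):
                rows.append((f"{chrom}_snp{i + 1:04d}", chrom, float(p)))
        return cls(pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_cM"]))


@dataclass
class GenotypePanel:
    """Individuals x SNPs genotype matrix plus metadata and a genetic map.

    ``metadata`` is indexed by individual id with columns
    ``recorded_species`` and ``reference_group`` (one of ``cultivar``,
    ``wild``, ``exotic``, ``unknown``).
    """

    gmap: GeneticMap
    metadata: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.metadata = self.metadata.copy()
        self.metadata.index = self.metadata.index.astype(str)
        if self.metadata.index.duplicated().any():
            raise ValueError("individual ids must be unique")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.metadata), self.gmap.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.metadata)} individuals x {self.gmap.n_snps} SNPs")
        self._row = {iid: i for i, iid in enumerate(self.metadata.index)}

    # -- queries -----------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def n_individuals(self) -> int:
        return len(self.metadata)

    def row(self, iid: str) -> int:
        if iid not in self._row:
            raise KeyError(f"unknown individual id {iid!r}")
        return self._row[iid]

    def genotypes(self, iid: str) -> np.ndarray:
        return self.calls[self.row(iid)]

    def group_ids(self, reference_group: str) -> list[str]:
        m = self.metadata["reference_group"] == reference_group
        return list(self.metadata.index[m])

    def snp_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0) if self.n_individuals else \
            np.ones(self.gmap.n_snps)

    def individual_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    # -- derivation --------------------------------------------------------
    def subset_individuals(self, ids: list[str]) -> "GenotypePanel":
        rows = [self.row(i) for i in ids]
        return GenotypePanel(self.gmap, self.metadata.loc[ids], self.calls[rows])

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(self.gmap.subset(keep), self.metadata,
                             self.calls[:, keep])

    def with_individual(self, iid: str, recorded_species: str,
                        reference_group: str, calls: np.ndarray) -> "GenotypePanel":
        meta = pd.concat([
            self.metadata,
            pd.DataFrame({"recorded_species": [recorded_species],
                          "reference_group": [reference_group]},
                         index=[iid])])
        return GenotypePanel(self.gmap, meta,
                             np.vstack([self.calls, np.asarray(calls, np.int8)]))

    def equals(self, other: "GenotypePanel") -> bool:
        return (self.gmap == other.gmap
                and self.metadata.equals(other.metadata)
                and np.array_equal(self.calls, other.calls))


def make_metadata(ids: list[str], recorded_species: list[str],
                  reference_group: list[str]) -> pd.DataFrame:
    return pd.DataFrame({"recorded_species": recorded_species,
                         "reference_group": reference_group},
                        index=pd.Index(ids, name="id"))


@dataclass(frozen=True)
class CurationConfig:
    """Call-rate curation thresholds (both fractions in [0, 1])."""

    min_snp_call_rate: float = 0.95
    min_individual_call_rate: float = 0.90

    def __post_init__(self) -> None:
        for v in (self.min_snp_call_rate, self.min_individual_call_rate):
            if not 0.0 <= v <= 1.0:
                raise ValueError("curation thresholds must lie in [0, 1]")


def curate(panel: GenotypePanel, config: CurationConfig = CurationConfig()
           ) -> GenotypePanel:
    """Drop low-call-rate SNPs, then low-call-rate individuals.

    SNP filtering is applied first so that an individual's call rate is
    judged on the retained SNP set.  Raises if no SNP survives.
    """
    keep_snps = panel.snp_call_rate() >= config.min_snp_call_rate
    n_snps_dropped = int((~keep_snps).sum())
    if not keep_snps.any():
        raise ValueError(
            f"curation removed all {panel.gmap.n_snps} SNPs at "
            f"min_snp_call_rate={config.min_snp_call_rate}")
    out = panel.subset_snps(np.flatnonzero(keep_snps)) if n_snps_dropped else panel
    keep_ind = out.individual_call_rate() >= config.min_individual_call_rate
    n_ind_dropped = int((~keep_ind).sum())
    if n_ind_dropped:
        out = out.subset_individuals([i for i, k in zip(out.ids, keep_ind) if k])
    log.info("curate: removed %d SNPs and %d individuals",
             n_snps_dropped, n_ind_dropped)
    return out
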