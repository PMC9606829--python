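"""SPLoSH: Summed Potential Lengths of Shared Haplotypes.

Two unphased genotypes *could* share a haplotype wherever they have no
opposing homozygotes (one individual ``AA`` while the other is ``BB``).
Maximal runs of such compatible SNPs are measured in cM from the first to
the last compatible SNP of the run; runs at least ``threshold_cM`` long
(and with at least ``min_snps_per_segment`` SNPs) are summed genome-wide.
The sum divided by twice the haploid map length is the fraction of the
diploid genome potentially shared: 256 cM on the default 1280 cM map is
10%, 512 cM is 20%.

A missing call can never contradict sharing, so MISSING is always
compatible (and still counts toward a run's SNP tally).  Optionally up to
``error_tolerance`` *isolated* opposing SNPs (both neighbours compatible)
are forgiven per run, a guard against undetected null alleles; the default
is 0, which keeps segmentation exactly equal to a brute-force maximal-run
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import HOM_A, HOM_B, GeneticMap, GenotypePanel


@dataclass(frozen=True)
class SploshConfig:
    threshold_cM: float = 20.0        # 20 for relationship work, 5 for ordination
    error_tolerance: int = 0          # isolated opposing SNPs forgiven per run
    min_snps_per_segment: int = 2

    def __post_init__(self) -> None:
        if self.threshold_cM < 0 or self.error_tolerance < 0:
            raise ValueError("threshold_cM and error_tolerance must be >= 0")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start_cM: float
    end_cM: float
    n_snps: int

    @property
    def span_cM(self) -> float:
        return self.end_cM - self.start_cM


@dataclass
class SegmentSet:
    pair: tuple[str, str]
    segments: list[Segment]
    threshold_cM: float

    @property
    def total_cM(self) -> float:
        return float(sum(s.span_cM for s in self.segments))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.chrom, round(s.start_cM, 2), round(s.end_cM, 2), s.n_snps,
              self.pair[0], self.pair[1]) for s in self.segments],
            columns=["chrom", "start_cM", "end_cM", "n_snps", "id_i", "id_j"])


def opposing_homozygote_mask(calls_i: np.ndarray, calls_j: np.ndarray
                             ) -> np.ndarray:
    """True exactly where one call is HOM_A and the other HOM_B."""
    calls_i = np.asarray(calls_i)
    calls_j = np.asarray(calls_j)
    if calls_i.shape != calls_j.shape:
        raise ValueError("genotype vectors differ in length")
    return (((calls_i == HOM_A) & (calls_j == HOM_B))
            | ((calls_i == HOM_B) & (calls_j == HOM_A)))


def _compatible_runs(opposing: np.ndarray, tolerance: int
                     ) -> list[tuple[int, int]]:
    """Maximal compatible runs as inclusive (start, end) index pairs.

    With ``tolerance`` 0 these are simply the stretches between opposing
    SNPs.  With tolerance t, a run may absorb up to t isolated opposing
    SNPs (an opposing SNP whose immediate neighbours are both compatible);
    runs always start and end on compatible SNPs.
    """
    n = opposing.size
    if tolerance == 0:
        idx = np.flatnonzero(opposing)
        bounds = np.concatenate(([-1], idx, [n]))
        return [(int(bounds[k]) + 1, int(bounds[k + 1]) - 1)
                for k in range(bounds.size - 1)
                if bounds[k + 1] - bounds[k] > 1]
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if opposing[i]:
            i += 1
            continue
        start = i
        last_compat = i
        forgiven = 0
        j = i + 1
        while j < n:
            if not opposing[j]:
                last_compat = j
                j += 1
                continue
            isolated = (not opposing[j - 1]) and (j + 1 >= n or not opposing[j + 1])
            if forgiven < tolerance and isolated:
                forgiven += 1
                j += 1
                continue
            break
        runs.append((start, last_compat))
        i = j + 1
    return runs


def segments_from_mask(incompatible: np.ndarray, gmap: GeneticMap,
                       config: SploshConfig) -> list[Segment]:
    """Chromosome-wise segmentation of a genome-wide incompatibility mask."""
    out: list[Segment] = []
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        pos = gmap.positions[sl]
        for i0, i1 in _compatible_runs(incompatible[sl], config.error_tolerance):
            span = pos[i1] - pos[i0]
            n_snps = i1 - i0 + 1
            if span >= config.threshold_cM and n_snps >= config.min_snps_per_segment:
                out.append(Segment(chrom, float(pos[i0]), float(pos[i1]), n_snps))
    return out


def shared_segments(panel: GenotypePanel, id_i: str, id_j: str,
                    config: SploshConfig = SploshConfig()) -> SegmentSet:
    """Retained compatible segments between a pair of individuals."""
    mask = opposing_homozygote_mask(panel.genotypes(id_i), panel.genotypes(id_j))
    return SegmentSet((id_i, id_j), segments_from_mask(mask, panel.gmap, config),
                      config.threshold_cM)


def splosh(panel: GenotypePanel, id_i: str, id_j: str,
           config: SploshConfig = SploshConfig()) -> float:
    """Genome-wide SPLoSH sum in cM for one pair."""
    return shared_segments(panel, id_i, id_j, config).total_cM


def genome_fraction(splosh_cM: float, gmap: GeneticMap) -> float:
    """Convert a SPLoSH sum to a fraction of the diploid genome."""
    if splosh_cM < 0:
        raise ValueError("splosh_cM must be non-negative")
    return splosh_cM / (2.0 * gmap.total_cM)


@dataclass
class SploshMatrix:
    """Symmetric all-pairs SPLoSH sums at one threshold.

    The diagonal holds each individual's SNP-covered map span (the
    self-sharing ceiling); downstream relationship rules never use it.
    """

    ids: list[str]
    values: np.ndarray
    threshold_cM: float
    gmap: GeneticMap
    _idx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._idx = {iid: i for i, iid in enumerate(self.ids)}

    def value(self, id_i: str, id_j: str) -> float:
        return float(self.values[self._idx[id_i], self._idx[id_j]])

    def row(self, iid: str) -> np.ndarray:
        return self.values[self._idx[iid]]

    def contains(self, iid: str) -> bool:
        return iid in self._idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def splosh_matrix(panel: GenotypePanel, config: SploshConfig = SploshConfig(),
                  subset: list[str] | None = None) -> SploshMatrix:
    """All-pairs SPLoSH; each unordered pair is computed once."""
    ids = subset if subset is not None else panel.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    gmap = panel.gmap
    rows = np.array([panel.row(i) for i in ids])
    calls = panel.calls[rows]
    n = len(ids)
    values = np.zeros((n, n))
    hom_a = calls == HOM_A
    hom_b = calls == HOM_B
    for i in range(n):
        for j in range(i + 1, n):
            mask = (hom_a[i] & hom_b[j]) | (hom_b[i] & hom_a[j])
            s = sum(seg.span_cM for seg in segments_from_mask(mask, gmap, config))
            values[i, j] = values[j, i] = s
    np.fill_diagonal(values, gmap.total_cM)
    return SploshMatrix(ids, values, config.threshold_cM, gmap)
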