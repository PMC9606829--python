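"""Relationship inference and parent imputation on unphased SNP panels.

The precedence chain is total and exclusive: duplicate > parent-offspring
> grandparent-level.  Duplicates are called on non-missing concordance,
parent-offspring on the opposing-homozygote (OH) rate, and likely
grandparent-grandchild (indistinguishable from half-sibs at this evidence
level) on the SPLoSH(20 cM) sum at 512 cM or more — i.e. at least 20% of
the diploid genome, just under the theoretical 25% for this relationship
so that segment-length attrition and meiotic variance do not exclude real
cases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import HET, HOM_A, HOM_B, MISSING, GenotypePanel
from .segments import (SploshConfig, SploshMatrix, genome_fraction,
                       opposing_homozygote_mask, segments_from_mask)

log = logging.getLogger(__name__)

DUPLICATE = "duplicate"
PARENT_OFFSPRING = "parent_offspring"
GRANDPARENT_LEVEL = "grandparent_level"

# Deduced-gamete allele codes.
GAMETE_A = 0
GAMETE_B = 1
GAMETE_AMBIGUOUS = 2
GAMETE_UNKNOWN = 3

UNRESOLVED = MISSING  # imputed-genotype code for an unresolved SNP


@dataclass(frozen=True)
class RelationshipConfig:
    duplicate_min_concordance: float = 0.995
    po_max_oh_rate: float = 0.005
    grandparent_min_splosh_cM: float = 512.0  # at the 20 cM segment threshold

    def __post_init__(self) -> None:
        if not 0.0 < self.duplicate_min_concordance <= 1.0:
            raise ValueError("duplicate_min_concordance must be in (0, 1]")
        if not 0.0 <= self.po_max_oh_rate < 1.0:
            raise ValueError("po_max_oh_rate must be in [0, 1)")
        if self.grandparent_min_splosh_cM < 0:
            raise ValueError("grandparent_min_splosh_cM must be >= 0")


@dataclass(frozen=True)
class RelationshipCall:
    pair: tuple[str, str]
    type: str
    concordance: float | None = None
    oh_rate: float | None = None
    splosh_cM: float | None = None
    genome_fraction: float | None = None


def pair_stats(panel: GenotypePanel, id_i: str, id_j: str
               ) -> tuple[float, float, int]:
    """(concordance, OH rate, co-called count) over co-called SNPs."""
    gi, gj = panel.genotypes(id_i), panel.genotypes(id_j)
    both = (gi != MISSING) & (gj != MISSING)
    n = int(both.sum())
    if n == 0:
        raise ValueError(f"no co-called SNPs for pair ({id_i}, {id_j})")
    conc = float((gi[both] == gj[both]).mean())
    oh = float(opposing_homozygote_mask(gi, gj)[both].mean())
    return conc, oh, n


def find_duplicates(panel: GenotypePanel,
                    config: RelationshipConfig = RelationshipConfig()
                    ) -> tuple[list[RelationshipCall], dict[str, str]]:
    """Duplicate pairs plus stable unique-genotype group codes.

    Groups are connected components over duplicate pairs (so A~B and B~C
    place all three in one group); codes are ``UG0001``... assigned in
    panel order, emulating collection-wide unique-genotype identifiers.
    """
    ids = panel.ids
    calls: list[RelationshipCall] = []
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            conc, oh, _ = pair_stats(panel, ids[i], ids[j])
            if conc >= config.duplicate_min_concordance:
                calls.append(RelationshipCall((ids[i], ids[j]), DUPLICATE,
                                              concordance=conc, oh_rate=oh))
                parent[find(ids[i])] = find(ids[j])
    codes: dict[str, str] = {}
    group_code: dict[str, str] = {}
    for iid in ids:
        root = find(iid)
        if root not in group_code:
            group_code[root] = f"UG{len(group_code) + 1:04d}"
        codes[iid] = group_code[root]
    return calls, codes


def find_parent_offspring(panel: GenotypePanel,
                          config: RelationshipConfig = RelationshipConfig(),
                          duplicate_pairs: set[frozenset[str]] | None = None
                          ) -> list[RelationshipCall]:
    """Unordered pairs with OH rate at or below the threshold.

    Direction (which one is the parent) is not asserted: the genotype
    evidence is symmetric and provenance must resolve it.  Pairs already
    called duplicates are excluded.
    """
    dup = duplicate_pairs or set()
    ids = panel.ids
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if frozenset((ids[i], ids[j])) in dup:
                continue
            conc, oh, _ = pair_stats(panel, ids[i], ids[j])
            if oh <= config.po_max_oh_rate:
                out.append(RelationshipCall((ids[i], ids[j]), PARENT_OFFSPRING,
                                            concordance=conc, oh_rate=oh))
    return out


def find_grandparent_level(splosh20: SploshMatrix, panel: GenotypePanel,
                           config: RelationshipConfig = RelationshipConfig(),
                           exclusions: set[frozenset[str]] | None = None
                           ) -> list[RelationshipCall]:
    """Pairs with SPLoSH(20 cM) >= 512 cM, minus duplicate/PO pairs.

    These are *likely* grandparent-grandchild; half-sib and comparable
    second-degree relationships can produce the same signal, which is why
    the type is reported as ``grandparent_level``.
    """
    excl = exclusions or set()
    ids = splosh20.ids
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if frozenset((ids[i], ids[j])) in excl:
                continue
            s = splosh20.value(ids[i], ids[j])
            if s >= config.grandparent_min_splosh_cM:
                out.append(RelationshipCall(
                    (ids[i], ids[j]), GRANDPARENT_LEVEL, splosh_cM=s,
                    genome_fraction=genome_fraction(s, panel.gmap)))
    return out


def relate(panel: GenotypePanel, splosh20: SploshMatrix,
           config: RelationshipConfig = RelationshipConfig()
           ) -> tuple[list[RelationshipCall], dict[str, str]]:
    """Full precedence-ordered relationship inference for a panel."""
    dups, codes = find_duplicates(panel, config)
    dup_pairs = {frozenset(c.pair) for c in dups}
    po = find_parent_offspring(panel, config, dup_pairs)
    excl = dup_pairs | {frozenset(c.pair) for c in po}
    gp = find_grandparent_level(splosh20, panel, config, excl)
    return dups + po + gp, codes


def relationships_frame(calls: list[RelationshipCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.pair[0], c.pair[1], c.type, c.concordance, c.oh_rate,
          c.splosh_cM, c.genome_fraction) for c in calls],
        columns=["id_i", "id_j", "type", "concordance", "oh_rate",
                 "splosh_cM", "genome_fraction"])


# ---------------------------------------------------------------------------
# deduced gametes and the hidden-parent scan
# ---------------------------------------------------------------------------

@dataclass
class DeducedGamete:
    """The haplotype an offspring received from its *unknown* parent.

    Per SNP: the transmitted allele where it is determined by the
    offspring/known-parent pair, AMBIGUOUS where both are heterozygous,
    UNKNOWN where either call is missing or the pair shows an opposing
    homozygote (counted in ``n_conflicts`` — possible null or error).
    """

    offspring: str
    known_parent: str
    alleles: np.ndarray
    n_conflicts: int

    @property
    def informative_fraction(self) -> float:
        return float(np.isin(self.alleles, [GAMETE_A, GAMETE_B]).mean())


def deduce_gamete(offspring: str, known_parent: str, panel: GenotypePanel
                  ) -> DeducedGamete:
    off = panel.genotypes(offspring)
    par = panel.genotypes(known_parent)
    out = np.full(panel.gmap.n_snps, GAMETE_UNKNOWN, dtype=np.int8)
    out[off == HOM_A] = GAMETE_A
    out[off == HOM_B] = GAMETE_B
    het = off == HET
    out[het & (par == HOM_A)] = GAMETE_B
    out[het & (par == HOM_B)] = GAMETE_A
    out[het & (par == HET)] = GAMETE_AMBIGUOUS
    out[(off == MISSING) | (par == MISSING)] = GAMETE_UNKNOWN
    conflicts = opposing_homozygote_mask(off, par)
    out[conflicts] = GAMETE_UNKNOWN
    return DeducedGamete(offspring, known_parent, out, int(conflicts.sum()))


def scan_gamete(gamete: DeducedGamete, panel: GenotypePanel,
                config: SploshConfig = SploshConfig(),
                candidates: list[str] | None = None
                ) -> tuple[pd.DataFrame, bool]:
    """Rank candidates by summed cM of gamete-compatible segments.

    A candidate is incompatible at a SNP where the deduced allele is X and
    the candidate is homozygous for the other allele; AMBIGUOUS/UNKNOWN
    positions can never contradict.  Returns the ranked table and an
    uninformative flag (no determined allele anywhere: every candidate
    saturates).
    """
    cand = [c for c in (candidates if candidates is not None else panel.ids)
            if c != gamete.offspring and c != gamete.known_parent]
    uninformative = not np.isin(gamete.alleles, [GAMETE_A, GAMETE_B]).any()
    rows = []
    for cid in cand:
        g = panel.genotypes(cid)
        incompat = ((gamete.alleles == GAMETE_A) & (g == HOM_B)) | \
                   ((gamete.alleles == GAMETE_B) & (g == HOM_A))
        s = sum(seg.span_cM
                for seg in segments_from_mask(incompat, panel.gmap, config))
        rows.append((cid, s))
    table = pd.DataFrame(rows, columns=["candidate", "compatible_cM"])
    table = table.sort_values(["compatible_cM", "candidate"],
                              ascending=[False, True]).reset_index(drop=True)
    return table, uninformative


def unilateral_allele_sharing(id_a: str, id_b: str, panel: GenotypePanel
                              ) -> float:
    """Fraction of co-called SNPs where the pair shares at least one allele.

    Equals 1 minus the opposing-homozygote rate; 1.0 is the signature of a
    parent-offspring link and, notably, of a triploid sharing a gamete
    contributor (screened through its diploid-coded calls).
    """
    _, oh, _ = pair_stats(panel, id_a, id_b)
    return 1.0 - oh


# ---------------------------------------------------------------------------
# ungenotyped-parent imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputedParent:
    id: str
    genotypes: np.ndarray          # call codes, UNRESOLVED where undecided
    imputed_fraction: float
    n_offspring_used: int
    excluded_offspring: list[str] = field(default_factory=list)


def impute_parent(parent_id: str,
                  offspring_with_known_parent: list[tuple[str, str]],
                  panel: GenotypePanel, min_support: int = 2,
                  config: RelationshipConfig = RelationshipConfig()
                  ) -> ImputedParent:
    """Impute an ungenotyped parent from its offspring.

    Each offspring contributes, per SNP, the allele it must have received
    from the missing parent (deduced against its genotyped other parent).
    Pooling over offspring: both alleles observed -> HET; a single allele
    observed with at least ``min_support`` unambiguous observations ->
    homozygous; otherwise UNRESOLVED.  ``imputed_fraction`` is the share
    of the 2 x n_SNPs allele slots resolved (HET and HOM both resolve two
    slots).  Offspring failing the parent-offspring test against their
    recorded known parent are excluded with a warning.
    """
    if len(offspring_with_known_parent) < 2:
        raise ValueError("need at least 2 offspring for imputation")
    n = panel.gmap.n_snps
    count_a = np.zeros(n, dtype=np.int32)
    count_b = np.zeros(n, dtype=np.int32)
    used = 0
    excluded: list[str] = []
    for off, known in offspring_with_known_parent:
        _, oh, _ = pair_stats(panel, off, known)
        if oh > config.po_max_oh_rate:
            warnings.warn(f"offspring {off!r} fails the parent-offspring test "
                          f"against {known!r} (OH rate {oh:.4f}); excluded")
            excluded.append(off)
            continue
        gam = deduce_gamete(off, known, panel)
        count_a += gam.alleles == GAMETE_A
        count_b += gam.alleles == GAMETE_B
        used += 1
    geno = np.full(n, UNRESOLVED, dtype=np.int8)
    geno[(count_a > 0) & (count_b > 0)] = HET
    geno[(count_a >= min_support) & (count_b == 0)] = HOM_A
    geno[(count_b >= min_support) & (count_a == 0)] = HOM_B
    imputed_fraction = float((geno != UNRESOLVED).mean())
    return ImputedParent(parent_id, geno, imputed_fraction, used, excluded)


# ---------------------------------------------------------------------------
# null-allele SNP flagging
# ---------------------------------------------------------------------------

def detect_null_snps(individual: str, confirmed_po_partners: list[str],
                     panel: GenotypePanel, min_partners: int = 2
                     ) -> set[str]:
    """SNPs where an individual looks null-homozygous.

    A SNP opposing-homozygous against at least ``min_partners`` distinct
    *confirmed* first-degree partners cannot be a single genotyping error
    and is flagged as a candidate null in the individual.  With fewer than
    ``min_partners`` partners available the result is empty (warned).
    """
    if len(confirmed_po_partners) < min_partners:
        warnings.warn(f"{individual!r}: only {len(confirmed_po_partners)} "
                      f"confirmed partners (< {min_partners}); cannot flag "
                      "null SNPs")
        return set()
    g = panel.genotypes(individual)
    hits = np.zeros(panel.gmap.n_snps, dtype=np.int32)
    for p in confirmed_po_partners:
        hits += opposing_homozygote_mask(g, panel.genotypes(p))
    return {str(s) for s in panel.gmap.snp_ids[hits >= min_partners]}
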